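"""Per-voxel vessel probability from non-contrast CT.

Desk-scale realization of multiscale patch-based feature learning: 3D
patches sampled inside the lung are whitened and clustered with spherical
k-means into a dictionary of unit-norm atoms; voxels are encoded with the
soft-threshold "triangle" activation of their whitened patch against the
atoms, at each downsampling scale; a logistic classifier trained on
labelled voxels maps the concatenated features to a vessel probability.
A classical multiscale Hessian tubularity filter is provided as an
alternative backend that needs no training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import hessian_matrix, hessian_matrix_eigvals

from .imgrid import BinaryMask, ValueKind, VolumeImage

__all__ = [
    "PatchDictionary",
    "VesselClassifier",
    "learn_dictionary",
    "encode",
    "encode_points",
    "train_classifier",
    "predict_probability",
    "hessian_vesselness",
    "save_model",
    "load_model",
]

_SD_GUARD = 1e-6


@dataclass
class PatchDictionary:
    """Unit-norm patch atoms with their whitening statistics.

    ``atoms`` has shape (K, p^3); ``whiten_mean``/``whiten_sd`` are the
    per-dimension z-score statistics of the training patches (shared by
    all scales).
    """

    atoms: np.ndarray
    patch_edge: int
    scales: tuple[int, ...]
    whiten_mean: np.ndarray
    whiten_sd: np.ndarray

    def __post_init__(self):
        self.atoms = np.asarray(self.atoms, dtype=float)
        norms = np.linalg.norm(self.atoms, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("dictionary atoms must have unit norm")
        if self.atoms.shape[0] < 2:
            raise ValueError("need at least 2 atoms")
        if self.patch_edge % 2 != 1:
            raise ValueError("patch_edge must be odd")

    @property
    def n_features(self) -> int:
        return self.atoms.shape[0] * len(self.scales)


@dataclass
class VesselClassifier:
    """Logistic model over dictionary features (standardized internally)."""

    weights: np.ndarray  # (n_features,)
    bias: float
    feat_mean: np.ndarray
    feat_sd: np.ndarray
    seed: int = 0
    n_samples: int = 0

    def __post_init__(self):
        if not np.isfinite(self.weights).all() or not np.isfinite(self.bias):
            raise ValueError("classifier weights must be finite")


def _downsample(data: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean downsampling (trailing partial blocks dropped)."""
    if factor == 1:
        return data
    s = [(dim // factor) * factor for dim in data.shape]
    d = data[: s[0], : s[1], : s[2]]
    return d.reshape(
        s[0] // factor, factor, s[1] // factor, factor, s[2] // factor, factor
    ).mean(axis=(1, 3, 5))


def _extract_patches(data: np.ndarray, centers: np.ndarray, p: int) -> np.ndarray:
    """Patches (n, p^3) around voxel centers, reflect-padded at the border."""
    half = p // 2
    padded = np.pad(data, half, mode="reflect")
    win = np.lib.stride_tricks.sliding_window_view(padded, (p, p, p))
    c = np.asarray(centers)
    return win[c[:, 0], c[:, 1], c[:, 2]].reshape(c.shape[0], p**3)


def learn_dictionary(
    ct_samples: list[VolumeImage],
    masks: list[BinaryMask],
    k: int = 32,
    patch_edge: int = 5,
    scales=(1, 2),
    seed: int = 0,
    n_patches: int = 20000,
) -> PatchDictionary:
    """Learn K unit-norm atoms by spherical k-means on whitened patches.

    Patches are sampled at in-mask voxels of every image at every scale,
    z-scored per dimension, then clustered for 10 iterations of cosine
    assignment + mean-and-renormalize updates.  Deterministic for a fixed
    seed.
    """
    rng = np.random.default_rng(seed)
    if patch_edge % 2 != 1:
        raise ValueError("patch_edge must be odd")
    all_patches = []
    per_image = max(n_patches // max(len(ct_samples) * len(scales), 1), 1)
    total_voxels = 0
    for ct, mask in zip(ct_samples, masks):
        coords = np.argwhere(mask.data)
        total_voxels += coords.shape[0]
        for sc in scales:
            data = _downsample(np.asarray(ct.data, dtype=float), sc)
            cs = coords // sc
            cs = cs[(cs < np.asarray(data.shape)).all(axis=1)]
            if cs.shape[0] == 0:
                continue
            pick = rng.choice(cs.shape[0], size=min(per_image, cs.shape[0]), replace=False)
            all_patches.append(_extract_patches(data, cs[pick], patch_edge))
    if total_voxels < 1000:
        raise ValueError(f"need at least 1000 in-mask voxels, got {total_voxels}")
    x = np.concatenate(all_patches, axis=0)
    if k > x.shape[0]:
        raise ValueError(f"K={k} exceeds the {x.shape[0]} sampled patches")
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd < _SD_GUARD] = 1.0
    xw = (x - mean) / sd
    norms = np.linalg.norm(xw, axis=1)
    xw = xw[norms > _SD_GUARD]
    xn = xw / np.linalg.norm(xw, axis=1, keepdims=True)
    atoms = xn[rng.choice(xn.shape[0], size=k, replace=False)]
    for _ in range(10):
        sim = xn @ atoms.T
        assign = np.argmax(sim, axis=1)
        for a in range(k):
            members = xn[assign == a]
            if members.shape[0] == 0:
                continue  # keep the old atom for empty clusters
            m = members.mean(axis=0)
            nrm = np.linalg.norm(m)
            if nrm > _SD_GUARD:
                atoms[a] = m / nrm
    atoms = atoms / np.linalg.norm(atoms, axis=1, keepdims=True)
    return PatchDictionary(
        atoms=atoms,
        patch_edge=patch_edge,
        scales=tuple(scales),
        whiten_mean=mean,
        whiten_sd=sd,
    )


def _triangle_encode(patches: np.ndarray, dic: PatchDictionary) -> np.ndarray:
    """Soft-threshold triangle features: max(0, a.x - mean_k(a.x)) per atom.

    Patches with near-zero variance map to the all-zero feature vector.
    """
    xw = (patches - dic.whiten_mean.astype(np.float32)) / dic.whiten_sd.astype(np.float32)
    live = patches.std(axis=1) >= _SD_GUARD
    sim = xw @ dic.atoms.T.astype(np.float32)
    feats = np.maximum(0.0, sim - sim.mean(axis=1, keepdims=True))
    feats[~live] = 0.0
    return feats


def encode_points(
    ct: VolumeImage, dic: PatchDictionary, centers: np.ndarray, chunk: int = 65536
) -> np.ndarray:
    """Concatenated multi-scale triangle features at given voxel centers.

    Processed in chunks in single precision to bound memory at full-grid
    prediction.
    """
    data = np.asarray(ct.data, dtype=np.float32)
    parts = []
    for sc in dic.scales:
        d = _downsample(data, sc)
        cs = np.minimum(centers // sc, np.asarray(d.shape) - 1)
        out = np.empty((cs.shape[0], dic.atoms.shape[0]), dtype=np.float32)
        for lo in range(0, cs.shape[0], chunk):
            patches = _extract_patches(d, cs[lo : lo + chunk], dic.patch_edge)
            out[lo : lo + chunk] = _triangle_encode(patches, dic)
        parts.append(out)
    return np.concatenate(parts, axis=1)


def encode(ct: VolumeImage, dic: PatchDictionary, stride: int = 2):
    """Feature grid at a regular stride; returns (features, stride_grid_shape).

    ``features`` is (n_grid_points, K * n_scales) in raster order of the
    stride grid.  Features are non-negative by construction.
    """
    shape = ct.shape
    gx = np.arange(0, shape[0], stride)
    gy = np.arange(0, shape[1], stride)
    gz = np.arange(0, shape[2], stride)
    centers = np.stack(np.meshgrid(gx, gy, gz, indexing="ij"), axis=-1).reshape(-1, 3)
    feats = encode_points(ct, dic, centers)
    return feats, (len(gx), len(gy), len(gz))


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def train_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    epochs: int = 200,
    step: float = 0.1,
    l2: float = 1e-4,
) -> VesselClassifier:
    """Fit the logistic vessel/non-vessel model by full-batch gradient descent.

    Features are standardized internally (statistics stored on the model).
    200 epochs at step 0.1 with L2 1e-4; deterministic for a fixed seed.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    fm = x.mean(axis=0)
    fs = x.std(axis=0)
    fs[fs < _SD_GUARD] = 1.0
    xs = (x - fm) / fs
    rng = np.random.default_rng(seed)
    w = rng.normal(scale=0.01, size=x.shape[1])
    b = 0.0
    n = x.shape[0]
    for _ in range(epochs):
        p = _sigmoid(xs @ w + b)
        err = p - y
        w -= step * (xs.T @ err / n + l2 * w)
        b -= step * float(err.mean())
    return VesselClassifier(
        weights=w, bias=b, feat_mean=fm, feat_sd=fs, seed=seed, n_samples=n
    )


def predict_probability(
    ct: VolumeImage, dic: PatchDictionary, clf: VesselClassifier, stride: int = 1
) -> VolumeImage:
    """Vessel probability map on the CT grid (stride grid upsampled NN)."""
    feats, grid_shape = encode(ct, dic, stride)
    if feats.shape[1] != clf.weights.shape[0]:
        raise ValueError(
            f"classifier expects {clf.weights.shape[0]} features, encoder produced {feats.shape[1]}"
        )
    xs = (feats - clf.feat_mean) / clf.feat_sd
    p = _sigmoid(xs @ clf.weights + clf.bias).reshape(grid_shape)
    up = np.repeat(np.repeat(np.repeat(p, stride, 0), stride, 1), stride, 2)
    up = up[: ct.shape[0], : ct.shape[1], : ct.shape[2]]
    return ct.like(np.clip(up, 0.0, 1.0), ValueKind.PROBABILITY)


def hessian_vesselness(ct: VolumeImage, scales_mm=(1.0, 2.0, 3.0)) -> VolumeImage:
    """Multiscale Hessian tubularity for bright tubes, rescaled to [0, 1].

    At each Gaussian scale the Hessian eigenvalues |l1| <= |l2| <= |l3|
    yield a Frangi-style response that is large where l2 and l3 are both
    strongly negative (bright tube cross-section) and l1 is small (axis);
    the response is maximized over scales and divided by its maximum.
    """
    scales_mm = tuple(scales_mm)
    if len(scales_mm) == 0:
        raise ValueError("need at least one scale")
    data = np.asarray(ct.data, dtype=float)
    mean_sp = float(np.mean(ct.spacing))
    best = np.zeros_like(data)
    for s_mm in scales_mm:
        sigma = max(s_mm / mean_sp, 0.5)
        h = hessian_matrix(data, sigma=sigma, use_gaussian_derivatives=True)
        ev = hessian_matrix_eigvals(h)  # ascending: ev[0] <= ev[1] <= ev[2]
        order = np.argsort(np.abs(ev), axis=0)
        ev_sorted = np.take_along_axis(ev, order, axis=0)
        l1, l2, l3 = ev_sorted
        resp = np.zeros_like(data)
        tube = (l2 < 0) & (l3 < 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ra = np.abs(l2) / np.abs(l3)
            rb = np.abs(l1) / np.sqrt(np.abs(l2 * l3))
        s2 = ev_sorted[0] ** 2 + ev_sorted[1] ** 2 + ev_sorted[2] ** 2
        s2max = np.percentile(np.sqrt(s2), 99.9) or 1.0
        frangi = (
            (1 - np.exp(-(ra**2) / 0.5))
            * np.exp(-(rb**2) / 0.5)
            * (1 - np.exp(-s2 / (2 * (0.5 * s2max) ** 2)))
        )
        resp[tube] = frangi[tube] * sigma**2  # gamma-normalized scale weight
        best = np.maximum(best, resp)
    mx = best.max()
    if mx > 0:
        best /= mx
    return ct.like(best, ValueKind.PROBABILITY)


# ---------------------------------------------------------------------------
# Model serialization (JSON)
# ---------------------------------------------------------------------------


def save_model(dic: PatchDictionary, clf: VesselClassifier, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "atoms": dic.atoms.tolist(),
                "patch_edge": dic.patch_edge,
                "scales": list(dic.scales),
                "whiten_mean": dic.whiten_mean.tolist(),
                "whiten_sd": dic.whiten_sd.tolist(),
                "weights": clf.weights.tolist(),
                "bias": clf.bias,
                "feat_mean": clf.feat_mean.tolist(),
                "feat_sd": clf.feat_sd.tolist(),
                "seed": clf.seed,
                "n_samples": clf.n_samples,
            },
            fh,
        )


def load_model(path) -> tuple[PatchDictionary, VesselClassifier]:
    with open(path) as fh:
        d = json.load(fh)
    dic = PatchDictionary(
        atoms=np.asarray(d["atoms"]),
        patch_edge=d["patch_edge"],
        scales=tuple(d["scales"]),
        whiten_mean=np.asarray(d["whiten_mean"]),
        whiten_sd=np.asarray(d["whiten_sd"]),
    )
    clf = VesselClassifier(
        weights=np.asarray(d["weights"]),
        bias=float(d["bias"]),
        feat_mean=np.asarray(d["feat_mean"]),
        feat_sd=np.asarray(d["feat_sd"]),
        seed=int(d["seed"]),
        n_samples=int(d["n_samples"]),
    )
    return dic, clf
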