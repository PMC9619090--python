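"""Block-wise lung texture classification (adaptive multi-feature method).

Lung parenchyma on CT is classified into seven texture classes — normal,
ground glass, ground glass reticular, honeycombing, bronchovascular,
emphysema, consolidated — by tiling the lung with small cubic blocks and,
per block: (1) edgementation preprocessing, a region merge that fuses
adjacent voxels with similar grey levels; (2) extraction of 17 features
(5 first-order, 5 run-length, 6 co-occurrence, 1 fractal); (3) divergence
based feature selection with correlation pruning; (4) a Gaussian naive
Bayes classifier.

Grey levels are quantized over a fixed HU window before the co-occurrence
and run-length matrices are built, so those features are comparable across
blocks and scans.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .imgrid import BinaryMask, VolumeImage

__all__ = [
    "TextureClass",
    "TextureMap",
    "BayesTextureModel",
    "FEATURE_NAMES",
    "AmfmConfig",
    "quantize",
    "edgementation",
    "first_order",
    "glcm_features",
    "rlm_features",
    "box_counting_dimension",
    "fractal_dimension",
    "block_features",
    "select_features",
    "train_bayes",
    "classify_block",
    "classify_textures",
]


class TextureClass(enum.IntEnum):
    """The seven parenchymal texture classes plus background.

    The integer order is the tie-break order of the Bayes classifier and
    the label encoding of :class:`TextureMap` files.
    """

    BACKGROUND = 0
    NORMAL = 1
    GROUND_GLASS = 2
    GROUND_GLASS_RETICULAR = 3
    HONEYCOMBING = 4
    BRONCHOVASCULAR = 5
    EMPHYSEMA = 6
    CONSOLIDATED = 7


FOREGROUND_CLASSES = tuple(c for c in TextureClass if c is not TextureClass.BACKGROUND)

#: Flat feature vector layout produced by :func:`block_features`.
FEATURE_NAMES = (
    "fo_mean",
    "fo_variance",
    "fo_skewness",
    "fo_kurtosis",
    "fo_grey_level_entropy",
    "rlm_short_run_emphasis",
    "rlm_long_run_emphasis",
    "rlm_grey_level_nonuniformity",
    "rlm_run_length_nonuniformity",
    "rlm_run_percentage",
    "glcm_angular_second_moment",
    "glcm_entropy",
    "glcm_inertia",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_inverse_difference_moment",
    "fractal_dimension",
)

# 13 unique 3D direction vectors (half of the 26-neighbourhood).
DIRECTIONS_3D = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)


@dataclass
class AmfmConfig:
    """Quantization window, block size and preprocessing defaults."""

    hu_window: tuple[float, float] = (-1024.0, 200.0)
    n_levels: int = 32
    block_edge: int = 16
    #: edgementation merge threshold, in quantization bins (converted to HU)
    merge_threshold_bins: float = 2.0
    min_in_lung_fraction: float = 0.5
    max_selected_features: int = 16
    correlation_prune: float = 0.95

    @property
    def bin_width_hu(self) -> float:
        return (self.hu_window[1] - self.hu_window[0]) / self.n_levels

    @property
    def merge_threshold_hu(self) -> float:
        return self.merge_threshold_bins * self.bin_width_hu


@dataclass
class TextureMap:
    """Per-voxel texture labels; background outside the lung."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.int16)
        valid = {int(c) for c in TextureClass}
        found = set(np.unique(arr).tolist())
        if not found <= valid:
            raise ValueError(f"texture map contains labels outside the enum: {found - valid}")
        self.data = arr

    @property
    def shape(self):
        return self.data.shape

    def mask_of(self, cls: TextureClass) -> BinaryMask:
        return BinaryMask((self.data == int(cls)).astype(np.uint8), self.spacing, self.origin)


def quantize(values: np.ndarray, cfg: AmfmConfig) -> np.ndarray:
    """Map HU to integer grey levels 0..n_levels-1 over the fixed window."""
    lo, hi = cfg.hu_window
    x = (np.asarray(values, dtype=float) - lo) / (hi - lo)
    return np.clip((x * cfg.n_levels).astype(np.int64), 0, cfg.n_levels - 1)


# ---------------------------------------------------------------------------
# Edgementation
# ---------------------------------------------------------------------------


def edgementation(block: np.ndarray, merge_threshold: float) -> np.ndarray:
    """Region-merge preprocessing: fuse adjacent voxels with similar values.

    6-adjacent voxels whose grey-level difference is <= ``merge_threshold``
    belong to one region; each region is replaced by its mean grey level.
    With threshold 0 only exactly-equal neighbours merge, so the output
    equals the input.
    """
    if merge_threshold < 0:
        raise ValueError("merge_threshold must be non-negative")
    g = np.asarray(block, dtype=float)
    n = g.size
    flat = g.ravel()
    idx = np.arange(n).reshape(g.shape)
    rows, cols = [], []
    for axis in range(3):
        a = [slice(None)] * 3
        b = [slice(None)] * 3
        a[axis] = slice(None, -1)
        b[axis] = slice(1, None)
        ia, ib = idx[tuple(a)].ravel(), idx[tuple(b)].ravel()
        ok = np.abs(flat[ia] - flat[ib]) <= merge_threshold
        rows.append(ia[ok])
        cols.append(ib[ok])
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    adj = coo_matrix((np.ones(r.size, dtype=np.int8), (r, c)), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    sums = np.bincount(labels, weights=flat)
    counts = np.bincount(labels)
    return (sums / counts)[labels].reshape(g.shape)


# ---------------------------------------------------------------------------
# First-order features
# ---------------------------------------------------------------------------


def first_order(block: np.ndarray, cfg: AmfmConfig | None = None) -> np.ndarray:
    """Mean, variance, skewness, kurtosis and grey-level entropy.

    Moments are computed on the raw grey values (population definitions;
    kurtosis is non-excess).  Entropy is Shannon entropy in bits of the
    quantized grey-level histogram; a constant block has entropy 0 and,
    by convention, skewness and kurtosis 0.
    """
    cfg = cfg or AmfmConfig()
    x = np.asarray(block, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty block")
    mean = x.mean()
    var = x.var()
    if var > 0:
        sd = np.sqrt(var)
        skew = np.mean(((x - mean) / sd) ** 3)
        kurt = np.mean(((x - mean) / sd) ** 4)
    else:
        skew = 0.0
        kurt = 0.0
    q = quantize(x, cfg)
    p = np.bincount(q, minlength=cfg.n_levels).astype(float)
    p = p[p > 0] / x.size
    entropy = float(-(p * np.log2(p)).sum())
    return np.array([mean, var, skew, kurt, entropy])


# ---------------------------------------------------------------------------
# Co-occurrence (GLCM) features
# ---------------------------------------------------------------------------


def _glcm_matrix(levels: np.ndarray, n_levels: int, offsets) -> np.ndarray:
    """Symmetric normalized grey-level co-occurrence matrix pooled over offsets."""
    g = np.asarray(levels)
    m = np.zeros((n_levels, n_levels), dtype=float)
    for off in offsets:
        sl_a, sl_b = [], []
        for d, size in zip(off, g.shape):
            if abs(d) >= size:
                sl_a = None
                break
            sl_a.append(slice(None, -d) if d > 0 else slice(-d, None))
            sl_b.append(slice(d, None) if d > 0 else slice(None, size + d))
        if sl_a is None:
            continue
        a = g[tuple(sl_a)].ravel()
        b = g[tuple(sl_b)].ravel()
        np.add.at(m, (a, b), 1.0)
        np.add.at(m, (b, a), 1.0)
    total = m.sum()
    if total > 0:
        m /= total
    return m


def glcm_features(block: np.ndarray, cfg: AmfmConfig | None = None, offsets=None) -> np.ndarray:
    """Six Haralick-style features of the pooled symmetric GLCM.

    Returns (ASM, entropy, inertia, contrast, correlation, IDM) where
    inertia = sum (i-j)^2 p and contrast = sum |i-j| p are kept as two
    distinct features; correlation of a zero-variance matrix is defined 0.
    """
    cfg = cfg or AmfmConfig()
    if cfg.n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    offsets = DIRECTIONS_3D if offsets is None else offsets
    p = _glcm_matrix(quantize(block, cfg), cfg.n_levels, offsets)
    i, j = np.indices(p.shape)
    asm = float((p**2).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum()) if nz.size else 0.0
    inertia = float(((i - j) ** 2 * p).sum())
    contrast = float((np.abs(i - j) * p).sum())
    px = p.sum(axis=1)
    mu = float((np.arange(p.shape[0]) * px).sum())
    sig2 = float(((np.arange(p.shape[0]) - mu) ** 2 * px).sum())
    if sig2 > 1e-12:
        corr = float(((i * j * p).sum() - mu * mu) / sig2)
    else:
        corr = 0.0
    idm = float((p / (1.0 + (i - j) ** 2)).sum())
    return np.array([asm, entropy, inertia, contrast, corr, idm])


# ---------------------------------------------------------------------------
# Run-length (RLM) features
# ---------------------------------------------------------------------------


def _rlm_matrix(levels: np.ndarray, n_levels: int, directions) -> np.ndarray:
    """Run-length matrix r(g, l) pooled over directions.

    For each direction every maximal digital line through the grid is
    traversed and its maximal constant runs are counted.  Implemented by
    concatenating all lines of a direction with a -1 sentinel between
    them and run-length-encoding the concatenation in one pass.
    """
    g = np.asarray(levels, dtype=np.int64)
    shape = g.shape
    max_len = max(shape)
    m = np.zeros((n_levels, max_len + 1), dtype=float)
    axes = np.indices(shape).reshape(3, -1)  # (3, n)
    for d in directions:
        d = np.asarray(d)
        # line starts: stepping backwards leaves the grid
        prev = axes - d.reshape(3, 1)
        is_start = ((prev < 0) | (prev >= np.reshape(shape, (3, 1)))).any(axis=0)
        starts = axes[:, is_start]  # (3, n_lines)
        steps = np.arange(max_len)
        coords = starts[:, :, None] + d.reshape(3, 1, 1) * steps[None, None, :]
        valid = (
            (coords >= 0) & (coords < np.reshape(shape, (3, 1, 1)))
        ).all(axis=0)  # (n_lines, max_len)
        cc = np.clip(coords, 0, np.reshape(np.asarray(shape) - 1, (3, 1, 1)))
        vals = g[cc[0], cc[1], cc[2]]
        vals = np.where(valid, vals, -1)
        flat = np.concatenate([vals, np.full((vals.shape[0], 1), -1, dtype=np.int64)], axis=1).ravel()
        change = np.flatnonzero(np.diff(flat)) + 1
        bounds = np.concatenate(([0], change, [flat.size]))
        run_starts = bounds[:-1]
        run_lens = np.diff(bounds)
        run_vals = flat[run_starts]
        keep = run_vals >= 0
        np.add.at(m, (run_vals[keep], run_lens[keep]), 1.0)
    used = np.flatnonzero(m.sum(axis=0))
    top = used.max() + 1 if used.size else 2
    return m[:, :top]


def rlm_features(block: np.ndarray, cfg: AmfmConfig | None = None, directions=None) -> np.ndarray:
    """Five run-length features of the pooled run-length matrix.

    Returns (SRE, LRE, GLN, RLN, RP).  RP divides the total number of runs
    by the number of voxel samples pooled over all directions, so a block
    of all-unit runs has RP exactly 1.
    """
    cfg = cfg or AmfmConfig()
    if cfg.n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    directions = DIRECTIONS_3D if directions is None else directions
    m = _rlm_matrix(quantize(block, cfg), cfg.n_levels, directions)
    n_runs = m.sum()
    if n_runs == 0:
        raise ValueError("empty block")
    lengths = np.arange(m.shape[1])
    lengths[0] = 1  # length-0 column is always empty; avoid 0/0
    r_l = m.sum(axis=0)
    r_g = m.sum(axis=1)
    sre = float((r_l / lengths**2).sum() / n_runs)
    lre = float((r_l * lengths**2).sum() / n_runs)
    gln = float((r_g**2).sum() / n_runs)
    rln = float((r_l**2).sum() / n_runs)
    n_samples = float((r_l * lengths).sum())  # voxels counted once per direction
    rp = float(n_runs / n_samples)
    return np.array([sre, lre, gln, rln, rp])


# ---------------------------------------------------------------------------
# Fractal dimension
# ---------------------------------------------------------------------------


def box_counting_dimension(edge_map: np.ndarray, box_edges=(1, 2, 4, 8)) -> float:
    """Box-counting dimension: LS slope of log N(box) vs log(1/box edge)."""
    e = np.asarray(edge_map).astype(bool)
    if not e.any():
        return 0.0
    logn, logs = [], []
    for s in box_edges:
        pad = [(0, (-dim) % s) for dim in e.shape]
        ep = np.pad(e, pad)
        view = ep.reshape(ep.shape[0] // s, s, ep.shape[1] // s, s, ep.shape[2] // s, s)
        n = int(view.any(axis=(1, 3, 5)).sum())
        logn.append(np.log(max(n, 1)))
        logs.append(np.log(1.0 / s))
    logn = np.asarray(logn)
    logs = np.asarray(logs)
    sxx = ((logs - logs.mean()) ** 2).sum()
    return float(((logs - logs.mean()) * (logn - logn.mean())).sum() / sxx)


def fractal_dimension(block: np.ndarray) -> float:
    """Geometric fractal dimension of the block's thresholded edge map.

    The edge map keeps voxels whose gradient magnitude exceeds the in-block
    median; its box-counting dimension over box edges {1, 2, 4, 8} is the
    feature.  Requires a block of at least 8 voxels per side.
    """
    b = np.asarray(block, dtype=float)
    if min(b.shape) < 8:
        raise ValueError("fractal dimension needs a block of at least 8^3")
    grads = np.gradient(b)
    mag = np.sqrt(sum(g**2 for g in grads))
    edge = mag > np.median(mag)
    return box_counting_dimension(edge)


# ---------------------------------------------------------------------------
# Full per-block feature vector
# ---------------------------------------------------------------------------


def block_features(block: np.ndarray, cfg: AmfmConfig | None = None) -> np.ndarray:
    """Edgementation followed by the 17-feature vector of a raw HU block."""
    cfg = cfg or AmfmConfig()
    merged = edgementation(np.asarray(block, dtype=float), cfg.merge_threshold_hu)
    return np.concatenate(
        [
            first_order(merged, cfg),
            rlm_features(merged, cfg),
            glcm_features(merged, cfg),
            [fractal_dimension(merged)],
        ]
    )


# ---------------------------------------------------------------------------
# Feature selection and Bayes classifier
# ---------------------------------------------------------------------------


def _pairwise_divergence(mu, var):
    """Sum over class pairs of the 1-D Gaussian divergence of one feature."""
    j = 0.0
    k = len(mu)
    for a in range(k):
        for b in range(a + 1, k):
            v1, v2 = max(var[a], 1e-12), max(var[b], 1e-12)
            j += 0.5 * (v1 / v2 + v2 / v1 - 2.0)
            j += 0.5 * (mu[a] - mu[b]) ** 2 * (1.0 / v1 + 1.0 / v2)
    return j


def select_features(
    features: np.ndarray,
    labels: np.ndarray,
    max_features: int = 16,
    correlation_prune: float = 0.95,
) -> list[int]:
    """Rank features by summed pairwise-class divergence, prune correlated ones.

    Features are ranked by the sum over class pairs of the 1-D Gaussian
    divergence; the ranked list is scanned greedily, skipping any feature
    whose |Pearson r| with an already-kept feature exceeds the pruning
    threshold, until ``max_features`` are kept.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"class {c} has fewer than 2 training samples")
    scores = []
    for f in range(x.shape[1]):
        mu = [x[y == c, f].mean() for c in classes]
        var = [x[y == c, f].var() for c in classes]
        scores.append(_pairwise_divergence(mu, var))
    order = np.argsort(scores)[::-1]
    kept: list[int] = []
    sd = x.std(axis=0)
    for f in order:
        if len(kept) >= max_features:
            break
        redundant = False
        for k in kept:
            if sd[f] < 1e-12 or sd[k] < 1e-12:
                redundant = sd[f] < 1e-12
                break
            r = np.corrcoef(x[:, f], x[:, k])[0, 1]
            if abs(r) > correlation_prune:
                redundant = True
                break
        if not redundant:
            kept.append(int(f))
    return kept


@dataclass
class BayesTextureModel:
    """Gaussian class-conditional model with diagonal covariance.

    Features are normalized by the stored training-set mean/sd (a fixed
    affine map applied identically at train and classify time) before the
    class Gaussians are evaluated.
    """

    classes: tuple[int, ...]
    selected: tuple[int, ...]
    means: np.ndarray  # (n_classes, n_selected), normalized space
    variances: np.ndarray  # (n_classes, n_selected)
    priors: np.ndarray  # (n_classes,)
    norm_mean: np.ndarray  # (n_features,) training normalization
    norm_sd: np.ndarray

    def __post_init__(self):
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")
        if (self.variances <= 0).any():
            raise ValueError("variances must be positive")

    def to_json(self) -> str:
        return json.dumps(
            {
                "classes": list(self.classes),
                "selected": list(self.selected),
                "means": self.means.tolist(),
                "variances": self.variances.tolist(),
                "priors": self.priors.tolist(),
                "norm_mean": self.norm_mean.tolist(),
                "norm_sd": self.norm_sd.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "BayesTextureModel":
        d = json.loads(text)
        return cls(
            classes=tuple(d["classes"]),
            selected=tuple(d["selected"]),
            means=np.asarray(d["means"]),
            variances=np.asarray(d["variances"]),
            priors=np.asarray(d["priors"]),
            norm_mean=np.asarray(d["norm_mean"]),
            norm_sd=np.asarray(d["norm_sd"]),
        )


def train_bayes(
    features: np.ndarray,
    labels: np.ndarray,
    selected: list[int] | None = None,
    cfg: AmfmConfig | None = None,
    var_shrinkage: float = 0.5,
) -> BayesTextureModel:
    """Fit the Gaussian Bayes model with uniform priors on selected features.

    Class-conditional variances are shrunk toward the pooled within-class
    variance (``var_shrinkage`` is the weight on the class's own estimate).
    Without shrinkage a homogeneous training class gets a near-degenerate
    variance and vetoes any block that deviates microscopically in that
    feature, even when every discriminative feature matches it.
    """
    cfg = cfg or AmfmConfig()
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if selected is None:
        selected = select_features(x, y, cfg.max_selected_features, cfg.correlation_prune)
    norm_mean = x.mean(axis=0)
    norm_sd = x.std(axis=0)
    norm_sd[norm_sd < 1e-12] = 1.0
    xs = ((x - norm_mean) / norm_sd)[:, selected]
    classes = tuple(int(c) for c in np.unique(y))
    means = np.stack([xs[y == c].mean(axis=0) for c in classes])
    variances = np.stack([xs[y == c].var(axis=0) for c in classes])
    counts = np.asarray([(y == c).sum() for c in classes], dtype=float)
    pooled = (variances * counts[:, None]).sum(axis=0) / counts.sum()
    variances = var_shrinkage * variances + (1.0 - var_shrinkage) * pooled[None, :]
    variances = np.maximum(variances, 1e-8)
    priors = np.full(len(classes), 1.0 / len(classes))
    return BayesTextureModel(
        classes=classes,
        selected=tuple(int(i) for i in selected),
        means=means,
        variances=variances,
        priors=priors,
        norm_mean=norm_mean,
        norm_sd=norm_sd,
    )


def train_from_patches(patches_labels, cfg: AmfmConfig | None = None) -> BayesTextureModel:
    """Feature-extract labelled patches and fit the Bayes model."""
    cfg = cfg or AmfmConfig()
    feats = np.stack([block_features(np.asarray(p.data, dtype=float), cfg) for p, _ in patches_labels])
    labels = np.asarray([int(c) for _, c in patches_labels])
    return train_bayes(feats, labels, cfg=cfg)


def _log_posteriors(features: np.ndarray, model: BayesTextureModel) -> np.ndarray:
    x = np.atleast_2d(np.asarray(features, dtype=float))
    xs = ((x - model.norm_mean) / model.norm_sd)[:, list(model.selected)]
    # (n_samples, n_classes)
    diff = xs[:, None, :] - model.means[None, :, :]
    ll = -0.5 * (diff**2 / model.variances[None]).sum(axis=2)
    ll -= 0.5 * np.log(model.variances[None]).sum(axis=2)
    return ll + np.log(model.priors)[None, :]

def classify_block(features: np.ndarray, model: BayesTextureModel) -> TextureClass:
    """Maximum-posterior class of one feature vector; ties break in enum order."""
    lp = _log_posteriors(features, model)[0]
    return TextureClass(model.classes[int(np.argmax(lp))])


def classify_textures(
    ct: VolumeImage,
    lung: BinaryMask,
    model: BayesTextureModel,
    cfg: AmfmConfig | None = None,
) -> TextureMap:
    """Tile the lung with blocks, classify each, paint labels on lung voxels.

    Non-overlapping ``block_edge``-cubed blocks with at least half their
    voxels in the lung are classified; their label is assigned to their
    in-lung voxels.  Lung voxels not covered by any qualifying block
    inherit the label of the nearest labelled block voxel.
    """
    cfg = cfg or AmfmConfig()
    e = cfg.block_edge
    data = np.asarray(ct.data, dtype=float)
    inlung = lung.data
    out = np.zeros(data.shape, dtype=np.int16)
    if not inlung.any():
        return TextureMap(out, ct.spacing, ct.origin)
    labeled_any = False
    feats = []
    slots = []
    for ix in range(0, data.shape[0] - e + 1, e):
        for iy in range(0, data.shape[1] - e + 1, e):
            for iz in range(0, data.shape[2] - e + 1, e):
                sl = (slice(ix, ix + e), slice(iy, iy + e), slice(iz, iz + e))
                frac = inlung[sl].mean()
                if frac < cfg.min_in_lung_fraction:
                    continue
                feats.append(block_features(data[sl], cfg))
                slots.append(sl)
    if not feats:
        raise ValueError("no blocks with sufficient in-lung coverage")
    lp = _log_posteriors(np.stack(feats), model)
    labels = [TextureClass(model.classes[int(i)]) for i in np.argmax(lp, axis=1)]
    for sl, lab in zip(slots, labels):
        region = out[sl]
        region[inlung[sl]] = int(lab)
        labeled_any = True
    # propagate to uncovered lung voxels from the nearest labelled voxel
    uncovered = inlung & (out == 0)
    if labeled_any and uncovered.any():
        _, idx = ndimage.distance_transform_edt(out == 0, return_indices=True)
        out[uncovered] = out[tuple(i[uncovered] for i in idx)]
    return TextureMap(out, ct.spacing, ct.origin)
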