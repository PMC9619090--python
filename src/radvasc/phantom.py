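"""Synthetic thorax phantoms with complete ground truth.

A phantom case emulates a paired pre/post-radiotherapy non-contrast CT
study: two ellipsoidal lungs in a soft-tissue body, a bifurcating vessel
tree system, a Gaussian-falloff dose grid centred on one vessel, programmed
per-dose-bin vessel atrophy, a radiographically damaged region painted with
ground-glass-reticular texture, a smooth synthetic respiratory/positioning
deformation (whose inverse is stored as the true registration field), a
fed / not-fed / contralateral partition of the lung, and a programmed
perfusion-change value per analysis region.

Each lung carries TWO disjoint trees (an anterior and a posterior one) and
the dose peaks on the root of the ipsilateral anterior tree.  With disjoint
trees, "territory supplied by vasculature branching from the irradiated
vessel" is identifiable both by branch descent (used for the stored truth)
and by skeleton connectivity (used by the analysis code), so the two
definitions coincide by construction.

Frames: ``ct_pre`` and all pre-RT truths live in the pre-RT frame; the
post-RT image, ``vessel_truth_post``, ``damage_truth`` and ``texture_truth``
live in the post-RT frame, related to the pre frame by the stored
``field_true`` (pre -> post positions, mm).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .amfm import TextureClass
from .imgrid import (
    BinaryMask,
    DisplacementField,
    LabelMap,
    ValueKind,
    VolumeImage,
    write_field,
    write_mask,
    write_volume,
    read_field,
    read_mask,
    read_volume,
)

__all__ = [
    "PhantomParams",
    "PhantomCase",
    "DOSE_BIN_EDGES",
    "DOSE_BIN_NAMES",
    "dose_bin_of",
    "radius_reduction_for_volume_change",
    "generate_case",
    "texture_patch",
    "TEXTURE_DEFAULTS",
    "write_case",
    "read_case",
]

# Dose bins shared with the change-analysis module: no (<5), low (5-20),
# medium (20-40), high (>=40 Gy).
DOSE_BIN_EDGES = (0.0, 5.0, 20.0, 40.0, np.inf)
DOSE_BIN_NAMES = ("no", "low", "medium", "high")

REGION_NAMES = (
    "fed_no",
    "fed_low",
    "fed_medium",
    "not_fed_no",
    "not_fed_low",
    "not_fed_medium",
    "contralateral",
)

FED_LABELS = {1: "fed", 2: "not_fed", 3: "contralateral"}


def dose_bin_of(dose_gy: float) -> str:
    for name, lo, hi in zip(DOSE_BIN_NAMES, DOSE_BIN_EDGES[:-1], DOSE_BIN_EDGES[1:]):
        if lo <= dose_gy < hi:
            return name
    return DOSE_BIN_NAMES[-1]


def radius_reduction_for_volume_change(pct: float) -> float:
    """Fractional radius reduction producing a given percent volume change.

    Tube volume scales with radius squared, so a programmed volume change
    of ``pct`` percent needs the radius scaled by sqrt(1 + pct/100).
    """
    if pct < -100 or pct > 0:
        raise ValueError("volume change percent must be in [-100, 0]")
    return 1.0 - float(np.sqrt(1.0 + pct / 100.0))


#: Programmed per-bin vessel-volume changes (percent) used by default.
DEFAULT_ATROPHY_VOLUME_PCT = {"no": -5.0, "low": -10.0, "medium": -25.0, "high": -40.0}


# ---------------------------------------------------------------------------
# Texture synthesis (shared between texture_patch and damage painting)
# ---------------------------------------------------------------------------

#: Per-class texture generator parameters (HU).  One config block so tests
#: can tighten or loosen contrast; the same generators that produce training
#: patches paint the damaged region of a phantom case.
TEXTURE_DEFAULTS: dict[TextureClass, dict] = {
    # normal parenchyma: low-variance noise around lung HU, usually with
    # one or two bright vessel tubes (real "normal" lung blocks contain
    # small vessels; without them every vessel-bearing block would look
    # like disease texture to the classifier)
    TextureClass.NORMAL: {
        "mean": -850.0,
        "sd": 30.0,
        "vessel_prob": 0.7,
        "vessel_hu": 50.0,
        "vessel_radius_range": (0.6, 2.2),
        "vessel_max_tubes": 2,
    },
    TextureClass.GROUND_GLASS: {"mean": -600.0, "sd_smooth": 60.0, "sigma": 2.0, "sd": 25.0},
    # hazy ground-glass base carrying sparse intense reticular filaments:
    # the filaments are what intensity-driven vessel detectors falsely
    # fire on, while the base stays below any aerated/vessel threshold
    # and the empty mid-HU range keeps optimal thresholding stable
    TextureClass.GROUND_GLASS_RETICULAR: {
        "mean": -700.0,
        "base_amp": 40.0,
        "base_sigma": 1.5,
        "streak_hu": -150.0,
        "streak_frac": 0.25,
        "band_lo": 0.6,
        "band_hi": 1.4,
        "sd": 40.0,
    },
    TextureClass.HONEYCOMBING: {
        "wall_hu": -150.0,
        "pocket_hu": -900.0,
        "pocket_frac": 0.45,
        "sigma": 1.8,
        "sd": 30.0,
    },
    TextureClass.BRONCHOVASCULAR: {
        "background": -800.0,
        "streak_hu": -50.0,
        "streak_frac": 0.22,
        "sigma_long": 2.5,
        "sigma_trans": 0.7,
        "sd": 40.0,
    },
    TextureClass.EMPHYSEMA: {"mean": -950.0, "sd": 15.0},
    TextureClass.CONSOLIDATED: {"mean": 20.0, "sd": 20.0},
}


def _unit_sd(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return x / sd if sd > 0 else x


def _texture_field(cls: TextureClass, shape, rng: np.random.Generator, params=None) -> np.ndarray:
    """Noise-free structural HU field of one texture class (no white noise)."""
    p = dict(TEXTURE_DEFAULTS[cls])
    if params:
        p.update(params)
    if cls is TextureClass.NORMAL:
        out = np.full(shape, p["mean"])
        if rng.uniform() < p["vessel_prob"]:
            # bright tubes through the patch: normal parenchyma blocks
            # contain vessels from capillary-adjacent up to trunk calibre,
            # and the classifier must not call them disease texture
            idx = np.moveaxis(np.indices(shape, dtype=float), 0, -1)
            for _ in range(int(rng.integers(1, p["vessel_max_tubes"] + 1))):
                point = rng.uniform(0, 1, 3) * np.asarray(shape)
                dirn = rng.standard_normal(3)
                dirn /= np.linalg.norm(dirn)
                rel = idx - point
                dist = np.linalg.norm(rel - (rel @ dirn)[..., None] * dirn, axis=-1)
                out[dist <= rng.uniform(*p["vessel_radius_range"])] = p["vessel_hu"]
        return out
    if cls in (TextureClass.EMPHYSEMA, TextureClass.CONSOLIDATED):
        return np.full(shape, p["mean"])
    if cls is TextureClass.GROUND_GLASS:
        smooth = _unit_sd(ndimage.gaussian_filter(rng.standard_normal(shape), p["sigma"]))
        return p["mean"] + p["sd_smooth"] * smooth
    if cls is TextureClass.GROUND_GLASS_RETICULAR:
        smooth = _unit_sd(ndimage.gaussian_filter(rng.standard_normal(shape), p["base_sigma"]))
        out = p["mean"] + p["base_amp"] * smooth
        w = rng.standard_normal(shape)
        band = ndimage.gaussian_filter(w, p["band_lo"]) - ndimage.gaussian_filter(w, p["band_hi"])
        thr = np.quantile(band, 1.0 - p["streak_frac"])
        out[band > thr] = p["streak_hu"]
        return out
    if cls is TextureClass.HONEYCOMBING:
        blob = _unit_sd(ndimage.gaussian_filter(rng.standard_normal(shape), p["sigma"]))
        thr = np.quantile(blob, 1.0 - p["pocket_frac"])
        out = np.full(shape, p["wall_hu"])
        out[blob > thr] = p["pocket_hu"]
        return out
    if cls is TextureClass.BRONCHOVASCULAR:
        t = _unit_sd(
            ndimage.gaussian_filter(
                rng.standard_normal(shape),
                (p["sigma_long"], p["sigma_trans"], p["sigma_trans"]),
            )
        )
        thr = np.quantile(t, 1.0 - p["streak_frac"])
        out = np.full(shape, p["background"])
        out[t > thr] = p["streak_hu"]
        return out
    raise ValueError(f"unknown texture class {cls!r}")


def texture_patch(
    cls: TextureClass,
    shape: tuple[int, int, int],
    seed: int,
    params: dict | None = None,
    spacing=(1.0, 1.0, 1.0),
) -> VolumeImage:
    """A CT patch with the class-specific texture statistics plus white noise.

    The same seed always yields the identical patch.  Raises on the
    background pseudo-class.
    """
    if not isinstance(cls, TextureClass) or cls is TextureClass.BACKGROUND:
        raise ValueError(f"not a foreground texture class: {cls!r}")
    rng = np.random.default_rng(seed)
    p = dict(TEXTURE_DEFAULTS[cls])
    if params:
        p.update(params)
    data = _texture_field(cls, shape, rng, params) + p["sd"] * rng.standard_normal(shape)
    return VolumeImage(data, spacing, (0.0, 0.0, 0.0), ValueKind.HU)


# ---------------------------------------------------------------------------
# Parameters and case container
# ---------------------------------------------------------------------------


def texture_training_set(
    shape=(16, 16, 16),
    n_per_class: int = 30,
    seed: int = 0,
    mixture_frac: float = 0.4,
    coverage=(0.4, 0.9),
    params: dict | None = None,
):
    """Labelled texture patches for classifier training: pure and partial.

    A fraction of each abnormal class's patches carry the class texture
    over a random half-space of the patch only (coverage drawn from
    ``coverage``), with normal parenchyma elsewhere — in-lung analysis
    blocks straddle lesion boundaries the same way, so the classifier must
    learn to call a majority-abnormal block by its abnormal texture.
    The normal class is sampled from the undamaged lung of a generated
    phantom case rather than synthesized per patch: an analysis block of
    healthy lung contains real vasculature (tapering, bifurcating, all
    calibres), and the classifier must learn that parenchyma-with-vessels
    is normal, not disease texture, or every vessel would be vetoed.

    Only ground-glass reticular receives mixture augmentation (class
    texture over a random half-space of normal parenchyma): it is the
    texture of radiation-induced change, the one abnormality that appears
    as partial blocks at lesion boundaries.  Returns a list of
    (VolumeImage, TextureClass) pairs.
    """
    from .amfm import TextureClass as TC

    rng = np.random.default_rng(seed)
    out = []
    # normal: random in-lung blocks of a damage- and atrophy-free case
    case_params = PhantomParams(
        seed=int(rng.integers(2**31)),
        atrophy_by_bin={b: 0.0 for b in DOSE_BIN_NAMES},
        deform_max_mm=0.0,
    )
    case = generate_case(case_params)
    ct = np.asarray(case.ct_pre.data)
    lung = case.lung_truth.data
    half = np.asarray(shape) // 2
    coords = np.argwhere(lung)
    ok = (
        (coords >= half).all(axis=1)
        & (coords + (np.asarray(shape) - half) <= np.asarray(ct.shape)).all(axis=1)
    )
    coords = coords[ok]
    # half real case crops (vessel trees with taper and bifurcations), half
    # synthetic parenchyma patches (a share of which are vessel-free), so
    # the class covers both vessel-rich and featureless normal blocks
    n_crops = (3 * n_per_class) // 4
    n_normal = 0
    while n_normal < n_crops:
        c = coords[int(rng.integers(coords.shape[0]))]
        sl = tuple(slice(c[d] - half[d], c[d] - half[d] + shape[d]) for d in range(3))
        if lung[sl].mean() < 0.98:  # interior blocks: parenchyma and vessels only
            continue
        out.append(
            (VolumeImage(ct[sl].copy(), case.ct_pre.spacing, (0, 0, 0), ValueKind.HU), TC.NORMAL)
        )
        n_normal += 1
    for _ in range(n_per_class - n_crops):
        out.append((texture_patch(TC.NORMAL, shape, int(rng.integers(2**31)), params), TC.NORMAL))

    classes = [c for c in TC if c not in (TC.BACKGROUND, TC.NORMAL)]
    mixture_classes = (TC.GROUND_GLASS_RETICULAR,)
    for cls in classes:
        for i in range(n_per_class):
            sub = int(rng.integers(2**31))
            patch = texture_patch(cls, shape, sub, params)
            if cls in mixture_classes and i < mixture_frac * n_per_class:
                cover = rng.uniform(*coverage)
                normal = texture_patch(TC.NORMAL, shape, int(rng.integers(2**31)), params)
                n_vec = rng.standard_normal(3)
                n_vec /= np.linalg.norm(n_vec)
                proj = (np.moveaxis(np.indices(shape, dtype=float), 0, -1) @ n_vec)
                thr = np.quantile(proj, 1.0 - cover)
                data = np.where(proj > thr, patch.data, normal.data)
                patch = VolumeImage(data, patch.spacing, patch.origin, ValueKind.HU)
            out.append((patch, cls))
    return out


@dataclass
class PhantomParams:
    """Everything the generator needs; identical params + seed => identical case."""

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lung_hu: float = -850.0
    vessel_hu: float = 50.0
    body_hu: float = 40.0
    damage_hu_mean: float = -700.0
    noise_sd_hu: float = 30.0
    tree_depth: int = 4
    root_radius_mm: float = 2.5
    radius_decay: float = 0.7
    root_length_mm: float = 12.0
    length_decay: float = 0.78
    branch_angle_deg: float = 34.0
    #: dose-bin name -> fractional radius reduction
    atrophy_by_bin: dict = field(
        default_factory=lambda: {
            b: radius_reduction_for_volume_change(p) for b, p in DEFAULT_ATROPHY_VOLUME_PCT.items()
        }
    )
    dose_max_gy: float = 60.0
    dose_sigma_mm: float = 9.0
    damage_dose_gy: float = 20.0
    large_vessel_radius_mm: float = 1.7
    deform_max_mm: float = 2.0
    n_deform_bumps: int = 3
    deform_sigma_mm: float = 15.0
    #: perfusion-change program: pct = perf_per_gy * mean_dose + perf_fed_offset * fed + perf_base
    perf_per_gy: float = -0.9
    perf_fed_offset: float = -35.0
    perf_base: float = -4.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.radius_decay < 1.0):
            raise ValueError("radius_decay must be in (0,1)")
        if self.root_radius_mm <= 0 or self.tree_depth < 1:
            raise ValueError("root_radius_mm must be > 0 and tree_depth >= 1")
        for b, f in self.atrophy_by_bin.items():
            if b not in DOSE_BIN_NAMES:
                raise ValueError(f"unknown dose bin {b!r}")
            if not (0.0 <= f <= 1.0):
                raise ValueError("atrophy fractions must be in [0,1]")
        extent = self.root_length_mm * sum(self.length_decay**g for g in range(self.tree_depth))
        if extent > 0.75 * min(
            n * s for n, s in zip(self.grid_shape, self.spacing_mm)
        ):
            raise ValueError(
                f"grid too small for {self.tree_depth} tree generations "
                f"(tree extent ~{extent:.0f} mm)"
            )


@dataclass
class PhantomCase:
    """A fully-labelled paired pre/post-RT phantom study."""

    ct_pre: VolumeImage
    ct_post: VolumeImage
    dose: VolumeImage
    lung_truth: BinaryMask
    vessel_truth_pre: BinaryMask
    vessel_truth_post: BinaryMask
    large_vessel_truth: BinaryMask
    damage_truth: BinaryMask
    texture_truth: LabelMap
    field_true: DisplacementField
    fed_truth: LabelMap
    perfusion_change_truth: dict
    atrophy_truth: dict
    params: PhantomParams


# ---------------------------------------------------------------------------
# Vessel tree construction
# ---------------------------------------------------------------------------


@dataclass
class _Segment:
    start: np.ndarray  # mm
    end: np.ndarray
    r_start: float
    r_end: float
    generation: int
    tree: int  # global tree id


def _rotate(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c)


def _grow_tree(
    root: np.ndarray,
    direction: np.ndarray,
    tree_id: int,
    params: PhantomParams,
    rng: np.random.Generator,
    y_range: tuple[float, float],
) -> list[_Segment]:
    """Recursive bifurcating tree confined to a y-slab of its lung."""
    segs: list[_Segment] = []

    def grow(start, dirn, gen):
        if gen >= params.tree_depth:
            return
        length = params.root_length_mm * params.length_decay**gen
        r0 = params.root_radius_mm * params.radius_decay**gen
        r1 = params.root_radius_mm * params.radius_decay ** (gen + 1)
        end = start + dirn * length
        segs.append(_Segment(start.copy(), end, r0, r1, gen, tree_id))
        angle = np.deg2rad(params.branch_angle_deg + rng.uniform(-5, 5))
        # alternate rotation planes so the tree fills 3D space
        axis = np.array([1.0, 0.0, 0.0]) if gen % 2 == 0 else np.array([0.0, 1.0, 0.0])
        for sign in (1.0, -1.0):
            child = _rotate(dirn, axis, sign * angle)
            # keep the tree inside its y slab: fold back escaping directions
            probe_y = end[1] + child[1] * length * params.length_decay
            if not (y_range[0] <= probe_y <= y_range[1]):
                child = child.copy()
                child[1] = -child[1]
            child = child / np.linalg.norm(child)
            grow(end, child, gen + 1)

    grow(np.asarray(root, dtype=float), np.asarray(direction, dtype=float), 0)
    return segs


def _raster_segments(
    segs, shape, spacing, radius_scale_fn=None
) -> np.ndarray:
    """Voxelize tapering tube segments: voxel in tube iff dist(axis) <= local radius.

    ``radius_scale_fn(points_mm)`` optionally returns a per-point radius
    multiplier (used for programmed atrophy).
    """
    out = np.zeros(shape, dtype=bool)
    sp = np.asarray(spacing)
    for s in segs:
        rmax = max(s.r_start, s.r_end)
        lo = np.maximum(np.floor((np.minimum(s.start, s.end) - rmax - 1) / sp).astype(int), 0)
        hi = np.minimum(
            np.ceil((np.maximum(s.start, s.end) + rmax + 1) / sp).astype(int) + 1, shape
        )
        if (hi <= lo).any():
            continue
        ii, jj, kk = np.meshgrid(
            *[np.arange(lo[d], hi[d]) for d in range(3)], indexing="ij"
        )
        pts = np.stack([ii * sp[0], jj * sp[1], kk * sp[2]], axis=-1)
        ab = s.end - s.start
        denom = float(np.dot(ab, ab))
        t = np.clip(((pts - s.start) @ ab) / denom, 0.0, 1.0)
        proj = s.start + t[..., None] * ab
        dist = np.linalg.norm(pts - proj, axis=-1)
        radius = s.r_start + t * (s.r_end - s.r_start)
        if radius_scale_fn is not None:
            radius = radius * radius_scale_fn(proj.reshape(-1, 3)).reshape(t.shape)
        sel = dist <= radius
        out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= sel
    return out


def _frustum_volume_ml(segs) -> float:
    """Closed-form tube-tree volume: sum of conical-frustum segment volumes."""
    total = 0.0
    for s in segs:
        h = float(np.linalg.norm(s.end - s.start))
        total += np.pi * h / 3.0 * (s.r_start**2 + s.r_start * s.r_end + s.r_end**2)
    return total / 1000.0


# ---------------------------------------------------------------------------
# Case generation
# ---------------------------------------------------------------------------


def _ellipsoid(shape, spacing, center_mm, semi_mm) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    world = idx * np.reshape(spacing, (3, 1, 1, 1))
    d = sum(
        ((world[a] - center_mm[a]) / semi_mm[a]) ** 2 for a in range(3)
    )
    return d <= 1.0


def generate_case(params: PhantomParams | None = None) -> PhantomCase:
    """Generate a fully-labelled paired pre/post-RT phantom case.

    Deterministic: identical params (including seed) give a bit-identical
    case.
    """
    params = params or PhantomParams()
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.grid_shape)
    sp = tuple(params.spacing_mm)
    extent = np.asarray(shape) * np.asarray(sp)
    c = extent / 2.0

    body = _ellipsoid(shape, sp, c, extent * np.array([0.48, 0.45, 0.48]))
    lung_semi = extent * np.array([0.16, 0.19, 0.31])
    right_center = c + np.array([0.21 * extent[0], 0.0, 0.0])
    left_center = c - np.array([0.21 * extent[0], 0.0, 0.0])
    lung_r = _ellipsoid(shape, sp, right_center, lung_semi)
    lung_l = _ellipsoid(shape, sp, left_center, lung_semi)
    lung = lung_r | lung_l

    # --- vessel trees: two disjoint trees per lung --------------------------
    down = np.array([0.0, 0.0, 1.0])
    segs: list[_Segment] = []
    tree_meta = []  # (tree_id, lung 'L'/'R')
    tid = 0
    for lung_name, center in (("R", right_center), ("L", left_center)):
        for side, y_off in (("ant", -0.35 * lung_semi[1]), ("post", 0.45 * lung_semi[1])):
            root = np.array(
                [
                    center[0] + rng.uniform(-2, 2),
                    center[1] + y_off + rng.uniform(-1.5, 1.5),
                    center[2] - 0.75 * lung_semi[2] + rng.uniform(-2, 2),
                ]
            )
            if side == "ant":
                y_range = (center[1] - lung_semi[1], center[1] + 0.02 * lung_semi[1])
            else:
                y_range = (center[1] + 0.18 * lung_semi[1], center[1] + lung_semi[1])
            tilt = _rotate(down, np.array([1.0, 0.0, 0.0]), np.deg2rad(rng.uniform(-8, 8)))
            segs_t = _grow_tree(root, tilt, tid, params, rng, y_range)
            segs.extend(segs_t)
            tree_meta.append((tid, lung_name, side))
            tid += 1

    # --- dose: Gaussian falloff centred on the right-anterior root ----------
    target_tree = next(t for t, lung_name, side in tree_meta if lung_name == "R" and side == "ant")
    root_seg = next(s for s in segs if s.tree == target_tree and s.generation == 0)
    dose_center = (root_seg.start + root_seg.end) / 2.0

    def dose_at(points_mm: np.ndarray) -> np.ndarray:
        d2 = ((np.asarray(points_mm) - dose_center) ** 2).sum(axis=-1)
        return params.dose_max_gy * np.exp(-d2 / (2.0 * params.dose_sigma_mm**2))

    world = np.moveaxis(
        np.indices(shape, dtype=float) * np.reshape(sp, (3, 1, 1, 1)), 0, -1
    )
    dose_grid = dose_at(world)

    # --- masks ---------------------------------------------------------------
    vessels_pre = _raster_segments(segs, shape, sp) & lung
    large = (
        _raster_segments([s for s in segs if s.r_start >= params.large_vessel_radius_mm], shape, sp)
        & lung
    )

    atrophy = params.atrophy_by_bin

    def radius_scale(points_mm: np.ndarray) -> np.ndarray:
        d = dose_at(points_mm)
        f = np.empty(d.shape)
        f.fill(1.0 - atrophy["no"])
        f[d >= 5.0] = 1.0 - atrophy["low"]
        f[d >= 20.0] = 1.0 - atrophy["medium"]
        f[d >= 40.0] = 1.0 - atrophy["high"]
        return f

    vessels_post_pf = _raster_segments(segs, shape, sp, radius_scale) & lung  # pre frame
    vessels_post_pf &= vessels_pre  # atrophy only removes

    # --- damage region (pre frame, kept clear of the lung boundary) ---------
    interior = ndimage.binary_erosion(lung, iterations=4)
    damage_pf = ndimage.binary_dilation((dose_grid >= params.damage_dose_gy) & lung, iterations=2)
    damage_pf &= interior

    # --- CT images (pre frame) ----------------------------------------------
    ct_pre = np.full(shape, -1000.0)
    ct_pre[body] = params.body_hu
    ct_pre[lung] = params.lung_hu
    ct_pre[vessels_pre] = params.vessel_hu

    # post-RT structural image in the pre frame (damage is painted after
    # warping so its texture statistics stay crisp in the post frame)
    ct_post_pf = np.full(shape, -1000.0)
    ct_post_pf[body] = params.body_hu
    ct_post_pf[lung] = params.lung_hu
    ct_post_pf[vessels_post_pf] = params.vessel_hu

    ggr_rng = np.random.default_rng(int(rng.integers(2**31)))

    tex_pf = np.zeros(shape, dtype=np.int16)
    tex_pf[lung] = int(TextureClass.NORMAL)
    tex_pf[damage_pf] = int(TextureClass.GROUND_GLASS_RETICULAR)

    ct_pre += params.noise_sd_hu * rng.standard_normal(shape)
    noise_post = params.noise_sd_hu * rng.standard_normal(shape)

    # --- synthetic deformation ----------------------------------------------
    bumps = []
    for _ in range(params.n_deform_bumps):
        if params.deform_max_mm <= 0:
            break
        center = rng.uniform(0.25, 0.75, size=3) * extent
        amp = rng.uniform(-1.0, 1.0, size=3)
        amp *= params.deform_max_mm / max(np.linalg.norm(amp), 1e-9) * rng.uniform(0.5, 1.0)
        bumps.append((center, amp, params.deform_sigma_mm))

    def v_of(points_mm: np.ndarray) -> np.ndarray:
        """Post-frame sampling displacement: post(y) = pre(y + v(y))."""
        out = np.zeros_like(points_mm)
        for center, amp, sigma in bumps:
            w = np.exp(-((points_mm - center) ** 2).sum(axis=-1) / (2.0 * sigma**2))
            out += w[..., None] * amp
        return out

    v_grid = v_of(world)
    sample_idx = np.moveaxis((world + v_grid) / np.asarray(sp), -1, 0)

    def deform(arr, order):
        return ndimage.map_coordinates(
            arr.astype(float), sample_idx, order=order, mode="nearest"
        )

    if bumps:
        ct_post = deform(ct_post_pf, 1)
        vessels_post = deform(vessels_post_pf, 0).astype(bool)
        damage = deform(damage_pf, 0).astype(bool)
        tex_post = deform(tex_pf, 0).astype(np.int16)
    else:
        ct_post = ct_post_pf.copy()
        vessels_post = vessels_post_pf
        damage = damage_pf
        tex_post = tex_pf
    # radiation-induced change painted in the post frame (sparing vessels)
    ggr = _texture_field(
        TextureClass.GROUND_GLASS_RETICULAR, shape, ggr_rng, {"mean": params.damage_hu_mean}
    )
    paint = damage & ~vessels_post
    ct_post[paint] = ggr[paint]
    ct_post += noise_post

    # true field (pre -> post positions) by fixed-point inversion of v
    u = np.zeros_like(world)
    for _ in range(10):
        u = -v_of(world + u)

    # --- fed / not-fed / contralateral truth --------------------------------
    fed_trees = set()
    for s in segs:
        mid = (s.start + s.end) / 2.0
        if max(dose_at(mid[None, :])[0], dose_at(s.start[None, :])[0]) >= 40.0:
            fed_trees.add(s.tree)
    centerline_tree = np.full(shape, -1, dtype=np.int16)
    for s in segs:
        n = max(int(np.linalg.norm(s.end - s.start) / min(sp)) * 2, 2)
        t = np.linspace(0, 1, n)
        pts = s.start + t[:, None] * (s.end - s.start)
        ijk = np.rint(pts / np.asarray(sp)).astype(int)
        ok = ((ijk >= 0) & (ijk < np.asarray(shape))).all(axis=1)
        ijk = ijk[ok]
        centerline_tree[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = s.tree
    right_trees = {t for t, lung_name, _ in tree_meta if lung_name == "R"}
    cl_right = np.isin(centerline_tree, list(right_trees)) & (centerline_tree >= 0)
    fed_lab = np.zeros(shape, dtype=np.int16)
    if cl_right.any():
        _, idx = ndimage.distance_transform_edt(~cl_right, sampling=sp, return_indices=True)
        nearest_tree = centerline_tree[tuple(i for i in idx)]
        is_fed = np.isin(nearest_tree, list(fed_trees & right_trees))
        fed_lab[lung_r] = np.where(is_fed[lung_r], 1, 2)
    fed_lab[lung_l] = 3

    # --- programmed perfusion change per analysis region --------------------
    bin_index = np.digitize(dose_grid, DOSE_BIN_EDGES[1:-1])  # 0..3
    perfusion = {}
    for region in REGION_NAMES:
        if region == "contralateral":
            sel = lung_l
            fed_flag = 0.0
        else:
            fed_name, bin_name = region.rsplit("_", 1) if region.startswith("fed") else (
                "not_fed",
                region.split("not_fed_")[1],
            )
            lab = 1 if fed_name == "fed" else 2
            sel = (fed_lab == lab) & (bin_index == DOSE_BIN_NAMES.index(bin_name))
            fed_flag = 1.0 if lab == 1 else 0.0
        mean_dose = float(dose_grid[sel].mean()) if sel.any() else 0.0
        perfusion[region] = (
            params.perf_per_gy * mean_dose + params.perf_fed_offset * fed_flag + params.perf_base
        )

    atrophy_truth = {
        b: 100.0 * ((1.0 - f) ** 2 - 1.0) for b, f in params.atrophy_by_bin.items()
    }

    mk = lambda d: BinaryMask(d.astype(np.uint8), sp, (0.0, 0.0, 0.0))
    return PhantomCase(
        ct_pre=VolumeImage(ct_pre, sp, (0, 0, 0), ValueKind.HU),
        ct_post=VolumeImage(ct_post, sp, (0, 0, 0), ValueKind.HU),
        dose=VolumeImage(dose_grid, sp, (0, 0, 0), ValueKind.DOSE),
        lung_truth=mk(lung),
        vessel_truth_pre=mk(vessels_pre),
        vessel_truth_post=mk(vessels_post),
        large_vessel_truth=mk(large),
        damage_truth=mk(damage),
        texture_truth=LabelMap(tex_post, sp, (0, 0, 0), {int(c): c.name.lower() for c in TextureClass}),
        field_true=DisplacementField(u, sp, (0, 0, 0)),
        fed_truth=LabelMap(fed_lab, sp, (0, 0, 0), dict(FED_LABELS)),
        perfusion_change_truth=perfusion,
        atrophy_truth=atrophy_truth,
        params=params,
    )


def analytic_tree_volume_ml(params: PhantomParams) -> float:
    """Closed-form total tube-tree volume for the case's tree system.

    Regenerates the tree geometry with the case's seed and sums the
    conical-frustum volumes of all segments.
    """
    case_segs = _regenerate_segments(params)
    return _frustum_volume_ml(case_segs)


def _regenerate_segments(params: PhantomParams) -> list[_Segment]:
    """Replay the generator's RNG stream far enough to rebuild the tree geometry."""
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.grid_shape)
    sp = tuple(params.spacing_mm)
    extent = np.asarray(shape) * np.asarray(sp)
    c = extent / 2.0
    lung_semi = extent * np.array([0.16, 0.19, 0.31])
    right_center = c + np.array([0.21 * extent[0], 0.0, 0.0])
    left_center = c - np.array([0.21 * extent[0], 0.0, 0.0])
    down = np.array([0.0, 0.0, 1.0])
    segs: list[_Segment] = []
    tid = 0
    for lung_name, center in (("R", right_center), ("L", left_center)):
        for side, y_off in (("ant", -0.35 * lung_semi[1]), ("post", 0.45 * lung_semi[1])):
            root = np.array(
                [
                    center[0] + rng.uniform(-2, 2),
                    center[1] + y_off + rng.uniform(-1.5, 1.5),
                    center[2] - 0.75 * lung_semi[2] + rng.uniform(-2, 2),
                ]
            )
            if side == "ant":
                y_range = (center[1] - lung_semi[1], center[1] + 0.02 * lung_semi[1])
            else:
                y_range = (center[1] + 0.18 * lung_semi[1], center[1] + lung_semi[1])
            tilt = _rotate(down, np.array([1.0, 0.0, 0.0]), np.deg2rad(rng.uniform(-8, 8)))
            segs.extend(_grow_tree(root, tilt, tid, params, rng, y_range))
            tid += 1
    return segs


# ---------------------------------------------------------------------------
# Case directory I/O
# ---------------------------------------------------------------------------

_VOLUMES = {"ct_pre": ValueKind.HU, "ct_post": ValueKind.HU, "dose": ValueKind.DOSE}
_MASKS = (
    "lung_truth",
    "vessel_truth_pre",
    "vessel_truth_post",
    "large_vessel_truth",
    "damage_truth",
)


def write_case(case: PhantomCase, out_dir) -> None:
    """Write a case directory of NIfTI files plus a JSON manifest."""
    os.makedirs(out_dir, exist_ok=True)
    manifest = {"files": {}, "params": asdict(case.params)}
    for name in _VOLUMES:
        path = os.path.join(out_dir, f"{name}.nii.gz")
        write_volume(getattr(case, name), path)
        manifest["files"][name] = f"{name}.nii.gz"
    for name in _MASKS:
        path = os.path.join(out_dir, f"{name}.nii.gz")
        write_mask(getattr(case, name), path)
        manifest["files"][name] = f"{name}.nii.gz"
    write_volume(
        VolumeImage(case.texture_truth.data.astype(float), case.ct_pre.spacing, case.ct_pre.origin),
        os.path.join(out_dir, "texture_truth.nii.gz"),
    )
    write_volume(
        VolumeImage(case.fed_truth.data.astype(float), case.ct_pre.spacing, case.ct_pre.origin),
        os.path.join(out_dir, "fed_truth.nii.gz"),
    )
    write_field(case.field_true, os.path.join(out_dir, "field_true.nii.gz"))
    manifest["files"]["texture_truth"] = "texture_truth.nii.gz"
    manifest["files"]["fed_truth"] = "fed_truth.nii.gz"
    manifest["files"]["field_true"] = "field_true.nii.gz"
    manifest["perfusion_change_truth"] = case.perfusion_change_truth
    manifest["atrophy_truth"] = case.atrophy_truth
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_case(case_dir) -> PhantomCase:
    """Read a case directory written by :func:`write_case`."""
    with open(os.path.join(case_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    p = manifest["params"]
    for key in ("grid_shape", "spacing_mm"):
        p[key] = tuple(p[key])
    params = PhantomParams(**p)
    f = lambda name: os.path.join(case_dir, manifest["files"][name])
    sp = params.spacing_mm
    tex = read_volume(f("texture_truth"))
    fed = read_volume(f("fed_truth"))
    return PhantomCase(
        ct_pre=read_volume(f("ct_pre"), ValueKind.HU),
        ct_post=read_volume(f("ct_post"), ValueKind.HU),
        dose=read_volume(f("dose"), ValueKind.DOSE),
        lung_truth=read_mask(f("lung_truth")),
        vessel_truth_pre=read_mask(f("vessel_truth_pre")),
        vessel_truth_post=read_mask(f("vessel_truth_post")),
        large_vessel_truth=read_mask(f("large_vessel_truth")),
        damage_truth=read_mask(f("damage_truth")),
        texture_truth=LabelMap(
            np.rint(tex.data).astype(np.int16), sp, (0, 0, 0),
            {int(c): c.name.lower() for c in TextureClass},
        ),
        field_true=read_field(f("field_true")),
        fed_truth=LabelMap(np.rint(fed.data).astype(np.int16), sp, (0, 0, 0), dict(FED_LABELS)),
        perfusion_change_truth=manifest["perfusion_change_truth"],
        atrophy_truth=manifest["atrophy_truth"],
        params=params,
    )
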