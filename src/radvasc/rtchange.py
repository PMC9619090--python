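"""Post-radiotherapy vascular-change quantification and statistics.

Vessel volume is compared pre vs post treatment inside dose bins
(no < 5 Gy, low 5-20, medium 20-40, high >= 40) and inside fed / not-fed /
contralateral lung territories, with the post-RT mask warped into the
pre-RT frame first.  Percent change per region is

    dVesselVolume% = (V_post - V_pre) / V_pre * 100%

and region-wise mean changes are correlated against perfusion changes by
ordinary least squares.  A published five-subject swine SBRT cohort
summary (seven analysis regions: fed and not-fed at no/low/medium dose,
plus the contralateral lung) ships with the module as the reference input
for the correlation worked example.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.morphology import skeletonize

from .imgrid import BinaryMask, GridMismatchError, LabelMap, VolumeImage, mask_volume_ml

__all__ = [
    "DoseBinning",
    "ChangeRecord",
    "RegionPartition",
    "CorrelationResult",
    "PairedTResult",
    "COHORT_REGION_MEANS",
    "percent_change",
    "dose_bin_change",
    "region_change",
    "fed_partition",
    "paired_t",
    "fit_line_r2",
    "dose_response_summary",
]


@dataclass
class DoseBinning:
    """Dose bins in Gy with display names and bin-center plotting positions."""

    edges_gy: tuple = (0.0, 5.0, 20.0, 40.0, np.inf)
    names: tuple = ("no", "low", "medium", "high")
    centers_gy: tuple = (2.5, 12.5, 30.0, 50.0)

    def __post_init__(self):
        e = np.asarray(self.edges_gy)
        if not (np.diff(e) > 0).all():
            raise ValueError("bin edges must be strictly increasing")
        for c, lo, hi in zip(self.centers_gy, e[:-1], e[1:]):
            if not (lo <= c < hi or (np.isinf(hi) and c >= lo)):
                raise ValueError(f"center {c} outside its bin [{lo},{hi})")

    def index_map(self, dose: np.ndarray) -> np.ndarray:
        return np.digitize(dose, np.asarray(self.edges_gy)[1:-1])


@dataclass
class ChangeRecord:
    """Pre/post vessel volume and percent change in one analysis region."""

    region_label: str
    volume_pre_ml: float
    volume_post_ml: float
    pct_change: float | None
    n_voxels_pre: int
    n_voxels_post: int
    empty_pre: bool = False  # flagged: no pre-RT vessel in the region


@dataclass
class RegionPartition:
    """fed / not-fed / contralateral territories over the lung."""

    labels: LabelMap
    seeded: bool = True  # False when no skeleton voxel reached the seed dose

    NAMES = {1: "fed", 2: "not_fed", 3: "contralateral"}

    def mask(self, name: str) -> BinaryMask:
        inv = {v: k for k, v in self.NAMES.items()}
        return self.labels.mask_of(inv[name])


@dataclass
class CorrelationResult:
    slope: float
    intercept: float
    r_squared: float
    pairs: list

    def __post_init__(self):
        if not (-1e-9 <= self.r_squared <= 1 + 1e-9):
            raise ValueError("r_squared outside [0,1]")


@dataclass
class PairedTResult:
    t: float
    p: float
    n: int
    degenerate: bool = False


#: Published cohort means per analysis region: percent vessel-volume change
#: and percent perfusion change (five-subject swine SBRT study, 5 x 12 Gy).
COHORT_REGION_MEANS = pd.DataFrame(
    {
        "region": [
            "no_dose_fed",
            "low_dose_fed",
            "mid_dose_fed",
            "no_dose_not_fed",
            "low_dose_not_fed",
            "mid_dose_not_fed",
            "contralateral",
        ],
        "vessel_change_pct": [-24.6, -24.9, -33.7, -4.0, -6.0, -9.1, -3.8],
        "perfusion_change_pct": [-55.0, -65.0, -55.7, -36.0, -24.0, -21.2, -5.0],
    }
)


def percent_change(pre_ml: float, post_ml: float) -> float:
    """Percent vessel-volume change: 100 * (post - pre) / pre."""
    if pre_ml <= 0:
        raise ValueError("pre-RT volume must be positive for a percent change")
    # evaluated as 100*post/pre - 100: exact for decimally-round ratios
    return 100.0 * post_ml / pre_ml - 100.0


def _record(label, pre_mask: BinaryMask, post_mask: BinaryMask, sel: np.ndarray) -> ChangeRecord:
    npre = int((pre_mask.data & sel).sum())
    npost = int((post_mask.data & sel).sum())
    vox_ml = float(np.prod(pre_mask.spacing)) / 1000.0
    vpre, vpost = npre * vox_ml, npost * vox_ml
    if npre == 0:
        return ChangeRecord(label, vpre, vpost, None, npre, npost, empty_pre=True)
    return ChangeRecord(label, vpre, vpost, percent_change(vpre, vpost), npre, npost)


def dose_bin_change(
    vessel_pre: BinaryMask,
    vessel_post_warped: BinaryMask,
    dose: VolumeImage,
    bins: DoseBinning | None = None,
    restrict: BinaryMask | None = None,
) -> list[ChangeRecord]:
    """Per-dose-bin vessel volumes and percent changes (post already in pre frame)."""
    bins = bins or DoseBinning()
    if vessel_pre.shape != vessel_post_warped.shape or vessel_pre.shape != dose.shape:
        raise GridMismatchError("vessel masks and dose grid must share a grid")
    sel_base = np.ones(vessel_pre.shape, dtype=bool)
    if restrict is not None:
        sel_base = restrict.data
    bin_idx = bins.index_map(np.asarray(dose.data))
    return [
        _record(name, vessel_pre, vessel_post_warped, sel_base & (bin_idx == b))
        for b, name in enumerate(bins.names)
    ]


def region_change(
    vessel_pre: BinaryMask,
    vessel_post_warped: BinaryMask,
    dose: VolumeImage,
    partition: RegionPartition,
    bins: DoseBinning | None = None,
) -> list[ChangeRecord]:
    """The seven-region analysis: fed/not-fed x no/low/medium dose + contralateral."""
    bins = bins or DoseBinning()
    bin_idx = bins.index_map(np.asarray(dose.data))
    lab = partition.labels.data
    records = []
    for fed_name, lab_val in (("fed", 1), ("not_fed", 2)):
        for b, bin_name in enumerate(bins.names[:3]):
            sel = (lab == lab_val) & (bin_idx == b)
            records.append(
                _record(f"{fed_name}_{bin_name}", vessel_pre, vessel_post_warped, sel)
            )
    records.append(_record("contralateral", vessel_pre, vessel_post_warped, lab == 3))
    return records


def fed_partition(
    vessel_pre: BinaryMask,
    dose: VolumeImage,
    lung: BinaryMask,
    rx_threshold_gy: float = 40.0,
    contralateral_max_gy: float = 5.0,
) -> RegionPartition:
    """Partition the lung into fed / not-fed / contralateral territories.

    The pre-RT vessel mask is skeletonized; skeleton voxels receiving at
    least the prescription threshold seed the fed set, which grows along
    26-connected skeleton paths.  Every ipsilateral lung voxel takes the
    label of its nearest skeleton voxel (Euclidean territories); the lung
    component whose dose stays below ``contralateral_max_gy`` everywhere
    is the contralateral control.
    """
    if vessel_pre.shape != dose.shape or vessel_pre.shape != lung.shape:
        raise GridMismatchError("masks and dose must share a grid")
    skel = skeletonize(vessel_pre.data)
    dose_arr = np.asarray(dose.data)
    lab = np.zeros(lung.shape, dtype=np.int16)

    # contralateral = connected lung components never exceeding the cap
    lung_cc, n_cc = ndimage.label(lung.data)
    contra = np.zeros(lung.shape, dtype=bool)
    for comp in range(1, n_cc + 1):
        m = lung_cc == comp
        if dose_arr[m].max() < contralateral_max_gy:
            contra |= m
    ipsi = lung.data & ~contra

    seeds = skel & (dose_arr >= rx_threshold_gy)
    seeded = bool(seeds.any())
    fed_skel = np.zeros_like(skel)
    if seeded:
        skel_cc, _ = ndimage.label(skel, structure=np.ones((3, 3, 3)))
        fed_ids = np.unique(skel_cc[seeds])
        fed_ids = fed_ids[fed_ids != 0]
        fed_skel = np.isin(skel_cc, fed_ids)
    if skel.any():
        _, idx = ndimage.distance_transform_edt(
            ~skel, sampling=vessel_pre.spacing, return_indices=True
        )
        nearest_is_fed = fed_skel[tuple(i for i in idx)]
        lab[ipsi] = np.where(nearest_is_fed[ipsi], 1, 2)
    else:
        lab[ipsi] = 2
    lab[contra] = 3
    return RegionPartition(
        labels=LabelMap(lab, vessel_pre.spacing, vessel_pre.origin, dict(RegionPartition.NAMES)),
        seeded=seeded,
    )


def paired_t(pre_vols, post_vols) -> PairedTResult:
    """Classical paired two-tailed t-test on per-subject volumes.

    Zero-variance differences are flagged: all-zero differences give
    t = 0, p = 1; constant nonzero differences are degenerate.
    """
    pre = np.asarray(pre_vols, dtype=float)
    post = np.asarray(post_vols, dtype=float)
    if pre.shape != post.shape or pre.size < 2:
        raise ValueError("need equal-length paired samples with n >= 2")
    d = post - pre
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if (d == 0).all():
            return PairedTResult(0.0, 1.0, n, degenerate=False)
        return PairedTResult(np.inf if d.mean() > 0 else -np.inf, 0.0, n, degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedTResult(float(t), float(p), n)


def fit_line_r2(x, y) -> CorrelationResult:
    """Ordinary least squares with r^2 = Sxy^2 / (Sxx Syy)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; the fit is degenerate")
    res = stats.linregress(x, y)
    return CorrelationResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        pairs=list(zip(x.tolist(), y.tolist())),
    )


def dose_response_summary(
    records_per_subject: list[list[ChangeRecord]],
    bins: DoseBinning | None = None,
) -> tuple[pd.DataFrame, CorrelationResult | None]:
    """Cohort mean/sd of percent change per dose bin plus the linear dose fit.

    Each inner list holds one subject's per-bin records.  Bins with no
    valid (non-empty-pre) subject are omitted from the OLS of mean change
    against bin centers; the fit is None when fewer than 3 bins survive or
    all changes are zero.
    """
    bins = bins or DoseBinning()
    rows = []
    for b, name in enumerate(bins.names):
        vals = []
        for recs in records_per_subject:
            rec = next((r for r in recs if r.region_label == name), None)
            if rec is not None and not rec.empty_pre:
                vals.append(rec.pct_change)
        if vals:
            rows.append(
                {
                    "bin": name,
                    "center_gy": bins.centers_gy[b],
                    "mean_pct_change": float(np.mean(vals)),
                    "sd_pct_change": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                    "n_subjects": len(vals),
                    "single_subject": len(vals) == 1,
                }
            )
    table = pd.DataFrame(rows)
    fit = None
    if len(table) >= 3 and np.ptp(table["center_gy"]) > 0:
        if np.allclose(table["mean_pct_change"], 0.0):
            fit = CorrelationResult(0.0, 0.0, 0.0, list(zip(table["center_gy"], table["mean_pct_change"])))
        else:
            fit = fit_line_r2(table["center_gy"].to_numpy(), table["mean_pct_change"].to_numpy())
    return table, fit
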