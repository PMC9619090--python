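"""Lung, aerated-lung and large-vessel masking.

The filled lung mask is obtained classically (HU threshold inside the body,
largest components, morphological closing that fills vessels and smooths
the mediastinal boundary); an externally supplied lung mask can be used
instead for real data.  Well-aerated lung is found by iterative optimal
thresholding (Ridler-Calvard) of the in-lung HU histogram plus light
morphology; the large-vessel mask is the lung minus its aerated part.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .imgrid import BinaryMask, GridMismatchError, VolumeImage, mask_ops

__all__ = [
    "SegmentationError",
    "segment_lungs_filled",
    "aerated_mask",
    "large_vessel_mask",
    "ridler_calvard_threshold",
]


class SegmentationError(RuntimeError):
    """No plausible lung found in the image."""


def _keep_largest(mask: np.ndarray, n: int, min_frac: float) -> np.ndarray:
    lab, nlab = ndimage.label(mask)
    if nlab == 0:
        return np.zeros_like(mask)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    order = np.argsort(sizes)[::-1]
    keep = [order[0]]
    for cand in order[1 : n]:
        if sizes[cand] >= min_frac * mask.size:
            keep.append(cand)
    return np.isin(lab, keep)


def segment_lungs_filled(
    ct: VolumeImage,
    lung_threshold_hu: float = -500.0,
    closing_radius: int = 5,
    min_component_frac: float = 0.01,
) -> BinaryMask:
    """Filled lung mask: air-like voxels inside the body, closed with a ball.

    Voxels below the HU threshold *inside* the body (exterior air is
    excluded by hole-filling the body) seed the mask; the two largest
    components are kept (one if the second is below 1% of the grid) and a
    ball closing fills the vessels and smooths the mediastinal boundary.
    """
    data = np.asarray(ct.data, dtype=float)
    body = ndimage.binary_fill_holes(data > lung_threshold_hu)
    cand = (data < lung_threshold_hu) & body
    lungs = _keep_largest(cand, 2, min_component_frac)
    if not lungs.any():
        raise SegmentationError("no lung-like component below the threshold inside the body")
    closed = ndimage.binary_closing(lungs, structure=ball(closing_radius))
    return BinaryMask.from_image(ct, closed)


def ridler_calvard_threshold(
    values: np.ndarray,
    tol_hu: float = 0.5,
    max_iter: int = 100,
    min_separation_hu: float = 50.0,
):
    """Iterative optimal threshold: t <- mean of the two class means.

    Starts at the median; returns (threshold, converged).  ``converged`` is
    False when one class empties or the converged class means sit closer
    than ``min_separation_hu`` (a unimodal histogram: the iteration then
    merely splits one mode at its median).
    """
    v = np.asarray(values, dtype=float)
    t = float(np.median(v))
    for _ in range(max_iter):
        lo = v[v < t]
        hi = v[v >= t]
        if lo.size == 0 or hi.size == 0:
            return t, False
        t_new = 0.5 * (lo.mean() + hi.mean())
        if abs(t_new - t) < tol_hu:
            if hi.mean() - lo.mean() < min_separation_hu:
                return t_new, False
            return t_new, True
        t = t_new
    return t, True


def aerated_mask(
    ct: VolumeImage,
    lung: BinaryMask,
    morph_radius: int = 1,
    max_hole_voxels: int = 30,
) -> BinaryMask:
    """Well-aerated lung by Ridler-Calvard thresholding plus morphology.

    Below-threshold in-lung voxels are opened then closed with a small
    ball and holes below ``max_hole_voxels`` are filled.  If the in-lung
    histogram is unimodal (threshold collapse) the entire lung is returned
    with a warning.
    """
    if ct.shape != lung.shape:
        raise GridMismatchError("CT and lung mask shapes differ")
    inlung = lung.data
    t, ok = ridler_calvard_threshold(np.asarray(ct.data, dtype=float)[inlung])
    if not ok:
        warnings.warn("unimodal in-lung histogram: aerated mask equals the lung mask")
        return lung.like(inlung.copy())
    aer = (np.asarray(ct.data) < t) & inlung
    st = ball(morph_radius)
    aer = ndimage.binary_opening(aer, structure=st)
    aer = ndimage.binary_closing(aer, structure=st)
    # fill small holes only
    holes = ~aer
    lab, nlab = ndimage.label(holes)
    if nlab:
        sizes = np.bincount(lab.ravel())
        small = np.flatnonzero(sizes <= max_hole_voxels)
        small = small[small != 0]
        aer |= np.isin(lab, small)
    aer &= inlung
    return lung.like(aer)


def large_vessel_mask(
    lung: BinaryMask,
    aerated: BinaryMask,
    min_component_voxels: int = 20,
    dilate_voxels: int = 0,
) -> BinaryMask:
    """Large vasculature: lung minus aerated, minus sub-threshold speckle.

    With ``dilate_voxels`` > 0 the surviving components are dilated
    (clipped to the lung): the aerated-mask morphology erodes the
    partial-volume shell of large vessels, and the combined workflow asks
    for one shell voxel back when it restores large vasculature.
    """
    diff = mask_ops(lung, aerated, "subtract")
    lab, nlab = ndimage.label(diff.data)
    if nlab == 0:
        return diff
    sizes = np.bincount(lab.ravel())
    keep = np.flatnonzero(sizes >= min_component_voxels)
    keep = keep[keep != 0]
    out = np.isin(lab, keep)
    if dilate_voxels:
        out = ndimage.binary_dilation(out, iterations=dilate_voxels) & lung.data
    return lung.like(out)
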