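"""The combined vessel-segmentation workflow.

Threshold the vessel probability map (strictly p > t), delete thresholded
voxels whose texture class marks radiation-induced change (ground glass
reticular / bronchovascular by default), then union the large-vessel mask
recovered from the lung/aerated difference.  The texture veto is what makes
the segmentation specific inside radiographically damaged lung; the
large-vessel re-addition restores the sensitivity the veto costs on big
vessels.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .amfm import AmfmConfig, BayesTextureModel, TextureClass, TextureMap, classify_textures
from .imgrid import BinaryMask, GridMismatchError, ValueKind, VolumeImage, mask_ops
from .lungmask import aerated_mask, large_vessel_mask, segment_lungs_filled
from .vesselprob import (
    PatchDictionary,
    VesselClassifier,
    hessian_vesselness,
    predict_probability,
)

__all__ = ["WorkflowConfig", "VesselSegResult", "threshold_prob", "remove_texture_fp", "run_workflow"]

DEFAULT_REMOVAL_CLASSES = frozenset(
    {TextureClass.GROUND_GLASS_RETICULAR, TextureClass.BRONCHOVASCULAR}
)


@dataclass
class WorkflowConfig:
    """Operating point and backend selection for the full workflow."""

    prob_threshold: float = 0.4
    removal_classes: frozenset = DEFAULT_REMOVAL_CLASSES
    backend: str = "feature_learning"  # or "vesselness"
    stride: int = 1
    #: dilation (voxels) of the large-vessel mask before re-addition, to
    #: recover the partial-volume shell the aerated morphology erodes
    large_shell_voxels: int = 1
    vesselness_scales_mm: tuple = (1.0, 2.0, 3.0)
    amfm: AmfmConfig = field(default_factory=AmfmConfig)

    def __post_init__(self):
        if not (0.0 < self.prob_threshold < 1.0):
            raise ValueError("prob_threshold must be in (0,1)")
        if not self.removal_classes:
            raise ValueError("removal_classes must be non-empty")
        if self.backend not in ("feature_learning", "vesselness"):
            raise ValueError(f"unknown backend {self.backend!r}")


@dataclass
class VesselSegResult:
    """All intermediate and final masks of one workflow run.

    Invariants (asserted by construction): refined <= raw,
    final = refined | large, final <= lung.
    """

    prob: VolumeImage
    raw_mask: BinaryMask
    refined_mask: BinaryMask
    large_mask: BinaryMask
    final_mask: BinaryMask
    texture: TextureMap
    lung_mask: BinaryMask
    aerated_mask: BinaryMask
    provenance: dict


def threshold_prob(prob: VolumeImage, t: float = 0.4) -> BinaryMask:
    """Voxels with probability strictly greater than t."""
    if not (0.0 < t < 1.0):
        raise ValueError("threshold must be in (0,1)")
    return BinaryMask.from_image(prob, np.asarray(prob.data) > t)


def remove_texture_fp(raw: BinaryMask, texture: TextureMap, removal) -> BinaryMask:
    """Clear raw-vessel voxels whose texture label is a removal class."""
    if raw.shape != texture.shape:
        raise GridMismatchError("mask and texture map shapes differ")
    bad = np.isin(texture.data, [int(c) for c in removal])
    return raw.like(raw.data & ~bad)


def run_workflow(
    ct: VolumeImage,
    config: WorkflowConfig | None = None,
    dictionary: PatchDictionary | None = None,
    classifier: VesselClassifier | None = None,
    texture_model: BayesTextureModel | None = None,
    external_lung_mask: BinaryMask | None = None,
) -> VesselSegResult:
    """Run probability map -> threshold -> texture veto -> large-vessel union.

    The final mask is clipped to the filled lung mask.  Stage failures
    propagate with the stage name attached.
    """
    config = config or WorkflowConfig()
    timings = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:
            raise RuntimeError(f"workflow stage {name!r} failed: {exc}") from exc
        timings[name] = time.perf_counter() - t0
        return out

    lung = external_lung_mask or stage("lungmask", lambda: segment_lungs_filled(ct))
    if config.backend == "feature_learning":
        if dictionary is None or classifier is None:
            raise ValueError("feature_learning backend needs a trained dictionary and classifier")
        prob = stage(
            "vesselprob", lambda: predict_probability(ct, dictionary, classifier, config.stride)
        )
    else:
        prob = stage("vesselness", lambda: hessian_vesselness(ct, config.vesselness_scales_mm))
    if texture_model is None:
        raise ValueError("workflow needs a trained texture model")
    raw = stage("threshold", lambda: threshold_prob(prob, config.prob_threshold))
    texture = stage("amfm", lambda: classify_textures(ct, lung, texture_model, config.amfm))
    refined = stage("texture_veto", lambda: remove_texture_fp(raw, texture, config.removal_classes))
    aer = stage("aerated", lambda: aerated_mask(ct, lung))
    large = stage(
        "large_vessels",
        lambda: large_vessel_mask(lung, aer, dilate_voxels=config.large_shell_voxels),
    )
    # the stored aerated mask cedes the large-vessel shell so that the
    # aerated / large-vessel masks partition the non-parenchymal lung
    aer = mask_ops(aer, large, "subtract")
    refined_in_lung = mask_ops(refined, lung, "intersect")
    final = mask_ops(refined_in_lung, large, "union")
    return VesselSegResult(
        prob=prob,
        raw_mask=raw,
        refined_mask=refined_in_lung,
        large_mask=large,
        final_mask=final,
        texture=texture,
        lung_mask=lung,
        aerated_mask=aer,
        provenance={
            "prob_threshold": config.prob_threshold,
            "removal_classes": sorted(int(c) for c in config.removal_classes),
            "backend": config.backend,
            "timings_s": timings,
        },
    )
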