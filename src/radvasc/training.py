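"""Standard model-building recipes for the phantom-trained workflow.

Training data comes from the phantom generator: the vessel
dictionary/classifier learn from a phantom pre-RT CT with its vessel truth
as labels, and the texture model learns from labelled texture patches.
The CLI, the test suite and the acceptance script all build their models
through these functions.
"""

from __future__ import annotations

import numpy as np

from . import amfm, phantom, vesselprob

__all__ = ["train_vessel_model", "train_texture_model", "default_models"]


def train_vessel_model(
    case: "phantom.PhantomCase",
    seed: int = 0,
    n_per_class: int = 3000,
    sample_stride: int = 2,
):
    """Dictionary + logistic classifier from one phantom case's pre-RT study.

    Patches are learned inside the true lung; the classifier trains on a
    balanced sample of vessel / non-vessel lung voxels on the sampling
    stride grid, labelled by the case's vessel truth.
    """
    dic = vesselprob.learn_dictionary([case.ct_pre], [case.lung_truth], seed=seed)
    feats, _ = vesselprob.encode(case.ct_pre, dic, sample_stride)
    s = sample_stride
    vessel = case.vessel_truth_pre.data[::s, ::s, ::s].ravel()
    lung = case.lung_truth.data[::s, ::s, ::s].ravel()
    rng = np.random.default_rng(seed)
    vi = np.flatnonzero(vessel)
    ni = np.flatnonzero(lung & ~vessel.astype(bool))
    pick_v = rng.choice(vi, n_per_class, replace=vi.size < n_per_class)
    pick_n = rng.choice(ni, n_per_class, replace=ni.size < n_per_class)
    x = np.concatenate([feats[pick_v], feats[pick_n]])
    y = np.concatenate([np.ones(n_per_class), np.zeros(n_per_class)])
    clf = vesselprob.train_classifier(x, y, seed=seed)
    return dic, clf


def train_texture_model(
    seed: int = 0, n_per_class: int = 100, cfg: amfm.AmfmConfig | None = None
) -> amfm.BayesTextureModel:
    """Bayes texture model from generator-labelled patches."""
    patches = phantom.texture_training_set(n_per_class=n_per_class, seed=seed)
    return amfm.train_from_patches(patches, cfg)


def default_models(seed: int = 0):
    """The standard trio (dictionary, classifier, texture model).

    The vessel model trains on a phantom whose seed is offset from the
    evaluation seeds so train and test cases never coincide.
    """
    train_case = phantom.generate_case(phantom.PhantomParams(seed=seed + 9000))
    dic, clf = train_vessel_model(train_case, seed=seed)
    bayes = train_texture_model(seed=seed + 1)
    return dic, clf, bayes
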