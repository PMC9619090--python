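import numpy as np
import pytest

from radvasc import vesselprob
from radvasc.imgrid import BinaryMask, ValueKind, VolumeImage
from radvasc.vesselprob import (
    PatchDictionary,
    VesselClassifier,
    encode,
    hessian_vesselness,
    learn_dictionary,
    predict_probability,
    train_classifier,
)


def _line_volume(axis, shape=(24, 24, 24), spacing=4):
    """Bright parallel lines along one axis on a dark background."""
    data = np.full(shape, -900.0)
    sl = [slice(None)] * 3
    others = [a for a in range(3) if a != axis]
    for p in range(2, shape[others[0]] - 2, spacing):
        for q in range(2, shape[others[1]] - 2, spacing):
            sl2 = list(sl)
            sl2[others[0]] = p
            sl2[others[1]] = q
            data[tuple(sl2)] = 100.0
    return VolumeImage(data)


def test_dictionary_deterministic_unit_norm(default_case):
    kwargs = dict(k=8, patch_edge=5, scales=(1, 2), seed=3, n_patches=4000)
    d1 = learn_dictionary([default_case.ct_pre], [default_case.lung_truth], **kwargs)
    d2 = learn_dictionary([default_case.ct_pre], [default_case.lung_truth], **kwargs)
    np.testing.assert_array_equal(d1.atoms, d2.atoms)
    np.testing.assert_allclose(np.linalg.norm(d1.atoms, axis=1), 1.0, atol=1e-6)


def test_dictionary_input_validation(default_case):
    tiny = BinaryMask(np.zeros((96, 96, 96), dtype=np.uint8))
    with pytest.raises(ValueError, match="1000"):
        learn_dictionary([default_case.ct_pre], [tiny], k=4)
    with pytest.raises(ValueError, match="exceeds"):
        learn_dictionary(
            [default_case.ct_pre], [default_case.lung_truth], k=10**7, n_patches=100
        )


def test_two_atoms_separate_orthogonal_orientations():
    """K=2 on two line orientations: each atom prefers a different one."""
    vol_x = _line_volume(0)
    vol_y = _line_volume(1)
    # sample patches only at line voxels so every patch shows one orientation
    masks = [BinaryMask((v.data > 0).astype(np.uint8)) for v in (vol_x, vol_y)]
    dic = learn_dictionary([vol_x, vol_y], masks, k=2, scales=(1,), seed=0, n_patches=4000)
    # mean activation per atom on each orientation's line voxels
    fx = vesselprob.encode_points(vol_x, dic, np.argwhere(vol_x.data > 0)).mean(axis=0)
    fy = vesselprob.encode_points(vol_y, dic, np.argwhere(vol_y.data > 0)).mean(axis=0)
    assert int(np.argmax(fx)) != int(np.argmax(fy))


def test_encode_nonnegative_and_zero_on_constant(default_case):
    dic = learn_dictionary(
        [default_case.ct_pre], [default_case.lung_truth], k=8, seed=0, n_patches=3000
    )
    feats, _ = encode(default_case.ct_pre, dic, stride=4)
    assert (feats >= 0).all()
    flat = VolumeImage(np.zeros((16, 16, 16)))
    feats_flat, _ = encode(flat, dic, stride=2)
    np.testing.assert_array_equal(feats_flat, 0.0)


def test_encode_translation_consistency(default_case):
    """Shifting the image by one stride shifts the feature grid one cell."""
    dic = learn_dictionary(
        [default_case.ct_pre], [default_case.lung_truth], k=8, seed=0, n_patches=3000
    )
    stride = 2
    data = np.asarray(default_case.ct_pre.data)
    shifted = VolumeImage(np.roll(data, stride, axis=0), default_case.ct_pre.spacing)
    f0, gs = encode(default_case.ct_pre, dic, stride)
    f1, _ = encode(shifted, dic, stride)
    f0 = f0.reshape(gs + (-1,))
    f1 = f1.reshape(gs + (-1,))
    # interior excludes the coarse-scale patch margin (2 cells per scale-2 side)
    inner = (slice(4, -4), slice(4, -4))
    np.testing.assert_allclose(
        f1[(slice(5, -4),) + inner], f0[(slice(4, -5),) + inner], rtol=1e-4, atol=1e-4
    )


def test_classifier_separable_and_deterministic():
    x = np.concatenate([np.zeros(50), np.ones(50)]).reshape(-1, 1)
    y = np.concatenate([np.zeros(50), np.ones(50)])
    c1 = train_classifier(x, y, seed=0)
    c2 = train_classifier(x, y, seed=0)
    np.testing.assert_array_equal(c1.weights, c2.weights)
    p = 1 / (1 + np.exp(-((x - c1.feat_mean) / c1.feat_sd) @ c1.weights - c1.bias))
    assert ((p.ravel() > 0.5) == y.astype(bool)).all()
    with pytest.raises(ValueError, match="single class"):
        train_classifier(x, np.zeros(100))


def test_holdout_voxel_auc(models, case_bank):
    """Rank AUC of the trained model on an unseen phantom's stride grid."""
    dic, clf, _ = models
    case = case_bank(2)
    feats, _ = encode(case.ct_pre, dic, stride=2)
    xs = (feats - clf.feat_mean) / clf.feat_sd
    score = xs @ clf.weights + clf.bias
    vessel = case.vessel_truth_pre.data[::2, ::2, ::2].ravel().astype(bool)
    lung = case.lung_truth.data[::2, ::2, ::2].ravel()
    pos = score[vessel]
    neg = score[lung & ~vessel]
    ranks = np.argsort(np.argsort(np.concatenate([pos, neg])))
    auc = (ranks[: pos.size].sum() - pos.size * (pos.size - 1) / 2) / (pos.size * neg.size)
    assert auc >= 0.9


def test_probability_map_range_and_contrast(models, default_case):
    dic, clf, _ = models
    prob = predict_probability(default_case.ct_pre, dic, clf)
    assert prob.value_kind == ValueKind.PROBABILITY
    assert prob.data.min() >= 0.0 and prob.data.max() <= 1.0
    vessel = default_case.vessel_truth_pre.data
    lung_only = default_case.lung_truth.data & ~vessel
    assert prob.data[vessel].mean() > prob.data[lung_only].mean()


def test_probability_thresholded_sensitivity_specificity(models, default_case):
    """The p > 0.4 operating point on an unseen phantom: sens >= 0.8, spec >= 0.95."""
    dic, clf, _ = models
    prob = predict_probability(default_case.ct_pre, dic, clf)
    hits = prob.data > 0.4
    vessel = default_case.vessel_truth_pre.data
    lung_only = default_case.lung_truth.data & ~vessel
    assert (hits & vessel).sum() / vessel.sum() >= 0.8
    assert 1.0 - (hits & lung_only).sum() / lung_only.sum() >= 0.95


def test_zero_weight_classifier_gives_half(models, default_case):
    dic, clf, _ = models
    flat = VesselClassifier(
        weights=np.zeros_like(clf.weights),
        bias=0.0,
        feat_mean=clf.feat_mean,
        feat_sd=clf.feat_sd,
    )
    prob = predict_probability(default_case.ct_pre, dic, flat, stride=4)
    np.testing.assert_allclose(prob.data, 0.5)


def test_model_json_roundtrip(tmp_path, models):
    dic, clf, _ = models
    path = tmp_path / "model.json"
    vesselprob.save_model(dic, clf, path)
    dic2, clf2 = vesselprob.load_model(path)
    np.testing.assert_allclose(dic2.atoms, dic.atoms)
    np.testing.assert_allclose(clf2.weights, clf.weights)
    assert dic2.scales == dic.scales


# ---------------------------------------------------------------------------
# Hessian vesselness fallback
# ---------------------------------------------------------------------------


def _cylinder(shape=(40, 40, 40), radius=3.0, axis=2, value=300.0):
    data = np.full(shape, -900.0)
    idx = np.indices(shape, dtype=float)
    others = [a for a in range(3) if a != axis]
    c = [s / 2.0 for s in shape]
    d = np.sqrt(sum((idx[a] - c[a]) ** 2 for a in others))
    data[d <= radius] = value
    return VolumeImage(data)


def test_vesselness_prefers_tube_over_sphere():
    cyl = hessian_vesselness(_cylinder())
    sphere = np.full((40, 40, 40), -900.0)
    idx = np.indices((40, 40, 40), dtype=float)
    d = np.sqrt(((idx - 20.0) ** 2).sum(axis=0))
    sphere[d <= 3.0] = 300.0
    sph = hessian_vesselness(VolumeImage(sphere))
    assert cyl.data[20, 20, 20] > sph.data[20, 20, 20]


def test_vesselness_constant_image_is_zero():
    out = hessian_vesselness(VolumeImage(np.full((20, 20, 20), -500.0)))
    np.testing.assert_array_equal(out.data, 0.0)
    with pytest.raises(ValueError):
        hessian_vesselness(VolumeImage(np.zeros((20, 20, 20))), scales_mm=())


def test_vesselness_rotation_invariance():
    """Axis response of a tube is stable (+-5%) under a 90-degree rotation."""
    a = hessian_vesselness(_cylinder(axis=2))
    b = hessian_vesselness(_cylinder(axis=0))
    assert a.data[20, 20, 20] == pytest.approx(b.data[20, 20, 20], rel=0.05)
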