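import numpy as np
import pytest

import oracles
from radvasc import amfm, phantom
from radvasc.amfm import (
    DIRECTIONS_3D,
    AmfmConfig,
    TextureClass,
    block_features,
    box_counting_dimension,
    classify_block,
    edgementation,
    first_order,
    fractal_dimension,
    glcm_features,
    rlm_features,
    select_features,
    train_bayes,
)

CFG = AmfmConfig()


# ---------------------------------------------------------------------------
# Edgementation
# ---------------------------------------------------------------------------


def test_edgementation_zero_threshold_is_identity():
    rng = np.random.default_rng(0)
    block = rng.normal(size=(5, 5, 5)) * 100
    np.testing.assert_allclose(edgementation(block, 0.0), block)


def test_edgementation_merges_two_close_values_to_mean():
    block = np.zeros((4, 4, 4))
    block[2:] = 10.0
    out = edgementation(block, 10.0)
    np.testing.assert_allclose(out, 5.0)


def test_edgementation_preserves_strong_boundaries():
    block = np.zeros((6, 6, 6))
    block[3:] = 500.0
    out = edgementation(block, 76.0)
    assert set(np.unique(out)) == {0.0, 500.0}


def test_edgementation_rejects_negative_threshold():
    with pytest.raises(ValueError):
        edgementation(np.zeros((3, 3, 3)), -1.0)


# ---------------------------------------------------------------------------
# Feature oracles
# ---------------------------------------------------------------------------


def test_first_order_degenerate_and_closed_forms():
    const = np.full((4, 4, 4), -500.0)
    mean, var, skew, kurt, ent = first_order(const, CFG)
    assert var == 0 and ent == 0 and skew == 0 and kurt == 0
    # two equiprobable quantization levels -> 1 bit of entropy
    two = np.full((4, 4, 4), -900.0)
    two[:2] = 0.0
    assert first_order(two, CFG)[4] == pytest.approx(1.0)


def test_first_order_moments_match_direct_formulas():
    """Skewness/kurtosis of a small printed list vs explicit moment sums."""
    values = np.array([3.0, 7.0, 7.0, 19.0, 25.0, 25.0, 25.0, 40.0]).reshape(2, 2, 2)
    got = first_order(values, CFG)
    exp = oracles.first_order(values, CFG.n_levels)
    np.testing.assert_allclose(got, exp, rtol=1e-12)


def test_glcm_checkerboard_asm():
    """Two-level checkerboard with one unit offset: two cells of mass 1/2."""
    i, j, k = np.indices((4, 4, 4))
    board = np.where((i + j + k) % 2 == 0, -900.0, 0.0)
    feats = glcm_features(board, CFG, offsets=[(1, 0, 0)])
    assert feats[0] == pytest.approx(0.5)  # ASM
    assert feats[1] == pytest.approx(1.0)  # entropy of two equal cells


def test_glcm_constant_block_limits():
    feats = glcm_features(np.full((4, 4, 4), -200.0), CFG)
    asm, ent, inertia, contrast, corr, idm = feats
    assert idm == pytest.approx(1.0)
    assert inertia == 0 and contrast == 0 and ent == 0
    assert corr == 0.0  # zero-variance convention


def test_glcm_symmetric_features_invariant_under_level_flip(rng):
    """|i-j|-based features are invariant when grey levels are mirrored."""
    block = rng.uniform(-1000, 150, size=(6, 6, 6))
    # mirror inside the window: maps level q to (n-1)-q exactly
    lo, hi = CFG.hu_window
    flipped = (lo + hi) - block
    f1 = glcm_features(block, CFG)
    f2 = glcm_features(flipped, CFG)
    for idx in (2, 3, 5):  # inertia, contrast, IDM
        assert f1[idx] == pytest.approx(f2[idx], rel=1e-9)


def test_glcm_matches_bruteforce_on_random_blocks(rng):
    for _ in range(3):
        block = rng.uniform(-1000, 150, size=(5, 5, 5))
        got = glcm_features(block, CFG)
        exp = oracles.glcm_features(block, CFG.n_levels, DIRECTIONS_3D)
        np.testing.assert_allclose(got, exp, rtol=1e-9, atol=1e-12)


def test_rlm_alternating_stripe_all_unit_runs():
    line = np.tile(np.array([-900.0, 0.0]), 4).reshape(8, 1, 1)
    feats = rlm_features(line, CFG, directions=[(1, 0, 0)])
    assert feats[0] == pytest.approx(1.0)  # SRE
    assert feats[4] == pytest.approx(1.0)  # RP


def test_rlm_constant_line_closed_form():
    block = np.full((6, 1, 1), -500.0)
    feats = rlm_features(block, CFG, directions=[(1, 0, 0)])
    assert feats[1] == pytest.approx(36.0)  # LRE = L^2
    assert feats[4] == pytest.approx(1.0 / 6.0)  # RP = 1/L


def test_rlm_matches_bruteforce_on_random_blocks(rng):
    for _ in range(3):
        block = rng.uniform(-1000, 150, size=(6, 6, 6))
        got = rlm_features(block, CFG)
        exp = oracles.rlm_features(block, CFG.n_levels, DIRECTIONS_3D)
        np.testing.assert_allclose(got, exp, rtol=1e-9)


def test_box_counting_limits():
    full = np.ones((16, 16, 16), dtype=bool)
    assert box_counting_dimension(full) == pytest.approx(3.0, abs=0.2)
    point = np.zeros((16, 16, 16), dtype=bool)
    point[5, 5, 5] = True
    assert box_counting_dimension(point) == pytest.approx(0.0, abs=0.2)
    plane = np.zeros((16, 16, 16), dtype=bool)
    plane[8] = True
    assert box_counting_dimension(plane) == pytest.approx(2.0, abs=0.2)


def test_box_counting_matches_bruteforce(rng):
    edge = rng.uniform(size=(8, 8, 8)) > 0.7
    got = box_counting_dimension(edge)
    exp = oracles.box_counting_dimension(edge)
    assert got == pytest.approx(exp, rel=1e-9)


def test_fractal_dimension_requires_min_block():
    with pytest.raises(ValueError):
        fractal_dimension(np.zeros((6, 6, 6)))


# ---------------------------------------------------------------------------
# Offset invariance
# ---------------------------------------------------------------------------


def test_moment_features_invariant_to_hu_offset(rng):
    block = rng.uniform(-800, -300, size=(6, 6, 6))
    base = first_order(block, CFG)
    shifted = first_order(block + 137.0, CFG)
    np.testing.assert_allclose(shifted[1:4], base[1:4], rtol=1e-9)  # var, skew, kurt


def test_quantized_features_invariant_to_whole_bin_shift(rng):
    """Shifting by an exact bin width permutes levels; GLCM/RLM stay fixed."""
    block = rng.uniform(-800, -300, size=(6, 6, 6))
    # snap to bin centers so the shift is an exact level translation
    lo, hi = CFG.hu_window
    width = (hi - lo) / CFG.n_levels
    block = lo + (np.floor((block - lo) / width) + 0.5) * width
    shifted = block + 2 * width
    np.testing.assert_allclose(
        rlm_features(shifted, CFG), rlm_features(block, CFG), rtol=1e-9
    )
    f1, f2 = glcm_features(block, CFG), glcm_features(shifted, CFG)
    np.testing.assert_allclose(f2[[0, 1, 2, 3, 5]], f1[[0, 1, 2, 3, 5]], rtol=1e-9)


# ---------------------------------------------------------------------------
# Selection and Bayes classifier
# ---------------------------------------------------------------------------


def test_divergent_feature_ranked_first(rng):
    n = 60
    labels = np.repeat([0, 1], n // 2)
    separator = np.where(labels == 0, 0.0, 10.0) + rng.normal(0, 0.1, n)
    noise = rng.normal(size=n)
    feats = np.column_stack([noise, separator])
    kept = select_features(feats, labels)
    assert kept[0] == 1


def test_duplicate_feature_pruned(rng):
    n = 60
    labels = np.repeat([0, 1], n // 2)
    f = np.where(labels == 0, 0.0, 5.0) + rng.normal(0, 0.1, n)
    feats = np.column_stack([f, f.copy()])
    kept = select_features(feats, labels)
    assert len(kept) == 1


def test_selection_requires_two_samples_per_class():
    feats = np.array([[0.0], [1.0], [2.0]])
    with pytest.raises(ValueError):
        select_features(feats, np.array([0, 0, 1]))


def test_bayes_classifies_class_means_and_breaks_ties_by_enum_order():
    # exactly symmetric two-class problem: means 0 and 10, equal variances
    labels = np.repeat([int(TextureClass.NORMAL), int(TextureClass.EMPHYSEMA)], 2)
    feats = np.array([-1.0, 1.0, 9.0, 11.0]).reshape(-1, 1)
    model = train_bayes(feats, labels, selected=[0])
    assert classify_block(np.array([0.0]), model) == TextureClass.NORMAL
    assert classify_block(np.array([10.0]), model) == TextureClass.EMPHYSEMA
    # exact midpoint of a symmetric problem: first class in enum order wins
    assert classify_block(np.array([5.0]), model) == TextureClass.NORMAL


def test_selection_on_phantom_patches_nonempty_and_bounded():
    patches = phantom.texture_training_set(n_per_class=8, seed=3)
    feats = np.stack([block_features(p.data) for p, _ in patches])
    labels = np.array([int(c) for _, c in patches])
    kept = select_features(feats, labels)
    assert 0 < len(kept) <= 16


def test_bayes_holdout_accuracy_on_texture_patches(models):
    _, _, bayes = models
    hits = 0
    total = 0
    for cls in amfm.FOREGROUND_CLASSES:
        for s in range(8):
            patch = phantom.texture_patch(cls, (16, 16, 16), seed=50_000 + s + int(cls) * 101)
            hits += classify_block(block_features(patch.data), bayes) == cls
            total += 1
    assert hits / total >= 0.8


def test_accuracy_degrades_as_contrast_vanishes():
    """Class contrast scaled toward uniform lung HU: accuracy must fall."""

    def patch_params(scale):
        lung = -850.0
        sc = lambda v: lung + scale * (v - lung)
        return {
            TextureClass.GROUND_GLASS: {"mean": sc(-600.0), "sd_smooth": 60.0 * scale},
            TextureClass.GROUND_GLASS_RETICULAR: {
                "mean": sc(-700.0),
                "base_amp": 40.0 * scale,
                "streak_hu": sc(-150.0),
            },
            TextureClass.HONEYCOMBING: {"wall_hu": sc(-150.0), "pocket_hu": sc(-900.0)},
            TextureClass.BRONCHOVASCULAR: {"background": sc(-800.0), "streak_hu": sc(-50.0)},
            TextureClass.EMPHYSEMA: {"mean": sc(-950.0)},
            TextureClass.CONSOLIDATED: {"mean": sc(20.0)},
            TextureClass.NORMAL: {"vessel_hu": sc(50.0)},
        }

    def accuracy(scale):
        overrides = patch_params(scale)
        shape = (12, 12, 12)
        feats, labels = [], []
        for cls in amfm.FOREGROUND_CLASSES:
            for s in range(12):
                p = phantom.texture_patch(cls, shape, seed=100 + s + int(cls) * 31,
                                          params=overrides[cls])
                feats.append(block_features(p.data))
                labels.append(int(cls))
        model = train_bayes(np.stack(feats), np.asarray(labels))
        hits = total = 0
        for cls in amfm.FOREGROUND_CLASSES:
            for s in range(6):
                p = phantom.texture_patch(cls, shape, seed=900 + s + int(cls) * 37,
                                          params=overrides[cls])
                hits += classify_block(block_features(p.data), model) == cls
                total += 1
        return hits / total

    accs = [accuracy(s) for s in (1.0, 0.3, 0.02)]
    assert accs[0] >= accs[1] >= accs[2] - 0.05
    assert accs[2] < accs[0]


def test_classify_textures_marks_insert_and_is_deterministic(models):
    """A consolidated insert in a noisy lung is found; distant lung is normal."""
    _, _, bayes = models
    rng = np.random.default_rng(5)
    shape = (48, 48, 48)
    data = np.full(shape, -850.0) + rng.normal(0, 30.0, shape)
    # insert aligned with the 16^3 block lattice so one block is pure insert
    data[16:32, 16:32, 0:16] = 20.0 + rng.normal(0, 20.0, (16, 16, 16))
    lung = np.zeros(shape, dtype=np.uint8)
    lung[2:46, 2:46, 2:46] = 1
    from radvasc.imgrid import BinaryMask, VolumeImage

    ct = VolumeImage(data)
    mask = BinaryMask(lung)
    tex1 = amfm.classify_textures(ct, mask, bayes)
    tex2 = amfm.classify_textures(ct, mask, bayes)
    np.testing.assert_array_equal(tex1.data, tex2.data)
    insert = tex1.data[17:31, 17:31, 3:15]
    assert (insert == int(TextureClass.CONSOLIDATED)).mean() > 0.9
    far = tex1.data[34:44, 34:44, 34:44]
    assert (far == int(TextureClass.NORMAL)).mean() > 0.9
    # all-background input -> all-background map
    empty = amfm.classify_textures(ct, mask.like(np.zeros(shape)), bayes)
    assert (empty.data == 0).all()
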