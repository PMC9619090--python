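import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from radvasc import imgrid, rtchange
from radvasc.imgrid import BinaryMask, ValueKind, VolumeImage
from radvasc.rtchange import (
    ChangeRecord,
    DoseBinning,
    dose_bin_change,
    dose_response_summary,
    fed_partition,
    fit_line_r2,
    paired_t,
    percent_change,
    region_change,
)


# ---------------------------------------------------------------------------
# Eq. 1
# ---------------------------------------------------------------------------


def test_percent_change_forced_arithmetic():
    assert percent_change(1.0, 0.8) == -20.0
    assert percent_change(2.5, 2.5) == 0.0
    assert percent_change(3.0, 0.0) == -100.0
    with pytest.raises(ValueError):
        percent_change(0.0, 1.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.floats(0.01, 1e6, allow_nan=False),
    st.floats(0.0, 1e6, allow_nan=False),
)
def test_percent_change_antisymmetry_identity(pre, post):
    assert percent_change(pre, post) == pytest.approx(-100.0 * (1.0 - post / pre), rel=1e-12)
    assert percent_change(pre, post) >= -100.0


# ---------------------------------------------------------------------------
# Dose-binned change
# ---------------------------------------------------------------------------


def test_dose_binning_validation():
    with pytest.raises(ValueError):
        DoseBinning(edges_gy=(0, 5, 5, 40, np.inf))
    with pytest.raises(ValueError):
        DoseBinning(centers_gy=(10.0, 12.5, 30.0, 50.0))


def _random_masks(rng, shape=(10, 10, 10)):
    pre = BinaryMask(rng.integers(0, 2, size=shape).astype(np.uint8))
    post = pre.like(pre.data & (rng.uniform(size=shape) > 0.3))
    return pre, post


def test_identical_masks_zero_change(rng):
    pre, _ = _random_masks(rng)
    dose = VolumeImage(np.full(pre.shape, 30.0), value_kind=ValueKind.DOSE)
    recs = dose_bin_change(pre, pre, dose)
    rec = next(r for r in recs if r.region_label == "medium")
    assert rec.pct_change == 0.0


def test_zero_dose_populates_only_no_bin(rng):
    pre, post = _random_masks(rng)
    dose = VolumeImage(np.zeros(pre.shape), value_kind=ValueKind.DOSE)
    recs = dose_bin_change(pre, post, dose)
    assert not recs[0].empty_pre
    assert all(r.empty_pre for r in recs[1:])


def test_per_bin_volumes_are_additive(rng):
    pre, post = _random_masks(rng)
    dose = VolumeImage(rng.uniform(0, 60, size=pre.shape), value_kind=ValueKind.DOSE)
    recs = dose_bin_change(pre, post, dose)
    assert sum(r.volume_pre_ml for r in recs) == pytest.approx(
        imgrid.mask_volume_ml(pre), abs=1e-9
    )


# ---------------------------------------------------------------------------
# Fed / not-fed partition
# ---------------------------------------------------------------------------


def test_fed_partition_matches_phantom_truth(default_case):
    part = fed_partition(
        default_case.vessel_truth_pre, default_case.dose, default_case.lung_truth
    )
    lung = default_case.lung_truth.data
    agreement = (part.labels.data[lung] == default_case.fed_truth.data[lung]).mean()
    assert agreement >= 0.9
    # the three labels partition the lung exactly
    np.testing.assert_array_equal(part.labels.data > 0, lung)


def test_zero_dose_gives_no_fed_region(default_case):
    dose = VolumeImage(np.zeros(default_case.dose.shape), value_kind=ValueKind.DOSE)
    part = fed_partition(default_case.vessel_truth_pre, dose, default_case.lung_truth)
    assert not part.seeded
    assert (part.labels.data == 1).sum() == 0


def test_single_straight_vessel_feeds_whole_ipsilateral_lung():
    shape = (30, 30, 30)
    lung = np.zeros(shape, dtype=np.uint8)
    lung[4:26, 4:26, 4:26] = 1
    vessel = np.zeros(shape, dtype=np.uint8)
    vessel[15, 15, 4:26] = 1
    dose = np.zeros(shape)
    idx = np.indices(shape, dtype=float)
    dose = 60.0 * np.exp(-((idx[0] - 15) ** 2 + (idx[1] - 15) ** 2 + (idx[2] - 15) ** 2) / 50.0)
    part = fed_partition(
        BinaryMask(vessel), VolumeImage(dose, value_kind=ValueKind.DOSE), BinaryMask(lung)
    )
    lab = part.labels.data[lung.astype(bool)]
    assert (lab == 1).all()


def test_region_change_covers_seven_regions(default_case):
    part = fed_partition(
        default_case.vessel_truth_pre, default_case.dose, default_case.lung_truth
    )
    warped = imgrid.warp_mask_nn(default_case.vessel_truth_post, default_case.field_true)
    recs = region_change(default_case.vessel_truth_pre, warped, default_case.dose, part)
    labels = [r.region_label for r in recs]
    assert labels == [
        "fed_no", "fed_low", "fed_medium",
        "not_fed_no", "not_fed_low", "not_fed_medium",
        "contralateral",
    ]
    contra = recs[-1]
    assert not contra.empty_pre
    # contralateral is programmed with the no-dose atrophy only
    assert contra.pct_change == pytest.approx(
        default_case.atrophy_truth["no"], abs=5.0
    )


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def test_paired_t_null_and_degenerate():
    res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.t == 0.0 and res.p == 1.0 and not res.degenerate
    res = paired_t([0.0] * 5, [1.0] * 5)
    assert res.degenerate
    with pytest.raises(ValueError):
        paired_t([1.0], [2.0])


def test_paired_t_matches_scipy(rng):
    pre = rng.normal(10, 2, 5)
    post = pre + rng.normal(-1, 0.5, 5)
    mine = paired_t(pre, post)
    ref = stats.ttest_rel(post, pre)
    assert mine.t == pytest.approx(ref.statistic, rel=1e-12)
    assert mine.p == pytest.approx(ref.pvalue, rel=1e-12)


def test_fit_line_r2_exact_and_null(rng):
    x = np.array([1.0, 2.0, 3.0, 4.0])
    res = fit_line_r2(x, 3.0 * x - 1.0)
    assert res.r_squared == pytest.approx(1.0)
    assert res.slope == pytest.approx(3.0)
    noise = fit_line_r2(rng.normal(size=1000), rng.normal(size=1000))
    assert noise.r_squared < 0.01
    with pytest.raises(ValueError):
        fit_line_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _records(change_by_bin):
    return [
        ChangeRecord(name, 1.0, 1.0 + pct / 100.0, pct, 100, 100)
        for name, pct in change_by_bin.items()
    ]


def test_dose_response_summary_monotone_cohort():
    cohort = [
        _records({"no": -4 - s, "low": -9 - s, "medium": -24 - s, "high": -39 - s})
        for s in range(5)
    ]
    table, fit = dose_response_summary(cohort)
    assert fit is not None and fit.slope < 0
    assert list(table["bin"]) == ["no", "low", "medium", "high"]


def test_dose_response_summary_degenerate_cases():
    flat = [_records({"no": 0.0, "low": 0.0, "medium": 0.0, "high": 0.0})]
    table, fit = dose_response_summary(flat)
    assert fit.slope == 0.0 and fit.r_squared == 0.0
    assert table["single_subject"].all()
    assert (table["sd_pct_change"] == 0.0).all()
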