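"""DVH construction, parameter extraction, deltas, tolerances."""

import numpy as np
import pytest

from liverbrachy.dvh import (
    check_tolerances,
    compare_doses,
    compute_dvh,
    d_at_volume,
    deviation_vs_volume,
    load_tolerances,
    structure_parameters,
    summarize_cohort,
    v_at_dose,
)
from liverbrachy.geometry import VoxelGrid


def _dose_and_mask(values, spacing=(10.0, 10.0, 10.0)):
    """Dose grid plus all-true mask; 10 mm spacing -> 1 cm^3 voxels."""
    g = VoxelGrid(np.asarray(values, dtype=float), np.array(spacing))
    mask = g.with_values(np.ones(g.shape, dtype=bool))
    return g, mask


def brute_force_v(doses, threshold):
    """Independent oracle: explicit counting."""
    hit = sum(1 for d in doses if d >= threshold)
    return 100.0 * hit / len(doses)


def brute_force_d(doses, volume_cm3, voxvol_cm3):
    """Independent oracle: sort descending, accumulate voxel volumes,
    report the dose of the voxel in which the target volume is reached."""
    acc = 0.0
    for d in sorted(doses, reverse=True):
        acc += voxvol_cm3
        if acc >= volume_cm3 - 1e-12:
            return d
    return sorted(doses)[0]


class TestCurve:
    def test_uniform_structure_step_function(self):
        dose, mask = _dose_and_mask(np.full((3, 3, 3), 10.0))
        curve = compute_dvh(dose, mask, bin_width_gy=0.5)
        assert curve.cum_volume_fraction[0] == 1.0
        below = curve.dose_bins <= 10.0
        np.testing.assert_array_equal(curve.cum_volume_fraction[below], 1.0)
        above = curve.dose_bins > 10.0
        np.testing.assert_array_equal(curve.cum_volume_fraction[above], 0.0)

    def test_bimodal_structure_plateau(self):
        vals = np.concatenate([np.full(4, 2.0), np.full(4, 8.0)])
        dose, mask = _dose_and_mask(vals.reshape(2, 2, 2))
        curve = compute_dvh(dose, mask, bin_width_gy=0.5)
        mid = (curve.dose_bins > 2.0) & (curve.dose_bins <= 8.0)
        np.testing.assert_array_equal(curve.cum_volume_fraction[mid], 0.5)

    def test_random_doses_match_sort_and_count_oracle(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 30, size=(6, 6, 6))
        dose, mask = _dose_and_mask(vals)
        curve = compute_dvh(dose, mask, bin_width_gy=0.25)
        flat = vals.ravel()
        for b, frac in zip(curve.dose_bins, curve.cum_volume_fraction):
            assert frac * 100 == pytest.approx(brute_force_v(flat, b))

    def test_empty_mask_rejected(self):
        dose, mask = _dose_and_mask(np.zeros((2, 2, 2)))
        empty = mask.with_values(np.zeros(mask.shape, dtype=bool))
        with pytest.raises(ValueError, match="empty"):
            compute_dvh(dose, empty)


class TestVAtDose:
    def test_inclusive_threshold_convention(self):
        dose, mask = _dose_and_mask(np.full((2, 2, 2), 10.0))
        assert v_at_dose(dose, mask, 5.0) == 100.0
        assert v_at_dose(dose, mask, 10.0) == 100.0  # "at least" is >=
        assert v_at_dose(dose, mask, 10.0 + 1e-9) == 0.0

    def test_matches_counting_oracle_on_random_grids(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            vals = rng.uniform(0, 25, size=(5, 4, 3))
            dose, mask = _dose_and_mask(vals)
            thr = float(rng.uniform(0, 25))
            assert v_at_dose(dose, mask, thr) == pytest.approx(
                brute_force_v(vals.ravel(), thr))


class TestDAtVolume:
    def test_uniform_structure(self):
        dose, mask = _dose_and_mask(np.full((5, 5, 2), 10.0))  # 50 cm^3
        assert d_at_volume(dose, mask, 1.0, "cm3") == 10.0
        assert d_at_volume(dose, mask, 95.0, "pct") == 10.0

    def test_two_voxel_structure(self):
        dose, mask = _dose_and_mask(np.array([[[20.0, 5.0]]]))
        assert d_at_volume(dose, mask, 1.0, "cm3") == 20.0
        assert d_at_volume(dose, mask, 2.0, "cm3") == 5.0

    def test_linear_ramp_matches_sorting_oracle(self):
        vals = np.linspace(0, 40, 1000).reshape(10, 10, 10)
        dose, mask = _dose_and_mask(vals)
        for v in (1.0, 10.0, 333.3, 950.0):
            assert d_at_volume(dose, mask, v, "cm3") == pytest.approx(
                brute_force_d(vals.ravel(), v, 1.0))

    def test_volume_beyond_structure_rejected(self):
        dose, mask = _dose_and_mask(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError, match="exceeds"):
            d_at_volume(dose, mask, 9.0, "cm3")

    def test_inverse_consistency_with_v_at_dose(self):
        rng = np.random.default_rng(13)
        vals = rng.uniform(0, 30, size=(8, 8, 8))
        dose, mask = _dose_and_mask(vals)
        for v_pct in np.linspace(1, 100, 34):
            d = d_at_volume(dose, mask, v_pct, "pct")
            assert v_at_dose(dose, mask, d) >= v_pct - 1e-9


class TestPropertyBased:
    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra import numpy as hnp

    doses = hnp.arrays(np.float64, (4, 4, 4),
                       elements=st.floats(0.0, 50.0, allow_nan=False))

    @given(doses, st.floats(0.0, 55.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_v_at_dose_is_exact_counting(self, vals, thr):
        dose, mask = _dose_and_mask(vals)
        assert v_at_dose(dose, mask, thr) == pytest.approx(
            brute_force_v(vals.ravel(), thr), abs=1e-12)

    @given(doses, st.floats(1.0, 100.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_inverse_consistency_holds_everywhere(self, vals, v_pct):
        dose, mask = _dose_and_mask(vals)
        d = d_at_volume(dose, mask, v_pct, "pct")
        assert v_at_dose(dose, mask, d) >= v_pct - 1e-9


class TestStructureParameters:
    def test_ctv_parameter_monotonicity(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            vals = rng.gamma(4.0, 4.0, size=(6, 6, 6))
            dose, mask = _dose_and_mask(vals)
            p = structure_parameters(dose, mask, "CTV", 15.0)
            assert p["V150_pct"] <= p["V100_pct"] <= p["V95_pct"] \
                <= p["V90_pct"]
            assert p["D95_Gy"] <= p["D90_Gy"]

    def test_liver_parameters_and_absolute_volume(self):
        vals = np.concatenate([np.full(30, 6.0), np.full(34, 2.0)])
        dose, mask = _dose_and_mask(vals.reshape(4, 4, 4))
        p = structure_parameters(dose, mask, "liver", 15.0)
        assert p["V5Gy_pct"] == pytest.approx(100 * 30 / 64)
        assert p["V10Gy_pct"] == 0.0
        assert p["V5Gy_cm3"] == pytest.approx(30.0)

    def test_parameters_agree_with_fine_binned_curve(self):
        rng = np.random.default_rng(31)
        vals = rng.uniform(0, 20, size=(6, 6, 6))
        dose, mask = _dose_and_mask(vals)
        bw = 0.01
        curve = compute_dvh(dose, mask, bin_width_gy=bw)
        v5_curve = 100 * np.interp(5.0, curve.dose_bins,
                                   curve.cum_volume_fraction)
        assert v_at_dose(dose, mask, 5.0) == pytest.approx(v5_curve, abs=1.0)


class TestComparison:
    def test_delta_in_native_units(self):
        ref = {"liver": {"V5Gy_pct": 72.0}, "stomach": {"D1cc_Gy": 14.2}}
        mbdc = {"liver": {"V5Gy_pct": 65.8}, "stomach": {"D1cc_Gy": 13.7}}
        deltas = compare_doses(ref, mbdc)
        assert deltas["liver"]["V5Gy_pct"] == pytest.approx(-6.2)
        assert deltas["stomach"]["D1cc_Gy"] == pytest.approx(-0.5)

    def test_identical_inputs_zero_delta(self):
        p = {"ctv_1": {"D90_pct": 139.0, "V100_pct": 100.0}}
        deltas = compare_doses(p, {k: dict(v) for k, v in p.items()})
        assert all(v == 0 for v in deltas["ctv_1"].values())

    def test_structure_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            compare_doses({"liver": {}}, {"stomach": {}})


class TestCohortSummary:
    def test_order_statistics(self):
        out = summarize_cohort([{"d": -1.0}, {"d": -2.0}, {"d": -3.0}])
        assert out.loc["d", "median"] == -2.0
        assert out.loc["d", "min"] == -3.0
        assert out.loc["d", "max"] == -1.0

    def test_single_case_degenerate(self):
        out = summarize_cohort([{"d": 4.5}])
        assert out.loc["d", "median"] == out.loc["d", "min"] \
            == out.loc["d", "max"] == 4.5

    def test_random_cohort_matches_numpy_order_statistics(self):
        rng = np.random.default_rng(17)
        vals = rng.normal(size=11)
        out = summarize_cohort([{"x": float(v)} for v in vals])
        assert out.loc["x", "median"] == pytest.approx(np.median(vals))
        assert out.loc["x", "min"] == vals.min()
        assert out.loc["x", "max"] == vals.max()


class TestTolerances:
    def test_bundled_limits_match_clinical_table(self):
        tol = load_tolerances()
        assert tol["liver"] == {"V5Gy_pct": 67.0, "V10Gy_pct": 33.0}
        assert tol["oar_d1cc_Gy"] == {
            "bile_duct": 21.0, "bowel": 15.0, "colon": 20.0,
            "duodenum": 12.0, "esophagus": 12.0, "gall_bladder": 20.0,
            "heart": 22.0, "stomach": 12.0, "kidney": None,
        }

    def test_worked_examples(self):
        assert check_tolerances({"V5Gy_pct": 72.0, "V10Gy_pct": 26.0},
                                "liver") == {"V5Gy_pct": "exceed",
                                             "V10Gy_pct": "pass"}
        assert check_tolerances({"D1cc_Gy": 14.2}, "stomach") \
            == {"D1cc_Gy": "exceed"}

    def test_kidney_never_flagged(self):
        assert check_tolerances({"D1cc_Gy": 25.0}, "kidney") == {}

    def test_unknown_structure_warns_and_skips(self):
        with pytest.warns(UserWarning, match="spleen"):
            assert check_tolerances({"D1cc_Gy": 5.0}, "spleen") == {}


class TestDeviationVsVolume:
    def test_constructed_trend_gives_negative_rank_correlation(self):
        ref = np.array([50.0, 120.0, 400.0, 900.0, 1500.0])
        rel = np.array([-0.01, -0.02, -0.04, -0.06, -0.09])
        pairs, rho = deviation_vs_volume(ref, ref * (1 + rel))
        np.testing.assert_allclose(pairs[:, 1], rel, rtol=1e-9)
        assert rho == pytest.approx(-1.0)

    def test_constant_relative_deviation_no_correlation(self):
        ref = np.array([50.0, 120.0, 400.0])
        pairs, rho = deviation_vs_volume(ref, ref * 0.97)
        assert np.isnan(rho)
        np.testing.assert_allclose(pairs[:, 1], -0.03, rtol=1e-12)

    def test_single_case_returns_pairs_only(self):
        pairs, rho = deviation_vs_volume([100.0], [95.0])
        assert pairs.shape == (1, 2)
        assert np.isnan(rho)

    def test_zero_reference_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            pairs, _ = deviation_vs_volume([0.0, 100.0], [0.0, 95.0])
        assert pairs.shape == (1, 2)
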