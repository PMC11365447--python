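"""Glycoscore, doubling time, expression ratios, calibration, group stats."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scramkit as sk
from scramkit.cells import GroupStats
from scramkit.errors import (
    CalibrationError,
    DomainError,
    InputError,
    NonGrowthError,
    WindowError,
)
from scramkit.simulate import (
    BandSimConfig,
    CalibrationSimConfig,
    simulate_band_table,
    simulate_calibration_series,
)


class TestGlycoscore:
    @pytest.mark.parametrize(
        "lane, expected",
        [
            ((100, 0, 0, 0, 0), 100.0),
            ((0, 0, 0, 0, 100), 0.0),
            ((50, 30, 10, 10, 0), 80.0),
        ],
    )
    def test_examples(self, lane, expected):
        assert sk.glycoscore(lane) == pytest.approx(expected)

    def test_all_zero_lane_rejected(self):
        with pytest.raises(InputError):
            sk.glycoscore((0, 0, 0, 0, 0))

    @given(
        lane=st.lists(st.floats(0.0, 1e4), min_size=5, max_size=5).filter(
            lambda v: sum(v) > 1e-6
        ),
        scale=st.floats(1e-3, 1e3),
    )
    @settings(deadline=None, derandomize=True)
    def test_scale_invariant_and_bounded(self, lane, scale):
        s = sk.glycoscore(lane)
        assert 0.0 <= s <= 100.0
        assert sk.glycoscore([x * scale for x in lane]) == pytest.approx(s, abs=1e-9)

    def test_strictly_decreasing_when_intensity_degrades(self):
        # moving intensity from a higher-glycan band to a lower one lowers the score
        assert sk.glycoscore((50, 40, 10, 0, 0)) > sk.glycoscore((40, 50, 10, 0, 0))
        assert sk.glycoscore((40, 50, 10, 0, 0)) > sk.glycoscore((40, 50, 0, 10, 10))

    def test_summary(self):
        s = sk.glycoscore_summary([(50, 30, 10, 10, 0)] * 3)
        assert (s.mean, s.sd, s.n) == (80.0, 0.0, 3)
        single = sk.glycoscore_summary([(50, 30, 10, 10, 0)])
        assert single.sd is None and single.n == 1

    def test_simulated_replicates_recover_truth(self):
        cfg = BandSimConfig(noise_cv=0.03)  # true Glycoscore 85
        table, truth = simulate_band_table(cfg, seed=9, n_lanes=30)
        scores = table.scores()
        assert truth["glycoscore"] == pytest.approx(85.0)
        assert scores.mean() == pytest.approx(85.0, abs=1.0)

    def test_band_table_validation(self):
        with pytest.raises(InputError):
            sk.BandTable.from_records([("bad", (0, 0, 0, 0, 0))])


class TestDoublingTime:
    def test_exact_exponential(self):
        t = np.arange(0, 700, 15.0)
        curve = sk.GrowthCurve(t, 0.01 * 2 ** (t / 90.0), "exp")
        assert sk.doubling_time(curve) == pytest.approx(90.0)

    def test_plateau_below_window_errors(self):
        t = np.arange(0, 700, 15.0)
        a = 0.3 * (1 - np.exp(-t / 100))
        with pytest.raises(WindowError):
            sk.doubling_time(sk.GrowthCurve(t, a, "flat"))

    def test_rescaled_curve_violates_window(self):
        """The window thresholds are absolute A600 values, so rescaling the
        curve breaks the rule rather than silently shifting the phase."""
        t = np.arange(0, 700, 15.0)
        a = 0.01 * 2 ** (t / 90.0)
        scaled = np.clip(a / 100.0, 0, 0.34)  # never reaches 0.35
        with pytest.raises(WindowError):
            sk.doubling_time(sk.GrowthCurve(t, scaled, "scaled"))

    def test_non_growing_window_errors(self):
        t = np.arange(0, 200, 15.0)
        a = np.linspace(0.45, 0.36, t.size)  # decaying through the window
        with pytest.raises(NonGrowthError):
            sk.doubling_time(sk.GrowthCurve(t, a, "dying"))


class TestExpressionLevel:
    def test_reference_pair_is_unity(self):
        assert sk.expression_level(3.0, 2.0, 3.0, 2.0) == pytest.approx(1.0)

    def test_copy_number_fold_difference(self):
        # expression ratio of the two tagged constructs from their copy numbers
        assert sk.expression_level(5500, 1.0, 800, 1.0) == pytest.approx(6.875)

    def test_loading_control_normalization(self):
        base = sk.expression_level(4.0, 2.0, 1.0, 1.0)
        assert sk.expression_level(4.0, 1.0, 1.0, 1.0) == pytest.approx(2 * base)

    def test_zero_control_rejected(self):
        with pytest.raises(InputError):
            sk.expression_level(1.0, 0.0, 1.0, 1.0)


class TestCalibration:
    def test_hand_computed_copies(self):
        series = sk.CalibrationSeries(
            np.array([0.5, 1.0, 2.0]), np.array([0.5, 1.0, 2.0]), 1e7, 60_000.0
        )
        res = sk.copies_from_calibration(series, 1.0)
        assert res.copies_per_cell == pytest.approx(1e-9 / 60_000 * 6.02214076e23 / 1e7)
        assert res.copies_per_cell == pytest.approx(1.0e3, rel=0.01)
        assert not res.extrapolated

    def test_zero_intensity_zero_intercept(self):
        series = sk.CalibrationSeries(
            np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]), 1e7, 60_000.0
        )
        with pytest.warns(UserWarning, match="extrapolating"):
            res = sk.copies_from_calibration(series, 0.0)
        assert res.copies_per_cell == 0.0
        assert res.extrapolated

    def test_generator_identity_noiseless(self):
        cfg = CalibrationSimConfig(noise_cv=0.0, true_copies_per_cell=800.0)
        series, sample_intensity, truth = simulate_calibration_series(cfg, seed=5)
        res = sk.copies_from_calibration(series, sample_intensity)
        assert res.copies_per_cell == pytest.approx(800.0, rel=1e-9)

    def test_noisy_recovery_within_ten_percent(self):
        cfg = CalibrationSimConfig(noise_cv=0.05)
        rel_errs = []
        for seed in range(10):
            series, sample_intensity, truth = simulate_calibration_series(cfg, seed=seed)
            res = sk.copies_from_calibration(series, sample_intensity)
            rel_errs.append(abs(res.copies_per_cell - 800.0) / 800.0)
        assert np.median(rel_errs) < 0.10

    def test_flat_standards_rejected(self):
        series = sk.CalibrationSeries(
            np.array([1.0, 2.0, 3.0]), np.array([2.0, 2.0, 2.0]), 1e7, 60_000.0
        )
        with pytest.raises(CalibrationError):
            sk.copies_from_calibration(series, 2.0)

    def test_too_few_standards_rejected(self):
        with pytest.raises(InputError):
            sk.CalibrationSeries(np.array([1.0, 2.0]), np.array([1.0, 2.0]), 1e7, 6e4)


class TestNuclearEnrichment:
    @pytest.mark.parametrize("f_nuc, f_total, expected", [(3.0, 3.0, 1.0), (0.0, 3.0, 0.0), (0.9, 3.0, 0.3)])
    def test_values(self, f_nuc, f_total, expected):
        assert sk.nuclear_enrichment_ratio(f_nuc, f_total) == pytest.approx(expected)

    def test_noise_clamped_large_violation_raises(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert sk.nuclear_enrichment_ratio(1.02, 1.0) == 1.0
        with pytest.raises(DomainError):
            sk.nuclear_enrichment_ratio(2.0, 1.0)
        with pytest.raises(InputError):
            sk.nuclear_enrichment_ratio(1.0, 0.0)


class TestSummarizeGroups:
    def test_identical_groups_not_significant(self):
        s = sk.summarize_groups({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}, reference="a")
        assert s.stats["a"] == GroupStats(mean=2.0, sd=1.0, n=3)
        assert s.anova_p == pytest.approx(1.0)
        assert s.p_vs_reference["b"] == pytest.approx(1.0)

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(3)
        groups = {
            "wt": (70 + 2 * rng.standard_normal(5)).tolist(),
            "mut": (50 + 2 * rng.standard_normal(5)).tolist(),
        }
        s = sk.summarize_groups(groups, reference="wt")
        assert s.anova_p < 1e-4
        assert s.p_vs_reference["mut"] < 1e-4

    def test_single_group_descriptive_only(self):
        s = sk.summarize_groups({"only": [1.0, 2.0]})
        assert s.anova_p is None and s.p_vs_reference == {}

    def test_singleton_reference_skips_tests(self):
        s = sk.summarize_groups({"ref": [1.0], "b": [1.0, 2.0, 3.0]}, reference="ref")
        assert s.stats["ref"].sd is None
        assert s.p_vs_reference == {}
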