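"""Occupancy and abundance math: mixture formulas, Poisson link, geometry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scramkit as sk
from scramkit.errors import (
    DegenerateBaselineError,
    DomainError,
    InconsistentInputsError,
    InfiniteOccupancyError,
)

PRINTED_PREP = dict(
    protein_volume_ml=0.4,
    protein_conc_mg_ml=0.5,
    lipid_mass_total_mg=10.0,
    lipid_mix_volume_ml=1.85,
    aliquot_volume_ml=0.6,
)


class TestPositiveFractions:
    @pytest.mark.parametrize(
        "dfp, dfl, expected",
        [
            (0.80, 0.57, 0.23 / 0.43),  # measured bleach drops -> ~53.5%
            (0.57, 0.57, 0.0),  # no excess bleaching
            (1.00, 0.57, 1.0),  # complete bleaching
        ],
    )
    def test_bleach_fraction_examples(self, dfp, dfl, expected):
        assert sk.scramblase_positive_fraction(dfp, dfl) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "cp, cl, expected",
        [(0.65, 0.50, 0.30), (0.50, 0.50, 0.0), (1.00, 0.50, 1.0)],
    )
    def test_capture_fraction_examples(self, cp, cl, expected):
        assert sk.capture_positive_fraction(cp, cl) == pytest.approx(expected)

    def test_out_of_range_inputs_raise(self):
        with pytest.raises(DomainError):
            sk.scramblase_positive_fraction(1.2, 0.5)
        with pytest.raises(DomainError):
            sk.capture_positive_fraction(-0.1, 0.5)

    def test_fully_bleaching_baseline_is_degenerate(self):
        with pytest.raises(DegenerateBaselineError):
            sk.scramblase_positive_fraction(0.9, 1.0)

    def test_noise_below_baseline_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert sk.scramblase_positive_fraction(0.50, 0.57) == 0.0

    @given(
        dfl=st.floats(0.0, 0.95),
        step=st.floats(0.001, 0.04),
    )
    @settings(deadline=None, derandomize=True)
    def test_monotone_in_proteoliposome_bleach(self, dfl, step):
        lo = sk.scramblase_positive_fraction(dfl + step, dfl)
        hi = sk.scramblase_positive_fraction(min(dfl + 2 * step, 1.0), dfl)
        assert hi > lo

    def test_decreasing_in_baseline_when_excess_bleaching(self):
        # for fixed dfp > dfl, a leakier baseline explains away more of the
        # drop, so the inferred positive fraction falls as dfl rises
        vals = [sk.scramblase_positive_fraction(0.8, dfl) for dfl in (0.3, 0.45, 0.6)]
        assert vals[0] > vals[1] > vals[2]

    def test_predicted_capture_is_inverse_of_positive_fraction(self):
        for f in (0.0, 0.3, 0.55, 0.9):
            c = sk.predicted_capture_fraction(f)
            assert sk.capture_positive_fraction(c, 0.5) == pytest.approx(f)


class TestPoissonLink:
    @pytest.mark.parametrize(
        "f, m",
        [(0.0, 0.0), (0.55, 0.7985), (0.30, 0.3567)],
    )
    def test_mean_from_fraction_examples(self, f, m):
        assert sk.poisson_mean_from_fraction(f) == pytest.approx(m, abs=5e-5)

    def test_fraction_strictly_below_one(self):
        # strictly below 1 wherever floating point can resolve the gap
        assert sk.fraction_from_poisson_mean(20.0) < 1.0
        assert sk.fraction_from_poisson_mean(50.0) <= 1.0

    def test_infinite_occupancy_error(self):
        with pytest.raises(InfiniteOccupancyError):
            sk.poisson_mean_from_fraction(1.0)
        with pytest.raises(DomainError):
            sk.fraction_from_poisson_mean(-0.1)

    @given(f=st.floats(0.0, 0.999))
    @settings(deadline=None, derandomize=True)
    def test_round_trip(self, f):
        assert sk.fraction_from_poisson_mean(
            sk.poisson_mean_from_fraction(f)
        ) == pytest.approx(f, abs=1e-10)

    def test_matches_brute_force_vesicle_simulation(self):
        """Mixture bleaching over 10^4 Poisson-occupied vesicles reproduces
        the closed-form positive fraction within 3 binomial SE."""
        rng = np.random.default_rng(42)
        for m in (0.2, 0.7985, 2.0):
            occupancies = rng.poisson(m, size=10_000)
            empirical = np.mean(occupancies > 0)
            f = sk.fraction_from_poisson_mean(m)
            se = math.sqrt(f * (1 - f) / 10_000)
            assert abs(empirical - f) < 3 * se


class TestGeometryAndAbundance:
    def test_lipids_per_vesicle_value(self):
        n = sk.lipids_per_vesicle(175, 0.71)
        assert n == pytest.approx(8 * math.pi * 87.5**2 / 0.71)
        assert n == pytest.approx(2.71e5, rel=0.01)

    def test_lipids_scaling_laws(self):
        base = sk.lipids_per_vesicle(175, 0.71)
        assert sk.lipids_per_vesicle(350, 0.71) == pytest.approx(4 * base)
        assert sk.lipids_per_vesicle(175, 1.42) == pytest.approx(base / 2)

    def test_ppr_from_printed_recipe(self):
        ppr = sk.ppr_from_prep(sk.VesiclePrep(**PRINTED_PREP))
        assert ppr == pytest.approx(47.5, abs=0.1)

    def test_ppr_linear_in_protein(self):
        full = sk.ppr_from_prep(sk.VesiclePrep(**PRINTED_PREP))
        half = sk.ppr_from_prep(sk.VesiclePrep(**{**PRINTED_PREP, "protein_conc_mg_ml": 0.25}))
        zero = sk.ppr_from_prep(sk.VesiclePrep(**{**PRINTED_PREP, "protein_volume_ml": 0.0}))
        assert half == pytest.approx(full / 2)
        assert zero == 0.0

    def test_prep_invariants(self):
        with pytest.raises(DomainError):
            sk.VesiclePrep(**{**PRINTED_PREP, "aliquot_volume_ml": 2.0})
        with pytest.raises(DomainError):
            sk.VesiclePrep(**{**PRINTED_PREP, "lipid_mass_total_mg": 0.0})

    def test_weight_fraction_value_and_scaling(self):
        w = sk.scramblase_weight_fraction(0.357, 2.71e5, 47.5, 50_000)
        assert w == pytest.approx(1.39e-3, rel=0.01)
        assert sk.scramblase_weight_fraction(0.0, 2.71e5, 47.5, 50_000) == 0.0
        assert sk.scramblase_weight_fraction(0.357, 2.71e5, 47.5, 100_000) == pytest.approx(2 * w)

    def test_weight_fraction_unit_invariance(self):
        # rescaling scramblase mass and PPR consistently (both are masses per
        # mole) leaves the weight fraction unchanged
        w1 = sk.scramblase_weight_fraction(0.5, 2.7e5, 45.0, 50_000)
        w2 = sk.scramblase_weight_fraction(0.5, 2.7e5, 45_000.0, 50_000_000)
        assert w1 == pytest.approx(w2)

    def test_impossible_weight_fraction_raises(self):
        with pytest.raises(InconsistentInputsError):
            sk.scramblase_weight_fraction(1e6, 100.0, 1.0, 50_000)

    @pytest.mark.parametrize(
        "w, total, ratio, expected",
        [(0.01, 2e6, 1.0, 20_000), (0.0, 2e6, 1.0, 0.0), (0.01, 2e6, 2.0, 10_000)],
    )
    def test_copies_per_cell(self, w, total, ratio, expected):
        assert sk.copies_per_cell(w, total, ratio) == pytest.approx(expected)

    def test_estimate_abundance_chain(self):
        prep = sk.VesiclePrep(**PRINTED_PREP)
        est = sk.estimate_abundance(0.357, prep)
        assert est.ppr_mg_per_mmol == pytest.approx(47.48, abs=0.01)
        assert est.weight_fraction == pytest.approx(
            0.357 * 50_000 / (est.lipids_per_vesicle * est.ppr_mg_per_mmol)
        )
        assert est.copies_per_cell == pytest.approx(est.weight_fraction * 2e6)


class TestOccupancyEstimate:
    def test_link_enforced(self):
        est = sk.OccupancyEstimate.from_fraction(0.55, "liposome-control")
        assert est.m_mean == pytest.approx(-math.log(0.45))
        with pytest.raises(InconsistentInputsError):
            sk.OccupancyEstimate(f_positive=0.55, m_mean=0.1)
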