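"""The two-extrusion mass-closure solver, error propagation and aggregation."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesiquant import (
    ExtrusionPair,
    StandardReference,
    aggregate_values,
    compute_gamma,
    concentration_from_standard,
    gamma_from_intensities,
    propagate_errors,
    solve_concentrations,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_pair(i1=200.0, d1=50.0, i2=250.0, d2=5.0, **kw):
    defaults = dict(m0_mg=1.0, v1_ml=0.8, v2_ml=0.8, vt_ml=1.8,
                    d1=d1, d2=d2, i1=i1, i2=i2)
    defaults.update(kw)
    return ExtrusionPair(**defaults)


class TestGamma:
    def test_symmetric_inputs_give_unity(self):
        assert compute_gamma(make_pair(i1=100.0, d1=5.0, i2=100.0, d2=5.0)) == 1.0

    def test_hand_arithmetic(self):
        # (200 * 50) / (250 * 5) = 8
        assert compute_gamma(make_pair()) == pytest.approx(8.0, rel=1e-14)

    @given(scale=st.floats(1e-3, 1e3))
    def test_invariant_under_common_intensity_rescaling(self, scale):
        base = gamma_from_intensities(200.0, 50.0, 250.0, 5.0)
        assert gamma_from_intensities(200.0 * scale, 50.0, 250.0 * scale, 5.0) == pytest.approx(
            base, rel=1e-12
        )

    def test_degenerate_extrusion_two_named_in_error(self):
        with pytest.raises(ValueError, match="extrusion-II"):
            ExtrusionPair(m0_mg=1, v1_ml=0.8, v2_ml=0.8, vt_ml=1.8,
                          d1=50, d2=5, i1=200.0, i2=0.0)


class TestSolveConcentrations:
    def test_worked_example(self):
        # alpha = 1.25, upsilon = 1.25, gamma = 8:
        # C2 = 1.25/9.25 = 0.13514, C1 = 8 * C2 = 1.08108 mg/mL
        res = solve_concentrations(make_pair())
        assert res.alpha == pytest.approx(1.25, rel=1e-14)
        assert res.upsilon == pytest.approx(1.25, rel=1e-14)
        assert res.gamma == pytest.approx(8.0, rel=1e-14)
        assert res.c2_mg_ml == pytest.approx(0.135135135, rel=1e-8)
        assert res.c1_mg_ml == pytest.approx(1.081081081, rel=1e-8)
        # closure: 1.08108*0.8 + 0.13514*1.0 = 1.000 mg
        assert res.c1_mg_ml * 0.8 + res.c2_mg_ml * 1.0 == pytest.approx(1.0, rel=1e-12)

    def test_large_gamma_limit(self):
        res = solve_concentrations(make_pair(i1=1e9, i2=1e-3))
        assert res.c2_mg_ml == pytest.approx(0.0, abs=1e-9)
        assert res.c1_mg_ml == pytest.approx(1.25, rel=1e-6)

    def test_gamma_equal_upsilon_splits_alpha(self):
        # gamma = upsilon => C1 = alpha * gamma / (2 gamma) = alpha / 2
        pair = ExtrusionPair(m0_mg=1.0, v1_ml=0.8, v2_ml=0.8, vt_ml=1.8,
                             d1=5.0, d2=4.0, i1=100.0, i2=100.0)  # gamma = 1.25 = upsilon
        res = solve_concentrations(pair)
        assert res.gamma == pytest.approx(res.upsilon, rel=1e-14)
        assert res.c1_mg_ml == pytest.approx(res.alpha / 2.0, rel=1e-12)

    @given(
        m0=st.floats(0.1, 10.0),
        v1=st.floats(0.2, 2.0),
        extra=st.floats(0.1, 3.0),
        gamma=st.floats(0.05, 500.0),
    )
    def test_closure_and_ratio_invariants(self, m0, v1, extra, gamma):
        vt = v1 + extra
        i2, d1, d2 = 100.0, 10.0, 5.0
        i1 = gamma * i2 * d2 / d1
        pair = ExtrusionPair(m0_mg=m0, v1_ml=v1, v2_ml=extra / 2, vt_ml=vt,
                             d1=d1, d2=d2, i1=i1, i2=i2)
        res = solve_concentrations(pair)
        closure = res.c1_mg_ml * v1 + res.c2_mg_ml * (vt - v1)
        assert closure == pytest.approx(m0, rel=1e-12)
        assert res.c1_mg_ml / res.c2_mg_ml == pytest.approx(res.gamma, rel=1e-12)

    def test_c2_decreasing_c1_increasing_in_gamma(self):
        gammas = [0.5, 1.0, 2.0, 8.0, 50.0]
        results = [
            solve_concentrations(make_pair(i1=g * 250.0 * 5.0 / 50.0))
            for g in gammas
        ]
        c1s = [r.c1_mg_ml for r in results]
        c2s = [r.c2_mg_ml for r in results]
        assert all(b > a for a, b in zip(c1s, c1s[1:]))
        assert all(b < a for a, b in zip(c2s, c2s[1:]))

    def test_setup_independence_bit_identical(self):
        res_a = solve_concentrations(make_pair(i1=200.0, i2=250.0))
        res_b = solve_concentrations(make_pair(i1=200.0 * 3.7, i2=250.0 * 3.7))
        assert res_b.c1_mg_ml == res_a.c1_mg_ml
        assert res_b.c2_mg_ml == res_a.c2_mg_ml

    def test_rejects_negative_dead_volume(self):
        with pytest.raises(ValueError, match="dead volume"):
            make_pair(vt_ml=1.5, v1_ml=0.8, v2_ml=0.8)


class TestErrorPropagation:
    def test_zero_intensity_se_gives_zero_and_warns(self):
        pair = make_pair()
        with pytest.warns(UserWarning, match="zero"):
            se1, se2 = propagate_errors(pair)
        assert se1 == 0.0 and se2 == 0.0
        res = solve_concentrations(pair)
        assert res.se_is_zero

    def test_delta_method_matches_monte_carlo(self):
        """First-order SEs within 5% of a 100,000-draw Monte-Carlo SD."""
        pair = make_pair(i1_se=200.0 * 0.03, i2_se=250.0 * 0.02)
        se1, se2 = propagate_errors(pair)
        rng = np.random.default_rng(2024)
        n = 100_000
        i1 = pair.i1 + pair.i1_se * rng.standard_normal(n)
        i2 = pair.i2 + pair.i2_se * rng.standard_normal(n)
        gamma = (i1 * pair.d1) / (i2 * pair.d2)
        alpha, upsilon = 1.25, 1.25
        c2 = alpha / (gamma + upsilon)
        c1 = alpha * gamma / (gamma + upsilon)
        assert se1 == pytest.approx(np.std(c1, ddof=1), rel=0.05)
        assert se2 == pytest.approx(np.std(c2, ddof=1), rel=0.05)

    def test_se_linear_in_common_se_scaling(self):
        p1 = make_pair(i1_se=2.0, i2_se=3.0)
        p2 = make_pair(i1_se=6.0, i2_se=9.0)
        se1a, se2a = propagate_errors(p1)
        se1b, se2b = propagate_errors(p2)
        assert se1b == pytest.approx(3.0 * se1a, rel=1e-12)
        assert se2b == pytest.approx(3.0 * se2a, rel=1e-12)

    def test_volume_and_mass_ses_enter_when_given(self):
        base = make_pair(i1_se=2.0, i2_se=3.0)
        with_m0 = make_pair(i1_se=2.0, i2_se=3.0, m0_se=0.01)
        assert propagate_errors(with_m0)[0] > propagate_errors(base)[0]


class TestAggregation:
    def test_identical_inputs(self):
        agg = aggregate_values(1.0, 0.05, 1.0, 0.05)
        assert agg.mean == 1.0
        assert agg.preparation_spread == 0.0
        assert agg.uncertainty == agg.measurement_error == pytest.approx(
            math.sqrt(2 * 0.05**2) / 2
        )
        assert agg.source == "measurement"

    def test_spread_dominates_discrepant_preparations(self):
        # values 1.0 and 1.2, tiny measurement errors:
        # sigma = sqrt(0.1^2 + 0.1^2) ~ 0.141 dominates
        agg = aggregate_values(1.0, 1e-4, 1.2, 1e-4)
        assert agg.mean == pytest.approx(1.1)
        assert agg.preparation_spread == pytest.approx(math.sqrt(0.02), rel=1e-12)
        assert agg.uncertainty == pytest.approx(0.1414, abs=1e-3)
        assert agg.source == "spread"

    @given(
        xa=st.floats(0.1, 5.0),
        xb=st.floats(0.1, 5.0),
        ea=st.floats(0.0, 0.5),
        eb=st.floats(0.0, 0.5),
    )
    def test_uncertainty_is_max_of_both_terms(self, xa, xb, ea, eb):
        agg = aggregate_values(xa, ea, xb, eb)
        assert agg.uncertainty >= agg.measurement_error - 1e-15
        assert agg.uncertainty >= agg.preparation_spread - 1e-15


class TestStandardShortcut:
    def test_identity(self):
        std = StandardReference(r_std=2.5, c_std_mg_ml=0.9, d_std=10.0)
        assert concentration_from_standard(2.5, 10.0, std) == pytest.approx(0.9, rel=1e-14)

    def test_linear_in_reading(self):
        std = StandardReference(r_std=2.5, c_std_mg_ml=0.9, d_std=10.0)
        assert concentration_from_standard(5.0, 10.0, std) == pytest.approx(1.8, rel=1e-12)

    def test_recovers_known_ratio_from_generator(self):
        """Standard and unknown simulated with the same instrument constant."""
        from vesiquant.simulate import simulate_extrusion_experiment

        pair_std, truth_std = simulate_extrusion_experiment(seed=10, noise_cv=0.0001)
        pair_unk, truth_unk = simulate_extrusion_experiment(
            m0_mg=1.6, seed=11, noise_cv=0.0001
        )
        std = StandardReference(
            r_std=pair_std.i1, c_std_mg_ml=truth_std.true_c1_mg_ml, d_std=pair_std.d1
        )
        rec = concentration_from_standard(pair_unk.i1, pair_unk.d1, std)
        assert rec == pytest.approx(truth_unk.true_c1_mg_ml, rel=0.005)

    def test_zero_standard_reading_rejected(self):
        with pytest.raises(ValueError):
            StandardReference(r_std=0.0, c_std_mg_ml=0.9)
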