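"""Unit and property tests of the 25-state equilibrium gating model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from girkgate.calibration import DoseResponseCurve, fit_hill
from girkgate.model import (
    AsymptoticRegimeWarning,
    GatingParams,
    OccupancyState,
    REFERENCE_FIT,
    activity,
    enumerate_states,
    eq1_activity,
    fold_affinity_gbg,
    fold_affinity_na,
    limiting_slope,
    log_state_weights,
    small_m_threshold,
    state_distribution,
    state_weight,
)
from conftest import microstate_partition_and_activity


# strategy for physically plausible but wide-ranging parameter sets
def _params_strategy():
    pos = st.floats(min_value=1e-2, max_value=1e2)
    coop = st.floats(min_value=0.05, max_value=2.0)
    return st.builds(
        lambda kdn, kdb, b, eta, t0, dt: GatingParams(
            kdn=kdn, kdb=kdb * 1e-2, b=b, eta=eta, theta04=t0, theta44=t0 + dt
        ),
        kdn=pos, kdb=pos, b=coop, eta=coop,
        t0=st.floats(min_value=0.0, max_value=1.0),
        dt=st.floats(min_value=0.0, max_value=1.0),
    )


class TestEnumeration:
    def test_exactly_25_states(self):
        states = enumerate_states()
        assert len(states) == 25
        assert len(set(states)) == 25

    def test_ordering_convention(self):
        states = enumerate_states()
        assert states[0] == OccupancyState(0, 0)
        assert states[-1] == OccupancyState(4, 4)


class TestStateWeights:
    def test_empty_ligand_reference_state(self, ref_params):
        assert state_weight(ref_params, 0.0, 0.0, OccupancyState(0, 0)) == 1.0
        for s in enumerate_states():
            if s.i + s.j > 0:
                assert state_weight(ref_params, 0.0, 0.0, s) == 0.0

    def test_stepwise_affinity_ratio_fourth_vs_first(self, ref_params):
        """Stepwise Kd(4th)/Kd(1st) = b^3, so the affinity gain is b^-3 ~ 37.

        Stepwise constants carry statistical factors: the ratio of the
        fourth to the first stepwise association constant is
        (w4/w3)/(w1/w0) * (4/1)/(1/4) with weights at fixed (na, m)."""
        m = 0.005
        w = [state_weight(ref_params, 0.0, m, OccupancyState(0, j)) for j in range(5)]
        # per-site stepwise association constants: strip statistical factors
        k4 = (w[4] / w[3]) / (1 / 4)  # 4th step: 1 way in, 4 ways out
        k1 = (w[1] / w[0]) / (4 / 1)  # 1st step: 4 ways in, 1 way out
        assert k4 / k1 == pytest.approx(ref_params.b**-3, rel=1e-12)
        assert round(k4 / k1) == 37

    def test_negative_concentration_rejected(self, ref_params):
        with pytest.raises(ValueError):
            state_weight(ref_params, -1.0, 0.01, OccupancyState(0, 0))
        with pytest.raises(ValueError):
            activity(ref_params, 1.0, -0.01)

    @settings(max_examples=50, deadline=None)
    @given(params=_params_strategy(),
           na=st.floats(min_value=0, max_value=100),
           m=st.floats(min_value=0, max_value=0.5))
    def test_partition_function_matches_microstate_enumeration(self, params, na, m):
        """The 25-macrostate binding polynomial equals the 256-microstate sum."""
        z_micro, _ = microstate_partition_and_activity(params, na, m)
        z_macro = float(np.exp(log_state_weights(params, na, m)).sum())
        assert z_macro == pytest.approx(z_micro, rel=1e-10)


class TestStateDistribution:
    def test_empty_conditions_concentrate_on_apo_state(self, ref_params):
        d = state_distribution(ref_params, 0.0, 0.0)
        assert d[(0, 0)] == 1.0
        assert d.populations.sum() == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(params=_params_strategy(),
           na=st.floats(min_value=0, max_value=100),
           m=st.floats(min_value=0, max_value=0.5))
    def test_populations_normalized_and_nonnegative(self, params, na, m):
        d = state_distribution(params, na, m)
        assert np.all(d.populations >= 0)
        assert d.populations.sum() == pytest.approx(1.0, abs=1e-12)

    def test_saturating_gbg_concentrates_on_fully_bound(self, ref_params):
        d = state_distribution(ref_params, 0.0, 1e5)
        assert d[(0, 4)] == pytest.approx(1.0, abs=1e-6)

    def test_extreme_parameters_do_not_overflow(self):
        p = GatingParams(kdn=1.0, kdb=1e-4, b=0.01, eta=0.01, theta04=0.1, theta44=1.0)
        d = state_distribution(p, 100.0, 0.5)
        assert np.isfinite(d.populations).all()
        assert d.populations.sum() == pytest.approx(1.0, abs=1e-12)


class TestActivity:
    def test_zero_without_gbg(self, ref_params):
        assert activity(ref_params, 32.0, 0.0) == 0.0

    def test_gbg_saturation_without_na_reaches_theta04(self, ref_params):
        assert activity(ref_params, 0.0, 1e5) == pytest.approx(0.49, abs=1e-6)

    def test_value_at_top_of_titration_grid(self, ref_params):
        # frozen from the independent microstate oracle
        assert activity(ref_params, 32.0, 0.03) == pytest.approx(1.012, abs=1e-3)

    @settings(max_examples=50, deadline=None)
    @given(params=_params_strategy(),
           na=st.floats(min_value=0, max_value=100),
           m=st.floats(min_value=1e-6, max_value=0.5))
    def test_closed_form_matches_microstate_oracle(self, params, na, m):
        _, a_micro = microstate_partition_and_activity(params, na, m)
        assert activity(params, na, m) == pytest.approx(a_micro, rel=1e-10, abs=1e-12)

    def test_monotone_in_gbg_and_na(self, ref_params):
        m_grid = np.geomspace(1e-5, 0.1, 40)
        for na in (0.0, 4.0, 8.0, 16.0, 32.0):
            a = np.array([activity(ref_params, na, m) for m in m_grid])
            assert np.all(np.diff(a) > 0)
        na_grid = np.linspace(0, 100, 40)
        for m in (1e-4, 1e-3, 0.01, 0.03):
            a = np.array([activity(ref_params, na, m) for na in na_grid])
            assert np.all(np.diff(a) >= -1e-14)

    def test_broadcasting_matches_scalar_calls(self, ref_params):
        na = np.array([0.0, 8.0, 32.0])
        m = np.array([1e-3, 3e-3, 1e-2])
        vec = activity(ref_params, na, m)
        scal = [activity(ref_params, n_, m_) for n_, m_ in zip(na, m)]
        np.testing.assert_allclose(vec, scal, rtol=1e-14)


class TestEq1:
    def test_zero_dose_returns_theta0(self):
        assert eq1_activity(0.019, 0.3, (0.2, 0, 0, 0, 1), 0.0) == pytest.approx(0.2)

    def test_independent_sites_reduce_to_binomial_occupancy(self):
        """b=1 and theta_j = j/4 gives the mean fractional occupancy of
        4 independent sites, m/(Kdb+m)."""
        kdb = 0.05
        thetas = np.arange(5) / 4
        for m in (0.0, 0.01, 0.05, 0.2, 1.0):
            expected = m / (kdb + m)
            assert eq1_activity(kdb, 1.0, thetas, m) == pytest.approx(expected, rel=1e-12)

    def test_matches_direct_polynomial(self):
        kdb, b, m = 0.019, 0.30, 0.019
        thetas = (0.0, 0.0, 0.0, 0.0, 1.0)
        num = m**4
        den = (b**6 * kdb**4 + 4 * b**6 * kdb**3 * m + 6 * b**5 * kdb**2 * m**2
               + 4 * b**3 * kdb * m**3 + m**4)
        assert eq1_activity(kdb, b, thetas, m) == pytest.approx(num / den, rel=1e-14)

    @settings(max_examples=30, deadline=None)
    @given(params=_params_strategy(), m=st.floats(min_value=0, max_value=0.5))
    def test_na_free_model_reduces_to_one_ligand_polynomial(self, params, m):
        thetas = (0.0, 0.0, 0.0, 0.0, params.theta04)
        full = activity(params, 0.0, m)
        reduced = eq1_activity(params.kdb, params.b, thetas, m)
        assert full == pytest.approx(reduced, rel=1e-12, abs=1e-300)


class TestLimitingSlope:
    def test_slope_four_when_four_gbg_required(self):
        kdb, b = 0.019, 0.30
        s = small_m_threshold(b)
        fn = lambda m: eq1_activity(kdb, b, (0, 0, 0, 0, 1.0), m)
        assert limiting_slope(fn, 1e-4 * s * kdb) == pytest.approx(4.0, abs=0.01)
        assert limiting_slope(fn, 1e-3 * s * kdb) == pytest.approx(4.0, abs=0.01)

    def test_hyperbola_has_unit_slope(self):
        fn = lambda m: m / (0.1 + m)
        assert limiting_slope(fn, 1e-6) == pytest.approx(1.0, abs=1e-3)

    def test_three_sufficient_gbg_lowers_the_slope(self):
        kdb, b = 0.019, 0.30
        s = small_m_threshold(b)
        fn = lambda m: eq1_activity(kdb, b, (0, 0, 0, 1.0, 1.0), m)
        assert limiting_slope(fn, 1e-3 * s * kdb) < 4.0 - 0.5

    def test_slope_never_exceeds_four(self):
        kdb, b = 0.019, 0.30
        fn = lambda m: eq1_activity(kdb, b, (0, 0, 0, 0, 1.0), m)
        for m in np.geomspace(1e-8, 0.1, 30):
            assert limiting_slope(fn, m) <= 4.0 + 1e-6

    def test_warns_outside_asymptotic_regime(self):
        fn = lambda m: eq1_activity(0.019, 0.30, (0, 0, 0, 0, 1.0), m)
        with pytest.warns(AsymptoticRegimeWarning):
            limiting_slope(fn, 0.019, regime_limit=1e-3 * 0.019)

    def test_rejects_nonpositive_m(self):
        with pytest.raises(ValueError):
            limiting_slope(lambda m: m, 0.0)


class TestSmallMThreshold:
    @pytest.mark.parametrize(
        "b,expected",
        [(1.0, 0.25), (0.30, 0.30**1.5)],
    )
    def test_known_values(self, b, expected):
        assert small_m_threshold(b) == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(b=st.floats(min_value=1e-3, max_value=1.0))
    def test_equals_min_of_candidates(self, b):
        cands = [0.25, math.sqrt(b / 6), b / 4 ** (1 / 3), b**1.5]
        assert small_m_threshold(b) == pytest.approx(min(cands), rel=1e-12)

    def test_nondecreasing_in_b(self):
        bs = np.linspace(1e-3, 1.0, 200)
        vals = [small_m_threshold(b) for b in bs]
        assert np.all(np.diff(vals) >= 0)


class TestFoldAffinities:
    def test_cooperativity_gains(self):
        assert round(fold_affinity_gbg(0.30)) == 37
        assert round(fold_affinity_na(0.63)) == 6
        assert fold_affinity_gbg(1.0) == 1.0
        assert fold_affinity_na(1.0) == 1.0


class TestHillLimit:
    def test_strong_cooperativity_approaches_hill_coefficient_four(self):
        """As b -> 0 with Kdb * b^(3/2) fixed, the one-ligand dose-response
        tends to a Hill curve with coefficient 4 and midpoint Kdb*b^(3/2)."""
        k_half = 1e-3  # limiting midpoint = kdb * b^(3/2)
        n_fitted, kd_err = [], []
        for b in (0.3, 0.03, 0.003):
            kdb = k_half / b**1.5
            doses = np.geomspace(k_half / 30, k_half * 30, 25)
            resp = np.array([eq1_activity(kdb, b, (0, 0, 0, 0, 1.0), m) for m in doses])
            fit = fit_hill(DoseResponseCurve(dose=doses, response=resp))
            n_fitted.append(fit.n_hill)
            kd_err.append(abs(fit.kd - k_half) / k_half)
        assert np.all(np.diff(n_fitted) > 0)  # steepens toward the limit
        assert n_fitted[-1] > 3.9
        assert np.all(np.diff(kd_err) < 0)  # midpoint converges to kdb*b^1.5
        assert kd_err[-1] < 0.01


class TestGatingParams:
    def test_rejects_nonpositive_constants(self):
        with pytest.raises(ValueError):
            GatingParams(kdn=0, kdb=0.019, b=0.3, eta=0.63, theta04=0.49, theta44=1.19)
        with pytest.raises(ValueError):
            GatingParams(kdn=60, kdb=0.019, b=-0.3, eta=0.63, theta04=0.49, theta44=1.19)

    def test_rejects_inverted_thetas(self):
        with pytest.raises(ValueError):
            GatingParams(kdn=60, kdb=0.019, b=0.3, eta=0.63, theta04=1.19, theta44=0.49)

    def test_dict_round_trip(self, ref_params):
        assert GatingParams.from_dict(ref_params.to_dict()) == ref_params

    def test_values_above_one_accepted_for_cooperativity_factors(self):
        # factors > 1 mean negative cooperativity; evaluation must accept them
        p = GatingParams(kdn=60, kdb=0.019, b=1.5, eta=1.2, theta04=0.4, theta44=1.0)
        assert np.isfinite(activity(p, 10.0, 0.01))
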