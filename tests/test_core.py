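"""Hierarchical model: recursion, closed forms, asymptotics, homeostatic case."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import senodyn as sd
from senodyn.core import _cc_seeded_curves, _csc_seeded_curves

GRID = [
    (delta, n, d)
    for delta in (-0.1, 0.0, 0.2, 0.9)
    for n in (1, 2, 5)
    for d in (0.0, 0.1, 1.0)
]


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"delta": -1.0, "n_senescence": 2},
            {"delta": 1.5, "n_senescence": 2},
            {"delta": 0.1, "n_senescence": 0},
            {"delta": 0.1, "n_senescence": 2, "death_prob": 1.2},
            {"delta": 0.1, "n_senescence": 2, "division_rate": 0.0},
            {"delta": 0.1, "n_senescence": 2, "csc_fraction_0": -0.1},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sd.HierarchicalParams(**kwargs)

    def test_delta_from_division_probs(self):
        p = sd.HierarchicalParams.from_division_probs(0.6, 0.4, n_senescence=3)
        assert p.delta == pytest.approx(0.2)
        with pytest.raises(ValueError):
            sd.HierarchicalParams.from_division_probs(0.8, 0.5, n_senescence=3)


class TestRecursion:
    def test_single_step_hand_example(self, csc_seed):
        p = sd.HierarchicalParams(0.0, 2, 0.0)
        nxt = sd.advance_generation(csc_seed(2), p)
        assert nxt.csc == 1.0
        assert np.allclose(nxt.cc_by_age, [1.0, 0.0])
        assert nxt.senescent == 0.0

    def test_homeostatic_totals_match_hand_enumeration(self, csc_seed):
        p = sd.HierarchicalParams(0.0, 2, 0.0)
        tr = sd.simulate_trajectory(p, csc_seed(2), 4)
        assert np.allclose(tr.totals, [1, 2, 4, 6, 8])

    def test_pure_csc_doubling_when_delta_is_one(self):
        p = sd.HierarchicalParams(1.0, 1, 0.0)
        state = sd.PopulationState(0, 5.0, np.zeros(1), 0.0)
        nxt = sd.advance_generation(state, p)
        assert nxt.csc == 10.0
        assert nxt.cc_by_age.sum() == 0.0

    def test_growing_trajectory_hand_values(self, csc_seed):
        p = sd.HierarchicalParams(0.2, 1, 0.0)
        tr = sd.simulate_trajectory(p, csc_seed(1), 3)
        assert np.allclose(tr.totals, [1.0, 2.0, 3.2, 4.64])
        assert np.allclose([s.senescent for s in tr.states], [0, 0, 0.8, 1.76])

    def test_dimension_mismatch_rejected(self, csc_seed):
        p = sd.HierarchicalParams(0.2, 3, 0.0)
        with pytest.raises(ValueError, match="n_senescence"):
            sd.advance_generation(csc_seed(2), p)

    def test_zero_length_trajectory(self, csc_seed):
        p = sd.HierarchicalParams(0.2, 2, 0.0)
        tr = sd.simulate_trajectory(p, csc_seed(2), 0)
        assert len(tr) == 1 and tr.cpd[0] == 0.0
        with pytest.raises(ValueError):
            sd.simulate_trajectory(p, csc_seed(2), -1)

    def test_growth_rate_approaches_one_plus_delta(self, csc_seed):
        p = sd.HierarchicalParams(0.2, 3, 0.1)
        tr = sd.simulate_trajectory(p, csc_seed(3), 200)
        ratio = tr.totals[-1] / tr.totals[-2]
        assert ratio == pytest.approx(1.2, abs=1e-9)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        delta=st.floats(-0.9, 1.0),
        n=st.integers(1, 8),
        d=st.floats(0.0, 1.0),
        k=st.integers(0, 30),
    )
    def test_populations_stay_non_negative_and_fractions_bounded(
        self, delta, n, d, k
    ):
        p = sd.HierarchicalParams(delta, n, d, csc_fraction_0=0.3)
        tr = sd.simulate_trajectory(p, k_max=k)
        assert all(s.total >= 0 for s in tr.states)
        assert np.all(tr.senescent_fraction >= -1e-15)
        assert np.all(tr.senescent_fraction + tr.csc_fraction <= 1 + 1e-12)


class TestClosedForms:
    @pytest.mark.parametrize("delta,n,d", GRID)
    def test_csc_seeded_matches_recursion(self, delta, n, d, csc_seed):
        p = sd.HierarchicalParams(delta, n, d)
        state = csc_seed(n)
        for k in range(41):
            cf = sd.csc_seeded_solution(p, k)
            for got, want in (
                (cf.csc, state.csc),
                (cf.senescent, state.senescent),
                (cf.total, state.total),
            ):
                assert got == pytest.approx(want, rel=1e-12, abs=1e-12)
            np.testing.assert_allclose(
                cf.cc_by_age, state.cc_by_age, rtol=1e-12, atol=1e-12
            )
            state = sd.advance_generation(state, p)

    @pytest.mark.parametrize("delta,n,d", GRID)
    def test_cc_seeded_matches_recursion(self, delta, n, d, cc_seed):
        p = sd.HierarchicalParams(delta, n, d)
        state = cc_seed(n)
        for k in range(41):
            cf = sd.cc_seeded_solution(p, k)
            assert cf.total == pytest.approx(state.total, rel=1e-12, abs=1e-12)
            assert cf.senescent == pytest.approx(
                state.senescent, rel=1e-12, abs=1e-12
            )
            assert cf.csc == 0.0
            state = sd.advance_generation(state, p)

    def test_csc_seeded_at_zero(self):
        cf = sd.csc_seeded_solution(sd.HierarchicalParams(0.3, 4, 0.2), 0)
        assert cf.csc == 1.0 and cf.total == 1.0

    def test_cc_seeded_at_zero_is_uniform(self):
        cf = sd.cc_seeded_solution(sd.HierarchicalParams(0.3, 4, 0.2), 0)
        assert np.allclose(cf.cc_by_age, 0.25)
        assert cf.total == pytest.approx(1.0)

    def test_homeostatic_csc_seeded_total_hand_value(self):
        # delta = 0, N = 3, k = 5: total = 2^{N-1} (k - N + 2) = 16
        cf = sd.csc_seeded_solution(sd.HierarchicalParams(0.0, 3, 0.0), 5)
        assert cf.total == pytest.approx(16.0)

    def test_cc_seeded_hand_cohorts(self):
        # N = 2, d = 0, k = 3: all mass senescent, total 1.5
        cf = sd.cc_seeded_solution(sd.HierarchicalParams(0.0, 2, 0.0), 3)
        assert cf.senescent == pytest.approx(1.5)
        assert cf.cc_by_age.sum() == 0.0

    def test_transience_of_cc_seeded_part(self):
        p = sd.HierarchicalParams(0.2, 4, 0.1)
        k = np.array([200.0])
        tot_s, _, _ = _csc_seeded_curves(p.delta, 4, p.death_prob, k)
        tot_c, _ = _cc_seeded_curves(4, p.death_prob, k)
        assert tot_c[0] / tot_s[0] < 1e-8


class TestTotalPopulation:
    def test_superposition_endpoints(self):
        for f in (0.0, 1.0):
            p = sd.HierarchicalParams(0.2, 3, 0.1, csc_fraction_0=f)
            seeded = (
                sd.csc_seeded_solution(p, 7) if f == 1.0 else sd.cc_seeded_solution(p, 7)
            )
            assert sd.total_population(p, 7) == pytest.approx(seeded.total, rel=1e-12)

    @pytest.mark.parametrize("f", [0.25, 0.5, 0.9])
    def test_superposition_linearity(self, f):
        mk = lambda ff: sd.HierarchicalParams(0.2, 3, 0.1, csc_fraction_0=ff)
        k = 11
        mixed = sd.total_population(mk(f), k)
        pure = f * sd.total_population(mk(1.0), k) + (1 - f) * sd.total_population(
            mk(0.0), k
        )
        assert mixed == pytest.approx(pure, rel=1e-12)

    def test_negative_generation_rejected(self):
        with pytest.raises(ValueError):
            sd.total_population(sd.HierarchicalParams(0.2, 3, 0.1), -1)

    def test_noninteger_k_interpolates_between_generations(self):
        p = sd.HierarchicalParams(0.2, 3, 0.1, csc_fraction_0=0.3)
        lo, mid, hi = (sd.total_population(p, kk) for kk in (5.0, 5.5, 6.0))
        assert lo < mid < hi


class TestAsymptotics:
    def test_senescent_fraction_formula_against_long_recursion(self):
        p = sd.HierarchicalParams(0.2, 3, 0.1)
        frac, _ = sd.converged_senescent_fraction(p)
        sen, csc = sd.asymptotic_fractions(p)
        assert sen == pytest.approx(0.8 / 1.4, rel=1e-9)
        assert frac == pytest.approx(sen, abs=1e-9)
        assert csc == pytest.approx((0.6 / 1.4) * 0.6**3, rel=1e-9)

    def test_n_independence_of_senescent_fraction(self):
        vals = [
            sd.asymptotic_fractions(sd.HierarchicalParams(0.2, n, 0.0))[0]
            for n in range(1, 11)
        ]
        assert max(vals) - min(vals) <= 1e-12
        assert vals[0] == pytest.approx(2.0 / 3.0, rel=1e-12)

    def test_homeostatic_limit_is_full_senescence(self):
        sen, csc = sd.asymptotic_fractions(sd.HierarchicalParams(0.0, 5, 0.0))
        assert (sen, csc) == (1.0, 0.0)
        # d -> 0+ approaches 100% senescent
        sen_small_d, _ = sd.asymptotic_fractions(sd.HierarchicalParams(0.0, 5, 1e-6))
        assert sen_small_d == pytest.approx(1.0, abs=1e-5)

    def test_csc_fraction_increases_with_delta(self):
        fracs = [
            sd.asymptotic_fractions(sd.HierarchicalParams(d, 4, 0.1))[1]
            for d in np.linspace(0.01, 0.9, 12)
        ]
        assert np.all(np.diff(fracs) > 0)

    def test_trajectory_converges_to_asymptotic_fractions(self, csc_seed):
        p = sd.HierarchicalParams(0.3, 4, 0.2)
        tr = sd.simulate_trajectory(p, csc_seed(4), 2000)
        sen, csc = sd.asymptotic_fractions(p)
        assert tr.senescent_fraction[-1] == pytest.approx(sen, abs=1e-6)
        assert tr.csc_fraction[-1] == pytest.approx(csc, abs=1e-6)


class TestHomeostaticCPD:
    def test_hand_value(self):
        assert sd.homeostatic_cpd(3, 1.0, 5.0) == pytest.approx(4.0)

    def test_continuity_at_crossover(self):
        n = 7
        assert sd.homeostatic_cpd(n, 1.0, float(n)) == pytest.approx(float(n))
        eps = 1e-9
        assert sd.homeostatic_cpd(n, 1.0, n + eps) == pytest.approx(n, abs=1e-6)

    def test_zero_time(self):
        assert sd.homeostatic_cpd(10, 0.5, 0.0) == 0.0

    def test_matches_recursion_totals(self, csc_seed):
        p = sd.HierarchicalParams(0.0, 4, 0.0)
        tr = sd.simulate_trajectory(p, csc_seed(4), 12)
        expected = [sd.homeostatic_cpd(4, 1.0, float(k)) for k in range(13)]
        assert np.allclose(tr.cpd, expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sd.homeostatic_cpd(4, 0.0, 1.0)
        with pytest.raises(ValueError):
            sd.homeostatic_cpd(4, 1.0, -1.0)
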