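"""Closed-form equilibrium, fitness, stability and comparative statics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hscniche as hn
from hscniche.equilibrium import NoPositiveEquilibrium
from hscniche.synthetic import sample_clone_params

rate = st.floats(min_value=1e-3, max_value=10.0, allow_nan=False)
gap = st.floats(min_value=1e-3, max_value=10.0, allow_nan=False)


def persistent_clone(b, u, d_A, g, d_I):
    return hn.CloneParams(b=b, u=u, r=d_A + g, d_A=d_A, d_I=d_I)


class TestFitness:
    def test_printed_formula(self):
        clone = hn.CloneParams(b=0.1, u=0.2, r=1.0, d_A=0.5, d_I=1.0)
        assert hn.fitness(clone) == pytest.approx(0.1 * 0.5 / (1.0 * 1.5), rel=1e-12)

    def test_non_persistent_clone_has_zero_fitness(self):
        clone = hn.CloneParams(b=0.1, u=0.2, r=0.5, d_A=0.5, d_I=1.0)
        assert hn.fitness(clone) == 0.0

    def test_codoubling_b_and_dI_leaves_fitness_unchanged(self):
        clone = hn.CloneParams(b=0.1, u=0.2, r=1.0, d_A=0.5, d_I=1.0)
        doubled = clone.with_(b=0.2, d_I=2.0)
        assert hn.fitness(doubled) == pytest.approx(hn.fitness(clone), rel=1e-12)

    def test_undefined_when_r_plus_dA_zero(self):
        clone = hn.CloneParams(b=0.1, u=0.2, r=0.0, d_A=0.0, d_I=1.0)
        with pytest.raises(ValueError, match="r \\+ d_A"):
            hn.fitness(clone)

    @given(b=rate, u1=rate, u2=rate, d_A=rate, g=gap, d_I=rate)
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_independent_of_detachment(self, b, u1, u2, d_A, g, d_I):
        c1 = persistent_clone(b, u1, d_A, g, d_I)
        c2 = persistent_clone(b, u2, d_A, g, d_I)
        assert hn.fitness(c1) == hn.fitness(c2)

    @given(b=rate, u=rate, d_A=rate, g=gap, d_I=rate)
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_fitness_times_vacancy_is_one(self, b, u, d_A, g, d_I):
        clone = persistent_clone(b, u, d_A, g, d_I)
        product = hn.fitness(clone) * hn.empty_niche_equilibrium(clone)
        assert product == pytest.approx(1.0, rel=1e-12)


class TestEmptyNiche:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(b=0.1, u=0.2, r=1.0, d_A=0.5, d_I=1.0), 30.0),
            (dict(b=0.5, u=0.1, r=0.03, d_A=0.01, d_I=0.05), 0.2),
        ],
    )
    def test_printed_formula(self, kwargs, expected):
        assert hn.empty_niche_equilibrium(hn.CloneParams(**kwargs)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_no_positive_equilibrium_when_not_persistent(self):
        clone = hn.CloneParams(b=0.1, u=0.2, r=0.4, d_A=0.5, d_I=1.0)
        with pytest.raises(NoPositiveEquilibrium):
            hn.empty_niche_equilibrium(clone)

    def test_independent_of_u_and_K(self, rng):
        """Vacancy E* and the ratio I*/A* depend only on b, r, d_A, d_I."""
        clone = sample_clone_params(rng)
        for u_scale, K in [(3.0, 100.0), (0.2, 1e4), (1.0, 50.0)]:
            variant = clone.with_(u=clone.u * u_scale)
            assert hn.empty_niche_equilibrium(variant) == pytest.approx(
                hn.empty_niche_equilibrium(clone), rel=1e-12
            )
            eq = hn.monoclonal_equilibrium(hn.SystemParams(K=K, clones=(variant,)))
            if eq.exists:
                assert eq.I_star / eq.A_star == pytest.approx(
                    (clone.r - clone.d_A) / clone.d_I, rel=1e-12
                )


class TestMonoclonalEquilibrium:
    def test_example_values(self, example_system):
        eq = hn.monoclonal_equilibrium(example_system)
        assert eq.exists and eq.stable
        assert eq.N_star == pytest.approx(70.0, rel=1e-12)
        assert eq.A_star == pytest.approx(28.0 / 3.0, rel=1e-12)
        assert eq.I_star == pytest.approx(14.0 / 3.0, rel=1e-12)
        assert eq.E_star == pytest.approx(30.0, rel=1e-12)
        assert eq.flux_star == pytest.approx(28.0 / 3.0, rel=1e-12)

    def test_flux_two_ways_agree(self, rng):
        for _ in range(20):
            clone = sample_clone_params(rng)
            eq = hn.monoclonal_equilibrium(hn.SystemParams(K=100.0, clones=(clone,)))
            assert eq.flux_star == pytest.approx(
                clone.d_A * eq.A_star + clone.d_I * eq.I_star, rel=1e-10
            )

    def test_zero_detachment_is_degenerate(self, example_system):
        params = example_system.replace_clone(0, example_system.clones[0].with_(u=0.0))
        eq = hn.monoclonal_equilibrium(params)
        assert not eq.exists
        assert eq.degenerate == "frozen-niche"
        assert eq.A_star == 0.0 and eq.I_star == 0.0 and eq.flux_star == 0.0

    def test_niche_too_small(self, example_system):
        params = hn.SystemParams(K=20.0, clones=example_system.clones)  # E* = 30 > K
        eq = hn.monoclonal_equilibrium(params)
        assert not eq.exists

    def test_equilibrium_zeroes_rhs_on_random_draws(self, rng):
        """Closed forms and the ODE right-hand side are mutually consistent."""
        for _ in range(50):
            clone = sample_clone_params(rng)
            params = hn.SystemParams(K=100.0, clones=(clone,))
            eq = hn.monoclonal_equilibrium(params, check_stability=False)
            state = hn.StateVector(N=[eq.N_star], A=[eq.A_star], I=[eq.I_star])
            d = hn.rhs(state, params)
            scale = max(eq.N_star, eq.A_star, eq.I_star)
            assert np.max(np.abs([d.N[0], d.A[0], d.I[0]])) < 1e-10 * scale

    def test_random_equilibria_are_stable(self, rng):
        for _ in range(20):
            clone = sample_clone_params(rng)
            eq = hn.monoclonal_equilibrium(hn.SystemParams(K=100.0, clones=(clone,)))
            assert eq.stable


class TestComparativeStatics:
    def test_detachment_row(self, example_system):
        assert hn.comparative_statics(example_system, "u", 1.0) == ("0", "+", "+", "+")

    def test_inactive_differentiation_row(self, example_system):
        assert hn.comparative_statics(example_system, "d_I", 1.0) == ("-", "-", "-", "-")

    def test_full_sign_table_at_example_baseline(self, example_system):
        table = hn.comparative_statics_table(example_system)
        assert table["K"] == ("+", "+", "+", "+")
        assert table["b"] == ("+", "+", "+", "+")
        assert table["d_A"] == ("-", "-", "-", "-")
        assert table["d_I"] == ("-", "-", "-", "-")
        assert table["u"][0] == "0"
        # division rate: N*, I*, flux* rise; A* is conditional (see below)
        assert table["r"][0] == "+" and table["r"][1] == "+" and table["r"][3] == "+"

    def test_active_pool_sign_under_division_rate_is_conditional(self, example_system):
        """A* increases with r only when r is close to d_A: the sign flips
        between r = 0.51 (near d_A = 0.5) and r = 5. A large niche keeps
        the equilibrium positive at the near-critical division rate."""
        near = hn.SystemParams(K=1e4, clones=(example_system.clones[0].with_(r=0.51),))
        far = hn.SystemParams(K=1e4, clones=(example_system.clones[0].with_(r=5.0),))
        assert hn.comparative_statics(near, "r")[2] == "+"
        assert hn.comparative_statics(far, "r")[2] == "-"

    def test_destroyed_equilibrium_raises(self, example_system):
        params = hn.SystemParams(K=31.0, clones=example_system.clones)  # E* = 30
        with pytest.raises(NoPositiveEquilibrium):
            hn.comparative_statics(params, "d_I", rel_step=1.0)
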