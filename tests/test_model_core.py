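"""Unit tests for the ODE core: right-hand side, integration, events."""

import numpy as np
import pytest

import hscniche as hn
from hscniche.model import IntegrationError


class TestRhs:
    def test_zero_at_closed_form_equilibrium(self, example_system, example_eq):
        state = hn.StateVector(
            N=[example_eq.N_star], A=[example_eq.A_star], I=[example_eq.I_star]
        )
        d = hn.rhs(state, example_system)
        for arr in (d.N, d.A, d.I):
            assert np.all(np.abs(arr) < 1e-10)

    def test_frozen_niche_is_stationary(self):
        """With u = 0 and empty unbound pools, any occupancy is stationary."""
        clone = hn.CloneParams(b=0.1, u=0.0, r=1.0, d_A=0.5, d_I=1.0)
        params = hn.SystemParams(K=100.0, clones=(clone,))
        state = hn.StateVector(N=[42.0], A=[0.0], I=[0.0])
        d = hn.rhs(state, params)
        assert np.all(d.N == 0) and np.all(d.A == 0) and np.all(d.I == 0)

    def test_two_clone_niche_flux_additivity(self, rng):
        """d(N1+N2)/dt equals the sum of per-clone attachment minus detachment
        fluxes evaluated at the shared empty-niche count."""
        c1 = hn.CloneParams(b=0.1, u=0.2, r=1.0, d_A=0.5, d_I=1.0)
        c2 = hn.CloneParams(b=0.3, u=0.05, r=0.8, d_A=0.2, d_I=0.6)
        params = hn.SystemParams(K=100.0, clones=(c1, c2))
        state = hn.StateVector(N=[40.0, 20.0], A=[3.0, 5.0], I=[2.0, 7.0])
        d = hn.rhs(state, params)
        E = 100.0 - 60.0
        expected = (c1.b * 2.0 + c2.b * 7.0) * E - c1.u * 40.0 - c2.u * 20.0
        assert d.N.sum() == pytest.approx(expected, rel=1e-12)

    def test_conservation_source_and_sinks(self, example_system):
        """Total stem-cell change is exactly division gain minus
        differentiation losses (attachment/detachment are internal moves)."""
        state = hn.StateVector(N=[50.0], A=[8.0], I=[6.0])
        c = example_system.clones[0]
        d = hn.rhs(state, example_system)
        total = d.N[0] + d.A[0] + d.I[0]
        assert total == pytest.approx(c.r * 8.0 - c.d_A * 8.0 - c.d_I * 6.0, rel=1e-12)

    def test_rejects_negative_state_and_overfull_niche(self, example_system):
        with pytest.raises(ValueError, match="negative"):
            hn.rhs(hn.StateVector(N=[-1.0], A=[0.0], I=[0.0]), example_system)
        with pytest.raises(ValueError, match="over-filled"):
            hn.rhs(hn.StateVector(N=[150.0], A=[0.0], I=[0.0]), example_system)


class TestProgenitorFlux:
    def test_equilibrium_value(self, example_system, example_eq):
        """At monoclonal equilibrium the flux equals r*u*(K - E*)/(r + d_A)."""
        state = hn.StateVector(
            N=[example_eq.N_star], A=[example_eq.A_star], I=[example_eq.I_star]
        )
        flux = hn.progenitor_flux(state, example_system)
        assert flux[0] == pytest.approx(1.0 * 0.2 * 70.0 / 1.5, rel=1e-12)  # 9.3333

    def test_zero_without_unbound_cells(self, example_system):
        state = hn.StateVector(N=[70.0], A=[0.0], I=[0.0])
        assert hn.progenitor_flux(state, example_system)[0] == 0.0

    def test_flux_jumps_when_inactive_differentiation_doubles(
        self, example_system, example_eq
    ):
        """Doubling d_I instantaneously doubles the d_I*I contribution."""
        state = hn.StateVector(
            N=[example_eq.N_star], A=[example_eq.A_star], I=[example_eq.I_star]
        )
        base = hn.progenitor_flux(state, example_system)[0]
        doubled = example_system.replace_clone(
            0, example_system.clones[0].with_(d_I=2.0)
        )
        jumped = hn.progenitor_flux(state, doubled)[0]
        assert jumped == pytest.approx(base + 1.0 * example_eq.I_star, rel=1e-12)
        assert jumped > base


class TestSimulate:
    def test_long_time_integration_reaches_closed_form(self, example_system, example_eq):
        init = hn.StateVector(N=[50.0], A=[0.0], I=[0.0])
        traj = hn.simulate(example_system, init, (0.0, 2000.0))
        final = traj.final_state()
        assert final.N[0] == pytest.approx(example_eq.N_star, rel=1e-6)
        assert final.A[0] == pytest.approx(example_eq.A_star, rel=1e-6)
        assert final.I[0] == pytest.approx(example_eq.I_star, rel=1e-6)

    def test_stem_cells_die_out_without_niche(self, example_system):
        """K = 0: the unbound subsystem has negative eigenvalues only."""
        params = hn.SystemParams(K=0.0, clones=example_system.clones)
        init = hn.StateVector(N=[0.0], A=[10.0], I=[10.0])
        traj = hn.simulate(params, init, (0.0, 50.0))
        totals = traj.final_state().total_stem()
        assert totals[0] < 1e-6

    def test_decay_with_attachment_disabled(self, example_system):
        params = example_system.replace_clone(0, example_system.clones[0].with_(b=0.0))
        init = hn.StateVector(N=[70.0], A=[5.0], I=[5.0])
        traj = hn.simulate(params, init, (0.0, 200.0))
        assert traj.final_state().total_stem()[0] < 1e-6

    def test_double_detachment_preserves_niche_occupancy(
        self, example_system, example_eq
    ):
        events = [hn.Event(time=1.0, kind="scale_param", target="u", magnitude=2.0)]
        init = hn.equilibrium_state(example_system)
        traj = hn.simulate(example_system, init, (0.0, 500.0), events=events)
        final = traj.final_state()
        assert final.N[0] == pytest.approx(example_eq.N_star, rel=1e-6)
        assert final.A[0] > example_eq.A_star
        assert final.I[0] > example_eq.I_star

    def test_invariants_along_trajectory(self, example_system):
        init = hn.StateVector(N=[99.0], A=[50.0], I=[0.5])
        traj = hn.simulate(example_system, init, (0.0, 100.0))
        assert np.all(traj.N >= -1e-8)
        assert np.all(traj.A >= -1e-8)
        assert np.all(traj.I >= -1e-8)
        assert np.all(traj.N.sum(axis=1) <= example_system.K * (1 + 1e-9))
        # stored flux is consistent with the stored state
        c = example_system.clones[0]
        np.testing.assert_allclose(
            traj.flux[:, 0], c.d_A * traj.A[:, 0] + c.d_I * traj.I[:, 0], rtol=1e-12
        )

    def test_recovery_after_depletion(self, example_system, example_eq):
        """Halving every compartment (acute blood loss) is transient: the
        same homeostatic equilibrium is re-established."""
        eq_state = hn.equilibrium_state(example_system)
        init = hn.StateVector(N=eq_state.N * 0.5, A=eq_state.A * 0.5, I=eq_state.I * 0.5)
        traj = hn.simulate(example_system, init, (0.0, 1000.0))
        final = traj.final_state()
        assert final.N[0] == pytest.approx(example_eq.N_star, rel=1e-6)
        assert final.I[0] == pytest.approx(example_eq.I_star, rel=1e-6)

    def test_rerun_is_bit_identical(self, example_system):
        events = [hn.Event(time=5.0, kind="scale_param", target="b", magnitude=2.0)]
        init = hn.StateVector(N=[50.0], A=[1.0], I=[1.0])
        t1 = hn.simulate(example_system, init, (0.0, 50.0), events=events)
        t2 = hn.simulate(example_system, init, (0.0, 50.0), events=events)
        assert np.array_equal(t1.N, t2.N)
        assert np.array_equal(t1.flux, t2.flux)

    def test_event_outside_span_rejected(self, example_system):
        init = hn.StateVector(N=[50.0], A=[0.0], I=[0.0])
        events = [hn.Event(time=99.0, kind="scale_param", target="b", magnitude=2.0)]
        with pytest.raises(hn.ConfigError, match="outside"):
            hn.simulate(example_system, init, (0.0, 10.0), events=events)

    def test_event_unknown_clone_rejected(self, example_system):
        init = hn.StateVector(N=[50.0], A=[0.0], I=[0.0])
        events = [hn.Event(time=1.0, kind="add_cells", clone=3, magnitude=5.0)]
        with pytest.raises(hn.ConfigError, match="clone 3"):
            hn.simulate(example_system, init, (0.0, 10.0), events=events)


class TestDownstreamPool:
    def test_progenitor_pool_tracks_amplified_flux(self, example_system, example_eq):
        params = hn.SystemParams(
            K=example_system.K,
            clones=example_system.clones,
            downstream=hn.DownstreamParams(amplification=10.0, clearance=2.0),
        )
        init = hn.StateVector(N=[50.0], A=[0.0], I=[0.0], D=[0.0])
        traj = hn.simulate(params, init, (0.0, 2000.0))
        # steady state: D* = amp * flux* / clearance
        assert traj.final_state().D[0] == pytest.approx(
            10.0 * example_eq.flux_star / 2.0, rel=1e-6
        )
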