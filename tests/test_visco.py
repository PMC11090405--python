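"""Viscoelastic actin-network engine: relations, ODE oracle, invariants."""

import math

import numpy as np
import pytest

from clutchsim import (clutch_rate, default_params, make_preset,
                       simulate_visco, spring_force, step_visco,
                       substrate_displacement, units_added)
from clutchsim.visco import ViscoClutchState


class TestUnitsAdded:
    def test_unloaded_gives_max(self, base_params):
        vp = base_params.visco
        assert units_added(0.0, vp) == vp.Nn_max

    def test_stall_gives_zero(self, base_params):
        vp = base_params.visco
        assert units_added(vp.Fs_actin, vp) == 0.0
        assert units_added(2 * vp.Fs_actin, vp) == 0.0

    def test_linear_at_half_stall(self, base_params):
        vp = base_params.visco
        assert units_added(vp.Fs_actin / 2, vp) == pytest.approx(
            vp.Nn_max / 2, rel=1e-12)

    def test_negative_force_raises(self, base_params):
        with pytest.raises(ValueError):
            units_added(-1.0, base_params.visco)


class TestSpringForce:
    def test_relaxed_network_zero(self, base_params):
        assert spring_force(50.0, 50.0, 100.0, base_params.visco) == 0.0

    def test_linearity_in_compression(self, base_params):
        vp = base_params.visco
        f1 = spring_force(10.0, 4.0, 100.0, vp)
        f2 = spring_force(16.0, 4.0, 100.0, vp)
        assert f2 == pytest.approx(2 * f1, rel=1e-12)

    def test_arithmetic_value(self, base_params):
        vp = base_params.visco
        vp.kactin = 1000.0
        # kactin*(Ladd - xc)/Ntot = 1000*11/10
        assert spring_force(11.0, 0.0, 10.0, vp) == pytest.approx(1100.0)

    def test_compression_only_clamp(self, base_params):
        vp = base_params.visco
        assert spring_force(0.0, 5.0, 10.0, vp) == 0.0
        assert spring_force(0.0, 5.0, 10.0, vp, clamp=False) < 0.0

    def test_unit_count_below_one_raises(self, base_params):
        with pytest.raises(ValueError):
            spring_force(1.0, 0.0, 0.5, base_params.visco)


class TestSubstrateDisplacement:
    def test_no_bound_clutches(self):
        assert substrate_displacement([5.0, 3.0], [False, False], 1.0, 2.0) == 0.0

    def test_single_clutch_equal_springs(self):
        assert substrate_displacement([8.0], [True], 2.0, 2.0) == pytest.approx(4.0)

    def test_rigid_substrate_limit(self):
        assert substrate_displacement([8.0], [True], 2.0, 1e12) == \
            pytest.approx(0.0, abs=1e-10)

    def test_reduces_to_lumped_form(self):
        xc = [3.0, 3.0, 3.0]
        bound = [True, True, True]
        kc, ks = 1.5, 4.0
        lumped = 3 * kc * 3.0 / (ks + 3 * kc)
        assert substrate_displacement(xc, bound, kc, ks) == \
            pytest.approx(lumped, rel=1e-12)

    def test_nonpositive_substrate_spring_raises(self):
        with pytest.raises(ValueError):
            substrate_displacement([1.0], [True], 1.0, 0.0)


class TestClutchRate:
    def test_mechanical_equilibrium(self, base_params):
        p = base_params
        vp = p.visco
        # choose xc so spring force equals total clutch force
        Ntot, Nc, Xsub = 100.0, 2, 1.0
        xc = 5.0
        Ladd = xc + Ntot * Nc * p.clutches.kc * (xc - Xsub) / vp.kactin
        assert clutch_rate(Ladd, xc, Ntot, Nc, Xsub, p) == pytest.approx(
            0.0, abs=1e-9)

    def test_viscosity_scaling(self, base_params):
        p = base_params
        v1 = clutch_rate(30.0, 5.0, 100.0, 1, 0.0, p)
        p.visco.eta *= 2
        assert clutch_rate(30.0, 5.0, 100.0, 1, 0.0, p) == pytest.approx(
            v1 / 2, rel=1e-12)

    def test_nonpositive_eta_raises(self, base_params):
        base_params.visco.eta = -1.0
        with pytest.raises(ValueError):
            clutch_rate(1.0, 0.0, 10.0, 1, 0.0, base_params)


class TestDampedRelaxationOracle:
    """Single permanently-bound clutch, frozen growth: the compression and
    extension relax exponentially to mechanical equilibrium.

    With conserved quantities e = alpha*(c0 - c), alpha = ks/(ks+kc), the
    compression obeys dc/dt = -[(ka/N + kc*alpha)*c - kc*alpha*c0]/eta, a
    linear ODE with closed-form solution.  The Euler trajectory must match
    it within 1% out to five time constants, improving as dt shrinks.
    """

    def _setup(self, dt):
        p = default_params()
        p.clutches.nf = 1
        p.clutches.kont = 0.0
        p.clutches.koff_scale = 0.0
        p.koff_mode = "constant"
        p.visco.Nn_max = 1e-300      # frozen growth
        p.visco.kactin = 1000.0
        p.visco.N0 = 100.0
        p.dt = dt
        return p

    def _analytic(self, p, c0, t):
        ks = p.substrate.ksub
        kc = p.clutches.kc
        ka_eff = p.visco.kactin / p.visco.N0
        alpha = ks / (ks + kc)
        lam = (ka_eff + kc * alpha) / p.visco.eta
        c_inf = kc * alpha * c0 / (ka_eff + kc * alpha)
        return c_inf + (c0 - c_inf) * np.exp(-lam * t), lam

    @pytest.mark.parametrize("dt", [2e-4, 1e-4])
    def test_euler_matches_closed_form(self, dt, rng):
        p = self._setup(dt)
        c0 = 25.0
        state = ViscoClutchState.initial(p)
        state.bound[0] = True
        state.comp = c0
        _, lam = self._analytic(p, c0, 0.0)
        t_end = 5.0 / lam
        n = int(round(t_end / dt))
        for _ in range(n):
            step_visco(state, p, rng)
        expected, _ = self._analytic(p, c0, state.t)
        assert state.comp == pytest.approx(float(expected), rel=0.01)
        # extension tracks the conservation law e = alpha*(c0 - c)
        alpha = p.substrate.ksub / (p.substrate.ksub + p.clutches.kc)
        assert state.ext[0] == pytest.approx(alpha * (c0 - state.comp),
                                             rel=1e-6)

    def test_refinement_improves_accuracy(self, rng):
        errs = []
        for dt in (4e-4, 1e-4):
            p = self._setup(dt)
            c0 = 25.0
            state = ViscoClutchState.initial(p)
            state.bound[0] = True
            state.comp = c0
            _, lam = self._analytic(p, c0, 0.0)
            n = int(round(2.0 / lam / dt))
            for _ in range(n):
                step_visco(state, p, rng)
            expected, _ = self._analytic(p, c0, state.t)
            errs.append(abs(state.comp - float(expected)))
        assert errs[1] < errs[0]


class TestStepVisco:
    def test_stalled_growth_freezes_unit_count(self, fast_visco, rng):
        p = fast_visco
        state = ViscoClutchState.initial(p)
        state.bound[0] = True
        state.ext[0] = 2 * p.visco.Fs_actin / p.clutches.kc
        ntot0 = state.Ntot
        step_visco(state, p, rng)
        assert state.Ntot == ntot0

    def test_full_release_decays_traction_and_relaxes(self, fast_visco, rng):
        p = fast_visco
        p.clutches.kont = 0.0
        state = ViscoClutchState.initial(p)
        state.comp = 50.0
        c0 = state.comp
        for _ in range(100):
            step_visco(state, p, rng)
        assert state.Fadh == 0.0
        assert state.Xsub == 0.0
        assert state.comp < c0  # damper dissipates the stored compression
        assert state.v_retro == 0.0

    def test_reset_release_mode_discards_compression(self, fast_visco, rng):
        p = fast_visco
        p.clutches.kont = 0.0
        p.release_mode = "reset"
        state = ViscoClutchState.initial(p)
        state.comp = 50.0
        step_visco(state, p, rng)
        assert state.comp == 0.0

    def test_invalid_state_raises(self, fast_visco, rng):
        state = ViscoClutchState.initial(fast_visco)
        state.comp = float("nan")
        with pytest.raises(ValueError):
            step_visco(state, fast_visco, rng)


class TestSimulateVisco:
    def test_fixed_seed_bit_identical(self, fast_visco):
        a, ev_a = simulate_visco(fast_visco)
        b, ev_b = simulate_visco(fast_visco)
        assert np.array_equal(a.vf, b.vf)
        assert np.array_equal(a.traction, b.traction)
        assert np.array_equal(ev_a.unclutch_times, ev_b.unclutch_times)

    def test_traction_nonnegative(self, fast_visco):
        ts, _ = simulate_visco(fast_visco)
        assert np.all(ts.traction >= 0.0)

    def test_requires_positive_substrate_spring(self, fast_visco):
        fast_visco.substrate.E = 0.0
        with pytest.raises(ValueError):
            simulate_visco(fast_visco)

    def test_python_step_matches_kernel(self):
        """Reference step function and numba kernel agree trajectory-wise."""
        p = make_preset("BBS", model="visco")
        p.clutches.nf = 4
        p.duration = 1.0
        p.sample_stride = 1
        p.seed = 3
        ts, _ = simulate_visco(p)
        rng = np.random.default_rng(3)
        state = ViscoClutchState.initial(p)
        ks = p.substrate.ksub
        for k in range(1, len(ts)):
            step_visco(state, p, rng)
            # force balance: Fsub = ks*Xsub = sum of clutch spring forces
            assert state.Fadh == pytest.approx(ks * state.Xsub, rel=1e-9,
                                               abs=1e-12)
            fsub_kernel = ts.traction[k] / 1e6 * math.pi * p.substrate.ra ** 2
            assert fsub_kernel == pytest.approx(state.Fadh, rel=1e-9,
                                                abs=1e-9)
            assert ts.nbound[k] == state.bound.sum()
            assert ts.vf[k] == pytest.approx(state.v_retro, rel=1e-9,
                                             abs=1e-12)

    def test_euler_convergence_deterministic_limit(self):
        """Halving dt changes mean traction and flow by well under 2% in
        the deterministic configuration (instant binding, no unbinding)."""
        means = {}
        for dt in (5e-4, 2.5e-4):
            p = make_preset("BBS", model="visco")
            p.clutches.kont = 1e6          # binding probability 1 per step
            p.clutches.koff_scale = 0.0    # no unbinding
            p.koff_mode = "constant"
            p.dt = dt
            p.sample_stride = max(1, int(round(0.01 / dt)))
            p.duration = 60.0
            # growth per unit time held fixed as dt changes
            p.visco.Nn_max = 2.5e-4 * dt / 5e-4
            ts, _ = simulate_visco(p)
            s = ts.summary(0.2)
            means[dt] = (s["traction_pa"], s["flow_nm_s"])
        for i in range(2):
            a, b = means[5e-4][i], means[2.5e-4][i]
            assert abs(a - b) / max(abs(b), 1e-12) < 0.02, means
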