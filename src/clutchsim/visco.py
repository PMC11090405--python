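"""Viscoelastic actin-network molecular-clutch engine.

The lamellipodial F-actin network is a 1-D chain of mesoscale elastic units
(per-unit spring constant kactin) in series with a viscous damper (eta),
growing at the membrane (a rigid wall) by addition of units of rest length
L.  Addition compresses the chain against the adhesion clutches at its
rear; the compressive elastic force drags the clutch ensemble, whose
springs (kc) load the elastic substrate (ks).  The network rear position Xc
obeys the damped force balance

    eta * dXc/dt = kactin*(Ladd - Xc)/Ntot - Fadh,

integrated by the explicit Euler method, where Ladd is the cumulative added
rest length, Ntot the current unit count (series softening) and Fadh the
total clutch force.  Unit addition per step is Nn = Nn_max*(1 -
Fc_max/Fs_actin), stalling as the largest single-clutch force approaches
the polymerization stall.

Integration uses the translation-invariant variables comp = Ladd - Xc (net
chain compression) and the per-clutch spring extensions e_i = xc_i - Xsub,
which evolve as de_i/dt = dXc/dt - dXsub/dt with the substrate following
quasi-statically, dXsub/dt = Nc*kc*dXc/dt / (ks + Nc*kc).  A clutch binds
with zero extension and unbinds by the same slip-bond law as the rigid
engine; on release the substrate recoils, redistributing load onto the
remaining clutches (the failure-cascade mechanism).  When the last clutch
releases the stored compression relaxes freely through the damper
(release_mode="relax") or is discarded ("reset").  The rearward flow speed
is the largest clutch displacement rate, |dXc/dt| while any clutch is
engaged and zero otherwise, so each full release drops the speed to zero
and each re-engagement of the still-compressed chain produces a drag
spike: load-and-fail cycling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .params import ParameterSet, force_to_stress
from .rigid import _koff_rate
from .series import EventLog, TimeSeries

__all__ = ["units_added", "spring_force", "substrate_displacement",
           "clutch_rate", "ViscoClutchState", "step_visco", "simulate_visco"]


# ---------------------------------------------------------------------------
# elementary relations
# ---------------------------------------------------------------------------

def units_added(Fc: float, vp) -> float:
    """Actin units added this step, Nn_max*(1 - Fc/Fs_actin), clamped to
    [0, Nn_max].  Fc is the largest instantaneous single-clutch force (pN)."""
    if Fc < 0:
        raise ValueError(f"clutch force must be non-negative, got {Fc}")
    return vp.Nn_max * min(max(1.0 - Fc / vp.Fs_actin, 0.0), 1.0)


def spring_force(Ladd: float, xc: float, Ntot: float, vp,
                 clamp: bool = True) -> float:
    """Elastic force of the compressed chain at rear position xc (pN).

    Fspring = kactin*(Ladd - xc)/Ntot; with clamp the chain cannot pull
    (compression only).
    """
    if Ntot < 1:
        raise ValueError(f"unit count must be >= 1, got {Ntot}")
    f = vp.kactin * (Ladd - xc) / Ntot
    return max(f, 0.0) if clamp else f


def substrate_displacement(xc, bound, kc: float, ks: float) -> float:
    """Substrate displacement from clutch/substrate force balance (nm).

    Xsub = kc * sum(xc over bound) / (ks + Nc*kc); reduces to the lumped
    single-position form when all bound positions coincide.
    """
    if ks <= 0:
        raise ValueError(f"substrate spring constant must be positive, got {ks}")
    xc = np.asarray(xc, dtype=float)
    bound = np.asarray(bound, dtype=bool)
    nc = int(np.count_nonzero(bound))
    if nc == 0:
        return 0.0
    return kc * float(np.sum(xc[bound])) / (ks + nc * kc)


def clutch_rate(Ladd: float, xc: float, Ntot: float, Nc: int, Xsub: float,
                p: ParameterSet) -> float:
    """Network-rear velocity dXc/dt (nm/s) from the damped force balance."""
    vp = p.visco
    if vp.eta <= 0:
        raise ValueError("viscosity must be positive")
    fspring = spring_force(Ladd, xc, Ntot, vp)
    fadh = Nc * p.clutches.kc * (xc - Xsub)
    return (fspring - fadh) / vp.eta


# ---------------------------------------------------------------------------
# state and single-step reference implementation
# ---------------------------------------------------------------------------

@dataclass
class ViscoClutchState:
    """Instantaneous engine state (arrays are length nf).

    ext holds the per-clutch spring extensions e_i = xc_i - Xsub (zero for
    unbound clutches); comp holds the net chain compression Ladd - Xc.
    Ladd and Ntot accumulate over the run.
    """

    t: float
    Ntot: float
    Ladd: float
    comp: float
    bound: np.ndarray
    ext: np.ndarray
    Xsub: float
    Fspring: float
    Fadh: float
    Fc_max_inst: float
    v_retro: float

    @property
    def xc(self) -> np.ndarray:
        """Per-clutch positions xc_i = Xsub + e_i (printed-form coordinates)."""
        return self.Xsub + self.ext

    @classmethod
    def initial(cls, p: ParameterSet) -> "ViscoClutchState":
        nf = p.clutches.nf
        return cls(t=0.0, Ntot=float(p.visco.N0), Ladd=0.0, comp=0.0,
                   bound=np.zeros(nf, dtype=np.bool_), ext=np.zeros(nf),
                   Xsub=0.0, Fspring=0.0, Fadh=0.0, Fc_max_inst=0.0,
                   v_retro=0.0)


def step_visco(state: ViscoClutchState, p: ParameterSet,
               rng: np.random.Generator) -> ViscoClutchState:
    """Advance the state by one Euler/Monte-Carlo step of length p.dt.

    Order: per-clutch forces, unit addition, stochastic binding/unbinding
    with substrate recoil, Euler update of the rear position and
    extensions, substrate force balance, rearward speed.  Mutates and
    returns the state.
    """
    if not np.isfinite(state.t) or state.t < 0:
        raise ValueError("invalid state time")
    if not (np.isfinite(state.comp) and np.isfinite(state.Ntot)):
        raise ValueError("non-finite network state")
    dt = p.dt
    kin = p.clutches
    vp = p.visco
    kc = kin.kc
    ks = p.substrate.ksub
    if ks <= 0:
        raise ValueError("viscoelastic engine requires a positive substrate "
                         "spring (E > 0)")

    # (i) per-clutch forces
    fc = np.where(state.bound, np.maximum(kc * state.ext, 0.0), 0.0)
    state.Fc_max_inst = float(fc.max()) if len(fc) else 0.0
    ext_sum = float(np.sum(state.ext[state.bound]))

    # (ii) unit addition
    nn = units_added(state.Fc_max_inst, vp)
    state.Ntot += nn
    state.Ladd += nn * vp.L
    state.comp += nn * vp.L

    # (iii) stochastic binding (zero extension) and unbinding (slip bond),
    # then substrate recoil redistributing load on the survivors
    for i in range(kin.nf):
        if not state.bound[i]:
            if rng.random() < kin.kon * dt:
                state.bound[i] = True
                state.ext[i] = 0.0
    released = False
    for i in np.flatnonzero(state.bound):
        rate = (kin.koff_scale if p.koff_mode == "constant"
                else _koff_rate(fc[i], kin.koff_a1, kin.koff_b1,
                                kin.koff_a2, kin.koff_b2,
                                kin.koff_branch_force, kin.koff_scale))
        if rng.random() < rate * dt:
            state.bound[i] = False
            state.ext[i] = 0.0
            released = True
    nc = int(np.count_nonzero(state.bound))
    if released and nc > 0:
        x_old = kc * ext_sum / ks  # substrate displacement before release
        s_rem = float(np.sum(state.ext[state.bound]))
        x_new = (kc * s_rem + nc * kc * x_old) / (ks + nc * kc)
        state.ext[state.bound] += x_old - x_new

    # (iv) Euler update of the rear position / free relaxation
    fspring = vp.kactin * max(state.comp, 0.0) / state.Ntot
    fadh = kc * float(np.sum(state.ext[state.bound]))
    xcdot = (fspring - fadh) / vp.eta
    if nc > 0:
        xsubdot = nc * kc * xcdot / (ks + nc * kc)
        state.ext[state.bound] += (xcdot - xsubdot) * dt
        state.comp -= xcdot * dt
        state.v_retro = abs(xcdot)
    else:
        # no clutch engaged: the rearward speed (a clutch displacement
        # rate) is zero while the free chain relaxes through the damper
        state.v_retro = 0.0
        if p.release_mode == "reset":
            state.comp = 0.0
        else:
            state.comp = max(state.comp - xcdot * dt, 0.0)
    if state.comp < 0.0:
        state.comp = 0.0

    # (v) substrate force balance: Fsub = ks*Xsub = Fadh
    state.Fadh = kc * float(np.sum(state.ext[state.bound]))
    state.Xsub = state.Fadh / ks
    state.Fspring = vp.kactin * max(state.comp, 0.0) / state.Ntot
    state.t += dt
    return state


# ---------------------------------------------------------------------------
# compiled full-run kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _visco_kernel(nsteps, dt, ks, kc, nf, kon,
                  a1, b1, a2, b2, branch, koff_scale, koff_constant,
                  kactin, eta, L, n0, nn_max, fs_actin,
                  release_reset, stride, rng, ev_cap):
    nsamples = nsteps // stride + 1
    t_s = np.empty(nsamples)
    v_s = np.empty(nsamples)
    f_s = np.empty(nsamples)
    nb_s = np.zeros(nsamples, dtype=np.int64)

    unbind_t = np.empty(ev_cap)
    bind_t = np.empty(ev_cap)
    collapse_t = np.empty(ev_cap)
    n_unbind = 0
    n_bind = 0
    n_collapse = 0

    bound = np.zeros(nf, dtype=np.bool_)
    ext = np.zeros(nf)
    ntot = n0
    comp = 0.0
    v_retro = 0.0
    pmax = 0.0
    engaged = False

    t_s[0] = 0.0
    v_s[0] = 0.0
    f_s[0] = 0.0
    nb_s[0] = 0
    isample = 1

    p_on = kon * dt
    if p_on > pmax:
        pmax = p_on

    for step in range(nsteps):
        t = step * dt

        # (i) per-clutch forces and their maximum
        fc_max = 0.0
        ext_sum = 0.0
        for i in range(nf):
            if bound[i]:
                fci = kc * ext[i]
                if fci < 0.0:
                    fci = 0.0
                if fci > fc_max:
                    fc_max = fci
                ext_sum += ext[i]

        # (ii) unit addition, stalling with the largest clutch force
        frac = 1.0 - fc_max / fs_actin
        if frac < 0.0:
            frac = 0.0
        elif frac > 1.0:
            frac = 1.0
        nn = nn_max * frac
        ntot += nn
        comp += nn * L

        # (iii) binding (zero extension) and slip-bond unbinding
        for i in range(nf):
            if not bound[i]:
                if rng.random() < p_on:
                    bound[i] = True
                    ext[i] = 0.0
                    if n_bind < ev_cap:
                        bind_t[n_bind] = t
                    n_bind += 1
        released = False
        for i in range(nf):
            if bound[i]:
                fci = kc * ext[i]
                if fci < 0.0:
                    fci = 0.0
                if koff_constant:
                    rate = koff_scale
                else:
                    rate = _koff_rate(fci, a1, b1, a2, b2, branch, koff_scale)
                p_off = rate * dt
                if p_off > pmax:
                    pmax = p_off
                if rng.random() < p_off:
                    bound[i] = False
                    ext[i] = 0.0
                    released = True
                    if n_unbind < ev_cap:
                        unbind_t[n_unbind] = t
                    n_unbind += 1

        nc = 0
        s_rem = 0.0
        for i in range(nf):
            if bound[i]:
                nc += 1
                s_rem += ext[i]

        # substrate recoil after release: load redistributes onto survivors
        if released and nc > 0:
            x_old = kc * ext_sum / ks
            x_new = (kc * s_rem + nc * kc * x_old) / (ks + nc * kc)
            delta = x_old - x_new
            for i in range(nf):
                if bound[i]:
                    ext[i] += delta
            s_rem += nc * delta

        # (iv) Euler update of the rear position / free relaxation
        cpos = comp if comp > 0.0 else 0.0
        fspring = kactin * cpos / ntot
        fadh = kc * s_rem
        xcdot = (fspring - fadh) / eta
        if nc > 0:
            engaged = True
            xsubdot = nc * kc * xcdot / (ks + nc * kc)
            de = (xcdot - xsubdot) * dt
            for i in range(nf):
                if bound[i]:
                    ext[i] += de
            comp -= xcdot * dt
            v_retro = abs(xcdot)
        else:
            if engaged:
                engaged = False
                if n_collapse < ev_cap:
                    collapse_t[n_collapse] = t
                n_collapse += 1
            v_retro = 0.0
            if release_reset:
                comp = 0.0
            else:
                comp -= xcdot * dt
        if comp < 0.0:
            comp = 0.0

        # (v) substrate force balance: Fsub = ks*Xsub = sum of clutch forces
        fsub = 0.0
        for i in range(nf):
            if bound[i]:
                fsub += kc * ext[i]

        if (step + 1) % stride == 0:
            t_s[isample] = (step + 1) * dt
            v_s[isample] = v_retro
            f_s[isample] = fsub
            nb_s[isample] = nc
            isample += 1

    return (t_s[:isample], v_s[:isample], f_s[:isample], nb_s[:isample],
            bind_t[:min(n_bind, ev_cap)], unbind_t[:min(n_unbind, ev_cap)],
            collapse_t[:min(n_collapse, ev_cap)], pmax)


def simulate_visco(p: ParameterSet) -> tuple[TimeSeries, EventLog]:
    """Run the viscoelastic-clutch engine for p.duration seconds.

    Returns the sampled TimeSeries (flow speed in nm/s, traction in Pa) and
    the EventLog of binding, unbinding and full-release instants.  Identical
    seeds give bit-identical output.
    """
    p.validate()
    if p.substrate.ksub <= 0:
        raise ValueError("viscoelastic engine requires a positive substrate "
                         "spring (E > 0)")
    nsteps = int(round(p.duration / p.dt))
    rng = np.random.default_rng(p.seed)
    kin = p.clutches
    vp = p.visco
    ev_cap = max(int(4 * kin.nf * max(p.duration, 1.0)), 1000)

    (t_s, v_s, f_s, nb_s, bind_t, unbind_t, collapse_t, pmax) = _visco_kernel(
        nsteps, p.dt, p.substrate.ksub, kin.kc, kin.nf, kin.kon,
        kin.koff_a1, kin.koff_b1, kin.koff_a2, kin.koff_b2,
        kin.koff_branch_force, kin.koff_scale, p.koff_mode == "constant",
        vp.kactin, vp.eta, vp.L, float(vp.N0), vp.Nn_max, vp.Fs_actin,
        p.release_mode == "reset", p.sample_stride, rng, ev_cap)

    if pmax > 0.1:
        warnings.warn(
            f"max event probability per step was {pmax:.3f} > 0.1; "
            "consider reducing dt", stacklevel=2)

    traction = np.array([force_to_stress(f, p.substrate.ra) for f in f_s])
    events = EventLog(unclutch_times=collapse_t, rebind_times=bind_t,
                      bond_release_times=unbind_t)
    meta = {"model": "visco", "condition": p.condition, "seed": p.seed,
            "dt": p.dt, "sample_stride": p.sample_stride,
            "stiffness_kpa": p.substrate.E / 1000.0}
    ts = TimeSeries(times=t_s, vf=v_s, traction=traction, nbound=nb_s,
                    events=events, meta=meta)
    return ts, events
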