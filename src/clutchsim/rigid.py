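"""Rigid-actin molecular-clutch engine.

Fixed-timestep Monte-Carlo simulation of nf integrin clutches engaging a
rigidly treadmilling F-actin filament.  Flow speed follows the sum of a
linear myosin force-velocity relation and a linear polymerization
force-velocity relation; bound clutches are slip bonds with a two-branch
exponential unbinding law; talin unfolding recruits vinculin, which raises
the effective integrin density and hence the binding rate (adhesion
reinforcement).

The inner loop is compiled with numba; a fixed-seed run is bit-identical
across calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .params import ParameterSet, force_to_stress
from .series import EventLog, TimeSeries

__all__ = ["koff_force", "retrograde_velocity", "RigidClutchState",
           "step_rigid", "simulate_rigid"]

_N_PER_PN = 1.0e-12  # force coefficients are published in 1/N; forces are pN


# ---------------------------------------------------------------------------
# rate laws and force-velocity relation
# ---------------------------------------------------------------------------

@njit(cache=True)
def _koff_rate(fc, a1, b1, a2, b2, branch, scale):
    if fc < branch:
        return scale * a1 * np.exp(b1 * fc * _N_PER_PN)
    return scale * a2 * np.exp(b2 * fc * _N_PER_PN)


def koff_force(Fc: float, kin) -> float:
    """Slip-bond unbinding rate koff(Fc) in 1/s, Fc in pN.

    Two-branch exponential a*exp(b*Fc): (a1, b1) strictly below the branch
    force (13.2 pN), (a2, b2) from there on (extrapolated past its stated
    30 pN range), the whole law scaled by koff_scale.
    """
    if Fc < 0:
        raise ValueError(f"clutch force must be non-negative, got {Fc}")
    return _koff_rate(Fc, kin.koff_a1, kin.koff_b1, kin.koff_a2, kin.koff_b2,
                      kin.koff_branch_force, kin.koff_scale)


def retrograde_velocity(Fsub: float, p: ParameterSet) -> float:
    """Retrograde flow speed (nm/s) at substrate force Fsub (pN).

    vf = Va*(1 - Fsub/(nm*Fm)) + vactin_max*(1 - Fsub/Fs_actin), with the
    myosin term dropped for myosin-inhibited conditions and each term
    clamped at zero unless allow_reversal is set.
    """
    if Fsub < 0:
        raise ValueError(f"substrate force must be non-negative, got {Fsub}")
    v = 0.0
    if p.myosin_enabled and p.motors.nm > 0:
        term = p.motors.Va * (1.0 - Fsub / p.motors.stall_force)
        v += term if p.allow_reversal else max(term, 0.0)
    fs_act = p.actin_stall_force()
    term = p.polymer.vactin_max * (1.0 - Fsub / fs_act)
    v += term if p.allow_reversal else max(term, 0.0)
    return v


# ---------------------------------------------------------------------------
# state and single-step reference implementation
# ---------------------------------------------------------------------------

@dataclass
class RigidClutchState:
    """Instantaneous engine state (arrays are length nf)."""

    t: float
    bound: np.ndarray
    x: np.ndarray
    talin_unfolded: np.ndarray
    vinculin: np.ndarray
    dint_eff: float
    xsub: float
    Fsub: float
    vf: float
    events: dict = field(default_factory=lambda: {"bind": [], "unbind": [],
                                                  "unfold": []})

    @classmethod
    def initial(cls, p: ParameterSet) -> "RigidClutchState":
        nf = p.clutches.nf
        return cls(
            t=0.0,
            bound=np.zeros(nf, dtype=np.bool_),
            x=np.zeros(nf),
            talin_unfolded=np.zeros(nf, dtype=np.bool_),
            vinculin=np.zeros(nf, dtype=np.int64),
            dint_eff=p.clutches.dint,
            xsub=0.0,
            Fsub=0.0,
            vf=retrograde_velocity(0.0, p),
        )


def step_rigid(state: RigidClutchState, p: ParameterSet,
               rng: np.random.Generator) -> RigidClutchState:
    """Advance the state by one Monte-Carlo step of length p.dt (in place).

    Event order: binding, unbinding, talin/vinculin, advection of bound
    clutches by vf*dt, force balance, flow-speed update.
    """
    if not np.isfinite(state.t) or state.t < 0:
        raise ValueError("invalid state time")
    if not np.isfinite(state.Fsub):
        raise ValueError("non-finite substrate force in state")
    dt = p.dt
    kin = p.clutches
    tal = p.talin
    kc = kin.kc
    ksub = p.substrate.ksub

    kon_eff = kin.kont * state.dint_eff
    if max(kon_eff, koff_force(0.0, kin)) * dt > 0.1:
        warnings.warn("event probability per step exceeds 0.1; reduce dt",
                      stacklevel=2)

    # (i) binding: unbound clutches engage at the current substrate position
    for i in np.flatnonzero(~state.bound):
        if rng.random() < kon_eff * dt:
            state.bound[i] = True
            state.x[i] = state.xsub
            state.events["bind"].append(state.t)

    # (ii) unbinding (slip bond), resetting talin/vinculin for that clutch
    for i in np.flatnonzero(state.bound):
        fc = max(kc * (state.x[i] - state.xsub), 0.0)
        rate = (kin.koff_scale if p.koff_mode == "constant"
                else koff_force(fc, kin))
        if rng.random() < rate * dt:
            state.bound[i] = False
            state.x[i] = state.xsub
            state.talin_unfolded[i] = False
            state.dint_eff -= tal.dint_increment * state.vinculin[i]
            state.vinculin[i] = 0
            state.events["unbind"].append(state.t)

    # (iii) talin unfolding/refolding and vinculin recruitment
    for i in np.flatnonzero(state.bound):
        fc = max(kc * (state.x[i] - state.xsub), 0.0)
        fpt = fc * _N_PER_PN * tal.pt
        if not state.talin_unfolded[i]:
            kuf = np.exp(tal.kuf_pref + tal.kuf_exp * fpt)
            if rng.random() < min(kuf * dt, 1.0):
                state.talin_unfolded[i] = True
                state.events["unfold"].append(state.t)
        else:
            kf = np.exp(tal.kf_pref + tal.kf_exp * fpt)
            if rng.random() < min(kf * dt, 1.0):
                state.talin_unfolded[i] = False
        if state.talin_unfolded[i] and state.vinculin[i] < tal.vinculin_max:
            if rng.random() < min(tal.konv * dt, 1.0):
                state.vinculin[i] += 1
                state.dint_eff += tal.dint_increment

    # (iv) bound clutches ride the flowing filament
    state.x[state.bound] += state.vf * dt

    # (v) force balance: Fsub*(ksub + nb*kc) = ksub*kc*sum(x)
    nb = int(np.count_nonzero(state.bound))
    xsum = float(np.sum(state.x[state.bound]))
    state.xsub = kc * xsum / (ksub + nb * kc) if nb else 0.0
    state.Fsub = ksub * state.xsub

    # (vi) flow speed from the force-velocity relations
    state.vf = retrograde_velocity(state.Fsub, p)
    state.t += dt
    return state


# ---------------------------------------------------------------------------
# compiled full-run kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _rigid_kernel(nsteps, dt, ksub, kc, nf, kont, dint0, dint_inc, vinc_max,
                  a1, b1, a2, b2, branch, koff_scale, koff_constant,
                  kuf_pref, kuf_exp, kf_pref, kf_exp, pt, konv,
                  va, fs_myo, vact, fs_act, allow_reversal,
                  stride, rng, ev_cap):
    nsamples = nsteps // stride + 1
    t_s = np.empty(nsamples)
    vf_s = np.empty(nsamples)
    f_s = np.empty(nsamples)
    nb_s = np.zeros(nsamples, dtype=np.int64)

    unbind_t = np.empty(ev_cap)
    bind_t = np.empty(ev_cap)
    collapse_t = np.empty(ev_cap)
    n_unbind = 0
    n_bind = 0
    n_collapse = 0

    bound = np.zeros(nf, dtype=np.bool_)
    x = np.zeros(nf)
    unfolded = np.zeros(nf, dtype=np.bool_)
    vinc = np.zeros(nf, dtype=np.int64)
    total_vinc = 0

    xsub = 0.0
    fsub = 0.0
    # unloaded flow speed
    vf = 0.0
    if va > 0.0:
        vf += va
    vf += vact
    pmax = 0.0

    t_s[0] = 0.0
    vf_s[0] = vf
    f_s[0] = 0.0
    nb_s[0] = 0
    isample = 1

    for step in range(nsteps):
        t = step * dt
        kon_eff = kont * (dint0 + dint_inc * total_vinc)
        p_on = kon_eff * dt
        if p_on > pmax:
            pmax = p_on

        # (i) binding
        for i in range(nf):
            if not bound[i]:
                if rng.random() < p_on:
                    bound[i] = True
                    x[i] = xsub
                    if n_bind < ev_cap:
                        bind_t[n_bind] = t
                    n_bind += 1

        # (ii) unbinding
        for i in range(nf):
            if bound[i]:
                fc = kc * (x[i] - xsub)
                if fc < 0.0:
                    fc = 0.0
                if koff_constant:
                    rate = koff_scale
                else:
                    rate = _koff_rate(fc, a1, b1, a2, b2, branch, koff_scale)
                p_off = rate * dt
                if p_off > pmax:
                    pmax = p_off
                if rng.random() < p_off:
                    bound[i] = False
                    x[i] = xsub
                    unfolded[i] = False
                    total_vinc -= vinc[i]
                    vinc[i] = 0
                    if n_unbind < ev_cap:
                        unbind_t[n_unbind] = t
                    n_unbind += 1

        # (iii) talin unfolding / refolding, vinculin recruitment
        for i in range(nf):
            if bound[i]:
                fc = kc * (x[i] - xsub)
                if fc < 0.0:
                    fc = 0.0
                fpt = fc * _N_PER_PN * pt
                if not unfolded[i]:
                    kuf = np.exp(kuf_pref + kuf_exp * fpt)
                    if rng.random() < min(kuf * dt, 1.0):
                        unfolded[i] = True
                else:
                    kf = np.exp(kf_pref + kf_exp * fpt)
                    if rng.random() < min(kf * dt, 1.0):
                        unfolded[i] = False
                if unfolded[i] and vinc[i] < vinc_max:
                    if rng.random() < min(konv * dt, 1.0):
                        vinc[i] += 1
                        total_vinc += 1

        # (iv) advect bound clutches
        nb = 0
        xsum = 0.0
        for i in range(nf):
            if bound[i]:
                x[i] += vf * dt
                nb += 1
                xsum += x[i]

        # (v) force balance
        if nb > 0:
            xsub = kc * xsum / (ksub + nb * kc)
        else:
            if fsub > 0.0 and n_collapse < ev_cap:
                collapse_t[n_collapse] = t
                n_collapse += 1
            xsub = 0.0
        fsub = ksub * xsub

        # (vi) flow speed
        vf = 0.0
        if va > 0.0:
            term = va * (1.0 - fsub / fs_myo)
            if allow_reversal or term > 0.0:
                vf += term
        term = vact * (1.0 - fsub / fs_act)
        if allow_reversal or term > 0.0:
            vf += term

        if (step + 1) % stride == 0:
            t_s[isample] = (step + 1) * dt
            vf_s[isample] = vf
            f_s[isample] = fsub
            nb_s[isample] = nb
            isample += 1

    return (t_s[:isample], vf_s[:isample], f_s[:isample], nb_s[:isample],
            bind_t[:min(n_bind, ev_cap)], unbind_t[:min(n_unbind, ev_cap)],
            collapse_t[:min(n_collapse, ev_cap)], pmax)


def simulate_rigid(p: ParameterSet) -> TimeSeries:
    """Run the rigid-clutch engine for p.duration seconds.

    Starts from the all-unbound, unloaded state.  Returns a TimeSeries
    sampled every p.sample_stride steps, carrying an EventLog of binding,
    unbinding and full-release instants.  Identical seeds give bit-identical
    output.
    """
    p.validate()
    nsteps = int(round(p.duration / p.dt))
    rng = np.random.default_rng(p.seed)

    va = p.motors.Va if (p.myosin_enabled and p.motors.nm > 0) else 0.0
    fs_myo = max(p.motors.stall_force, 1e-300)
    fs_act = p.actin_stall_force()
    ev_cap = max(int(2 * p.clutches.nf * max(p.duration, 1.0)), 1000)

    (t_s, vf_s, f_s, nb_s, bind_t, unbind_t, collapse_t, pmax) = _rigid_kernel(
        nsteps, p.dt, p.substrate.ksub, p.clutches.kc, p.clutches.nf,
        p.clutches.kont, p.clutches.dint, p.talin.dint_increment,
        p.talin.vinculin_max,
        p.clutches.koff_a1, p.clutches.koff_b1, p.clutches.koff_a2,
        p.clutches.koff_b2, p.clutches.koff_branch_force,
        p.clutches.koff_scale, p.koff_mode == "constant",
        p.talin.kuf_pref, p.talin.kuf_exp, p.talin.kf_pref, p.talin.kf_exp,
        p.talin.pt, p.talin.konv,
        va, fs_myo, p.polymer.vactin_max, fs_act, p.allow_reversal,
        p.sample_stride, rng, ev_cap)

    if pmax > 0.1:
        warnings.warn(
            f"max event probability per step was {pmax:.3f} > 0.1; "
            "consider reducing dt", stacklevel=2)

    traction = np.array([force_to_stress(f, p.substrate.ra) for f in f_s])
    events = EventLog(unclutch_times=collapse_t, rebind_times=bind_t,
                      bond_release_times=unbind_t)
    meta = {"model": "rigid", "condition": p.condition, "seed": p.seed,
            "dt": p.dt, "sample_stride": p.sample_stride,
            "stiffness_kpa": p.substrate.E / 1000.0}
    return TimeSeries(times=t_s, vf=vf_s, traction=traction, nbound=nb_s,
                      events=events, meta=meta)
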