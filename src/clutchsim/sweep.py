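"""Stiffness sweeps over seeded ensembles and the two response-curve fits.

Traction vs stiffness is summarized by the power law T = a*E^b; flow speed
vs stiffness by the negative exponential V = a*exp(R0*E) + V0 (R0 < 0 for a
decaying flow).  Both fits are nonlinear least squares seeded from simple
closed-form initializations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .params import DEFAULT_STIFFNESS_KPA, ParameterSet
from .rigid import simulate_rigid
from .visco import simulate_visco

__all__ = ["SweepResult", "FitResult", "run_sweep", "fit_power_law",
           "fit_neg_exp", "derive_seeds"]


class FitError(RuntimeError):
    """Raised when a curve fit fails to converge or is singular."""


@dataclass
class SweepResult:
    """Per-stiffness ensemble summaries (mean +/- sem) for one condition."""

    stiffness: np.ndarray        # kPa
    traction_mean: np.ndarray    # Pa
    traction_sem: np.ndarray     # Pa
    flow_mean: np.ndarray        # nm/s
    flow_sem: np.ndarray         # nm/s
    n_reps: int
    condition: str
    model: str

    def __post_init__(self) -> None:
        for name in ("stiffness", "traction_mean", "traction_sem",
                     "flow_mean", "flow_sem"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.stiffness)
        for name in ("traction_mean", "traction_sem", "flow_mean", "flow_sem"):
            if len(getattr(self, name)) != n:
                raise ValueError("SweepResult channels must have equal length")


@dataclass
class FitResult:
    """Fitted response curve: form, parameters, adjusted R^2, covariance."""

    form: str                 # "power_law" | "neg_exp"
    params: tuple[float, ...]
    adj_R2: float
    covariance: np.ndarray

    def predict(self, E) -> np.ndarray:
        E = np.asarray(E, dtype=float)
        if self.form == "power_law":
            a, b = self.params
            return a * E ** b
        a, r0, v0 = self.params
        return a * np.exp(r0 * E) + v0


def derive_seeds(base_seed: int, n: int) -> np.ndarray:
    """n deterministic child seeds (< 2**31) from one base seed."""
    ss = np.random.SeedSequence(base_seed)
    return (ss.generate_state(n, dtype=np.uint32) >> 1).astype(np.int64)


def run_sweep(p: ParameterSet, model: str = "visco",
              stiffness_kpa=DEFAULT_STIFFNESS_KPA, n_reps: int = 20,
              base_seed: int = 0) -> SweepResult:
    """Ensemble stiffness sweep: n_reps seeded runs per stiffness.

    Each run's summary statistic is the post-burn-in time-average of
    traction and flow speed; seeds are derived deterministically from
    base_seed, so identical calls give identical results.
    """
    if model not in ("rigid", "visco"):
        raise ValueError(f"unknown model {model!r}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    stiffness = np.asarray(stiffness_kpa, dtype=float)
    if stiffness.size == 0:
        raise ValueError("stiffness list must be non-empty")

    seeds = derive_seeds(base_seed, stiffness.size * n_reps)
    tr_mean = np.empty(stiffness.size)
    tr_sem = np.empty(stiffness.size)
    fl_mean = np.empty(stiffness.size)
    fl_sem = np.empty(stiffness.size)

    for j, e_kpa in enumerate(stiffness):
        tr = np.empty(n_reps)
        fl = np.empty(n_reps)
        for r in range(n_reps):
            pj = replace(p, substrate=replace(p.substrate, E=e_kpa * 1000.0),
                         seed=int(seeds[j * n_reps + r]))
            if model == "rigid":
                ts = simulate_rigid(pj)
            else:
                ts, _ = simulate_visco(pj)
            s = ts.summary(p.burn_in_fraction)
            tr[r] = s["traction_pa"]
            fl[r] = s["flow_nm_s"]
        tr_mean[j] = tr.mean()
        fl_mean[j] = fl.mean()
        tr_sem[j] = tr.std(ddof=1) / np.sqrt(n_reps) if n_reps > 1 else 0.0
        fl_sem[j] = fl.std(ddof=1) / np.sqrt(n_reps) if n_reps > 1 else 0.0

    return SweepResult(stiffness=stiffness, traction_mean=tr_mean,
                       traction_sem=tr_sem, flow_mean=fl_mean,
                       flow_sem=fl_sem, n_reps=n_reps,
                       condition=p.condition, model=model)


# ---------------------------------------------------------------------------
# response-curve fits
# ---------------------------------------------------------------------------

def _adj_r2(y: np.ndarray, yhat: np.ndarray, n_params: int) -> float:
    y = np.asarray(y, dtype=float)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    n = len(y)
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    if n - n_params - 1 <= 0:
        return r2
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def fit_power_law(E, T, sigma=None) -> FitResult:
    """Least-squares fit of T = a*E^b.

    Initialized from a log-log linear regression (on the strictly positive
    T values).  Optionally weighted by sigma (per-point standard errors).
    """
    E = np.asarray(E, dtype=float)
    T = np.asarray(T, dtype=float)
    if len(E) < 3:
        raise ValueError("power-law fit needs at least 3 points")
    if np.any(E <= 0):
        raise ValueError("power-law fit requires strictly positive stiffness")

    pos = T > 0
    if np.count_nonzero(pos) >= 2:
        res = stats.linregress(np.log(E[pos]), np.log(T[pos]))
        p0 = (float(np.exp(res.intercept)), float(res.slope))
    else:
        p0 = (max(float(np.mean(T)), 1e-12), 0.0)

    def model(e, a, b):
        return a * e ** b

    try:
        popt, pcov = optimize.curve_fit(model, E, T, p0=p0, sigma=sigma,
                                        maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise FitError(f"power-law fit failed: {exc}; p0={p0}") from exc
    yhat = model(E, *popt)
    return FitResult(form="power_law", params=(float(popt[0]), float(popt[1])),
                     adj_R2=_adj_r2(T, yhat, 2), covariance=pcov)


def fit_neg_exp(E, V, sigma=None) -> FitResult:
    """Least-squares fit of V = a*exp(R0*E) + V0.

    Initialized at (Vmax - Vmin, -1/median(E), Vmin), the geometry of a flow
    curve decaying from soft to stiff substrates.
    """
    E = np.asarray(E, dtype=float)
    V = np.asarray(V, dtype=float)
    if len(E) < 4:
        raise ValueError("negative-exponential fit needs at least 4 points")

    vmax, vmin = float(np.max(V)), float(np.min(V))
    p0 = (vmax - vmin, -1.0 / float(np.median(E)), vmin)

    def model(e, a, r0, v0):
        return a * np.exp(r0 * e) + v0

    try:
        popt, pcov = optimize.curve_fit(model, E, V, p0=p0, sigma=sigma,
                                        maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"negative-exponential fit failed: {exc}; p0={p0}") from exc
    yhat = model(E, *popt)
    return FitResult(form="neg_exp",
                     params=tuple(float(v) for v in popt),
                     adj_R2=_adj_r2(V, yhat, 3), covariance=pcov)
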