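"""Seeded synthetic-data generators for testing every analysis stage.

Three families: load-and-fail ("sawtooth") flow-speed traces with
Poisson-timed release spikes, grids of such traces emulating windowed flow
fields, and noisy stiffness-response datasets drawn from the power-law or
negative-exponential forms with multiplicative lognormal noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .spectrum import WindowGrid

__all__ = ["SawtoothSpec", "ResponseSpec", "gen_sawtooth", "gen_flow_grid",
           "gen_response"]


@dataclass
class SawtoothSpec:
    """Load-and-fail trace: baseline v_load, Poisson(lambda_fail) release
    spikes of amplitude v_spike decaying over spike_decay, Gaussian noise."""

    lambda_fail: float = 0.02   # 1/s
    v_load: float = 2.0         # nm/s
    v_spike: float = 20.0       # nm/s
    spike_decay: float = 12.0   # s
    noise_sd: float = 0.2       # nm/s
    dt: float = 6.0             # s
    duration: float = 600.0     # s
    seed: int = 0
    #: gamma shape of the inter-event gaps; 1 = Poisson, larger values give
    #: the quasi-periodic cycling of load-and-fail traces (mean rate is
    #: lambda_fail regardless)
    regularity: float = 4.0

    def validate(self) -> None:
        if self.lambda_fail < 0 or self.noise_sd < 0:
            raise ValueError("rates and noise must be non-negative")
        if self.dt <= 0 or self.duration <= 0 or self.spike_decay <= 0:
            raise ValueError("times must be positive")
        if self.regularity <= 0:
            raise ValueError("regularity must be positive")


@dataclass
class ResponseSpec:
    """Noisy dataset on a stiffness grid following one of the two fit forms."""

    form: str = "power_law"                 # "power_law" | "neg_exp"
    true_params: tuple = (16.098, 0.173)
    noise_sd: float = 0.05                  # sd of log multiplicative noise
    E_grid: tuple = (0.6, 1.3, 2.6, 6.0, 12.7)
    n_per_E: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.form not in ("power_law", "neg_exp"):
            raise ValueError(f"unknown form {self.form!r}")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if any(e <= 0 for e in self.E_grid):
            raise ValueError("stiffness grid must be strictly positive")
        npar = 2 if self.form == "power_law" else 3
        if len(self.true_params) != npar:
            raise ValueError(f"{self.form} needs {npar} parameters")


def gen_sawtooth(spec: SawtoothSpec, rng: np.random.Generator | None = None,
                 return_events: bool = False):
    """Generate one load-and-fail speed trace sampled at spec.dt.

    Event times are a gamma renewal process with mean rate lambda_fail
    (shape spec.regularity; shape 1 recovers a Poisson process); each event
    adds a spike v_spike*exp(-(t-te)/spike_decay) for t >= te.  Seeded and
    deterministic.  With return_events the realized event times are
    returned alongside the trace.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration / spec.dt))
    t = np.arange(n) * spec.dt

    trace = np.full(n, spec.v_load, dtype=float)
    events = []
    if spec.lambda_fail > 0:
        shape = spec.regularity
        scale = 1.0 / (spec.lambda_fail * shape)
        te = 0.0
        while True:
            te += rng.gamma(shape, scale)
            if te >= spec.duration:
                break
            events.append(te)
            mask = t >= te
            trace[mask] += spec.v_spike * np.exp(-(t[mask] - te) / spec.spike_decay)
    if spec.noise_sd > 0:
        trace += rng.normal(0.0, spec.noise_sd, size=n)
    if return_events:
        return trace, np.asarray(events)
    return trace


def gen_flow_grid(n_windows: int, lambda_of_E: Callable[[float], float],
                  E_kpa: float, base: SawtoothSpec) -> WindowGrid:
    """Grid of independent sawtooth traces with lambda_fail = lambda_of_E(E).

    Window seeds derive deterministically from base.seed; the grid carries
    the stiffness label on every window.
    """
    if n_windows < 1:
        raise ValueError("need at least one window")
    lam = float(lambda_of_E(E_kpa))
    ss = np.random.SeedSequence(base.seed)
    traces = []
    for child in ss.spawn(n_windows):
        rng = np.random.default_rng(child)
        traces.append(gen_sawtooth(replace(base, lambda_fail=lam), rng=rng))
    return WindowGrid(traces=np.asarray(traces), dt_frame=base.dt,
                      stiffness_kpa=np.full(n_windows, E_kpa))


def gen_response(spec: ResponseSpec) -> tuple[np.ndarray, np.ndarray]:
    """Noisy (E, value) dataset from the declared response form.

    values = model(E; true_params) * exp(noise_sd * z), z ~ N(0, 1), so the
    log-residuals follow the declared normal noise model exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    E = np.repeat(np.asarray(spec.E_grid, dtype=float), spec.n_per_E)
    if spec.form == "power_law":
        a, b = spec.true_params
        model = a * E ** b
    else:
        a, r0, v0 = spec.true_params
        model = a * np.exp(r0 * E) + v0
    noise = np.exp(spec.noise_sd * rng.standard_normal(E.size)) \
        if spec.noise_sd > 0 else 1.0
    return E, model * noise
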