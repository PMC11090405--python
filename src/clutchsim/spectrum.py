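"""Frequency-domain analysis of retrograde-flow speed traces.

A mean-subtracted one-sided periodogram characterizes flow-speed
fluctuations; summaries are the power-weighted mean frequency and the
normalized power in named frequency bands (low 0.005-0.01 Hz, high
0.04-0.08 Hz, zoom 0.06-0.08 Hz).  Windowed grids of traces (one trace per
1x1 um spatial window sampled every 6 s) are aggregated into per-window
mean frequencies and a pooled normalized spectrum, and stiffness-labeled
aggregates can be fit with the same power law as the traction curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import signal

from .series import EventLog
from .sweep import FitResult, fit_power_law

__all__ = ["SpectrumResult", "WindowGrid", "power_spectrum", "mean_frequency",
           "band_power", "aggregate_windows", "unclutch_frequency",
           "DEFAULT_BANDS", "fit_mean_freq_power_law"]

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "low": (0.005, 0.01),
    "high": (0.04, 0.08),
    "zoom": (0.06, 0.08),
}


@dataclass
class SpectrumResult:
    """One-sided spectrum with normalized power and derived summaries.

    norm_power sums to 1 over non-DC bins (all zero for a constant trace);
    mean_freq is the power-weighted average frequency, NaN when the total
    power vanishes.
    """

    freqs: np.ndarray
    power: np.ndarray
    norm_power: np.ndarray
    mean_freq: float
    band_powers: dict[str, float] = field(default_factory=dict)

    @property
    def nyquist(self) -> float:
        return float(self.freqs[-1])


@dataclass
class WindowGrid:
    """Per-window flow-speed traces of equal length.

    traces has shape (n_windows, n_frames); stiffness_kpa optionally labels
    each window for downstream trend fitting.
    """

    traces: np.ndarray
    dt_frame: float = 6.0       # s
    window_size: float = 1.0    # um
    stiffness_kpa: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if self.window_size <= 0 or self.dt_frame <= 0:
            raise ValueError("window_size and dt_frame must be positive")
        if self.stiffness_kpa is not None:
            self.stiffness_kpa = np.asarray(self.stiffness_kpa, dtype=float)
            if len(self.stiffness_kpa) != self.traces.shape[0]:
                raise ValueError("one stiffness label per window required")

    @property
    def n_windows(self) -> int:
        return self.traces.shape[0]


def power_spectrum(trace, dt: float, window: str = "boxcar",
                   bands: dict[str, tuple[float, float]] | None = None
                   ) -> SpectrumResult:
    """Mean-subtracted one-sided periodogram of a speed trace.

    The DC bin is excluded from normalization, band powers and the mean
    frequency.  Total (unnormalized, boxcar) power equals the trace
    variance (Parseval).  A constant trace yields zero power everywhere and
    an undefined (NaN) mean frequency.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or len(trace) < 8:
        raise ValueError("trace must be 1-D with at least 8 samples")
    if dt <= 0:
        raise ValueError("sampling interval must be positive")

    freqs, pxx = signal.periodogram(trace, fs=1.0 / dt, window=window,
                                    detrend="constant", scaling="density")
    total = float(np.sum(pxx[1:]))
    norm = np.zeros_like(pxx)
    mean_freq = float("nan")
    if total > 0.0:
        norm[1:] = pxx[1:] / total
        mean_freq = float(np.sum(freqs[1:] * pxx[1:]) / total)

    spec = SpectrumResult(freqs=freqs, power=pxx, norm_power=norm,
                          mean_freq=mean_freq)
    use_bands = DEFAULT_BANDS if bands is None else bands
    spec.band_powers = {name: band_power(spec, lo, hi)
                        for name, (lo, hi) in use_bands.items()
                        if hi <= spec.nyquist * (1 + 1e-12)}
    return spec


def mean_frequency(spec: SpectrumResult) -> float:
    """Power-weighted mean frequency over non-DC bins (Hz).

    Raises ValueError when the spectrum carries no power.
    """
    total = float(np.sum(spec.power[1:]))
    if total <= 0.0:
        raise ValueError("mean frequency undefined: zero total power")
    return float(np.sum(spec.freqs[1:] * spec.power[1:]) / total)


def band_power(spec: SpectrumResult, f_lo: float, f_hi: float) -> float:
    """Fraction of normalized power in [f_lo, f_hi).

    The upper edge is included when it reaches the Nyquist frequency so
    that the full band sums to 1 while adjacent bands stay disjoint.
    """
    if not (0.0 <= f_lo < f_hi):
        raise ValueError(f"invalid band [{f_lo}, {f_hi})")
    if f_hi > spec.nyquist * (1 + 1e-12):
        raise ValueError(f"band upper edge {f_hi} exceeds Nyquist {spec.nyquist}")
    sel = (spec.freqs >= f_lo) & (spec.freqs < f_hi)
    if f_hi >= spec.nyquist * (1 - 1e-12):
        sel |= np.isclose(spec.freqs, spec.nyquist)
    sel[0] = False
    return float(np.sum(spec.norm_power[sel]))


def aggregate_windows(grid: WindowGrid, window: str = "boxcar"
                      ) -> tuple[np.ndarray, SpectrumResult]:
    """Per-window mean frequencies and the pooled normalized spectrum.

    The pooled spectrum is the average of the per-window normalized spectra
    (windows with zero power contribute a zero spectrum); its summaries are
    recomputed from the pooled normalized power.
    """
    if grid.n_windows < 1:
        raise ValueError("need at least one window")
    mean_freqs = np.empty(grid.n_windows)
    pooled = None
    freqs = None
    for w in range(grid.n_windows):
        spec = power_spectrum(grid.traces[w], grid.dt_frame, window=window)
        mean_freqs[w] = spec.mean_freq
        if pooled is None:
            pooled = np.zeros_like(spec.norm_power)
            freqs = spec.freqs
        pooled += spec.norm_power
    pooled /= grid.n_windows

    total = float(np.sum(pooled[1:]))
    mf = float("nan")
    norm = np.zeros_like(pooled)
    if total > 0:
        norm[1:] = pooled[1:] / total
        mf = float(np.sum(freqs[1:] * pooled[1:]) / total)
    agg = SpectrumResult(freqs=freqs, power=pooled, norm_power=norm,
                         mean_freq=mf)
    agg.band_powers = {name: band_power(agg, lo, hi)
                       for name, (lo, hi) in DEFAULT_BANDS.items()
                       if hi <= agg.nyquist * (1 + 1e-12)}
    return mean_freqs, agg


def fit_mean_freq_power_law(grids: dict[float, WindowGrid]) -> FitResult:
    """Fit mean frequency vs stiffness with f = a*E^b across labeled grids."""
    E = []
    f = []
    for e_kpa, grid in sorted(grids.items()):
        mean_freqs, _ = aggregate_windows(grid)
        E.append(e_kpa)
        f.append(float(np.nanmean(mean_freqs)))
    return fit_power_law(np.asarray(E), np.asarray(f))


def unclutch_frequency(events: EventLog, duration: float) -> float:
    """Unclutching event rate, count/duration (Hz)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return len(events.unclutch_times) / duration
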