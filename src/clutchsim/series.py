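"""Sampled time-series and event-log containers shared by both engines."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class EventLog:
    """Instants of clutch events, in seconds, sorted.

    unclutch_times are full network releases (the last bound clutch letting
    go, dropping the rearward speed to zero) -- the unclutching events whose
    rate rises with substrate stiffness.  bond_release_times are individual
    clutch unbinding instants; rebind_times are binding instants.
    """

    unclutch_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    rebind_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    bond_release_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.unclutch_times = np.asarray(self.unclutch_times, dtype=float)
        self.rebind_times = np.asarray(self.rebind_times, dtype=float)
        self.bond_release_times = np.asarray(self.bond_release_times,
                                             dtype=float)


@dataclass
class TimeSeries:
    """Equal-length sampled channels from one simulation run.

    times are strictly increasing with uniform spacing dt*sample_stride;
    vf is the retrograde flow speed (nm/s), traction the substrate stress
    (Pa), nbound the engaged-clutch count.
    """

    times: np.ndarray
    vf: np.ndarray
    traction: np.ndarray
    nbound: np.ndarray
    events: EventLog | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.vf = np.asarray(self.vf, dtype=float)
        self.traction = np.asarray(self.traction, dtype=float)
        self.nbound = np.asarray(self.nbound)
        n = len(self.times)
        if not (len(self.vf) == len(self.traction) == len(self.nbound) == n):
            raise ValueError("TimeSeries channels must have equal length")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("TimeSeries times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def steady_slice(self, burn_in_fraction: float = 0.2) -> slice:
        """Index slice dropping the leading burn-in fraction of samples."""
        start = int(np.ceil(burn_in_fraction * len(self.times)))
        return slice(min(start, max(len(self.times) - 1, 0)), None)

    def summary(self, burn_in_fraction: float = 0.2) -> dict[str, float]:
        """Post-burn-in time-averages of traction (Pa) and flow speed (nm/s)."""
        sl = self.steady_slice(burn_in_fraction)
        return {
            "traction_pa": float(np.mean(self.traction[sl])),
            "flow_nm_s": float(np.mean(self.vf[sl])),
            "nbound": float(np.mean(self.nbound[sl])),
        }
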