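"""Plain-text I/O: CSV for all tabular objects, YAML for configs.

Every writer embeds a metadata comment header (lines starting with '#')
holding a JSON payload with the resolved settings and seed; readers parse
it back.  CSV dialect: comma-separated, header row, '.' decimal, UTF-8.
Floats are written with 17 significant digits so a write-then-read round
trip is value-exact.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .params import ParameterSet
from .series import EventLog, TimeSeries
from .spectrum import SpectrumResult, WindowGrid
from .sweep import FitResult, SweepResult

__all__ = ["ParseError", "write_timeseries", "read_timeseries",
           "write_events", "read_events", "write_sweep", "read_sweep",
           "write_grid", "read_grid", "write_spectrum", "read_spectrum",
           "write_fit", "read_fit", "save_config", "load_config"]

_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """Malformed input file; the message names the file and offending field."""


def _write_csv(path, df: pd.DataFrame, meta: dict[str, Any], kind: str) -> None:
    buf = _io.StringIO()
    buf.write(f"# clutchsim {kind} v1\n")
    buf.write("# meta " + json.dumps(meta, sort_keys=True) + "\n")
    df.to_csv(buf, index=False, float_format=_FLOAT_FMT)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def _read_csv(path, kind: str, required: tuple[str, ...]
              ) -> tuple[pd.DataFrame, dict[str, Any]]:
    path = Path(path)
    meta: dict[str, Any] = {}
    try:
        with path.open(encoding="utf-8") as fh:
            first = fh.readline()
            if not first.startswith(f"# clutchsim {kind}"):
                raise ParseError(
                    f"{path}, line 1: expected '# clutchsim {kind}' header, "
                    f"got {first.strip()!r}")
            pos = fh.tell()
            second = fh.readline()
            if second.startswith("# meta "):
                try:
                    meta = json.loads(second[len("# meta "):])
                except json.JSONDecodeError as exc:
                    raise ParseError(f"{path}, line 2: bad meta JSON: {exc}")
            else:
                fh.seek(pos)
            df = pd.read_csv(fh, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: CSV parse failure: {exc}") from exc
    for col in required:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    return df, meta


# ---------------------------------------------------------------------------
# time series and events
# ---------------------------------------------------------------------------

def write_timeseries(ts: TimeSeries, path) -> None:
    df = pd.DataFrame({"time_s": ts.times, "vf_nm_s": ts.vf,
                       "traction_pa": ts.traction,
                       "n_bound": np.asarray(ts.nbound, dtype=int)})
    _write_csv(path, df, ts.meta, "timeseries")


def read_timeseries(path) -> TimeSeries:
    df, meta = _read_csv(path, "timeseries",
                         ("time_s", "vf_nm_s", "traction_pa", "n_bound"))
    return TimeSeries(times=df["time_s"].to_numpy(),
                      vf=df["vf_nm_s"].to_numpy(),
                      traction=df["traction_pa"].to_numpy(),
                      nbound=df["n_bound"].to_numpy(), meta=meta)


def write_events(events: EventLog, path, meta: dict[str, Any] | None = None) -> None:
    rows = []
    for kind, arr in (("bind", events.rebind_times),
                      ("bond_release", events.bond_release_times),
                      ("unclutch", events.unclutch_times)):
        rows.append(pd.DataFrame({"time_s": arr, "event": kind}))
    df = pd.concat(rows, ignore_index=True).sort_values(
        "time_s", kind="stable").reset_index(drop=True)
    _write_csv(path, df, meta or {}, "events")


def read_events(path) -> EventLog:
    df, _ = _read_csv(path, "events", ("time_s", "event"))
    by = {k: g["time_s"].to_numpy() for k, g in df.groupby("event")}
    return EventLog(unclutch_times=np.sort(by.get("unclutch", np.empty(0))),
                    rebind_times=np.sort(by.get("bind", np.empty(0))),
                    bond_release_times=np.sort(by.get("bond_release",
                                                      np.empty(0))))


# ---------------------------------------------------------------------------
# sweeps, spectra, grids, fits
# ---------------------------------------------------------------------------

def write_sweep(sw: SweepResult, path) -> None:
    df = pd.DataFrame({"stiffness_kpa": sw.stiffness,
                       "traction_mean_pa": sw.traction_mean,
                       "traction_sem_pa": sw.traction_sem,
                       "flow_mean_nm_s": sw.flow_mean,
                       "flow_sem_nm_s": sw.flow_sem})
    meta = {"n_reps": sw.n_reps, "condition": sw.condition, "model": sw.model}
    _write_csv(path, df, meta, "sweep")


def read_sweep(path) -> SweepResult:
    df, meta = _read_csv(path, "sweep",
                         ("stiffness_kpa", "traction_mean_pa",
                          "traction_sem_pa", "flow_mean_nm_s",
                          "flow_sem_nm_s"))
    return SweepResult(stiffness=df["stiffness_kpa"].to_numpy(),
                       traction_mean=df["traction_mean_pa"].to_numpy(),
                       traction_sem=df["traction_sem_pa"].to_numpy(),
                       flow_mean=df["flow_mean_nm_s"].to_numpy(),
                       flow_sem=df["flow_sem_nm_s"].to_numpy(),
                       n_reps=int(meta.get("n_reps", 1)),
                       condition=str(meta.get("condition", "")),
                       model=str(meta.get("model", "")))


def write_grid(grid: WindowGrid, path) -> None:
    nw, nt = grid.traces.shape
    df = pd.DataFrame({
        "window_id": np.repeat(np.arange(nw), nt),
        "frame": np.tile(np.arange(nt), nw),
        "speed_nm_s": grid.traces.ravel(),
    })
    if grid.stiffness_kpa is not None:
        df["stiffness_kpa"] = np.repeat(grid.stiffness_kpa, nt)
    meta = {"dt_frame": grid.dt_frame, "window_size": grid.window_size}
    _write_csv(path, df, meta, "grid")


def read_grid(path) -> WindowGrid:
    df, meta = _read_csv(path, "grid", ("window_id", "frame", "speed_nm_s"))
    pivot = df.pivot(index="window_id", columns="frame", values="speed_nm_s")
    if pivot.isna().any().any():
        raise ParseError(f"{path}: ragged grid (unequal trace lengths)")
    stiff = None
    if "stiffness_kpa" in df.columns:
        stiff = df.groupby("window_id")["stiffness_kpa"].first().to_numpy()
    return WindowGrid(traces=pivot.to_numpy(),
                      dt_frame=float(meta.get("dt_frame", 6.0)),
                      window_size=float(meta.get("window_size", 1.0)),
                      stiffness_kpa=stiff)


def write_spectrum(spec: SpectrumResult, path) -> None:
    df = pd.DataFrame({"freq_hz": spec.freqs, "power": spec.power,
                       "norm_power": spec.norm_power})
    meta = {"mean_freq_hz": spec.mean_freq, "band_powers": spec.band_powers}
    _write_csv(path, df, meta, "spectrum")


def read_spectrum(path) -> SpectrumResult:
    df, meta = _read_csv(path, "spectrum", ("freq_hz", "power", "norm_power"))
    return SpectrumResult(freqs=df["freq_hz"].to_numpy(),
                          power=df["power"].to_numpy(),
                          norm_power=df["norm_power"].to_numpy(),
                          mean_freq=float(meta.get("mean_freq_hz", "nan")),
                          band_powers=dict(meta.get("band_powers", {})))


def write_fit(fit: FitResult, path, inputs_hash: str | None = None) -> None:
    payload = {"form": fit.form, "params": list(fit.params),
               "adj_R2": fit.adj_R2,
               "covariance": np.asarray(fit.covariance).tolist()}
    if inputs_hash is not None:
        payload["inputs_hash"] = inputs_hash
    Path(path).write_text(json.dumps(payload, indent=2) + "\n",
                          encoding="utf-8")


def read_fit(path) -> FitResult:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return FitResult(form=data["form"], params=tuple(data["params"]),
                     adj_R2=data["adj_R2"],
                     covariance=np.asarray(data["covariance"]))


# ---------------------------------------------------------------------------
# config files
# ---------------------------------------------------------------------------

def save_config(p: ParameterSet, path) -> None:
    Path(path).write_text(yaml.safe_dump(p.to_dict(), sort_keys=False),
                          encoding="utf-8")


def load_config(path) -> ParameterSet:
    try:
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: bad YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a mapping of sections")
    return ParameterSet.from_dict(data)
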