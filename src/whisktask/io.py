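"""File dialects and run configuration.

The event list is a CSV with columns (t_s, device, value); device tokens
are beam_L/beam_M/beam_R (IR beam crossings), lick_L/lick_R (lick port
piezo events), aperture_L/aperture_R (aperture width in mm at trial
start), outcome (reward/punishment), and touch (whisker-aperture contact
from the high-speed video).  Time series are CSVs with a t_s column and
one value column per channel; dropped frames are represented as explicit
NaN markers, never silently interpolated.  All files are UTF-8 with a
header row and '.' decimals.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core import AngleTrace, CalciumTrace, PositionTrace, Session

__all__ = [
    "DEVICES",
    "RunConfig",
    "read_event_csv",
    "write_event_csv",
    "session_to_events",
    "read_timeseries_csv",
    "write_timeseries_csv",
]

DEVICES = ("beam_L", "beam_M", "beam_R", "lick_L", "lick_R",
           "aperture_L", "aperture_R", "outcome", "touch")


# --------------------------------------------------------------------------
# event lists
# --------------------------------------------------------------------------

def read_event_csv(path) -> list[tuple[float, str, str]]:
    """Raw event stream [(t_s, device, value), ...], time-sorted.

    Unknown device tokens raise with the offending line number; out-of-order
    rows are re-sorted with a warning; an empty file yields an empty stream.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"value": str}, keep_default_na=False)
    if df.empty:
        return []
    bad = ~df["device"].isin(DEVICES)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2   # header is line 1
        raise ValueError(
            f"{path.name}:{line}: unknown device token {df['device'][bad].iloc[0]!r}")
    t = df["t_s"].astype(float).to_numpy()
    if np.any(np.diff(t) < 0):
        warnings.warn(f"{path.name}: events out of order; re-sorting by time")
        df = df.sort_values("t_s", kind="stable")
    return [(float(r.t_s), str(r.device), str(r.value))
            for r in df.itertuples(index=False)]


def write_event_csv(path, events) -> None:
    pd.DataFrame(events, columns=["t_s", "device", "value"]).to_csv(path, index=False)


def session_to_events(session: Session) -> list[tuple[float, str, str]]:
    """Serialize a scored session back into the raw event dialect."""
    events = []
    for tr in session.trials:
        beam = "beam_L" if tr.side == "left" else "beam_R"
        ap_dev = "aperture_L" if tr.side == "left" else "aperture_R"
        lick = "lick_L" if tr.side == "left" else "lick_R"
        events.append((tr.t_beam, beam, ""))
        events.append((tr.t_beam, ap_dev, f"{tr.aperture_mm:g}"))
        events.append((tr.t_touch, "touch", ""))
        if tr.t_lick is not None:
            events.append((tr.t_lick, lick, ""))
            if tr.outcome != "none":
                events.append((tr.t_lick, "outcome", tr.outcome))
    return sorted(events, key=lambda e: e[0])


# --------------------------------------------------------------------------
# time series
# --------------------------------------------------------------------------

def write_timeseries_csv(path, trace, value_cols: Optional[dict] = None) -> None:
    """Write a trace as a (t_s, value...) CSV."""
    if value_cols is None:
        if isinstance(trace, PositionTrace):
            value_cols = {"x_mm": trace.x}
        else:
            value_cols = {"value": trace.values}
    t = trace.t0 + np.arange(len(next(iter(value_cols.values())))) / trace.fps
    pd.DataFrame({"t_s": t, **value_cols}).to_csv(path, index=False)


def read_timeseries_csv(
    path,
    expected_fps: float,
    kind: str = "angle",
    fps_tol: float = 0.01,
):
    """Read a uniformly sampled trace, validating the frame rate.

    The median frame interval must match ``expected_fps`` within 1%;
    dropped frames (gaps of more than 1.5 frame intervals) are filled with
    NaN markers on a regular grid.
    """
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{Path(path).name}: need at least two samples")
    dt = float(np.median(np.diff(t)))
    fps = 1.0 / dt
    if abs(fps - expected_fps) / expected_fps > fps_tol:
        raise ValueError(
            f"{Path(path).name}: frame rate {fps:.3f} Hz deviates more than "
            f"{fps_tol:.0%} from expected {expected_fps} Hz")
    n = int(round((t[-1] - t[0]) / dt)) + 1
    cols = [c for c in df.columns if c != "t_s"]
    grid_idx = np.round((t - t[0]) / dt).astype(int)
    filled = {}
    for c in cols:
        v = np.full(n, np.nan)
        v[grid_idx] = df[c].to_numpy(dtype=float)
        filled[c] = v
    if kind == "angle":
        return AngleTrace(fps=expected_fps, values=filled[cols[0]], t0=float(t[0]))
    if kind == "position":
        return PositionTrace(fps=expected_fps, x=filled[cols[0]], t0=float(t[0]))
    if kind == "calcium":
        return [CalciumTrace(fps=expected_fps, values=v, unit_id=c, t0=float(t[0]))
                for c, v in filled.items()]
    raise ValueError(f"unknown trace kind {kind!r}")


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Complete, serializable description of one pipeline run."""

    seed: int = 0
    out_dir: str = "whisktask_run"
    stage: str = "initial"
    n_trials: int = 80
    n_units: int = 6
    n_calcium_units: int = 12
    learner: dict = field(default_factory=dict)      # LearnerParams overrides
    whisk_freq_hz: float = 14.5
    whisk_amp_deg: float = 15.0
    run_speed_mms: float = 200.0
    calcium_noise_sd: float = 0.05
    n_shuffles: int = 100
    cnn_epochs: int = 100
    decode_bin_s: float = 0.05

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**yaml.safe_load(text))

    def save(self, path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())
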