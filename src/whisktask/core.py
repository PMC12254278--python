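"""Core data containers for the aperture-discrimination pipeline.

Conventions used throughout the package: all times are in seconds, positions
in millimetres with 0 at the middle beam, whisker angles in degrees on
[0, 180] (0 = full retraction, 180 = full protraction), whisking phase in
radians on [0, 2*pi) with pi = full protraction.  Spatial bins are half-open
[lo, hi).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

STAGES = ("habituation", "initial", "neutral", "reversed", "extinction")

#: aperture widths (mm) by role
WIDE_MM = 45.0
NEUTRAL_MM = 35.0
NARROW_MM = 25.0

#: half-length of the linear track, mm (0 = middle beam)
TRACK_HALF_MM = 410.0

REGIONS = ("BC", "VPM", "POm", "ZIv")


@dataclass
class TrialRecord:
    """One scored approach to an aperture."""

    trial_index: int
    side: str                      # {"left", "right"}
    aperture_mm: float
    response: str                  # {"lick", "no-lick"}
    score: str                     # {"hit", "miss", "FA", "CR", "none"}
    outcome: str                   # {"reward", "punishment", "none"}
    t_beam: float
    t_touch: float
    t_lick: Optional[float] = None

    def __post_init__(self) -> None:
        if self.t_beam > self.t_touch:
            raise ValueError("t_beam must not exceed t_touch")
        if self.response == "lick" and self.t_lick is not None and self.t_lick < self.t_touch:
            raise ValueError("t_lick must not precede t_touch")


@dataclass
class Session:
    """An ordered list of trials from one training session."""

    mouse_id: str
    stage: str
    session_index: int
    trials: list[TrialRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(
                f"unknown stage {self.stage!r}; valid stages: {', '.join(STAGES)}"
            )
        idx = [t.trial_index for t in self.trials]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("trial_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.trials)

    def counts(self) -> dict[str, int]:
        """Score counts; every trial lands in exactly one bucket."""
        c = {"hit": 0, "miss": 0, "FA": 0, "CR": 0, "none": 0}
        for t in self.trials:
            c[t.score] += 1
        return c

    @property
    def touch_times(self) -> np.ndarray:
        return np.array([t.t_touch for t in self.trials])

    @property
    def duration(self) -> float:
        if not self.trials:
            return 0.0
        last = self.trials[-1]
        t_end = last.t_lick if last.t_lick is not None else last.t_touch
        return float(t_end + 5.0)


@dataclass
class AngleTrace:
    """Uniformly sampled angle time series (whisker angle or head azimuth)."""

    fps: float
    values: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fps

    @property
    def duration(self) -> float:
        return self.values.size / self.fps

    def __len__(self) -> int:
        return self.values.size


@dataclass
class PhaseTrace:
    """Instantaneous whisking phase, radians in [0, 2*pi)."""

    fps: float
    values: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() >= 2 * np.pi):
            raise ValueError("phase values must lie in [0, 2*pi)")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fps

    def __len__(self) -> int:
        return self.values.size


@dataclass
class PositionTrace:
    """Position along the track at 60 Hz; velocity is a derived trace."""

    fps: float
    x: np.ndarray
    velocity: Optional[np.ndarray] = None
    y: Optional[np.ndarray] = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if np.nanmax(np.abs(self.x)) > TRACK_HALF_MM + 1e-9:
            raise ValueError(f"|x| must not exceed {TRACK_HALF_MM} mm")
        if self.velocity is None:
            self.velocity = centered_velocity(self.x, self.fps)
        else:
            self.velocity = np.asarray(self.velocity, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.x.size) / self.fps

    @property
    def duration(self) -> float:
        return self.x.size / self.fps

    def __len__(self) -> int:
        return self.x.size


def centered_velocity(x: np.ndarray, fps: float) -> np.ndarray:
    """Centered 3-point finite-difference velocity (units of x per second)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return np.zeros_like(x)
    return np.gradient(x) * fps


@dataclass
class CalciumTrace:
    """dF/F0 trace of one imaged neuron."""

    fps: float
    values: np.ndarray
    unit_id: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fps

    def __len__(self) -> int:
        return self.values.size


@dataclass
class SpikeTrain:
    """One curated unit: event times plus region and waveform metadata."""

    unit_id: str
    region: str
    spike_times: np.ndarray
    recording_duration: float
    trough_to_peak_us: float = 400.0
    isolation_distance: Optional[float] = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size and (
            np.any(np.diff(self.spike_times) < 0)
            or self.spike_times[0] < 0
            or self.spike_times[-1] > self.recording_duration + 1e-9
        ):
            raise ValueError("spike times must be sorted within [0, duration]")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; valid: {', '.join(REGIONS)}")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def mean_rate(self) -> float:
        return self.n_spikes / self.recording_duration


@dataclass
class Segment:
    t_start: float
    t_end: float
    label: str

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


class StateSegments(list):
    """Non-overlapping labelled intervals within one label family."""

    def __init__(self, segments: Sequence[Segment] = ()):  # noqa: D107
        super().__init__(sorted(segments, key=lambda s: s.t_start))
        for a, b in zip(self, self[1:]):
            if a.label == b.label and b.t_start < a.t_end - 1e-12:
                raise ValueError("segments of one label must not overlap")

    def with_label(self, label: str) -> "StateSegments":
        return StateSegments([s for s in self if s.label == label])

    def total_duration(self, label: Optional[str] = None) -> float:
        return sum(s.duration for s in self if label is None or s.label == label)

    def contains(self, times: np.ndarray, label: Optional[str] = None) -> np.ndarray:
        """Boolean mask of which times fall inside any (matching) segment."""
        times = np.asarray(times, dtype=float)
        mask = np.zeros(times.shape, dtype=bool)
        for s in self:
            if label is None or s.label == label:
                mask |= (times >= s.t_start) & (times < s.t_end)
        return mask
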