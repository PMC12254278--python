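"""Whisker and locomotion kinematics.

Whisker angle traces (240 Hz) are band-pass filtered to the whisking band
(2-30 Hz), the instantaneous whisking phase is taken from the Hilbert
transform (0 = full retraction, pi = full protraction), and whisking
amplitude is the peak-to-peak angle within a centered 100 ms window.
Whisking/quiescence and locomotion/rest states are segmented by amplitude
and velocity thresholds; track occupancy is binned into 10 x 1 mm cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .core import AngleTrace, PhaseTrace, PositionTrace, Segment, StateSegments

__all__ = [
    "bandpass_whisker",
    "whisking_phase",
    "whisking_amplitude",
    "segment_whisking",
    "whisk_cycle_stats",
    "segment_locomotion",
    "occupancy_map",
    "AmplitudeSeries",
    "OccupancyMap",
]


def bandpass_whisker(
    trace: AngleTrace, lo: float = 2.0, hi: float = 30.0, order: int = 4
) -> AngleTrace:
    """Zero-phase Butterworth band-pass of a whisker angle trace.

    Forward-backward filtering preserves timing of whisking cycles; the DC
    offset (set-point) is removed along with slow drift below ``lo``.
    """
    if trace.fps < 2 * hi:
        raise ValueError(
            f"sampling rate {trace.fps} Hz cannot represent the {lo}-{hi} Hz band"
        )
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=trace.fps, output="sos")
    return AngleTrace(fps=trace.fps, values=signal.sosfiltfilt(sos, trace.values),
                      t0=trace.t0)


def whisking_phase(filtered: AngleTrace) -> PhaseTrace:
    """Instantaneous whisking phase from the analytic signal.

    Phase 0 corresponds to full retraction and pi to full protraction;
    values lie in [0, 2*pi).  An all-zero input has no defined phase and
    yields NaN throughout.
    """
    x = filtered.values
    if not np.any(np.abs(x) > 0):
        return PhaseTrace(fps=filtered.fps, values=np.full(x.size, np.nan),
                          t0=filtered.t0)
    analytic = signal.hilbert(x)
    # angle(analytic)=0 at protraction peaks; shift so retraction troughs sit at 0
    phi = np.mod(np.angle(analytic) + np.pi, 2 * np.pi)
    phi[phi >= 2 * np.pi] = 0.0
    return PhaseTrace(fps=filtered.fps, values=phi, t0=filtered.t0)


@dataclass
class AmplitudeSeries:
    """Per-frame whisking amplitude with a truncated-window edge flag."""

    fps: float
    values: np.ndarray        # degrees, peak-to-peak
    edge: np.ndarray          # True where the centered window was truncated
    t0: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fps


def whisking_amplitude(
    trace: AngleTrace, window_s: float = 0.100, method: str = "peak_to_peak"
) -> AmplitudeSeries:
    """Whisking amplitude per frame over a centered moving window.

    The default is the peak-to-peak angle within the window (50 ms margin on
    each side of the frame); a Hilbert-envelope alternative is available via
    ``method='hilbert'`` (returns 2x the analytic-signal envelope so both
    methods share the peak-to-peak scale for a pure tone).
    """
    n = int(round(window_s * trace.fps))
    if n < 3:
        raise ValueError("window must span at least 3 samples")
    x = pd.Series(trace.values)
    if method == "peak_to_peak":
        amp = (x.rolling(n, center=True, min_periods=1).max()
               - x.rolling(n, center=True, min_periods=1).min()).to_numpy()
    elif method == "hilbert":
        amp = 2.0 * np.abs(signal.hilbert(trace.values - trace.values.mean()))
    else:
        raise ValueError(f"unknown amplitude method {method!r}")
    half = n // 2
    edge = np.zeros(len(x), dtype=bool)
    edge[:half] = True
    if half:
        edge[-half:] = True
    return AmplitudeSeries(fps=trace.fps, values=np.asarray(amp), edge=edge,
                           t0=trace.t0)


def _mask_to_segments(mask: np.ndarray, fps: float, label: str, t0: float,
                      min_dur: float = 0.0) -> list[Segment]:
    segs = []
    padded = np.concatenate([[False], mask, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    for s, e in zip(starts, ends):
        dur = (e - s) / fps
        if dur >= min_dur - 1e-12:
            segs.append(Segment(t0 + s / fps, t0 + e / fps, label))
    return segs


def segment_whisking(
    amplitude: AmplitudeSeries,
    hi: float = 5.0,
    lo: float = 3.0,
    touch_times: Optional[Sequence[float]] = None,
    exclusion_s: float = 0.100,
    min_dur: float = 0.0,
) -> StateSegments:
    """Whisking (amp > hi) and quiescent (amp < lo) segments.

    Frames within ``exclusion_s`` of a touch event are excluded from both
    states, as are frames in the [lo, hi] dead band.
    """
    t = amplitude.times
    excluded = np.zeros(t.size, dtype=bool)
    for tt in (touch_times if touch_times is not None else []):
        excluded |= np.abs(t - tt) <= exclusion_s
    whisk = (amplitude.values > hi) & ~excluded
    quiet = (amplitude.values < lo) & ~excluded
    segs = _mask_to_segments(whisk, amplitude.fps, "whisking", amplitude.t0, min_dur)
    segs += _mask_to_segments(quiet, amplitude.fps, "quiescent", amplitude.t0, min_dur)
    return StateSegments(segs)


def whisk_cycle_stats(
    filtered: AngleTrace,
    windows: Sequence[tuple[float, float]],
) -> tuple[np.ndarray, np.ndarray]:
    """(cycles, frequency Hz) per trial window.

    A cycle is one full 2*pi progression of the unwrapped Hilbert phase
    within the window; the per-window frequency is cycles / duration.
    """
    phase = whisking_phase(filtered)
    t = phase.times
    cycles = np.zeros(len(windows))
    freq = np.zeros(len(windows))
    for i, (a, b) in enumerate(windows):
        m = (t >= a) & (t < b)
        if m.sum() < 2 or not np.all(np.isfinite(phase.values[m])):
            continue
        unwrapped = np.unwrap(phase.values[m])
        cycles[i] = np.floor((unwrapped[-1] - unwrapped[0]) / (2 * np.pi))
        cycles[i] = max(cycles[i], 0.0)
        freq[i] = cycles[i] / (b - a)
    return cycles, freq


def segment_locomotion(
    position: PositionTrace,
    hi: float = 100.0,
    lo: float = 10.0,
    min_dur: float = 0.200,
    roi_mm: Optional[tuple[float, float]] = None,
) -> StateSegments:
    """Locomotion (|v| > hi) and rest (|v| < lo) segments of minimum duration.

    ``roi_mm`` restricts the analysis to a region of the track away from
    the lick ports and apertures; frames outside it join neither state.
    """
    # 50 ms median filter of the finite-difference velocity suppresses
    # single-frame tracking jitter before thresholding
    k = int(round(0.05 * position.fps))
    k = k + 1 if k % 2 == 0 else k
    v = signal.medfilt(position.velocity, k) if k >= 3 else position.velocity
    speed = np.abs(v)
    in_roi = np.ones(speed.size, dtype=bool)
    if roi_mm is not None:
        in_roi = (position.x >= roi_mm[0]) & (position.x < roi_mm[1])
    loco = (speed > hi) & in_roi
    rest = (speed < lo) & in_roi
    segs = _mask_to_segments(loco, position.fps, "locomotion", position.t0, min_dur)
    segs += _mask_to_segments(rest, position.fps, "rest", position.t0, min_dur)
    return StateSegments(segs)


@dataclass
class OccupancyMap:
    counts: np.ndarray          # frames per cell, shape (n_x, n_y)
    x_edges: np.ndarray         # mm, half-open [lo, hi) bins
    y_edges: np.ndarray
    velocity_mean: np.ndarray   # mm/s per longitudinal bin
    velocity_sd: np.ndarray


def occupancy_map(
    position: PositionTrace,
    x_bin_mm: float = 10.0,
    y_bin_mm: float = 1.0,
    x_range: tuple[float, float] = (-410.0, 410.0),
    y_range: tuple[float, float] = (0.0, 100.0),
) -> OccupancyMap:
    """Frame-count occupancy over 10 x 1 mm track cells plus the mean and SD
    of speed per longitudinal bin.  Cell counts sum to the number of
    analyzed frames."""
    x = position.x
    y = position.y if position.y is not None else np.full(x.size, y_range[0])
    x_edges = np.arange(x_range[0], x_range[1] + x_bin_mm / 2, x_bin_mm)
    y_edges = np.arange(y_range[0], y_range[1] + y_bin_mm / 2, y_bin_mm)
    # half-open binning with the top edge inclusive into the last bin
    xi = np.clip(np.digitize(x, x_edges) - 1, 0, x_edges.size - 2)
    yi = np.clip(np.digitize(y, y_edges) - 1, 0, y_edges.size - 2)
    counts = np.zeros((x_edges.size - 1, y_edges.size - 1))
    np.add.at(counts, (xi, yi), 1)
    speed = np.abs(position.velocity)
    vmean = np.full(x_edges.size - 1, np.nan)
    vsd = np.full(x_edges.size - 1, np.nan)
    for b in range(x_edges.size - 1):
        m = xi == b
        if np.any(m):
            vmean[b] = speed[m].mean()
            vsd[b] = speed[m].std()
    return OccupancyMap(counts=counts, x_edges=x_edges, y_edges=y_edges,
                        velocity_mean=vmean, velocity_sd=vsd)
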