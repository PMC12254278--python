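"""Per-unit statistics: quality control, RS/FS classification, response
onset latency, touch modulation, behavioral-state modulation, and angle /
phase / spatial tuning with circular-shift shuffle or analytic nulls.

The shuffle null rotates all spike times of a unit by a random offset drawn
uniformly below the recording duration, wrapping around the end.  This
preserves the spike count and interval structure while decoupling spikes
from behavior; observed statistics exceeding the 95th percentile of 100
such shuffles are deemed significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats as sps

from .core import AngleTrace, CalciumTrace, PhaseTrace, PositionTrace, SpikeTrain, StateSegments
from .stats import circular_mean, kuiper_test

__all__ = [
    "UnitClass",
    "LatencyResult",
    "TouchModulationResult",
    "StateModulationResult",
    "AngleTuningResult",
    "PhaseTuningResult",
    "SpatialTuningResult",
    "qc_filter_units",
    "classify_rs_fs",
    "onset_latency",
    "touch_modulation_ephys",
    "touch_modulation_calcium",
    "modulated_proportion",
    "circular_shift_null",
    "state_rate_modulation",
    "angle_tuning",
    "phase_tuning",
    "population_phase_vector",
    "spatial_tuning",
]

#: RS/FS trough-to-peak threshold (us) per region: cortical and incertal
#: waveforms are longer than thalamic ones.
RS_FS_THRESHOLD_US = {"BC": 350.0, "ZIv": 350.0, "VPM": 300.0, "POm": 300.0}

#: region-specific class retained for tuning analyses
KEPT_CLASS = {"BC": "RS", "VPM": "RS", "POm": "RS", "ZIv": "FS"}

PHASE_SNR_WINDOW_S = 0.111   # average whisk-cycle window for the SNR formula


# --------------------------------------------------------------------------
# QC and cell-type classification
# --------------------------------------------------------------------------

def isi_violation_fraction(spike_times: np.ndarray, isi_thresh_s: float = 0.0015) -> float:
    isi = np.diff(np.asarray(spike_times, dtype=float))
    if isi.size == 0:
        return 0.0
    return float(np.mean(isi < isi_thresh_s))


def qc_filter_units(
    units: Sequence[SpikeTrain],
    iso_min: float = 15.0,
    isi_viol_max: float = 0.03,
    isi_thresh_s: float = 0.0015,
) -> list[SpikeTrain]:
    """Retain well-isolated single units: isolation distance strictly above
    ``iso_min`` and ISI-violation fraction strictly below ``isi_viol_max``.
    Units without an isolation distance cannot be verified and are dropped
    with a warning."""
    kept = []
    missing = 0
    for u in units:
        if u.isolation_distance is None:
            missing += 1
            continue
        if u.isolation_distance <= iso_min:
            continue
        if isi_violation_fraction(u.spike_times, isi_thresh_s) >= isi_viol_max:
            continue
        kept.append(u)
    if missing:
        warnings.warn(f"excluded {missing} unit(s) with missing isolation distance")
    return kept


@dataclass
class UnitClass:
    label: str              # "RS" or "FS"
    threshold_used_us: float
    kept: bool              # retained for the region's tuning analyses


def classify_rs_fs(unit: SpikeTrain) -> UnitClass:
    """Regular- vs fast-spiking by trough-to-peak duration against the
    region's threshold; RS are kept for BC/VPM/POm and FS for ZIv."""
    thr = RS_FS_THRESHOLD_US[unit.region]
    label = "FS" if unit.trough_to_peak_us < thr else "RS"
    return UnitClass(label=label, threshold_used_us=thr,
                     kept=(label == KEPT_CLASS[unit.region]))


# --------------------------------------------------------------------------
# onset latency (Poisson baseline model)
# --------------------------------------------------------------------------

@dataclass
class LatencyResult:
    latency_ms: Optional[int]
    baseline_rate: float      # Hz
    p_at_onset: float
    baseline_floored: bool = False


def onset_latency(
    unit: SpikeTrain,
    touch_times: Sequence[float],
    baseline_window_s: tuple[float, float] = (-0.800, -0.600),
    search_s: float = 0.200,
    bin_s: float = 0.001,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> LatencyResult:
    """First 1 ms PSTH bin after touch whose trial-summed count exceeds the
    Poisson baseline at p <= alpha (upper tail only: excitatory onsets).

    Counts are summed over trials; the expected count per bin is the
    baseline rate times n_trials * bin width.  An empty baseline is floored
    at 0.1 Hz and flagged.
    """
    touch_times = np.asarray(touch_times, dtype=float)
    if touch_times.size < 10:
        raise ValueError("need at least 10 touch events")
    s = unit.spike_times
    n_trials = touch_times.size
    # baseline rate from the pre-stimulus window, pooled over trials
    b0, b1 = baseline_window_s
    base_count = 0
    for tt in touch_times:
        base_count += np.count_nonzero((s >= tt + b0) & (s < tt + b1))
    base_rate = base_count / (n_trials * (b1 - b0))
    floored = False
    if base_rate == 0.0:
        base_rate = 0.1
        floored = True
    n_bins = int(round(search_s / bin_s))
    counts = np.zeros(n_bins, dtype=int)
    for tt in touch_times:
        rel = s[(s >= tt) & (s < tt + search_s)] - tt
        np.add.at(counts, np.minimum((rel / bin_s).astype(int), n_bins - 1), 1)
    mu = base_rate * n_trials * bin_s
    p = sps.poisson.sf(counts - 1, mu)      # P(X >= observed)
    thr = alpha / n_bins if bonferroni else alpha
    hits = np.flatnonzero(p <= thr)
    if hits.size == 0:
        return LatencyResult(latency_ms=None, baseline_rate=base_rate,
                             p_at_onset=float(p.min()), baseline_floored=floored)
    i = int(hits[0])
    return LatencyResult(latency_ms=int(round(i * bin_s * 1000)),
                         baseline_rate=base_rate, p_at_onset=float(p[i]),
                         baseline_floored=floored)


# --------------------------------------------------------------------------
# touch modulation
# --------------------------------------------------------------------------

@dataclass
class TouchModulationResult:
    p_wide: float
    p_narrow: float
    sig_wide: bool
    sig_narrow: bool
    category: str        # {"wide-only", "narrow-only", "both", "none"}


def _paired_counts(s: np.ndarray, touches: np.ndarray,
                   response_s: float, baseline_s: float) -> tuple[np.ndarray, np.ndarray]:
    pre = np.array([np.count_nonzero((s >= tt - baseline_s) & (s < tt))
                    for tt in touches], dtype=float)
    post = np.array([np.count_nonzero((s >= tt) & (s < tt + response_s))
                     for tt in touches], dtype=float)
    return pre, post


def _touch_increase_p(s, touches, response_s, baseline_s, alpha) -> tuple[float, bool]:
    touches = np.asarray(touches, dtype=float)
    if touches.size < 5:
        return 1.0, False
    pre, post = _paired_counts(s, touches, response_s, baseline_s)
    diff = post - pre
    if np.all(diff == 0):
        return 1.0, False
    p = float(sps.wilcoxon(post, pre, zero_method="wilcox",
                           alternative="two-sided").pvalue)
    increase = float(np.median(diff)) > 0
    return p, (p <= alpha and increase)


def touch_modulation_ephys(
    unit: SpikeTrain,
    touches_wide: Sequence[float],
    touches_narrow: Sequence[float],
    response_s: float = 0.200,
    baseline_s: float = 0.200,
    alpha: float = 0.05,
) -> TouchModulationResult:
    """Touch responsiveness per aperture: paired per-trial spike counts in a
    200 ms response window vs an equal baseline window, two-sided Wilcoxon
    signed-rank, with an increase enforced via a positive median paired
    difference."""
    p_w, sig_w = _touch_increase_p(unit.spike_times, touches_wide,
                                   response_s, baseline_s, alpha)
    p_n, sig_n = _touch_increase_p(unit.spike_times, touches_narrow,
                                   response_s, baseline_s, alpha)
    cat = {(True, True): "both", (True, False): "wide-only",
           (False, True): "narrow-only", (False, False): "none"}[(sig_w, sig_n)]
    return TouchModulationResult(p_wide=p_w, p_narrow=p_n, sig_wide=sig_w,
                                 sig_narrow=sig_n, category=cat)


def touch_modulation_calcium(
    trace: CalciumTrace,
    touch_times: Sequence[float],
    window_s: float = 0.400,
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """Paired two-tailed t-test of summed dF/F in the 400 ms windows before
    vs after each touch (12 frames each at 30 Hz; converted by time for
    other frame rates).  Returns (p, significant)."""
    n_frames = int(round(window_s * trace.fps))
    pre, post = [], []
    for tt in touch_times:
        i = int(round((tt - trace.t0) * trace.fps))
        if i - n_frames < 0 or i + n_frames > len(trace):
            continue
        pre.append(trace.values[i - n_frames:i].sum())
        post.append(trace.values[i:i + n_frames].sum())
    if len(pre) < 5:
        return 1.0, False
    p = float(sps.ttest_rel(post, pre).pvalue)
    return p, p <= alpha


def modulated_proportion(n_modulated: int, n_total: int) -> float:
    """Percentage of modulated units, reported to one decimal."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_modulated / n_total, 1)


# --------------------------------------------------------------------------
# circular-shift shuffle null
# --------------------------------------------------------------------------

def circular_shift_null(
    unit: SpikeTrain, n_shuffles: int = 100, seed: int = 0
) -> np.ndarray:
    """Shuffled spike-time sets, shape (n_shuffles, n_spikes).

    Each shuffle shifts all spike times by one Uniform(0, duration) offset,
    wrapping the end of the sequence to the beginning; spike counts and all
    but the single wrap interval are preserved.
    """
    rng = np.random.default_rng(seed)
    shifts = rng.uniform(0.0, unit.recording_duration, n_shuffles)
    shuffled = np.mod(unit.spike_times[None, :] + shifts[:, None],
                      unit.recording_duration)
    return np.sort(shuffled, axis=1)


# --------------------------------------------------------------------------
# behavioral-state rate modulation
# --------------------------------------------------------------------------

@dataclass
class StateModulationResult:
    rate_a: float
    rate_b: float
    observed_diff: float      # rate_a - rate_b
    null_95th: float          # 95th percentile of shuffled |diff|
    label: str                # {"enhanced", "suppressed", "none"}


def _segment_bounds(segments: StateSegments, label: str) -> tuple[np.ndarray, float]:
    segs = segments.with_label(label)
    if not segs:
        raise ValueError(f"no segments with label {label!r}")
    bounds = np.array([[s.t_start, s.t_end] for s in segs]).ravel()
    return bounds, float(sum(s.duration for s in segs))


def _rate_in(times: np.ndarray, bounds: np.ndarray, total: float) -> np.ndarray:
    """Spike rate inside the intervals encoded by sorted ``bounds``; works on
    1-D or 2-D (shuffles x spikes) time arrays."""
    inside = np.searchsorted(bounds, times, side="right") % 2 == 1
    return inside.sum(axis=-1) / total


def state_rate_modulation(
    unit: SpikeTrain,
    segments: StateSegments,
    label_a: str = "locomotion",
    label_b: str = "rest",
    n_shuffles: int = 100,
    seed: int = 0,
) -> StateModulationResult:
    """Firing-rate difference between two state families against the
    circular-shift null: significant when the observed |difference| exceeds
    the 95th percentile of the shuffled |difference| distribution.
    'Enhanced' means a higher rate in state A (e.g. locomotion)."""
    bounds_a, dur_a = _segment_bounds(segments, label_a)
    bounds_b, dur_b = _segment_bounds(segments, label_b)
    s = unit.spike_times
    rate_a = float(_rate_in(s, bounds_a, dur_a))
    rate_b = float(_rate_in(s, bounds_b, dur_b))
    obs = rate_a - rate_b
    shuffled = circular_shift_null(unit, n_shuffles, seed)
    null = np.abs(_rate_in(shuffled, bounds_a, dur_a)
                  - _rate_in(shuffled, bounds_b, dur_b))
    # 'higher' order statistic: the conventional conservative percentile for
    # a finite permutation null
    q95 = float(np.percentile(null, 95, method="higher"))
    if abs(obs) > q95:
        label = "enhanced" if obs > 0 else "suppressed"
    else:
        label = "none"
    return StateModulationResult(rate_a=rate_a, rate_b=rate_b, observed_diff=obs,
                                 null_95th=q95, label=label)


# --------------------------------------------------------------------------
# angle tuning (whisker angle or head azimuth)
# --------------------------------------------------------------------------

@dataclass
class AngleTuningResult:
    bin_edges: np.ndarray
    rates: np.ndarray                 # Hz per included bin, NaN where excluded
    r_max: float
    r_min: float
    r_mean: float
    modulation_depth: float
    null_95th: float
    significant: bool


def _spike_bins(spike_times: np.ndarray, frame_bin: np.ndarray, fps: float,
                t0: float, n_bins: int) -> np.ndarray:
    """Per-bin spike counts given a frame -> bin lookup (-1 = excluded)."""
    idx = np.clip(((spike_times - t0) * fps).astype(int), 0, frame_bin.size - 1)
    b = frame_bin[idx]
    counts = np.zeros(n_bins)
    valid = b >= 0
    if spike_times.ndim == 1:
        np.add.at(counts, b[valid], 1)
        return counts
    raise NotImplementedError


def angle_tuning(
    unit: SpikeTrain,
    angle: AngleTrace,
    bin_deg: float = 5.0,
    angle_range: tuple[float, float] = (0.0, 180.0),
    touch_times: Optional[Sequence[float]] = None,
    exclusion_s: float = 0.100,
    min_occupancy_s: float = 0.5,
    n_shuffles: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> AngleTuningResult:
    """Angle tuning with modulation depth (r_max - r_min)/r_mean against a
    circular-shift null.

    Per-bin rates are spikes divided by time in the bin; frames (and
    spikes) during or within 100 ms of touch events are excluded, as are
    bins occupied for less than ``min_occupancy_s``.  The head-azimuth
    variant uses ``angle_range=(-90, 90)``.
    """
    edges = np.arange(angle_range[0], angle_range[1] + bin_deg / 2, bin_deg)
    n_bins = edges.size - 1
    frame_bin = np.clip(np.digitize(angle.values, edges) - 1, 0, n_bins - 1)
    t_frames = angle.times
    excluded = np.zeros(t_frames.size, dtype=bool)
    for tt in (touch_times if touch_times is not None else []):
        excluded |= np.abs(t_frames - tt) <= exclusion_s
    frame_bin = np.where(excluded, -1, frame_bin)
    occupancy = np.bincount(frame_bin[frame_bin >= 0], minlength=n_bins) / angle.fps
    included = occupancy >= min_occupancy_s

    def depth_of(times: np.ndarray) -> tuple[float, np.ndarray]:
        counts = _spike_bins(times, frame_bin, angle.fps, angle.t0, n_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            rates = np.where(included, counts / occupancy, np.nan)
        r = rates[included]
        if r.size == 0 or np.nanmean(r) == 0:
            return np.nan, rates
        return float((np.nanmax(r) - np.nanmin(r)) / np.nanmean(r)), rates

    obs_depth, rates = depth_of(unit.spike_times)
    if not np.isfinite(obs_depth):
        raise ValueError("mean rate is zero over included bins; tuning undefined")
    shuffled = circular_shift_null(unit, n_shuffles, seed)
    null = np.array([depth_of(row)[0] for row in shuffled])
    q95 = float(np.nanpercentile(null, 100 * (1 - alpha), method="higher"))
    r = rates[included]
    return AngleTuningResult(
        bin_edges=edges, rates=rates,
        r_max=float(np.nanmax(r)), r_min=float(np.nanmin(r)),
        r_mean=float(np.nanmean(r)),
        modulation_depth=obs_depth, null_95th=q95,
        significant=bool(obs_depth > q95))


# --------------------------------------------------------------------------
# whisking phase tuning
# --------------------------------------------------------------------------

@dataclass
class PhaseTuningResult:
    mean_rate: float          # <lambda>, Hz
    amp: float                # Amp_tuning, Hz
    preferred_phase: float    # radians in [0, 2*pi)
    snr: float
    kuiper_v: float
    kuiper_p: float
    bin_centers: np.ndarray = field(default_factory=lambda: np.array([]))
    bin_rates: np.ndarray = field(default_factory=lambda: np.array([]))
    T: float = PHASE_SNR_WINDOW_S

    @property
    def significant(self) -> bool:
        return self.kuiper_p <= 0.05


def _sine_fit(centers: np.ndarray, rates: np.ndarray) -> tuple[float, float, float]:
    """Least-squares fit of r = <r> + A*cos(phi - phi0) on binned rates.

    The regression on (1, cos phi, sin phi) returns the first circular
    Fourier coefficient of the profile.
    """
    X = np.column_stack([np.ones_like(centers), np.cos(centers), np.sin(centers)])
    beta, *_ = np.linalg.lstsq(X, rates, rcond=None)
    mean, bc, bs = beta
    amp = float(np.hypot(bc, bs))
    pref = float(np.mod(np.arctan2(bs, bc), 2 * np.pi))
    return float(mean), amp, pref


def phase_snr(amp: float, mean_rate: float, T: float = PHASE_SNR_WINDOW_S) -> float:
    """SNR = 2 * Amp * sqrt(T / <lambda>) for a Poisson point process
    observed over one average whisk cycle (T = 111 ms)."""
    if mean_rate <= 0:
        return np.nan
    return float(2.0 * amp * np.sqrt(T / mean_rate))


def phase_tuning(
    unit: SpikeTrain,
    phase: PhaseTrace,
    n_bins: int = 32,
    kuiper_on: str = "spike_phases",
    bin_rates: Optional[np.ndarray] = None,
) -> PhaseTuningResult:
    """Cosine phase tuning fitted by linear least squares on 32-bin rates.

    Spikes are assigned to the phase at their time; per-bin rates are spike
    counts over occupancy time.  ``kuiper_on`` selects the significance
    variant: the default tests the spike phase distribution against
    circular uniformity; 'binned_rates' applies the test to the
    occupancy-normalized rate distribution across bins.  ``bin_rates``
    bypasses binning and fits a supplied noiseless profile directly.
    """
    centers = (np.arange(n_bins) + 0.5) * 2 * np.pi / n_bins
    if bin_rates is not None:
        rates = np.asarray(bin_rates, dtype=float)
        mean, amp, pref = _sine_fit(centers, rates)
        return PhaseTuningResult(mean_rate=mean, amp=amp, preferred_phase=pref,
                                 snr=phase_snr(amp, mean), kuiper_v=np.nan,
                                 kuiper_p=np.nan, bin_centers=centers,
                                 bin_rates=rates)
    finite = np.isfinite(phase.values)
    frame_bin = np.where(
        finite,
        np.clip((phase.values / (2 * np.pi) * n_bins).astype(int), 0, n_bins - 1),
        -1)
    occupancy = np.bincount(frame_bin[frame_bin >= 0], minlength=n_bins) / phase.fps
    if np.count_nonzero(occupancy > 0) < 2:
        raise ValueError("fewer than 2 occupied phase bins")
    idx = np.clip(((unit.spike_times - phase.t0) * phase.fps).astype(int),
                  0, frame_bin.size - 1)
    spike_bins = frame_bin[idx]
    spike_phases = phase.values[idx][spike_bins >= 0]
    counts = np.bincount(spike_bins[spike_bins >= 0], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(occupancy > 0, counts / occupancy, np.nan)
    m = np.isfinite(rates)
    mean, amp, pref = _sine_fit(centers[m], rates[m])
    if kuiper_on == "spike_phases":
        if spike_phases.size == 0:
            v, p = np.nan, 1.0
        else:
            v, p = kuiper_test(spike_phases)
    elif kuiper_on == "binned_rates":
        # treat the normalized rate profile as a circular distribution
        w = np.clip(rates[m], 0, None)
        if w.sum() == 0:
            v, p = np.nan, 1.0
        else:
            reps = np.maximum((1000 * w / w.sum()).astype(int), 0)
            v, p = kuiper_test(np.repeat(centers[m], reps))
    else:
        raise ValueError(f"unknown kuiper_on variant {kuiper_on!r}")
    return PhaseTuningResult(mean_rate=mean, amp=amp, preferred_phase=pref,
                             snr=phase_snr(amp, mean), kuiper_v=v, kuiper_p=p,
                             bin_centers=centers, bin_rates=rates)


def population_phase_vector(
    results: Sequence[PhaseTuningResult],
    amplitude_weighted: bool = False,
    only_significant: bool = True,
) -> tuple[float, float]:
    """Circular mean (degrees) and resultant length of the preferred phases
    of (significant) phase-tuned units."""
    use = [r for r in results if (not only_significant) or r.significant]
    if not use:
        raise ValueError("no qualifying units")
    angles = np.array([r.preferred_phase for r in use])
    weights = np.array([r.amp for r in use]) if amplitude_weighted else None
    mean, length = circular_mean(angles, weights)
    return float(np.rad2deg(mean)), length


# --------------------------------------------------------------------------
# spatial tuning (Gaussian place field with a speed nuisance term)
# --------------------------------------------------------------------------

@dataclass
class SpatialTuningResult:
    amplitude: float          # A, Hz
    mu_mm: float
    sigma_mm: float
    speed_coef: float         # Hz per mm/s
    intercept: float          # Hz
    ci95: dict[str, tuple[float, float]]
    amp_null_95th: float      # 95th percentile of shuffled |A|
    spatially_tuned: bool
    converged: bool
    bin_centers: np.ndarray = field(default_factory=lambda: np.array([]))
    bin_rates: np.ndarray = field(default_factory=lambda: np.array([]))


def _place_model(X, A, mu, sigma, speed_coef, intercept):
    x, v = X
    return A * np.exp(-((x - mu) ** 2) / (2 * sigma**2)) + speed_coef * v + intercept


def _grid_amplitude(rates: np.ndarray, pinvs: np.ndarray, designs: np.ndarray,
                    w: np.ndarray) -> np.ndarray:
    """Best |A| over a (mu, sigma) grid by profiled weighted least squares.

    For fixed (mu, sigma) the model is linear in (A, speed_coef, intercept);
    ``pinvs`` holds the precomputed WLS solution operators per grid cell.
    ``rates`` may be (n_bins,) or (n_shuffles, n_bins).
    """
    y = np.atleast_2d(rates)                          # (S, n_bins)
    beta = np.einsum("gpk,sk->sgp", pinvs, y)         # (S, G, 3)
    yhat = np.einsum("gkp,sgp->sgk", designs, beta)   # (S, G, n_bins)
    rss = np.einsum("k,sgk->sg", w, (y[:, None, :] - yhat) ** 2)
    gbest = rss.argmin(axis=1)
    amp = np.abs(beta[np.arange(y.shape[0]), gbest, 0])
    return amp, gbest


def spatial_tuning(
    unit: SpikeTrain,
    position: PositionTrace,
    time_bin_s: float = 0.100,
    pos_bin_mm: float = 20.0,
    sigma_grid_mm: tuple[float, ...] = (20.0, 40.0, 80.0),
    min_occupancy_s: float = 0.5,
    n_shuffles: int = 100,
    seed: int = 0,
) -> SpatialTuningResult:
    """Gaussian place-field fit with a linear speed term.

    Firing rates in 100 ms time bins are averaged into 20 mm position bins
    (with the mean speed per bin) and the model
    rate = A*exp(-(x-mu)^2/(2 sigma^2)) + speed_coef*v + intercept
    is fitted by occupancy-weighted least squares: (mu, sigma) over a grid
    with the linear parameters profiled out, then polished by a bounded
    nonlinear fit.  A unit is spatially tuned when its best-fit |A| exceeds
    the 95th percentile of |A| refit on circular-shift shuffled spikes
    (which corrects the selection over candidate field locations) and zero
    lies inside the 95% CI of the speed coefficient -- a location-specific
    response not explained by running speed.  Bins occupied for less than
    ``min_occupancy_s`` are excluded.
    """
    t_edges = np.arange(0.0, position.duration + time_bin_s, time_bin_s)
    n_t = t_edges.size - 1
    # mean position and speed per time bin
    frame_bin = np.clip((position.times / time_bin_s).astype(int), 0, n_t - 1)
    pos_t = np.bincount(frame_bin, weights=position.x, minlength=n_t)
    spd_t = np.bincount(frame_bin, weights=np.abs(position.velocity),
                        minlength=n_t)
    nf = np.bincount(frame_bin, minlength=n_t)
    ok = nf > 0
    pos_t, spd_t = pos_t[ok] / nf[ok], spd_t[ok] / nf[ok]
    # map time bins to spatial bins
    x_edges = np.arange(-420.0, 420.0 + pos_bin_mm / 2, pos_bin_mm)
    xb = np.clip(np.digitize(pos_t, x_edges) - 1, 0, x_edges.size - 2)
    n_xb = x_edges.size - 1
    nb = np.bincount(xb, minlength=n_xb)
    min_bins = max(int(np.ceil(min_occupancy_s / time_bin_s)), 2)
    occ = nb >= min_bins
    spd_x = np.bincount(xb, weights=spd_t, minlength=n_xb)[occ] / nb[occ]
    x_cent = ((x_edges[:-1] + x_edges[1:]) / 2)[occ]
    if x_cent.size < 6:
        return SpatialTuningResult(np.nan, np.nan, np.nan, np.nan, np.nan, {},
                                   np.nan, spatially_tuned=False,
                                   converged=False, bin_centers=x_cent,
                                   bin_rates=np.array([]))

    def binned_rates(spike_times: np.ndarray) -> np.ndarray:
        counts, _ = np.histogram(spike_times, bins=t_edges)
        rate_t = (counts / time_bin_s)[ok]
        return np.bincount(xb, weights=rate_t, minlength=n_xb)[occ] / nb[occ]

    rate_x = binned_rates(unit.spike_times)
    # occupancy-based Poisson weights: SE_b ~ sqrt(rbar / occupancy_time)
    rbar = max(unit.mean_rate, 1e-3)
    se_x = np.sqrt(rbar / (nb[occ] * time_bin_s))
    w = 1.0 / se_x**2
    # profiled WLS operators per (mu, sigma) grid cell
    designs, pinvs = [], []
    for mu0 in x_cent:
        for s0 in sigma_grid_mm:
            X = np.column_stack([np.exp(-((x_cent - mu0) ** 2) / (2 * s0**2)),
                                 spd_x, np.ones_like(x_cent)])
            Xw = X * w[:, None]
            pinvs.append(np.linalg.solve(X.T @ Xw, Xw.T))
            designs.append(X)
    designs = np.stack(designs)          # (G, n_bins, 3)
    pinvs = np.stack(pinvs)              # (G, 3, n_bins)
    grid = [(mu0, s0) for mu0 in x_cent for s0 in sigma_grid_mm]
    amp_obs, gbest = _grid_amplitude(rate_x, pinvs, designs, w)
    amp_obs, gbest = float(amp_obs[0]), int(gbest[0])
    # shuffle null of the same statistic
    shuffled = circular_shift_null(unit, n_shuffles, seed)
    null_rates = np.stack([binned_rates(row) for row in shuffled])
    amp_null, _ = _grid_amplitude(null_rates, pinvs, designs, w)
    amp_q95 = float(np.percentile(amp_null, 95, method="higher"))
    # polish the observed fit for parameter estimates and CIs
    mu0, s0 = grid[gbest]
    span = x_cent.max() - x_cent.min()
    bounds = ([-np.inf, x_cent.min(), pos_bin_mm / 2, -np.inf, -np.inf],
              [np.inf, x_cent.max(), span, np.inf, np.inf])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = optimize.curve_fit(
                _place_model, (x_cent, spd_x), rate_x,
                p0=[rate_x.max() - rate_x.mean(), mu0, s0, 0.0, rate_x.mean()],
                sigma=se_x, absolute_sigma=True, bounds=bounds, maxfev=2000)
    except (RuntimeError, ValueError):
        return SpatialTuningResult(np.nan, np.nan, np.nan, np.nan, np.nan, {},
                                   amp_q95, spatially_tuned=False,
                                   converged=False, bin_centers=x_cent,
                                   bin_rates=rate_x)
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    names = ["A", "mu", "sigma", "speed_coef", "intercept"]
    ci = {nm: (float(popt[i] - 1.96 * se[i]), float(popt[i] + 1.96 * se[i]))
          for i, nm in enumerate(names)}
    a_sig = amp_obs > amp_q95
    speed_ns = ci["speed_coef"][0] <= 0.0 <= ci["speed_coef"][1]
    return SpatialTuningResult(
        amplitude=float(popt[0]), mu_mm=float(popt[1]),
        sigma_mm=float(abs(popt[2])), speed_coef=float(popt[3]),
        intercept=float(popt[4]), ci95=ci, amp_null_95th=amp_q95,
        spatially_tuned=bool(a_sig and speed_ns),
        converged=True, bin_centers=x_cent, bin_rates=rate_x)
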