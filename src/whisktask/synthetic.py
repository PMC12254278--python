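"""Synthetic experiment generator with known ground truth.

Emulates a full aperture-discrimination session: stage-ruled trial events
from a parametric learner, a 240 Hz whisker angle trace with ~14.5 Hz
whisking bouts and touch-locked deflections, 60 Hz run-pause locomotion on
an 820 mm linear track, inhomogeneous-Poisson spike trains with injected
touch/angle/phase/place/state tuning, and spike-convolved dF/F calcium
transients.  Every stream derives an independent sub-seed from the master
seed, so identical (config, seed) pairs regenerate bit-identical data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import kinematics
from .behavior import _score
from .core import (
    NARROW_MM,
    NEUTRAL_MM,
    TRACK_HALF_MM,
    WIDE_MM,
    AngleTrace,
    CalciumTrace,
    PhaseTrace,
    PositionTrace,
    Session,
    SpikeTrain,
    TrialRecord,
)

__all__ = [
    "LearnerParams",
    "TuningSpec",
    "SyntheticGroundTruth",
    "KinematicBundle",
    "generate_session_events",
    "generate_whisker_trace",
    "generate_position_trace",
    "generate_spike_trains",
    "generate_calcium",
]

_STAGE_APERTURES = {
    "habituation": (WIDE_MM,),
    "initial": (WIDE_MM, NARROW_MM),
    "neutral": (WIDE_MM, NEUTRAL_MM, NARROW_MM),
    "reversed": (WIDE_MM, NARROW_MM),
    "extinction": (WIDE_MM, NARROW_MM),
}


def _substream(seed: int, stream: int) -> np.random.Generator:
    """Independent generator for one named stream of the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stream + 1)[stream])


# --------------------------------------------------------------------------
# learner and tuning ground truth
# --------------------------------------------------------------------------

@dataclass
class LearnerParams:
    """Parametric go/no-go learner: trial-indexed lick probabilities.

    Both lick probabilities follow a logistic trajectory from their initial
    to their final value; an optional insight trial applies an abrupt
    drop of the no-go lick probability by ``insight_factor`` on top of the
    gradual trajectory, mimicking an insight-like jump in no-go success.
    """

    p_lick_go_initial: float = 0.85
    p_lick_go_final: float = 0.95
    p_lick_nogo_initial: float = 0.80
    p_lick_nogo_final: float = 0.05
    learning_midpoint_trials: int = 400
    learning_rate: float = 0.01      # 1/trials
    insight_trial: Optional[int] = None
    insight_factor: float = 5.0

    def __post_init__(self) -> None:
        for p in (self.p_lick_go_initial, self.p_lick_go_final,
                  self.p_lick_nogo_initial, self.p_lick_nogo_final):
            if not 0.0 <= p <= 1.0:
                raise ValueError("lick probabilities must lie in [0, 1]")
        if self.learning_midpoint_trials <= 0:
            raise ValueError("learning midpoint must be positive")
        if self.insight_factor < 5.0:
            raise ValueError("insight factor must be >= 5")

    def _sigmoid(self, i: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.learning_rate
                                   * (i - self.learning_midpoint_trials)))

    def p_lick_go(self, trial: np.ndarray) -> np.ndarray:
        s = self._sigmoid(np.asarray(trial, dtype=float))
        return self.p_lick_go_initial + (self.p_lick_go_final
                                         - self.p_lick_go_initial) * s

    def p_lick_nogo(self, trial: np.ndarray) -> np.ndarray:
        i = np.asarray(trial, dtype=float)
        s = self._sigmoid(i)
        p = self.p_lick_nogo_initial + (self.p_lick_nogo_final
                                        - self.p_lick_nogo_initial) * s
        if self.insight_trial is not None:
            p = np.where(i >= self.insight_trial, p / self.insight_factor, p)
        return p


@dataclass
class TuningSpec:
    """Injected tuning of one simulated unit (the recovery ground truth)."""

    baseline_rate: float = 10.0           # Hz
    touch_gain_wide: float = 1.0          # multiplicative, 200 ms post-touch
    touch_gain_narrow: float = 1.0
    angle_pref_deg: float = 90.0
    angle_kappa: float = 0.0              # 0 = untuned
    phase_amp: float = 0.0                # Hz
    phase_pref: float = np.pi             # radians
    place_center_mm: float = 0.0
    place_sigma_mm: float = 40.0
    place_amp: float = 0.0                # Hz
    locomotion_gain: float = 1.0          # multiplicative while running

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.place_sigma_mm <= 0:
            raise ValueError("place_sigma_mm must be positive")
        if self.phase_amp > self.baseline_rate:
            raise ValueError("phase_amp must not exceed baseline_rate")


@dataclass
class SyntheticGroundTruth:
    """Everything needed to regenerate and verify one synthetic experiment."""

    learner: LearnerParams
    units: list[TuningSpec]
    whisk_freq_hz: float
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {"learner": asdict(self.learner),
             "units": [asdict(u) for u in self.units],
             "whisk_freq_hz": self.whisk_freq_hz,
             "seed": self.seed},
            indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticGroundTruth":
        d = json.loads(text)
        return cls(learner=LearnerParams(**d["learner"]),
                   units=[TuningSpec(**u) for u in d["units"]],
                   whisk_freq_hz=d["whisk_freq_hz"], seed=d["seed"])


# --------------------------------------------------------------------------
# behavioral events
# --------------------------------------------------------------------------

def generate_session_events(
    stage: str,
    learner: LearnerParams,
    n_trials: int,
    seed: int,
    mouse_id: str = "sim",
    session_index: int = 0,
    trial_offset: int = 0,
    iti_range_s: tuple[float, float] = (5.0, 15.0),
    touch_delay_s: float = 0.5,
) -> Session:
    """Simulate one session of stage-ruled trials.

    Apertures are drawn i.i.d. uniformly from the stage's aperture set, lick
    decisions from the learner's trial-indexed probabilities (neutral
    apertures use the mean of the go and no-go probabilities), and scoring
    follows the stage rule; extinction outcomes are random coin flips
    independent of the aperture.  ``trial_offset`` indexes the learner's
    position in training across multi-session simulations.
    """
    if stage not in _STAGE_APERTURES:
        raise ValueError(
            f"unknown stage {stage!r}; valid stages: {', '.join(_STAGE_APERTURES)}")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = _substream(seed, 0)
    apertures = np.array(_STAGE_APERTURES[stage])
    trials: list[TrialRecord] = []
    t = 0.0
    for i in range(n_trials):
        global_i = trial_offset + i
        ap = float(rng.choice(apertures))
        go_ap = WIDE_MM if stage in ("habituation", "initial", "neutral") else NARROW_MM
        if abs(ap - NEUTRAL_MM) < 1e-9 and stage == "neutral":
            p = 0.5 * (learner.p_lick_go(global_i) + learner.p_lick_nogo(global_i))
        elif abs(ap - go_ap) < 1e-9 or stage == "habituation":
            p = learner.p_lick_go(global_i)
        else:
            p = learner.p_lick_nogo(global_i)
        licked = bool(rng.random() < float(p))
        t += float(rng.uniform(*iti_range_s))
        t_beam = t
        t_touch = t_beam + touch_delay_s
        t_lick = t_touch + float(rng.uniform(0.2, 0.8)) if licked else None
        score, outcome = _score(stage, ap, licked)
        if stage == "extinction" and licked:
            outcome = "reward" if rng.random() < 0.5 else "punishment"
        trials.append(TrialRecord(
            trial_index=global_i, side="left" if i % 2 == 0 else "right",
            aperture_mm=ap, response="lick" if licked else "no-lick",
            score=score, outcome=outcome,
            t_beam=t_beam, t_touch=t_touch, t_lick=t_lick))
        t = t_lick if t_lick is not None else t_touch
    return Session(mouse_id=mouse_id, stage=stage, session_index=session_index,
                   trials=trials)


# --------------------------------------------------------------------------
# kinematics
# --------------------------------------------------------------------------

def generate_whisker_trace(
    session: Session,
    whisk_freq_hz: float = 14.5,
    amp_deg: float = 15.0,
    seed: int = 0,
    fps: float = 240.0,
    setpoint_deg: float = 90.0,
    bout_range_s: tuple[float, float] = (0.5, 2.0),
    quiet_jitter_deg: float = 0.3,
    touch_deflection_deg: float = 15.0,
) -> AngleTrace:
    """240 Hz whisker angle trace with whisking bouts and touch transients.

    Whisking bouts oscillate at ``whisk_freq_hz`` with sinusoid amplitude
    ``amp_deg`` around the set-point; quiescent bouts carry sub-3 degree
    jitter; each trial's touch adds a decaying deflection transient.
    Angles are clipped to [0, 180].
    """
    if not 2.0 < whisk_freq_hz < 30.0:
        raise ValueError("whisk frequency must lie inside the 2-30 Hz analysis band")
    rng = _substream(seed, 1)
    n = int(np.ceil(session.duration * fps))
    t = np.arange(n) / fps
    # alternating whisk/quiet bouts
    whisking = np.zeros(n, dtype=bool)
    pos = 0.0
    state = True
    while pos < t[-1]:
        dur = float(rng.uniform(*bout_range_s))
        if state:
            whisking[(t >= pos) & (t < pos + dur)] = True
        pos += dur
        state = not state
    phase0 = float(rng.uniform(0, 2 * np.pi))
    osc = amp_deg * np.cos(2 * np.pi * whisk_freq_hz * t + phase0)
    values = setpoint_deg + np.where(whisking, osc, 0.0)
    values = values + rng.normal(0.0, quiet_jitter_deg, n)
    # touch-locked deflections: fast protraction transient decaying over 100 ms
    kernel_t = np.arange(0, int(0.1 * fps)) / fps
    kernel = touch_deflection_deg * np.exp(-kernel_t / 0.03)
    for tt in session.touch_times:
        i0 = int(round(tt * fps))
        i1 = min(i0 + kernel.size, n)
        if i0 < n:
            values[i0:i1] += kernel[: i1 - i0]
    return AngleTrace(fps=fps, values=np.clip(values, 0.0, 180.0))


def generate_position_trace(
    session: Session,
    run_speed_mms: float = 200.0,
    seed: int = 0,
    fps: float = 60.0,
    dwell_range_s: tuple[float, float] = (2.0, 6.0),
    dwell_only: bool = False,
    end_margin_mm: float = 30.0,
    dwell_jitter_mm: float = 0.1,
) -> PositionTrace:
    """60 Hz run-pause position trace on the +/-410 mm linear track.

    The simulated mouse dwells at alternating track ends and runs across at
    approximately ``run_speed_mms``; ``dwell_only`` keeps it parked (no
    locomotion bouts).  Velocity is the centered finite difference.
    """
    if run_speed_mms <= 0:
        raise ValueError("run_speed_mms must be positive")
    rng = _substream(seed, 2)
    n = int(np.ceil(session.duration * fps))
    lo, hi = -TRACK_HALF_MM + end_margin_mm, TRACK_HALF_MM - end_margin_mm
    x = np.empty(n)
    i = 0
    here = lo
    while i < n:
        dwell = int(float(rng.uniform(*dwell_range_s)) * fps)
        j = min(i + dwell, n)
        x[i:j] = here + rng.normal(0, dwell_jitter_mm, j - i)
        i = j
        if i >= n or dwell_only:
            if dwell_only and i < n:
                continue
            break
        target = hi if here == lo else lo
        run_frames = int(round(abs(target - here) / run_speed_mms * fps))
        j = min(i + run_frames, n)
        x[i:j] = np.linspace(here, target, run_frames)[: j - i]
        here = target
        i = j
    if dwell_only:
        pass
    x = np.clip(x, -TRACK_HALF_MM, TRACK_HALF_MM)
    return PositionTrace(fps=fps, x=x)


@dataclass
class KinematicBundle:
    """Whisker and position traces plus the derived whisking phase."""

    whisker: AngleTrace
    position: PositionTrace
    _phase: Optional[PhaseTrace] = field(default=None, repr=False)

    @property
    def phase(self) -> PhaseTrace:
        if self._phase is None:
            filt = kinematics.bandpass_whisker(self.whisker)
            self._phase = kinematics.whisking_phase(filt)
        return self._phase


# --------------------------------------------------------------------------
# spikes and calcium
# --------------------------------------------------------------------------

def _rate_on_grid(
    spec: TuningSpec,
    session: Session,
    bundle: KinematicBundle,
    t: np.ndarray,
    loco_hi_mms: float = 100.0,
    touch_window_s: float = 0.200,
) -> np.ndarray:
    """Instantaneous rate lambda(t) of one unit on the thinning grid."""
    n = t.size
    rate = np.full(n, spec.baseline_rate)
    # touch kernel: rectangular aperture-specific gain for 200 ms post touch
    if spec.touch_gain_wide != 1.0 or spec.touch_gain_narrow != 1.0:
        gain = np.ones(n)
        for tr in session.trials:
            g = (spec.touch_gain_wide if tr.aperture_mm >= NEUTRAL_MM
                 else spec.touch_gain_narrow)
            m = (t >= tr.t_touch) & (t < tr.t_touch + touch_window_s)
            gain[m] = g
        rate *= gain
    # locomotion gain while the instantaneous speed exceeds the run threshold
    if spec.locomotion_gain != 1.0:
        speed = np.interp(t, bundle.position.times,
                          np.abs(bundle.position.velocity))
        rate *= np.where(speed > loco_hi_mms, spec.locomotion_gain, 1.0)
    # von-Mises whisker-angle factor, [0,180] deg mapped to the full circle
    if spec.angle_kappa > 0:
        ang = np.interp(t, bundle.whisker.times, bundle.whisker.values)
        theta = np.deg2rad(ang) * 2.0
        theta0 = np.deg2rad(spec.angle_pref_deg) * 2.0
        rate *= np.exp(spec.angle_kappa * (np.cos(theta - theta0) - 1.0))
    # cosine phase tuning
    if spec.phase_amp > 0:
        idx = np.clip((t * bundle.phase.fps).astype(int), 0,
                      len(bundle.phase) - 1)
        phi = bundle.phase.values[idx]
        mod = 1.0 + (spec.phase_amp / spec.baseline_rate) * np.cos(
            phi - spec.phase_pref)
        rate *= np.where(np.isfinite(phi), mod, 1.0)
    # additive place field expressed as a multiplicative bump
    if spec.place_amp > 0:
        x = np.interp(t, bundle.position.times, bundle.position.x)
        rate *= 1.0 + (spec.place_amp / spec.baseline_rate) * np.exp(
            -((x - spec.place_center_mm) ** 2) / (2 * spec.place_sigma_mm**2))
    return np.clip(rate, 0.0, None)


def generate_spike_trains(
    session: Session,
    bundle: KinematicBundle,
    specs: Sequence[TuningSpec],
    dt_s: float = 0.001,
    seed: int = 0,
    regions: Optional[Sequence[str]] = None,
    trough_to_peak_us: float = 400.0,
    touch_kernel_s: float = 0.200,
) -> list[SpikeTrain]:
    """Inhomogeneous-Poisson spike trains via Bernoulli thinning at ``dt_s``.

    The rate is the product of the baseline with the injected touch,
    locomotion, angle, phase, and place factors, clipped at zero.
    ``touch_kernel_s`` sets the duration of the rectangular post-touch gain.
    The grid must satisfy rate*dt <= 0.1 everywhere for thinning validity.
    """
    duration = min(bundle.whisker.duration, bundle.position.duration)
    t = np.arange(0.0, duration, dt_s)
    trains = []
    for u, spec in enumerate(specs):
        rng = _substream(seed, 3 + u)
        rate = _rate_on_grid(spec, session, bundle, t,
                             touch_window_s=touch_kernel_s)
        p = rate * dt_s
        if np.any(p > 0.1):
            raise ValueError(
                "dt_s too coarse: rate*dt exceeds 0.1 somewhere; refine the grid")
        fired = rng.random(t.size) < p
        times = t[fired] + rng.uniform(0.0, dt_s, int(fired.sum()))
        times = np.sort(np.clip(times, 0.0, duration))
        trains.append(SpikeTrain(
            unit_id=f"u{u:03d}",
            region=(regions[u] if regions is not None else "BC"),
            spike_times=times, recording_duration=duration,
            trough_to_peak_us=trough_to_peak_us, isolation_distance=25.0))
    return trains


def calcium_kernel_peak(tau_rise_s: float, tau_decay_s: float) -> float:
    """Closed-form maximum of the double-exponential unit kernel."""
    t_star = (np.log(tau_decay_s / tau_rise_s)
              * tau_rise_s * tau_decay_s / (tau_decay_s - tau_rise_s))
    return float(np.exp(-t_star / tau_decay_s) - np.exp(-t_star / tau_rise_s))


def generate_calcium(
    spikes: Sequence[SpikeTrain],
    tau_rise_s: float = 0.05,
    tau_decay_s: float = 0.5,
    noise_sd: float = 0.05,
    fps: float = 30.0,
    seed: int = 0,
) -> list[CalciumTrace]:
    """dF/F: spike trains convolved with a double-exponential transient
    kernel plus Gaussian noise, sampled at ``fps`` (default 30 Hz, so 12
    frames span 400 ms).  Each unit draws noise from its own stream."""
    if tau_decay_s <= tau_rise_s:
        raise ValueError("tau_decay must exceed tau_rise")
    traces = []
    for u, st in enumerate(spikes):
        rng = _substream(seed, 100 + u)
        n = int(np.ceil(st.recording_duration * fps)) + 1
        counts = np.zeros(n)
        idx = np.clip((st.spike_times * fps).astype(int), 0, n - 1)
        np.add.at(counts, idx, 1.0)
        kt = np.arange(0, int(np.ceil(6 * tau_decay_s * fps))) / fps
        kernel = np.exp(-kt / tau_decay_s) - np.exp(-kt / tau_rise_s)
        dff = np.convolve(counts, kernel)[:n]
        if noise_sd > 0:
            dff = dff + rng.normal(0.0, noise_sd, n)
        traces.append(CalciumTrace(fps=fps, values=dff, unit_id=st.unit_id))
    return traces
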