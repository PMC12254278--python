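"""Behavioral analysis: trial scoring, signal-detection performance,
learning-curve statistics, lick-latency fits, and retraction metrics.

The task is a go/no-go aperture discrimination: in the initial rule the wide
(45 mm) aperture is rewarded on lick (hit) and the narrow (25 mm) aperture
punished on lick (false alarm, FA); withholding gives miss / correct
rejection (CR).  In the reversed rule the contingencies swap; the neutral
(35 mm) aperture and all extinction trials are unscored.  Performance is
summarized by the discriminability index d' = z(hit rate) - z(FA rate),
with rates of 0 and 1 adjusted to 1/(2n) and 1 - 1/(2n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.special import ndtri

from .core import (
    NARROW_MM,
    NEUTRAL_MM,
    STAGES,
    WIDE_MM,
    Session,
    TrialRecord,
)

__all__ = [
    "DPrimeResult",
    "LickLatencyFit",
    "RetractionMetrics",
    "score_trials",
    "compute_dprime",
    "expert_threshold",
    "running_dprime",
    "success_rates",
    "detect_insight",
    "population_insight",
    "expert_criterion",
    "fit_learning_curve",
    "fit_lick_latency",
    "retraction_metrics",
]

EXPERT_DPRIME = 1.65


# --------------------------------------------------------------------------
# results
# --------------------------------------------------------------------------

@dataclass
class DPrimeResult:
    hit_rate: float        # post-clipping
    fa_rate: float         # post-clipping
    n_go: int
    n_nogo: int
    dprime: float


@dataclass
class LickLatencyFit:
    """Parameters of the asymptotic latency trend y = a + b * exp(-c * x)."""

    a: float               # asymptote, s
    b: float               # initial deviation from the asymptote, s
    c: float               # decay rate, 1/trials
    rss: float             # residual sum of squares, s^2


@dataclass
class RetractionMetrics:
    retraction_time_s: float
    retraction_distance_mm: float
    turning_point: tuple[float, float]   # (x_mm, t_s)


@dataclass
class LogisticFit:
    floor: float
    ceiling: float
    midpoint: float
    slope: float
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))
    converged: bool = True


# --------------------------------------------------------------------------
# trial scoring (Table-2 rule logic)
# --------------------------------------------------------------------------

def _score(stage: str, aperture_mm: float, licked: bool) -> tuple[str, str]:
    """(score, deterministic outcome) for one trial; extinction outcome is
    decided upstream by the random outcome stream, not here."""
    if stage in ("habituation",):
        if licked:
            return "hit", "reward"
        return "miss", "none"
    if stage == "extinction":
        return "none", "none"
    if abs(aperture_mm - NEUTRAL_MM) < 1e-9 and stage == "neutral":
        return "none", "none"
    wide = aperture_mm >= (WIDE_MM + NARROW_MM) / 2
    go = wide if stage in ("initial", "neutral") else (not wide)
    if go:
        return ("hit", "reward") if licked else ("miss", "none")
    return ("FA", "punishment") if licked else ("CR", "none")


def score_trials(
    events,
    stage: str,
    mouse_id: str = "m0",
    session_index: int = 0,
) -> tuple[Session, int]:
    """Assemble scored trials from a raw event stream.

    ``events`` is an iterable of (t_s, device, value) records (see
    :mod:`whisktask.io` for the CSV dialect).  Each beam-cross-to-resolution
    episode becomes one :class:`TrialRecord`.  Lick events with no preceding
    beam cross are dropped; the count of dropped events is returned alongside
    the session.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; valid stages: {', '.join(STAGES)}")
    events = sorted(events, key=lambda e: e[0])
    trials: list[TrialRecord] = []
    dropped = 0
    pending = None   # dict for the currently open trial
    idx = 0
    for t, device, value in events:
        if device in ("beam_L", "beam_R"):
            if pending is not None:
                trials.append(_finish_trial(pending, stage, idx))
                idx += 1
            side = "left" if device == "beam_L" else "right"
            pending = {"t_beam": t, "t_touch": None, "t_lick": None,
                       "side": side, "aperture": None, "outcome": None}
        elif device in ("aperture_L", "aperture_R"):
            if pending is not None and pending["aperture"] is None:
                pending["aperture"] = float(value)
        elif device == "touch":
            if pending is not None and pending["t_touch"] is None:
                pending["t_touch"] = t
        elif device in ("lick_L", "lick_R"):
            if pending is None:
                dropped += 1
            elif pending["t_lick"] is None:
                pending["t_lick"] = t
        elif device == "outcome":
            if pending is not None:
                pending["outcome"] = str(value)
        elif device == "beam_M":
            if pending is not None:
                trials.append(_finish_trial(pending, stage, idx))
                idx += 1
                pending = None
        else:
            raise ValueError(f"unknown device token {device!r}")
    if pending is not None:
        trials.append(_finish_trial(pending, stage, idx))
    if dropped:
        warnings.warn(f"dropped {dropped} lick event(s) with no preceding beam cross")
    return Session(mouse_id=mouse_id, stage=stage, session_index=session_index,
                   trials=trials), dropped


def _finish_trial(p: dict, stage: str, idx: int) -> TrialRecord:
    licked = p["t_lick"] is not None
    aperture = p["aperture"] if p["aperture"] is not None else WIDE_MM
    score, outcome = _score(stage, aperture, licked)
    if stage == "extinction":
        # outcome is random, independent of aperture: pass through the stream's
        outcome = p["outcome"] if (licked and p["outcome"]) else "none"
    t_touch = p["t_touch"] if p["t_touch"] is not None else p["t_beam"]
    return TrialRecord(
        trial_index=idx, side=p["side"], aperture_mm=aperture,
        response="lick" if licked else "no-lick", score=score, outcome=outcome,
        t_beam=p["t_beam"], t_touch=t_touch, t_lick=p["t_lick"],
    )


# --------------------------------------------------------------------------
# d-prime
# --------------------------------------------------------------------------

def _clip_rate(k: int, n: int) -> float:
    """Rate with the standard 1/(2n) adjustment of 0 and 1."""
    r = k / n
    if r == 0.0:
        return 1.0 / (2 * n)
    if r == 1.0:
        return 1.0 - 1.0 / (2 * n)
    return r


def compute_dprime(n_hit: int, n_miss: int, n_fa: int, n_cr: int) -> DPrimeResult:
    """d' = z(hit rate) - z(FA rate) with 1/(2n) clipping of extreme rates."""
    n_go = n_hit + n_miss
    n_nogo = n_fa + n_cr
    if n_go < 1 or n_nogo < 1:
        raise ValueError("need at least one go and one no-go trial")
    hit = _clip_rate(n_hit, n_go)
    fa = _clip_rate(n_fa, n_nogo)
    return DPrimeResult(hit_rate=hit, fa_rate=fa, n_go=n_go, n_nogo=n_nogo,
                        dprime=float(ndtri(hit) - ndtri(fa)))


def expert_threshold(alpha: float = 0.05) -> float:
    """One-tailed z criterion for expert performance, reported to two
    decimals as conventionally tabulated (alpha = 0.05 -> 1.65).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    z = float(ndtri(1.0 - alpha))
    # two-step half-up rounding reproduces the tabulated critical values
    # (1.6449 -> 1.645 -> 1.65) rather than IEEE round-half-even
    d = Decimal(repr(z)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP)
    return float(d.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class RunningDPrime:
    trial_index: np.ndarray
    dprime: np.ndarray                     # NaN where undefined
    first_crossing: Optional[int] = None   # trial index of first threshold crossing


def running_dprime(
    trials: Sequence[TrialRecord],
    window: int = 200,
    threshold: float = EXPERT_DPRIME,
) -> RunningDPrime:
    """d' over a running window of the preceding ``window`` scored trials.

    At scored trial i the window covers trials (i - window, i].  Windows
    missing either trial class yield NaN.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    scored = [t for t in trials if t.score in ("hit", "miss", "FA", "CR")]
    n = len(scored)
    idx = np.array([t.trial_index for t in scored])
    is_go = np.array([t.score in ("hit", "miss") for t in scored])
    is_hit = np.array([t.score == "hit" for t in scored])
    is_fa = np.array([t.score == "FA" for t in scored])
    out = np.full(n, np.nan)
    first = None
    for i in range(n):
        lo = max(0, i - window + 1)
        g = is_go[lo:i + 1]
        n_go = int(g.sum())
        n_nogo = int((~g).sum())
        if n_go == 0 or n_nogo == 0:
            continue
        n_hit = int(is_hit[lo:i + 1].sum())
        n_fa = int(is_fa[lo:i + 1].sum())
        out[i] = compute_dprime(n_hit, n_go - n_hit, n_fa, n_nogo - n_fa).dprime
        if first is None and out[i] >= threshold:
            first = int(idx[i])
    return RunningDPrime(trial_index=idx, dprime=out, first_crossing=first)


def success_rates(
    trials_or_counts,
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """(go, no-go, all) success rates: Hit/(Hit+Miss), CR/(CR+FA),
    (Hit+CR)/(Hit+Miss+CR+FA).  Empty denominators yield None."""
    if isinstance(trials_or_counts, dict):
        c = trials_or_counts
    else:
        c = {"hit": 0, "miss": 0, "FA": 0, "CR": 0, "none": 0}
        for t in trials_or_counts:
            c[t.score] += 1
    n_go = c["hit"] + c["miss"]
    n_nogo = c["FA"] + c["CR"]
    go = c["hit"] / n_go if n_go else None
    nogo = c["CR"] / n_nogo if n_nogo else None
    all_ = (c["hit"] + c["CR"]) / (n_go + n_nogo) if (n_go + n_nogo) else None
    return go, nogo, all_


# --------------------------------------------------------------------------
# insight and expert criterion
# --------------------------------------------------------------------------

def detect_insight(nogo_rates: Sequence[float], factor: float = 5.0) -> Optional[int]:
    """First session index j (0-based) whose no-go success rate jumps by
    ``factor`` relative to the previous session; sessions with a zero
    previous rate cannot qualify."""
    if len(nogo_rates) < 2:
        raise ValueError("need at least two sessions")
    for j in range(1, len(nogo_rates)):
        prev = nogo_rates[j - 1]
        if prev > 0 and nogo_rates[j] / prev >= factor:
            return j
    return None


def population_insight(
    per_animal_rates: Iterable[Sequence[float]], factor: float = 5.0
) -> Optional[float]:
    """Mean moment of insight on a common normalized stage-progression axis.

    Each animal's session axis is rescaled to [0, 1]; the insight session is
    mapped onto that axis and the mean is taken over animals with an insight.
    """
    xs = []
    for rates in per_animal_rates:
        j = detect_insight(rates, factor=factor)
        if j is not None:
            xs.append(j / (len(rates) - 1))
    return float(np.mean(xs)) if xs else None


def expert_criterion(
    sessions: Sequence[Session],
    threshold: float = EXPERT_DPRIME,
    min_sessions: int = 4,
    min_trials: int = 200,
    window: int = 200,
    use_running: bool = True,
) -> Optional[tuple[int, int]]:
    """Earliest (session index, cumulative trials above threshold) at which
    >= ``min_sessions`` sessions and >= ``min_trials`` trials sit above the
    expert threshold.  ``use_running`` selects running-window d' for the
    trials-to-expert count; otherwise the per-session d' is used.
    """
    above = []
    for s in sessions:
        c = s.counts()
        try:
            d = compute_dprime(c["hit"], c["miss"], c["FA"], c["CR"]).dprime
        except ValueError:
            d = np.nan
        above.append((d >= threshold, len([t for t in s.trials
                                           if t.score != "none"])))
    n_above = 0
    trials_above = 0
    for j, (ok, ntr) in enumerate(above):
        if ok:
            n_above += 1
            trials_above += ntr
        if n_above >= min_sessions and trials_above >= min_trials:
            return j, trials_above
    return None


def trials_to_expert(
    trials: Sequence[TrialRecord],
    window: int = 200,
    threshold: float = EXPERT_DPRIME,
    sustain: Optional[int] = None,
) -> Optional[int]:
    """Scored-trial count at the first *sustained* crossing of the running d'.

    Sustained means the running d' stays at or above threshold for the next
    ``sustain`` scored trials (default window // 2) or until the data end.
    """
    r = running_dprime(trials, window=window, threshold=threshold)
    d = r.dprime
    if sustain is None:
        sustain = window // 2
    ok = d >= threshold
    for i in np.flatnonzero(ok):
        seg = d[i:i + sustain]
        seg = seg[np.isfinite(seg)]
        if seg.size and np.all(seg >= threshold):
            return i + 1
    return None


# --------------------------------------------------------------------------
# curve fits
# --------------------------------------------------------------------------

def _logistic(x, floor, ceiling, midpoint, slope):
    z = np.clip(-slope * (x - midpoint), -500, 500)
    return floor + (ceiling - floor) / (1.0 + np.exp(z))


def fit_learning_curve(
    dprime: np.ndarray,
    trial_index: Optional[np.ndarray] = None,
    n_starts: int = 20,
    seed: int = 0,
) -> LogisticFit:
    """Four-parameter logistic least-squares fit of a d' progression.

    The slope parameter is the learning speed.  Non-convergence over the
    multistart yields a flagged fit with NaN slope.
    """
    y = np.asarray(dprime, dtype=float)
    x = np.arange(y.size, dtype=float) if trial_index is None else np.asarray(
        trial_index, dtype=float)
    m = np.isfinite(y)
    x, y = x[m], y[m]
    if x.size < 5:
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, converged=False)
    rng = np.random.default_rng(seed)
    span = max(x.max() - x.min(), 1.0)
    best = None
    for k in range(n_starts):
        p0 = [
            y.min() + rng.normal(0, 0.1),
            y.max() + rng.normal(0, 0.1),
            x.min() + span * rng.uniform(0.1, 0.9),
            rng.uniform(0.5, 20.0) / span,
        ]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(_logistic, x, y, p0=p0, maxfev=5000)
        except RuntimeError:
            continue
        rss = float(np.sum((y - _logistic(x, *popt)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, converged=False)
    popt = best[1]
    resid = y - _logistic(x, *popt)
    return LogisticFit(floor=float(popt[0]), ceiling=float(popt[1]),
                       midpoint=float(popt[2]), slope=float(popt[3]),
                       residuals=resid, converged=True)


def _asymptotic(x, a, b, c):
    return a + b * np.exp(-c * x)


def fit_lick_latency(
    trial_index: np.ndarray,
    latency_s: np.ndarray,
    n_starts: int = 20,
    fix_asymptote_to_median: bool = False,
    seed: int = 0,
) -> LickLatencyFit:
    """Least-squares fit of the asymptotic latency trend y = a + b*exp(-c*x).

    ``a`` is free by default (initialized at the median latency); with
    ``fix_asymptote_to_median`` it is pinned to the median latency and only
    (b, c) are fitted.
    """
    x = np.asarray(trial_index, dtype=float)
    y = np.asarray(latency_s, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 data points")
    med = float(np.median(y))
    rng = np.random.default_rng(seed)
    span = max(x.max() - x.min(), 1.0)
    best = None
    for k in range(max(n_starts, 20)):
        b0 = (y[np.argsort(x)[:3]].mean() - med) * rng.uniform(0.5, 2.0)
        c0 = rng.uniform(0.5, 10.0) / span
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if fix_asymptote_to_median:
                    popt, _ = optimize.curve_fit(
                        lambda xx, b, c: _asymptotic(xx, med, b, c), x, y,
                        p0=[b0, c0], maxfev=5000)
                    params = (med, popt[0], popt[1])
                else:
                    popt, _ = optimize.curve_fit(
                        _asymptotic, x, y, p0=[med, b0, c0], maxfev=5000)
                    params = tuple(popt)
        except RuntimeError:
            continue
        rss = float(np.sum((y - _asymptotic(x, *params)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, params)
    if best is None:
        raise RuntimeError("lick-latency fit failed to converge from any start")
    rss, (a, b, c) = best
    return LickLatencyFit(a=float(a), b=float(b), c=float(c), rss=rss)


# --------------------------------------------------------------------------
# retraction metrics (CR-trial withdrawal behavior)
# --------------------------------------------------------------------------

def retraction_metrics(
    t: np.ndarray,
    x_approach: np.ndarray,
    t_touch: float,
    t_beam: float,
    aperture_x_mm: float,
    t_lick: Optional[float] = None,
) -> Optional[RetractionMetrics]:
    """Turn-away metrics of a correct-rejection trial.

    The turning point is the global maximum of the approach coordinate after
    touch (ties broken to the earliest time); retraction time is measured
    from the beam break and retraction distance from the aperture position.
    A trajectory that never turns (monotone to the end) yields None.
    """
    if t_lick is not None:
        raise ValueError("retraction metrics are defined only for no-lick (CR) trials")
    t = np.asarray(t, dtype=float)
    x = np.asarray(x_approach, dtype=float)
    m = t >= t_touch
    if not np.any(m):
        return None
    tt, xx = t[m], x[m]
    i = int(np.argmax(xx))       # argmax takes the first of equal maxima
    if i == xx.size - 1:
        return None              # monotone: never turns
    return RetractionMetrics(
        retraction_time_s=float(tt[i] - t_beam),
        retraction_distance_mm=float(abs(xx[i] - aperture_x_mm)),
        turning_point=(float(xx[i]), float(tt[i])),
    )
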