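"""Behavioral statistics: scoring rules, d', learning curves, lick fits."""

import numpy as np
import pytest
from scipy.special import ndtri

import whisktask.behavior as bh
import whisktask.synthetic as syn


# --------------------------------------------------------------------------
# trial scoring
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "stage,aperture,licked,expected_score",
    [
        ("initial", 45.0, True, "hit"),
        ("initial", 45.0, False, "miss"),
        ("initial", 25.0, True, "FA"),
        ("initial", 25.0, False, "CR"),
        ("reversed", 45.0, True, "FA"),
        ("reversed", 25.0, True, "hit"),
        ("neutral", 35.0, True, "none"),
        ("neutral", 45.0, True, "hit"),
        ("extinction", 45.0, True, "none"),
    ],
)
def test_stage_rule_logic(stage, aperture, licked, expected_score):
    """The stage rule table maps (aperture, response) to the right score."""
    score, _ = bh._score(stage, aperture, licked)
    assert score == expected_score


def test_score_trials_from_event_stream():
    events = [
        (1.0, "beam_L", ""), (1.0, "aperture_L", "45"), (1.5, "touch", ""),
        (1.9, "lick_L", ""), (1.9, "outcome", "reward"),
        (10.0, "beam_R", ""), (10.0, "aperture_R", "25"), (10.5, "touch", ""),
        (12.0, "beam_M", ""),
    ]
    session, dropped = bh.score_trials(events, "initial")
    assert dropped == 0
    assert [t.score for t in session.trials] == ["hit", "CR"]
    assert session.trials[0].t_lick == pytest.approx(1.9)


def test_orphan_lick_dropped_with_warning():
    events = [(0.5, "lick_L", ""), (1.0, "beam_L", ""), (1.0, "aperture_L", "45"),
              (2.0, "beam_M", "")]
    with pytest.warns(UserWarning, match="dropped 1"):
        session, dropped = bh.score_trials(events, "initial")
    assert dropped == 1
    assert [t.score for t in session.trials] == ["miss"]


def test_score_trials_unknown_stage_names_valid_stages():
    with pytest.raises(ValueError, match="habituation.*initial.*neutral"):
        bh.score_trials([], "warmup")


def test_scoring_conservation(base_session):
    """Score counts partition the trial list; hit+miss = go trials."""
    c = base_session.counts()
    assert sum(c.values()) == len(base_session)
    n_go = sum(t.aperture_mm == 45.0 for t in base_session.trials)
    assert c["hit"] + c["miss"] == n_go
    assert c["FA"] + c["CR"] == len(base_session) - n_go


# --------------------------------------------------------------------------
# d-prime
# --------------------------------------------------------------------------

def test_dprime_equal_rates_is_zero():
    assert bh.compute_dprime(5, 5, 5, 5).dprime == pytest.approx(0.0)


def test_dprime_perfect_performance_clipped():
    r = bh.compute_dprime(10, 0, 0, 10)
    assert r.hit_rate == pytest.approx(0.95)
    assert r.fa_rate == pytest.approx(0.05)
    assert r.dprime == pytest.approx(2 * ndtri(0.95), abs=1e-9)


def test_dprime_unit_value_from_symmetric_rates():
    # hit 0.69146 and fa 0.30854 are z = +/-0.5
    r = bh.compute_dprime(69146, 100000 - 69146, 30854, 100000 - 30854)
    assert r.dprime == pytest.approx(1.0, abs=1e-3)


def test_dprime_requires_both_classes():
    with pytest.raises(ValueError):
        bh.compute_dprime(0, 0, 5, 5)


def test_dprime_oracle_antisymmetry_and_clipping_bound():
    """1000 random count tuples agree with direct inverse-normal evaluation
    to 1e-9; antisymmetry and the clipping bound hold."""
    rng = np.random.default_rng(0)
    for _ in range(1000):
        n_go, n_nogo = rng.integers(1, 400, 2)
        n_hit = int(rng.integers(0, n_go + 1))
        n_fa = int(rng.integers(0, n_nogo + 1))
        res = bh.compute_dprime(n_hit, n_go - n_hit, n_fa, n_nogo - n_fa)
        hit = min(max(n_hit / n_go, 1 / (2 * n_go)), 1 - 1 / (2 * n_go))
        fa = min(max(n_fa / n_nogo, 1 / (2 * n_nogo)), 1 - 1 / (2 * n_nogo))
        assert res.dprime == pytest.approx(ndtri(hit) - ndtri(fa), abs=1e-9)
        anti = bh.compute_dprime(n_fa, n_nogo - n_fa, n_hit, n_go - n_hit)
        assert anti.dprime == pytest.approx(-res.dprime, abs=1e-9)
        bound = ndtri(1 - 1 / (2 * n_go)) + ndtri(1 - 1 / (2 * n_nogo))
        assert abs(res.dprime) <= bound + 1e-12


def test_dprime_monotonicity():
    base = bh.compute_dprime(10, 10, 5, 15).dprime
    assert bh.compute_dprime(11, 9, 5, 15).dprime > base
    assert bh.compute_dprime(10, 10, 6, 14).dprime < base


@pytest.mark.parametrize("alpha,expected", [(0.05, 1.65), (0.5, 0.0), (0.025, 1.96)])
def test_expert_threshold_tabulated_values(alpha, expected):
    assert bh.expert_threshold(alpha) == pytest.approx(expected)


def test_expert_threshold_rejects_bad_alpha():
    for bad in (0.0, 1.0, -0.1, 2.0):
        with pytest.raises(ValueError):
            bh.expert_threshold(bad)


# --------------------------------------------------------------------------
# running d' and success rates
# --------------------------------------------------------------------------

def test_running_dprime_chance_learner_hovers_near_zero():
    learner = syn.LearnerParams(p_lick_go_initial=0.5, p_lick_go_final=0.5,
                                p_lick_nogo_initial=0.5, p_lick_nogo_final=0.5)
    s = syn.generate_session_events("initial", learner, 600, seed=3)
    r = bh.running_dprime(s.trials, window=200)
    d = r.dprime[np.isfinite(r.dprime)][200:]
    assert np.mean(np.abs(d)) < 0.5


def test_running_dprime_window_larger_than_session(base_session):
    r = bh.running_dprime(base_session.trials, window=10_000)
    c = base_session.counts()
    full = bh.compute_dprime(c["hit"], c["miss"], c["FA"], c["CR"]).dprime
    assert r.dprime[-1] == pytest.approx(full)


def test_running_dprime_perfect_learner_plateaus_at_clipping_bound():
    learner = syn.LearnerParams(p_lick_go_initial=1.0, p_lick_go_final=1.0,
                                p_lick_nogo_initial=0.0, p_lick_nogo_final=0.0)
    s = syn.generate_session_events("initial", learner, 400, seed=4)
    r = bh.running_dprime(s.trials, window=200)
    scored = [t for t in s.trials if t.score != "none"]
    n_go = sum(t.score in ("hit", "miss") for t in scored[-200:])
    n_nogo = 200 - n_go
    expected = ndtri(1 - 1 / (2 * n_go)) + ndtri(1 - 1 / (2 * n_nogo))
    assert r.dprime[-1] == pytest.approx(expected, abs=1e-9)
    assert r.first_crossing is not None


@pytest.mark.parametrize(
    "counts,expected",
    [({"hit": 5, "miss": 5, "FA": 5, "CR": 5, "none": 0}, (0.5, 0.5, 0.5)),
     ({"hit": 10, "miss": 0, "FA": 0, "CR": 10, "none": 0}, (1.0, 1.0, 1.0)),
     ({"hit": 8, "miss": 2, "FA": 3, "CR": 7, "none": 0}, (0.8, 0.7, 0.75))],
)
def test_success_rates(counts, expected):
    assert bh.success_rates(counts) == pytest.approx(expected)


def test_success_rates_empty_denominator_is_none():
    go, nogo, allr = bh.success_rates({"hit": 0, "miss": 0, "FA": 1, "CR": 1,
                                       "none": 0})
    assert go is None and nogo == 0.5 and allr == 0.5


# --------------------------------------------------------------------------
# insight and expert criterion
# --------------------------------------------------------------------------

def test_detect_insight_five_fold_jump():
    assert bh.detect_insight([0.1, 0.5, 0.6]) == 1


def test_detect_insight_absent():
    assert bh.detect_insight([0.4, 0.6, 0.9]) is None


def test_detect_insight_zero_denominator_excluded():
    assert bh.detect_insight([0.0, 0.3]) is None


def test_detect_insight_needs_two_sessions():
    with pytest.raises(ValueError):
        bh.detect_insight([0.5])


def test_population_insight_normalized_axis():
    rates = [[0.1, 0.5, 0.6], [0.1, 0.1, 0.6]]   # insights at 1/2 and 2/2
    assert bh.population_insight(rates) == pytest.approx(0.75)


def _expert_sessions(n_above):
    learner = syn.LearnerParams(p_lick_go_initial=0.95, p_lick_go_final=0.95,
                                p_lick_nogo_initial=0.05, p_lick_nogo_final=0.05)
    return [syn.generate_session_events("initial", learner, 60, seed=10 + i,
                                        session_index=i)
            for i in range(n_above)]


def test_expert_criterion_needs_four_sessions():
    assert bh.expert_criterion(_expert_sessions(3)) is None


def test_expert_criterion_reached():
    res = bh.expert_criterion(_expert_sessions(5))
    assert res is not None
    j, trials_above = res
    assert j == 3 and trials_above >= 200


def test_expert_criterion_chance_learner_none():
    learner = syn.LearnerParams(p_lick_go_initial=0.5, p_lick_go_final=0.5,
                                p_lick_nogo_initial=0.5, p_lick_nogo_final=0.5)
    sessions = [syn.generate_session_events("initial", learner, 60, seed=20 + i)
                for i in range(6)]
    assert bh.expert_criterion(sessions) is None


def test_trials_to_expert_tracks_learner_midpoint():
    """First sustained 1.65-crossing lands between the configured midpoint
    and 120% of midpoint plus the logistic rise."""
    mid, rate = 400, 0.02
    learner = syn.LearnerParams(learning_midpoint_trials=mid, learning_rate=rate,
                                p_lick_go_initial=0.6, p_lick_go_final=0.95,
                                p_lick_nogo_initial=0.6, p_lick_nogo_final=0.05)
    s = syn.generate_session_events("initial", learner, 1200, seed=6)
    n = bh.trials_to_expert(s.trials)
    assert n is not None
    rise = np.log(81) / rate
    assert 0.8 * mid <= n <= 1.2 * (mid + rise)


# --------------------------------------------------------------------------
# curve fits
# --------------------------------------------------------------------------

def test_learning_curve_noiseless_recovery():
    x = np.arange(0, 1000, 10, dtype=float)
    true = (0.1, 3.0, 400.0, 0.02)
    y = bh._logistic(x, *true)
    fit = bh.fit_learning_curve(y, trial_index=x)
    assert fit.converged
    for got, want in zip((fit.floor, fit.ceiling, fit.midpoint, fit.slope), true):
        assert got == pytest.approx(want, rel=1e-3)


def test_learning_curve_flat_series_slope_negligible():
    y = np.full(100, 1.2)
    fit = bh.fit_learning_curve(y)
    assert abs(fit.slope * (fit.ceiling - fit.floor)) < 1e-3


def test_learning_curve_simulated_learner_midpoint():
    mid = 400
    learner = syn.LearnerParams(learning_midpoint_trials=mid, learning_rate=0.02,
                                p_lick_nogo_initial=0.8)
    s = syn.generate_session_events("initial", learner, 1000, seed=7)
    r = bh.running_dprime(s.trials, window=200)
    fit = bh.fit_learning_curve(r.dprime, trial_index=r.trial_index.astype(float))
    # the running window trails the learner by up to half a window
    assert fit.midpoint == pytest.approx(mid + 100, rel=0.30)


def test_lick_latency_noiseless_recovery():
    x = np.arange(300, dtype=float)
    y = 0.2 + 0.6 * np.exp(-0.01 * x)
    fit = bh.fit_lick_latency(x, y)
    assert fit.a == pytest.approx(0.2, rel=1e-3)
    assert fit.b == pytest.approx(0.6, rel=1e-3)
    assert fit.c == pytest.approx(0.01, rel=1e-3)


def test_lick_latency_constant_input_has_no_decay_term():
    x = np.arange(50, dtype=float)
    fit = bh.fit_lick_latency(x, np.full(50, 0.3))
    assert abs(fit.b * np.exp(-fit.c * x[0])) < 1e-6 or abs(fit.b) < 1e-6


def test_lick_latency_noisy_recovery_of_asymptote():
    rng = np.random.default_rng(8)
    x = np.arange(300, dtype=float)
    y = 0.2 + 0.6 * np.exp(-0.01 * x) + rng.normal(0, 0.05, 300)
    fit = bh.fit_lick_latency(x, y)
    assert fit.a == pytest.approx(0.2, abs=0.03)


def test_lick_latency_needs_five_points():
    with pytest.raises(ValueError):
        bh.fit_lick_latency(np.arange(4.0), np.ones(4))


# --------------------------------------------------------------------------
# retraction metrics
# --------------------------------------------------------------------------

def test_retraction_triangular_trajectory():
    t = np.linspace(0.0, 2.0, 201)
    x = np.where(t <= 1.0, 100 * t, 100 * (2.0 - t))   # peak 100 mm at t=1
    m = bh.retraction_metrics(t, x, t_touch=0.3, t_beam=0.2, aperture_x_mm=50.0)
    assert m.retraction_time_s == pytest.approx(0.8, abs=0.02)
    assert m.retraction_distance_mm == pytest.approx(50.0, abs=1.0)


def test_retraction_tie_takes_earliest():
    t = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    x = np.array([0.0, 5.0, 5.0, 5.0, 1.0])
    m = bh.retraction_metrics(t, x, t_touch=0.0, t_beam=0.0, aperture_x_mm=0.0)
    assert m.turning_point[1] == pytest.approx(1.0)


def test_retraction_monotone_returns_none():
    t = np.linspace(0, 1, 50)
    assert bh.retraction_metrics(t, t * 100, 0.0, 0.0, 0.0) is None


def test_retraction_rejects_lick_trials():
    t = np.linspace(0, 1, 50)
    with pytest.raises(ValueError):
        bh.retraction_metrics(t, np.sin(t), 0.0, 0.0, 0.0, t_lick=0.5)
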