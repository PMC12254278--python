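"""Per-unit statistics: QC, cell classes, latency, touch/state/angle/phase/
spatial tuning, and shuffle-null machinery."""

import numpy as np
import pytest

import whisktask.synthetic as syn
import whisktask.tuning as tun
from whisktask.core import AngleTrace, Segment, SpikeTrain, StateSegments
from whisktask.stats import kuiper_test

from conftest import make_unit


def _train(times, dur=100.0, region="BC", iso=20.0, t2p=400.0):
    return SpikeTrain("u", region, np.asarray(times, float), dur,
                      trough_to_peak_us=t2p, isolation_distance=iso)


# --------------------------------------------------------------------------
# QC and RS/FS
# --------------------------------------------------------------------------

def test_qc_regular_train_retained():
    u = _train(np.arange(0, 100, 0.1))
    assert tun.qc_filter_units([u]) == [u]


def test_qc_doublet_train_excluded():
    base = np.arange(0, 100, 0.1)
    doublets = base[:: 20] + 0.0005       # 5% of ISIs below 1.5 ms
    u = _train(np.sort(np.concatenate([base, doublets])))
    assert tun.qc_filter_units([u]) == []


def test_qc_isolation_distance_strictly_greater():
    u = _train(np.arange(0, 100, 0.1), iso=15.0)
    assert tun.qc_filter_units([u]) == []


def test_qc_missing_isolation_warns_and_drops():
    u = _train(np.arange(0, 100, 0.1), iso=None)
    with pytest.warns(UserWarning, match="missing isolation"):
        assert tun.qc_filter_units([u]) == []


@pytest.mark.parametrize(
    "region,t2p,label,kept",
    [("BC", 400.0, "RS", True), ("VPM", 280.0, "FS", False),
     ("ZIv", 300.0, "FS", True), ("POm", 320.0, "RS", True),
     ("BC", 300.0, "FS", False)],
)
def test_rs_fs_classification(region, t2p, label, kept):
    cls = tun.classify_rs_fs(_train([1.0], region=region, t2p=t2p))
    assert cls.label == label and cls.kept == kept


# --------------------------------------------------------------------------
# onset latency
# --------------------------------------------------------------------------

def _step_unit(latency_s=0.008, base_hz=5.0, burst_hz=80.0, n_trials=50,
               seed=0):
    rng = np.random.default_rng(seed)
    dur = 4.0 * n_trials + 4.0
    touches = np.arange(2.0, dur - 2.0, 4.0)[:n_trials]
    spikes = [np.sort(rng.uniform(0, dur, rng.poisson(base_hz * dur)))]
    for tt in touches:
        n = rng.poisson((burst_hz - base_hz) * 0.05)
        spikes.append(tt + latency_s + rng.uniform(0, 0.05, n))
    return _train(np.sort(np.concatenate(spikes)), dur=dur), touches


def test_latency_detects_injected_step():
    u, touches = _step_unit(seed=1)
    lat = tun.onset_latency(u, touches)
    assert lat.latency_ms is not None
    assert abs(lat.latency_ms - 8) <= 2


def test_latency_none_without_rate_change():
    """A homogeneous unit yields no onset under the corrected scan (the
    uncorrected 200-bin rule admits ~5% of bins by construction)."""
    rng = np.random.default_rng(2)
    u = _train(np.sort(rng.uniform(0, 200, 1000)), dur=200.0)
    lat = tun.onset_latency(u, np.arange(2, 198, 4.0), bonferroni=True)
    assert lat.latency_ms is None


def test_latency_ignores_inhibition():
    """Purely suppressed responses never trigger the upper-tail test."""
    rng = np.random.default_rng(3)
    dur = 200.0
    touches = np.arange(2, 198, 4.0)
    s = np.sort(rng.uniform(0, dur, 2000))
    for tt in touches:          # silence 200 ms after each touch
        s = s[(s < tt) | (s > tt + 0.2)]
    lat = tun.onset_latency(_train(s, dur=dur), touches)
    assert lat.latency_ms is None


def test_latency_requires_ten_touches():
    with pytest.raises(ValueError):
        tun.onset_latency(_train([1.0]), np.arange(5.0))


def test_latency_baseline_floored_when_silent():
    u, touches = _step_unit(base_hz=0.001, seed=4)
    lat = tun.onset_latency(u, touches)
    assert lat.baseline_floored
    assert lat.baseline_rate == pytest.approx(0.1)


# --------------------------------------------------------------------------
# touch modulation
# --------------------------------------------------------------------------

def _touch_mod_unit(base_session, bundle, gw, gn, seed):
    spec = syn.TuningSpec(baseline_rate=10.0, touch_gain_wide=gw,
                          touch_gain_narrow=gn)
    return make_unit(base_session, bundle, spec, seed)


def _touches_by_aperture(session):
    wide = [t.t_touch for t in session.trials if t.aperture_mm >= 35.0]
    narrow = [t.t_touch for t in session.trials if t.aperture_mm < 35.0]
    return wide, narrow


@pytest.mark.parametrize("gains,category", [((3.0, 1.0), "wide-only"),
                                            ((3.0, 3.0), "both"),
                                            ((1.0, 1.0), "none")])
def test_touch_modulation_categories(base_session, bundle, gains, category):
    u = _touch_mod_unit(base_session, bundle, *gains, seed=30)
    wide, narrow = _touches_by_aperture(base_session)
    res = tun.touch_modulation_ephys(u, wide, narrow)
    assert res.category == category


def test_touch_modulation_calcium_detects_responder(base_session, bundle):
    u = _touch_mod_unit(base_session, bundle, 5.0, 5.0, seed=31)
    ca = syn.generate_calcium([u], noise_sd=0.02, seed=31)[0]
    p, sig = tun.touch_modulation_calcium(ca, base_session.touch_times)
    assert sig


def test_touch_modulation_calcium_noise_not_significant(base_session):
    rng = np.random.default_rng(5)
    from whisktask.core import CalciumTrace
    ca = CalciumTrace(fps=30.0, values=rng.normal(0, 0.05,
                                                  int(30 * base_session.duration)))
    p, sig = tun.touch_modulation_calcium(ca, base_session.touch_times)
    assert not sig


def test_modulated_proportion_one_decimal():
    assert tun.modulated_proportion(261, 413) == 63.2


# --------------------------------------------------------------------------
# shuffle null
# --------------------------------------------------------------------------

def test_circular_shift_preserves_count_and_isis(untuned_unit):
    sh = tun.circular_shift_null(untuned_unit, n_shuffles=20, seed=1)
    assert sh.shape == (20, untuned_unit.n_spikes)
    from collections import Counter

    orig = Counter(np.round(np.diff(untuned_unit.spike_times), 9))
    for row in sh:
        shuf = Counter(np.round(np.diff(row), 9))
        # the ISI multiset is preserved up to the single wrap interval:
        # one original ISI is replaced by (at most) two new ones
        diff = (orig - shuf) + (shuf - orig)
        assert sum(diff.values()) <= 3


def test_circular_shift_within_duration(untuned_unit):
    sh = tun.circular_shift_null(untuned_unit, n_shuffles=10, seed=2)
    assert sh.min() >= 0 and sh.max() <= untuned_unit.recording_duration


# --------------------------------------------------------------------------
# state modulation
# --------------------------------------------------------------------------

def test_state_modulation_locomotion_gain_enhanced(base_session, bundle):
    import whisktask.kinematics as kin

    segs = kin.segment_locomotion(bundle.position)
    spec = syn.TuningSpec(baseline_rate=10.0, locomotion_gain=2.0)
    u = make_unit(base_session, bundle, spec, seed=33)
    res = tun.state_rate_modulation(u, segs, seed=33)
    assert res.label == "enhanced"
    assert res.rate_a > res.rate_b


def test_state_modulation_empty_family_errors(untuned_unit):
    segs = StateSegments([Segment(0.0, 1.0, "locomotion")])
    with pytest.raises(ValueError, match="rest"):
        tun.state_rate_modulation(untuned_unit, segs)


# --------------------------------------------------------------------------
# angle tuning
# --------------------------------------------------------------------------

def test_angle_modulation_depth_formula():
    """Handcrafted occupancy and spike counts reproduce
    depth = (r_max - r_min)/r_mean exactly."""
    fps = 240.0
    # 1 s at 12.5 deg, 1 s at 22.5 deg, 1 s at 32.5 deg
    values = np.concatenate([np.full(240, 12.5), np.full(240, 22.5),
                             np.full(240, 32.5)])
    trace = AngleTrace(fps=fps, values=values)
    spikes = np.concatenate([np.linspace(0.01, 0.99, 15),
                             np.linspace(1.01, 1.99, 5),
                             np.linspace(2.01, 2.99, 10)])
    u = _train(spikes, dur=3.0)
    res = tun.angle_tuning(u, trace, n_shuffles=10, seed=0)
    assert res.r_max == pytest.approx(15.0)
    assert res.r_min == pytest.approx(5.0)
    assert res.r_mean == pytest.approx(10.0)
    assert res.modulation_depth == pytest.approx(1.0)


def test_angle_tuning_flat_unit_not_significant(base_session, bundle,
                                                untuned_unit):
    res = tun.angle_tuning(untuned_unit, bundle.whisker,
                           touch_times=base_session.touch_times, seed=7)
    assert not res.significant


def test_angle_tuning_von_mises_peak_recovered(long_session, long_bundle):
    spec = syn.TuningSpec(baseline_rate=10.0, angle_kappa=4.0,
                          angle_pref_deg=90.0)
    u = make_unit(long_session, long_bundle, spec, seed=34)
    res = tun.angle_tuning(u, long_bundle.whisker,
                           touch_times=long_session.touch_times, seed=34)
    assert res.significant
    centers = res.bin_edges[:-1] + 2.5
    peak = centers[np.nanargmax(res.rates)]
    assert abs(peak - 90.0) <= 10.0


def test_angle_tuning_zero_rate_unit_rejected(bundle):
    u = _train([], dur=bundle.whisker.duration)
    with pytest.raises(ValueError, match="mean rate"):
        tun.angle_tuning(u, bundle.whisker, seed=0)


# --------------------------------------------------------------------------
# phase tuning
# --------------------------------------------------------------------------

def test_phase_fit_noiseless_profile_exact():
    centers = (np.arange(32) + 0.5) * 2 * np.pi / 32
    rates = 10.0 + 4.0 * np.cos(centers - np.pi)
    dummy = _train([1.0], dur=10.0)
    res = tun.phase_tuning(dummy, None, bin_rates=rates)
    assert res.mean_rate == pytest.approx(10.0, abs=1e-12)
    assert res.amp == pytest.approx(4.0, abs=1e-12)
    assert res.preferred_phase == pytest.approx(np.pi, abs=1e-12)
    assert res.snr == pytest.approx(8.0 * np.sqrt(0.111 / 10.0), abs=1e-12)


def test_phase_fit_matches_fourier_coefficient_oracle():
    """The regression solution equals the first circular Fourier
    coefficient of the binned rates."""
    rng = np.random.default_rng(6)
    centers = (np.arange(32) + 0.5) * 2 * np.pi / 32
    rates = np.abs(rng.normal(10, 3, 32))
    res = tun.phase_tuning(_train([1.0], dur=10.0), None, bin_rates=rates)
    c = 2.0 / 32 * np.sum(rates * np.cos(centers))
    s = 2.0 / 32 * np.sum(rates * np.sin(centers))
    assert res.amp == pytest.approx(np.hypot(c, s), abs=1e-9)
    assert np.angle(np.exp(1j * (res.preferred_phase - np.arctan2(s, c)))) \
        == pytest.approx(0.0, abs=1e-9)


def test_phase_recovery_from_poisson_spikes(long_session, long_bundle):
    spec = syn.TuningSpec(baseline_rate=10.0, phase_amp=4.0,
                          phase_pref=np.pi)
    u = make_unit(long_session, long_bundle, spec, seed=35)
    res = tun.phase_tuning(u, long_bundle.phase)
    err = np.angle(np.exp(1j * (res.preferred_phase - np.pi)))
    assert abs(np.rad2deg(err)) <= 15.0
    assert res.kuiper_p < 0.05


def test_phase_tuning_requires_occupied_bins():
    from whisktask.core import PhaseTrace
    ph = PhaseTrace(fps=240.0, values=np.full(240, 1.0))
    with pytest.raises(ValueError, match="occupied"):
        tun.phase_tuning(_train([0.5], dur=1.0), ph)


def test_kuiper_uniform_phases_not_significant():
    rng = np.random.default_rng(7)
    v, p = kuiper_test(rng.uniform(0, 2 * np.pi, 2000))
    assert p > 0.05


def test_kuiper_concentrated_phases_significant():
    rng = np.random.default_rng(8)
    v, p = kuiper_test(np.mod(rng.normal(np.pi, 0.5, 500), 2 * np.pi))
    assert p < 1e-6


# --------------------------------------------------------------------------
# population phase vector
# --------------------------------------------------------------------------

def _phase_result(pref, amp=1.0, p=0.01):
    return tun.PhaseTuningResult(mean_rate=10.0, amp=amp, preferred_phase=pref,
                                 snr=1.0, kuiper_v=0.5, kuiper_p=p)


def test_population_vector_mean_of_two_units():
    mean, length = tun.population_phase_vector(
        [_phase_result(np.pi - 0.1), _phase_result(np.pi + 0.1)])
    assert mean == pytest.approx(180.0, abs=0.5)


def test_population_vector_uniform_angles_short_resultant():
    results = [_phase_result(a) for a in np.linspace(0, 2 * np.pi, 36,
                                                     endpoint=False)]
    _, length = tun.population_phase_vector(results)
    assert length < 0.05


def test_population_vector_recovers_injected_center():
    rng = np.random.default_rng(9)
    prefs = np.mod(np.deg2rad(170.0) + rng.normal(0, 0.4, 40), 2 * np.pi)
    mean, _ = tun.population_phase_vector([_phase_result(a) for a in prefs])
    err = np.angle(np.exp(1j * np.deg2rad(mean - 170.0)))
    assert abs(np.rad2deg(err)) <= 10.0


# --------------------------------------------------------------------------
# spatial tuning
# --------------------------------------------------------------------------

def test_spatial_place_field_recovered(long_session, long_bundle):
    spec = syn.TuningSpec(baseline_rate=10.0, place_amp=10.0,
                          place_center_mm=-200.0, place_sigma_mm=40.0)
    u = make_unit(long_session, long_bundle, spec, seed=36)
    res = tun.spatial_tuning(u, long_bundle.position, seed=36)
    assert res.spatially_tuned
    assert abs(res.mu_mm - (-200.0)) <= 20.0


def test_spatial_speed_only_unit_rejected(long_session, long_bundle):
    spec = syn.TuningSpec(baseline_rate=10.0, locomotion_gain=2.0)
    u = make_unit(long_session, long_bundle, spec, seed=37)
    res = tun.spatial_tuning(u, long_bundle.position, seed=37)
    assert not res.spatially_tuned


def test_spatial_homogeneous_unit_untuned(long_session, long_bundle):
    u = make_unit(long_session, long_bundle,
                  syn.TuningSpec(baseline_rate=10.0), seed=38)
    res = tun.spatial_tuning(u, long_bundle.position, seed=38)
    assert not res.spatially_tuned
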