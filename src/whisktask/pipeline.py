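"""Session orchestration: synthetic generation -> behavior -> kinematics ->
tuning -> decoding, with a JSON manifest linking every result file.

Each stage logs its parameters and seed into the manifest; a stage failure
is recorded and the manifest marks the run as partially complete instead of
aborting the whole pipeline.
"""

from __future__ import annotations

import hashlib
import json
import time
import traceback
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, decoding, kinematics, synthetic, tuning
from .core import NEUTRAL_MM
from .io import RunConfig, session_to_events, write_event_csv, write_timeseries_csv

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic pipeline and return the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": json.loads(json.dumps(config.__dict__)),
                      "seed": config.seed, "stages": {}, "complete": True}
    state: dict = {}

    stages = [
        ("simulate", _stage_simulate),
        ("behavior", _stage_behavior),
        ("kinematics", _stage_kinematics),
        ("tuning", _stage_tuning),
        ("decoding", _stage_decoding),
    ]
    for name, fn in stages:
        t0 = time.time()
        entry = {"seed": config.seed, "status": "ok", "files": []}
        try:
            entry["files"] = fn(config, out, state)
        except Exception as exc:           # record partial completion
            entry["status"] = "failed"
            entry["error"] = f"{type(exc).__name__}: {exc}"
            entry["traceback"] = traceback.format_exc(limit=3)
            manifest["complete"] = False
        entry["elapsed_s"] = round(time.time() - t0, 3)
        entry["file_hashes"] = {f: _sha256(out / f) for f in entry["files"]}
        manifest["stages"][name] = entry
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, out: Path, state: dict) -> list[str]:
    rng = np.random.default_rng(config.seed)
    learner = synthetic.LearnerParams(**config.learner)
    session = synthetic.generate_session_events(
        config.stage, learner, config.n_trials, seed=config.seed)
    whisker = synthetic.generate_whisker_trace(
        session, config.whisk_freq_hz, config.whisk_amp_deg, seed=config.seed)
    position = synthetic.generate_position_trace(
        session, config.run_speed_mms, seed=config.seed)
    bundle = synthetic.KinematicBundle(whisker=whisker, position=position)
    specs = []
    for u in range(config.n_units):
        specs.append(synthetic.TuningSpec(
            baseline_rate=float(rng.uniform(5, 15)),
            touch_gain_wide=float(rng.choice([1.0, 3.0])),
            phase_amp=float(rng.choice([0.0, 3.0])),
            place_amp=float(rng.choice([0.0, 10.0])),
            place_center_mm=float(rng.uniform(-300, 300)),
            locomotion_gain=float(rng.choice([1.0, 2.0]))))
    # finer thinning grid: stacked gains can exceed 100 Hz instantaneously
    spikes = synthetic.generate_spike_trains(
        session, bundle, specs, seed=config.seed, dt_s=0.0005)
    ca_specs = [synthetic.TuningSpec(
        baseline_rate=5.0,
        touch_gain_wide=float(rng.choice([1.0, 4.0])),
        touch_gain_narrow=float(rng.choice([1.0, 4.0])))
        for _ in range(config.n_calcium_units)]
    ca_spikes = synthetic.generate_spike_trains(
        session, bundle, ca_specs, seed=config.seed + 1, dt_s=0.0005)
    calcium = synthetic.generate_calcium(
        ca_spikes, noise_sd=config.calcium_noise_sd, seed=config.seed)
    gt = synthetic.SyntheticGroundTruth(
        learner=learner, units=specs, whisk_freq_hz=config.whisk_freq_hz,
        seed=config.seed)

    write_event_csv(out / "events.csv", session_to_events(session))
    write_timeseries_csv(out / "whisker_angle.csv", whisker)
    write_timeseries_csv(out / "position.csv", position)
    pd.DataFrame(
        [(st.unit_id, st.region, st.trough_to_peak_us, st.isolation_distance, t)
         for st in spikes for t in st.spike_times],
        columns=["unit_id", "region", "trough_to_peak_us",
                 "isolation_distance", "t_s"],
    ).to_csv(out / "spikes.csv", index=False)
    write_timeseries_csv(out / "calcium.csv", calcium[0],
                         value_cols={tr.unit_id: tr.values for tr in calcium})
    (out / "ground_truth.json").write_text(gt.to_json())
    state.update(session=session, bundle=bundle, spikes=spikes, specs=specs,
                 ca_specs=ca_specs, calcium=calcium, gt=gt)
    return ["events.csv", "whisker_angle.csv", "position.csv", "spikes.csv",
            "calcium.csv", "ground_truth.json"]


def _stage_behavior(config: RunConfig, out: Path, state: dict) -> list[str]:
    session = state["session"]
    c = session.counts()
    go, nogo, allr = behavior.success_rates(c)
    try:
        d = behavior.compute_dprime(c["hit"], c["miss"], c["FA"], c["CR"]).dprime
    except ValueError:
        d = np.nan
    pd.DataFrame([{
        "mouse_id": session.mouse_id, "stage": session.stage,
        "session_index": session.session_index, **c,
        "go_rate": go, "nogo_rate": nogo, "all_rate": allr, "dprime": d,
    }]).to_csv(out / "session_metrics.csv", index=False)
    r = behavior.running_dprime(session.trials)
    pd.DataFrame({"trial_index": r.trial_index, "dprime": r.dprime}
                 ).to_csv(out / "running_dprime.csv", index=False)
    return ["session_metrics.csv", "running_dprime.csv"]


def _stage_kinematics(config: RunConfig, out: Path, state: dict) -> list[str]:
    session, bundle = state["session"], state["bundle"]
    filt = kinematics.bandpass_whisker(bundle.whisker)
    amp = kinematics.whisking_amplitude(filt)
    whisk_segs = kinematics.segment_whisking(
        amp, touch_times=session.touch_times)
    loco_segs = kinematics.segment_locomotion(bundle.position)
    rows = [(s.t_start, s.t_end, s.label) for s in (*whisk_segs, *loco_segs)]
    pd.DataFrame(rows, columns=["start_s", "end_s", "label"]
                 ).to_csv(out / "segments.csv", index=False)
    occ = kinematics.occupancy_map(bundle.position)
    pd.DataFrame({
        "x_mm": (occ.x_edges[:-1] + occ.x_edges[1:]) / 2,
        "frames": occ.counts.sum(axis=1),
        "velocity_mean": occ.velocity_mean, "velocity_sd": occ.velocity_sd,
    }).to_csv(out / "occupancy.csv", index=False)
    state.update(segments=kinematics.StateSegments([*whisk_segs, *loco_segs]),
                 filtered=filt)
    return ["segments.csv", "occupancy.csv"]


def _stage_tuning(config: RunConfig, out: Path, state: dict) -> list[str]:
    session, bundle, spikes = state["session"], state["bundle"], state["spikes"]
    segments = state["segments"]
    phase = bundle.phase
    touch_times = session.touch_times
    wide = [t.t_touch for t in session.trials if t.aperture_mm >= NEUTRAL_MM]
    narrow = [t.t_touch for t in session.trials if t.aperture_mm < NEUTRAL_MM]
    rows = []
    for u in tuning.qc_filter_units(spikes):
        cls = tuning.classify_rs_fs(u)
        row = {"unit_id": u.unit_id, "region": u.region, "class": cls.label,
               "kept": cls.kept, "mean_rate": u.mean_rate}
        try:
            lat = tuning.onset_latency(u, touch_times)
            row["latency_ms"] = lat.latency_ms
        except ValueError:
            row["latency_ms"] = None
        if len(wide) >= 5 and len(narrow) >= 5:
            tm = tuning.touch_modulation_ephys(u, wide, narrow)
            row["touch_category"] = tm.category
        ang = tuning.angle_tuning(u, bundle.whisker, touch_times=touch_times,
                                  n_shuffles=config.n_shuffles, seed=config.seed)
        row.update(angle_depth=ang.modulation_depth,
                   angle_significant=ang.significant)
        ph = tuning.phase_tuning(u, phase)
        row.update(phase_amp=ph.amp, phase_pref=ph.preferred_phase,
                   phase_snr=ph.snr, phase_p=ph.kuiper_p)
        try:
            sm = tuning.state_rate_modulation(u, segments,
                                              n_shuffles=config.n_shuffles,
                                              seed=config.seed)
            row.update(rate_locomotion=sm.rate_a, rate_rest=sm.rate_b,
                       state_label=sm.label)
        except ValueError:
            row["state_label"] = "n/a"
        sp = tuning.spatial_tuning(u, bundle.position)
        row.update(place_mu=sp.mu_mm, place_A=sp.amplitude,
                   spatially_tuned=sp.spatially_tuned)
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "unit_results.csv", index=False)
    return ["unit_results.csv"]


def _stage_decoding(config: RunConfig, out: Path, state: dict) -> list[str]:
    session, spikes = state["session"], state["spikes"]
    calcium = state["calcium"]
    scored = [t for t in session.trials
              if t.aperture_mm != NEUTRAL_MM or session.stage != "neutral"]
    touches = [t.t_touch for t in scored]
    labels = ["wide" if t.aperture_mm >= NEUTRAL_MM else "narrow"
              for t in scored]
    results = {}
    feats = decoding.spike_count_features(spikes, touches, labels,
                                          bin_s=config.decode_bin_s,
                                          allow_imbalance=True)
    res = decoding.decode_spikes(feats, seed=config.seed)
    pd.DataFrame({"t_s": res.bin_times, "accuracy": res.accuracy_series}
                 ).to_csv(out / "decoding_spikes.csv", index=False)
    results["spikes"] = {"windowed_accuracy": res.accuracy}
    wf = decoding.whisker_angle_features(state["bundle"].whisker, touches,
                                         labels, allow_imbalance=True)
    wres = decoding.decode_whisker_angles(wf, seed=config.seed)
    results["whisker"] = {"accuracy": wres.accuracy, "auc": wres.auc}
    try:
        cf = decoding.calcium_features(calcium, touches, labels,
                                       allow_imbalance=True)
        cres = decoding.decode_calcium_cnn(cf, epochs=config.cnn_epochs,
                                           seed=config.seed)
        results["calcium_cnn"] = {"validation_accuracy": cres.accuracy}
    except ValueError as exc:
        results["calcium_cnn"] = {"skipped": str(exc)}
    (out / "decoding_results.json").write_text(json.dumps(results, indent=2))
    return ["decoding_spikes.csv", "decoding_results.json"]
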