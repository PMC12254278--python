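"""Recover injected tuning from simulated spike trains.

Builds a ~600 s session, injects three units -- phase-tuned, place-tuned,
and untuned -- and runs the phase (sine fit + Kuiper test), spatial
(Gaussian + speed term, shuffle-calibrated amplitude), and whisker-angle
(modulation depth vs circular-shift null) analyses.
"""

import numpy as np

import whisktask.synthetic as syn
import whisktask.tuning as tun

session = syn.generate_session_events("initial", syn.LearnerParams(), 58, seed=21)
whisker = syn.generate_whisker_trace(session, 14.5, 15.0, seed=21)
position = syn.generate_position_trace(session, 200.0, seed=21)
bundle = syn.KinematicBundle(whisker=whisker, position=position)

specs = [
    syn.TuningSpec(baseline_rate=10.0, phase_amp=4.0, phase_pref=np.pi),
    syn.TuningSpec(baseline_rate=10.0, place_amp=10.0,
                   place_center_mm=-200.0, place_sigma_mm=40.0),
    syn.TuningSpec(baseline_rate=10.0),
]
units = syn.generate_spike_trains(session, bundle, specs, seed=3)

ph = tun.phase_tuning(units[0], bundle.phase)
print(f"phase-tuned unit: amp {ph.amp:.2f} Hz, preferred phase "
      f"{np.rad2deg(ph.preferred_phase):.0f} deg (injected 180), "
      f"SNR {ph.snr:.2f}, Kuiper p {ph.kuiper_p:.2g}")

sp = tun.spatial_tuning(units[1], position, seed=3)
print(f"place unit: center {sp.mu_mm:.0f} mm (injected -200), sigma "
      f"{sp.sigma_mm:.0f} mm, tuned={sp.spatially_tuned}")

ang = tun.angle_tuning(units[2], whisker, touch_times=session.touch_times,
                       seed=3)
print(f"untuned unit: angle modulation depth {ang.modulation_depth:.2f} vs "
      f"null 95th {ang.null_95th:.2f} -> significant={ang.significant}")
print("-> injected parameters are recovered; the homogeneous unit stays "
      "below its shuffle null.")
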