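"""Generate one synthetic DC-neuromodulation session and inspect it.

A session is one animal's recording series for one stimulus modality: pre-DC
baseline sets, four during-DC sets covering {500, 1000} uA x {cathodic,
anodic} in pseudorandom order, and post-DC sets at increasing time since DC
end.  Ground truth (per-unit spike trains and windowed-count expectations)
travels with the session.
"""

import numpy as np

from dcblock import synthgen as sg

config = sg.GeneratorConfig(modality="noxious_press", treatment_group="neuropathic",
                            n_units_per_modality=3, seed=7)
session = sg.generate_session(config)

print("recording sets (phase, amplitude uA, polarity, minutes since DC end):")
for s in session.sets:
    t = s.schedule.time_since_dc_end_s
    print(f"  {s.set_id}: {s.phase:6s} {s.schedule.amplitude_uA:6.0f} "
          f"{s.schedule.polarity:15s} {'' if t is None else t / 60.0}")

print("\nground truth per unit (main-window expected counts per trial):")
for uid, u in session.truth.units.items():
    exp = u.expected_window_counts["main"]
    print(f"  unit {uid}: gain {u.gain:.2f}  pre {exp['pre']:.2f}  "
          f"during@1000uA {exp[1000.0]:.2f}  "
          f"block release at {u.tau_release_s / 60:.1f} min")

pre = session.sets_by_phase("pre")[0]
counts = [len(t) for t in pre.unit_times.values()]
print(f"\nfirst pre-DC set: {len(pre.triggers_s)} trials, "
      f"{np.sum(counts)} true spikes across {len(counts)} units")
print("the during/pre expectation ratio above equals 1 - r by construction;")
print("r is the generator's true reduction fraction for this condition.")
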