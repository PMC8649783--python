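"""Filter, segment and window a recording into classifier-ready snippets.

EEG is band-passed to 0.5-40 Hz and EMG to 20-500 Hz (both zero-phase),
the movement portion is cut out at the markers, and 250 ms windows with
50% overlap become the classification unit.
"""

import numpy as np

import biofusion as bf

spec = bf.SessionSpec(subject_id="DEMO", rng_seed=0,
                      slow_duration=4.0, fast_duration=2.0)
rec = bf.generate_recording(spec, bf.EffectModel())
rec = bf.segment_movement(bf.filter_recording(rec))
ws = bf.make_windows(rec)

print(f"{len(ws)} windows of shape {ws.samples.shape[1:]} "
      f"(channels x samples)")
for c in sorted(set(ws.weight_class.tolist())):
    n = int(np.sum(ws.weight_class == c))
    print(f"  class {c} ({ws.class_weights[c]:.0f} lbs): {n} windows")

slow = int(np.sum(ws.speed_label == "slow"))
print(f"  {slow} slow-movement and {len(ws) - slow} fast-movement windows")
print("-> every 250 ms window carries its weight class, speed, trial and "
      "repetition, ready for the train/validation/test protocol.")
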