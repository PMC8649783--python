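"""Turn windows into normalized spectrogram images under several fusion layouts.

Each 250 ms window becomes a 32x68 spectrogram per channel (56-sample Hann
window, 75% overlap; EEG cropped to 1.25-40 Hz, EMG to 15.6-500 Hz).  The
five channel images are then fused at the input level: stacked vertically
by modality ('grouped'), interleaved ('mixed'), or along depth ('stacked').
"""

import biofusion as bf

spec = bf.SessionSpec(subject_id="DEMO", rng_seed=0,
                      slow_duration=4.0, fast_duration=2.0)
rec = bf.segment_movement(bf.filter_recording(
    bf.generate_recording(spec, bf.EffectModel())))
ws = bf.make_windows(rec)

for layout in ("grouped", "mixed", "stacked", "eeg_stack", "emg_stack",
               "signal_full"):
    ds = bf.build_image_dataset(ws, layout)
    print(f"  {layout:>12}: {len(ds)} images of shape {ds.input_shape}, "
          f"values in [{ds.images.min():.2f}, {ds.images.max():.2f}]")

g = bf.build_image_dataset(ws, "grouped")
print(f"row order in 'grouped': {g.row_order}")
print("-> all layouts contain the same normalized pixels; only their "
      "arrangement (and hence the CNN's receptive field) differs.")
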