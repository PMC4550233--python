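"""Galvo drive waveforms and frame-interleave schedules.

Builds the sine/cosine lookup table that spins the laser spot in a
circle at the objective back focal plane, then interleaves three
presets (spinning TIRF, widefield, skimming) frame by frame.
"""

import numpy as np

import spintirf as st

# One-period lookup table at the DAC sample rate: 200 Hz -> 5000 samples.
preset = st.ScanPreset(label="spin", frequency_hz=200.0, radius=0.95)
table = st.synthesize_waveforms(preset, sample_rate=1_000_000)
radius = np.hypot(table.x_samples, table.y_samples)
print(f"table length: {len(table.x_samples)} samples "
      f"({preset.frequency_hz:.0f} Hz at 1 MHz)")
print(f"scan radius: {radius.min():.6f}..{radius.max():.6f} "
      "(constant = circular scan)")

# A requested frequency that does not fit the exposure is snapped so an
# integer number of revolutions fills each frame (full 360 deg averaging).
presets = [
    st.ScanPreset(label="tirf", mode_tag="spinning_tirf",
                  frequency_hz=230.0, radius=0.97),
    st.ScanPreset(label="wf", mode_tag="widefield", radius=0.3),
    st.ScanPreset(label="skim", mode_tag="skimming", radius=0.90),
]
schedule = st.build_schedule(presets, exposure_time_s=0.005, n_frames=9)
print(f"snapped frequency: 230 -> {schedule.presets[0].frequency_hz:.0f} Hz "
      f"({schedule.presets[0].frequency_hz * 0.005:.0f} revolution/frame)")
print("frame cycle:", " ".join(schedule.frame_preset_labels))
for i, t0, label in st.frame_triggers(schedule)[:4]:
    print(f"  trigger {i}: t = {t0 * 1000:.0f} ms -> {label}")
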