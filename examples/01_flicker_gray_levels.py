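"""Flicker design: modulation depth -> gray levels and frame schedule.

A flicker alternates between the background gray and an ON gray whose
distance from the background is the amplitude modulation depth (fraction
of the background-to-white range).
"""

from periflick import FlickerSpec, depth_to_gray, frame_sequence, ideal_waveform_spectrum

for depth, label in [(0.70, "control"), (0.02, "periliminal-ish"), (0.0198, "one step lower")]:
    spec = FlickerSpec(freq=13.0, modulation_depth=depth)
    print(f"{label:16s} depth={depth:<7g} ON gray = {depth_to_gray(spec):3d} (OFF stays 130)")

spec15 = FlickerSpec(freq=15.0, modulation_depth=0.70)
states = frame_sequence(spec15, duration=1.0)
print(f"\n15 Hz on a 120 Hz monitor: first cycle = {states[:8].astype(int)} "
      "(4 frames ON, 4 OFF; 8-frame period)")

spec13 = FlickerSpec(freq=13.0, modulation_depth=0.70)
states13 = frame_sequence(spec13, duration=9.0)
print(f"13 Hz over 9 s: {len(states13)} frames, ON fraction {states13.mean():.3f} "
      "(non-integer 9.23 frames/cycle still averages to a 50% duty cycle)")

spectrum = ideal_waveform_spectrum(spec13, n_harmonics=5)
print("\nIdeal square-wave line spectrum (odd harmonics only, amplitude ~ 1/n):")
print(spectrum[spectrum.amplitude > 0].to_string(index=False))
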