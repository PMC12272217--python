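"""Visibility-threshold staircase on a simulated observer.

The descending phase lowers the modulation depth from 5% in 0.1-point
steps until a four-stimulus block contains more than two errors; the
ascending phase then raises it in 0.02-point steps until both flickers in
a block are detected.  The final depth is the periliminal level and one
ascending step below it the subliminal level.
"""

from periflick import Observer, run_staircase

observer = Observer(true_threshold=0.018, slope=20000.0, lapse_rate=0.02,
                    guess_rate=0.1, seed=1)
result = run_staircase(observer)

print(f"true threshold      : {observer.true_threshold:.4f}")
print(f"periliminal depth   : {result.periliminal:.4f}  "
      f"(recovery error {abs(result.periliminal - observer.true_threshold):.4f})")
print(f"subliminal depth    : {result.subliminal:.4f}  (one 0.0002 step below)")
print(f"descending blocks   : {result.n_descending_blocks}")
print(f"ascending blocks    : {result.n_ascending_blocks}")
print("\nlast few staircase trials:")
print(result.trace.tail(8).to_string(index=False))
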