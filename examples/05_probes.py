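"""Probe a trained recognizer: severed laterals, reversed pattern, speed.

The chain is a finite-state recognizer: its last (accepting) neuron should
fire only when the complete pattern is presented in the right order at the
trained speed.
"""

from synchain import NetworkConfig, run_test, run_training, run_speed_variation_test
from synchain.analysis import compute_reliability

cfg = NetworkConfig(seed=3).scaled_down()
record = run_training(cfg)

on = compute_reliability(run_test(record, 10))
members = on.members()
print("members and reliabilities:",
      [(int(m), round(float(on.p_fire[m]), 2)) for m in members])

rev = compute_reliability(run_test(record, 10, pattern=record.patterns[0].reversed()))
print("same neurons on the reversed pattern:",
      [(int(m), round(float(rev.p_fire[m]), 2)) for m in members])

if members.size:
    for factor in (1.0, 1.02, 2.0):
        out = run_speed_variation_test(record, factor)
        print(f"speed x{factor}: recognition {out['recognition_rate']:.2f}, "
              f"accepting neuron fires in {out['accepting_fire_rate']:.2f} of presentations")
    print("full-chain recognition requires every member; it degrades as the "
          "replay speed moves the input off the trained rising edges")
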