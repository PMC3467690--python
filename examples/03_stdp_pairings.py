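"""STDP pairing schemes: window values and nearest-vs-all-to-all totals.

Potentiation decays with the pre-to-post delay; depression with the
post-to-pre delay and a 40% overweight so that uncorrelated activity
depresses a synapse on average.
"""

import numpy as np

from synchain import STDPParams, pair_sum_oracle, stdp_window
from synchain.plasticity import compute_learning_rates

a_p, a_d = compute_learning_rates(0.45, depression_bias=1.4)
print(f"learning rates for the feed-forward class: A_p={a_p:.2e}, A_d={a_d:.2e}")
for tau in (0.0, 10.0, -10.0):
    print(f"  window f(tau={tau:+.0f} ms) = {stdp_window(tau, a_p, a_d):+.2e}")

pre = [0.0, 30.0, 60.0]
post = [35.0]
for mode in ("all_to_all", "nearest_neighbor"):
    p = STDPParams(a_p, a_d, mode=mode)
    total = pair_sum_oracle(pre, post, p)
    print(f"{mode}: total change for pre={pre}, post={post}: {total:+.2e}")
print("all-to-all sums every pair; nearest-neighbor pairs the post spike only "
      "with its closest pre spike (here the one 5 ms before it)")
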