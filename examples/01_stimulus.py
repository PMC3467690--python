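"""Build the afferent stimulus and check its first-order statistics.

A frozen 50-ms spike pattern is re-inserted at random times on half of the
2000 afferents; everything else is Poisson at the same rates, so only the
repeating spatio-temporal structure distinguishes pattern from noise.
"""

import numpy as np

from synchain import StimulusConfig, build_schedule, generate_pattern, render_stimulus
from synchain.stimulus import label_noise_fraction

cfg = StimulusConfig(total_duration=20_000.0, seed=0)
rng = np.random.default_rng(0)

pattern = generate_pattern(cfg, rng)
schedule = build_schedule(cfg, rng)
raster = render_stimulus(pattern, schedule, cfg, rng)

print(f"frozen pattern: {pattern.n_spikes} spikes on {pattern.n_afferents} afferents "
      f"over {pattern.duration:.0f} ms")
print(f"schedule: {schedule.n_presentations} presentations, "
      f"min gap {schedule.gaps().min():.1f} ms, duty cycle {schedule.duty_cycle():.2f}")
print(f"rendered: {raster.n_spikes} spikes; mean afferent rate "
      f"{raster.rates_hz().mean():.1f} Hz (expected 64 = 54 carrier + 10 background)")
print(f"noise fraction: {100 * label_noise_fraction(raster):.1f}% of spikes are "
      "carrier/background rather than frozen-pattern spikes")
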