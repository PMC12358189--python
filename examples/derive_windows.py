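"""Derive response windows from pooled latency histograms.

The window runs from the first to the last post-stimulus bin whose relative
frequency reaches 1.5x the pre-stimulus baseline, with each edge rounded
away from the peak bin by one significant digit (38 -> 40, 850 -> 800, ...).
"""

import numpy as np

from dcblock import windows as w

rng = np.random.default_rng(0)

# pooled trial-aligned spike times (ms): a tactile-like response at ~8 ms
# riding on a uniform spontaneous baseline
baseline = rng.uniform(-40, 40, 4000)
response = rng.normal(8.0, 6.0, 6000)
pool = np.concatenate([baseline, response[(response >= 0) & (response < 40)]])

hist = w.build_latency_histogram(pool, "tactile", bin_width_ms=1.0,
                                 span_ms=(-40, 40))
start, end = w.derive_window(hist)
print(f"pooled spikes: {hist.n}, baseline frequency {hist.baseline:.4f}/bin")
print(f"derived tactile post-stimulus window: {start:.0f} to {end:.0f} ms")
print("canonical fixed window:", w.FIXED_WINDOWS['tactile'].post_ms)

counts = w.windowed_counts(np.array([-0.020, 0.005, 0.020]) + 10.0, [10.0],
                           w.FIXED_WINDOWS["tactile"])
print(f"\nper-trial (pre, post) counts for spikes at -20/+5/+20 ms: "
      f"{tuple(counts[0])}")
print("counting is half-open [start, end): a spike exactly at 40 ms is not")
print("counted; the sustained-thermal window multiplies pre counts by 3.")
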