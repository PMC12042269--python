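"""Trend segmentation of an energy trajectory.

Segments a simulated energy trace into linear-trend segments and prints
each segment's stochastic coordinates (trend, mean, std, dwelling time).
Long dwellings with near-zero trend are kinetic-trap candidates.
"""

import slmassembly as sa
from slmassembly.segmentation import (
    SegmentationConfig, resample_uniform, segment_series,
)

state, targets, params, system = sa.fixture_small_system("trap9", seed=2)
tr = sa.run_trajectory(state, params, targets, system.t_cap, seed=2)

series = resample_uniform(tr.times, tr.energy, 1000)
segments = segment_series(series, SegmentationConfig())

print(f"{len(segments)} segments over {tr.t_total:.3g} s of simulated time")
print(f"{'t_start':>10} {'dwell (s)':>10} {'trend (kBT/s)':>14} {'mean':>8} {'std':>6}")
for s in segments:
    print(f"{s.t_start:10.3g} {s.dwell:10.3g} {s.trend:14.3g} {s.mean:8.2f} {s.std:6.2f}")
print("Negative trend = assembly progress; a long dwell at near-zero trend "
      "is a metastable (possibly trapped) macrostate.")
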