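"""From coverage estimates to on/off spray decisions and trial filtering.

Shows the yield-loss threshold table, per-level decisions for a few
coverage estimates, the camera-to-nozzle actuation delay, and the
quantile-based exclusion of outlier plots.
"""

import numpy as np

from modicovi.spray_decision import (
    PlotRecord,
    actuation_delay,
    default_thresholds,
    filter_plots,
    net_plot_region,
    spray_on,
)

table = default_thresholds()
print("threshold table (expected yield loss % -> coverage threshold %):")
for loss, cover in table.levels:
    print(f"  {loss:5.1f} -> {cover:5.2f}")

for estimate in (0.5, 3.0, 15.0, 90.0):
    decisions = ["ON" if spray_on(estimate, t) else "off" for t in table.coverage_thresholds]
    print(f"coverage {estimate:5.1f}%: " + "  ".join(
        f"M{i + 1}={d}" for i, d in enumerate(decisions)))

print(f"\nactuation delay at 0.35 m/s over 0.7 m: {actuation_delay(0.35, 0.7):.2f} s")
net = net_plot_region()
print(f"net plot: {net.length_m} m x {net.width_m} m ({net.area_m2} m^2)")

rng = np.random.default_rng(0)
records = [
    PlotRecord(str(i), drive_through_time=t, initial_weed_coverage_percent=c)
    for i, (t, c) in enumerate(zip(rng.uniform(8, 12, 100), rng.uniform(0.5, 20, 100)))
]
records[0].drive_through_time = 300.0  # stuck in mud
kept = filter_plots(records)
print(f"plots kept after quantile filtering: {len(kept)} of {len(records)}")
# The slow outlier plot falls outside the 5-95% drive-through-time
# quantiles and is excluded before any treatment comparison.
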