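"""On/off spray decisions and trial record filtering.

Expected relative crop-yield losses are mapped to relative weed-coverage
thresholds; a frame (one camera image driving one nozzle group) is
sprayed when its estimated coverage strictly exceeds the active
threshold.  The five levels used in the field trial:

    yield loss (%)   2.5   5     20    40   80
    coverage  (%)    1.27  2.5   11.5  27   83

Also provided: the camera-to-nozzle actuation delay, the trial's plot
trimming (net 3 m x 1.5 m from a gross 4 m x 3 m plot, keeping spray
away from the vehicle tracks) and the record-exclusion rules (plots
with extreme drive-through times or extreme initial weed coverage are
dropped by empirical quantiles).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np


@dataclass
class ThresholdTable:
    """Ordered (expected_yield_loss_percent, coverage_threshold_percent) pairs."""

    levels: tuple

    def __post_init__(self):
        self.levels = tuple((float(a), float(b)) for a, b in self.levels)
        losses = [a for a, _ in self.levels]
        covers = [b for _, b in self.levels]
        if sorted(losses) != losses or len(set(losses)) != len(losses):
            raise ValueError("yield losses must be strictly increasing")
        if sorted(covers) != covers or len(set(covers)) != len(covers):
            raise ValueError("coverage thresholds must be strictly increasing")

    def __len__(self) -> int:
        return len(self.levels)

    def threshold_for_loss(self, loss_percent: float) -> float:
        for loss, cover in self.levels:
            if loss == loss_percent:
                return cover
        raise KeyError(f"no threshold level for expected yield loss {loss_percent}%")

    @property
    def coverage_thresholds(self) -> tuple:
        return tuple(b for _, b in self.levels)


def default_thresholds() -> ThresholdTable:
    """The five field-trial levels (M1..M5)."""
    return ThresholdTable(
        levels=((2.5, 1.27), (5.0, 2.5), (20.0, 11.5), (40.0, 27.0), (80.0, 83.0))
    )


def spray_on(estimated_coverage_percent: float, threshold_percent: float) -> bool:
    """Spray iff the coverage estimate strictly exceeds the threshold."""
    if estimated_coverage_percent < 0 or threshold_percent < 0:
        raise ValueError("coverage and threshold must be non-negative")
    return estimated_coverage_percent > threshold_percent


def actuation_delay(velocity_mps: float, camera_to_nozzle_m: float) -> float:
    """Seconds between image acquisition and valve actuation.

    Compensates the mounting distance between camera and nozzle at the
    current ground speed.  Zero or negative velocity is an error: the
    timing assumes constant forward motion, and a stopped vehicle would
    place the spray incorrectly.
    """
    if velocity_mps <= 0:
        raise ValueError("velocity must be positive; spray timing assumes motion")
    if camera_to_nozzle_m < 0:
        raise ValueError("camera-to-nozzle distance must be non-negative")
    return camera_to_nozzle_m / velocity_mps


@dataclass
class PlotRecord:
    """One trial plot's logged summary."""

    plot_id: str
    drive_through_time: float
    initial_weed_coverage_percent: float
    nozzle_on_fraction: float = 0.0

    def __post_init__(self):
        if self.drive_through_time < 0:
            raise ValueError("drive-through time must be non-negative")
        if not 0.0 <= self.nozzle_on_fraction <= 1.0:
            raise ValueError("nozzle-on fraction must lie in [0, 1]")


def filter_plots(
    records: Sequence[PlotRecord],
    time_quantiles: tuple[float, float] = (0.05, 0.95),
    coverage_band: tuple[float, float] = (0.5, 99.5),
) -> list[PlotRecord]:
    """Drop outlier plots by empirical quantiles of time and coverage.

    Plots outside the [5%, 95%] drive-through-time quantiles (stuck in
    mud, system crash, ...) or outside the [0.5%, 99.5%] initial-weed-
    coverage quantiles are excluded.  Quantiles use linear interpolation
    of order statistics (numpy default, R type 7); bounds are inclusive,
    so identical records all survive.  A plot violating both rules is
    removed once.
    """
    if not records:
        raise ValueError("at least one record is required")
    times = np.array([r.drive_through_time for r in records], dtype=float)
    covers = np.array([r.initial_weed_coverage_percent for r in records], dtype=float)
    t_lo, t_hi = np.quantile(times, time_quantiles)
    c_lo, c_hi = np.quantile(covers, (coverage_band[0] / 100.0, coverage_band[1] / 100.0))
    return [
        r
        for r, t, c in zip(records, times, covers)
        if t_lo <= t <= t_hi and c_lo <= c <= c_hi
    ]


class PlotRegion(NamedTuple):
    length_m: float
    width_m: float

    @property
    def area_m2(self) -> float:
        return self.length_m * self.width_m


def net_plot_region(
    gross_length_m: float = 4.0,
    gross_width_m: float = 3.0,
    trim_each_end_m: float = 0.5,
    net_width_m: float = 1.5,
) -> PlotRegion:
    """Centered net evaluation region of a gross plot.

    Defaults reproduce the trial: 4 m x 3 m gross, half a meter trimmed
    at each end and width reduced to the six-nozzle span, giving a net
    3 m x 1.5 m.
    """
    length = gross_length_m - 2.0 * trim_each_end_m
    if length <= 0 or not 0 < net_width_m <= gross_width_m:
        raise ValueError("trimming leaves no net region")
    return PlotRegion(length_m=length, width_m=net_width_m)
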