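"""Arithmetic of the field-trial design and camera geometry.

Small closed-form helpers for the quantities fixed by the trial layout
and the imaging optics: the factorial plot count, the crop plant
density implied by the seeding pattern, and the in-focus object height
range implied by the lens depth of field.
"""

from __future__ import annotations

from typing import NamedTuple


def factorial_plot_count(
    n_decision_treatments: int = 7,
    n_weed_levels: int = 2,
    n_camera_positions: int = 2,
    replicates: int = 10,
) -> int:
    """Minimum plot count of the full factorial trial.

    Seven on/off decision treatments (always-on, always-off, five
    coverage-threshold levels) x seeded/unseeded weeds x camera above
    or between rows, at ten replicates each.
    """
    return n_decision_treatments * n_weed_levels * n_camera_positions * replicates


def plant_density_per_m2(row_spacing_m: float = 0.75, seed_spacing_m: float = 0.1) -> float:
    """Crop plants per square meter from row and in-row seed spacing."""
    if row_spacing_m <= 0 or seed_spacing_m <= 0:
        raise ValueError("spacings must be positive")
    return 1.0 / (row_spacing_m * seed_spacing_m)


class FocusRange(NamedTuple):
    below_soil_mm: float
    above_soil_mm: float


def in_focus_height_range_mm(
    focus_plane_above_soil_mm: float = 920.0,
    near_limit_from_camera_mm: float = 737.0,
    far_limit_from_camera_mm: float = 924.0,
) -> FocusRange:
    """Object heights rendered in focus, relative to the soil surface.

    With the camera's focal point ``focus_plane_above_soil_mm`` above
    the ground and acceptable sharpness between the near and far limits
    measured from the camera, objects from
    ``far - focus_plane`` below to ``focus_plane - near`` above the
    soil are in focus (defaults: 4 mm below to 183 mm above).
    """
    if not near_limit_from_camera_mm < far_limit_from_camera_mm:
        raise ValueError("near limit must be closer than far limit")
    return FocusRange(
        below_soil_mm=far_limit_from_camera_mm - focus_plane_above_soil_mm,
        above_soil_mm=focus_plane_above_soil_mm - near_limit_from_camera_mm,
    )
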