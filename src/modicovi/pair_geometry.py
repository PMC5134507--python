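"""Relative geometry of nearby edge-segment pairs.

For an ordered pair (P1, P2) of oriented edge segments a coordinate
frame is centered on and aligned with P1; P2's position in that frame is
(dx, dy) and its relative orientation dtheta = theta2 - theta1 (wrapped
to (-pi, pi]).  Because the description is relative it is invariant to
any rigid motion of the whole scene.  Two derived features complete the
pair descriptor:

    d = sqrt(dx^2 + dy^2)                   (separation, pixels)
    k = sqrt(2 - 2 cos(dtheta)) / d         (curvature, 1/pixels)

k equals 1/r exactly for two tangentially oriented samples on a circle
of radius r: the chord is d = 2 r sin(phi/2) while the tangents differ
by the central angle phi and sqrt(2 - 2 cos phi) = 2 sin(phi/2).

Only ordered pairs separated by strictly fewer than ``max_dist`` pixels
(default 125) are enumerated — far enough to span a plant, near enough
to keep the pair count manageable.  2-D histograms of chosen coordinate
pairs ("fingerprints") separate monocot from dicot contour structure:
long parallel monocot edges concentrate mass near dtheta = 0 and pi,
while lobed dicot outlines spread mass across angles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.spatial import cKDTree

from ._util import wrap_angle
from .edge_extraction import EdgeSegment

logger = logging.getLogger(__name__)

#: axis order used everywhere a pair is a 5-vector
PAIR_AXES = ("dx", "dy", "dtheta", "d", "k")
ANGLE_AXIS = PAIR_AXES.index("dtheta")

DEFAULT_MAX_PAIR_DIST = 125.0


class EdgePair(NamedTuple):
    """Relative pose and derived features of one ordered segment pair."""

    dx: float
    dy: float
    dtheta: float
    d: float
    k: float


def relative_pose(p1: EdgeSegment, p2: EdgeSegment) -> tuple[float, float, float]:
    """P2's pose in the frame centered on and aligned with P1.

    The world offset (x2-x1, y2-y1) is rotated by -theta1; dtheta is the
    wrapped orientation difference.  Coordinates: x = column rightward,
    y = row downward, angles measured in the (x, y) plane.
    """
    dxw = p2.x - p1.x
    dyw = p2.y - p1.y
    c, s = math.cos(p1.theta), math.sin(p1.theta)
    dx = c * dxw + s * dyw
    dy = -s * dxw + c * dyw
    return dx, dy, wrap_angle(p2.theta - p1.theta)


def pair_features(dx: float, dy: float, dtheta: float) -> tuple[float, float]:
    """Separation d and curvature k from a relative pose; rejects d = 0."""
    d = math.hypot(dx, dy)
    if d == 0.0:
        raise ValueError("coincident segments: curvature undefined at zero separation")
    k = math.sqrt(max(2.0 - 2.0 * math.cos(dtheta), 0.0)) / d
    return d, k


def enumerate_pairs(
    segments: Sequence[EdgeSegment],
    max_dist: float = DEFAULT_MAX_PAIR_DIST,
) -> list[EdgePair]:
    """All ordered pairs (i != j) separated by strictly less than ``max_dist``.

    Uses a k-d tree for the neighbor search; the result equals the
    all-pairs scan.  Coincident segments (d = 0) are dropped with a
    logged count since curvature is undefined for them.
    """
    arr = pair_array(segments, max_dist=max_dist)
    return [EdgePair(*row) for row in arr]


def pair_array(
    segments: Sequence[EdgeSegment],
    max_dist: float = DEFAULT_MAX_PAIR_DIST,
) -> np.ndarray:
    """Vectorized pair enumeration: an (M, 5) array over PAIR_AXES.

    Same semantics as :func:`enumerate_pairs`; this is the form the
    density features consume.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    n = len(segments)
    if n < 2:
        return np.empty((0, 5), dtype=float)
    xy = np.array([(s.x, s.y) for s in segments], dtype=float)
    th = np.array([s.theta for s in segments], dtype=float)

    tree = cKDTree(xy)
    unordered = tree.query_pairs(r=max_dist, output_type="ndarray")
    if unordered.size == 0:
        return np.empty((0, 5), dtype=float)
    # both directions; query_pairs is <= r, the cutoff is strict <
    i = np.concatenate([unordered[:, 0], unordered[:, 1]])
    j = np.concatenate([unordered[:, 1], unordered[:, 0]])
    off = xy[j] - xy[i]
    d = np.hypot(off[:, 0], off[:, 1])
    keep = d < max_dist
    zero = d == 0.0
    if zero.any():
        logger.info("dropping %d coincident segment pair(s)", int(zero.sum() // 2))
        keep &= ~zero
    i, j, off, d = i[keep], j[keep], off[keep], d[keep]
    c, s = np.cos(th[i]), np.sin(th[i])
    dx = c * off[:, 0] + s * off[:, 1]
    dy = -s * off[:, 0] + c * off[:, 1]
    dtheta = wrap_angle(th[j] - th[i])
    k = np.sqrt(np.maximum(2.0 - 2.0 * np.cos(dtheta), 0.0)) / d
    return np.column_stack([dx, dy, dtheta, d, k])


@dataclass
class Fingerprint:
    """2-D histogram of one pair-coordinate projection."""

    axes: tuple[str, str]
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray


def fingerprint(
    pairs,
    axes: tuple[str, str] = ("dx", "dtheta"),
    bins: int | tuple[int, int] = 64,
    ranges=None,
) -> Fingerprint:
    """Project pair coordinates onto two axes and histogram them."""
    if axes[0] == axes[1]:
        raise ValueError("fingerprint axes must be distinct")
    for ax in axes:
        if ax not in PAIR_AXES:
            raise ValueError(f"unknown axis {ax!r}; choose from {PAIR_AXES}")
    arr = pairs if isinstance(pairs, np.ndarray) else np.asarray(
        [tuple(p) for p in pairs], dtype=float
    ).reshape(-1, 5)
    ia, ib = PAIR_AXES.index(axes[0]), PAIR_AXES.index(axes[1])
    if arr.shape[0] == 0:
        nb = bins if isinstance(bins, tuple) else (bins, bins)
        return Fingerprint(
            axes=tuple(axes),
            x_edges=np.linspace(0, 1, nb[0] + 1),
            y_edges=np.linspace(0, 1, nb[1] + 1),
            counts=np.zeros(nb, dtype=int),
        )
    counts, xe, ye = np.histogram2d(arr[:, ia], arr[:, ib], bins=bins, range=ranges)
    return Fingerprint(axes=tuple(axes), x_edges=xe, y_edges=ye, counts=counts.astype(int))
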