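"""Oriented edge segments from a binary vegetation mask.

Edges are located with a first-order complex moment filter: the mask
(cast to {0, 1}) is convolved with the complex kernel

    K(x, y) = (x + i y) * (1 / (2 pi sigma^2)) * exp(-(x^2 + y^2) / (2 sigma^2))

whose response is zero on constant regions (the kernel is odd) and whose
phase rotates with the local edge direction.  The magnitude image is
thresholded, thinned to a one-pixel skeleton (Zhang-Suen, iterated to
convergence), and subsampled so at most one segment survives per 8x8
cell — keeping the pair-enumeration stage downstream tractable.

The retained phase convention is fixed by the kernel and the
convolution: for a bright region on dark ground the phase points along
the *outward* boundary normal.  Downstream geometry uses only phase
differences, so the convention itself is irrelevant there; rotating the
input rotates all retained phases by the same angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.signal import fftconvolve
from skimage.morphology import skeletonize

from ._util import wrap_angle


class EdgeSegment(NamedTuple):
    """One oriented contour sample: column x, row y, orientation theta (radians)."""

    x: int
    y: int
    theta: float


@dataclass
class ComplexResponse:
    """Polar form of the complex moment filter response."""

    magnitude: np.ndarray
    phase: np.ndarray


def complex_moment_kernel(sigma: float, m: int = 1, n: int = 0) -> np.ndarray:
    """The (m, n) complex moment kernel on a (2*ceil(3 sigma)+1)^2 support.

    m=1, n=0 selects step edges.  The 3-sigma truncation leaves
    negligible kernel mass outside the support.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    r = int(math.ceil(3.0 * sigma))
    y, x = np.mgrid[-r : r + 1, -r : r + 1].astype(float)
    gauss = np.exp(-(x**2 + y**2) / (2.0 * sigma**2)) / (2.0 * np.pi * sigma**2)
    return (x + 1j * y) ** m * (x - 1j * y) ** n * gauss


def complex_edge_response(image: np.ndarray, sigma: float = 2.0) -> ComplexResponse:
    """Convolve an intensity (or binary) image with the m=1, n=0 edge kernel."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    kernel = complex_moment_kernel(sigma)
    resp = fftconvolve(img, kernel, mode="same")
    return ComplexResponse(magnitude=np.abs(resp), phase=wrap_angle(np.angle(resp)))


def extract_edge_segments(
    resp: ComplexResponse,
    mag_threshold: float | None = None,
    cell: int = 8,
    max_per_cell: int = 1,
) -> list[EdgeSegment]:
    """Threshold, thin and subsample the edge response into segments.

    Parameters
    ----------
    mag_threshold : absolute magnitude threshold; ``None`` uses
        0.2 x the image's maximum magnitude.
    cell : side of the square subsampling cells (pixels).
    max_per_cell : segments retained per cell, strongest first; ties
        broken by row-major pixel order for determinism.
    """
    mag = resp.magnitude
    if mag_threshold is None:
        mag_threshold = 0.2 * float(mag.max())
    if mag_threshold < 0:
        raise ValueError("magnitude threshold must be non-negative")
    binary = mag > mag_threshold
    if not binary.any():
        return []
    skel = skeletonize(binary, method="zhang")
    ys, xs = np.nonzero(skel)
    if ys.size == 0:
        return []
    mags = mag[ys, xs]
    ncols = -(-mag.shape[1] // cell)
    cell_id = (ys // cell) * ncols + (xs // cell)
    # row-major within cell, then by descending magnitude, then by cell:
    # the first occurrence per cell id is the strongest candidate.
    order = np.lexsort((xs, ys, -mags, cell_id))
    out: list[EdgeSegment] = []
    taken: dict[int, int] = {}
    phase = resp.phase
    for idx in order:
        cid = int(cell_id[idx])
        got = taken.get(cid, 0)
        if got >= max_per_cell:
            continue
        taken[cid] = got + 1
        x, y = int(xs[idx]), int(ys[idx])
        out.append(EdgeSegment(x=x, y=y, theta=float(phase[y, x])))
    out.sort(key=lambda s: (s.y, s.x))
    return out
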