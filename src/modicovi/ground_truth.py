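"""Reference weed coverage from known crop-row positions.

The ground-truth procedure marks a corridor ("crop band") around each
crop-row centerline: the supplied waypoints are densified by piecewise
linear interpolation at sub-pixel spacing and dilated with a disc
(default radius 350 px, about 146 mm at 2.4 px/mm — wide enough to
cover most crop leaves).  Vegetation blobs are then classified by where
their centroid falls: inside the band the whole blob counts as crop —
letting leaves extend beyond the marked area — otherwise all its pixels
count as weed.  Weed coverage is the count of vegetation pixels not
classified as crop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class RowPath:
    """Ordered crop-row centerline waypoints in image coordinates (x, y)."""

    waypoints: np.ndarray

    def __post_init__(self):
        self.waypoints = np.asarray(self.waypoints, dtype=float).reshape(-1, 2)
        if self.waypoints.shape[0] < 2:
            raise ValueError("a row path needs at least two waypoints")
        if np.any(np.all(np.diff(self.waypoints, axis=0) == 0, axis=1)):
            raise ValueError("consecutive waypoints must be distinct")

    def densify(self, spacing: float = 0.5) -> np.ndarray:
        """Piecewise-linear interpolation at <= ``spacing`` px steps."""
        pts = [self.waypoints[0]]
        for a, b in zip(self.waypoints[:-1], self.waypoints[1:]):
            seg = np.linalg.norm(b - a)
            n = max(1, int(np.ceil(seg / spacing)))
            t = np.linspace(0.0, 1.0, n + 1)[1:, None]
            pts.append(a[None, :] * (1 - t) + b[None, :] * t)
        return np.vstack([pts[0][None, :] if pts[0].ndim == 1 else pts[0], *pts[1:]])


@dataclass
class CoverageResult:
    """Per-image weed/crop pixel bookkeeping."""

    weed_pixels: int
    crop_pixels: int
    weed_fraction_of_image: float
    blob_labels: list  # "crop"/"weed" per connected component, label order


def crop_band_mask(paths, radius_px: float = 350.0, shape=None) -> np.ndarray:
    """Union of discs of ``radius_px`` swept along each interpolated path.

    Implemented as a Euclidean distance transform from the rasterized
    densified paths: band = distance <= radius (an exact disc).  An
    empty path list yields an all-false mask.
    """
    if radius_px <= 0:
        raise ValueError("dilation radius must be positive")
    if shape is None:
        raise ValueError("an output shape is required")
    h, w = shape
    raster = np.zeros((h, w), dtype=bool)
    for path in paths:
        if not isinstance(path, RowPath):
            path = RowPath(np.asarray(path))
        pts = np.round(path.densify(0.5)).astype(int)
        inside = (pts[:, 0] >= 0) & (pts[:, 0] < w) & (pts[:, 1] >= 0) & (pts[:, 1] < h)
        raster[pts[inside, 1], pts[inside, 0]] = True
    if not raster.any():
        return raster
    dist = ndimage.distance_transform_edt(~raster)
    return dist <= radius_px


def classify_blobs(veg, band: np.ndarray) -> CoverageResult:
    """Blob-label the vegetation and split crop from weed by centroid.

    8-connectivity keeps thin diagonal stems attached.  A blob whose
    (rounded) centroid lies on a band pixel is crop in full, even where
    its leaves leave the band; everything else is weed.
    """
    veg_values = veg.values if hasattr(veg, "values") else np.asarray(veg, dtype=bool)
    if veg_values.shape != band.shape:
        raise ValueError("vegetation mask and band must share a shape")
    labels, n = ndimage.label(veg_values, structure=np.ones((3, 3), dtype=bool))
    weed = 0
    crop = 0
    blob_labels = []
    if n:
        centroids = ndimage.center_of_mass(veg_values, labels, index=range(1, n + 1))
        sizes = ndimage.sum_labels(veg_values, labels, index=range(1, n + 1)).astype(int)
        for (cy, cx), size in zip(centroids, sizes):
            r = min(max(int(round(cy)), 0), band.shape[0] - 1)
            c = min(max(int(round(cx)), 0), band.shape[1] - 1)
            if band[r, c]:
                crop += size
                blob_labels.append("crop")
            else:
                weed += size
                blob_labels.append("weed")
    return CoverageResult(
        weed_pixels=int(weed),
        crop_pixels=int(crop),
        weed_fraction_of_image=float(weed) / veg_values.size,
        blob_labels=blob_labels,
    )


def dilation_radius_mm(radius_px: float = 350.0, px_per_mm: float = 2.4) -> float:
    """Physical radius of the crop-band dilation disc."""
    return radius_px / px_per_mm


def overlay(veg, band: np.ndarray, result: CoverageResult | None = None) -> np.ndarray:
    """RGB visualization: green crop, red weed, blue band, black soil."""
    veg_values = veg.values if hasattr(veg, "values") else np.asarray(veg, dtype=bool)
    if result is None:
        result = classify_blobs(veg_values, band)
    labels, n = ndimage.label(veg_values, structure=np.ones((3, 3), dtype=bool))
    img = np.zeros(veg_values.shape + (3,), dtype=np.uint8)
    img[band & ~veg_values] = (60, 60, 200)
    for blob_id, cls in zip(range(1, n + 1), result.blob_labels):
        img[labels == blob_id] = (0, 200, 0) if cls == "crop" else (220, 0, 0)
    return img
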