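"""Vegetation/soil segmentation.

Two routes produce a binary vegetation mask from a top-down image of a
field scene:

* **Excess green (ExG)** — a normalized color index contrasting green
  against red + blue, computed directly on the raw Bayer mosaic (no
  demosaicing) and thresholded.  For each pixel a 2x2 sensor square is
  placed above-left of it so that the pixel is the square's lower-right
  corner; any such square on a Bayer grid holds two green samples (G1,
  G2), one red (R) and one blue (B), and

      ExG = (G1 + G2 - R - B) / (R + G1/2 + G2/2 + B)

  which is bounded in [-1, 2] for non-negative sensor counts and is
  invariant to a global gain (it is a ratio).

* **Naive Bayes** — a per-pixel classifier with per-channel Gaussian
  class-conditionals on (R, G, B) and empirical class priors, trained
  from labeled pixels.  Useful when the camera's spectral filtering
  makes a fixed ExG threshold unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from sklearn.naive_bayes import GaussianNB

BAYER_LAYOUTS = ("RGGB", "BGGR", "GRBG", "GBRG")

#: channel letter at (row parity, column parity) for each layout
_LAYOUT_GRID = {
    "RGGB": (("R", "G"), ("G", "B")),
    "BGGR": (("B", "G"), ("G", "R")),
    "GRBG": (("G", "R"), ("B", "G")),
    "GBRG": (("G", "B"), ("R", "G")),
}


@dataclass
class BayerMosaic:
    """Raw single-chip sensor grid with a declared color-filter layout.

    Parameters
    ----------
    values : 2-D array of non-negative sensor counts.
    layout : one of ``RGGB``, ``BGGR``, ``GRBG``, ``GBRG`` — the channel
        pattern of the top-left 2x2 square.
    bit_depth : sensor bit depth; values must lie in [0, 2**bit_depth - 1].
    """

    values: np.ndarray
    layout: str = "RGGB"
    bit_depth: int = 8

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.layout not in BAYER_LAYOUTS:
            raise ValueError(
                f"unknown Bayer layout {self.layout!r}; expected one of {BAYER_LAYOUTS}"
            )
        if self.values.ndim != 2:
            raise ValueError("mosaic must be a 2-D grid")
        h, w = self.values.shape
        if h % 2 or w % 2:
            raise ValueError("mosaic dimensions must be even for full 2x2 coverage")
        if h < 2 or w < 2:
            raise ValueError("mosaic must be at least 2x2")
        vmax = 2.0**self.bit_depth - 1.0
        if self.values.min() < 0 or self.values.max() > vmax:
            raise ValueError(f"sensor counts must lie in [0, {vmax}]")

    def channel_masks(self):
        """Boolean masks (R, G, B) marking which grid cells carry each channel."""
        h, w = self.values.shape
        rows = np.arange(h)[:, None] % 2
        cols = np.arange(w)[None, :] % 2
        grid = _LAYOUT_GRID[self.layout]
        letters = np.empty((h, w), dtype="U1")
        for rp in (0, 1):
            for cp in (0, 1):
                letters[(rows == rp) & (cols == cp)] = grid[rp][cp]
        return letters == "R", letters == "G", letters == "B"


@dataclass
class ExGMap:
    """Excess-green index per pixel plus a validity mask.

    Invalid pixels are those without a complete 2x2 square above-left of
    them (first row/column) or with a zero denominator (an all-black
    square carries no vegetation signal).
    """

    values: np.ndarray
    valid: np.ndarray


@dataclass
class VegetationMask:
    """Binary vegetation (True) / soil (False) image."""

    values: np.ndarray

    @property
    def vegetation_pixels(self) -> int:
        return int(np.count_nonzero(self.values))


def excess_green_from_bayer(mosaic: BayerMosaic) -> ExGMap:
    """Compute the normalized excess-green index directly on a Bayer mosaic.

    Each output pixel (r, c) with r >= 1 and c >= 1 reads the 2x2 square
    spanning rows r-1..r and columns c-1..c.  Output has the mosaic's
    shape; the first row and column are flagged invalid rather than
    padded with invented sensor values.
    """
    v = mosaic.values
    is_r, is_g, is_b = mosaic.channel_masks()

    def window_sum(a):
        return a[:-1, :-1] + a[:-1, 1:] + a[1:, :-1] + a[1:, 1:]

    g_sum = window_sum(np.where(is_g, v, 0.0))
    r_sum = window_sum(np.where(is_r, v, 0.0))
    b_sum = window_sum(np.where(is_b, v, 0.0))

    num = g_sum - r_sum - b_sum
    den = r_sum + g_sum / 2.0 + b_sum

    values = np.zeros_like(v)
    valid = np.zeros(v.shape, dtype=bool)
    ok = den > 0
    values[1:, 1:][ok] = num[ok] / den[ok]
    valid[1:, 1:] = ok
    return ExGMap(values=values, valid=valid)


def excess_green_from_rgb(rgb: np.ndarray) -> ExGMap:
    """Normalized excess green (2G - R - B)/(R + G + B) on a demosaiced image.

    An approximation of the mosaic-level index for when only demosaiced
    RGB is available.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ValueError("expected an H x W x 3 RGB image")
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    den = r + g + b
    ok = den > 0
    values = np.zeros(r.shape, dtype=float)
    values[ok] = (2 * g - r - b)[ok] / den[ok]
    return ExGMap(values=values, valid=ok)


def segment_fixed_threshold(exg: ExGMap, threshold: float = 0.1) -> VegetationMask:
    """Threshold an ExG map: vegetation iff valid and strictly above threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return VegetationMask(values=exg.valid & (exg.values > threshold))


@dataclass
class BayesSegmenter:
    """Per-pixel naive Bayes vegetation classifier (Gaussian per channel)."""

    _nb: GaussianNB = field(repr=False)

    @property
    def vegetation_prior(self) -> float:
        return float(self._nb.class_prior_[list(self._nb.classes_).index(1)])


def train_bayes_segmenter(rgb_pixels, labels) -> BayesSegmenter:
    """Fit the naive Bayes segmenter from labeled (R, G, B) pixels.

    ``labels`` entries are ``"veg"``/``"soil"`` (or truthy/falsy).  Both
    classes must be represented.
    """
    x = np.asarray(rgb_pixels, dtype=float).reshape(-1, 3)
    y = np.asarray([1 if (lab == "veg" or lab is True or lab == 1) else 0 for lab in labels])
    if x.shape[0] != y.shape[0]:
        raise ValueError("pixels and labels differ in length")
    if len(np.unique(y)) < 2:
        raise ValueError("both vegetation and soil examples are required")
    nb = GaussianNB()
    nb.fit(x, y)
    return BayesSegmenter(_nb=nb)


def segment_bayes(rgb_image: np.ndarray, model: BayesSegmenter) -> VegetationMask:
    """Classify every pixel of an H x W x 3 image: True where posterior(veg) wins."""
    rgb = np.asarray(rgb_image, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ValueError("expected an H x W x 3 RGB image")
    h, w = rgb.shape[:2]
    pred = model._nb.predict(rgb[..., :3].reshape(-1, 3))
    return VegetationMask(values=(pred == 1).reshape(h, w))


# ---------------------------------------------------------------------------
# I/O


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as a numpy array (grayscale 2-D or RGB 3-D)."""
    return np.asarray(iio.imread(path))


def read_mosaic(path, layout: str, bit_depth: int = 8) -> BayerMosaic:
    """Read a single-channel PNG/TIFF as a raw Bayer mosaic."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        raise ValueError("a raw mosaic must be single-channel")
    return BayerMosaic(values=arr, layout=layout, bit_depth=bit_depth)


def write_mask(path, mask: VegetationMask) -> None:
    """Write a vegetation mask as an 8-bit PNG (vegetation=255, soil=0)."""
    iio.imwrite(path, (np.asarray(mask.values, bool) * np.uint8(255)))
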