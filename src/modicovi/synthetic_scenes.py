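"""Synthetic plant scenes with exact per-pixel class labels.

Field imagery of maize and broadleaf weeds is emulated by compositing
parametric sprites onto a soil canvas:

* **monocot** sprites — long, gently curved ribbons of near-constant
  width tapering at the tip, caricaturing maize/grass leaves whose two
  long edges run near-parallel;
* **dicot** sprites — compact radially lobed blobs (smoothed polar
  perturbations of a disc), caricaturing broadleaf weed leaves whose
  edge orientations spread over all angles.

Sprites are minimal caricatures sufficient to reproduce the
monocot/dicot edge-pair fingerprint contrast, not botanical models.
Scenes are built by depth-ordered placement, so the visible class of
every pixel — and hence the true weed pixel count — is known exactly
even under overlap.  The default canvas is 512 x 512 at a nominal
2.4 px/mm, so the 125-px pair cutoff spans about 52 mm.

Calibration shapes (circle, line, square) provide analytic ground truth
for the edge and curvature pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

SOIL, MONOCOT, DICOT = 0, 1, 2
CLASS_NAMES = {SOIL: "soil", MONOCOT: "monocot", DICOT: "dicot"}

DEFAULT_CANVAS = (512, 512)
PX_PER_MM = 2.4


@dataclass
class Sprite:
    """A single annotated plant: boolean mask plus class label."""

    mask: np.ndarray
    cls: str  # "monocot" or "dicot"

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.cls not in ("monocot", "dicot"):
            raise ValueError("sprite class must be 'monocot' or 'dicot'")
        if not self.mask.any():
            raise ValueError("sprite mask is empty")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class Scene:
    """A composited scene with exact labels.

    label_map holds SOIL/MONOCOT/DICOT per pixel after depth-order
    overlap resolution; true_weed_pixels counts visible dicot pixels.
    """

    label_map: np.ndarray
    placements: list = field(default_factory=list)

    @property
    def veg_mask(self) -> np.ndarray:
        return self.label_map != SOIL

    @property
    def true_weed_pixels(self) -> int:
        return int(np.count_nonzero(self.label_map == DICOT))

    @property
    def true_total_veg_pixels(self) -> int:
        return int(np.count_nonzero(self.label_map != SOIL))


def _crop_to_content(mask: np.ndarray, margin: int = 1) -> np.ndarray:
    ys, xs = np.nonzero(mask)
    out = mask[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]
    return np.pad(out, margin)


def make_monocot(
    length_px: int = 200,
    width_px: int = 10,
    curvature: float = 0.002,
    rng_seed: int | None = None,
    taper_frac: float = 0.15,
) -> Sprite:
    """A ribbon leaf: near-constant width along a curved spine, tapered tip.

    ``curvature`` is the spine's turning rate in rad/px; 0 gives an
    axis-aligned ribbon whose two long edges are exactly parallel.  With
    a seed, a small smooth random wobble is added to the turning rate.
    """
    if length_px < 8 or width_px < 2:
        raise ValueError("leaf too small to rasterize")
    s = np.arange(length_px, dtype=float)
    turn = np.full(length_px, float(curvature))
    if rng_seed is not None:
        rng = np.random.default_rng(rng_seed)
        wobble = rng.normal(0.0, 0.3 * (abs(curvature) + 1e-3), size=length_px)
        turn = turn + ndimage.gaussian_filter1d(wobble, sigma=25.0)
    theta = np.concatenate([[0.0], np.cumsum(turn[:-1])])
    x = np.concatenate([[0.0], np.cumsum(np.cos(theta[:-1]))])
    y = np.concatenate([[0.0], np.cumsum(np.sin(theta[:-1]))])

    half = np.full(length_px, width_px / 2.0)
    n_tip = max(2, int(taper_frac * length_px))
    half[-n_tip:] = np.linspace(width_px / 2.0, 0.5, n_tip)
    nx, ny = -np.sin(theta), np.cos(theta)  # unit normal to the spine

    left_x, left_y = x + nx * half, y + ny * half
    right_x, right_y = x - nx * half, y - ny * half
    poly_x = np.concatenate([left_x, right_x[::-1]])
    poly_y = np.concatenate([left_y, right_y[::-1]])

    pad = width_px + 2
    poly_x = poly_x - poly_x.min() + pad
    poly_y = poly_y - poly_y.min() + pad
    h = int(np.ceil(poly_y.max())) + pad
    w = int(np.ceil(poly_x.max())) + pad
    mask = np.zeros((h, w), dtype=bool)
    rr, cc = draw_polygon(poly_y, poly_x, shape=mask.shape)
    mask[rr, cc] = True
    return Sprite(mask=_crop_to_content(mask), cls="monocot")


def make_dicot(
    radius_px: int = 30,
    n_lobes: int = 5,
    rng_seed: int | None = None,
    lobe_depth: float = 0.3,
) -> Sprite:
    """A compact lobed leaf: disc with a smooth polar radius perturbation.

    ``n_lobes = 0`` yields an exact rasterized disc.  With a seed, the
    lobe phase and a mild second harmonic are randomized.
    """
    if radius_px < 3:
        raise ValueError("radius too small to rasterize")
    phase, second = 0.0, 0.0
    if rng_seed is not None:
        rng = np.random.default_rng(rng_seed)
        phase = rng.uniform(0, 2 * np.pi)
        second = rng.uniform(0, 0.1)
    rmax = radius_px * (1.0 + lobe_depth + second) + 2
    n = int(np.ceil(rmax))
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1].astype(float)
    rho = np.hypot(xx, yy)
    phi = np.arctan2(yy, xx)
    if n_lobes == 0:
        boundary = float(radius_px)
    else:
        boundary = radius_px * (
            1.0 + lobe_depth * np.cos(n_lobes * phi + phase) + second * np.cos(2 * phi)
        )
    mask = rho <= boundary
    return Sprite(mask=_crop_to_content(mask), cls="dicot")


def make_calibration(kind: str, size: int, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Exact rasterization of an analytic shape for pipeline calibration.

    kind="circle": filled disc of radius ``size``; "square": filled
    axis-aligned square of side ``size``; "line": filled straight bar of
    length ``size`` and thickness max(3, size // 16).
    """
    if kind == "circle":
        shape = shape or (2 * size + 21, 2 * size + 21)
        mask = np.zeros(shape, dtype=bool)
        rr, cc = draw_disk((shape[0] // 2, shape[1] // 2), size, shape=shape)
        mask[rr, cc] = True
    elif kind == "square":
        shape = shape or (size + 20, size + 20)
        mask = np.zeros(shape, dtype=bool)
        r0 = (shape[0] - size) // 2
        c0 = (shape[1] - size) // 2
        mask[r0 : r0 + size, c0 : c0 + size] = True
    elif kind == "line":
        t = max(3, size // 16)
        shape = shape or (t + 20, size + 20)
        mask = np.zeros(shape, dtype=bool)
        r0 = (shape[0] - t) // 2
        c0 = (shape[1] - size) // 2
        mask[r0 : r0 + t, c0 : c0 + size] = True
    else:
        raise ValueError("kind must be one of: circle, line, square")
    return mask


def _rotate_sprite(mask: np.ndarray, angle_deg: float) -> np.ndarray:
    if angle_deg == 0.0:
        return mask
    rot = ndimage.rotate(mask.astype(np.uint8), angle_deg, reshape=True, order=0)
    rot = rot > 0
    return _crop_to_content(rot, margin=0) if rot.any() else mask


def compose(
    sprites: list[Sprite],
    canvas_shape: tuple[int, int] = DEFAULT_CANVAS,
    rng_seed: int | None = 0,
    rotate: bool = True,
) -> Scene:
    """Composite sprites onto a soil canvas in depth order (later = on top).

    Each sprite is rotated by a uniform random angle (if ``rotate``) and
    placed uniformly at random, rejecting placements that leave the
    canvas.  The label map records the visible (topmost) class per
    pixel, so overlap extents are exact.
    """
    h, w = canvas_shape
    if h <= 0 or w <= 0:
        raise ValueError("canvas must have positive area")
    rng = np.random.default_rng(rng_seed)
    label_map = np.zeros((h, w), dtype=np.uint8)
    placements = []
    for idx, sprite in enumerate(sprites):
        angle = float(rng.uniform(0, 360)) if rotate else 0.0
        mask = _rotate_sprite(sprite.mask, angle)
        sh, sw = mask.shape
        if sh > h or sw > w:
            raise ValueError(f"sprite {idx} ({sh}x{sw}) larger than canvas {h}x{w}")
        # uniform over all fully in-canvas placements (rejection-free form
        # of "reject when a sprite exits the canvas")
        r0 = int(rng.integers(0, h - sh + 1))
        c0 = int(rng.integers(0, w - sw + 1))
        cls_code = MONOCOT if sprite.cls == "monocot" else DICOT
        region = label_map[r0 : r0 + sh, c0 : c0 + sw]
        region[mask] = cls_code
        placements.append(
            {"sprite": idx, "cls": sprite.cls, "row": r0, "col": c0, "angle_deg": angle, "depth": idx}
        )
    return Scene(label_map=label_map, placements=placements)


def sprite_bank(
    rng_seed: int = 0,
    n_monocot: int = 8,
    n_dicot: int = 8,
) -> list[Sprite]:
    """A varied pool of annotated single plants at the nominal 2.4 px/mm scale.

    Monocot leaves: 150-260 px long (about 60-110 mm), 8-14 px wide.
    Dicot leaves: 20-40 px radius (about 8-17 mm), 4-7 lobes.
    """
    rng = np.random.default_rng(rng_seed)
    bank: list[Sprite] = []
    for _ in range(n_monocot):
        bank.append(
            make_monocot(
                length_px=int(rng.integers(150, 261)),
                width_px=int(rng.integers(8, 15)),
                curvature=float(rng.uniform(0.0005, 0.004)) * rng.choice([-1, 1]),
                rng_seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    for _ in range(n_dicot):
        bank.append(
            make_dicot(
                radius_px=int(rng.integers(20, 41)),
                n_lobes=int(rng.integers(4, 8)),
                rng_seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return bank


def random_scene(
    bank: list[Sprite],
    rng_seed: int,
    canvas_shape: tuple[int, int] = DEFAULT_CANVAS,
    max_monocots: int = 6,
    max_dicots: int = 6,
    rotate: bool = True,
) -> Scene:
    """A random field patch: 0..max of each class drawn from the bank."""
    rng = np.random.default_rng(rng_seed)
    monocots = [s for s in bank if s.cls == "monocot"]
    dicots = [s for s in bank if s.cls == "dicot"]
    chosen: list[Sprite] = []
    if monocots:
        chosen += [monocots[int(i)] for i in rng.integers(0, len(monocots), rng.integers(0, max_monocots + 1))]
    if dicots:
        chosen += [dicots[int(i)] for i in rng.integers(0, len(dicots), rng.integers(0, max_dicots + 1))]
    order = rng.permutation(len(chosen))
    chosen = [chosen[int(i)] for i in order]
    return compose(
        chosen,
        canvas_shape=canvas_shape,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
        rotate=rotate,
    )
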