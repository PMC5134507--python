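"""Gaussian density features over pair coordinates and the weed estimator.

The distribution of relative edge-pair coordinates is summarized by its
density near a set of interest points ("Gaussian features").  A feature
with center Fcntr and per-axis bandwidth Fsigma, both 5-vectors over
(dx, dy, dtheta, d, k), scores a scene's pair set {dP} as

    Gm = sum_over_pairs exp( - sum_over_axes ((dP - Fcntr) / Fsigma)^2 )

optionally divided by the number of pairs N.  The normalized form
measures a density ratio; the unnormalized form measures an absolute
pair density, appropriate when the photographed area is constant and
the target is weed amount per image rather than a weed/crop ratio.

The estimator is linear in the features,

    est = w1 G1 + w2 G2 + ... + wK GK      (K = 20 by default)

with features chosen from a pool of 450 random candidates by a
random-swap hill climb: start from a random K-subset, fit weights by
least squares, then repeatedly propose swapping one in-set feature for
one outside the set, keeping the swap only when the training MSE
strictly decreases.

Training scenes are composed artificially from annotated single-plant
sprites, so the visible weed pixel count of every scene — including
overlaps — is known exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import edge_extraction, pair_geometry, synthetic_scenes
from ._util import wrap_angle
from .pair_geometry import ANGLE_AXIS, PAIR_AXES

#: per-axis center sampling ranges: dx, dy in [-125, 125] px; dtheta in
#: (-pi, pi]; d in (0, 125] px; k in [0, 2] 1/px (k <= 2/d with d >= 1)
DEFAULT_RANGES = (
    (-125.0, 125.0),
    (-125.0, 125.0),
    (-np.pi, np.pi),
    (0.0, 125.0),
    (0.0, 2.0),
)
#: bandwidths are log-uniform between these fractions of each axis range
DEFAULT_BANDWIDTH_FRACTIONS = (0.01, 1.0)

DEFAULT_POOL_SIZE = 450
DEFAULT_K = 20
DEFAULT_ITERATIONS = 10_000


@dataclass
class GaussianFeature:
    """One kernel interest point in the 5-D pair-coordinate space."""

    center: np.ndarray
    bandwidth: np.ndarray

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(5)
        self.bandwidth = np.asarray(self.bandwidth, dtype=float).reshape(5)
        if np.any(self.bandwidth <= 0):
            raise ValueError("all bandwidth components must be positive")


@dataclass
class TrainingScene:
    """Pairs of one composed scene plus its exact pixel bookkeeping."""

    pairs: np.ndarray
    true_weed_pixels: int
    true_total_veg_pixels: int

    def __post_init__(self):
        if self.true_weed_pixels > self.true_total_veg_pixels:
            raise ValueError("weed pixels cannot exceed total vegetation pixels")


def _as_pair_array(pairs) -> np.ndarray:
    if isinstance(pairs, np.ndarray):
        return pairs.reshape(-1, 5)
    return np.asarray([tuple(p) for p in pairs], dtype=float).reshape(-1, 5)


def feature_value(pairs, feature: GaussianFeature, normalized: bool = False) -> float:
    """Evaluate one Gaussian feature on a pair set; empty set scores 0.

    The angular axis difference is wrapped to (-pi, pi] before scaling.
    """
    arr = _as_pair_array(pairs)
    n = arr.shape[0]
    if n == 0:
        return 0.0
    diff = arr - feature.center[None, :]
    diff[:, ANGLE_AXIS] = wrap_angle(diff[:, ANGLE_AXIS])
    z = (diff / feature.bandwidth[None, :]) ** 2
    total = float(np.exp(-z.sum(axis=1)).sum())
    return total / n if normalized else total


def feature_matrix(scenes_pairs, features, normalized: bool = False, chunk: int = 128) -> np.ndarray:
    """(n_scenes, n_features) matrix of feature values.

    Equivalent to calling :func:`feature_value` per scene and feature,
    but the squared Mahalanobis-like distance over the four linear axes
    is expanded into three matrix products; only the wrapped angular
    axis needs an explicit pairwise difference.
    """
    n_feat = len(features)
    centers = np.stack([f.center for f in features]) if n_feat else np.empty((0, 5))
    inv_b2 = (
        1.0 / np.stack([f.bandwidth for f in features]) ** 2 if n_feat else np.empty((0, 5))
    )
    lin = [a for a in range(5) if a != ANGLE_AXIS]
    if n_feat:
        centers = centers.copy()
        centers[:, ANGLE_AXIS] = wrap_angle(centers[:, ANGLE_AXIS])
    c_lin, ib_lin = centers[:, lin], inv_b2[:, lin]
    const_lin = (c_lin**2 * ib_lin).sum(axis=1)  # per feature

    out = np.zeros((len(scenes_pairs), n_feat), dtype=float)
    for si, pairs in enumerate(scenes_pairs):
        arr = _as_pair_array(pairs)
        n = arr.shape[0]
        if n == 0 or n_feat == 0:
            continue
        p_lin = arr[:, lin]
        p_ang = wrap_angle(arr[:, ANGLE_AXIS])
        for f0 in range(0, n_feat, chunk):
            sl = slice(f0, min(f0 + chunk, n_feat))
            z = (p_lin**2) @ ib_lin[sl].T
            z -= 2.0 * p_lin @ (c_lin[sl] * ib_lin[sl]).T
            z += const_lin[sl][None, :]
            # |wrapped difference|: both angles lie in (-pi, pi], so the
            # raw difference is in (-2pi, 2pi) and min(|da|, 2pi - |da|)
            # equals |wrap(da)| without a costly modulo
            da = np.abs(p_ang[:, None] - centers[sl, ANGLE_AXIS][None, :])
            np.minimum(da, 2.0 * np.pi - da, out=da)
            z += da * da * inv_b2[sl, ANGLE_AXIS][None, :]
            # tiny negative values can appear from cancellation in the expansion
            np.maximum(z, 0.0, out=z)
            vals = np.exp(-z).sum(axis=0)
            out[si, sl] = vals / n if normalized else vals
    return out


def sample_feature_pool(
    n: int = DEFAULT_POOL_SIZE,
    ranges=DEFAULT_RANGES,
    rng_seed: int | np.random.Generator | None = 0,
    bandwidth_fractions=DEFAULT_BANDWIDTH_FRACTIONS,
) -> list[GaussianFeature]:
    """Random feature candidates: uniform centers, log-uniform bandwidths.

    Bandwidths are drawn per axis, log-uniformly between
    ``bandwidth_fractions`` of the axis range width.
    """
    ranges = np.asarray(ranges, dtype=float)
    if ranges.shape != (5, 2) or np.any(ranges[:, 1] <= ranges[:, 0]):
        raise ValueError("ranges must be five finite (lo, hi) intervals with hi > lo")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    widths = ranges[:, 1] - ranges[:, 0]
    lo_f, hi_f = bandwidth_fractions
    pool = []
    for _ in range(n):
        center = rng.uniform(ranges[:, 0], ranges[:, 1])
        log_bw = rng.uniform(np.log(lo_f * widths), np.log(hi_f * widths))
        pool.append(GaussianFeature(center=center, bandwidth=np.exp(log_bw)))
    return pool


def scene_pairs(
    mask: np.ndarray,
    sigma: float = 2.0,
    mag_threshold: float | None = None,
    cell: int = 8,
    max_pair_dist: float = pair_geometry.DEFAULT_MAX_PAIR_DIST,
) -> np.ndarray:
    """Binary mask -> edge segments -> (M, 5) pair array (full edge pipeline)."""
    resp = edge_extraction.complex_edge_response(mask.astype(float), sigma=sigma)
    segments = edge_extraction.extract_edge_segments(resp, mag_threshold=mag_threshold, cell=cell)
    return pair_geometry.pair_array(segments, max_dist=max_pair_dist)


def compose_training_scenes(
    sprites,
    n_scenes: int,
    canvas_shape: tuple[int, int] = synthetic_scenes.DEFAULT_CANVAS,
    rng_seed: int = 0,
    max_monocots: int = 6,
    max_dicots: int = 6,
    rotate: bool = True,
) -> list[TrainingScene]:
    """Compose random scenes from annotated sprites and run the edge pipeline.

    ``sprites`` is a list of :class:`~modicovi.synthetic_scenes.Sprite`
    or (mask, cls) tuples containing at least one sprite of each class.
    """
    bank = [s if isinstance(s, synthetic_scenes.Sprite) else synthetic_scenes.Sprite(*s) for s in sprites]
    classes = {s.cls for s in bank}
    if classes != {"monocot", "dicot"}:
        raise ValueError("need at least one sprite of each class (monocot and dicot)")
    rng = np.random.default_rng(rng_seed)
    scenes = []
    for _ in range(n_scenes):
        scene = synthetic_scenes.random_scene(
            bank,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
            canvas_shape=canvas_shape,
            max_monocots=max_monocots,
            max_dicots=max_dicots,
            rotate=rotate,
        )
        total = scene.true_total_veg_pixels
        scenes.append(
            TrainingScene(
                pairs=scene_pairs(scene.veg_mask),
                true_weed_pixels=scene.true_weed_pixels,
                true_total_veg_pixels=max(total, 1),
            )
        )
    return scenes


@dataclass
class WeedModel:
    """Selected Gaussian features plus least-squares weights."""

    features: list[GaussianFeature]
    weights: np.ndarray
    intercept: float = 0.0
    normalized: bool = False
    target_mode: str = "area"  # "area": weed pixels per image; "ratio": weed/veg
    mse_trace: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        if len(self.features) != self.weights.size:
            raise ValueError("feature and weight counts differ")
        if self.target_mode not in ("area", "ratio"):
            raise ValueError("target_mode must be 'area' or 'ratio'")

    # -- persistence -------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "format": "modicovi-weed-model",
                "version": 1,
                "axes": list(PAIR_AXES),
                "features": [
                    {"center": f.center.tolist(), "bandwidth": f.bandwidth.tolist()}
                    for f in self.features
                ],
                "weights": self.weights.tolist(),
                "intercept": self.intercept,
                "normalized": self.normalized,
                "target_mode": self.target_mode,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "WeedModel":
        doc = json.loads(text)
        if doc.get("format") != "modicovi-weed-model" or doc.get("version") != 1:
            raise ValueError("not a recognized weed model document")
        return cls(
            features=[GaussianFeature(f["center"], f["bandwidth"]) for f in doc["features"]],
            weights=np.asarray(doc["weights"]),
            intercept=float(doc.get("intercept", 0.0)),
            normalized=bool(doc["normalized"]),
            target_mode=doc["target_mode"],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "WeedModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _fit_weights(g: np.ndarray, targets: np.ndarray, intercept: bool):
    """Minimum-norm least squares; returns (weights, intercept, mse)."""
    design = np.column_stack([g, np.ones(len(targets))]) if intercept else g
    coef, *_ = np.linalg.lstsq(design, targets, rcond=None)
    resid = design @ coef - targets
    mse = float(np.mean(resid**2))
    if intercept:
        return coef[:-1], float(coef[-1]), mse
    return coef, 0.0, mse


def _scene_targets(scenes, target_mode: str) -> np.ndarray:
    if target_mode == "area":
        return np.array([s.true_weed_pixels for s in scenes], dtype=float)
    return np.array(
        [s.true_weed_pixels / s.true_total_veg_pixels for s in scenes], dtype=float
    )


def select_features(
    pool,
    scenes,
    k: int = DEFAULT_K,
    iterations: int = DEFAULT_ITERATIONS,
    rng_seed: int = 0,
    normalized: bool = False,
    intercept: bool = False,
    target_mode: str = "area",
    precomputed_matrix: np.ndarray | None = None,
    targets: np.ndarray | None = None,
) -> WeedModel:
    """Random-swap feature-subset search with least-squares refits.

    The full pool's feature matrix is computed once; each proposal then
    refits only the selected columns.  A swap is kept iff the training
    MSE strictly decreases, so the accepted-MSE trace (stored on the
    returned model) is strictly decreasing.  ``targets`` overrides the
    regression targets derived from the scenes (the scenes then only
    supply pair sets).
    """
    pool = list(pool)
    if len(pool) < k:
        raise ValueError("pool smaller than the number of features to select")
    if targets is None:
        targets = _scene_targets(scenes, target_mode)
    targets = np.asarray(targets, dtype=float)
    g_all = (
        precomputed_matrix
        if precomputed_matrix is not None
        else feature_matrix([s.pairs for s in scenes], pool, normalized=normalized)
    )
    rng = np.random.default_rng(rng_seed)
    active = list(rng.choice(len(pool), size=k, replace=False))
    weights, icpt, best_mse = _fit_weights(g_all[:, active], targets, intercept)
    trace = [best_mse]
    if len(pool) > k:
        inactive = [i for i in range(len(pool)) if i not in set(active)]
        for _ in range(iterations):
            ai = int(rng.integers(0, k))
            bi = int(rng.integers(0, len(inactive)))
            candidate = active.copy()
            candidate[ai] = inactive[bi]
            w, c, mse = _fit_weights(g_all[:, candidate], targets, intercept)
            if mse < best_mse:
                inactive[bi] = active[ai]
                active = candidate
                weights, icpt, best_mse = w, c, mse
                trace.append(mse)
    return WeedModel(
        features=[pool[i] for i in active],
        weights=weights,
        intercept=icpt,
        normalized=normalized,
        target_mode=target_mode,
        mse_trace=trace,
    )


def predict(pairs, model: WeedModel) -> float:
    """Linear weed estimate for one scene's pair set.

    In ``area`` mode the value estimates visible weed pixels per image
    (the photographed area is constant); in ``ratio`` mode, the
    weed/vegetation ratio.
    """
    g = np.array([feature_value(pairs, f, normalized=model.normalized) for f in model.features])
    return float(model.intercept + g @ model.weights)
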