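"""End-to-end wiring: segment -> edges -> pairs -> features -> decision.

`run_pipeline` turns one image (or an already-binary scene mask) plus a
trained weed model into a per-frame report: the weed estimate, the
coverage percentage of the image, and the on/off decision at each
threshold level.  `simulate_trial` runs a desk-scale stand-in for the
field trial on synthetic plots and summarizes nozzle activity per
threshold level.  `train_weed_model` bundles sprite generation, scene
composition, feature-pool sampling and the swap search.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import density_model, edge_extraction, pair_geometry, segmentation, spray_decision, synthetic_scenes


@dataclass
class PipelineConfig:
    """Every tunable default of the pipeline, overridable per run."""

    exg_threshold: float = 0.1
    bayer_layout: str = "RGGB"
    edge_sigma: float = 2.0
    edge_mag_fraction: float = 0.2  # of max magnitude; None-able via absolute
    edge_mag_threshold: float | None = None
    subsample_cell: int = 8
    max_pair_dist: float = pair_geometry.DEFAULT_MAX_PAIR_DIST
    pool_size: int = density_model.DEFAULT_POOL_SIZE
    k_features: int = density_model.DEFAULT_K
    iterations: int = density_model.DEFAULT_ITERATIONS
    canvas: tuple[int, int] = synthetic_scenes.DEFAULT_CANVAS
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = open(path, "rb").read()
        if str(path).endswith(".toml"):
            import tomllib

            doc = tomllib.loads(text.decode())
        else:
            doc = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "canvas" in doc:
            doc["canvas"] = tuple(doc["canvas"])
        return cls(**doc)


def segment_image(image: np.ndarray, config: PipelineConfig, mode: str = "exg", bayes_model=None):
    """Image (mosaic 2-D or RGB 3-D) -> vegetation mask per the config."""
    if mode == "bayes":
        if bayes_model is None:
            raise ValueError("bayes mode requires a trained segmenter")
        return segmentation.segment_bayes(image, bayes_model)
    if image.ndim == 2:
        exg = segmentation.excess_green_from_bayer(
            segmentation.BayerMosaic(values=image, layout=config.bayer_layout,
                                     bit_depth=16 if image.max() > 255 else 8)
        )
    else:
        exg = segmentation.excess_green_from_rgb(image)
    return segmentation.segment_fixed_threshold(exg, config.exg_threshold)


def mask_to_segments(mask: np.ndarray, config: PipelineConfig):
    resp = edge_extraction.complex_edge_response(np.asarray(mask, float), sigma=config.edge_sigma)
    threshold = config.edge_mag_threshold
    if threshold is None:
        threshold = config.edge_mag_fraction * float(resp.magnitude.max())
    return edge_extraction.extract_edge_segments(resp, mag_threshold=threshold, cell=config.subsample_cell)


def mask_to_pairs(mask: np.ndarray, config: PipelineConfig) -> np.ndarray:
    return pair_geometry.pair_array(mask_to_segments(mask, config), max_dist=config.max_pair_dist)


@dataclass
class FrameReport:
    """Per-frame output of the pipeline."""

    estimate: float
    coverage_percent: float
    decisions: dict  # level name -> bool
    n_segments: int
    n_pairs: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(
    scene_mask: np.ndarray,
    model: density_model.WeedModel,
    config: PipelineConfig | None = None,
    thresholds: spray_decision.ThresholdTable | None = None,
) -> FrameReport:
    """Binary vegetation mask -> weed estimate and per-level decisions.

    The estimate is converted to percent of image area (area mode:
    estimated weed pixels / canvas pixels; ratio mode: the ratio itself
    as a percentage) and compared against every threshold level.
    """
    config = config or PipelineConfig()
    thresholds = thresholds or spray_decision.default_thresholds()
    mask = np.asarray(scene_mask, dtype=bool)
    segments = mask_to_segments(mask, config)
    pairs = pair_geometry.pair_array(segments, max_dist=config.max_pair_dist)
    estimate = density_model.predict(pairs, model) if pairs.size else 0.0
    estimate = max(estimate, 0.0)
    if model.target_mode == "area":
        coverage = 100.0 * estimate / mask.size
    else:
        coverage = 100.0 * estimate
    decisions = {
        f"M{i + 1}": spray_decision.spray_on(coverage, thr)
        for i, thr in enumerate(thresholds.coverage_thresholds)
    }
    return FrameReport(
        estimate=float(estimate),
        coverage_percent=float(coverage),
        decisions=decisions,
        n_segments=len(segments),
        n_pairs=int(pairs.shape[0]),
    )


def train_weed_model(
    seed: int = 0,
    n_scenes: int = 200,
    config: PipelineConfig | None = None,
    sprites=None,
    iterations: int | None = None,
    normalized: bool = False,
    target_mode: str = "area",
) -> tuple[density_model.WeedModel, list[density_model.TrainingScene]]:
    """Compose scenes, sample the feature pool, run the swap search."""
    config = config or PipelineConfig(seed=seed)
    rng = np.random.default_rng(seed)
    if sprites is None:
        sprites = synthetic_scenes.sprite_bank(rng_seed=int(rng.integers(0, 2**31 - 1)))
    scenes = density_model.compose_training_scenes(
        sprites, n_scenes=n_scenes, canvas_shape=config.canvas,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )
    pool = density_model.sample_feature_pool(
        n=config.pool_size, rng_seed=int(rng.integers(0, 2**31 - 1))
    )
    model = density_model.select_features(
        pool,
        scenes,
        k=config.k_features,
        iterations=iterations if iterations is not None else config.iterations,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
        normalized=normalized,
        target_mode=target_mode,
    )
    return model, scenes


def simulate_trial(
    n_plots: int,
    model: density_model.WeedModel,
    thresholds: spray_decision.ThresholdTable | None = None,
    rng_seed: int = 0,
    config: PipelineConfig | None = None,
    max_dicots: int = 10,
) -> pd.DataFrame:
    """Desk-scale trial stand-in: synthetic plots through the full pipeline.

    Each plot is one synthetic frame with a random weed load (0 to
    ``max_dicots`` dicots over a few monocot crop leaves).  Returns a
    per-plot table with the true weed pixels, the estimate, and the
    on/off decision per threshold level; mean nozzle activity per level
    is the column mean of the on/off indicators.
    """
    thresholds = thresholds or spray_decision.default_thresholds()
    config = config or PipelineConfig()
    rng = np.random.default_rng(rng_seed)
    bank = synthetic_scenes.sprite_bank(rng_seed=int(rng.integers(0, 2**31 - 1)))
    rows = []
    for plot in range(n_plots):
        scene = synthetic_scenes.random_scene(
            bank,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
            canvas_shape=config.canvas,
            max_monocots=4,
            max_dicots=max_dicots,
        )
        report = run_pipeline(scene.veg_mask, model, config, thresholds)
        row = {
            "plot_id": plot,
            "true_weed_pixels": scene.true_weed_pixels,
            "estimate": report.estimate,
            "coverage_percent": report.coverage_percent,
        }
        for name, on in report.decisions.items():
            row[f"on_{name}"] = bool(on)
        rows.append(row)
    return pd.DataFrame(rows)


def nozzle_activity(trial: pd.DataFrame) -> dict:
    """Mean on-fraction per threshold level from a simulate_trial table."""
    return {
        col.removeprefix("on_"): float(trial[col].mean())
        for col in trial.columns
        if col.startswith("on_")
    }
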