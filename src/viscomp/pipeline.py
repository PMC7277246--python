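"""End-to-end synthetic replication: simulate -> rate -> features -> fit -> parts.

One call runs the full pipeline on synthetic data at a configurable scale
and writes a JSON report of every summary statistic together with the
exact configuration (and its hash) that produced it.  Re-running with the
same seed reproduces the report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .design import DesignSpec, generate_design, participation_counts
from .errors import ViscompError
from .features import FeatureConfig, extract_all
from .models import ModelConfig, correlation_metrics, fit_feature_models
from .parts import disc_grid_centers, part_whole_predictors, rate_discs
from .rating import RatingConfig, consistency_score, rate_comparisons
from .simulate import (
    LatentWorld,
    ObserverModel,
    SyntheticImageSpec,
    generate_image,
    sample_latent,
    simulate_comparisons,
)

__all__ = ["ReplicationConfig", "run_synthetic_replication"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReplicationConfig:
    """Scales and noise levels of the synthetic replication.

    The whole-image stage defaults to the full experimental scale: 4000
    items, 75,020 balanced comparisons over 62 observers, latent scores
    ~ Normal(25.0, 5.5).  Observer noise sd 2.0 (score units) gives a
    mostly-consistent but imperfect synthetic observer.  The feature and
    part-whole substudies run at fixed desk scale independent of the main
    stage.
    """

    n_items: int = 4000
    n_comparisons: int = 75_020
    n_observers: int = 62
    score_mean: float = 25.0
    score_sd: float = 5.5
    observer_noise_sd: float = 2.0
    lapse_rate: float = 0.0
    seed: int = 0
    # feature substudy
    n_feature_images: int = 48
    feature_comparisons_per_image: int = 30
    image_width: int = 96
    image_height: int = 72
    # part-whole substudy (latent-level, on a 375x500 disc grid)
    n_part_images: int = 20
    part_image_shape: tuple[int, int] = (375, 500)
    disc_radius: int = 50
    disc_comparisons_per_disc: int = 25
    run_features: bool = True
    run_parts: bool = True


def _config_hash(config: ReplicationConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ViscompError:
                raise
            except Exception as exc:  # annotate unexpected failures with the stage
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


@_stage("rate")
def _rating_stage(config: ReplicationConfig) -> dict:
    world = sample_latent(
        config.n_items, config.score_mean, config.score_sd, seed=config.seed
    )
    design = generate_design(
        DesignSpec(
            n_items=config.n_items,
            n_comparisons=config.n_comparisons,
            n_observers=config.n_observers,
            seed=config.seed + 1,
            item_ids=world.items(),
        )
    )
    observer = ObserverModel(
        noise_sd=config.observer_noise_sd, lapse_rate=config.lapse_rate
    )
    records = simulate_comparisons(world, design, observer, seed=config.seed + 2)
    table = rate_comparisons(
        records, RatingConfig(shuffle_seed=config.seed + 3), items=world.items()
    )
    mus = np.array([table[i].mu for i in world.items()])
    latents = np.array([world.scores[i] for i in world.items()])
    counts = np.array(list(participation_counts(records).values()))
    r, rho = correlation_metrics(latents, mus)
    return {
        "n_items": config.n_items,
        "n_comparisons": len(records),
        "mean_participation": float(counts.mean()),
        "participation_spread": int(counts.max() - counts.min()),
        "mean_mu": float(mus.mean()),
        "sd_mu": float(mus.std()),
        "consistency": consistency_score(records, table),
        "recovery_pearson_r": r,
        "recovery_spearman_rho": rho,
        "epochs_run": len(table.epoch_trace),
        "epoch_trace": [float(d) for d in table.epoch_trace],
    }


@_stage("features")
def _feature_stage(config: ReplicationConfig) -> dict:
    rng = np.random.default_rng(config.seed + 10)
    images = {}
    latents = {}
    for i in range(config.n_feature_images):
        n_shapes = int(rng.integers(0, 24))
        spec = SyntheticImageSpec(
            width=config.image_width,
            height=config.image_height,
            n_shapes=n_shapes,
            palette_size=int(rng.integers(2, 9)),
            texture_noise_sd=float(rng.uniform(0.0, 0.08)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        image_id = f"img{i:04d}"
        images[image_id], _ = generate_image(spec, image_id=image_id)
        # latent complexity driven by shape count plus rating-scale noise
        latents[image_id] = 18.0 + 0.8 * n_shapes + float(rng.normal(0, 1.0))
    world = LatentWorld(scores=latents, score_mean=config.score_mean, score_sd=config.score_sd)
    design = DesignSpec(
        n_items=len(images),
        n_comparisons=config.feature_comparisons_per_image * len(images) // 2,
        n_observers=4,
        seed=config.seed + 11,
        item_ids=list(images),
    )
    records = simulate_comparisons(
        world, design, ObserverModel(noise_sd=config.observer_noise_sd), seed=config.seed + 12
    )
    table = rate_comparisons(records, RatingConfig(shuffle_seed=config.seed + 13))
    ratings = {i: table[i].mu for i in images}
    frame = extract_all(images, FeatureConfig())
    # ridge rather than plain OLS: at desk scale the image count is close to
    # the feature count, where unregularised least squares is ill-posed
    fit = fit_feature_models(
        frame, ratings, ModelConfig(model_kind="ridge", cv_scheme="loo", seed=config.seed)
    )
    return {
        "n_images": len(images),
        "n_features": int(frame.shape[1]),
        "loo_pearson_r": fit.pearson_r,
        "loo_spearman_rho": fit.spearman_rho,
    }


@_stage("parts")
def _parts_stage(config: ReplicationConfig) -> dict:
    rng = np.random.default_rng(config.seed + 20)
    rows, cols = disc_grid_centers(config.part_image_shape, config.disc_radius)
    discs_per_image = len(rows) * len(cols)
    disc_latents: dict[str, float] = {}
    disc_to_image: dict[str, str] = {}
    whole_latents: dict[str, float] = {}
    # hierarchical latents: each image has its own complexity level and its
    # discs scatter around it (within-image sd = half the between-image sd);
    # the whole-image latent is the disc mean plus judgement-level noise
    for i in range(config.n_part_images):
        image_id = f"part{i:04d}"
        level = float(rng.normal(config.score_mean, config.score_sd))
        members = []
        for d in range(discs_per_image):
            disc_id = f"{image_id}_d{d:03d}"
            disc_latents[disc_id] = level + float(rng.normal(0, 0.5 * config.score_sd))
            disc_to_image[disc_id] = image_id
            members.append(disc_latents[disc_id])
        whole_latents[image_id] = float(
            np.mean(members) + rng.normal(0, 0.5 * config.score_sd)
        )

    disc_world = LatentWorld(scores=disc_latents)
    n_discs = len(disc_latents)
    disc_design = DesignSpec(
        n_items=n_discs,
        n_comparisons=config.disc_comparisons_per_disc * n_discs // 2,
        n_observers=8,
        seed=config.seed + 21,
        item_ids=list(disc_latents),
    )
    disc_records = simulate_comparisons(
        disc_world, disc_design, ObserverModel(noise_sd=config.observer_noise_sd),
        seed=config.seed + 22,
    )
    disc_table = rate_discs(disc_records, RatingConfig(shuffle_seed=config.seed + 23))
    disc_mus = {d: disc_table[d].mu for d in disc_latents}
    mean_pred, sum_pred, comparable = part_whole_predictors(disc_mus, disc_to_image)

    whole_world = LatentWorld(scores=whole_latents)
    whole_design = DesignSpec(
        n_items=len(whole_latents),
        n_comparisons=40 * len(whole_latents) // 2,
        n_observers=4,
        seed=config.seed + 24,
        item_ids=list(whole_latents),
    )
    whole_records = simulate_comparisons(
        whole_world, whole_design, ObserverModel(noise_sd=config.observer_noise_sd),
        seed=config.seed + 25,
    )
    whole_table = rate_comparisons(whole_records, RatingConfig(shuffle_seed=config.seed + 26))
    image_ids = list(whole_latents)
    whole_mus = [whole_table[i].mu for i in image_ids]
    r_mean, _ = correlation_metrics([mean_pred[i] for i in image_ids], whole_mus)
    r_sum, _ = correlation_metrics([sum_pred[i] for i in image_ids], whole_mus)
    return {
        "n_part_images": config.n_part_images,
        "discs_per_image": discs_per_image,
        "n_discs": n_discs,
        "sums_comparable": comparable,
        "r_mean_predictor": r_mean,
        "r_sum_predictor": r_sum,
        "disc_recovery_spearman": correlation_metrics(
            [disc_latents[d] for d in disc_latents], [disc_mus[d] for d in disc_latents]
        )[1],
    }


def run_synthetic_replication(
    config: ReplicationConfig | None = None, out: str | Path | None = None
) -> dict:
    """Execute the full synthetic pipeline and return (optionally write) the report."""
    config = config or ReplicationConfig()
    report: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": _config_hash(config),
    }
    logger.info("replication %s: rating stage", report["config_hash"])
    report["ratings"] = _rating_stage(config)
    if config.run_features:
        logger.info("replication %s: feature stage", report["config_hash"])
        report["features"] = _feature_stage(config)
    if config.run_parts:
        logger.info("replication %s: part-whole stage", report["config_hash"])
        report["part_whole"] = _parts_stage(config)
    if out is not None:
        Path(out).write_text(json.dumps(report, indent=1, default=list))
    return report
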