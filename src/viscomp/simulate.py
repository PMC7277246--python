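"""Synthetic observers, latent complexity worlds, and procedural tagged images.

The simulator stands in for a human 2AFC experiment: latent per-item
complexity scores are drawn from a normal distribution (mean 25.0,
sd 5.5 by default, matching the empirical distribution the rating engine is
expected to reproduce), and each simulated choice follows a Thurstone
Case V model — both items evoke an internal value corrupted by independent
Gaussian noise, so P(choose A) = Phi((s_A - s_B) / (sqrt(2) * noise_sd)),
optionally mixed with a uniform lapse.

Procedural images have known complexity drivers (shape count, palette size,
texture noise) and carry one bounding-box tag per shape, so every
downstream stage (features, tag predictors, disc analysis) can be exercised
against a known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import ndtr
from skimage.draw import ellipse as _ellipse
from skimage.draw import polygon as _polygon

from .design import ComparisonRecord, DesignSpec, generate_design
from .errors import ValidationError
from .tags import ObjectTag

__all__ = [
    "LatentWorld",
    "ObserverModel",
    "SyntheticImageSpec",
    "VOC_CLASSES",
    "sample_latent",
    "choice_probability",
    "simulate_choice",
    "simulate_comparisons",
    "generate_image",
]

# the 20-class vocabulary of the VOC-style annotation format
VOC_CLASSES = (
    "person", "bird", "cat", "cow", "dog", "horse", "sheep",
    "aeroplane", "bicycle", "boat", "bus", "car", "motorbike", "train",
    "bottle", "chair", "diningtable", "pottedplant", "sofa", "tvmonitor",
)

DEFAULT_SCORE_MEAN = 25.0
DEFAULT_SCORE_SD = 5.5


@dataclass(frozen=True)
class LatentWorld:
    """Ground-truth complexity scores; used only by the simulator."""

    scores: dict[str, float]
    score_mean: float = DEFAULT_SCORE_MEAN
    score_sd: float = DEFAULT_SCORE_SD

    def __post_init__(self) -> None:
        if not (self.score_sd > 0):
            raise ValidationError("score_sd must be > 0")

    def items(self) -> list[str]:
        return list(self.scores)


@dataclass(frozen=True)
class ObserverModel:
    """Thurstonian observer: perceptual noise sd plus a uniform lapse rate."""

    noise_sd: float = 0.0
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not (0.0 <= self.lapse_rate <= 1.0):
            raise ValidationError("lapse_rate must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Procedural image: shapes from a colour palette over a textured background."""

    width: int = 128
    height: int = 96
    n_shapes: int = 8
    palette_size: int = 6
    texture_noise_sd: float = 0.02
    seed: int = 0
    palette: Sequence[Sequence[float]] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.width < 8 or self.height < 8:
            raise ValidationError("width and height must both be >= 8")
        if self.n_shapes < 0:
            raise ValidationError("n_shapes must be >= 0")
        if self.palette_size < 1:
            raise ValidationError("palette_size must be >= 1")
        if not (0.0 <= self.texture_noise_sd <= 1.0):
            raise ValidationError("texture_noise_sd must be in [0, 1]")


def sample_latent(
    n_items: int,
    mean: float = DEFAULT_SCORE_MEAN,
    sd: float = DEFAULT_SCORE_SD,
    seed: int = 0,
    item_ids: Sequence[str] | None = None,
) -> LatentWorld:
    """Draw latent complexity scores ~ Normal(mean, sd) for n_items items."""
    if n_items <= 0:
        raise ValidationError("n_items must be positive")
    if not (sd > 0):
        raise ValidationError("sd must be > 0")
    rng = np.random.default_rng(seed)
    if item_ids is None:
        width = max(4, len(str(n_items - 1)))
        item_ids = [f"item{i:0{width}d}" for i in range(n_items)]
    elif len(item_ids) != n_items:
        raise ValidationError("item_ids length must equal n_items")
    values = rng.normal(mean, sd, size=n_items)
    return LatentWorld(
        scores=dict(zip(item_ids, values.tolist())), score_mean=mean, score_sd=sd
    )


def choice_probability(score_a: float, score_b: float, obs: ObserverModel) -> float:
    """P(choose A) under Thurstone Case V with a lapse mixture."""
    if obs.noise_sd == 0:
        if score_a == score_b:
            p = 0.5
        else:
            p = 1.0 if score_a > score_b else 0.0
    else:
        p = float(ndtr((score_a - score_b) / (math.sqrt(2.0) * obs.noise_sd)))
    return obs.lapse_rate * 0.5 + (1.0 - obs.lapse_rate) * p


def simulate_choice(
    score_a: float, score_b: float, obs: ObserverModel, rng: np.random.Generator
) -> int:
    """Simulate one 2AFC trial; returns 0 if side A is chosen, 1 for side B."""
    return 0 if rng.random() < choice_probability(score_a, score_b, obs) else 1


def simulate_comparisons(
    world: LatentWorld,
    design: Sequence[ComparisonRecord] | DesignSpec,
    observers: ObserverModel | Mapping[str, ObserverModel],
    seed: int = 0,
) -> list[ComparisonRecord]:
    """Fill in the chosen field of every design record via simulated observers.

    ``observers`` is either one model shared by everyone or a mapping from
    observer id to model.  Deterministic for a given seed.
    """
    if isinstance(design, DesignSpec):
        design = generate_design(design)
    rng = np.random.default_rng(seed)
    out: list[ComparisonRecord] = []
    for rec in design:
        for item in (rec.item_a, rec.item_b):
            if item not in world.scores:
                raise ValidationError(f"item {item!r} is not in the latent world")
        if isinstance(observers, ObserverModel):
            obs = observers
        else:
            try:
                obs = observers[rec.observer_id]
            except KeyError:
                raise ValidationError(f"no observer model for {rec.observer_id!r}") from None
        side = simulate_choice(world.scores[rec.item_a], world.scores[rec.item_b], obs, rng)
        out.append(rec.with_choice(rec.item_a if side == 0 else rec.item_b))
    return out


def _random_palette(rng: np.random.Generator, size: int) -> np.ndarray:
    # saturated-ish colours so palette size shows up in colour statistics
    return rng.uniform(0.05, 0.95, size=(size, 3))


def generate_image(spec: SyntheticImageSpec, image_id: str = "synthetic") -> tuple[np.ndarray, list[ObjectTag]]:
    """Render a procedural RGB image in [0,1] with one bounding-box tag per shape.

    Background is mid-gray plus Gaussian texture noise; each shape is a
    random ellipse or polygon filled with a palette colour.  Shape classes
    are drawn from the 20-name VOC vocabulary.  Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    image = np.full((h, w, 3), 0.5, dtype=np.float64)
    if spec.texture_noise_sd > 0:
        image += rng.normal(0.0, spec.texture_noise_sd, size=(h, w, 3))
    palette = (
        np.asarray(spec.palette, dtype=np.float64)
        if spec.palette is not None
        else _random_palette(rng, spec.palette_size)
    )
    tags: list[ObjectTag] = []
    min_dim = min(h, w)
    for _ in range(spec.n_shapes):
        colour = palette[rng.integers(len(palette))]
        cls = VOC_CLASSES[rng.integers(len(VOC_CLASSES))]
        cy = rng.uniform(0.1 * h, 0.9 * h)
        cx = rng.uniform(0.1 * w, 0.9 * w)
        if rng.random() < 0.5:
            ry = rng.uniform(min_dim / 16, min_dim / 5)
            rx = rng.uniform(min_dim / 16, min_dim / 5)
            rr, cc = _ellipse(cy, cx, ry, rx, shape=(h, w))
        else:
            n_vert = int(rng.integers(3, 7))
            radius = rng.uniform(min_dim / 12, min_dim / 4, size=n_vert)
            angles = np.sort(rng.uniform(0, 2 * np.pi, size=n_vert))
            rows = np.clip(cy + radius * np.sin(angles), 0, h - 1)
            cols = np.clip(cx + radius * np.cos(angles), 0, w - 1)
            rr, cc = _polygon(rows, cols, shape=(h, w))
        if rr.size == 0:
            # degenerate draw entirely off-raster: fall back to a 2x2 patch
            r0 = int(np.clip(cy, 0, h - 2))
            c0 = int(np.clip(cx, 0, w - 2))
            rr, cc = np.mgrid[r0 : r0 + 2, c0 : c0 + 2]
            rr, cc = rr.ravel(), cc.ravel()
        image[rr, cc] = colour
        tags.append(
            ObjectTag(
                image_id=image_id,
                class_name=cls,
                bbox=(int(cc.min()), int(rr.min()), int(cc.max()) + 1, int(rr.max()) + 1),
            )
        )
    return np.clip(image, 0.0, 1.0), tags
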