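"""Part-whole complexity analysis: disc decomposition, maps, and predictors.

Whole images are split into overlapping discs of radius 50 pixels — small
enough that most objects span several discs — which can be rated by the
same 2AFC machinery as whole images.  Disc ratings are interpolated into
dense per-pixel complexity maps and aggregated (mean, sum) into
predictors of the whole image's rating.  Validation splits are grouped by
source image so no image contributes discs to both sides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.interpolate import RectBivariateSpline, RegularGridInterpolator

from .design import ComparisonRecord
from .errors import ValidationError
from .rating import RatingConfig, RatingTable, rate_comparisons

__all__ = [
    "DiscSpec",
    "decompose_discs",
    "rate_discs",
    "complexity_map",
    "part_whole_predictors",
    "grouped_split",
    "disc_grid_centers",
]

DEFAULT_RADIUS = 50
STRIDE_FACTOR = 1.2  # stride = round(1.2 * radius) -> overlapping discs


@dataclass(frozen=True)
class DiscSpec:
    """One disc: source image, 0-based (row, col) centre, and radius."""

    image_id: str
    center: tuple[int, int]
    radius: int = DEFAULT_RADIUS
    disc_id: str | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError("disc radius must be positive")


def _axis_centers(dim: int, radius: int, stride: int) -> list[int]:
    if dim > 2 * radius:
        return list(range(radius, dim - radius + 1, stride))
    # image no wider than the disc: one clamped centre
    return [(dim - 1) // 2]


def disc_grid_centers(
    shape: tuple[int, int], radius: int = DEFAULT_RADIUS
) -> tuple[list[int], list[int]]:
    """Row and column centre coordinates of the disc grid for an image shape."""
    stride = round(STRIDE_FACTOR * radius)
    return _axis_centers(shape[0], radius, stride), _axis_centers(shape[1], radius, stride)


def decompose_discs(
    image: np.ndarray, radius: int = DEFAULT_RADIUS, image_id: str = "image"
) -> list[tuple[DiscSpec, np.ndarray]]:
    """Split an image into overlapping discs on a square grid.

    Centres run from ``radius`` to ``dim - radius`` at stride
    round(1.2*radius) (so neighbouring discs overlap); a dimension smaller
    than the disc collapses to a single centred disc.  Each extracted
    raster is the square crop around the centre with pixels outside the
    disc masked to mid-gray (0.5), so feature extraction on discs is
    well-defined.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = image[..., None]
    h, w = image.shape[:2]
    rows, cols = disc_grid_centers((h, w), radius)
    side = 2 * radius + 1
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    disc_mask = (yy**2 + xx**2) <= radius**2

    out: list[tuple[DiscSpec, np.ndarray]] = []
    index = 0
    for r in rows:
        for c in cols:
            patch = np.full((side, side, image.shape[2]), 0.5)
            r0, r1 = max(r - radius, 0), min(r + radius + 1, h)
            c0, c1 = max(c - radius, 0), min(c + radius + 1, w)
            pr0, pc0 = r0 - (r - radius), c0 - (c - radius)
            patch[pr0 : pr0 + (r1 - r0), pc0 : pc0 + (c1 - c0)] = image[r0:r1, c0:c1]
            patch[~disc_mask] = 0.5
            spec = DiscSpec(
                image_id=image_id,
                center=(r, c),
                radius=radius,
                disc_id=f"{image_id}_d{index:03d}",
            )
            out.append((spec, patch.squeeze()))
            index += 1
    return out


def rate_discs(
    comparisons: list[ComparisonRecord],
    cfg: RatingConfig | None = None,
    discs: list[str] | None = None,
) -> RatingTable:
    """Rate disc comparisons; identical contract to whole-image rating."""
    return rate_comparisons(comparisons, cfg, items=discs)


def complexity_map(
    ratings: Mapping[str, float] | Sequence[float],
    centers: Sequence[tuple[int, int]],
    image_shape: tuple[int, int],
    disc_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Dense per-pixel complexity surface interpolated from disc ratings.

    The disc centres must form a rectangular grid (as produced by
    :func:`decompose_discs`).  Interpolation is bicubic when both axes have
    at least 4 centres, otherwise bilinear (with a warning); pixels beyond
    the outermost centres take the boundary value.  The surface passes
    through each disc's rating at its centre.
    """
    import warnings

    if isinstance(ratings, Mapping):
        if disc_ids is None:
            raise ValidationError("mapping ratings need disc_ids aligned with centers")
        try:
            values = [float(ratings[d]) for d in disc_ids]
        except KeyError as exc:
            raise ValidationError(f"no rating for disc {exc.args[0]!r}") from None
    else:
        values = [float(v) for v in ratings]
    if len(values) != len(centers):
        raise ValidationError(
            f"{len(values)} ratings but {len(centers)} centers"
        )

    rows = sorted({r for r, _ in centers})
    cols = sorted({c for _, c in centers})
    if len(rows) * len(cols) != len(centers):
        raise ValidationError("disc centers do not form a rectangular grid")
    grid = np.full((len(rows), len(cols)), np.nan)
    row_pos = {r: i for i, r in enumerate(rows)}
    col_pos = {c: j for j, c in enumerate(cols)}
    for (r, c), v in zip(centers, values):
        grid[row_pos[r], col_pos[c]] = v
    if np.isnan(grid).any():
        raise ValidationError("disc centers do not cover the full grid")

    h, w = image_shape
    if len(rows) == 1 and len(cols) == 1:
        return np.full((h, w), grid[0, 0])

    bicubic = len(rows) >= 4 and len(cols) >= 4
    if not bicubic:
        warnings.warn("fewer than 4 centers per axis: bilinear fallback for complexity map")
    # degenerate single row/col: extend to 2 identical lines so the
    # interpolator stays 2-D
    gr, gc = list(rows), list(cols)
    g = grid
    if len(gr) == 1:
        gr = [gr[0] - 1, gr[0] + 1]
        g = np.vstack([g, g])
    if len(gc) == 1:
        gc = [gc[0] - 1, gc[0] + 1]
        g = np.hstack([g, g])
    # edge pixels beyond the outermost centers take the boundary value
    rr = np.clip(np.arange(h, dtype=float), gr[0], gr[-1])
    cc = np.clip(np.arange(w, dtype=float), gc[0], gc[-1])
    if bicubic:
        spline = RectBivariateSpline(
            np.asarray(gr, float), np.asarray(gc, float), g, kx=3, ky=3, s=0
        )
        return spline(rr, cc)
    interp = RegularGridInterpolator(
        (np.asarray(gr, dtype=float), np.asarray(gc, dtype=float)),
        g, method="linear", bounds_error=False, fill_value=None,
    )
    pts = np.stack(np.meshgrid(rr, cc, indexing="ij"), axis=-1).reshape(-1, 2)
    return interp(pts).reshape(h, w)


def part_whole_predictors(
    disc_ratings: Mapping[str, float],
    disc_to_image: Mapping[str, str],
) -> tuple[dict[str, float], dict[str, float], bool]:
    """Mean and summed disc ratings per image.

    Returns ``(mean_rating, sum_rating, sums_comparable)``;
    ``sums_comparable`` is False when images have unequal disc counts, in
    which case the summed predictor confounds complexity with image size
    and should only be compared within same-size image groups.
    """
    grouped: dict[str, list[float]] = {}
    for disc_id, rating in disc_ratings.items():
        if disc_id not in disc_to_image:
            raise ValidationError(f"disc {disc_id!r} is not assigned to an image")
        grouped.setdefault(disc_to_image[disc_id], []).append(float(rating))
    mean_rating = {img: float(np.mean(v)) for img, v in grouped.items()}
    sum_rating = {img: float(np.sum(v)) for img, v in grouped.items()}
    counts = {len(v) for v in grouped.values()}
    return mean_rating, sum_rating, len(counts) <= 1


def grouped_split(
    discs: Sequence[str] | Mapping[str, str],
    holdout_fraction: float = 0.1,
    seed: int = 0,
    disc_to_image: Mapping[str, str] | None = None,
) -> tuple[list[str], list[str]]:
    """Split discs into train/validation by holding out whole images.

    The held-out fraction applies to the images, not the discs: validation
    contains all and only the discs of the held-out images, so nothing in
    validation shares a source image with training.  At least one image is
    always held out; deterministic per seed.
    """
    if isinstance(discs, Mapping):
        disc_to_image = discs
        disc_list = list(discs)
    else:
        if disc_to_image is None:
            raise ValidationError("grouped_split needs a disc -> image mapping")
        disc_list = list(discs)
    images = sorted({disc_to_image[d] for d in disc_list})
    if len(images) < 2:
        raise ValidationError("grouped_split needs at least 2 source images")
    rng = np.random.default_rng(seed)
    shuffled = list(images)
    rng.shuffle(shuffled)
    n_holdout = max(1, round(holdout_fraction * len(images)))
    held = set(shuffled[:n_holdout])
    train = [d for d in disc_list if disc_to_image[d] not in held]
    valid = [d for d in disc_list if disc_to_image[d] in held]
    return train, valid
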