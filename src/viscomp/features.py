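"""Scalar image statistics used as complexity predictors.

The battery covers grey-level co-occurrence texture, colour statistics in
CIELAB, channel entropies and variances, feature-congestion clutter,
edge/compression/spectral structure, and keypoint/region counts.  Features
needing trained models (deep salience, detector object counts, search RTs)
are never computed here; they are merged from external CSV columns.

All computed features are deterministic functions of the pixel array and
the configuration: identical pixels give bitwise-identical values
regardless of the file container they came from.
"""

from __future__ import annotations

import io
import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pywt
from PIL import Image
from scipy.ndimage import gaussian_filter, uniform_filter
from skimage import color as skcolor
from skimage import feature as skfeature
from skimage import measure as skmeasure
from skimage import transform as sktransform
from sklearn.cluster import MeanShift

from .errors import ValidationError

__all__ = [
    "FeatureConfig",
    "luminance",
    "glcm_features",
    "colour_features",
    "entropy_variance_features",
    "clutter_features",
    "structure_features",
    "count_features",
    "image_features",
    "extract_all",
    "ImageFeatureExtractor",
    "COMPUTED_FEATURES",
]

logger = logging.getLogger(__name__)

# canonical order of the computed columns
COMPUTED_FEATURES = [
    "glcm_contrast", "glcm_correlation", "glcm_energy", "glcm_homogeneity",
    "colourfulness", "colour_count", "colour_harmony",
    "entropy_r", "entropy_g", "entropy_b", "entropy_h", "entropy_s", "entropy_v",
    "variance_all", "variance_r", "variance_g", "variance_b",
    "contrast_clutter_mean", "contrast_clutter_var", "colour_clutter", "subband_entropy",
    "sift_count", "surf_count", "mser_count", "meanshift_region_count",
    "mean_luminance", "image_size", "whole_entropy",
    "frequency_factor", "edge_density", "jpeg_ratio",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs of the feature battery.

    Canny thresholds/sigma follow the convention of the complexity
    literature ([0.11, 0.27], sigma 1 on the luminance channel); GLCM uses
    8 grey levels at offset (0,1), symmetric and normalised; entropies use
    256 bins on [0,1]; JPEG ratio compares 3 bytes/pixel to quality-75 JPEG
    bytes; clutter pools over 3 Gaussian-pyramid scales; colour count bins
    CIELAB at 10-unit width.
    """

    glcm_levels: int = 8
    glcm_offset: tuple[int, int] = (0, 1)
    entropy_bins: int = 256
    canny_low: float = 0.11
    canny_high: float = 0.27
    canny_sigma: float = 1.0
    jpeg_quality: int = 75
    clutter_scales: int = 3
    clutter_window: int = 5
    colour_bin_width: float = 10.0
    colour_count_min_fraction: float = 1e-4
    wavelet: str = "db4"
    wavelet_levels: int = 3
    meanshift_max_px: int = 48
    meanshift_bandwidth: float = 14.0
    mser_delta_levels: int = 8
    mser_min_area: int = 25
    mser_max_area_fraction: float = 0.9
    mser_stability: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.canny_low < self.canny_high < 1):
            raise ValidationError("need 0 < canny_low < canny_high < 1")
        if self.glcm_levels < 2:
            raise ValidationError("glcm_levels must be >= 2")


def _as_float_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.dtype == np.uint8:
        image = image.astype(np.float64) / 255.0
    else:
        image = image.astype(np.float64)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    if image.ndim != 3 or image.shape[-1] < 3:
        raise ValidationError(f"expected an RGB raster, got shape {image.shape}")
    return np.clip(image[..., :3], 0.0, 1.0)


def luminance(image: np.ndarray) -> np.ndarray:
    """Rec.601 luma: 0.299 R + 0.587 G + 0.114 B on [0,1] floats."""
    rgb = _as_float_rgb(image)
    return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


def _hist_entropy(values: np.ndarray, bins: int, value_range=(0.0, 1.0)) -> float:
    """Shannon entropy (bits) of a fixed-range histogram; 0*log0 := 0."""
    hist, _ = np.histogram(values.ravel(), bins=bins, range=value_range)
    p = hist[hist > 0] / values.size
    return max(0.0, float(-(p * np.log2(p)).sum()))


# ---------------------------------------------------------------------------
# grey-level co-occurrence


def glcm_features(image: np.ndarray, cfg: FeatureConfig | None = None) -> dict[str, float]:
    """Contrast, correlation, energy, homogeneity of the symmetric GLCM.

    Luminance is quantised uniformly into ``glcm_levels`` bins; the
    co-occurrence matrix at offset (0,1) is symmetrised and normalised.
    Energy is the angular second moment (sum of squared probabilities), so a
    constant image scores exactly 1.  Correlation of a constant image is
    undefined and returned as 0 with a warning.
    """
    cfg = cfg or FeatureConfig()
    lum = luminance(image)
    levels = cfg.glcm_levels
    quant = np.clip((lum * levels).astype(np.uint8), 0, levels - 1)
    dr, dc = cfg.glcm_offset
    distance = math.hypot(dr, dc)
    angle = math.atan2(-dr, dc)
    glcm = skfeature.graycomatrix(
        quant, distances=[distance], angles=[angle], levels=levels,
        symmetric=True, normed=True,
    )
    p = glcm[:, :, 0, 0]
    i = np.arange(levels, dtype=np.float64)
    contrast = float((p * (i[:, None] - i[None, :]) ** 2).sum())
    energy = float((p**2).sum())
    homogeneity = float((p / (1.0 + np.abs(i[:, None] - i[None, :]))).sum())
    mu_i = float((p.sum(axis=1) * i).sum())
    var_i = float((p.sum(axis=1) * (i - mu_i) ** 2).sum())
    if var_i <= 0:
        warnings.warn("GLCM correlation undefined for a constant image; returning 0")
        correlation = 0.0
    else:
        correlation = float(
            ((i[:, None] - mu_i) * (i[None, :] - mu_i) * p).sum() / var_i
        )
    return {
        "glcm_contrast": contrast,
        "glcm_correlation": correlation,
        "glcm_energy": energy,
        "glcm_homogeneity": homogeneity,
    }


# ---------------------------------------------------------------------------
# colour

_HARMONY_TEMPLATES = (
    # arcs on the hue circle as (centre offset, width) in radians
    ((0.0, math.radians(18)),),                                  # i
    ((0.0, math.radians(94)),),                                  # V
    ((0.0, math.radians(180)),),                                 # T
    ((0.0, math.radians(18)), (math.pi, math.radians(18))),      # I
    ((0.0, math.radians(94)), (math.pi, math.radians(94))),      # X
    ((0.0, math.radians(94)), (math.pi, math.radians(18))),      # Y
)


def colour_features(image: np.ndarray, cfg: FeatureConfig | None = None) -> dict[str, float]:
    """Colourfulness, colour count, and a hue-template harmony score.

    Colourfulness combines chroma spread and mean in CIELAB:
    sqrt(sigma_a^2 + sigma_b^2) + 0.3 * sqrt(mu_a^2 + mu_b^2).  Colour count
    is the number of occupied CIELAB bins (10-unit cubes) holding at least
    0.01% of the pixels.  Harmony is the best chroma-weighted fit of the hue
    histogram to a small set of rotatable harmonic arc templates, in [0,1];
    a zero-chroma (grey) image is trivially harmonious (1).
    """
    cfg = cfg or FeatureConfig()
    rgb = _as_float_rgb(image)
    lab = skcolor.rgb2lab(rgb)
    a = lab[..., 1].ravel()
    b = lab[..., 2].ravel()
    colourfulness = float(
        math.sqrt(a.std() ** 2 + b.std() ** 2) + 0.3 * math.hypot(a.mean(), b.mean())
    )
    # the sRGB->Lab conversion leaves ~1e-3 chroma residue on neutral greys;
    # anything below a hundredth of a Lab unit is achromatic
    if colourfulness < 0.01:
        colourfulness = 0.0

    width = cfg.colour_bin_width
    bins_l = np.floor(lab[..., 0].ravel() / width)
    bins_a = np.floor(a / width)
    bins_b = np.floor(b / width)
    codes = (bins_l * 1000 + bins_a) * 1000 + bins_b
    _, counts = np.unique(codes, return_counts=True)
    threshold = max(1.0, cfg.colour_count_min_fraction * a.size)
    colour_count = float((counts >= threshold).sum())

    chroma = np.hypot(a, b)
    total_chroma = chroma.sum()
    if total_chroma <= 1e-9:
        harmony = 1.0
    else:
        hue = np.arctan2(b, a)
        best = 0.0
        rotations = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        for template in _HARMONY_TEMPLATES:
            for rot in rotations:
                inside = np.zeros_like(hue, dtype=bool)
                for centre, arc_width in template:
                    diff = np.angle(np.exp(1j * (hue - centre - rot)))
                    inside |= np.abs(diff) <= arc_width / 2.0
                best = max(best, float(chroma[inside].sum() / total_chroma))
        harmony = best
    return {
        "colourfulness": colourfulness,
        "colour_count": colour_count,
        "colour_harmony": harmony,
    }


# ---------------------------------------------------------------------------
# entropies & variances


def entropy_variance_features(
    image: np.ndarray, cfg: FeatureConfig | None = None
) -> dict[str, float]:
    """Channel entropies (R,G,B,H,S,V, whole), variances, luminance, size."""
    cfg = cfg or FeatureConfig()
    rgb = _as_float_rgb(image)
    hsv = skcolor.rgb2hsv(rgb)
    bins = cfg.entropy_bins
    out = {
        "entropy_r": _hist_entropy(rgb[..., 0], bins),
        "entropy_g": _hist_entropy(rgb[..., 1], bins),
        "entropy_b": _hist_entropy(rgb[..., 2], bins),
        "entropy_h": _hist_entropy(hsv[..., 0], bins),
        "entropy_s": _hist_entropy(hsv[..., 1], bins),
        "entropy_v": _hist_entropy(hsv[..., 2], bins),
        "whole_entropy": _hist_entropy(rgb, bins),
        "variance_all": float(rgb.var()),
        "variance_r": float(rgb[..., 0].var()),
        "variance_g": float(rgb[..., 1].var()),
        "variance_b": float(rgb[..., 2].var()),
        "mean_luminance": float(luminance(rgb).mean()),
        "image_size": float(rgb.shape[0] * rgb.shape[1]),
    }
    return out


# ---------------------------------------------------------------------------
# feature-congestion clutter


def _local_moments(x: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    m = uniform_filter(x, size=window, mode="reflect")
    m2 = uniform_filter(x * x, size=window, mode="reflect")
    var = m2 - m * m
    var[var < 1e-9] = 0.0
    return m, var


def clutter_features(image: np.ndarray, cfg: FeatureConfig | None = None) -> dict[str, float]:
    """Feature-congestion style clutter statistics.

    Colour clutter pools, over a Gaussian pyramid, the local CIELAB (a,b)
    covariance "volume" sqrt(det) per pixel.  Contrast clutter is the local
    standard deviation of a band-pass (difference-of-Gaussians) luminance
    response, summarised by its mean and variance over pixels and scales.
    Subband entropy is the mean fixed-bin-width Shannon entropy of the
    detail subbands of a 3-level wavelet decomposition.  All four are
    exactly zero for a constant image, and the colour terms vanish on any
    achromatic image.
    """
    cfg = cfg or FeatureConfig()
    rgb = _as_float_rgb(image)
    lab = skcolor.rgb2lab(rgb)

    colour_maps: list[np.ndarray] = []
    contrast_values: list[np.ndarray] = []
    current = lab
    scales_used = 0
    for scale in range(cfg.clutter_scales):
        if min(current.shape[:2]) < 2 * cfg.clutter_window:
            if scale == 0:
                warnings.warn("image too small for clutter pyramid; single scale used")
            break
        a_ch, b_ch, l_ch = current[..., 1], current[..., 2], current[..., 0]
        _, var_a = _local_moments(a_ch, cfg.clutter_window)
        _, var_b = _local_moments(b_ch, cfg.clutter_window)
        m_ab = uniform_filter(a_ch * b_ch, size=cfg.clutter_window, mode="reflect")
        m_a = uniform_filter(a_ch, size=cfg.clutter_window, mode="reflect")
        m_b = uniform_filter(b_ch, size=cfg.clutter_window, mode="reflect")
        cov = m_ab - m_a * m_b
        det = var_a * var_b - cov * cov
        det[det < 1e-9] = 0.0
        colour_maps.append(np.sqrt(det))

        bandpass = gaussian_filter(l_ch, 1.0, mode="reflect") - gaussian_filter(
            l_ch, 3.0, mode="reflect"
        )
        _, var_c = _local_moments(bandpass, cfg.clutter_window)
        contrast_values.append(np.sqrt(var_c).ravel())

        scales_used += 1
        current = sktransform.rescale(
            current, 0.5, channel_axis=-1, anti_aliasing=True, mode="reflect"
        )

    if scales_used == 0:  # degenerate tiny image
        colour_clutter = 0.0
        contrast_mean = 0.0
        contrast_var = 0.0
    else:
        colour_clutter = float(np.mean([m.mean() for m in colour_maps]))
        pooled = np.concatenate(contrast_values)
        contrast_mean = float(pooled.mean())
        contrast_var = float(pooled.var())

    lum = luminance(rgb)
    max_level = pywt.dwtn_max_level(lum.shape, cfg.wavelet)
    levels = min(cfg.wavelet_levels, max(max_level, 1))
    coeffs = pywt.wavedec2(lum, cfg.wavelet, level=levels)
    entropies = []
    bin_width = 1.0 / 256.0
    for detail in coeffs[1:]:
        for band in detail:
            span = float(band.max() - band.min())
            if span < bin_width:
                entropies.append(0.0)
                continue
            n_bins = min(int(math.ceil(span / bin_width)), 4096)
            hist, _ = np.histogram(band.ravel(), bins=n_bins)
            p = hist[hist > 0] / band.size
            entropies.append(float(-(p * np.log2(p)).sum()))
    subband_entropy = float(np.mean(entropies)) if entropies else 0.0

    return {
        "colour_clutter": colour_clutter,
        "contrast_clutter_mean": contrast_mean,
        "contrast_clutter_var": contrast_var,
        "subband_entropy": subband_entropy,
    }


# ---------------------------------------------------------------------------
# structure: edges, compression, spectrum


def structure_features(image: np.ndarray, cfg: FeatureConfig | None = None) -> dict[str, float]:
    """Edge density, JPEG compression ratio, and the 99%-energy frequency factor.

    Edge density is the fraction of Canny edge pixels on the luminance
    channel.  JPEG ratio divides the uncompressed size (3 bytes/pixel) by
    the JPEG byte count at the configured quality.  The frequency factor is
    the radial spatial frequency (cycles/pixel) below which 99% of the FFT
    power (DC included) lies, divided by the Nyquist frequency 0.5 and
    clipped to [0,1]; a constant image has all power at DC and scores 0.
    """
    cfg = cfg or FeatureConfig()
    rgb = _as_float_rgb(image)
    lum = luminance(rgb)

    if lum.max() - lum.min() < 1e-12:
        edge_density = 0.0  # Canny on a constant image is trivially edge-free
    else:
        edges = skfeature.canny(
            lum, sigma=cfg.canny_sigma,
            low_threshold=cfg.canny_low, high_threshold=cfg.canny_high,
        )
        edge_density = float(edges.mean())

    pil = Image.fromarray((rgb * 255.0 + 0.5).astype(np.uint8))
    buf = io.BytesIO()
    pil.save(buf, format="JPEG", quality=cfg.jpeg_quality)
    jpeg_ratio = float(3 * lum.size / len(buf.getvalue()))

    power = np.abs(np.fft.fft2(lum)) ** 2
    fy = np.fft.fftfreq(lum.shape[0])
    fx = np.fft.fftfreq(lum.shape[1])
    radius = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    order = np.argsort(radius, axis=None, kind="stable")
    cumulative = np.cumsum(power.ravel()[order])
    total = cumulative[-1]
    if total <= 0:
        frequency_factor = 0.0
    else:
        idx = int(np.searchsorted(cumulative, 0.99 * total))
        r99 = float(radius.ravel()[order][min(idx, radius.size - 1)])
        frequency_factor = min(r99 / 0.5, 1.0)

    return {
        "edge_density": edge_density,
        "jpeg_ratio": jpeg_ratio,
        "frequency_factor": frequency_factor,
    }


# ---------------------------------------------------------------------------
# keypoint / region counts


def _stable_region_count(lum: np.ndarray, cfg: FeatureConfig) -> int:
    """MSER-style count: extremal regions stable across a threshold ladder.

    For both polarities the luminance is swept with a ladder of thresholds;
    a connected component at level t counts as a stable region if the
    component holding the same seed pixel at the next level has a relative
    area change below ``mser_stability``.  Near-full-frame and tiny
    components are excluded.
    """
    g = np.clip((lum * 255.0), 0, 255).astype(np.uint8)
    n_px = g.size
    max_area = cfg.mser_max_area_fraction * n_px
    step = max(256 // (cfg.mser_delta_levels * 2), 8)
    thresholds = list(range(step, 256, step))
    count = 0
    for polarity in (0, 1):
        field = g if polarity == 0 else (255 - g)
        labels_per_t = [skmeasure.label(field <= t, connectivity=2) for t in thresholds]
        for i in range(len(thresholds) - 1):
            lab_now, lab_next = labels_per_t[i], labels_per_t[i + 1]
            if lab_now.max() == 0:
                continue
            areas_now = np.bincount(lab_now.ravel())
            areas_next = np.bincount(lab_next.ravel())
            for region_id in range(1, lab_now.max() + 1):
                area = areas_now[region_id]
                if area < cfg.mser_min_area or area > max_area:
                    continue
                seed = np.argwhere(lab_now == region_id)[0]
                next_id = lab_next[seed[0], seed[1]]
                if next_id == 0:
                    continue
                growth = abs(int(areas_next[next_id]) - int(area)) / area
                if growth <= cfg.mser_stability and areas_next[next_id] <= max_area:
                    count += 1
    return count


def _meanshift_regions(rgb: np.ndarray, cfg: FeatureConfig) -> int:
    """Region count of a mean-shift segmentation on a downscaled CIELAB raster."""
    scale = cfg.meanshift_max_px / max(rgb.shape[:2])
    small = (
        sktransform.rescale(rgb, scale, channel_axis=-1, anti_aliasing=True)
        if scale < 1.0
        else rgb
    )
    lab = skcolor.rgb2lab(np.clip(small, 0, 1))
    X = lab.reshape(-1, 3)
    if np.allclose(X, X[0], atol=1e-6):
        return 1
    ms = MeanShift(bandwidth=cfg.meanshift_bandwidth, bin_seeding=True)
    labels = ms.fit_predict(X).reshape(lab.shape[:2])
    n_regions = 0
    for cluster in np.unique(labels):
        n_regions += int(skmeasure.label(labels == cluster, connectivity=2).max())
    return n_regions


def count_features(
    image: np.ndarray,
    backend: str = "reference",
    cfg: FeatureConfig | None = None,
    external: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Keypoint and region counts.

    The ``reference`` backend is self-contained: difference-of-Gaussians
    keypoints (a multiscale SIFT-style detector for ``sift_count`` and a
    blob detector for ``surf_count``), a stable-threshold extremal-region
    counter (``mser_count``), and mean-shift segmentation on a downscaled
    CIELAB raster (``meanshift_region_count``).  The ``external`` backend
    reads the four counts from a supplied mapping instead.
    """
    cfg = cfg or FeatureConfig()
    keys = ("sift_count", "surf_count", "mser_count", "meanshift_region_count")
    if backend == "external":
        if external is None:
            raise ValidationError("external backend needs an `external` mapping")
        missing = [k for k in keys if k not in external]
        if missing:
            raise ValidationError(f"external counts missing: {missing}")
        return {k: float(external[k]) for k in keys}
    if backend != "reference":
        raise ValidationError(f"unknown count backend {backend!r}")

    rgb = _as_float_rgb(image)
    lum = luminance(rgb)
    if lum.max() - lum.min() < 1e-12:
        return {
            "sift_count": 0.0, "surf_count": 0.0,
            "mser_count": 0.0, "meanshift_region_count": 1.0,
        }

    try:
        sift = skfeature.SIFT()
        sift.detect(lum)
        sift_count = float(len(sift.keypoints))
    except RuntimeError:  # featureless image
        sift_count = 0.0
    blobs = skfeature.blob_dog(lum, min_sigma=1.0, max_sigma=10.0, threshold=0.02)
    surf_count = float(len(blobs))
    mser_count = float(_stable_region_count(lum, cfg))
    region_count = float(_meanshift_regions(rgb, cfg))
    return {
        "sift_count": sift_count,
        "surf_count": surf_count,
        "mser_count": mser_count,
        "meanshift_region_count": region_count,
    }


# ---------------------------------------------------------------------------
# full battery


def image_features(
    image: np.ndarray, cfg: FeatureConfig | None = None, backend: str = "reference"
) -> dict[str, float]:
    """All computed features for one image, in canonical column order."""
    cfg = cfg or FeatureConfig()
    row: dict[str, float] = {}
    row.update(glcm_features(image, cfg))
    row.update(colour_features(image, cfg))
    row.update(entropy_variance_features(image, cfg))
    row.update(clutter_features(image, cfg))
    row.update(count_features(image, backend=backend, cfg=cfg))
    row.update(structure_features(image, cfg))
    return {name: row[name] for name in COMPUTED_FEATURES}


def _load_image(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def extract_all(
    images: str | Path | Mapping[str, np.ndarray],
    cfg: FeatureConfig | None = None,
    backend: str = "reference",
    external_csv: str | Path | pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Feature table: one row per image, computed columns plus external ones.

    ``images`` is a directory of PNG/JPEG/BMP files (ids are file stems) or
    a mapping id -> array.  External columns (e.g. object_count, salience
    statistics, search RTs) are merged by image id; values missing for an
    image stay as NaN, never silent zeros.  Unreadable image files are
    skipped with a log message; a duplicate id in the external table is an
    error.
    """
    cfg = cfg or FeatureConfig()
    rows: dict[str, dict[str, float]] = {}
    if isinstance(images, (str, Path)):
        image_dir = Path(images)
        if not image_dir.is_dir():
            raise ValidationError(f"{image_dir} is not a directory")
        paths = sorted(
            p for p in image_dir.iterdir()
            if p.suffix.lower() in {".png", ".jpg", ".jpeg", ".bmp"}
        )
        for path in paths:
            try:
                array = _load_image(path)
            except OSError as exc:
                logger.warning("skipping unreadable image %s: %s", path, exc)
                continue
            rows[path.stem] = image_features(array, cfg, backend=backend)
    else:
        for image_id, array in images.items():
            rows[image_id] = image_features(array, cfg, backend=backend)

    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "image_id"

    if external_csv is not None:
        ext = (
            external_csv
            if isinstance(external_csv, pd.DataFrame)
            else pd.read_csv(external_csv)
        )
        if "image_id" in ext.columns:
            ext = ext.set_index("image_id")
        if ext.index.has_duplicates:
            dupes = ext.index[ext.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate image ids in external features: {dupes}")
        frame = frame.join(ext, how="left")
    return frame


class ImageFeatureExtractor:
    """sklearn-style transformer over the feature battery.

    ``transform`` accepts a mapping id -> RGB array, a list of arrays, or an
    image directory, and returns the feature DataFrame.  Stateless: ``fit``
    is a no-op kept for pipeline compatibility.
    """

    def __init__(self, config: FeatureConfig | None = None, backend: str = "reference"):
        self.config = config
        self.backend = backend

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config, "backend": self.backend}

    def set_params(self, **params) -> "ImageFeatureExtractor":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValidationError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X=None, y=None) -> "ImageFeatureExtractor":
        return self

    def transform(self, X) -> pd.DataFrame:
        cfg = self.config or FeatureConfig()
        if isinstance(X, (str, Path, Mapping)):
            return extract_all(X, cfg, backend=self.backend)
        rows = {f"image{i:04d}": img for i, img in enumerate(X)}
        return extract_all(rows, cfg, backend=self.backend)

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X, y).transform(X)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(COMPUTED_FEATURES, dtype=object)
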