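"""Feature battery identities, determinism, and direction checks."""

import numpy as np
import pytest
from PIL import Image
from scipy.stats import spearmanr

from viscomp.errors import ValidationError
from viscomp.features import (
    COMPUTED_FEATURES,
    FeatureConfig,
    ImageFeatureExtractor,
    clutter_features,
    colour_features,
    count_features,
    entropy_variance_features,
    extract_all,
    glcm_features,
    image_features,
    structure_features,
)
from viscomp.simulate import SyntheticImageSpec, generate_image


@pytest.fixture(scope="module")
def constant_image():
    return np.full((64, 64, 3), 0.5)


@pytest.fixture(scope="module")
def shapes_image():
    image, _ = generate_image(SyntheticImageSpec(width=96, height=72, n_shapes=10, seed=2))
    return image


class TestGLCM:
    def test_constant_image_identities(self, constant_image):
        with pytest.warns(UserWarning, match="correlation"):
            f = glcm_features(constant_image)
        assert f["glcm_contrast"] == 0.0
        assert f["glcm_energy"] == 1.0
        assert f["glcm_homogeneity"] == 1.0
        assert f["glcm_correlation"] == 0.0  # undefined -> flagged 0

    def test_checkerboard_two_levels(self):
        # 1-px checkerboard at 2 levels: co-occurrences are all (0,1)/(1,0)
        board = np.indices((16, 16)).sum(axis=0) % 2
        image = np.stack([board.astype(float)] * 3, axis=-1)
        f = glcm_features(image, FeatureConfig(glcm_levels=2))
        assert f["glcm_contrast"] == pytest.approx(1.0)
        assert f["glcm_energy"] == pytest.approx(0.5)
        assert f["glcm_homogeneity"] == pytest.approx(0.5)

    def test_energy_bounded_by_one(self, shapes_image):
        assert 0 < glcm_features(shapes_image)["glcm_energy"] <= 1


class TestColour:
    def test_grayscale_has_zero_colourfulness(self):
        gray = np.stack([np.linspace(0, 1, 64).reshape(8, 8)] * 3, axis=-1)
        f = colour_features(gray)
        assert f["colourfulness"] == 0.0

    def test_two_distant_colours_count_two(self):
        image = np.zeros((20, 20, 3))
        image[:, :10] = [1.0, 0.0, 0.0]
        image[:, 10:] = [0.0, 0.0, 1.0]
        assert colour_features(image)["colour_count"] == 2.0

    def test_uniform_hue_colourfulness_is_mean_term_only(self):
        image = np.zeros((16, 16, 3))
        image[...] = [0.8, 0.2, 0.2]
        from skimage.color import rgb2lab

        lab = rgb2lab(image)
        expected = 0.3 * np.hypot(lab[..., 1].mean(), lab[..., 2].mean())
        assert colour_features(image)["colourfulness"] == pytest.approx(expected, abs=1e-6)


class TestEntropyVariance:
    def test_constant_image_all_zero(self, constant_image):
        f = entropy_variance_features(constant_image)
        for key in ("entropy_r", "entropy_g", "entropy_b", "entropy_h",
                    "entropy_s", "entropy_v", "whole_entropy",
                    "variance_all", "variance_r", "variance_g", "variance_b"):
            assert f[key] == 0.0
        assert f["mean_luminance"] == pytest.approx(0.5)

    def test_two_equiprobable_levels_one_bit(self):
        image = np.zeros((10, 10, 3))
        image[:, 5:] = 1.0
        f = entropy_variance_features(image)
        assert f["whole_entropy"] == pytest.approx(1.0)
        assert f["entropy_r"] == pytest.approx(1.0)

    def test_pixel_count(self):
        f = entropy_variance_features(np.zeros((375, 500, 3)))
        assert f["image_size"] == 187_500.0


class TestClutter:
    def test_constant_image_all_zero(self, constant_image):
        f = clutter_features(constant_image)
        assert f["colour_clutter"] == 0.0
        assert f["contrast_clutter_mean"] == 0.0
        assert f["contrast_clutter_var"] == 0.0
        assert f["subband_entropy"] == 0.0

    def test_grayscale_has_zero_colour_clutter(self):
        rng = np.random.default_rng(0)
        gray = np.stack([rng.random((48, 48))] * 3, axis=-1)
        assert clutter_features(gray)["colour_clutter"] == 0.0

    def test_subband_entropy_grows_with_texture_noise(self):
        """Doubling generator texture noise raises mean subband entropy."""
        def mean_entropy(noise):
            vals = []
            for seed in range(20):
                image, _ = generate_image(
                    SyntheticImageSpec(width=64, height=64, n_shapes=0,
                                       texture_noise_sd=noise, seed=seed)
                )
                vals.append(clutter_features(image)["subband_entropy"])
            return float(np.mean(vals))

        assert mean_entropy(0.08) > mean_entropy(0.04)


class TestStructure:
    def test_constant_image(self, constant_image):
        f = structure_features(constant_image)
        assert f["edge_density"] == 0.0
        assert f["frequency_factor"] == 0.0

    def test_jpeg_compresses_constant_better_than_noise(self, rng):
        const = np.full((64, 64, 3), 0.5)
        noise = rng.random((64, 64, 3))
        assert (
            structure_features(const)["jpeg_ratio"]
            > structure_features(noise)["jpeg_ratio"]
        )
        assert structure_features(const)["jpeg_ratio"] >= 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_white_noise_frequency_factor_high(self, seed):
        noise = np.random.default_rng(seed).random((64, 64, 3))
        assert structure_features(noise)["frequency_factor"] >= 0.9

    def test_edge_density_bounded(self, shapes_image):
        assert 0 <= structure_features(shapes_image)["edge_density"] <= 1


class TestCounts:
    def test_constant_image(self, constant_image):
        f = count_features(constant_image)
        assert f["sift_count"] == 0.0
        assert f["surf_count"] == 0.0
        assert f["meanshift_region_count"] == 1.0

    def test_unknown_backend_rejected(self, constant_image):
        with pytest.raises(ValidationError, match="backend"):
            count_features(constant_image, backend="magic")

    def test_external_backend_requires_all_counts(self, constant_image):
        with pytest.raises(ValidationError, match="missing"):
            count_features(constant_image, backend="external", external={"sift_count": 1})
        f = count_features(
            constant_image, backend="external",
            external={"sift_count": 3, "surf_count": 4, "mser_count": 5,
                      "meanshift_region_count": 6},
        )
        assert f["mser_count"] == 5.0

    def test_more_shapes_more_regions(self):
        """10 shapes vs 1 shape: region counters should average higher."""
        mser = {1: [], 10: []}
        regions = {1: [], 10: []}
        for n_shapes in (1, 10):
            for seed in range(20):
                image, _ = generate_image(
                    SyntheticImageSpec(width=80, height=60, n_shapes=n_shapes,
                                       palette_size=8, texture_noise_sd=0.0, seed=seed)
                )
                f = count_features(image)
                mser[n_shapes].append(f["mser_count"])
                regions[n_shapes].append(f["meanshift_region_count"])
        assert np.mean(mser[10]) > np.mean(mser[1])
        assert np.mean(regions[10]) > np.mean(regions[1])


class TestBattery:
    def test_deterministic_bitwise(self, shapes_image):
        f1 = image_features(shapes_image)
        f2 = image_features(shapes_image)
        assert f1 == f2
        assert list(f1) == COMPUTED_FEATURES

    def test_container_invariance(self, shapes_image, tmp_path):
        """Identical pixels through PNG and BMP give identical features."""
        pixels = (shapes_image * 255 + 0.5).astype(np.uint8)
        Image.fromarray(pixels).save(tmp_path / "img.png")
        Image.fromarray(pixels).save(tmp_path / "img.bmp")
        png = image_features(np.asarray(Image.open(tmp_path / "img.png")))
        bmp = image_features(np.asarray(Image.open(tmp_path / "img.bmp")))
        assert png == bmp

    def test_shape_and_palette_correlations_positive(self):
        """Edge density tracks shape count; colour count tracks palette size."""
        rng = np.random.default_rng(7)
        edge, shapes = [], []
        for seed in range(20):
            n_shapes = int(rng.integers(0, 30))
            image, _ = generate_image(
                SyntheticImageSpec(width=80, height=60, n_shapes=n_shapes,
                                   palette_size=8, seed=seed)
            )
            edge.append(structure_features(image)["edge_density"])
            shapes.append(n_shapes)
        assert spearmanr(edge, shapes).statistic > 0

        colours, palettes = [], []
        for seed in range(20):
            palette = int(rng.integers(1, 10))
            image, _ = generate_image(
                SyntheticImageSpec(width=80, height=60, n_shapes=12,
                                   palette_size=palette, texture_noise_sd=0.0,
                                   seed=seed)
            )
            colours.append(colour_features(image)["colour_count"])
            palettes.append(palette)
        assert spearmanr(colours, palettes).statistic > 0

    def test_extract_all_with_external_columns(self, tmp_path):
        images = {}
        for i in range(3):
            image, _ = generate_image(SyntheticImageSpec(width=48, height=48,
                                                         n_shapes=3, seed=i))
            images[f"img{i}"] = image
        external = tmp_path / "external.csv"
        external.write_text("image_id,object_count\nimg0,4\nimg1,2\n")
        frame = extract_all(images, external_csv=external)
        assert frame.shape[0] == 3
        assert "object_count" in frame.columns
        assert frame.loc["img0", "object_count"] == 4
        assert np.isnan(frame.loc["img2", "object_count"])  # explicit null
        assert np.isfinite(frame[COMPUTED_FEATURES].to_numpy()).all()

    def test_duplicate_external_id_rejected(self, tmp_path):
        image, _ = generate_image(SyntheticImageSpec(width=48, height=48, seed=0))
        external = tmp_path / "dup.csv"
        external.write_text("image_id,object_count\nimg0,1\nimg0,2\n")
        with pytest.raises(ValidationError, match="duplicate"):
            extract_all({"img0": image}, external_csv=external)

    def test_transformer_interface(self, shapes_image):
        ext = ImageFeatureExtractor()
        frame = ext.fit_transform([shapes_image])
        assert frame.shape == (1, len(COMPUTED_FEATURES))
        assert list(ext.get_feature_names_out()) == COMPUTED_FEATURES
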