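"""Feature blocks vs hand computations and brute-force oracles."""

import colorsys

import numpy as np
import pandas as pd
import pytest
from skimage.feature import graycomatrix, graycoprops

from grainscan.errors import (
    EmptyPairsError,
    InvalidDistributionError,
    InvalidRegionError,
)
from grainscan.features import (
    ANGLE_OFFSETS,
    FeatureConfig,
    GEOMETRY_NAMES,
    build_feature_table,
    channel_histograms,
    feature_registry,
    feature_vector,
    geometry_features,
    glcm,
    glcm_stats,
    rgb_to_hsv,
    save_feature_table,
    texture_features,
    trace_contour,
)
from grainscan.contours import contour_mask
from grainscan.synth import VarietyProfile, make_grain_sprite

from conftest import disk_mask, make_region


def sprite_region(length, width, seed=0, jitter=0.0, angle=0.0):
    profile = VarietyProfile(
        "X", length, 0.0, width, 0.0, (240, 238, 228), 3.0, 0.0
    )
    mask, rgb, _, _ = make_grain_sprite(
        profile, np.random.default_rng(seed), jitter=jitter, angle=angle
    )
    return make_region(mask, rgb)


class TestContour:
    def test_single_pixel(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        assert trace_contour(mask).tolist() == [[1, 1]]

    def test_square_boundary_count(self):
        mask = np.zeros((14, 14), bool)
        mask[2:12, 2:12] = True  # 10x10 square
        contour = trace_contour(mask)
        assert len(contour) == 36

    def test_fill_recovers_mask(self, rng):
        for seed in range(5):
            region = sprite_region(30, 12, seed=seed, jitter=0.05)
            refilled = contour_mask(region.contour, region.mask_crop.shape)
            assert np.array_equal(refilled, region.mask_crop)

    def test_rejects_empty_and_multi_component(self):
        with pytest.raises(InvalidRegionError):
            trace_contour(np.zeros((4, 4), bool))
        two = np.zeros((5, 5), bool)
        two[0, 0] = two[4, 4] = True
        with pytest.raises(InvalidRegionError):
            trace_contour(two)


class TestGeometry:
    def test_disk_limit(self):
        region = make_region(disk_mask(20))
        geo = geometry_features(region)
        assert geo["area"] == pytest.approx(np.pi * 400, rel=0.02)
        assert geo["roundness"] == pytest.approx(1.0, abs=0.05)
        assert geo["aspect_ratio"] == pytest.approx(1.0, abs=0.05)
        assert geo["equivalent_diameter"] == pytest.approx(40, rel=0.02)

    def test_ellipse_axes_recovered(self):
        region = sprite_region(60, 24)
        geo = geometry_features(region)
        assert geo["length"] == pytest.approx(60, rel=0.05)
        assert geo["width"] == pytest.approx(24, rel=0.05)
        assert geo["aspect_ratio"] == pytest.approx(2.5, rel=0.07)

    def test_solidity_of_convex_disk_and_notch(self):
        disk = disk_mask(15)
        solid = geometry_features(make_region(disk))["solidity"]
        assert solid == pytest.approx(1.0, abs=0.05)  # hull rasterization bias
        notched = disk.copy()
        notched[12:22, 15:19] = False  # carve a wedge through the middle edge
        notched_solidity = geometry_features(make_region(notched))["solidity"]
        assert notched_solidity < solid - 0.01

    def test_dimensionless_features_are_scale_invariant(self):
        small = geometry_features(sprite_region(120, 48))
        big = geometry_features(sprite_region(240, 96))
        for name in ("aspect_ratio", "roundness", "solidity", "extent"):
            assert big[name] == pytest.approx(small[name], rel=0.03)


class TestHsv:
    def test_black_and_red_anchors(self):
        assert rgb_to_hsv(0, 0, 0) == (0.0, 0.0, 0.0)
        h, s, v = rgb_to_hsv(255, 0, 0)
        assert (h, s, v) == (0.0, 1.0, 255.0)

    def test_matches_reference_conversion(self, rng):
        triples = rng.integers(0, 256, (1000, 3))
        h, s, v = rgb_to_hsv(triples[:, 0], triples[:, 1], triples[:, 2])
        for k in range(1000):
            r, g, b = triples[k] / 255.0
            rh, rs, rv = colorsys.rgb_to_hsv(r, g, b)
            dh = abs(h[k] - rh * 360.0)
            assert min(dh, 360 - dh) < 1.0
            assert abs(s[k] - rs) < 1 / 255
            assert abs(v[k] - rv * 255.0) < 1.0


class TestChannelHistograms:
    def test_uniform_gray_lands_in_bin_24(self):
        mask = np.ones((4, 4), bool)
        rgb = np.full((4, 4, 3), 128, np.uint8)
        hist = channel_histograms(make_region(mask, rgb))
        for c in range(3):  # R, G, B channels
            channel = hist[c * 48 : (c + 1) * 48]
            assert channel[24] == 16 and channel.sum() == 16

    def test_bin_sums_equal_pixel_count(self, rng):
        region = sprite_region(25, 10, seed=3, jitter=0.05)
        hist = channel_histograms(region)
        n = region.mask_crop.sum()
        for c in range(6):
            assert hist[c * 48 : (c + 1) * 48].sum() == n

    def test_matches_per_pixel_tally_oracle(self, rng):
        mask = rng.random((9, 9)) > 0.3
        mask[4, 4] = True
        rgb = rng.integers(0, 256, (9, 9, 3), dtype=np.uint8)
        from grainscan.contours import trace_contour as tc
        from scipy import ndimage as ndi

        lab, _ = ndi.label(mask, np.ones((3, 3)))
        mask = lab == lab[4, 4]
        hist = channel_histograms(make_region(mask, rgb))
        tally = np.zeros((6, 48), int)
        for r, c in np.argwhere(mask):
            rr, gg, bb = (float(x) for x in rgb[r, c])
            h, s, v = rgb_to_hsv(rr, gg, bb)
            vals = [rr, gg, bb, h * 255.0 / 360.0, s * 255.0, v]
            for ch, val in enumerate(vals):
                tally[ch, min(int(val * 48 / 256), 47)] += 1
        assert np.array_equal(hist, tally.ravel())

    def test_empty_region_rejected(self):
        region = sprite_region(20, 8)
        region.mask_crop = np.zeros_like(region.mask_crop)
        with pytest.raises(InvalidRegionError):
            channel_histograms(region)


def brute_force_glcm(gray, mask, d1, d2, levels=256):
    G = np.zeros((levels, levels), np.int64)
    h, w = gray.shape
    for r in range(h):
        for c in range(w):
            rr, cc = r + d1, c + d2
            if 0 <= rr < h and 0 <= cc < w and mask[r, c] and mask[rr, cc]:
                G[gray[r, c], gray[rr, cc]] += 1
    return G


def brute_force_stats(p):
    n, m = p.shape
    con = dis = ho = asm = 0.0
    for i in range(n):
        for j in range(m):
            con += (i - j) ** 2 * p[i, j]
            dis += abs(i - j) * p[i, j]
            ho += p[i, j] / (1 + abs(i - j))
            asm += p[i, j] ** 2
    mu_i = sum(i * p[i, j] for i in range(n) for j in range(m))
    mu_j = sum(j * p[i, j] for i in range(n) for j in range(m))
    var_i = sum((i - mu_i) ** 2 * p[i, j] for i in range(n) for j in range(m))
    var_j = sum((j - mu_j) ** 2 * p[i, j] for i in range(n) for j in range(m))
    corr = sum(
        (i - mu_i) * (j - mu_j) * p[i, j] for i in range(n) for j in range(m)
    ) / np.sqrt(var_i * var_j)
    return con, dis, ho, asm, np.sqrt(asm), corr


class TestGlcm:
    def test_hand_counted_row(self):
        gray = np.array([[5, 5, 9]], np.uint8)
        mat = glcm(gray, np.ones((1, 3), bool), 0)
        assert mat.G[5, 5] == 1 and mat.G[5, 9] == 1 and mat.G.sum() == 2

    def test_constant_crop(self):
        gray = np.full((4, 4), 7, np.uint8)
        mat = glcm(gray, np.ones((4, 4), bool), 90)
        assert mat.G[7, 7] == 12 and mat.G.sum() == 12  # 3 rows x 4 cols pairs

    @pytest.mark.parametrize("angle", [0, 45, 90, 135])
    def test_matches_double_loop_oracle(self, rng, angle):
        gray = rng.integers(0, 256, (12, 12), dtype=np.uint8)
        mask = rng.random((12, 12)) > 0.25
        d1, d2 = ANGLE_OFFSETS[angle]
        mat = glcm(gray, mask, angle)
        assert np.array_equal(mat.G, brute_force_glcm(gray, mask, d1, d2))
        assert mat.n_pairs == mat.G.sum()
        assert mat.p.sum() == pytest.approx(1.0)

    def test_matches_skimage_on_full_mask(self, rng):
        gray = rng.integers(0, 256, (10, 10), dtype=np.uint8)
        full = np.ones((10, 10), bool)
        # skimage angle 0 is our (0, 1) offset exactly
        ref0 = graycomatrix(gray, [1], [0.0], levels=256)[:, :, 0, 0]
        assert np.array_equal(glcm(gray, full, 0).G, ref0)
        # skimage's 90 deg offset is (+1, 0), the reversed pair of our
        # (-1, 0): the matrices are transposes of each other
        ref90 = graycomatrix(gray, [1], [np.pi / 2], levels=256)[:, :, 0, 0]
        assert np.array_equal(glcm(gray, full, 90).G, ref90.T)

    def test_single_pixel_has_no_pairs(self):
        with pytest.raises(EmptyPairsError):
            glcm(np.array([[3]], np.uint8), np.ones((1, 1), bool), 0)


class TestGlcmStats:
    def test_constant_image_limit(self):
        p = np.zeros((8, 8))
        p[3, 3] = 1.0
        stats = glcm_stats(p)
        assert stats["CON"] == 0 and stats["DIS"] == 0
        assert stats["HO"] == 1 and stats["ASM"] == 1 and stats["EN"] == 1
        assert stats["CORR"] == 1  # degenerate variance convention

    def test_two_cell_hand_computation(self):
        p = np.zeros((4, 4))
        p[0, 0] = p[0, 1] = 0.5
        stats = glcm_stats(p)
        assert stats["CON"] == pytest.approx(0.5)
        assert stats["DIS"] == pytest.approx(0.5)
        assert stats["HO"] == pytest.approx(0.75)
        assert stats["ASM"] == pytest.approx(0.5)
        assert stats["EN"] == pytest.approx(np.sqrt(0.5))

    def test_matches_double_loop_oracle(self, rng):
        p = rng.random((8, 8))
        p /= p.sum()
        stats = glcm_stats(p)
        con, dis, ho, asm, en, corr = brute_force_stats(p)
        assert stats["CON"] == pytest.approx(con, abs=1e-10)
        assert stats["DIS"] == pytest.approx(dis, abs=1e-10)
        assert stats["HO"] == pytest.approx(ho, abs=1e-10)
        assert stats["ASM"] == pytest.approx(asm, abs=1e-10)
        assert stats["EN"] == pytest.approx(en, abs=1e-10)
        assert stats["CORR"] == pytest.approx(corr, abs=1e-10)

    def test_matches_skimage_graycoprops(self, rng):
        gray = rng.integers(0, 64, (12, 12), dtype=np.uint8)
        mat = glcm(gray, np.ones((12, 12), bool), 0, levels=64)
        stats = glcm_stats(mat.p)
        G4 = mat.G[:, :, None, None]
        # homogeneity excluded: skimage weights by 1/(1+(i-j)^2), whereas
        # the inverse-difference form here uses 1/(1+|i-j|)
        for name, key in [
            ("contrast", "CON"), ("dissimilarity", "DIS"),
            ("ASM", "ASM"), ("energy", "EN"), ("correlation", "CORR"),
        ]:
            ref = graycoprops(G4.astype(np.uint32), name)[0, 0]
            assert stats[key] == pytest.approx(float(ref), rel=1e-8)

    def test_unnormalized_input_rejected(self):
        with pytest.raises(InvalidDistributionError):
            glcm_stats(np.ones((4, 4)))

    def test_transpose_identity_across_angles(self, rng):
        """Texture at 0 deg equals texture at 90 deg on the transposed crop."""
        region = sprite_region(30, 14, seed=9, jitter=0.05)
        stats0 = texture_features(region, FeatureConfig(angles=(0,)))
        flipped = make_region(region.mask_crop.T.copy(),
                              region.rgb_crop.transpose(1, 0, 2).copy())
        # transposing maps the (0, 1) offset onto (1, 0) = reverse of 90 deg;
        # all six statistics are invariant under pair reversal
        stats90 = texture_features(flipped, FeatureConfig(angles=(90,)))
        for stat in ("CON", "DIS", "HO", "ASM", "EN", "CORR"):
            assert stats0[f"glcm_{stat}_000"] == pytest.approx(
                stats90[f"glcm_{stat}_090"], rel=1e-9
            )


class TestFeatureVector:
    def test_registry_arithmetic(self):
        names = feature_registry()
        assert len(names) == 330
        assert len(GEOMETRY_NAMES) == 18
        assert sum(n.startswith("hist_") for n in names) == 288
        assert sum(n.startswith("glcm_") for n in names) == 24

    def test_vector_finite_and_deterministic(self):
        region = sprite_region(40, 16, seed=2, jitter=0.03)
        v1 = feature_vector(region)
        v2 = feature_vector(region)
        assert v1.shape == (330,)
        assert np.isfinite(v1).all()
        assert np.array_equal(v1, v2)

    def test_aspect_ratio_separates_long_from_short(self):
        """Long-grain vs short-grain profiles are separable by the fitted
        aspect ratio alone (pairwise AUC > 0.95)."""
        rng_seeds = range(100)
        long_ar = [
            geometry_features(sprite_region(88, 14, seed=s, jitter=0.03))["aspect_ratio"]
            for s in rng_seeds
        ]
        short_ar = [
            geometry_features(sprite_region(38, 19, seed=s, jitter=0.03))["aspect_ratio"]
            for s in rng_seeds
        ]
        wins = sum(
            (a > b) + 0.5 * (a == b) for a in long_ar for b in short_ar
        )
        auc = wins / (len(long_ar) * len(short_ar))
        assert auc > 0.95

    def test_table_shape_and_roundtrip(self, tmp_path):
        regions = [sprite_region(30 + i, 12, seed=i, jitter=0.03) for i in range(6)]
        labels = ["A", "A", "A", "B", "B", "B"]
        table = build_feature_table(regions, labels=labels)
        assert table.shape == (6, 333)  # scene, grain_id, variety + 330
        path = tmp_path / "features.csv"
        save_feature_table(table, path)
        back = pd.read_csv(path, float_precision="round_trip")
        feat_cols = feature_registry()
        assert np.array_equal(table[feat_cols].to_numpy(), back[feat_cols].to_numpy())
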