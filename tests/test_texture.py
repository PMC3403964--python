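"""Texture features: hand-computed GLCM oracle, Haralick closed forms,
filter-bank sanity, radial statistics, and invariance properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cocluster import (
    DegenerateGLCMError,
    ImageSet,
    LabelMask,
    ValidationError,
    compute_glcm,
    extract_cell,
    extract_features,
    gabor_features,
    haralick_features,
    mean_intensity,
    quantize,
    radial_moments,
    radial_shift_haralick,
    ser_features,
)
from cocluster.texture import DEFAULT_OFFSETS, FEATURE_NAMES, GLCM


def glcm_bruteforce(raster, mask, offsets, levels):
    """Independent pair-enumeration oracle for the co-occurrence matrix."""
    H, W = raster.shape
    counts = np.zeros((levels, levels))
    for r in range(H):
        for c in range(W):
            if not mask[r, c]:
                continue
            for dr, dc in offsets:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < H and 0 <= c2 < W and mask[r2, c2]:
                    counts[raster[r, c], raster[r2, c2]] += 1
    counts = counts + counts.T
    return counts / counts.sum()


# the printed 4x4 two-level raster: each row is [0, 0, 1, 1]
HAND_RASTER = np.tile(np.array([0, 0, 1, 1]), (4, 1))
HAND_GLCM = np.array([[1 / 3, 1 / 6], [1 / 6, 1 / 3]])


class TestQuantize:
    def test_constant_cell(self):
        assert np.array_equal(quantize(np.full(9, 7.0)), np.zeros(9, dtype=int))

    def test_range_contract(self):
        q = quantize(np.arange(256.0), levels=8)
        assert q.min() == 0 and q.max() == 7

    def test_two_level_example(self):
        q = quantize(np.array([10.0, 20.0, 30.0, 40.0]), levels=2)
        assert q.tolist() == [0, 0, 1, 1]

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            quantize(np.array([]))


class TestGLCM:
    def test_hand_counted_example(self):
        glcm = compute_glcm(HAND_RASTER, offsets=[(0, 1)], levels=2)
        np.testing.assert_allclose(glcm.matrix, HAND_GLCM, atol=1e-15)

    def test_constant_raster(self):
        glcm = compute_glcm(np.zeros((4, 4), dtype=int), levels=8)
        assert glcm.matrix[0, 0] == 1.0
        assert glcm.matrix.sum() == 1.0

    def test_transpose_with_rotated_offsets(self):
        rng = np.random.default_rng(0)
        raster = rng.integers(0, 8, size=(10, 10))
        g1 = compute_glcm(raster, offsets=[(0, 1)], levels=8)
        g2 = compute_glcm(raster.T, offsets=[(1, 0)], levels=8)
        np.testing.assert_allclose(g1.matrix, g2.matrix, atol=1e-15)

    def test_one_pixel_cell_degenerate(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        with pytest.raises(DegenerateGLCMError):
            compute_glcm(np.zeros((3, 3), dtype=int), mask=mask, levels=8)

    def test_agrees_with_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            raster = rng.integers(0, 8, size=(8, 8))
            mask = rng.uniform(size=(8, 8)) < 0.8
            mask[0:2, 0:2] = True  # guarantee valid pairs
            ours = compute_glcm(raster, mask=mask, levels=8)
            ref = glcm_bruteforce(raster, mask, DEFAULT_OFFSETS, 8)
            np.testing.assert_allclose(ours.matrix, ref, atol=1e-12)


class TestHaralick:
    def test_closed_form_on_hand_example(self):
        feats = haralick_features(GLCM(HAND_GLCM, levels=2, offsets=((0, 1),)))
        assert abs(feats["haralick_01"] - 5 / 18) < 1e-12  # ASM
        assert abs(feats["haralick_02"] - 1 / 3) < 1e-12   # contrast

    def test_constant_cell_conventions(self):
        m = np.zeros((8, 8))
        m[0, 0] = 1.0
        feats = haralick_features(GLCM(m, levels=8, offsets=((0, 1),)))
        assert feats["haralick_01"] == 1.0   # ASM
        assert feats["haralick_02"] == 0.0   # contrast
        assert feats["haralick_03"] == 0.0   # correlation, by convention
        assert feats["haralick_09"] == 0.0   # entropy

    def test_bounds_on_random_glcms(self, rng):
        for _ in range(20):
            m = rng.uniform(size=(8, 8))
            m = m + m.T
            m /= m.sum()
            feats = haralick_features(GLCM(m, levels=8, offsets=((0, 1),)))
            assert 0 < feats["haralick_01"] <= 1
            assert 0 < feats["haralick_05"] <= 1
            assert feats["haralick_02"] >= 0
            assert all(np.isfinite(v) for v in feats.values())

    def test_unnormalized_rejected(self):
        with pytest.raises(ValidationError):
            GLCM(np.ones((2, 2)), levels=2, offsets=((0, 1),))


class TestGabor:
    def test_constant_cell_zero(self):
        mask = np.ones((32, 32), dtype=bool)
        feats, _ = gabor_features(np.full((32, 32), 50.0), mask)
        assert all(abs(v) < 1e-6 for v in feats.values())

    def test_frequency_selectivity(self):
        cc = np.arange(64)[None, :] * np.ones((64, 1))
        img = 100 + 50 * np.sin(2 * np.pi * cc / 4.0)
        feats, _ = gabor_features(img, np.ones((64, 64), dtype=bool))
        assert feats["gabor_f4_mean"] > feats["gabor_f8_mean"]

    def test_offset_invariance(self, rng):
        img = rng.uniform(0, 100, size=(40, 40))
        mask = np.ones((40, 40), dtype=bool)
        f1, _ = gabor_features(img, mask)
        f2, _ = gabor_features(img + 50.0, mask)
        for k in f1:
            assert abs(f1[k] - f2[k]) < 1e-9

    def test_small_cell_warns(self):
        feats, warn = gabor_features(np.ones((5, 5)), np.ones((5, 5), bool))
        assert feats["gabor_f8_mean"] == 0.0
        assert warn


class TestSER:
    def test_constant_cell(self):
        feats, _ = ser_features(np.full((20, 20), 9.0), np.ones((20, 20), bool))
        assert feats == {"ser_spot": 0.0, "ser_edge": 0.0, "ser_ridge": 0.0}

    def test_punctum_responses(self):
        # An isolated Gaussian punctum excites the spot operator strongly;
        # the tangential curvature f'/r is negative across the whole blob,
        # so the ridge response is of the same order (analytically the disc
        # integrals are 0.74 A vs A) -- both must be positive, with spot
        # within a factor ~2 of ridge, and the blob must stand far above
        # the response of a flat cell.
        rr, cc = np.mgrid[0:33, 0:33]
        img = 100 * np.exp(-((rr - 16) ** 2 + (cc - 16) ** 2) / (2 * 2.0**2))
        feats, _ = ser_features(img, np.ones((33, 33), bool))
        assert feats["ser_spot"] > 0
        assert 0.5 < feats["ser_spot"] / feats["ser_ridge"] < 2.0

    def test_step_edge_dominates(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 100.0
        feats, _ = ser_features(img, np.ones((32, 32), bool))
        assert feats["ser_edge"] > feats["ser_spot"]
        assert feats["ser_edge"] > feats["ser_ridge"]


class TestRadial:
    def _disc_coords(self, radius=15):
        rr, cc = np.mgrid[0:2 * radius + 1, 0:2 * radius + 1]
        member = (rr - radius) ** 2 + (cc - radius) ** 2 <= radius**2
        return np.column_stack([rr[member], cc[member]]), (radius, radius)

    def test_central_concentration(self):
        coords, centroid = self._disc_coords()
        values = np.zeros(len(coords))
        centre = np.all(coords == centroid, axis=1)
        values[centre] = 100.0
        feats = radial_moments(values, coords, centroid)
        assert feats["radial_moment_1"] == 0.0

    def test_maximal_ring(self):
        coords, centroid = self._disc_coords()
        d = np.hypot(coords[:, 0] - centroid[0], coords[:, 1] - centroid[1])
        values = (d == d.max()).astype(float)
        feats = radial_moments(values, coords, centroid)
        assert feats["radial_moment_1"] == 1.0
        assert feats["radial_moment_2"] == 0.0

    def test_uniform_disc_matches_continuum(self):
        # for uniform intensity on a disc, E[r] = int r * 2r dr = 2/3
        coords, centroid = self._disc_coords(radius=40)
        feats = radial_moments(np.ones(len(coords)), coords, centroid)
        assert abs(feats["radial_moment_1"] - 2 / 3) < 0.02
        assert feats["radial_moment_2"] <= 0.25

    def test_all_zero_rejected(self):
        coords, centroid = self._disc_coords()
        with pytest.raises(ValidationError):
            radial_moments(np.zeros(len(coords)), coords, centroid)

    def test_radial_shift_constant(self):
        mask = np.ones((11, 11), dtype=bool)
        val, _ = radial_shift_haralick(np.zeros((11, 11), dtype=int), mask,
                                       (5.0, 5.0))
        assert val == 0.0

    def test_ring_radial_exceeds_standard_contrast(self):
        rr, cc = np.mgrid[0:41, 0:41]
        d = np.hypot(rr - 20, cc - 20)
        mask = d <= 18
        raster = np.where((d > 9) & (d < 13), 7, 0)
        raster[~mask] = 0
        radial, _ = radial_shift_haralick(raster, mask, (20.0, 20.0))
        standard = haralick_features(
            compute_glcm(raster, mask=mask, offsets=[(0, 1)], levels=8)
        )["haralick_02"]
        assert radial > standard

    def test_rotation_invariance(self, rng):
        rr, cc = np.mgrid[0:31, 0:31]
        mask = (rr - 15) ** 2 + (cc - 15) ** 2 <= 13**2
        raster = rng.integers(0, 8, size=(31, 31))
        raster[~mask] = 0
        v1, _ = radial_shift_haralick(raster, mask, (15.0, 15.0))
        v2, _ = radial_shift_haralick(np.rot90(raster).copy(),
                                      np.rot90(mask).copy(), (15.0, 15.0))
        assert abs(v1 - v2) < 0.1 * max(v1, v2)


class TestExtractFeatures:
    def _cell_view(self, seed=0):
        from cocluster import SyntheticClassSpec, generate_cell

        spec = SyntheticClassSpec(n_cells=1, cell_radius_px=16,
                                  puncta_count=30, marker_puncta_count=15,
                                  seed=seed)
        a, b, labels, _ = generate_cell(spec, 0)
        image = ImageSet(channels={"protein": a, "marker": b})
        return extract_cell(image, LabelMask.from_labels(labels), 1)

    def test_canonical_vector(self):
        vec = extract_features(self._cell_view())
        assert tuple(vec.values.keys()) == FEATURE_NAMES
        assert len(vec.values) == 24
        assert all(np.isfinite(v) for v in vec.values.values())

    def test_purity(self):
        v1 = extract_features(self._cell_view(seed=3))
        v2 = extract_features(self._cell_view(seed=3))
        assert v1.values == v2.values

    def test_affine_intensity_invariance_of_glcm_features(self):
        view = self._cell_view(seed=5)
        transformed = self._cell_view(seed=5)
        transformed.pixels["protein"] = 3.0 * view.pixels["protein"] + 7.0
        transformed.rasters["protein"] = 3.0 * view.rasters["protein"] + 7.0
        v1 = extract_features(view)
        v2 = extract_features(transformed)
        for name in [f"haralick_{i:02d}" for i in range(1, 14)] + [
                "radial_haralick_contrast"]:
            assert abs(v1.values[name] - v2.values[name]) < 1e-9, name

    def test_mean_intensity(self):
        assert mean_intensity(np.array([10.0, 20.0, 30.0])) == 20.0
        with pytest.raises(ValidationError):
            mean_intensity(np.array([]))


@settings(max_examples=30, deadline=None, database=None)
@given(st.lists(st.integers(min_value=0, max_value=7), min_size=8,
                max_size=64))
def test_glcm_is_normalized_probability(levels_list):
    """Any raster with at least one valid pair yields a proper distribution."""
    n = len(levels_list)
    side = int(math.ceil(math.sqrt(n)))
    raster = np.zeros(side * side, dtype=int)
    raster[:n] = levels_list
    raster = raster.reshape(side, side)
    glcm = compute_glcm(raster, levels=8)
    assert glcm.matrix.min() >= 0
    assert abs(glcm.matrix.sum() - 1.0) < 1e-12
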