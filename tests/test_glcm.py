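"""Co-occurrence counting, normalisation, and the stack contract."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biospeckle.glcm import (DIRECTIONS, GLCM, CountMatrix, GlcmSpec,
                             compute_glcm, glcm_stack, normalize_glcm)


def brute_force_glcm(image: np.ndarray, spec: GlcmSpec) -> np.ndarray:
    """Literal pair enumeration over every pixel (the oracle)."""
    rows, cols = image.shape
    dr, dc = spec.offset
    counts = np.zeros((spec.levels, spec.levels), dtype=np.int64)
    offsets = [(dr, dc), (-dr, -dc)] if spec.symmetric else [(dr, dc)]
    for r in range(rows):
        for c in range(cols):
            for odr, odc in offsets:
                r2, c2 = r + odr, c + odc
                if 0 <= r2 < rows and 0 <= c2 < cols:
                    counts[image[r, c], image[r2, c2]] += 1
    return counts


class TestCounting:
    def test_constant_image_horizontal(self):
        image = np.full((4, 4), 5, dtype=np.uint8)
        cm = compute_glcm(image, GlcmSpec(distance=1, direction=0, levels=8))
        assert cm.counts[5, 5] == 24  # 12 horizontal pairs, both orientations
        assert cm.total == 24

    def test_two_by_two_example(self):
        image = np.array([[0, 1], [2, 3]], dtype=np.uint8)
        cm = compute_glcm(image, GlcmSpec(distance=1, direction=0, levels=4))
        expected = np.zeros((4, 4), dtype=np.int64)
        expected[0, 1] = expected[1, 0] = expected[2, 3] = expected[3, 2] = 1
        np.testing.assert_array_equal(cm.counts, expected)

    @pytest.mark.parametrize("direction", [0, 45, 90, 135])
    def test_symmetric_counts_equal_transpose(self, direction, rng):
        image = rng.integers(0, 8, size=(9, 9), dtype=np.uint8)
        cm = compute_glcm(image, GlcmSpec(distance=2, direction=direction, levels=8))
        np.testing.assert_array_equal(cm.counts, cm.counts.T)

    def test_offset_larger_than_image_rejected(self):
        image = np.zeros((4, 4), dtype=np.uint8)
        with pytest.raises(ValueError):
            compute_glcm(image, GlcmSpec(distance=4, direction=0, levels=4))

    def test_pixels_above_levels_rejected(self):
        image = np.array([[0, 9]], dtype=np.uint8)
        with pytest.raises(ValueError):
            compute_glcm(image, GlcmSpec(distance=1, direction=0, levels=8))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            GlcmSpec(distance=0)
        with pytest.raises(ValueError):
            GlcmSpec(direction=30)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        data=st.data(),
        rows=st.integers(2, 16), cols=st.integers(2, 16),
        distance=st.integers(1, 3),
        direction=st.sampled_from([0, 45, 90, 135]),
        symmetric=st.booleans(),
    )
    def test_matches_brute_force_oracle(self, data, rows, cols, distance,
                                        direction, symmetric):
        image = np.asarray(
            data.draw(st.lists(st.lists(st.integers(0, 7), min_size=cols,
                                        max_size=cols),
                               min_size=rows, max_size=rows)),
            dtype=np.uint8)
        spec = GlcmSpec(distance=distance, direction=direction, levels=8,
                        symmetric=symmetric)
        dr, dc = spec.offset
        if abs(dr) >= rows or abs(dc) >= cols:
            with pytest.raises(ValueError):
                compute_glcm(image, spec)
            return
        cm = compute_glcm(image, spec)
        np.testing.assert_array_equal(cm.counts, brute_force_glcm(image, spec))

    def test_matches_skimage_reference(self, rng):
        """Cross-check against skimage's graycomatrix.  Its pi/4 offset is
        down-right (our 135-degree left diagonal) and vice versa; diagonals
        are only comparable at d = 1 because skimage rounds d*sin(45deg)
        per component while we step d cells along the diagonal."""
        from skimage.feature import graycomatrix

        image = rng.integers(0, 16, size=(24, 24), dtype=np.uint8)
        cases = {(0, 1): 0.0, (0, 3): 0.0, (90, 1): np.pi / 2,
                 (90, 3): np.pi / 2, (135, 1): np.pi / 4, (45, 1): 3 * np.pi / 4}
        for (direction, d), angle in cases.items():
            ours = compute_glcm(image, GlcmSpec(distance=d,
                                                direction=direction,
                                                levels=16)).counts
            theirs = graycomatrix(image, [d], [angle], levels=16,
                                  symmetric=True)[:, :, 0, 0]
            np.testing.assert_array_equal(ours, theirs)


class TestNormalisation:
    def test_single_cell(self):
        counts = np.zeros((8, 8), dtype=np.int64)
        counts[5, 5] = 24
        glcm = normalize_glcm(CountMatrix(counts=counts, spec=GlcmSpec(levels=8)))
        assert glcm.probabilities[5, 5] == 1.0
        assert glcm.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_four_cell_quarters(self):
        image = np.array([[0, 1], [2, 3]], dtype=np.uint8)
        glcm = normalize_glcm(compute_glcm(image, GlcmSpec(distance=1,
                                                           direction=0, levels=4)))
        assert glcm.probabilities[0, 1] == 0.25
        assert glcm.probabilities[3, 2] == 0.25

    def test_all_zero_counts_rejected(self):
        cm = CountMatrix(counts=np.zeros((4, 4), dtype=np.int64),
                         spec=GlcmSpec(levels=4))
        with pytest.raises(ValueError):
            normalize_glcm(cm)

    def test_every_stack_entry_sums_to_one(self, rng):
        image = rng.integers(0, 32, size=(48, 48), dtype=np.uint8)
        stack = glcm_stack(image, levels=32)
        for glcm in stack.values():
            assert glcm.probabilities.sum() == pytest.approx(1.0, abs=1e-12)


class TestStack:
    def test_default_grid_has_forty_matrices(self, rng):
        image = rng.integers(0, 64, size=(32, 32), dtype=np.uint8)
        stack = glcm_stack(image, levels=64)
        assert len(stack) == 40
        assert set(d for d, _ in stack) == set(range(1, 11))

    def test_single_combination(self, rng):
        image = rng.integers(0, 8, size=(16, 16), dtype=np.uint8)
        stack = glcm_stack(image, distances=[1], directions=[0], levels=8)
        assert list(stack) == [(1, 0)]

    def test_entries_match_individual_computation(self, rng):
        image = rng.integers(0, 8, size=(16, 16), dtype=np.uint8)
        stack = glcm_stack(image, distances=[2, 5], directions=[45, 90], levels=8)
        for (d, theta), glcm in stack.items():
            spec = GlcmSpec(distance=d, direction=theta, levels=8)
            expected = normalize_glcm(compute_glcm(image, spec))
            np.testing.assert_array_equal(glcm.probabilities, expected.probabilities)


class TestRoughnessConcentration:
    def test_diagonal_mass_grows_with_roughness(self, study_images):
        """Rougher surfaces concentrate GLCM mass near the principal diagonal."""
        def near_diagonal_mass(image):
            glcm = glcm_stack(image, distances=[1], directions=[0])[(1, 0)]
            levels = glcm.spec.levels
            i = np.arange(levels)
            band = np.abs(i[:, None] - i[None, :]) <= 2
            return glcm.probabilities[band].sum()

        masses = [near_diagonal_mass(im) for im in study_images]
        assert all(a <= b for a, b in zip(masses, masses[1:]))
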