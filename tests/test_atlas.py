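"""Atlas construction: bounding boxes, resampling, signed distance, sigmoid."""

import numpy as np
import pytest

from atlascut import (
    AtlasConfig,
    LabelMask,
    bounding_box,
    build_atlas,
    resample_to_lattice,
    sigmoid_probability,
    signed_distance,
)
from atlascut.atlas import case_probability_map


def _mask(shape, fill=False):
    return LabelMask(np.full(shape, fill, dtype=bool))


class TestBoundingBox:
    def test_single_voxel(self):
        m = _mask((8, 8, 8))
        m.data[3, 4, 5] = True
        assert bounding_box(m) == ((3, 4), (4, 5), (5, 6))

    def test_full_volume(self):
        assert bounding_box(_mask((4, 5, 6), True)) == ((0, 4), (0, 5), (0, 6))

    def test_two_corner_voxels(self):
        m = _mask((10, 4, 4))
        m.data[0, 0, 0] = m.data[9, 0, 0] = True
        assert bounding_box(m) == ((0, 10), (0, 1), (0, 1))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            bounding_box(_mask((4, 4, 4)))


class TestResample:
    def test_identity_when_box_matches_lattice(self):
        rng = np.random.default_rng(7)
        cfg = AtlasConfig(lattice=(8, 8, 8), gain=1.0)
        data = rng.random((8, 8, 8)) < 0.5
        data[0, 0, 0] = data[-1, -1, -1] = True  # box spans the volume
        m = LabelMask(data)
        out = resample_to_lattice(m, bounding_box(m), cfg)
        np.testing.assert_array_equal(out.data, data)

    def test_half_cube_fills_half_the_lattice(self):
        # Solid cube occupying the lower half of its (full-volume) box in
        # each axis; the resampled lattice must be filled in the same ratio.
        m = _mask((16, 16, 16))
        m.data[:8, :8, :8] = True
        box = ((0, 16), (0, 16), (0, 16))
        cfg = AtlasConfig(lattice=(12, 12, 12), gain=1.0)
        out = resample_to_lattice(m, box, cfg)
        # independent nearest-neighbour oracle
        src = np.floor((np.arange(12) + 0.5) * 16 / 12).astype(int)
        oracle = m.data[np.ix_(src, src, src)]
        np.testing.assert_array_equal(out.data, oracle)
        frac = out.data.mean()
        assert abs(frac - 0.125) < 0.06  # within one-voxel boundary tolerance

    def test_random_masks_match_nn_oracle(self):
        rng = np.random.default_rng(3)
        cfg = AtlasConfig(lattice=(10, 7, 5), gain=1.0)
        for _ in range(5):
            data = rng.random((14, 11, 9)) < 0.4
            data[0, 0, 0] = data[-1, -1, -1] = True
            m = LabelMask(data)
            box = bounding_box(m)
            out = resample_to_lattice(m, box, cfg)
            axes = [
                np.clip(
                    np.round(lo + (np.arange(s) + 0.5) * (hi - lo) / s - 0.5), lo, hi - 1
                ).astype(int)
                for (lo, hi), s in zip(box, cfg.lattice)
            ]
            oracle = m.data[np.ix_(*axes)]
            np.testing.assert_array_equal(out.data, oracle)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            resample_to_lattice(_mask((4, 4, 4), True), ((1, 1), (0, 4), (0, 4)), AtlasConfig())


def _brute_signed_distance(data: np.ndarray) -> np.ndarray:
    """All-pairs Euclidean oracle for the signed distance."""
    pts = np.indices(data.shape).reshape(3, -1).T
    fg = pts[data.ravel()]
    bg = pts[~data.ravel()]
    out = np.empty(data.shape)
    for p in pts:
        opposite = bg if data[tuple(p)] else fg
        d2 = ((opposite - p) ** 2).sum(axis=1).min()
        out[tuple(p)] = np.sqrt(d2) * (1 if data[tuple(p)] else -1)
    return out


class TestSignedDistance:
    def test_matches_brute_force_on_random_small_masks(self, rng):
        for _ in range(10):
            data = rng.random((5, 5, 5)) < 0.5
            if data.all() or not data.any():
                continue
            d = signed_distance(LabelMask(data))
            np.testing.assert_allclose(d, _brute_signed_distance(data), atol=1e-12)

    def test_adjacent_voxels_have_unit_magnitude(self):
        data = np.zeros((5, 5, 5), bool)
        data[:, :, :2] = True
        d = signed_distance(LabelMask(data))
        assert d[2, 2, 1] == 1.0 and d[2, 2, 2] == -1.0

    def test_sign_flip_under_complement(self, rng):
        data = rng.random((6, 6, 6)) < 0.5
        data[0, 0, 0], data[1, 1, 1] = True, False
        d = signed_distance(LabelMask(data))
        d_c = signed_distance(LabelMask(~data))
        np.testing.assert_allclose(d_c, -d, atol=1e-12)

    def test_ball_centre_distance_is_radius(self):
        g = np.indices((21, 21, 21)) - 10
        ball = (g**2).sum(axis=0) <= 49  # radius 7
        d = signed_distance(LabelMask(ball))
        assert d[10, 10, 10] == pytest.approx(7.0, abs=0.7)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            signed_distance(_mask((4, 4, 4), True))


class TestSigmoid:
    def test_midpoint_asymptotes_and_symmetry(self):
        assert sigmoid_probability(np.array(0.0), gain=3.7) == pytest.approx(0.5)
        assert sigmoid_probability(np.array(1e4), gain=1.0) == pytest.approx(1.0)
        assert sigmoid_probability(np.array(-1e4), gain=1.0) == pytest.approx(0.0)
        d = np.linspace(-20, 20, 41)
        np.testing.assert_allclose(
            sigmoid_probability(d, 0.8) + sigmoid_probability(-d, 0.8), 1.0, atol=1e-12
        )

    def test_gain_sharpens_monotonically(self):
        d = np.array([-3.0, -1.0, 1.0, 3.0])
        lo = sigmoid_probability(d, 0.5)
        hi = sigmoid_probability(d, 2.0)
        assert (hi[d > 0] >= lo[d > 0]).all()
        assert (hi[d < 0] <= lo[d < 0]).all()


class TestBuildAtlas:
    def test_single_case_equals_its_sigmoid_map(self, rng):
        g = np.indices((12, 12, 12)) - 6
        data = ((g / 4.0) ** 2).sum(axis=0) <= 1.0
        cfg = AtlasConfig(lattice=(8, 8, 8), gain=0.7)
        atlas = build_atlas([LabelMask(data)], cfg)
        np.testing.assert_allclose(atlas.data, case_probability_map(LabelMask(data), cfg))

    def test_identical_cases_are_idempotent(self):
        g = np.indices((10, 10, 10)) - 5
        data = ((g / np.array([4, 3, 4]).reshape(3, 1, 1, 1)) ** 2).sum(axis=0) <= 1.0
        cfg = AtlasConfig(lattice=(6, 6, 6), gain=1.0)
        one = build_atlas([LabelMask(data)], cfg)
        three = build_atlas([LabelMask(data)] * 3, cfg)
        np.testing.assert_allclose(three.data, one.data)

    def test_mean_matches_second_code_path(self, rng):
        cfg = AtlasConfig(lattice=(6, 6, 6), gain=1.0)
        masks = []
        for _ in range(5):
            data = rng.random((9, 9, 9)) < 0.5
            data[4, 4, 4], data[0, 0, 0] = True, False
            masks.append(LabelMask(data))
        atlas = build_atlas(masks, cfg)
        oracle = sum(case_probability_map(m, cfg) for m in masks) / len(masks)
        np.testing.assert_allclose(atlas.data, oracle, atol=1e-12)
        assert 0.0 < atlas.data.min() and atlas.data.max() < 1.0

    def test_empty_training_list_rejected(self):
        with pytest.raises(ValueError):
            build_atlas([], AtlasConfig())
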