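"""Fraction-based threshold selection and hysteresis binarization tests."""

import numpy as np
import pytest

from retivess.binarize import (
    HysteresisParams,
    fraction_to_threshold,
    hysteresis_threshold,
    seed_noise_floor,
)


class TestFractionToThreshold:
    def test_ramp_order_statistic(self, rng):
        # 100 distinct values, fraction 0.1 -> the 10th largest value
        vals = rng.permutation(np.linspace(0.01, 1.0, 100)).reshape(10, 10)
        t = fraction_to_threshold(vals, 0.1)
        assert t == pytest.approx(np.sort(vals.ravel())[-10])
        assert np.count_nonzero(vals >= t) == 10

    def test_fraction_near_one_gives_min(self, rng):
        vals = rng.random((8, 8))
        assert fraction_to_threshold(vals, 0.999999) == pytest.approx(vals.min())

    def test_constant_map_returns_constant(self):
        assert fraction_to_threshold(np.full((5, 5), 0.5), 0.3) == 0.5

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.1])
    def test_invalid_fraction(self, frac):
        with pytest.raises(ValueError):
            fraction_to_threshold(np.zeros((4, 4)), frac)

    def test_at_least_fraction_of_pixels_above(self, rng):
        vals = rng.random((37, 41))
        for frac in (0.02, 0.12, 0.5):
            t = fraction_to_threshold(vals, frac)
            assert np.count_nonzero(vals >= t) >= frac * vals.size


def _bfs_hysteresis(v, t_low, t_high):
    """Brute-force oracle: BFS flood fill from every high pixel over the
    low mask with 8-connectivity."""
    low = v >= t_low
    high = v >= t_high
    out = np.zeros_like(low)
    h, w = v.shape
    stack = list(zip(*np.nonzero(high)))
    for y, x in stack:
        out[y, x] = True
    while stack:
        y, x = stack.pop()
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                yy, xx = y + dy, x + dx
                if 0 <= yy < h and 0 <= xx < w and low[yy, xx] and not out[yy, xx]:
                    out[yy, xx] = True
                    stack.append((yy, xx))
    return out


class TestHysteresis:
    def test_bridge_through_low_pixels_kept(self):
        # weak pixels survive when connected to a strong seed
        v = np.array([[0.9, 0.4, 0.4, 0.9]])
        p = HysteresisParams(
            high_fraction=0.25, low_fraction=0.9, seed_floor_factor=0.0
        )
        np.testing.assert_array_equal(hysteresis_threshold(v, p), 1)

    def test_isolated_weak_pixel_dropped(self):
        v = np.zeros((7, 7))
        v[3, 3] = 0.4
        v[0, 0] = 0.9
        # low threshold catches 0.4, but it is not connected to the seed
        m = _bfs_hysteresis(v, 0.3, 0.8)
        assert not m[3, 3] and m[0, 0]

    def test_matches_bfs_oracle_on_random_maps(self, rng):
        p = HysteresisParams(
            high_fraction=0.05, low_fraction=0.3, seed_floor_factor=0.0
        )
        for _ in range(50):
            v = rng.random((32, 32))
            got = hysteresis_threshold(v, p).astype(bool)
            t_high = fraction_to_threshold(v, 0.05)
            t_low = fraction_to_threshold(v, 0.3)
            np.testing.assert_array_equal(got, _bfs_hysteresis(v, t_low, t_high))

    def test_high_subset_output_subset_low(self, rng):
        v = rng.random((40, 40))
        p = HysteresisParams(
            high_fraction=0.03, low_fraction=0.25, seed_floor_factor=0.0
        )
        out = hysteresis_threshold(v, p).astype(bool)
        high = v >= fraction_to_threshold(v, 0.03)
        low = v >= fraction_to_threshold(v, 0.25)
        assert np.all(high <= out) and np.all(out <= low)

    def test_monotone_in_fractions(self, rng):
        # larger fractions (lower thresholds) never remove pixels
        v = rng.random((32, 32))
        small = hysteresis_threshold(
            v, HysteresisParams(0.02, 0.1, seed_floor_factor=0.0)
        )
        large = hysteresis_threshold(
            v, HysteresisParams(0.05, 0.2, seed_floor_factor=0.0)
        )
        assert np.all(small <= large)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            HysteresisParams(high_fraction=0.3, low_fraction=0.2)
        with pytest.raises(ValueError):
            HysteresisParams(connectivity=4)


class TestSeedFloor:
    def test_vessel_like_map_unaffected(self, rng):
        # sparse strong responses over a weak background: the floor stays
        # below the fraction-derived seed threshold
        v = np.abs(rng.normal(0.0, 0.01, (64, 64)))
        v[10:12, :] = 0.9
        floor = seed_noise_floor(v, 8.0)
        assert floor < fraction_to_threshold(v, 0.02)

    def test_structureless_map_blocks_seeding(self, rng):
        # tight unimodal noise: the floor exceeds every response, so the
        # hysteresis output is empty rather than a forced pixel fraction
        v = np.abs(rng.normal(0.0, 0.01, (64, 64))) + 0.05
        assert seed_noise_floor(v, 8.0) > v.max()
        p = HysteresisParams(high_fraction=0.02, low_fraction=0.12)
        assert hysteresis_threshold(v, p).sum() == 0

    def test_disabled_floor(self, rng):
        v = rng.random((8, 8))
        assert seed_noise_floor(v, 0.0) == -np.inf

    def test_per_level_resolution(self):
        p = HysteresisParams(
            high_fraction=[0.01, 0.02],
            low_fraction=[0.1, 0.2],
            seed_floor_factor=[30.0, 8.0],
        )
        p1 = p.at_level(1)
        assert p1.high_fraction == 0.02
        assert p1.low_fraction == 0.2
        assert p1.seed_floor_factor == 8.0
        # indices past the end clamp to the last entry
        assert p.at_level(5).low_fraction == 0.2
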