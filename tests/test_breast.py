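"""Boundary cost, DP minimum path (vs exhaustive oracle), breast masks."""

import itertools

import numpy as np
import pytest

import bpeq
from bpeq.breast import (
    DegenerateSliceError,
    InfeasibleBandError,
    boundary_cost,
    dp_min_path,
)
from conftest import dice


def brute_force_min_cost(cost: np.ndarray, smoothness: int) -> float:
    """Exhaustive enumeration of all feasible one-row-per-column paths."""
    n_rows, n_cols = cost.shape
    best = np.inf
    for path in itertools.product(range(n_rows), repeat=n_cols):
        if any(abs(a - b) > smoothness for a, b in zip(path, path[1:])):
            continue
        total = 0.0
        for c in reversed(range(n_cols)):  # same accumulation order as the DP
            total = cost[path[c], c] + total
        best = min(best, total)
    return best


class TestBoundaryCost:
    def test_step_edge_minimises_cost_at_the_step(self):
        img = np.zeros((12, 10))
        img[6:, :] = 100.0
        cost = boundary_cost(img, direction="increasing")
        assert (cost.argmin(axis=0) >= 5).all() and (cost.argmin(axis=0) <= 6).all()
        assert cost.min() == 0.0 and cost.max() <= 1.0 and cost.min() >= 0.0

    def test_constant_image_is_degenerate(self):
        with pytest.raises(DegenerateSliceError):
            boundary_cost(np.full((16, 16), 7.0))

    def test_too_small_slice_rejected(self):
        with pytest.raises(ValueError, match="8 rows"):
            boundary_cost(np.zeros((4, 30)))

    def test_phantom_skin_ridge_matches_truth(self, clean_phantom):
        """Noise-free: per-column argmin of the dark-to-bright cost is within
        one voxel of the true skin line (the strongest edge of that
        polarity)."""
        _, pre, _, truth = clean_phantom
        s = pre.shape[2] // 2
        cost = boundary_cost(pre.data[:, :, s], direction="increasing")
        ridge = cost.argmin(axis=0)
        assert np.abs(ridge - truth.skin_rows[:, s]).max() <= 1

    def test_all_fat_phantom_chest_ridge_matches_truth(self):
        """With no FGT the only bright-to-dark edge is the chest wall."""
        spec = bpeq.PhantomSpec(shape=(64, 64, 32), fgt_fraction=0.0, sigma_noise=0.0, seed=9)
        pre, _, truth = bpeq.generate_phantom(spec)
        s = 16
        cost = boundary_cost(pre.data[:, :, s], direction="decreasing")
        ridge = cost.argmin(axis=0)
        assert np.abs(ridge - truth.chest_rows[:, s]).max() <= 1


class TestDpMinPath:
    def test_uniform_grid_cost_and_tiebreak(self):
        cost = np.full((5, 5), 0.3)
        p_low = dp_min_path(cost, smoothness=1, prefer="low")
        p_high = dp_min_path(cost, smoothness=1, prefer="high")
        assert p_low.cost == pytest.approx(5 * 0.3)
        np.testing.assert_array_equal(p_low.rows, 0)
        np.testing.assert_array_equal(p_high.rows, 4)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_enumeration(self, seed):
        """DP optimum equals brute force exactly (dyadic costs, no fp slack)."""
        rng = np.random.default_rng(seed)
        shape = rng.integers(4, 9, size=2)
        cost = rng.integers(0, 1024, size=shape) / 1024.0
        for smoothness in (1, 2):
            path = dp_min_path(cost, smoothness=smoothness)
            assert path.cost == brute_force_min_cost(cost, smoothness)
            # returned cost is the sum of traversed cells
            assert path.cost == pytest.approx(cost[path.rows, np.arange(shape[1])].sum())
            assert np.abs(np.diff(path.rows)).max() <= smoothness

    def test_band_width_zero_returns_prior(self):
        rng = np.random.default_rng(3)
        cost = rng.random((10, 8))
        prior = np.array([2, 3, 4, 4, 3, 2, 2, 3])
        path = dp_min_path(cost, smoothness=2, band=(prior, 0))
        np.testing.assert_array_equal(path.rows, prior)

    def test_infeasible_band_raises(self):
        cost = np.ones((10, 3))
        prior = np.array([0, 9, 0])  # jump of 9 with width 0, smoothness 1
        with pytest.raises(InfeasibleBandError):
            dp_min_path(cost, smoothness=1, band=(prior, 0))

    def test_band_constrains_rows(self):
        rng = np.random.default_rng(4)
        cost = rng.random((12, 6))
        prior = np.full(6, 6)
        path = dp_min_path(cost, smoothness=2, band=(prior, 2))
        assert (np.abs(path.rows - 6) <= 2).all()


class TestSegmentWholeBreast:
    def test_noise_free_dice(self, clean_phantom, clean_breast_masks):
        _, _, _, truth = clean_phantom
        assert dice(clean_breast_masks.left, truth.breast["left"]) >= 0.95
        assert dice(clean_breast_masks.right, truth.breast["right"]) >= 0.95

    def test_noisy_dice(self, noisy_phantom, noisy_breast_masks):
        """5% of fat-intensity Gaussian noise still yields Dice >= 0.90."""
        _, _, _, truth = noisy_phantom
        assert dice(noisy_breast_masks.left, truth.breast["left"]) >= 0.90
        assert dice(noisy_breast_masks.right, truth.breast["right"]) >= 0.90

    def test_masks_disjoint_and_inside_boundaries(self, clean_breast_masks):
        m = clean_breast_masks
        assert not (m.left & m.right).any()
        skin, chest = m.skin_rows(), m.chest_rows()
        rows = np.arange(m.left.shape[0])[:, None, None]
        inside = (rows > skin[None]) & (rows < chest[None])
        assert not (m.union & ~inside).any()

    def test_cross_slice_continuity(self, clean_breast_masks):
        """Adjacent slices' curves differ by at most the band width."""
        for paths in (clean_breast_masks.skin_paths, clean_breast_masks.chest_paths):
            rows = np.stack([p.rows for p in paths], axis=1)
            assert np.abs(np.diff(rows, axis=1)).max() <= 3

    def test_mirrored_volume_swaps_labels(self, clean_phantom):
        _, pre, _, _ = clean_phantom
        masks = bpeq.segment_whole_breast(pre)
        flipped = bpeq.Volume(pre.data[:, ::-1, :].copy(), pre.spacing, pre.phase)
        masks_f = bpeq.segment_whole_breast(flipped)
        np.testing.assert_array_equal(masks_f.left, masks.right[:, ::-1, :])
        np.testing.assert_array_equal(masks_f.right, masks.left[:, ::-1, :])

    def test_constant_volume_errors_with_slice_named(self):
        vol = bpeq.Volume(np.zeros((40, 40, 9)), (1, 1, 1))
        with pytest.raises(DegenerateSliceError, match="slice 4"):
            bpeq.segment_whole_breast(vol)

    def test_voi_crop_identity_and_fraction(self, clean_phantom):
        _, pre, _, _ = clean_phantom
        same, off = bpeq.voi_crop(pre, 1.0)
        assert same is pre and off == (0, 0)
        cropped, (r0, c0) = bpeq.voi_crop(pre, 0.8)
        assert cropped.shape[0] == 2 * round(0.8 * pre.shape[0] / 2)
        np.testing.assert_array_equal(
            cropped.data, pre.data[r0 : r0 + cropped.shape[0], c0 : c0 + cropped.shape[1], :]
        )
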