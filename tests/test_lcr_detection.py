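import numpy as np
import pytest

from lcrtrack import ImageStack, RunConfig
from lcrtrack.lcr_detection import (
    CellMask,
    averaging_window,
    candidacy,
    condition_stack,
    despeckle,
    differential_filter,
    find_clusters,
    max_filter_mask,
    normalize,
    remove_transient,
)


def full_mask(h, w):
    return CellMask(mask=np.ones((h, w), dtype=bool), area_px=h * w)


class TestAveragingWindow:
    def test_default_search_distance_geometry(self):
        side, area = averaging_window(3, 0.2539)
        assert side == 7
        assert area == pytest.approx(7 * 7 * 0.2539**2)
        assert area == pytest.approx(3.16, abs=0.005)


class TestMaxFilterMask:
    def test_cut_is_mean_of_maxima(self):
        # 75% of pixels max 10, 25% max 200 -> cut 57.5 -> mask = bright pixels
        frames = np.full((4, 8, 8), 10.0)
        frames[:, :4, :4] = 200.0
        stack = ImageStack(frames, 0.25, 10.0)
        m = max_filter_mask(stack)
        assert m.area_px == 16
        assert m.mask[:4, :4].all() and not m.mask[4:, :].any()

    def test_uniform_stack_rejected(self):
        stack = ImageStack(np.full((3, 8, 8), 50.0), 0.25, 10.0)
        with pytest.raises(ValueError, match="empty"):
            max_filter_mask(stack)

    def test_off_cell_speckle_removed_by_largest_component(self):
        frames = np.full((3, 16, 16), 10.0)
        frames[:, 4:12, 2:12] = 200.0  # cell
        frames[:, 14, 14] = 250.0  # speckle
        m = max_filter_mask(ImageStack(frames, 0.25, 10.0))
        assert not m.mask[14, 14]
        assert m.mask[5, 5]


class TestNormalize:
    def test_anchors_and_linearity(self):
        frames = np.full((2, 8, 8), 50.0)
        frames[1, 0, 0] = 150.0
        frames[0, 3, 3] = 100.0
        stack = ImageStack(frames, 0.25, 10.0)
        F = normalize(stack, full_mask(8, 8))
        assert F[1, 0, 0] == pytest.approx(255.0)  # masked max -> 255
        assert F.min() == pytest.approx(0.0)  # masked min -> 0
        assert F[0, 3, 3] == pytest.approx(127.5)  # midpoint stays midpoint

    def test_constant_signal_rejected(self):
        stack = ImageStack(np.full((2, 8, 8), 9.0), 0.25, 10.0)
        with pytest.raises(ValueError, match="constant"):
            normalize(stack, full_mask(8, 8))

    def test_explicit_bounds_override(self):
        stack = ImageStack(np.full((2, 8, 8), 60.0), 0.25, 10.0)
        F = normalize(stack, full_mask(8, 8), bounds=(10.0, 110.0))
        np.testing.assert_allclose(F, 255.0 * 0.5)


class TestRemoveTransient:
    def test_uniform_frame_zeroed(self):
        F = np.full((3, 6, 6), 80.0)
        F_nt, F_a = remove_transient(F, full_mask(6, 6))
        np.testing.assert_allclose(F_a, 80.0)
        assert not F_nt.any()

    def test_below_mean_clipped_above_mean_kept(self):
        F = np.full((1, 4, 4), 100.0)
        F[0, 0, 0] = 95.0  # mean shifts: 16 px, sum = 100*15+95
        F[0, 1, 1] = 110.0
        F_nt, F_a = remove_transient(F, full_mask(4, 4))
        mean = (100.0 * 14 + 95.0 + 110.0) / 16
        assert F_a[0] == pytest.approx(mean)
        assert F_nt[0, 0, 0] == 0.0  # below-mean pixel clipped
        assert F_nt[0, 1, 1] == pytest.approx(110.0 - mean)


class TestDespeckle:
    def test_lone_spike_removed_by_median(self):
        frames = np.full((1, 9, 9), 10.0)
        frames[0, 4, 4] = 200.0
        out = despeckle(frames, full_mask(9, 9), median_flag=True, mean_flag=False)
        assert out[0, 4, 4] == 10.0

    def test_no_flags_identity(self, rng):
        frames = rng.uniform(0, 100, (2, 8, 8))
        out = despeckle(frames, full_mask(8, 8), False, False)
        assert out is frames

    def test_constant_region_unchanged(self):
        frames = np.full((1, 9, 9), 42.0)
        out = despeckle(frames, full_mask(9, 9), True, True)
        np.testing.assert_allclose(out, 42.0)


def brute_force_differential(F_nt, mask, d):
    """Independent double-loop oracle for the differential filter."""
    T, H, W = F_nt.shape
    S = np.zeros_like(F_nt)
    for t in range(T):
        for y in range(H):
            for x in range(W):
                if not mask[y, x]:
                    continue
                vals = []
                for yy in range(max(0, y - d), min(H, y + d + 1)):
                    for xx in range(max(0, x - d), min(W, x + d + 1)):
                        if mask[yy, xx]:
                            vals.append(F_nt[t, yy, xx])
                S[t, y, x] = np.mean(vals)
    D = np.zeros_like(F_nt)
    D[1:] = S[1:] - S[:-1]
    D[:, ~mask] = 0.0
    sigma = D[1:, mask].std()
    return D, sigma


class TestDifferentialFilter:
    def test_window_side_is_2d_plus_1(self):
        side, _ = averaging_window(3, 1.0)
        assert side == 7

    def test_constant_stack_zero_differential(self):
        F = np.full((5, 10, 10), 33.0)
        D, sigma = differential_filter(F, full_mask(10, 10), 3)
        assert not D.any() and sigma == 0.0

    def test_unit_step_spread_over_window(self):
        # one pixel steps 0 -> 49 inside a fully masked 7x7 window:
        # every window containing it changes its mean by exactly 1
        F = np.zeros((2, 15, 15))
        F[1, 7, 7] = 49.0
        D, _ = differential_filter(F, full_mask(15, 15), 3)
        assert D[1, 7, 7] == pytest.approx(1.0)
        assert D[1, 4, 4] == pytest.approx(1.0)
        assert D[1, 3, 3] == pytest.approx(0.0)

    def test_matches_brute_force_oracle(self, rng):
        for trial in range(8):
            F = rng.uniform(0, 255, (6, 12, 12))
            mask = rng.uniform(size=(12, 12)) > 0.3
            mask[5:8, 5:8] = True
            D, sigma = differential_filter(F, CellMask(mask, int(mask.sum())), 2)
            D0, sigma0 = brute_force_differential(F, mask, 2)
            np.testing.assert_allclose(D, D0, atol=1e-9)
            assert sigma == pytest.approx(sigma0, abs=1e-9)

    def test_mask_truncation_excludes_background(self):
        # a masked pixel at the mask edge averages only over in-mask pixels
        F = np.zeros((2, 8, 8))
        mask = np.zeros((8, 8), dtype=bool)
        mask[4, 4] = mask[4, 5] = True
        F[1, 4, 5] = 10.0
        D, _ = differential_filter(F, CellMask(mask, 2), 1)
        assert D[1, 4, 4] == pytest.approx(5.0)  # mean over the 2 masked px


class TestCandidacy:
    def test_detection_threshold(self):
        D = np.zeros((2, 8, 8))
        D[1, 3, 3] = 1.5
        cand = candidacy(D, 1.0, 1.0, frozenset(), full_mask(8, 8))
        assert cand[1, 3, 3]
        assert not cand[0].any()

    def test_suspended_frame_cleared(self):
        D = np.full((3, 8, 8), 5.0)
        cand = candidacy(D, 1.0, 1.0, frozenset({1}), full_mask(8, 8))
        assert not cand[1].any() and cand[2].all()

    @pytest.mark.parametrize("n_neighbors, filled", [(7, True), (6, False)])
    def test_seven_of_eight_fill(self, n_neighbors, filled):
        D = np.zeros((2, 8, 8))
        neigh = [(2, 2), (2, 3), (2, 4), (3, 2), (3, 4), (4, 2), (4, 3), (4, 4)]
        for (y, x) in neigh[:n_neighbors]:
            D[1, y, x] = 5.0
        cand = candidacy(D, 1.0, 1.0, frozenset(), full_mask(8, 8))
        assert bool(cand[1, 3, 3]) is filled

    def test_fill_is_single_simultaneous_pass(self):
        # a pixel filled in this pass must not enable further fills
        D = np.zeros((2, 8, 8))
        for (y, x) in [(2, 2), (2, 3), (2, 4), (3, 2), (3, 4), (4, 2), (4, 3)]:
            D[1, y, x] = 5.0
        cand = candidacy(D, 1.0, 1.0, frozenset(), full_mask(8, 8))
        assert cand[1, 3, 3]  # 7 neighbors -> filled
        # (4,4) has neighbors (3,4),(4,3),(3,3 filled) = 3 candidates max
        assert not cand[1, 4, 4]


def brute_force_clusters(cand, connectivity=4):
    """Flood-fill oracle for 4-connected components."""
    H, W = cand.shape
    seen = np.zeros_like(cand, dtype=bool)
    comps = []
    for y in range(H):
        for x in range(W):
            if cand[y, x] and not seen[y, x]:
                stack = [(y, x)]
                comp = set()
                seen[y, x] = True
                while stack:
                    cy, cx = stack.pop()
                    comp.add((cy, cx))
                    for ny, nx in ((cy - 1, cx), (cy + 1, cx), (cy, cx - 1), (cy, cx + 1)):
                        if 0 <= ny < H and 0 <= nx < W and cand[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
                comps.append(frozenset(comp))
    return set(comps)


class TestFindClusters:
    def test_size_threshold_blocks_birth(self):
        cand = np.zeros((8, 8), dtype=bool)
        cand[2, 2:5] = True  # 3-pixel component
        D = np.full((8, 8), 50.0)
        (c,) = find_clusters(cand, D, 4, 0.0)
        assert not c.birth_eligible
        assert c.size == 3

    def test_intensity_and_size_are_boolean_and(self):
        cand = np.zeros((8, 8), dtype=bool)
        cand[2:4, 2:5] = True  # 6 pixels
        intensity = np.full((8, 8), 80.0 / 6)  # sums to 80 < 100
        (c,) = find_clusters(cand, intensity, 4, 100.0)
        assert not c.birth_eligible  # large enough but too dim

    def test_empty_frame(self):
        assert find_clusters(np.zeros((8, 8), dtype=bool), np.zeros((8, 8)), 4, 0.0) == []

    def test_components_match_flood_fill_oracle(self, rng):
        for _ in range(10):
            cand = rng.uniform(size=(16, 16)) > 0.6
            D = rng.uniform(0, 10, (16, 16))
            got = {c.pixels for c in find_clusters(cand, D, 1, 0.0)}
            assert got == brute_force_clusters(cand)

    def test_diagonal_pixels_are_separate_clusters(self):
        cand = np.zeros((8, 8), dtype=bool)
        cand[2, 2] = cand[3, 3] = True
        cl = find_clusters(cand, np.ones((8, 8)), 1, 0.0)
        assert len(cl) == 2


class TestConditionStack:
    def test_two_sigma_scales_positive(self, small_stack, default_config):
        cond = condition_stack(small_stack, default_config)
        assert cond.sigma_cell > 0
        assert cond.sigma_fnt > 0
        assert cond.sigma_fnt > cond.sigma_cell  # averaging + differencing shrink noise

    def test_transients_off_keeps_normalized_signal(self, small_stack):
        cfg = RunConfig(transients_present=False)
        cond = condition_stack(small_stack, cfg)
        np.testing.assert_allclose(cond.F_nt, cond.F_norm)

    def test_norm_range_on_mask(self, small_stack, default_config):
        cond = condition_stack(small_stack, default_config)
        vals = cond.F_norm[:, cond.mask.mask]
        assert vals.min() == pytest.approx(0.0)
        assert vals.max() == pytest.approx(255.0)
        assert (cond.F_nt >= 0).all()
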