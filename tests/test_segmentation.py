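"""Fuzzy clustering, type-II thresholding, and gradual-focusing tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dermoborder import classify, fixtures, segmentation
from dermoborder.segmentation import (
    DegenerateImageError,
    FuzzyPartition,
    ambiguity_threshold,
    extract_lesion_mask,
    fcm_cluster,
    gradual_focus_defuzzify,
    s_membership,
    smooth_edges,
    to_grayscale,
    type2_bounds,
    ultrafuzziness,
)


def brute_force_objective(values, memberships, centroids, m):
    """Independent loop evaluation of the FCM objective."""
    total = 0.0
    for j, x in enumerate(values):
        for i, v in enumerate(centroids):
            total += memberships[i, j] ** m * (x - v) ** 2
    return total


class TestToGrayscale:
    def test_gray_rgb_passes_value_through(self):
        rgb = np.full((4, 4, 3), 97, dtype=np.uint8)
        assert np.all(to_grayscale(rgb) == 97)

    def test_grayscale_identity(self, noisy_ellipse):
        assert np.array_equal(to_grayscale(noisy_ellipse.image), noisy_ellipse.image)

    def test_red_maps_to_itu601_luminance(self):
        rgb = np.zeros((2, 2, 3), dtype=np.uint8)
        rgb[..., 0] = 255
        assert np.all(to_grayscale(rgb) == 76)  # round(0.299 * 255)

    def test_bad_channel_count_rejected(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((4, 4, 2)))


class TestFCM:
    def test_two_valued_image_recovers_levels(self):
        img = np.zeros((16, 16))
        img[:, 8:] = 255
        part = fcm_cluster(img, c=2)
        assert np.allclose(np.sort(part.centroids), [0, 255], atol=1.0)
        assert part.memberships.max(axis=0).min() >= 0.99

    def test_objective_never_increases(self, noisy_ellipse):
        part = fcm_cluster(noisy_ellipse.image[::4, ::4], c=2)
        objs = part.objective
        assert len(objs) >= 2
        assert all(b <= a + 1e-6 for a, b in zip(objs[:-1], objs[1:]))

    def test_objective_matches_brute_force(self, rng):
        values = rng.integers(0, 256, size=50).astype(float)
        part = fcm_cluster(values, c=2)
        direct = brute_force_objective(values, part.memberships, part.centroids, part.m)
        assert segmentation.fcm_objective(
            values, part.memberships, part.centroids, part.m
        ) == pytest.approx(direct, rel=1e-9)

    def test_membership_identity_midpoint(self):
        # pixel at 5 with centroids {0, 10} and m = 2 splits memberships evenly
        x = np.array([0.0, 5.0, 10.0])
        v = np.array([0.0, 10.0])
        d = np.maximum(np.abs(x[None, :] - v[:, None]), 1e-12)
        inv = d ** (-2.0)  # 2/(m-1) with m=2
        u = inv / inv.sum(axis=0)
        assert u[:, 1] == pytest.approx([0.5, 0.5])

    def test_memberships_sum_to_one(self, noisy_ellipse):
        part = fcm_cluster(noisy_ellipse.image[::4, ::4], c=3)
        assert np.allclose(part.memberships.sum(axis=0), 1.0, atol=1e-9)

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateImageError):
            fcm_cluster(np.full((8, 8), 7.0), c=2)


class TestSMembership:
    def test_boundary_branches(self):
        assert s_membership(0.0, 0.0, 0.5, 1.0) == 0.0
        assert s_membership(1.0, 0.0, 0.5, 1.0) == 1.0

    def test_crossover_point(self):
        assert s_membership(0.5, 0.0, 0.5, 1.0) == pytest.approx(0.5)

    def test_upper_quadratic_branch(self):
        assert s_membership(0.75, 0.0, 0.5, 1.0) == pytest.approx(0.875)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(min_value=0.0, max_value=1.0), st.floats(min_value=0.0, max_value=1.0))
    def test_monotone_non_decreasing(self, g1, g2):
        lo, hi = sorted([g1, g2])
        assert s_membership(lo, 0.0, 0.5, 1.0) <= s_membership(hi, 0.0, 0.5, 1.0)

    def test_unordered_knots_rejected(self):
        with pytest.raises(ValueError):
            s_membership(0.5, 0.8, 0.5, 1.0)


class TestType2Bounds:
    def test_fixed_points(self):
        assert type2_bounds(0.0) == (0.0, 0.0)
        assert type2_bounds(1.0) == (1.0, 1.0)

    def test_example_values(self):
        lo, hi = type2_bounds(0.81, alpha=2.0)
        assert lo == pytest.approx(0.6561)
        assert hi == pytest.approx(0.9)

    def test_band_width_peaks_mid_range(self):
        mu = np.linspace(0, 1, 201)
        lo, hi = type2_bounds(mu)
        width = hi - lo
        peak = mu[np.argmax(width)]
        assert 0.2 < peak < 0.8
        assert width[np.argmax(width)] >= width[10]
        assert width[np.argmax(width)] >= width[-10]

    def test_ordering_lower_le_upper(self, rng):
        mu = rng.uniform(0, 1, 100)
        lo, hi = type2_bounds(mu, alpha=1.5)
        assert np.all(lo <= mu + 1e-12)
        assert np.all(mu <= hi + 1e-12)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="1, 2"):
            type2_bounds(0.5, alpha=3.0)


class TestUltrafuzziness:
    def test_crisp_membership_gives_zero(self):
        hist = np.ones(256)
        mu = (np.arange(256) >= 128).astype(float)
        assert ultrafuzziness(hist, mu) == 0.0

    def test_single_level_half_membership(self):
        hist = np.zeros(256)
        hist[100] = 77
        mu = np.zeros(256)
        mu[100] = 0.5
        expected = 0.5**0.5 - 0.5**2
        assert ultrafuzziness(hist, mu) == pytest.approx(expected)

    def test_matches_explicit_loop(self, rng):
        for _ in range(5):
            hist = rng.integers(0, 50, size=256).astype(float)
            hist[0] += 1  # nonempty
            mu = rng.uniform(0, 1, size=256)
            direct = sum(
                h * (m**0.5 - m**2) for h, m in zip(hist, mu)
            ) / hist.sum()
            assert ultrafuzziness(hist, mu) == pytest.approx(direct, rel=1e-12)

    def test_bounded_unit_interval(self, rng):
        hist = rng.integers(1, 10, size=256).astype(float)
        mu = rng.uniform(0, 1, size=256)
        assert 0.0 <= ultrafuzziness(hist, mu) <= 1.0


class TestAmbiguityThreshold:
    def test_bimodal_threshold_between_modes(self, rng):
        # a scan bandwidth spanning half the gray range keeps both modes
        # inside the S-function's ramp, so maximum ultrafuzziness falls
        # between them; narrower bands localize on a single mode instead
        img = np.where(rng.uniform(size=(64, 64)) < 0.5, 64, 192).astype(np.uint8)
        scan = ambiguity_threshold(img, bandwidth=127.5)
        assert 96 <= scan.g_pos <= 160

    def test_narrow_band_localizes_on_a_mode(self, rng):
        img = np.where(rng.uniform(size=(64, 64)) < 0.5, 64, 192).astype(np.uint8)
        scan = ambiguity_threshold(img)  # default quarter-range band
        assert min(abs(scan.g_pos - 64), abs(scan.g_pos - 192)) <= 16

    def test_tau_attains_profile_maximum(self, noisy_ellipse):
        scan = ambiguity_threshold(noisy_ellipse.image)
        assert scan.gamma[scan.g_pos] == scan.gamma.max()

    def test_transpose_invariant(self, noisy_ellipse):
        a = ambiguity_threshold(noisy_ellipse.image)
        b = ambiguity_threshold(noisy_ellipse.image.T)
        assert a.g_pos == b.g_pos
        assert np.allclose(a.gamma, b.gamma)

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateImageError):
            ambiguity_threshold(np.full((8, 8), 128, dtype=np.uint8))


def _partition_from_memberships(u_fg: np.ndarray) -> FuzzyPartition:
    """Two-cluster partition with cluster 1 = foreground membership map."""
    u = np.stack([1.0 - u_fg.ravel(), u_fg.ravel()])
    return FuzzyPartition(
        memberships=u, centroids=np.array([0.0, 255.0]), m=2.0, shape=u_fg.shape
    )


class TestGradualFocusing:
    def test_weak_pixel_joins_neighborhood_majority(self):
        # centre pixel ambiguous with argmax cluster A, but the committed
        # neighborhood majority is cluster B (=1): majority must win
        u_fg = np.array(
            [
                [0.9, 0.9, 0.9],
                [0.9, 0.45, 0.9],
                [0.9, 0.1, 0.1],
            ]
        )
        labels = gradual_focus_defuzzify(_partition_from_memberships(u_fg), tau=0.8)
        assert labels[1, 1] == 1  # majority of committed neighbors

    def test_tie_keeps_original_argmax_cluster(self):
        # 4 committed neighbors per cluster: frequencies tie, pixel keeps
        # its own highest-membership cluster (here cluster 0)
        u_fg = np.array(
            [
                [0.9, 0.9, 0.9],
                [0.9, 0.45, 0.1],
                [0.1, 0.1, 0.1],
            ]
        )
        labels = gradual_focus_defuzzify(_partition_from_memberships(u_fg), tau=0.8)
        assert labels[1, 1] == 0  # argmax of (0.55, 0.45)

    def test_tau_zero_is_plain_argmax(self, rng):
        u_fg = rng.uniform(0, 1, size=(8, 8))
        labels = gradual_focus_defuzzify(_partition_from_memberships(u_fg), tau=0.0)
        assert np.array_equal(labels, (u_fg > 0.5).astype(int))

    def test_all_weak_terminates_via_argmax_seed(self, rng):
        u_fg = rng.uniform(0.4, 0.6, size=(6, 6))
        labels = gradual_focus_defuzzify(_partition_from_memberships(u_fg), tau=1.0)
        assert np.all(labels >= 0)
        assert np.array_equal(labels, (u_fg > 0.5).astype(int))


class TestSmoothEdges:
    def test_step_edge_stays_put(self):
        img = np.zeros((16, 16))
        img[:, 8:] = 200.0
        sm = smooth_edges(img, scale=2)
        edge_cols = np.argmax(np.abs(np.diff(sm, axis=1)), axis=1)
        assert np.all(np.abs(edge_cols - 7) <= 1)

    def test_speckle_removed(self):
        img = np.zeros((9, 9))
        img[4, 4] = 255.0
        assert smooth_edges(img, scale=1).max() == 0.0

    def test_scale_zero_identity(self, noisy_ellipse):
        assert np.array_equal(smooth_edges(noisy_ellipse.image, 0), noisy_ellipse.image)


class TestExtractLesionMask:
    def test_high_jaccard_on_noisy_fixture(self, noisy_ellipse):
        mask = extract_lesion_mask(noisy_ellipse.image)
        assert classify.jaccard_index(mask, noisy_ellipse.mask) > 95.0

    def test_inverted_contrast_with_lighter_rule(self, noisy_ellipse):
        inverted = (255 - noisy_ellipse.image).astype(np.uint8)
        mask = extract_lesion_mask(noisy_ellipse.image)
        mask_inv = extract_lesion_mask(inverted, darker_is_lesion=False)
        assert classify.jaccard_index(mask, mask_inv) > 99.0

    def test_jaccard_self_is_hundred(self, noisy_ellipse):
        assert classify.jaccard_index(noisy_ellipse.mask, noisy_ellipse.mask) == 100.0

    def test_segmentation_property_across_conditions(self):
        # contrast >= 100, noise <= 10 must stay above 90% overlap
        for seed, noise in ((3, 5.0), (4, 10.0)):
            s = fixtures.make_regular_lesion(contrast=100.0, noise_sd=noise, seed=seed)
            mask = extract_lesion_mask(s.image)
            assert classify.jaccard_index(mask, s.mask) > 90.0
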