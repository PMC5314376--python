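"""Canonical head feature maps, Otsu binarisation, PCA orientation, dF."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fintrack.blob import HeadDetection, detect_heads
from fintrack.features import (DegeneratePatchError, binarize_otsu,
                               central_crop, extract_patch, feature_distance,
                               head_orientation_pca, make_feature_map,
                               rotate_patch)
from fintrack.synth import fixture_tracker_config
from tests.conftest import render_single_pose


def _bruteforce_otsu(patch: np.ndarray) -> float:
    """Exhaustive between-class variance maximiser over integer cuts."""
    v = patch.ravel().astype(float)
    best_t, best_s = 0, -1.0
    for t in range(int(v.min()), int(v.max())):
        lo, hi = v[v <= t], v[v > t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        s = len(lo) * len(hi) * (lo.mean() - hi.mean()) ** 2
        if s > best_s:
            best_s, best_t = s, t
    return best_t


class TestExtractPatch:
    def test_center_pixel_preserved(self, rng):
        frame = rng.integers(0, 255, (50, 60)).astype(np.uint8)
        patch, mask = extract_patch(frame, 30, 20, 5)
        assert patch.shape == (11, 11)
        assert patch[5, 5] == frame[20, 30]
        assert mask.all()

    def test_corner_detection_padded_and_masked(self, rng):
        frame = rng.integers(0, 255, (50, 50)).astype(np.uint8)
        patch, mask = extract_patch(frame, 1, 1, 5)
        assert patch.shape == (11, 11)
        assert not mask[0, 0] and mask[5, 5]
        assert patch[0, 0] == np.median(frame)

    def test_full_head_inside_patch_for_default_halfside(self):
        frame, scene = render_single_pose(128, 128, 30.0)
        patch, _ = extract_patch(frame, 128, 128, 46)
        binary, _ = binarize_otsu(patch)
        # no foreground on the patch border towards the head side
        assert binary[0, :].sum() == 0 and binary[:, -1].sum() == 0


class TestOtsu:
    def test_bimodal_disk(self):
        patch = np.full((40, 40), 200, np.uint8)
        yy, xx = np.mgrid[0:40, 0:40]
        disk = (xx - 20) ** 2 + (yy - 20) ** 2 < 100
        patch[disk] = 50
        binary, t = binarize_otsu(patch)
        assert 50 <= t < 200
        assert (binary[disk] == 1).all() and (binary[~disk] == 0).all()

    def test_matches_exhaustive_search(self, rng):
        patch = rng.integers(0, 256, (30, 30)).astype(np.uint8)
        _, t = binarize_otsu(patch)
        assert abs(t - _bruteforce_otsu(patch)) <= 1

    def test_inversion_symmetry(self, rng):
        patch = rng.integers(0, 250, (20, 20)).astype(np.uint8)
        b_dark, _ = binarize_otsu(patch, dark_foreground=True)
        b_inv, _ = binarize_otsu(255 - patch, dark_foreground=False)
        assert (b_dark == b_inv).all()

    def test_constant_patch_raises(self):
        with pytest.raises(DegeneratePatchError):
            binarize_otsu(np.full((10, 10), 42, np.uint8))


class TestOrientation:
    def _bar(self, darker_left: bool):
        binary = np.zeros((21, 21), np.uint8)
        binary[9:12, 5:16] = 1
        gray = np.full((21, 21), 200.0)
        gray[9:12, 5:10] = 30 if darker_left else 90
        gray[9:12, 11:16] = 90 if darker_left else 30
        return binary, gray

    def test_horizontal_bar_darker_left(self):
        binary, gray = self._bar(darker_left=True)
        assert head_orientation_pca(binary, gray) == pytest.approx(180.0)

    def test_horizontal_bar_darker_right(self):
        binary, gray = self._bar(darker_left=False)
        assert head_orientation_pca(binary, gray) == pytest.approx(0.0)

    def test_too_few_pixels_raises(self):
        with pytest.raises(DegeneratePatchError):
            head_orientation_pca(np.zeros((5, 5), np.uint8))

    @pytest.mark.parametrize("phi", [0.0, 45.0, 137.0, 251.0, 333.0])
    def test_rendered_fish_pose_recovered(self, phi):
        frame, _ = render_single_pose(128, 128, phi)
        patch, _ = extract_patch(frame, 128, 128, 46)
        binary, _ = binarize_otsu(patch)
        theta = head_orientation_pca(binary, patch)
        assert abs((theta - phi + 180) % 360 - 180) <= 5.0


class TestFeatureMap:
    def test_zero_pose_is_central_crop(self):
        """A fish already pointing right needs no rotation: the map is
        (nearly) the central 65x65 crop of the patch."""
        frame, _ = render_single_pose(128, 128, 0.0)
        det = HeadDetection(0, 128.0, 128.0, 4.3, 1e3, float(frame[128, 128]))
        cfg = fixture_tracker_config("lone_fish")
        fm = make_feature_map(frame, det, cfg)
        assert abs((fm.theta + 180) % 360 - 180) < 3.0
        patch, _ = extract_patch(frame, 128, 128, 46)
        crop = central_crop(patch, 65).astype(float)
        assert np.abs(fm.gray - crop).mean() < 3.0

    def test_canonicalisation_rotation_invariance(self):
        """Maps of the same fish rendered at 0 and 90 degrees differ by
        less than 5% of the map area."""
        cfg = fixture_tracker_config("lone_fish")
        maps = []
        for phi in (0.0, 90.0):
            frame, _ = render_single_pose(128, 128, phi)
            det = detect_heads(frame, cfg)[0]
            maps.append(make_feature_map(frame, det, cfg))
        df = feature_distance(maps[0].binary, maps[1].binary)
        assert df < 0.05 * 65 * 65

    def test_theta_matches_prerotation_pca(self):
        from fintrack.features import central_component
        frame, _ = render_single_pose(128, 128, 77.0)
        cfg = fixture_tracker_config("lone_fish")
        det = detect_heads(frame, cfg)[0]
        fm = make_feature_map(frame, det, cfg)
        patch, _ = extract_patch(frame, det.x, det.y, cfg.patch_halfside)
        binary, _ = binarize_otsu(patch)
        assert fm.theta == head_orientation_pca(central_component(binary), patch)

    def test_canonicalisation_idempotence(self, lone_fish_maps):
        """Binary maps of one fish across frames stay within 5% area."""
        maps, _ = lone_fish_maps
        base = maps[0].binary
        for m in maps[1:]:
            assert feature_distance(base, m.binary) < 0.05 * 65 * 65


class TestFeatureDistance:
    def test_identity_and_complement(self, rng):
        b = (rng.random((65, 65)) < 0.3).astype(np.uint8)
        assert feature_distance(b, b) == 0
        assert feature_distance(b, 1 - b) == 65 * 65

    def test_matches_bruteforce_double_loop(self, rng):
        b1 = (rng.random((65, 65)) < 0.4).astype(np.uint8)
        b2 = (rng.random((65, 65)) < 0.4).astype(np.uint8)
        want = sum(
            int(b1[i, j] != b2[i, j]) for i in range(65) for j in range(65)
        )
        assert feature_distance(b1, b2) == want

    def test_shape_mismatch_fatal(self):
        with pytest.raises(ValueError):
            feature_distance(np.zeros((65, 65)), np.zeros((64, 65)))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_metric_axioms(self, seed):
        """dF is a metric: symmetry, identity of indiscernibles and the
        triangle inequality (Hamming distance on binary maps)."""
        r = np.random.default_rng(seed)
        a, b, c = [(r.random((16, 16)) < 0.5).astype(np.uint8) for _ in range(3)]
        assert feature_distance(a, b) == feature_distance(b, a)
        assert (feature_distance(a, b) == 0) == bool((a == b).all())
        assert feature_distance(a, c) <= feature_distance(a, b) + feature_distance(b, c)


def test_rotate_patch_moves_feature_to_positive_x():
    p = np.zeros((21, 21))
    p[16, 10] = 1.0  # below centre: theta = 90 deg
    r = rotate_patch(p, 90.0)
    assert np.unravel_index(np.argmax(r), r.shape) == (10, 16)
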