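"""Flow propagation, duplicate resolution, gap filling, verification."""

import numpy as np
import pytest

from fintrack.blob import HeadDetection
from fintrack.config import TrackerConfig
from fintrack.correction import (auto_displacement_threshold,
                                 detect_duplicate_segments, fill_gaps,
                                 fill_gaps_until_stable, make_flow_fn,
                                 propagate_point, resolve_duplicates,
                                 verify_trajectories)
from fintrack.features import HeadFeatureMap
from fintrack.io import FrameSequence
from fintrack.linking import Trajectory
from fintrack.segments import TrajectorySegment


def _textured_disk_frames(n_frames, v=(3.0, 0.0), start=(30.0, 40.0),
                          size=96, radius=10, seed=0):
    """A textured rigid disk translating at constant velocity."""
    rng = np.random.default_rng(seed)
    texture = rng.integers(0, 120, (2 * radius + 1, 2 * radius + 1))
    frames = []
    centres = []
    for t in range(n_frames):
        cx, cy = start[0] + v[0] * t, start[1] + v[1] * t
        centres.append((cx, cy))
        img = np.full((size, size), 200, np.uint8)
        yy, xx = np.mgrid[0:size, 0:size]
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        inside = d2 <= radius**2
        ty = np.clip((yy - cy + radius).astype(int), 0, 2 * radius)
        tx = np.clip((xx - cx + radius).astype(int), 0, 2 * radius)
        img[inside] = texture[ty[inside], tx[inside]]
        frames.append(img)
    return FrameSequence(np.stack(frames)), centres


def _static_frames(n=5, size=64):
    img = np.full((size, size), 150, np.uint8)
    img[20:30, 20:30] = 60
    return FrameSequence(np.stack([img] * n))


def seg(seg_id, start, length, x0, y0, vx=0.0, vy=0.0):
    ds = [HeadDetection(start + t, x0 + vx * t, y0 + vy * t, 4.0, 1.0, 50.0)
          for t in range(length)]
    maps = [HeadFeatureMap(np.zeros((65, 65)), np.zeros((65, 65), np.uint8),
                           0.0, 128.0)] * length
    return TrajectorySegment(seg_id, ds, maps)


def cfg(**kw):
    base = dict(num_fish=2, sigma_range=(2.5, 7.0), intensity_range=(0, 90),
                doh_threshold=500.0, flow_window=20, resolution_scale=1.0)
    base.update(kw)
    return TrackerConfig(**base)


class TestPropagation:
    def test_static_scene_point_stays(self):
        frames = _static_frames()
        prop = propagate_point(frames, (32.0, 32.0), 0, 4, w=20)
        assert prop.final == (32.0, 32.0)
        assert prop.ratios == [0.0] * 4
        assert len(prop.points) == 4

    def test_translating_disk_followed(self):
        frames, centres = _textured_disk_frames(8)
        prop = propagate_point(frames, centres[0], 0, 7, w=20)
        fx, fy = prop.final
        assert np.hypot(fx - centres[7][0], fy - centres[7][1]) <= 2.0

    def test_direction_within_one_histogram_bin(self):
        frames, _ = _textured_disk_frames(4, v=(2.5, 2.5), start=(25.0, 25.0))
        prop = propagate_point(frames, (25.0, 25.0), 0, 3, w=20)
        dx = prop.final[0] - 25.0
        dy = prop.final[1] - 25.0
        ang = np.degrees(np.arctan2(dy, dx)) % 360
        assert abs((ang - 45 + 180) % 360 - 180) <= 18.0

    def test_bad_interval_rejected(self):
        frames = _static_frames()
        with pytest.raises(ValueError):
            propagate_point(frames, (1.0, 1.0), 3, 3, w=10)


class TestDuplicates:
    def test_detection_and_bruteforce_count(self):
        shared = seg(2, 20, 10, 0, 0)
        trajs = [Trajectory(0, [seg(0, 0, 10, 0, 0), shared]),
                 Trajectory(1, [seg(1, 0, 10, 50, 50), shared]),
                 Trajectory(2, [seg(3, 0, 10, 80, 80)])]
        dups = detect_duplicate_segments(trajs)
        assert dups == [(2, [0, 1])]
        # brute-force occurrence sum over membership lists
        count = sum(t.segment_ids.count(2) for t in trajs)
        assert count == 2

    def test_no_duplicates_empty(self):
        trajs = [Trajectory(0, [seg(0, 0, 10, 0, 0)]),
                 Trajectory(1, [seg(1, 0, 10, 9, 9)])]
        assert detect_duplicate_segments(trajs) == []

    def test_flow_consistent_owner_wins(self):
        """The disputed segment continues the moving disk's path; the
        true owner's propagation lands on it, the impostor's does not."""
        frames, centres = _textured_disk_frames(30)
        # owner follows the disk frames 0..9; disputed segment frames 20..29
        owner_pre = seg(0, 0, 10, centres[0][0], centres[0][1], vx=3.0)
        disputed = seg(2, 20, 10, centres[20][0], centres[20][1], vx=3.0)
        impostor_pre = seg(1, 0, 10, 75.0, 80.0)   # static far corner
        t_own = Trajectory(0, [owner_pre, disputed])
        t_imp = Trajectory(1, [impostor_pre, disputed])
        resolve_duplicates([t_own, t_imp], frames, cfg(dis_max=15.0))
        assert disputed in t_own.segments
        assert disputed not in t_imp.segments
        occurrences = sum(t.segment_ids.count(2) for t in (t_own, t_imp))
        assert occurrences == 1

    def test_no_owner_below_ceiling_removes_everywhere(self):
        frames = _static_frames(30)
        disputed = seg(2, 20, 5, 55.0, 55.0)
        a = Trajectory(0, [seg(0, 0, 10, 5, 5), disputed])
        b = Trajectory(1, [seg(1, 0, 10, 20, 20), disputed])
        resolve_duplicates([a, b], frames, cfg(dis_max=5.0))
        assert all(2 not in t.segment_ids for t in (a, b))


class TestGapFilling:
    def test_zero_flow_gap_filled_with_start_point(self):
        frames = _static_frames(12)
        traj = Trajectory(0, [seg(0, 0, 3, 25.0, 25.0), seg(1, 8, 3, 25.0, 25.0)])
        removed = fill_gaps(traj, frames, cfg())
        assert not removed
        for f in range(3, 8):
            assert traj.filled_points[f] == (25.0, 25.0)
            assert f in traj.filled_frames

    def test_linear_fill_arithmetic(self):
        """Ambiguous flow (static scene, distant endpoints) falls back to
        exact linear interpolation."""
        frames = _static_frames(10)
        traj = Trajectory(0, [seg(0, 0, 3, 0.0, 0.0), seg(1, 7, 3, 10.0, 0.0)])
        fill_gaps(traj, frames, cfg(gap_near_px=0.5))
        # 4-frame gap from (0,0) at frame 2 to (10,0) at frame 7
        assert traj.filled_points[3][1] == 0.0
        xs = [traj.filled_points[f][0] for f in range(3, 7)]
        assert xs == pytest.approx([2.0, 4.0, 6.0, 8.0])

    def test_smooth_motion_flow_fill_close_to_truth(self):
        frames, centres = _textured_disk_frames(20)
        pre = seg(0, 0, 3, centres[0][0], centres[0][1], vx=3.0)
        post = seg(1, 17, 3, centres[17][0], centres[17][1], vx=3.0)
        traj = Trajectory(0, [pre, post])
        fill_gaps_until_stable(traj, frames, cfg())
        for f in range(3, 17):
            fx, fy = traj.filled_points[f]
            assert np.hypot(fx - centres[f][0], fy - centres[f][1]) <= 10.0


class TestVerification:
    def test_teleport_segment_removed_and_refilled(self):
        frames = _static_frames(30)
        good1 = seg(0, 0, 10, 20.0, 20.0)
        teleport = seg(1, 10, 5, 55.0, 55.0)   # 49 px jump, static elsewhere
        good2 = seg(2, 15, 15, 20.0, 20.0)
        traj = Trajectory(0, [good1, teleport, good2])
        config = cfg(displacement_threshold=10.0)
        verify_trajectories([traj], frames, config)
        assert 1 not in traj.segment_ids
        pts = traj.points
        steps = [np.hypot(pts[f + 1][0] - pts[f][0], pts[f + 1][1] - pts[f][1])
                 for f in sorted(pts) if f + 1 in pts]
        assert max(steps) <= 10.0
        assert not traj.low_credibility

    def test_clean_trajectory_unchanged(self):
        frames = _static_frames(12)
        traj = Trajectory(0, [seg(0, 0, 12, 30.0, 30.0)])
        verify_trajectories([traj], frames, cfg(displacement_threshold=10.0))
        assert traj.segment_ids == [0] and not traj.low_credibility

    def test_auto_threshold_scales_with_motion(self):
        fast = [Trajectory(0, [seg(0, 0, 20, 0.0, 0.0, vx=4.0)])]
        slow = [Trajectory(0, [seg(0, 0, 20, 0.0, 0.0, vx=1.0)])]
        assert auto_displacement_threshold(fast) == pytest.approx(12.0, rel=0.05)
        assert auto_displacement_threshold(slow) == pytest.approx(3.0, rel=0.05)
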