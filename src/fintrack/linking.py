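"""Assembly of ID-labelled segments into per-fish trajectories."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import TrackerConfig
from .segments import TrajectorySegment

log = logging.getLogger(__name__)


@dataclass
class Trajectory:
    """Per-identity time series of head positions."""

    fish_id: int
    segments: list[TrajectorySegment] = field(default_factory=list)
    filled_frames: set[int] = field(default_factory=set)
    filled_points: dict[int, tuple[float, float]] = field(default_factory=dict)
    low_credibility: bool = False

    @property
    def segment_ids(self) -> list[int]:
        return [s.seg_id for s in self.segments]

    @property
    def points(self) -> dict[int, tuple[float, float]]:
        pts: dict[int, tuple[float, float]] = {}
        for s in self.segments:
            for d in s.detections:
                pts[d.frame] = (d.x, d.y)
        pts.update(self.filled_points)
        return pts

    def gaps(self) -> list[tuple[int, int]]:
        """(last frame before gap, first frame after gap) pairs between
        consecutive member segments, ignoring filled frames."""
        out = []
        segs = sorted(self.segments, key=lambda s: s.start_frame)
        for a, b in zip(segs, segs[1:]):
            if b.start_frame > a.end_frame + 1:
                out.append((a.end_frame, b.start_frame))
        return out

    def remove_segment(self, seg_id: int) -> None:
        self.segments = [s for s in self.segments if s.seg_id != seg_id]
        # filled points bridging into a removed segment are stale
        self.filled_points.clear()
        self.filled_frames.clear()


def link_segments_by_id(
    segments: Sequence[TrajectorySegment],
    config: TrackerConfig,
) -> list[Trajectory]:
    """Greedy temporal chaining of same-ID segments.

    Per identity: seed with the earliest-starting segment carrying that
    ID, then repeatedly link the candidate successor (same ID, start
    within 1,000 frames after the current end and within 2,000 scaled
    pixels of the current end point) with the smallest start frame,
    nearer start point on ties.  A multi-ID segment may provisionally
    join several trajectories; duplicates are resolved later.
    """
    max_px = config.px(config.link_max_px)
    trajectories = []
    for fish_id in range(config.num_fish):
        pool = [s for s in segments if fish_id in s.candidate_ids]
        traj = Trajectory(fish_id=fish_id)
        if not pool:
            log.warning("identity %d has no segments; empty trajectory", fish_id)
            trajectories.append(traj)
            continue
        pool.sort(key=lambda s: (s.start_frame, s.seg_id))
        cur = pool.pop(0)
        traj.segments.append(cur)
        while True:
            ex, ey = cur.end_point
            cands = [
                s for s in pool
                if 0 < s.start_frame - cur.end_frame <= config.link_max_frames
                and np.hypot(s.start_point[0] - ex, s.start_point[1] - ey) <= max_px
            ]
            if not cands:
                break
            cur = min(
                cands,
                key=lambda s: (
                    s.start_frame,
                    np.hypot(s.start_point[0] - ex, s.start_point[1] - ey),
                ),
            )
            pool.remove(cur)
            traj.segments.append(cur)
        trajectories.append(traj)
    return trajectories
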