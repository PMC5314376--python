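"""Trajectory error detection, optical-flow point propagation, gap
filling and final verification.

A segment claimed by more than one trajectory is an error.  It is
adjudicated by propagating a point from each claiming trajectory's
preceding segment through dense optical flow up to the disputed
segment's start frame: the trajectory whose propagated point lands
nearest (below a ceiling) keeps the segment.

Per frame step the propagation takes the pixels around the current
point whose flow magnitude exceeds one pixel, histograms their flow
orientations into ten 36-degree bins, takes the winning bin centre as
the step direction, and steps by the largest flow magnitude sampled
along a ray of that direction.  The same machinery fills occlusion gaps
(with a linear-interpolation fallback), and a final pass removes
segments that cause implausibly large per-frame displacements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from skimage.registration import optical_flow_ilk

from .config import TrackerConfig
from .io import FrameSequence
from .linking import Trajectory

log = logging.getLogger(__name__)

FlowFn = Callable[[int], np.ndarray]  # frame index n -> (2, H, W) flow n -> n+1


def make_flow_fn(frames: FrameSequence, cache_size: int = 64) -> FlowFn:
    """Dense optical flow between consecutive frames, with a small cache
    (duplicate resolution and gap filling often revisit the same steps)."""
    cache: dict[int, np.ndarray] = {}

    def flow(n: int) -> np.ndarray:
        if n not in cache:
            if len(cache) >= cache_size:
                cache.pop(next(iter(cache)))
            v, u = optical_flow_ilk(
                frames[n].astype(np.float32), frames[n + 1].astype(np.float32),
                radius=7,
            )
            cache[n] = np.stack([u, v])  # (dx, dy)
        return cache[n]

    return flow


@dataclass
class FlowPropagation:
    start: tuple[float, float]
    n_start: int
    n_end: int
    window: int
    points: list[tuple[float, float]] = field(default_factory=list)  # l_p
    ratios: list[float] = field(default_factory=list)                # l_r
    stopped_early: bool = False

    @property
    def final(self) -> tuple[float, float]:
        return self.points[-1] if self.points else self.start


N_BINS = 10
BIN_WIDTH = 360.0 / N_BINS


def propagate_point(
    frames: FrameSequence,
    p_start: tuple[float, float],
    n_start: int,
    n_end: int,
    w: int,
    flow_fn: FlowFn | None = None,
) -> FlowPropagation:
    """Step a point from frame ``n_start`` to ``n_end`` through the flow.

    Per step: mask = pixels within the w-neighbourhood of p with flow
    magnitude > 1 px; theta = centre of the winning ten-bin orientation
    histogram bin; rho = max magnitude among w equidistant samples along
    the theta-ray of length w; p moves by rho in direction theta.  An
    empty mask leaves p in place with ratio 0.
    """
    if not n_start < n_end <= len(frames) - 1:
        raise ValueError("need n_start < n_end <= T-1")
    h, wd = frames.shape
    if not (0 <= p_start[0] < wd and 0 <= p_start[1] < h):
        raise ValueError("start point outside the frame")
    flow_fn = flow_fn or make_flow_fn(frames)
    prop = FlowPropagation(p_start, n_start, n_end, w)
    p = np.asarray(p_start, float)
    half = w // 2
    for n in range(n_start, n_end):
        if not (0 <= p[0] < wd and 0 <= p[1] < h):
            prop.stopped_early = True
            log.debug("propagation left the frame at step %d", n)
            break
        fl = flow_fn(n)
        x0, x1 = max(int(p[0]) - half, 0), min(int(p[0]) + half + 1, wd)
        y0, y1 = max(int(p[1]) - half, 0), min(int(p[1]) + half + 1, h)
        dx = fl[0, y0:y1, x0:x1]
        dy = fl[1, y0:y1, x0:x1]
        mag = np.hypot(dx, dy)
        mask = mag > 1.0
        if not mask.any():
            prop.points.append((float(p[0]), float(p[1])))
            prop.ratios.append(0.0)
            continue
        # bins centred on multiples of 36 deg: bin k covers
        # [k*36 - 18, k*36 + 18), so axis-aligned flow is unbiased
        ang = (np.degrees(np.arctan2(dy[mask], dx[mask])) + BIN_WIDTH / 2) % 360.0
        hist, _ = np.histogram(ang, bins=N_BINS, range=(0.0, 360.0))
        major = int(np.argmax(hist))
        theta = np.radians(major * BIN_WIDTH)
        r = float(hist[major] / mask.sum())
        # max magnitude sampled at w equidistant points on the theta-ray
        ts = np.linspace(0.0, w, w, endpoint=True)
        sx = np.clip(p[0] + ts * np.cos(theta), 0, wd - 1).astype(int)
        sy = np.clip(p[1] + ts * np.sin(theta), 0, h - 1).astype(int)
        # a step cannot credibly exceed the ray length: spurious flow
        # estimates on textureless background would otherwise teleport p
        rho = min(float(np.hypot(fl[0, sy, sx], fl[1, sy, sx]).max()), float(w))
        p = p + rho * np.array([np.cos(theta), np.sin(theta)])
        prop.points.append((float(p[0]), float(p[1])))
        prop.ratios.append(r)
    return prop


# ----------------------------------------------------------------------
# Duplicate-segment resolution

def detect_duplicate_segments(
    trajectories: Sequence[Trajectory],
) -> list[tuple[int, list[int]]]:
    """Segments whose occurrence sum across trajectories exceeds one."""
    owners: dict[int, list[int]] = {}
    for traj in trajectories:
        for sid in traj.segment_ids:
            owners.setdefault(sid, []).append(traj.fish_id)
    return sorted((sid, ids) for sid, ids in owners.items() if len(ids) > 1)


def resolve_duplicates(
    trajectories: list[Trajectory],
    frames: FrameSequence,
    config: TrackerConfig,
    flow_fn: FlowFn | None = None,
) -> list[Trajectory]:
    """Keep each duplicated segment only in its flow-consistent owner.

    For every owning trajectory, the end point of the segment preceding
    the disputed one is propagated to the disputed segment's start frame;
    the owner with the smallest propagated-to-start distance (below the
    scaled ceiling) wins.  With no owner below the ceiling the segment is
    removed everywhere.
    """
    flow_fn = flow_fn or make_flow_fn(frames)
    by_fish = {t.fish_id: t for t in trajectories}
    dis_max = config.px(config.dis_max)
    for sid, owner_ids in detect_duplicate_segments(trajectories):
        distances: dict[int, float] = {}
        for fid in owner_ids:
            traj = by_fish[fid]
            seg = next(s for s in traj.segments if s.seg_id == sid)
            prev = [s for s in traj.segments if s.end_frame < seg.start_frame]
            if not prev:
                distances[fid] = np.inf
                continue
            last = max(prev, key=lambda s: s.end_frame)
            if last.end_frame >= seg.start_frame:
                distances[fid] = np.inf
                continue
            prop = propagate_point(
                frames, last.end_point, last.end_frame, seg.start_frame,
                config.flow_window, flow_fn,
            )
            px, py = prop.final
            sx, sy = seg.start_point
            distances[fid] = float(np.hypot(px - sx, py - sy))
        best = min(distances, key=lambda f: distances[f])
        keep = best if distances[best] < dis_max else None
        if keep is None:
            log.info("segment %d: no flow-consistent owner; removed everywhere", sid)
        for fid in owner_ids:
            if fid != keep:
                by_fish[fid].remove_segment(sid)
    return trajectories


# ----------------------------------------------------------------------
# Gap filling and verification

def fill_gaps(
    traj: Trajectory,
    frames: FrameSequence,
    config: TrackerConfig,
    flow_fn: FlowFn | None = None,
) -> bool:
    """Fill the temporal gaps of one trajectory.

    Flow propagation across the gap is trusted when it lands within
    20 px (scaled) of the far endpoint; a far miss (> 300 px scaled)
    with consistently dominant flow orientation (> 0.6 of steps) means
    the segment after the gap is a misassignment — it is removed and the
    caller must re-process.  Anything else is filled linearly.  Returns
    True when a segment was removed.
    """
    flow_fn = flow_fn or make_flow_fn(frames)
    near = config.px(config.gap_near_px)
    far = config.px(config.gap_far_px)
    for n_start, n_end in traj.gaps():
        pts = traj.points
        p_start, p_end = pts[n_start], pts[n_end]
        prop = propagate_point(frames, p_start, n_start, n_end,
                               config.flow_window, flow_fn)
        p_r = float(np.mean([r > 0.5 for r in prop.ratios])) if prop.ratios else 0.0
        dist = float(np.hypot(prop.final[0] - p_end[0], prop.final[1] - p_end[1]))
        gap_frames = range(n_start + 1, n_end)
        if dist < near and not prop.stopped_early:
            for f, p in zip(gap_frames, prop.points):
                traj.filled_points[f] = p
                traj.filled_frames.add(f)
        elif dist > far and p_r > config.gap_ratio:
            offender = next(s for s in traj.segments if s.start_frame == n_end)
            log.info(
                "trajectory %d: flow disagrees with segment %d after gap; removing",
                traj.fish_id, offender.seg_id,
            )
            traj.remove_segment(offender.seg_id)
            return True
        else:
            for f in gap_frames:
                a = (f - n_start) / (n_end - n_start)
                traj.filled_points[f] = (
                    p_start[0] + a * (p_end[0] - p_start[0]),
                    p_start[1] + a * (p_end[1] - p_start[1]),
                )
                traj.filled_frames.add(f)
    return False


def fill_gaps_until_stable(
    traj: Trajectory,
    frames: FrameSequence,
    config: TrackerConfig,
    flow_fn: FlowFn | None = None,
    max_passes: int = 10,
) -> None:
    for _ in range(max_passes):
        if not fill_gaps(traj, frames, config, flow_fn):
            return
    log.warning("trajectory %d: gap filling did not stabilise", traj.fish_id)


def auto_displacement_threshold(
    trajectories: Sequence[Trajectory], factor: float = 3.0
) -> float:
    """xi default: ``factor`` times the 95th percentile of the per-frame
    displacements observed inside segments."""
    steps = []
    for traj in trajectories:
        for seg in traj.segments:
            d = seg.detections
            steps.extend(
                np.hypot(b.x - a.x, b.y - a.y) for a, b in zip(d, d[1:])
            )
    if not steps:
        return np.inf
    return factor * float(np.percentile(steps, 95))


def verify_trajectories(
    trajectories: list[Trajectory],
    frames: FrameSequence,
    config: TrackerConfig,
    flow_fn: FlowFn | None = None,
    max_passes: int = 5,
) -> list[Trajectory]:
    """Remove segments causing per-frame displacements above xi.

    The displacement profile of each trajectory is scanned; at a
    violation the member segment at the jump (the shorter one when two
    adjoin) is deleted and the gap refilled.  A trajectory still in
    violation after ``max_passes`` passes is flagged low-credibility.
    """
    flow_fn = flow_fn or make_flow_fn(frames)
    xi = config.displacement_threshold
    if xi is None:
        xi = auto_displacement_threshold(trajectories)
        log.info("displacement threshold xi = %.1f px (auto)", xi)
    for traj in trajectories:
        for _ in range(max_passes):
            viol = _first_violation(traj, xi)
            if viol is None:
                break
            f = viol
            owners = [s for s in (_segment_at(traj, f + 1), _segment_at(traj, f)) if s]
            owner = min(owners, key=len) if owners else None
            if owner is None:
                # jump between filled points: refill after clearing
                traj.filled_points.clear()
                traj.filled_frames.clear()
                fill_gaps_until_stable(traj, frames, config, flow_fn)
                continue
            log.info(
                "trajectory %d: displacement %s exceeds xi at frame %d; "
                "removing segment %d", traj.fish_id, "jump", f, owner.seg_id,
            )
            traj.remove_segment(owner.seg_id)
            fill_gaps_until_stable(traj, frames, config, flow_fn)
        else:
            if _first_violation(traj, xi) is not None:
                traj.low_credibility = True
                log.warning("trajectory %d flagged low-credibility", traj.fish_id)
    return trajectories


def _first_violation(traj: Trajectory, xi: float) -> int | None:
    pts = traj.points
    for f in sorted(pts):
        if f + 1 in pts:
            (x0, y0), (x1, y1) = pts[f], pts[f + 1]
            if np.hypot(x1 - x0, y1 - y0) > xi:
                return f
    return None


def _segment_at(traj: Trajectory, frame: int):
    hits = [s for s in traj.segments if s.start_frame <= frame <= s.end_frame]
    if not hits:
        return None
    return min(hits, key=len)
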