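"""Inter-frame head matching and trajectory-segment formation.

Consecutive frames are matched greedily: candidate pairs are detections
within ``match_radius`` of each other, accepted in ascending order of
the binary feature-map distance dF, each detection used at most once.
The per-frame pair lists are then chained into maximal segments of
strictly consecutive frames; segments shorter than ``eta`` frames are
pruned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .blob import HeadDetection
from .features import HeadFeatureMap, feature_distance


@dataclass
class FramePairList:
    """Matched head pairs between frames ``i`` and ``i + 1``."""

    i: int
    pairs: list[tuple[int, int]]  # indices into (prev_dets, cur_dets)


@dataclass
class TrajectorySegment:
    seg_id: int
    detections: list[HeadDetection]
    feature_maps: list[HeadFeatureMap]
    candidate_ids: set[int] = field(default_factory=set)
    assigned_id: Optional[int] = None

    def __post_init__(self) -> None:
        frames = [d.frame for d in self.detections]
        if any(b != a + 1 for a, b in zip(frames, frames[1:])):
            raise ValueError("segment frames must be strictly consecutive")

    def __len__(self) -> int:
        return len(self.detections)

    @property
    def start_frame(self) -> int:
        return self.detections[0].frame

    @property
    def end_frame(self) -> int:
        return self.detections[-1].frame

    @property
    def start_point(self) -> tuple[float, float]:
        d = self.detections[0]
        return (d.x, d.y)

    @property
    def end_point(self) -> tuple[float, float]:
        d = self.detections[-1]
        return (d.x, d.y)

    def head_maps(self, k: int) -> list[np.ndarray]:
        """Binary maps of the first ``k`` detections."""
        return [m.binary for m in self.feature_maps[:k]]

    def tail_maps(self, k: int) -> list[np.ndarray]:
        """Binary maps of the last ``k`` detections."""
        return [m.binary for m in self.feature_maps[-k:]]


def match_frames(
    prev_dets: Sequence[HeadDetection],
    cur_dets: Sequence[HeadDetection],
    prev_maps: Sequence[HeadFeatureMap],
    cur_maps: Sequence[HeadFeatureMap],
    match_radius: float,
    frame_index: int = 0,
) -> FramePairList:
    """Greedy one-to-one matching of detections across one frame step.

    Among candidate pairs within ``match_radius``, pairs are accepted in
    ascending dF order (ties: smaller displacement, then smaller
    orientation change), skipping pairs whose endpoint is taken.
    """
    if len(prev_dets) != len(prev_maps) or len(cur_dets) != len(cur_maps):
        raise ValueError("feature maps must parallel detections")
    candidates = []
    for pi, (pd, pm) in enumerate(zip(prev_dets, prev_maps)):
        for ci, (cd, cm) in enumerate(zip(cur_dets, cur_maps)):
            disp = float(np.hypot(cd.x - pd.x, cd.y - pd.y))
            if disp > match_radius:
                continue
            df = feature_distance(pm.binary, cm.binary)
            dtheta = abs((cm.theta - pm.theta + 180.0) % 360.0 - 180.0)
            candidates.append((df, disp, dtheta, pi, ci))
    candidates.sort()
    used_prev: set[int] = set()
    used_cur: set[int] = set()
    pairs = []
    for _, _, _, pi, ci in candidates:
        if pi in used_prev or ci in used_cur:
            continue
        used_prev.add(pi)
        used_cur.add(ci)
        pairs.append((pi, ci))
    return FramePairList(i=frame_index, pairs=sorted(pairs))


def build_segments(
    pair_lists: Sequence[FramePairList],
    detections: Sequence[Sequence[HeadDetection]],
    feature_maps: Sequence[Sequence[HeadFeatureMap]],
) -> list[TrajectorySegment]:
    """Chain matched pairs into maximal consecutive-frame segments.

    Scans the pair lists in frame order: the first unused pair seeds a
    segment, which extends while the next frame's list contains a pair
    starting at the current tail; consumed pairs are removed, so every
    pair ends up in exactly one segment.
    """
    by_frame: dict[int, dict[int, int]] = {
        pl.i: dict(pl.pairs) for pl in pair_lists
    }
    order = sorted(by_frame)
    segments: list[TrajectorySegment] = []
    for i in order:
        while by_frame[i]:
            pi = next(iter(by_frame[i]))
            ci = by_frame[i].pop(pi)
            chain = [(i, pi), (i + 1, ci)]
            j, tail = i + 1, ci
            while j in by_frame and tail in by_frame[j]:
                tail = by_frame[j].pop(tail)
                chain.append((j + 1, tail))
                j += 1
            dets = [detections[f][k] for f, k in chain]
            maps = [feature_maps[f][k] for f, k in chain]
            segments.append(
                TrajectorySegment(seg_id=len(segments), detections=dets,
                                  feature_maps=maps)
            )
    return segments


def prune_short_segments(
    segments: Sequence[TrajectorySegment], eta: int
) -> list[TrajectorySegment]:
    """Drop segments spanning fewer than ``eta`` frames; order preserved."""
    return [s for s in segments if len(s) >= eta]


def split_segments_at_proximity(
    segments: Sequence[TrajectorySegment],
    detections: Sequence[Sequence[HeadDetection]],
    radius: float,
) -> list[TrajectorySegment]:
    """Split segments around frames where two heads come within the
    matching radius of each other.

    When two heads are that close, frame-to-frame matching cannot tell
    them apart and a chain can glide from one fish onto the other with
    no displacement jump.  Cutting the chain at the boundaries of such
    ambiguous stretches keeps every piece identity-pure; the ambiguous
    middles are typically shorter than eta and get pruned.
    """
    ambiguous: set[tuple[int, float, float]] = set()
    for frame_dets in detections:
        for i, a in enumerate(frame_dets):
            for b in frame_dets[i + 1:]:
                if np.hypot(a.x - b.x, a.y - b.y) <= radius:
                    ambiguous.add((a.frame, a.x, a.y))
                    ambiguous.add((b.frame, b.x, b.y))
    out: list[TrajectorySegment] = []
    for s in segments:
        flags = [(d.frame, d.x, d.y) in ambiguous for d in s.detections]
        cut = [0] + [i for i in range(1, len(flags)) if flags[i] != flags[i - 1]] \
              + [len(flags)]
        for lo, hi in zip(cut, cut[1:]):
            if hi > lo:
                out.append(TrajectorySegment(
                    seg_id=len(out),
                    detections=list(s.detections[lo:hi]),
                    feature_maps=list(s.feature_maps[lo:hi]),
                ))
    return out


def split_segments_at_jumps(
    segments: Sequence[TrajectorySegment], factor: float = 3.0
) -> list[TrajectorySegment]:
    """Split segments at implausibly large single-frame displacements.

    A step far above the typical swimming displacement (``factor`` times
    the 95th percentile over all segments) almost always marks a
    matching error at a crossing — two fish swapped inside one chain.
    Splitting there keeps both halves identity-pure.  Segment IDs are
    renumbered consecutively.
    """
    steps = []
    for s in segments:
        d = s.detections
        steps.extend(np.hypot(b.x - a.x, b.y - a.y) for a, b in zip(d, d[1:]))
    if not steps:
        return list(segments)
    limit = factor * float(np.percentile(steps, 95))
    out: list[TrajectorySegment] = []
    for s in segments:
        cut = [0]
        d = s.detections
        for i, (a, b) in enumerate(zip(d, d[1:])):
            if np.hypot(b.x - a.x, b.y - a.y) > limit:
                cut.append(i + 1)
        cut.append(len(d))
        for lo, hi in zip(cut, cut[1:]):
            if hi > lo:
                out.append(
                    TrajectorySegment(
                        seg_id=len(out),
                        detections=list(d[lo:hi]),
                        feature_maps=list(s.feature_maps[lo:hi]),
                    )
                )
    return out


def segment_df(
    a: TrajectorySegment, b: TrajectorySegment, k: int = 5
) -> float:
    """dF between two segments: mean pairwise dF of a's last and b's
    first ``k`` binary maps."""
    tails = a.tail_maps(k)
    heads = b.head_maps(k)
    return float(np.mean([[feature_distance(t, h) for h in heads] for t in tails]))
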