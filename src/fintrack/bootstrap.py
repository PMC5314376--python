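"""Automatic generation of labelled training data.

No human labels anything: the initial per-identity labels come from two
structural facts — a trajectory segment belongs to exactly one fish, and
the number of fish is known.  Segments are first chained into ``num``
initial trajectories by spatio-temporal proximity plus binary-map
distance (dF); independently, *collections* (intervals where exactly
``num`` segments are alive simultaneously, one per fish) are mined and
adjacent collections are paired by smallest dF.  The feature maps of the
chained segments, labelled by chain index and augmented with +-1 px
re-extractions, form the initial training set of the classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .blob import HeadDetection
from .config import TrackerConfig
from .features import DegeneratePatchError, make_feature_map
from .io import FrameSequence
from .segments import TrajectorySegment, segment_df

log = logging.getLogger(__name__)


class BootstrapError(RuntimeError):
    """The automatic training-data generation could not proceed."""


@dataclass(frozen=True)
class Collection:
    """Exactly ``num`` co-temporal segments over a shared frame interval."""

    segment_ids: frozenset[int]
    start: int
    end: int  # inclusive

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TrainingItem:
    gray: np.ndarray
    label: int
    source_seg: int
    augmented: bool = False
    source_key: tuple[int, int] = (0, 0)  # (seg_id, index within segment)


@dataclass
class TrainingSet:
    items: list[TrainingItem] = field(default_factory=list)
    train_idx: list[int] = field(default_factory=list)
    test_idx: list[int] = field(default_factory=list)

    def arrays(self, which: str = "train") -> tuple[np.ndarray, np.ndarray]:
        idx = self.train_idx if which == "train" else self.test_idx
        maps = np.stack([self.items[i].gray for i in idx]) if idx else np.empty((0, 65, 65))
        labels = np.array([self.items[i].label for i in idx], dtype=int)
        return maps, labels


# ----------------------------------------------------------------------
# Initial trajectories (chains of segment IDs)

def generate_initial_trajectories(
    segments: Sequence[TrajectorySegment],
    num_fish: int,
    config: TrackerConfig,
) -> list[list[int]]:
    """Chain segments into ``num_fish`` initial identities.

    From each unused base segment, candidate continuations start within
    600 px (scaled) and 200 frames of its end.  A lone candidate starting
    within 90 px and 10 frames links directly (guarded by the dF
    ceiling: right after a crossing the lone nearby candidate is often
    the other fish); otherwise the candidate with smallest segment dF
    links, provided dF stays below the linking ceiling (100).  Chains stop when no candidate qualifies.  Segment IDs
    that end up in more than one chain are deleted from all of them.
    """
    by_id = {s.seg_id: s for s in segments}
    order = sorted(by_id, key=lambda i: (by_id[i].start_frame, i))
    seeded: set[int] = set()
    chains: list[list[int]] = []
    radius = config.px(config.candidate_radius)
    direct_r = config.px(config.direct_link_px)
    for seed in order:
        if len(chains) == num_fish:
            break
        if seed in seeded:
            continue
        chain = [seed]
        seeded.add(seed)
        base = by_id[seed]
        while True:
            nxt = _next_link(base, by_id, chain, radius, direct_r, config)
            if nxt is None:
                break
            chain.append(nxt)
            seeded.add(nxt)
            base = by_id[nxt]
        chains.append(chain)
    if len(chains) < num_fish:
        raise BootstrapError(
            f"could only seed {len(chains)} initial trajectories for "
            f"{num_fish} fish; not enough trajectory segments"
        )
    counts: dict[int, int] = {}
    for chain in chains:
        for sid in chain:
            counts[sid] = counts.get(sid, 0) + 1
    deduped = [[sid for sid in chain if counts[sid] == 1] for chain in chains]
    dropped = sum(c - 1 for c in counts.values() if c > 1)
    if dropped:
        log.info("initial trajectories: removed %d duplicated segment uses", dropped)
    return deduped


def _next_link(base, by_id, chain, radius, direct_r, config):
    ex, ey = base.end_point
    cands = []
    for sid, s in by_id.items():
        if sid in chain:
            continue
        dt = s.start_frame - base.end_frame
        if not 0 < dt <= config.candidate_max_frames:
            continue
        sx, sy = s.start_point
        dist = np.hypot(sx - ex, sy - ey)
        if dist <= radius:
            cands.append((sid, dt, dist))
    if not cands:
        return None
    direct = [
        sid for sid, dt, dist in cands
        if dist <= direct_r and dt <= config.direct_link_frames
    ]
    if len(direct) == 1:
        # sanity-gate the direct link on appearance: right after a
        # crossing the lone nearby candidate is often the *other* fish
        if segment_df(base, by_id[direct[0]], config.seg_df_k) < config.df_link_max:
            return direct[0]
    scored = sorted(
        (segment_df(base, by_id[sid], config.seg_df_k), sid) for sid, _, _ in cands
    )
    best_df, best_sid = scored[0]
    return best_sid if best_df < config.df_link_max else None


# ----------------------------------------------------------------------
# Collections

def find_collections(
    segments: Sequence[TrajectorySegment], num_fish: int
) -> list[Collection]:
    """Maximal frame intervals where exactly ``num_fish`` segments are
    alive and the alive set is constant; sorted by interval length
    descending (longest overlap first)."""
    if not segments:
        return []
    t_min = min(s.start_frame for s in segments)
    t_max = max(s.end_frame for s in segments)
    collections = []
    cur_set: frozenset[int] | None = None
    cur_start = 0
    for t in range(t_min, t_max + 2):
        alive = frozenset(
            s.seg_id for s in segments if s.start_frame <= t <= s.end_frame
        ) if t <= t_max else frozenset()
        if alive != cur_set:
            if cur_set is not None and len(cur_set) == num_fish:
                collections.append(Collection(cur_set, cur_start, t - 1))
            cur_set, cur_start = alive, t
    collections.sort(key=lambda c: (-c.length, c.start))
    return collections


def link_adjacent_collections(
    c1: Collection,
    c2: Collection,
    segments: Sequence[TrajectorySegment],
    k: int = 5,
) -> list[tuple[int, int]]:
    """Pair the segments of two time-adjacent collections by greedy
    ascending segment dF; returns disjoint (seg in c1, seg in c2) pairs."""
    by_id = {s.seg_id: s for s in segments}
    scored = sorted(
        (segment_df(by_id[a], by_id[b], k), a, b)
        for a in c1.segment_ids
        for b in c2.segment_ids
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, a, b in scored:
        if a in used_a or b in used_b:
            continue
        used_a.add(a)
        used_b.add(b)
        pairs.append((a, b))
    return pairs


# ----------------------------------------------------------------------
# Augmentation and training-set assembly

def augment_detection(
    frames: FrameSequence,
    det: HeadDetection,
    config: TrackerConfig,
) -> list[np.ndarray]:
    """Re-extract the feature map at the four +-1 px shifts of the head
    point; shifts that leave the frame are skipped."""
    h, w = frames.shape
    out = []
    for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        x, y = det.x + dx, det.y + dy
        if not (0 <= x < w and 0 <= y < h):
            log.debug("augmentation shift (%d,%d) leaves frame; skipped", dx, dy)
            continue
        shifted = HeadDetection(det.frame, x, y, det.sigma, det.doh_score,
                                det.center_intensity, det.near_border)
        try:
            out.append(make_feature_map(frames[det.frame], shifted, config).gray)
        except DegeneratePatchError:
            log.debug("augmentation shift (%d,%d) degenerate; skipped", dx, dy)
    return out


def build_training_items(
    labelled_segments: dict[int, int],
    segments: Sequence[TrajectorySegment],
    frames: FrameSequence,
    config: TrackerConfig,
    rng: np.random.Generator,
    augment: bool = True,
) -> list[TrainingItem]:
    """Labelled (possibly subsampled) feature maps + their augmentations.

    ``labelled_segments`` maps seg_id -> fish label.  When a label has
    more source maps than ``max_train_maps_per_label``, an evenly spread
    seeded subsample is kept.
    """
    by_id = {s.seg_id: s for s in segments}
    per_label: dict[int, list[tuple[int, int]]] = {}
    for sid, label in labelled_segments.items():
        for idx in range(len(by_id[sid])):
            per_label.setdefault(label, []).append((sid, idx))
    items: list[TrainingItem] = []
    cap = config.max_train_maps_per_label
    for label, sources in sorted(per_label.items()):
        if cap is not None and len(sources) > cap:
            pick = np.linspace(0, len(sources) - 1, cap).round().astype(int)
            sources = [sources[i] for i in np.unique(pick)]
        for sid, idx in sources:
            seg = by_id[sid]
            items.append(TrainingItem(seg.feature_maps[idx].gray, label, sid,
                                      False, (sid, idx)))
            if augment:
                for g in augment_detection(frames, seg.detections[idx], config):
                    items.append(TrainingItem(g, label, sid, True, (sid, idx)))
    return items


def split_training_set(
    items: list[TrainingItem],
    rng: np.random.Generator,
    test_fraction: float = 0.2,
) -> TrainingSet:
    """80/20 stratified split at source-map level: all augmented copies
    of one source map land on the same side as their original."""
    sources: dict[tuple[int, int], list[int]] = {}
    for i, it in enumerate(items):
        sources.setdefault(it.source_key, []).append(i)
    by_label: dict[int, list[tuple[int, int]]] = {}
    for key, idxs in sources.items():
        by_label.setdefault(items[idxs[0]].label, []).append(key)
    tset = TrainingSet(items=items)
    for label in sorted(by_label):
        keys = sorted(by_label[label])
        perm = rng.permutation(len(keys))
        n_test = max(1, int(round(test_fraction * len(keys))))
        test_keys = {keys[i] for i in perm[:n_test]}
        for key in keys:
            target = tset.test_idx if key in test_keys else tset.train_idx
            target.extend(sources[key])
    tset.train_idx.sort()
    tset.test_idx.sort()
    return tset


def dump_training_set(tset: TrainingSet, directory) -> None:
    """Write the training set as PNG tiles plus a labels.csv manifest."""
    import imageio.v3 as iio
    import pandas as pd
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    test_idx = set(tset.test_idx)
    rows = []
    for i, item in enumerate(tset.items):
        name = f"map{i:06d}.png"
        iio.imwrite(directory / name,
                    np.clip(item.gray, 0, 255).astype(np.uint8))
        rows.append((name, item.label, item.source_seg, int(item.augmented),
                     "test" if i in test_idx else "train"))
    pd.DataFrame(rows, columns=["file", "label", "source_seg", "augmented",
                                "split"]).to_csv(directory / "labels.csv",
                                                 index=False)


def build_initial_training_set(
    chains: list[list[int]],
    collections: list[Collection],
    segments: Sequence[TrajectorySegment],
    frames: FrameSequence,
    config: TrackerConfig,
) -> tuple[TrainingSet, set[int]]:
    """Initial training set from chain labels merged with collection links.

    Chain k labels its member segments k.  Segment pairs produced by
    linking adjacent collections are merged into the same identity group
    (union-find); groups that touch exactly one chain inherit its label.
    Returns the training set and the set of collection indices whose
    segments all carry labels (already consumed as training data).
    """
    parent: dict[int, int] = {}

    def find(a: int) -> int:
        parent.setdefault(a, a)
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        parent[find(a)] = find(b)

    for chain in chains:
        for sid in chain[1:]:
            union(chain[0], sid)
    by_id = {s.seg_id: s for s in segments}
    ordered = sorted(collections, key=lambda c: c.start)
    for c1, c2 in zip(ordered, ordered[1:]):
        for a, b in link_adjacent_collections(c1, c2, segments, config.seg_df_k):
            # trust a link only when both segments are substantial and the
            # map distance clears the linking ceiling: scraps produced at
            # crossing moments carry corrupted maps, and one wrong merge
            # here poisons the labels of everything it touches.  Unmerged
            # collections are resolved later by the classifier loop.
            if min(len(by_id[a]), len(by_id[b])) < 10:
                continue
            if segment_df(by_id[a], by_id[b], config.seg_df_k) >= config.df_link_max:
                continue
            la = _chain_label(find(a), chains, find)
            lb = _chain_label(find(b), chains, find)
            if la is None or lb is None or la == lb:
                union(a, b)

    root_label: dict[int, int] = {}
    conflict: set[int] = set()
    for k, chain in enumerate(chains):
        for sid in chain:
            r = find(sid)
            if root_label.setdefault(r, k) != k:
                conflict.add(r)
    labelled: dict[int, int] = {}
    for s in segments:
        r = find(s.seg_id)
        if r in root_label and r not in conflict:
            labelled[s.seg_id] = root_label[r]

    rng = np.random.default_rng(config.seed + 1)
    items = build_training_items(labelled, segments, frames, config, rng)
    counts = {}
    for it in items:
        if not it.augmented:
            counts[it.label] = counts.get(it.label, 0) + 1
    missing = [k for k in range(len(chains)) if counts.get(k, 0) < config.min_maps_per_label]
    if missing:
        raise BootstrapError(
            f"labels {missing} have fewer than {config.min_maps_per_label} "
            "feature maps before augmentation; video too short or detection too sparse"
        )
    tset = split_training_set(items, rng)
    consumed = {
        i for i, c in enumerate(collections)
        if all(sid in labelled for sid in c.segment_ids)
    }
    return tset, consumed


def _chain_label(root, chains, find):
    for k, chain in enumerate(chains):
        if any(find(sid) == root for sid in chain):
            return k
    return None
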