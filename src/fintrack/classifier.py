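"""Per-segment identity assignment and the iterative retraining loop.

The classifier (see :mod:`fintrack.cnn`) votes on every feature map of a
segment; identities whose vote frequency exceeds the threshold (0.2)
become the segment's candidate IDs.  Collections — one segment per fish
over a common interval — let ambiguous votes be resolved by elimination:
identities already claimed by single-ID segments are struck from the
candidate sets of the rest.  Fully resolved collections are appended to
the training set (with augmentation) and the classifier is retrained,
until more than half of all collections have been consumed.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .bootstrap import (Collection, TrainingSet, build_training_items,
                        split_training_set)
from .cnn import FishCNN, train_classifier
from .config import TrackerConfig
from .io import FrameSequence
from .segments import TrajectorySegment

log = logging.getLogger(__name__)


def assign_segment_ids(
    model: FishCNN, seg: TrajectorySegment, freq_threshold: float = 0.2
) -> set[int]:
    """Candidate IDs: labels voted for by more than ``freq_threshold`` of
    the segment's feature maps."""
    maps = np.stack([m.gray for m in seg.feature_maps])
    pred = model.predict(maps)
    counts = np.bincount(pred, minlength=model.num_fish)
    freqs = counts / len(pred)
    candidates = {int(k) for k in np.nonzero(freqs > freq_threshold)[0]}
    seg.candidate_ids = candidates
    return candidates


def filter_ambiguous_segments(
    segments: Sequence[TrajectorySegment], min_len: int = 10, max_ids: int = 3
) -> list[TrajectorySegment]:
    """Drop short segments (< ``min_len`` frames) with >= ``max_ids``
    candidate identities; they would derail segment linkage."""
    kept = [
        s for s in segments
        if not (len(s) < min_len and len(s.candidate_ids) >= max_ids)
    ]
    if len(kept) != len(segments):
        log.info("filtered %d short multi-ID segments", len(segments) - len(kept))
    return kept


def _resolve_collection(
    model: FishCNN,
    col: Collection,
    by_id: dict[int, TrajectorySegment],
    num_fish: int,
    freq_threshold: float,
    cache: dict[int, set[int]] | None = None,
) -> dict[int, int] | None:
    """Try to give every segment of a collection exactly one identity.

    Single-ID segments fix their identity; those identities are struck
    from multi-ID candidate sets.  Returns seg_id -> label, or None if
    the collection stays ambiguous or resolves with a conflict.  A
    ``cache`` of per-segment candidate sets avoids re-classifying a
    segment that belongs to several collections.
    """
    if cache is None:
        cache = {}
    for sid in col.segment_ids:
        if sid not in cache:
            cache[sid] = set(assign_segment_ids(model, by_id[sid], freq_threshold))
    cands = {sid: set(cache[sid]) for sid in col.segment_ids}
    id_true = set()
    for sid, c in cands.items():
        if len(c) == 1:
            id_true |= c
    for sid, c in cands.items():
        if len(c) > 1:
            c -= id_true
    if any(len(c) != 1 for c in cands.values()):
        return None
    labels = {sid: next(iter(c)) for sid, c in cands.items()}
    if len(set(labels.values())) != num_fish:
        log.info("collection %s resolved with duplicate identities; skipped",
                 sorted(col.segment_ids))
        return None
    return labels


def iterative_training(
    model: FishCNN,
    collections: Sequence[Collection],
    segments: Sequence[TrajectorySegment],
    tset: TrainingSet,
    frames: FrameSequence,
    config: TrackerConfig,
    consumed: set[int] | None = None,
) -> tuple[FishCNN, TrainingSet, set[int]]:
    """Grow the training set from resolvable collections and retrain.

    Each sweep classifies the segments of every unconsumed collection,
    resolves what it can by elimination, appends the resolved maps
    (augmented) to the training set and retrains.  Stops once more than
    half of all collections are consumed, or when a full sweep makes no
    progress (with a warning).
    """
    by_id = {s.seg_id: s for s in segments}
    consumed = set(consumed or ())
    total = len(collections)
    rng = np.random.default_rng(config.seed + 2)
    sweep = 0
    while total and len(consumed) <= total / 2:
        sweep += 1
        additions: dict[int, int] = {}
        resolved_now: set[int] = set()
        cache: dict[int, set[int]] = {}
        for i, col in enumerate(collections):
            if i in consumed:
                continue
            labels = _resolve_collection(model, col, by_id, config.num_fish,
                                         config.id_freq_threshold, cache)
            if labels is None:
                continue
            additions.update(labels)
            resolved_now.add(i)
        if not resolved_now:
            log.warning(
                "iterative training stalled after %d sweeps: %d/%d collections consumed",
                sweep, len(consumed), total,
            )
            break
        consumed |= resolved_now
        new_items = build_training_items(additions, segments, frames, config, rng)
        items = tset.items + new_items
        tset = split_training_set(items, rng)
        train_maps, train_labels = tset.arrays("train")
        test_maps, test_labels = tset.arrays("test")
        report = train_classifier(
            model, train_maps, train_labels, test_maps, test_labels,
            epochs=config.effective_retrain_epochs, lr=config.learning_rate,
            batch_size=config.batch_size, seed=config.seed + 100 + sweep,
        )
        log.info(
            "sweep %d: consumed %d/%d collections, training set %d, test error %.3f",
            sweep, len(consumed), total, len(tset.train_idx), report.test_error,
        )
    return model, tset, consumed
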