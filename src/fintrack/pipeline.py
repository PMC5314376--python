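"""End-to-end tracking pipeline.

Stage order: head detection -> feature maps -> inter-frame matching ->
segment formation -> automatic training-data bootstrap -> classifier
training (with the iterative collection-consuming loop) -> per-segment
identity assignment -> temporal linking -> duplicate resolution ->
gap filling -> verification.  Everything downstream of the seed is
deterministic: two runs with the same configuration and frames produce
identical trajectories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Optional

from tqdm import tqdm

from .blob import detect_heads
from .bootstrap import (BootstrapError, build_initial_training_set,
                        find_collections, generate_initial_trajectories)
from .classifier import (assign_segment_ids, filter_ambiguous_segments,
                         iterative_training)
from .cnn import FishCNN, train_classifier
from .config import TrackerConfig
from .correction import (fill_gaps_until_stable, make_flow_fn,
                         resolve_duplicates, verify_trajectories)
from .features import DegeneratePatchError, make_feature_map
from .io import FrameSequence
from .linking import Trajectory, link_segments_by_id
from .segments import (build_segments, match_frames, prune_short_segments,
                       split_segments_at_jumps, split_segments_at_proximity)

log = logging.getLogger(__name__)


@dataclass
class PipelineState:
    """Intermediate products of one tracking run (for diagnostics)."""

    detections: list = field(default_factory=list)
    feature_maps: list = field(default_factory=list)
    pair_lists: list = field(default_factory=list)
    segments: list = field(default_factory=list)
    chains: list = field(default_factory=list)
    collections: list = field(default_factory=list)
    training_set: Any = None
    model: Any = None
    train_report: Any = None
    consumed: set = field(default_factory=set)
    trajectories: list = field(default_factory=list)


def run_tracking(
    config: TrackerConfig,
    frames: FrameSequence,
    progress: bool = False,
    return_state: bool = False,
):
    """Track ``config.num_fish`` fish through a frame sequence.

    Returns the list of trajectories; with ``return_state`` also the
    :class:`PipelineState` carrying every intermediate product.
    """
    if len(frames) < 2 * config.eta:
        raise ValueError(f"need at least {2 * config.eta} frames")

    bar = tqdm if progress else (lambda x, **k: x)

    # 1-2: detection and canonical feature maps
    detections, feature_maps = [], []
    for t in bar(range(len(frames)), desc="detect"):
        dets = detect_heads(frames[t], config, t)
        kept_d, kept_m = [], []
        for d in dets:
            try:
                kept_m.append(make_feature_map(frames[t], d, config))
                kept_d.append(d)
            except DegeneratePatchError as e:
                log.info("frame %d: detection dropped (%s)", t, e)
        detections.append(kept_d)
        feature_maps.append(kept_m)
    n_det = sum(len(d) for d in detections)
    log.info("detection: %d head points over %d frames", n_det, len(frames))

    # 3-4: matching and segments
    pair_lists = [
        match_frames(detections[t], detections[t + 1], feature_maps[t],
                     feature_maps[t + 1], config.match_radius, t)
        for t in range(len(frames) - 1)
    ]
    segments = build_segments(pair_lists, detections, feature_maps)
    segments = split_segments_at_proximity(segments, detections, config.match_radius)
    segments = split_segments_at_jumps(segments)
    segments = prune_short_segments(segments, config.eta)
    log.info("segments: %d after jump-splitting and pruning (eta=%d)",
             len(segments), config.eta)
    state = PipelineState(detections=detections, feature_maps=feature_maps,
                          pair_lists=pair_lists, segments=segments)

    if config.num_fish == 1:
        for s in segments:
            s.candidate_ids = {0}
        model = None
    else:
        # 5-7: bootstrap
        chains = generate_initial_trajectories(segments, config.num_fish, config)
        state.chains = chains
        collections = find_collections(segments, config.num_fish)
        state.collections = collections
        if not collections:
            raise BootstrapError(
                "no frame interval where all "
                f"{config.num_fish} fish are tracked simultaneously"
            )
        log.info("bootstrap: %d chains, %d collections", len(chains), len(collections))
        tset, consumed = build_initial_training_set(
            chains, collections, segments, frames, config
        )
        # 8: initial training
        model = FishCNN(config.num_fish, seed=config.seed,
                        dropout=config.dropout,
                        relu_all_convs=config.relu_all_convs,
                        input_size=config.map_size)
        train_maps, train_labels = tset.arrays("train")
        test_maps, test_labels = tset.arrays("test")
        report = train_classifier(
            model, train_maps, train_labels, test_maps, test_labels,
            epochs=config.epochs, lr=config.learning_rate,
            batch_size=config.batch_size, seed=config.seed,
        )
        log.info("initial training: %d maps, test error %.3f",
                 len(tset.train_idx), report.test_error)
        state.train_report = report
        # 9: iterative retraining over collections
        model, tset, consumed = iterative_training(
            model, collections, segments, tset, frames, config, consumed
        )
        state.model, state.training_set, state.consumed = model, tset, consumed
        # 10: identity assignment for every segment
        for seg in segments:
            assign_segment_ids(model, seg, config.id_freq_threshold)
        segments = filter_ambiguous_segments(segments)
        state.segments = segments

    # 11: temporal linking
    trajectories = link_segments_by_id(segments, config)

    # 12-14: correction, gap filling, verification
    flow_fn = make_flow_fn(frames)
    trajectories = resolve_duplicates(trajectories, frames, config, flow_fn)
    for traj in trajectories:
        fill_gaps_until_stable(traj, frames, config, flow_fn)
    trajectories = verify_trajectories(trajectories, frames, config, flow_fn)
    for traj in trajectories:
        log.info(
            "trajectory %d: %d segments, %d points, %d filled%s",
            traj.fish_id, len(traj.segments), len(traj.points),
            len(traj.filled_frames),
            " (low credibility)" if traj.low_credibility else "",
        )
    if return_state:
        state.trajectories = trajectories
        return trajectories, state
    return trajectories
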