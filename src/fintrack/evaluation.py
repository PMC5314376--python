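"""Tracking evaluation against ground truth.

Seven metrics, with a tracked point counted correct when it lies within
the distance criterion (70 px at full resolution, scaled with the
configuration's ``resolution_scale``) of the ground-truth position of
the *same identity* in the same frame:

==========  =========================================================
precision   correct points / total ground-truth points
recall      correct points / total tracked points
F1          harmonic mean of the two
MT          fraction of trajectories correct on > 80% of their length
ML          fraction correct on < 20%
Frag        fraction correct on 20%-80%
IDS         identity-switch events (the matched ground-truth identity
            of a trajectory changes between consecutive matched frames)
==========  =========================================================

Note: the precision and recall definitions above follow the source
material literally; they are swapped relative to the usual detection
conventions (where precision would divide by the tracked count).  The
JSON report also carries the conventional values under distinct keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_TOLERANCE = 70.0


@dataclass
class EvalReport:
    precision: float
    recall: float
    f1: float
    mt: float
    ml: float
    frag: float
    ids: int
    per_trajectory: dict[int, float] = field(default_factory=dict)
    label_map: dict[int, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "MT": self.mt,
            "ML": self.ml,
            "Frag": self.frag,
            "IDS": self.ids,
            # conventional definitions (divide by tracked resp. ground truth)
            "precision_conventional": self.recall,
            "recall_conventional": self.precision,
            "per_trajectory_correct_fraction": self.per_trajectory,
        }

    def __str__(self) -> str:
        d = self.to_dict()
        rows = ["precision", "recall", "f1", "MT", "ML", "Frag", "IDS"]
        width = max(len(r) for r in rows)
        return "\n".join(
            f"{r:<{width}}  {d[r]:.4f}" if r != "IDS" else f"{r:<{width}}  {d[r]}"
            for r in rows
        )


def _as_points(df: pd.DataFrame) -> dict[int, dict[int, np.ndarray]]:
    """id -> frame -> (x, y)."""
    out: dict[int, dict[int, np.ndarray]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(int(row.id), {})[int(row.frame)] = np.array([row.x, row.y])
    return out


def map_labels(pred: pd.DataFrame, gt: pd.DataFrame) -> dict[int, int]:
    """One-to-one predicted-label -> ground-truth-label correspondence by
    greedy majority vote of nearest ground-truth identities per frame."""
    gt_pts = _as_points(gt)
    votes: dict[int, dict[int, int]] = {}
    for row in pred.itertuples(index=False):
        frame = int(row.frame)
        best, best_d = None, np.inf
        for gid, pts in gt_pts.items():
            if frame in pts:
                d = float(np.hypot(*(pts[frame] - (row.x, row.y))))
                if d < best_d:
                    best, best_d = gid, d
        if best is not None:
            votes.setdefault(int(row.id), {})[best] = (
                votes.get(int(row.id), {}).get(best, 0) + 1
            )
    pairs = sorted(
        ((count, pid, gid) for pid, v in votes.items() for gid, count in v.items()),
        reverse=True,
    )
    mapping: dict[int, int] = {}
    used_gt: set[int] = set()
    for _, pid, gid in pairs:
        if pid in mapping or gid in used_gt:
            continue
        mapping[pid] = gid
        used_gt.add(gid)
    return mapping


def match_frame(
    tracked: dict[int, tuple[float, float]],
    gt: dict[int, tuple[float, float]],
    tol: float = DEFAULT_TOLERANCE,
) -> dict[int, bool]:
    """Identity-aware correctness flags for one frame (strict < tol)."""
    out = {}
    for k, p in tracked.items():
        if k in gt:
            out[k] = bool(np.hypot(p[0] - gt[k][0], p[1] - gt[k][1]) < tol)
        else:
            out[k] = False
    return out


def compute_metrics(
    pred: pd.DataFrame,
    gt: pd.DataFrame,
    tol: float = DEFAULT_TOLERANCE,
    relabel: bool = True,
) -> EvalReport:
    """Evaluate predicted trajectories against ground truth.

    Both frames are CSV-shaped DataFrames with columns frame,id,x,y.
    When ``relabel`` is set, predicted labels are first mapped to
    ground-truth labels by majority vote (labels need not coincide).
    """
    if gt.empty:
        raise ValueError("ground truth is empty")
    mapping = map_labels(pred, gt) if relabel else {
        int(i): int(i) for i in pred["id"].unique()
    }
    pred = pred.assign(id=pred["id"].map(lambda i: mapping.get(int(i), -1)))
    pred = pred[pred["id"] >= 0]
    gt_pts = _as_points(gt)
    pred_pts = _as_points(pred)

    total_gt = len(gt)
    total_tracked = len(pred)
    correct_per_gt: dict[int, int] = {gid: 0 for gid in gt_pts}
    n_correct = 0
    for gid, gpts in gt_pts.items():
        ppts = pred_pts.get(gid, {})
        for f, gp in gpts.items():
            if f in ppts and np.hypot(*(ppts[f] - gp)) < tol:
                n_correct += 1
                correct_per_gt[gid] += 1

    precision = n_correct / total_gt
    recall = n_correct / total_tracked if total_tracked else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if precision + recall else 0.0

    fractions = {
        gid: correct_per_gt[gid] / len(gt_pts[gid]) for gid in gt_pts
    }
    n = len(fractions)
    mt = sum(f > 0.8 for f in fractions.values()) / n
    ml = sum(f < 0.2 for f in fractions.values()) / n
    frag = 1.0 - mt - ml

    ids = _count_id_switches(pred_pts, gt_pts, tol)
    return EvalReport(precision, recall, f1, mt, ml, frag, ids,
                      per_trajectory=fractions, label_map=mapping)


def _count_id_switches(pred_pts, gt_pts, tol) -> int:
    """Events where a trajectory's matched ground-truth identity changes.

    Matching is sticky: while the previously matched identity is still
    within tolerance, it is retained.  During an occlusion two fish can
    both sit within tolerance of a trajectory; without hysteresis every
    crossing would register a spurious pair of switches even when the
    tracker holds identity perfectly.  A genuine post-occlusion swap is
    still counted: the old identity eventually leaves the tolerance
    radius while the trajectory follows the wrong fish.
    """
    switches = 0
    for pid, ppts in pred_pts.items():
        prev_gid = None
        for f in sorted(ppts):
            if prev_gid is not None and f in gt_pts.get(prev_gid, {}):
                if np.hypot(*(gt_pts[prev_gid][f] - ppts[f])) < tol:
                    continue
            best, best_d = None, np.inf
            for gid, gpts in gt_pts.items():
                if f in gpts:
                    d = float(np.hypot(*(gpts[f] - ppts[f])))
                    if d < best_d:
                        best, best_d = gid, d
            if best is None or best_d >= tol:
                continue
            if prev_gid is not None and best != prev_gid:
                switches += 1
            prev_gid = best
    return switches
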