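"""Frame-sequence and trajectory CSV input/output."""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, TYPE_CHECKING

import imageio.v3 as iio
import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .linking import Trajectory

#: Rec. 601 luminance weights used to collapse colour frames to grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])

_NUM_RE = re.compile(r"(\d+)")


@dataclass
class FrameSequence:
    """An ordered stack of same-sized 8-bit grayscale frames."""

    frames: np.ndarray  # (T, H, W) uint8

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")

    def __len__(self) -> int:
        return self.frames.shape[0]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) frame to 8-bit luminance; pass grayscale through."""
    if img.ndim == 2:
        return img.astype(np.uint8, copy=False)
    rgb = img[..., :3].astype(float)
    return np.clip(rgb @ _LUMA, 0, 255).round().astype(np.uint8)


def _numeric_index(name: str) -> int:
    m = _NUM_RE.findall(name)
    if not m:
        raise ValueError(f"filename {name!r} carries no frame index")
    return int(m[-1])


def read_frames(path: str | Path, pattern: str = "*.png") -> FrameSequence:
    """Read a numbered image sequence, sorted by the index in each filename.

    Frame indices must be consecutive (a missing frame is a hard error:
    the tracker's inter-frame matching assumes a fixed time step).
    """
    directory = Path(path)
    if not directory.is_dir():
        raise FileNotFoundError(f"frame directory {directory} does not exist")
    files = sorted(directory.glob(pattern), key=lambda p: _numeric_index(p.name))
    if len(files) < 2:
        raise ValueError(
            f"need at least 2 frames matching {pattern!r} in {directory}, "
            f"found {len(files)}"
        )
    indices = [_numeric_index(f.name) for f in files]
    for prev, cur, f in zip(indices, indices[1:], files[1:]):
        if cur == prev:
            raise ValueError(f"duplicate frame index in {f.name}")
        if cur != prev + 1:
            stem = _NUM_RE.sub(lambda m: str(prev + 1).zfill(len(m.group(1))), f.name, count=1)
            raise ValueError(f"frame sequence has a gap: missing {stem}")
    frames = np.stack([to_grayscale(iio.imread(f)) for f in files])
    return FrameSequence(frames)


def write_frames(seq: FrameSequence, directory: str | Path, prefix: str = "f") -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(len(seq) - 1)))
    paths = []
    for i, frame in enumerate(seq):
        p = directory / f"{prefix}{i:0{width}d}.png"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths


def trajectories_to_frame(trajs: list["Trajectory"]) -> pd.DataFrame:
    rows = []
    for traj in trajs:
        for frame in sorted(traj.points):
            x, y = traj.points[frame]
            rows.append(
                (frame, traj.fish_id, float(x), float(y), int(frame in traj.filled_frames))
            )
    df = pd.DataFrame(rows, columns=["frame", "id", "x", "y", "filled"])
    if df.duplicated(["frame", "id"]).any():
        dup = df[df.duplicated(["frame", "id"])].iloc[0]
        raise ValueError(f"duplicate (frame, id) row: ({dup.frame}, {dup.id})")
    return df.sort_values(["frame", "id"], kind="stable").reset_index(drop=True)


def write_trajectories(trajs: list["Trajectory"], path: str | Path) -> None:
    """Write trajectories as CSV ``frame,id,x,y,filled``; round-trip safe."""
    trajectories_to_frame(trajs).to_csv(path, index=False, float_format="%.3f")


def read_trajectories(path: str | Path) -> pd.DataFrame:
    """Read a trajectory or ground-truth CSV (``filled`` column optional)."""
    df = pd.read_csv(path)
    required = {"frame", "id", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    if "filled" not in df.columns:
        df["filled"] = 0
    if df.duplicated(["frame", "id"]).any():
        raise ValueError("duplicate (frame, id) rows in trajectory CSV")
    return df
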