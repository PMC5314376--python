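"""Tracker and scene configuration.

The user-facing detection parameters are ``num_fish``, ``sigma_range``,
``intensity_range``, ``match_radius`` and ``doh_threshold``; everything
else has defaults taken from the tracking procedure itself and rarely
needs touching.  Pixel-valued thresholds that were tuned for full
2048-pixel-wide video frames scale linearly with ``resolution_scale`` so
the same configuration works on smaller frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import yaml


@dataclass
class TrackerConfig:
    """All knobs of the tracking pipeline.

    Parameters
    ----------
    num_fish:
        Number of individuals in the video (known in advance).
    sigma_range:
        ``(sigma_min, sigma_max)`` in pixels; accepted blob scales for a
        fish head.
    intensity_range:
        ``(i_min, i_max)`` grayscale bounds on the intensity at a blob
        centre.  Fish are dark on a light background, so ``i_max`` acts
        as the polarity filter.
    doh_threshold:
        Minimum scale-normalised determinant-of-Hessian response.
    match_radius:
        Inter-frame candidate search radius in pixels.
    eta:
        Minimum segment length in frames; shorter segments are pruned.
    """

    num_fish: int
    sigma_range: tuple[float, float] = (2.0, 8.0)
    intensity_range: tuple[float, float] = (0.0, 120.0)
    doh_threshold: float = 500.0
    match_radius: float = 20.0
    eta: int = 3

    # Segment linking / bootstrap (pixel values at full resolution).
    df_link_max: float = 100.0
    candidate_radius: float = 600.0
    candidate_max_frames: int = 200
    direct_link_px: float = 90.0
    direct_link_frames: int = 10
    seg_df_k: int = 5

    # Classifier.
    id_freq_threshold: float = 0.2
    epochs: int = 30
    retrain_epochs: Optional[int] = None  # defaults to `epochs`
    learning_rate: float = 0.005
    batch_size: int = 64
    dropout: float = 0.2
    relu_all_convs: bool = False
    max_train_maps_per_label: Optional[int] = None
    min_maps_per_label: int = 10

    # Trajectory assembly / correction.
    link_max_frames: int = 1000
    link_max_px: float = 2000.0
    flow_window: int = 30
    dis_max: float = 100.0
    gap_near_px: float = 20.0
    gap_far_px: float = 300.0
    gap_ratio: float = 0.6
    displacement_threshold: Optional[float] = None  # xi; None -> auto

    # Feature maps.
    patch_halfside: int = 46
    map_size: int = 65

    # Scaling of pixel thresholds for non-native frame sizes.
    resolution_scale: float = 1.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_fish < 1:
            raise ValueError("num_fish must be >= 1")
        lo, hi = self.sigma_range
        if not lo < hi:
            raise ValueError("sigma_range must satisfy sigma_min < sigma_max")
        if lo <= 0:
            raise ValueError("sigma_min must be positive")
        if min(self.intensity_range) < 0 or self.doh_threshold < 0:
            raise ValueError("pixel thresholds must be non-negative")
        if not 0.0 < self.id_freq_threshold < 1.0:
            raise ValueError("id_freq_threshold must lie in (0, 1)")

    # Pixel thresholds below were tuned on full-resolution frames and
    # shrink proportionally on smaller frames.
    def px(self, value: float) -> float:
        return value * self.resolution_scale

    @property
    def effective_retrain_epochs(self) -> int:
        return self.epochs if self.retrain_epochs is None else self.retrain_epochs

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["sigma_range"] = list(self.sigma_range)
        d["intensity_range"] = list(self.intensity_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrackerConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("sigma_range", "intensity_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SceneConfig:
    """Parameters of the synthetic fish-swimming scene generator."""

    num_fish: int = 5
    width: int = 512
    height: int = 512
    n_frames: int = 300
    body_length: float = 36.0
    body_width: float = 10.0
    head_length: float = 18.0
    head_width: float = 12.0
    speed_mean: float = 3.0
    speed_std: float = 0.6
    heading_kappa: float = 40.0  # persistence; noise std = 1/sqrt(kappa) rad
    wall_margin: float = 30.0
    crossings: Sequence[tuple[int, int, int]] = field(default_factory=list)
    clutter_specks: int = 0
    speck_radius: float = 1.5
    background: float = 200.0
    body_intensity: float = 120.0
    head_intensity: float = 55.0
    snout_intensity: float = 55.0
    texture_fraction: float = 0.5
    ripple_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        reach = self.body_length + self.wall_margin
        if 2 * reach >= min(self.width, self.height):
            raise ValueError("fish geometry does not fit inside the frame")
        seen: dict[int, list[int]] = {}
        for frame, a, b in self.crossings:
            if a == b:
                raise ValueError("crossing needs two distinct fish")
            for f in (a, b):
                if not 0 <= f < self.num_fish:
                    raise ValueError(f"crossing fish index {f} out of range")
                for other in seen.get(f, []):
                    if abs(other - frame) < 60:
                        raise ValueError(
                            f"fish {f} scheduled in two crossings within 60 frames"
                        )
                seen.setdefault(f, []).append(frame)
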