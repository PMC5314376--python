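"""Shared fixtures: small rendered scenes and matched tracker configs.

Everything is generated at test time from fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from fintrack.blob import detect_heads
from fintrack.config import SceneConfig
from fintrack.features import make_feature_map
from fintrack.synth import FIXTURES, fixture_tracker_config, generate


@pytest.fixture(scope="session")
def lone_fish():
    """(gt, frames, config) for a single fish in a small arena."""
    gt, frames = generate(FIXTURES["lone_fish"])
    return gt, frames, fixture_tracker_config("lone_fish")


@pytest.fixture(scope="session")
def clutter_scene():
    """Five fish plus three out-of-scale specks."""
    gt, frames = generate(FIXTURES["clutter"])
    return gt, frames, fixture_tracker_config("clutter")


@pytest.fixture(scope="session")
def lone_fish_maps(lone_fish):
    """Canonical feature maps of the lone fish at every 4th frame."""
    gt, frames, config = lone_fish
    maps, headings = [], []
    for t in range(0, len(frames), 4):
        dets = detect_heads(frames[t], config, t)
        assert len(dets) == 1
        maps.append(make_feature_map(frames[t], dets[0], config))
        headings.append(float(gt[gt.frame == t].iloc[0].heading))
    return maps, headings


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def render_single_pose(x: float, y: float, heading: float,
                       size: int = 256, fish_id: int = 0,
                       scene: SceneConfig | None = None):
    """Render one fish at an exact pose; returns (frame, scene)."""
    import pandas as pd

    from fintrack.synth import _fish_textures, render_frame

    scene = scene or SceneConfig(num_fish=max(1, fish_id + 1), width=size,
                                 height=size, n_frames=2, seed=5)
    gt = pd.DataFrame([{"frame": 0, "id": fish_id, "x": x, "y": y,
                        "heading": heading}])
    frame = render_frame(gt, scene, _fish_textures(scene), np.empty((0, 2)))
    return frame, scene
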