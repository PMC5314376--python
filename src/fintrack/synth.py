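"""Synthetic ground-truthed fish-swimming videos.

The generator emulates the top view of a shallow tank: dark elongated
fish on a light background.  Each fish is an oriented body ellipse with
a darker, partially elliptical head, stamped with a unique fixed stripe
texture that rotates rigidly with the fish.  The texture plays the role
of the individual appearance differences that make per-fish
classification possible; texture "holes" take the background intensity,
so they survive Otsu binarisation into the binary feature map.

Motion is a correlated-heading random walk (heading noise with
persistence ``kappa``; specular wall reflection), and pairwise crossings
can be scheduled: the designated pair is steered toward a common meeting
point so their heads pass within about one body length at the scheduled
frame, producing genuine occlusions.

Ground truth is the per-frame head-centre coordinate of every identity.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import SceneConfig, TrackerConfig
from .io import FrameSequence, write_frames

_TWO_PI = 2.0 * np.pi


def simulate_trajectories(scene: SceneConfig) -> pd.DataFrame:
    """Simulate head-centre trajectories; columns frame,id,x,y,heading."""
    rng = np.random.default_rng(scene.seed)
    n, t_total = scene.num_fish, scene.n_frames
    margin = scene.wall_margin + scene.body_length
    lo = np.array([margin, margin])
    hi = np.array([scene.width - margin, scene.height - margin])
    pos = lo + rng.random((n, 2)) * (hi - lo)
    heading = rng.uniform(0, _TWO_PI, n)
    noise_std = 1.0 / np.sqrt(scene.heading_kappa)
    window = 30

    # active steering targets: fish -> (target_point, arrival_frame)
    steering: dict[int, tuple[np.ndarray, int]] = {}
    schedule = sorted(scene.crossings)

    rows = []
    for t in range(t_total):
        for frame, a, b in schedule:
            if t == max(0, frame - window):
                meet = 0.5 * (pos[a] + pos[b])
                meet = np.clip(meet, lo, hi)
                steering[a] = (meet, frame)
                steering[b] = (meet, frame)
        for i in range(n):
            rows.append((t, i, pos[i, 0], pos[i, 1], np.degrees(heading[i]) % 360.0))
        speed = np.clip(
            rng.normal(scene.speed_mean, scene.speed_std, n), 0.2 * scene.speed_mean, None
        )
        heading = heading + rng.normal(0.0, noise_std, n)
        for i, (target, arrive) in list(steering.items()):
            if t >= arrive:
                del steering[i]
                continue
            delta = target - pos[i]
            dist = float(np.hypot(*delta))
            want = np.arctan2(delta[1], delta[0])
            turn = (want - heading[i] + np.pi) % _TWO_PI - np.pi
            heading[i] += np.clip(turn, -0.3, 0.3)
            steps_left = max(arrive - t, 1)
            speed[i] = np.clip(dist / steps_left, 0.5 * scene.speed_mean,
                               2.0 * scene.speed_mean)
        # mild mutual avoidance so that close approaches happen only at
        # the scheduled crossings
        for i in range(n):
            if i in steering:
                continue
            for j in range(n):
                if j == i:
                    continue
                delta = pos[i] - pos[j]
                dist = float(np.hypot(*delta))
                if 0 < dist < 2.5 * scene.body_length:
                    away = np.arctan2(delta[1], delta[0])
                    turn = (away - heading[i] + np.pi) % _TWO_PI - np.pi
                    heading[i] += np.clip(turn, -0.2, 0.2)
        step = np.stack([np.cos(heading), np.sin(heading)], axis=1) * speed[:, None]
        pos = pos + step
        # specular reflection off the arena walls
        for axis in (0, 1):
            low, high = lo[axis], hi[axis]
            under = pos[:, axis] < low
            over = pos[:, axis] > high
            pos[under, axis] = 2 * low - pos[under, axis]
            pos[over, axis] = 2 * high - pos[over, axis]
            if axis == 0:
                heading[under | over] = np.pi - heading[under | over]
            else:
                heading[under | over] = -heading[under | over]
        heading %= _TWO_PI
    return pd.DataFrame(rows, columns=["frame", "id", "x", "y", "heading"]).astype(
        {"frame": int, "id": int}
    )


def _fish_textures(scene: SceneConfig) -> list[np.ndarray]:
    """Per-fish fixed boolean stripe grids over fish-local coordinates.

    Oblique low-frequency bands spanning the whole fish; wide bands keep
    the hole boundary short, so the pattern is stable under rotation and
    re-binarisation.  Periods are spaced deterministically and slopes
    alternate in sign so no two individuals can draw near-identical
    patterns — the premise of appearance-based identification is that
    individuals differ.  Phases (and the period-to-fish assignment) come
    from the scene seed.
    """
    rng = np.random.default_rng(scene.seed + 7919)
    length = scene.body_length + scene.head_length
    rows, cols = max(6, int(scene.body_width)), max(12, int(length))
    jj, ii = np.meshgrid(np.arange(cols), np.arange(rows), indexing="xy")
    n = scene.num_fish
    periods = np.linspace(6.0, 11.0, n) if n > 1 else np.array([8.0])
    rng.shuffle(periods)
    textures = []
    for k in range(n):
        slope = (0.25 + 0.12 * (k // 2)) * (1 if k % 2 else -1)
        phase = rng.uniform(0, _TWO_PI)
        wave = np.sin(_TWO_PI * (jj + slope * ii) / periods[k] + phase)
        textures.append(wave > np.cos(np.pi * scene.texture_fraction))
    return textures


def render_frame(
    gt_frame: pd.DataFrame,
    scene: SceneConfig,
    textures: list[np.ndarray],
    speck_xy: np.ndarray,
    phase: float = 0.0,
) -> np.ndarray:
    h, w = scene.height, scene.width
    img = np.full((h, w), scene.background, np.float64)
    if scene.ripple_amplitude > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        img += scene.ripple_amplitude * np.sin(_TWO_PI * (xx / 96.0 + phase)) * np.sin(
            _TWO_PI * yy / 64.0
        )
    a_b, b_b = scene.body_length / 2, scene.body_width / 2
    a_h, b_h = scene.head_length / 2, scene.head_width / 2
    reach = int(np.ceil(scene.body_length + a_h)) + 2
    for row in gt_frame.itertuples(index=False):
        cx, cy, th = float(row.x), float(row.y), np.radians(float(row.heading))
        u = np.array([np.cos(th), np.sin(th)])
        x0, x1 = int(cx) - reach, int(cx) + reach + 1
        y0, y1 = int(cy) - reach, int(cy) + reach + 1
        x0c, x1c = max(x0, 0), min(x1, w)
        y0c, y1c = max(y0, 0), min(y1, h)
        if x0c >= x1c or y0c >= y1c:
            continue
        yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
        dx, dy = xx - cx, yy - cy
        xi = dx * u[0] + dy * u[1]          # along heading
        et = -dx * u[1] + dy * u[0]         # across heading
        # body ellipse, centred behind the head centre
        bc = a_h * 0.4 + a_b
        body = ((xi + bc) / a_b) ** 2 + (et / b_b) ** 2 <= 1.0
        head = (xi / a_h) ** 2 + (et / b_h) ** 2 <= 1.0
        tile = img[y0c:y1c, x0c:x1c]
        tile[body] = scene.body_intensity
        head_val = np.where(xi > 0.45 * a_h, scene.snout_intensity, scene.head_intensity)
        tile[head] = head_val[head]
        # rigid speckle texture in fish-local coordinates; holes take the
        # background value so they drop out of the Otsu foreground and
        # imprint the individual pattern on the binary feature map.  A
        # core disk around the head centre stays hole-free so the blob
        # centre is stable.
        tex = textures[int(row.id)]
        length = a_h + 2 * a_b + bc - a_b  # snout tip to tail tip
        gi = np.clip(((et / b_h + 1) / 2 * tex.shape[0]).astype(int), 0, tex.shape[0] - 1)
        gj = np.clip(((a_h - xi) / length * tex.shape[1]).astype(int), 0, tex.shape[1] - 1)
        fish = body | head
        holes = fish & tex[gi, gj] & (dx**2 + dy**2 > 5.0**2)
        tile[holes] = scene.background
    # slight optical blur: stabilises silhouette edges under rotation and
    # mimics the camera point-spread function
    img = ndimage.gaussian_filter(img, 0.8)
    for sx, sy in speck_xy:
        yy, xx = np.mgrid[max(0, int(sy) - 4) : min(h, int(sy) + 5),
                          max(0, int(sx) - 4) : min(w, int(sx) + 5)]
        speck = (xx - sx) ** 2 + (yy - sy) ** 2 <= scene.speck_radius**2
        img[max(0, int(sy) - 4) : min(h, int(sy) + 5),
            max(0, int(sx) - 4) : min(w, int(sx) + 5)][speck] = scene.head_intensity
    return np.clip(img, 0, 255).round().astype(np.uint8)


def render_frames(gt: pd.DataFrame, scene: SceneConfig) -> FrameSequence:
    """Render the ground truth into an 8-bit grayscale frame stack."""
    textures = _fish_textures(scene)
    rng = np.random.default_rng(scene.seed + 104729)
    margin = scene.wall_margin
    speck_xy = margin + rng.random((scene.clutter_specks, 2)) * (
        np.array([scene.width, scene.height]) - 2 * margin
    )
    frames = np.stack(
        [
            render_frame(gt[gt["frame"] == t], scene, textures, speck_xy,
                         phase=t / 40.0)
            for t in range(scene.n_frames)
        ]
    )
    return FrameSequence(frames)


def generate(scene: SceneConfig) -> tuple[pd.DataFrame, FrameSequence]:
    gt = simulate_trajectories(scene)
    return gt, render_frames(gt, scene)


# ----------------------------------------------------------------------
# Canonical fixtures

_BASE = SceneConfig()

FIXTURES: dict[str, SceneConfig] = {
    "lone_fish": replace(_BASE, num_fish=1, width=256, height=256, n_frames=120,
                         seed=3),
    "five_fish_crossings": replace(
        _BASE, num_fish=5, n_frames=600, seed=7,
        crossings=[(100, 0, 1), (180, 2, 3), (260, 1, 4), (340, 0, 2),
                   (430, 3, 4), (520, 1, 2)],
    ),
    "clutter": replace(_BASE, num_fish=5, n_frames=120, clutter_specks=3, seed=11),
    "swap_injection": replace(
        _BASE, num_fish=2, width=384, height=384, n_frames=200, seed=13,
        crossings=[(100, 0, 1)],
    ),
}


def fixture_tracker_config(name: str, **overrides) -> TrackerConfig:
    """Tracker configuration matched to the synthetic fixtures.

    Fixture frames are 512 px wide rather than the 2048 px the
    pixel-valued linking thresholds were tuned for, hence
    ``resolution_scale = 0.25``.  Training is scaled to the per-video
    regime of the fixtures: 10 epochs (5 on retraining sweeps) over at
    most 150 maps per fish before augmentation.
    """
    scene = FIXTURES[name]
    base = dict(
        num_fish=scene.num_fish,
        sigma_range=(3.0, 6.5),
        intensity_range=(0.0, 90.0),
        doh_threshold=500.0,
        match_radius=20.0,
        eta=3,
        resolution_scale=scene.width / 2048.0,
        epochs=10,
        retrain_epochs=5,
        max_train_maps_per_label=150,
        flow_window=16,
        dis_max=200.0,
        seed=scene.seed,
    )
    base.update(overrides)
    return TrackerConfig(**base)


def make_fixture(name: str, out_dir: str | Path) -> tuple[Path, Path, Path]:
    """Write a registered fixture to disk: frames/, gt.csv, config.yaml."""
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    scene = FIXTURES[name]
    out = Path(out_dir)
    frames_dir = out / "frames"
    gt, seq = generate(scene)
    write_frames(seq, frames_dir)
    gt_path = out / "gt.csv"
    gt.to_csv(gt_path, index=False, float_format="%.3f")
    cfg_path = out / "config.yaml"
    fixture_tracker_config(name).to_yaml(cfg_path)
    return frames_dir, gt_path, cfg_path
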