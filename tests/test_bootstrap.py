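"""Automatic training-data generation: chains, collections, augmentation."""

import numpy as np
import pytest

from fintrack.blob import HeadDetection
from fintrack.bootstrap import (BootstrapError, augment_detection,
                                build_training_items, find_collections,
                                generate_initial_trajectories,
                                link_adjacent_collections, split_training_set,
                                TrainingItem)
from fintrack.features import HeadFeatureMap
from fintrack.segments import TrajectorySegment
from fintrack.synth import fixture_tracker_config


def _map_with_ones(n, size=65):
    b = np.zeros((size, size), np.uint8)
    b.flat[:n] = 1
    return HeadFeatureMap(gray=b * 255.0, binary=b, theta=0.0, threshold=128.0)


def seg(seg_id, start, length, x=0.0, y=0.0, ones=0):
    ds = [HeadDetection(start + t, x + t, y, 4.0, 100.0, 50.0)
          for t in range(length)]
    return TrajectorySegment(seg_id, ds, [_map_with_ones(ones)] * length)


class TestInitialTrajectories:
    def _cfg(self, **kw):
        return fixture_tracker_config("five_fish_crossings", **kw)

    def test_single_close_candidate_links_directly(self):
        """A lone candidate within the 90 px / 10 frame window links
        without comparing dF against other candidates — it wins even
        when a farther candidate has smaller dF — but it must still
        clear the dF ceiling (a near candidate that looks like a
        different fish is the classic post-crossing trap)."""
        cfg = self._cfg(resolution_scale=1.0)
        base = seg(0, 0, 20, x=0, ones=0)
        near = seg(1, 24, 20, x=31, ones=80)            # 5 frames, 12 px
        far_better = seg(2, 24, 20, x=150, ones=5)      # smaller dF, not direct
        chains = generate_initial_trajectories([base, near, far_better], 1, cfg)
        assert chains[0][:2] == [0, 1]

    def test_direct_candidate_failing_df_ceiling_rejected(self):
        cfg = self._cfg(resolution_scale=1.0)
        base = seg(0, 0, 20, x=0, ones=0)
        impostor = seg(1, 24, 20, x=31, ones=3000)      # direct window, dF 3000
        chains = generate_initial_trajectories([base, impostor], 1, cfg)
        assert chains == [[0]]

    def test_df_selection_and_threshold(self):
        """Two distant candidates: the one with mean dF 40 links; a
        candidate with dF 350 would also fail the dF < 100 ceiling."""
        cfg = self._cfg(resolution_scale=1.0)
        base = seg(0, 0, 20, x=0, ones=0)
        good = seg(1, 30, 20, x=150, ones=40)
        bad = seg(2, 30, 20, x=160, y=30, ones=350)
        chains = generate_initial_trajectories([base, good, bad], 2, cfg)
        assert chains[0] == [0, 1]

    def test_df_ceiling_blocks_link(self):
        cfg = self._cfg(resolution_scale=1.0)
        base = seg(0, 0, 20, x=0, ones=0)
        far = seg(1, 30, 20, x=150, ones=350)
        chains = generate_initial_trajectories([base, far], 2, cfg)
        assert chains == [[0], [1]]

    def test_duplicate_segments_removed_from_all_chains(self):
        # two bases both link segment 2; deduplication removes it from both
        cfg = self._cfg(resolution_scale=1.0)
        a = seg(0, 0, 10, x=0, y=0, ones=10)
        b = seg(1, 0, 10, x=300, y=300, ones=10)
        shared = seg(2, 15, 10, x=150, y=150, ones=10)
        chains = generate_initial_trajectories([a, b, shared], 2, cfg)
        assert all(2 not in c for c in chains)

    def test_insufficient_segments_fatal(self):
        cfg = self._cfg(resolution_scale=1.0)
        with pytest.raises(BootstrapError):
            generate_initial_trajectories([seg(0, 0, 10)], 3, cfg)


class TestCollections:
    def test_reference_six_segment_topology(self):
        """Three identities, six segments; {1,2,3} share 4 frames and
        {4,5,6} share 9 frames -> two collections, {4,5,6} ranked first."""
        segs = [
            seg(1, 0, 12),        # frames 0..11
            seg(2, 5, 7),         # frames 5..11
            seg(3, 8, 4),         # frames 8..11   -> {1,2,3} share 8..11 (4)
            seg(4, 14, 15),       # frames 14..28
            seg(5, 16, 13),       # frames 16..28
            seg(6, 20, 9),        # frames 20..28  -> {4,5,6} share 20..28 (9)
        ]
        cols = find_collections(segs, 3)
        assert len(cols) == 2
        assert cols[0].segment_ids == {4, 5, 6} and cols[0].length == 9
        assert cols[1].segment_ids == {1, 2, 3} and cols[1].length == 4

    def test_partial_frames_not_in_collection(self):
        segs = [seg(0, 0, 10), seg(1, 0, 10), seg(2, 5, 5)]
        cols = find_collections(segs, 3)
        assert all(c.start >= 5 for c in cols)
        for c in cols:
            for sid in c.segment_ids:
                s = next(x for x in segs if x.seg_id == sid)
                assert s.start_frame <= c.start and s.end_frame >= c.end

    def test_empty_when_never_complete(self):
        assert find_collections([seg(0, 0, 10)], 2) == []


class TestCollectionLinking:
    def test_identical_textures_recover_identity(self):
        c1_segs = [seg(0, 0, 10, ones=10), seg(1, 0, 10, ones=200),
                   seg(2, 0, 10, ones=400)]
        c2_segs = [seg(3, 20, 10, ones=395), seg(4, 20, 10, ones=12),
                   seg(5, 20, 10, ones=198)]
        segs = c1_segs + c2_segs
        cols = find_collections(segs, 3)
        cols.sort(key=lambda c: c.start)
        pairs = link_adjacent_collections(cols[0], cols[1], segs)
        assert sorted(pairs) == [(0, 4), (1, 5), (2, 3)]

    def test_single_fish_trivial_pair(self):
        segs = [seg(0, 0, 10), seg(1, 20, 10)]
        cols = sorted(find_collections(segs, 1), key=lambda c: c.start)
        assert link_adjacent_collections(cols[0], cols[-1], segs) == [(0, 1)]

    def test_pairs_disjoint_and_covering(self):
        segs = [seg(i, 0, 10, ones=i * 50) for i in range(4)] + \
               [seg(4 + i, 20, 10, ones=i * 60 + 5) for i in range(4)]
        cols = sorted(find_collections(segs, 4), key=lambda c: c.start)
        pairs = link_adjacent_collections(cols[0], cols[1], segs)
        assert len(pairs) == 4
        assert len({a for a, _ in pairs}) == 4 and len({b for _, b in pairs}) == 4


class TestAugmentation:
    def test_four_shifts_plus_original(self, lone_fish):
        gt, frames, config = lone_fish
        from fintrack.blob import detect_heads
        d = detect_heads(frames[10], config, 10)[0]
        shifted = augment_detection(frames, d, config)
        assert len(shifted) == 4

    def test_augmented_maps_close_to_original(self, lone_fish):
        gt, frames, config = lone_fish
        from fintrack.blob import detect_heads
        from fintrack.features import make_feature_map
        d = detect_heads(frames[10], config, 10)[0]
        orig = make_feature_map(frames[10], d, config)
        for g in augment_detection(frames, d, config):
            df = np.count_nonzero((g <= orig.threshold) != orig.binary)
            assert df < 0.15 * 65 * 65

    def test_out_of_frame_shift_skipped(self, lone_fish):
        from fintrack.io import FrameSequence
        _, _, config = lone_fish
        rng = np.random.default_rng(0)
        frames = FrameSequence(rng.integers(0, 255, (2, 128, 128), dtype=np.uint8))
        d = HeadDetection(0, 0.0, 0.0, 4.0, 100.0, 50.0)
        assert len(augment_detection(frames, d, config)) == 2  # only +x, +y

    def test_labels_preserved_and_counts(self, lone_fish):
        _, frames, config = lone_fish
        from fintrack.blob import detect_heads
        from fintrack.features import make_feature_map
        ds = [detect_heads(frames[t], config, t)[0] for t in range(4)]
        s = TrajectorySegment(0, ds, [
            make_feature_map(frames[d.frame], d, config) for d in ds
        ])
        rng = np.random.default_rng(0)
        items = build_training_items({0: 3}, [s], frames, config, rng)
        assert len(items) == 4 * 5          # 4 sources x (1 + 4 shifts)
        assert all(it.label == 3 for it in items)


class TestSplit:
    def _items(self, n_sources, label=0):
        items = []
        for i in range(n_sources):
            for aug in range(5):
                items.append(TrainingItem(np.zeros((65, 65)), label, 0,
                                          aug > 0, (0, i)))
        return items

    def test_80_20_arithmetic(self):
        items = self._items(100, 0) + [
            TrainingItem(np.zeros((65, 65)), 1, 1, a > 0, (1, i))
            for i in range(100) for a in range(5)
        ]
        tset = split_training_set(items, np.random.default_rng(0))
        assert len(tset.train_idx) == 800 and len(tset.test_idx) == 200

    def test_no_augmented_leakage_across_split(self):
        tset = split_training_set(self._items(20), np.random.default_rng(1))
        train_sources = {tset.items[i].source_key for i in tset.train_idx}
        test_sources = {tset.items[i].source_key for i in tset.test_idx}
        assert not train_sources & test_sources


def test_training_set_dump(tmp_path, rng):
    from fintrack.bootstrap import TrainingSet, dump_training_set
    import pandas as pd
    items = [TrainingItem(rng.random((65, 65)) * 255, k % 2, k, False, (k, 0))
             for k in range(6)]
    tset = TrainingSet(items=items, train_idx=[0, 1, 2, 3], test_idx=[4, 5])
    dump_training_set(tset, tmp_path / "dump")
    manifest = pd.read_csv(tmp_path / "dump" / "labels.csv")
    assert len(manifest) == 6
    assert (manifest.split == "test").sum() == 2
    assert len(list((tmp_path / "dump").glob("*.png"))) == 6
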