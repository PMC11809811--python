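"""Tracker specs, proxy-box IoU, training contracts, trained behaviour."""

import numpy as np
import pytest

from seedtrack import tracker as trk
from seedtrack.core import Clip, make_seed_channel
from seedtrack.tracker import (
    TrackerNet, TrainConfig, build_tracker_spec, mean_proxy_iou,
    proxy_box_iou, reduced_tracker_spec, track_clip, track_movie_general,
    train_tracker,
)
from seedtrack import synthetic as syn


class TestSpecs:
    def test_tracker5_branch_output_width(self):
        spec = build_tracker_spec(5)
        assert spec.branch_output_width == 10
        assert (spec.fc1, spec.dropout, spec.fc2) == (1024, 0.05, 512)

    def test_tracker1_single_fc(self):
        spec = build_tracker_spec(1)
        assert spec.fc1 == 256 and spec.fc2 is None and spec.dropout is None
        assert spec.branch_output_width == 2

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5])
    def test_whole_clip_output_length(self, n):
        assert build_tracker_spec(n).output_length == 2 * 4 * n

    def test_dedicated_conv_stack_matches_reference_table(self):
        spec = build_tracker_spec(3)
        assert spec.conv_stack == [64, 64, "P", 128, "P", 256, "P", 512]

    def test_general_variant_enlarged(self):
        spec = build_tracker_spec(1, general=True)
        assert spec.conv_stack.count(64) == 4      # doubled 64s
        assert spec.conv_stack.count(128) == 2     # doubled 128
        assert spec.conv_stack[:2] == [32, 32]     # extra front double layer
        assert spec.fc1 == 1024 and spec.fc2 == 1024
        assert spec.dropout is None

    def test_general_requires_single_cell(self):
        with pytest.raises(ValueError):
            build_tracker_spec(2, general=True)

    def test_unsupported_cell_count(self):
        with pytest.raises(ValueError):
            build_tracker_spec(6)

    def test_no_pooling_along_time_structurally(self):
        # every pooling layer is (2,2,1); the temporal depth of a seeded
        # clip survives the whole conv stack
        rng = np.random.default_rng(0)
        spec = reduced_tracker_spec(1, general=True, input_side=32)
        net = TrackerNet(spec, rng)
        x = rng.normal(size=(1, 32, 32, 5, 1)).astype(np.float32)
        net.forward(x)
        assert net._conv_out_shape[3] == 5


class TestProxyBoxIoU:
    def test_identical_centroids(self):
        assert proxy_box_iou((10, 10), (10, 10), 40) == 1.0

    def test_half_offset_arithmetic(self):
        # offset (20, 0), side 40: intersection 20*40=800, union 2400
        assert proxy_box_iou((0, 0), (20, 0), 40) == pytest.approx(1 / 3)

    def test_disjoint_boxes(self):
        assert proxy_box_iou((0, 0), (40, 0), 40) == 0.0
        assert proxy_box_iou((0, 0), (0, 41), 40) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b = rng.uniform(0, 100, size=(2, 2))
            assert proxy_box_iou(a, b) == pytest.approx(proxy_box_iou(b, a))

    def test_matches_rasterized_oracle(self):
        """Closed-form square IoU equals pixel-counted IoU on integer
        grids for 1000 random integer centroid pairs."""
        rng = np.random.default_rng(2)
        side = 40
        for _ in range(1000):
            ax, ay, bx, by = rng.integers(20, 120, size=4)
            canvas = np.zeros((180, 180), dtype=np.uint8)
            canvas[ay - side // 2:ay + side // 2,
                   ax - side // 2:ax + side // 2] += 1
            canvas[by - side // 2:by + side // 2,
                   bx - side // 2:bx + side // 2] += 1
            inter = (canvas == 2).sum()
            union = (canvas >= 1).sum()
            assert proxy_box_iou((ax, ay), (bx, by), side) == \
                pytest.approx(inter / union)

    def test_invalid_side(self):
        with pytest.raises(ValueError):
            proxy_box_iou((0, 0), (0, 0), 0)


class TestTrainingContracts:
    def _tiny_dataset(self, rng, n=24):
        spec = reduced_tracker_spec(1, general=True, input_side=16)
        ds = trk.make_tracker_training_set(n, spec, rng,
                                           n_distractors=(0, 0))
        return spec, ds

    def test_determinism_same_seed_same_history(self):
        spec, ds = self._tiny_dataset(np.random.default_rng(10))
        cfg = TrainConfig(learning_rate=1e-3, batch_size=8, epochs=2, seed=3)
        _, h1 = train_tracker(spec, ds, cfg)
        _, h2 = train_tracker(spec, ds, cfg)
        assert h1.equals(h2)

    def test_loss_decreases(self):
        spec, ds = self._tiny_dataset(np.random.default_rng(11))
        cfg = TrainConfig(learning_rate=1e-3, batch_size=8, epochs=5, seed=3)
        _, hist = train_tracker(spec, ds, cfg)
        assert hist["train_loss"].iloc[-1] < hist["train_loss"].iloc[0]

    def test_batch_size_default_is_32(self):
        assert TrainConfig().batch_size == 32
        assert TrainConfig().optimizer == "adam"
        assert TrainConfig().epochs == 150

    def test_unnormalized_labels_rejected(self):
        spec, ds = self._tiny_dataset(np.random.default_rng(12))
        ds.labels = ds.labels * 382
        with pytest.raises(ValueError, match="normalized"):
            train_tracker(spec, ds, TrainConfig(epochs=1))

    def test_scrambled_seed_audit_fails(self):
        spec, ds = self._tiny_dataset(np.random.default_rng(13))
        ds.seed_centroids = 1.0 - ds.seed_centroids[::-1]
        with pytest.raises(ValueError, match="mismatch"):
            train_tracker(spec, ds, TrainConfig(epochs=1))

    def test_seed_count_mismatch_instructs_switch(self):
        rng = np.random.default_rng(14)
        spec = reduced_tracker_spec(1, general=True, input_side=16)
        net = TrackerNet(spec, rng)
        frames = rng.random((4, 382, 382)).astype(np.float32)
        seed = make_seed_channel([(1, (50, 50)), (2, (150, 150))],
                                 (382, 382))
        clip = Clip(frames=frames, start_index=0, seed=seed)
        with pytest.raises(ValueError, match="Tracker-2"):
            track_clip(net, clip)

    def test_unseeded_clip_rejected(self):
        rng = np.random.default_rng(15)
        net = TrackerNet(reduced_tracker_spec(1, input_side=16), rng)
        clip = Clip(frames=rng.random((4, 64, 64)).astype(np.float32),
                    start_index=0)
        with pytest.raises(ValueError, match="seed"):
            track_clip(net, clip)


class TestTrainedGeneralTracker:
    def test_heldout_proxy_iou_above_half(self, toy_general_tracker):
        """Desk-scale single-seeded-cell tracking reaches proxy-box IoU
        > 0.5 on fresh synthetic clips."""
        net, _ = toy_general_tracker
        ds = trk.make_tracker_training_set(
            80, net.spec, np.random.default_rng(555), n_distractors=(0, 2))
        pred = net.forward(ds.clips)
        iou = mean_proxy_iou(pred * ds.label_side, ds.labels * ds.label_side)
        assert iou > 0.5

    def test_stationary_cell_low_variance(self, toy_general_tracker):
        net, _ = toy_general_tracker
        cfg = syn.SimConfig(n_frames=5, n_cells=1, seed=77,
                            motion=syn.MotionModel(b=0.0))
        movie, _, tree, _ = syn.simulate_movie(cfg)
        pos0 = tree.positions_at(0)[1]
        seed = make_seed_channel([(0, pos0)], movie.frame_shape,
                                 palette=(255,))
        clip = Clip(frames=movie.fluor[1:5], start_index=1, seed=seed)
        pred = track_clip(net, clip)[:, 0, :]
        assert np.var(pred, axis=0).max() < 20 ** 2  # well under cell radius

    def test_unseeded_distractors_ignored(self, toy_general_tracker):
        """With one seeded cell among two unseeded ones, the output stays
        on the seeded cell's ground truth."""
        net, _ = toy_general_tracker
        rng = np.random.default_rng(556)
        ds = trk.make_tracker_training_set(40, net.spec, rng,
                                           n_distractors=(2, 2))
        pred = net.forward(ds.clips)
        iou = mean_proxy_iou(pred * ds.label_side, ds.labels * ds.label_side)
        assert iou > 0.4  # tracks the seeded cell, not a distractor blend

    def test_general_passes_not_worse_than_dedicated(self, toy_general_tracker,
                                                     toy_tracker2):
        """Running the single-cell general tracker once per cell matches a
        dedicated 2-cell tracker: no loss of accuracy from going general
        (both scored against ground truth on the same movies)."""
        general, _ = toy_general_tracker
        dedicated, _ = toy_tracker2
        gen_scores, ded_scores = [], []
        for seed in (88, 188, 288):
            cfg = syn.SimConfig(n_frames=8, n_cells=2, seed=seed)
            movie, _, tree, _ = syn.simulate_movie(cfg)
            pos0 = tree.positions_at(0)
            gen_tracks = track_movie_general(
                general, movie, [(cid, pos0[cid]) for cid in sorted(pos0)])
            from seedtrack.core import slice_clips
            pos = dict(pos0)
            ded_states = {cid: {} for cid in sorted(pos0)}
            for idx, frames in slice_clips(movie):
                seed_ch = make_seed_channel(
                    [(cid, pos[cid]) for cid in sorted(pos)],
                    movie.frame_shape)
                pred = track_clip(dedicated,
                                  Clip(frames=frames, start_index=idx[0],
                                       seed=seed_ch))
                for rank, cid in enumerate(sorted(pos)):
                    for t_local, f in enumerate(idx):
                        ded_states[cid][f] = tuple(pred[t_local, rank])
                    pos[cid] = tuple(pred[-1, rank])
            for cid in sorted(pos0):
                gen_xy = {f: (x, y) for f, x, y in gen_tracks[cid].states}
                for f in gen_xy:
                    truth = tree.positions_at(f)[cid]
                    gen_scores.append(proxy_box_iou(gen_xy[f], truth))
                    ded_scores.append(proxy_box_iou(ded_states[cid][f],
                                                    truth))
        assert np.mean(gen_scores) > np.mean(ded_scores) - 0.05

    def test_single_cell_movie_equals_clip_loop(self, toy_general_tracker):
        net, _ = toy_general_tracker
        cfg = syn.SimConfig(n_frames=8, n_cells=1, seed=89)
        movie, _, tree, _ = syn.simulate_movie(cfg)
        pos0 = tree.positions_at(0)[1]
        tracks = track_movie_general(net, movie, [(1, pos0)])
        # manual loop over the same two clips
        from seedtrack.core import slice_clips
        manual = []
        pos = pos0
        for idx, frames in slice_clips(movie):
            seed = make_seed_channel([(0, pos)], movie.frame_shape,
                                     palette=(255,))
            pred = track_clip(net, Clip(frames=frames, start_index=idx[0],
                                        seed=seed))
            for t_local, f in enumerate(idx):
                manual.append((f, *pred[t_local, 0]))
            pos = tuple(pred[-1, 0])
        assert tracks[1].states == [(f, x, y) for f, x, y in manual]


class TestSeedEquivariance:
    def test_identity_follows_seed_rank(self, toy_tracker2):
        """Swapping the two seed squares swaps which output slot tracks
        which cell: identity is carried by the seed, not image order."""
        net, _ = toy_tracker2
        cfg = syn.SimConfig(n_frames=5, n_cells=2, seed=90)
        movie, _, tree, _ = syn.simulate_movie(cfg)
        pos0 = tree.positions_at(0)
        truth = np.array([[tree.positions_at(f)[cid] for cid in sorted(pos0)]
                          for f in range(1, 5)])
        frames = movie.fluor[1:5]

        def run(id_assignment):
            seed = make_seed_channel(
                [(rank, pos0[cid]) for rank, cid in id_assignment],
                movie.frame_shape)
            return track_clip(net, Clip(frames=frames, start_index=1,
                                        seed=seed))

        ids = sorted(pos0)
        direct = run([(0, ids[0]), (1, ids[1])])
        swapped = run([(0, ids[1]), (1, ids[0])])
        iou_direct = np.mean([
            mean_proxy_iou(direct[:, 0], truth[:, 0]),
            mean_proxy_iou(direct[:, 1], truth[:, 1])])
        iou_swapped = np.mean([
            mean_proxy_iou(swapped[:, 0], truth[:, 1]),
            mean_proxy_iou(swapped[:, 1], truth[:, 0])])
        iou_wrong = np.mean([
            mean_proxy_iou(swapped[:, 0], truth[:, 0]),
            mean_proxy_iou(swapped[:, 1], truth[:, 1])])
        assert iou_direct > 0.15
        assert iou_swapped > iou_wrong

    def test_close_x_coordinates_resolved(self, toy_tracker2):
        """Two seeded cells with (nearly) equal x are still assigned to
        their own identities via the distinct seed intensities."""
        net, _ = toy_tracker2
        # find a simulated movie whose two cells have close x at frame 0
        best = None
        for seed in range(200, 260):
            cfg = syn.SimConfig(n_frames=5, n_cells=2, seed=seed,
                                render=False)
            _, _, tree, _ = syn.simulate_movie(cfg)
            pos = tree.positions_at(0)
            dx = abs(pos[1][0] - pos[2][0])
            if best is None or dx < best[1]:
                best = (seed, dx)
        cfg = syn.SimConfig(n_frames=5, n_cells=2, seed=best[0])
        movie, _, tree, _ = syn.simulate_movie(cfg)
        pos0 = tree.positions_at(0)
        seed_ch = make_seed_channel([(cid, pos0[cid])
                                     for cid in sorted(pos0)],
                                    movie.frame_shape)
        pred = track_clip(net, Clip(frames=movie.fluor[1:5], start_index=1,
                                    seed=seed_ch))
        truth = np.array([[tree.positions_at(f)[cid]
                           for cid in sorted(pos0)] for f in range(1, 5)])
        matched = np.mean([mean_proxy_iou(pred[:, k], truth[:, k])
                           for k in range(2)])
        crossed = np.mean([mean_proxy_iou(pred[:, k], truth[:, 1 - k])
                           for k in range(2)])
        assert matched > crossed
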