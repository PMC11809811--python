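"""Patch extraction, weight maps, U-Net specs, the trained ensemble."""

import numpy as np
import pytest

from seedtrack import segmentation as seg
from seedtrack import synthetic as syn
from seedtrack.segmentation import (
    WeightMapParams, augment_sample, build_refiner_spec,
    build_segmentor_spec, compute_difference, compute_weight_map_refiner,
    compute_weight_map_segmentor, extract_patch, make_patch_seed,
    make_training_samples, refine_centroid, segment_patch_ensemble,
)
from seedtrack.synthetic import _disk_mask_at


class TestPatchPlumbing:
    def test_central_crop_has_no_padding(self):
        frame = np.arange(382 * 382, dtype=np.float32).reshape(382, 382)
        patch, offset = extract_patch(frame, (191, 191), 96)
        assert patch.shape == (96, 96)
        assert offset == (143, 143)
        np.testing.assert_array_equal(patch, frame[143:239, 143:239])

    def test_corner_crop_zero_padded(self):
        frame = np.ones((382, 382), dtype=np.float32)
        patch, offset = extract_patch(frame, (10, 10), 96)
        # centred at (10,10): 48 - 10 = 38 rows/cols of padding at top/left
        assert offset == (-38, -38)
        assert (patch[:38, :] == 0).all() and (patch[:, :38] == 0).all()
        assert (patch[38:, 38:] == 1).all()

    def test_patch_covers_about_six_percent(self):
        assert 100 * 96 ** 2 / 382 ** 2 == pytest.approx(6.0, abs=0.5)

    def test_patch_seed_is_255_square(self):
        plane = make_patch_seed((48, 48), 96)
        assert set(np.unique(plane)) == {0.0, 255.0}
        assert (plane[28:68, 28:68] == 255).all()
        assert plane.sum() == 255 * 1600

    def test_patch_seed_clipped_near_corner(self):
        plane = make_patch_seed((5, 5), 96)
        assert 0 < np.count_nonzero(plane) < 1600


class TestWeightMaps:
    def test_border_term_is_w0_where_d1_plus_d2_vanishes(self):
        # two rectangles separated by a 1-px background ridge: the ridge
        # lies on both instance borders, so d1 = d2 = 0 there and the
        # border term equals exactly W0 = 10
        label = np.zeros((40, 40), bool)
        unwanted = np.zeros((40, 40), bool)
        label[10:30, 5:20] = True
        unwanted[10:30, 21:35] = True
        w = compute_weight_map_segmentor(label, unwanted)
        params = WeightMapParams()
        wc = seg._class_balance_map(label)
        assert w[20, 20] == pytest.approx(wc[20, 20] + params.w0, abs=1e-5)
        assert w.max() <= wc.max() + params.w0 + params.w_fragments + 1e-5

    def test_unwanted_pixels_add_exactly_wfr(self):
        label = np.zeros((64, 64), bool)
        label[5:15, 5:15] = True
        unwanted = np.zeros((64, 64), bool)
        unwanted[45:55, 45:55] = True
        with_fr = compute_weight_map_segmentor(label, unwanted)
        without = compute_weight_map_segmentor(
            label, unwanted, WeightMapParams(w_fragments=0.0))
        diff = with_fr - without
        np.testing.assert_allclose(diff[unwanted], 8.0, atol=1e-6)
        assert (diff[~unwanted] == 0).all()

    def test_border_term_negligible_far_from_cells(self):
        label = np.zeros((64, 64), bool)
        label[2:12, 2:12] = True
        unwanted = np.zeros((64, 64), bool)
        unwanted[52:62, 52:62] = True
        w = compute_weight_map_segmentor(label, unwanted)
        wc = seg._class_balance_map(label)
        # d1 + d2 ~ 50 px at sigma 5 -> border term 10*exp(-50) ~ 0
        assert w[30, 5] - wc[30, 5] < 1e-6

    def test_single_instance_has_no_border_term(self):
        label = np.zeros((64, 64), bool)
        label[20:40, 20:40] = True
        w = compute_weight_map_segmentor(label, np.zeros_like(label))
        np.testing.assert_allclose(w, seg._class_balance_map(label),
                                   atol=1e-6)

    def test_weights_positive_and_finite(self):
        rng = np.random.default_rng(0)
        label = rng.random((48, 48)) > 0.7
        unwanted = (rng.random((48, 48)) > 0.7) & ~label
        w = compute_weight_map_segmentor(label, unwanted)
        assert np.isfinite(w).all() and (w > 0).all()

    def test_refiner_map_adds_error_weight(self):
        base = np.full((32, 32), 2.0, np.float32)
        err = np.zeros((32, 32), np.uint8)
        np.testing.assert_array_equal(
            compute_weight_map_refiner(base, err), base)
        err[5, 7] = 1
        w = compute_weight_map_refiner(base, err)
        assert w[5, 7] == pytest.approx(12.0)
        assert w.sum() == pytest.approx(base.sum() + 10.0)
        w_full = compute_weight_map_refiner(base, np.ones_like(err))
        np.testing.assert_allclose(w_full, base + 10.0)


class TestDifference:
    def test_identical_masks_zero(self):
        m = (np.arange(64).reshape(8, 8) % 3 == 0).astype(np.uint8)
        assert compute_difference(m, m).sum() == 0

    def test_single_extra_pixel(self):
        a = np.zeros((8, 8), np.uint8)
        b = a.copy()
        b[3, 4] = 1
        d = compute_difference(b, a)
        assert d.sum() == 1 and d[3, 4] == 1

    def test_equals_xor_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a = (rng.random((16, 16)) > 0.5).astype(np.uint8)
            b = (rng.random((16, 16)) > 0.5).astype(np.uint8)
            np.testing.assert_array_equal(compute_difference(a, b),
                                          np.bitwise_xor(a, b))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            compute_difference(np.full((4, 4), 2), np.zeros((4, 4)))


class TestSpecs:
    def test_segmentor_dropouts(self):
        spec = build_segmentor_spec()
        assert spec.dropouts == {2: 0.5, 3: 0.3, 4: 0.5, 5: 0.5}
        assert spec.in_channels == 3 and spec.side == 96

    def test_refiner_adds_only_early_dropouts(self):
        spec = build_refiner_spec()
        assert spec.dropouts[2] == 0.5 and spec.dropouts[3] == 0.3
        assert spec.dropouts[4] == 0.3 and spec.dropouts[5] == 0.3

    def test_spec_serialization_roundtrip(self):
        spec = build_segmentor_spec()
        back = seg.UNetSpec.from_dict(spec.to_dict())
        assert back == spec

    def test_unet_output_shape(self):
        rng = np.random.default_rng(2)
        net = seg.UNet(seg.reduced_unet_spec(32), rng)
        x = rng.normal(size=(2, 32, 32, 3)).astype(np.float32)
        assert net.forward(x).shape == (2, 32, 32)


@pytest.fixture(scope="module")
def sample_movie():
    cfg = syn.SimConfig(n_frames=10, n_cells=2, divisions=[(6, 1)], seed=21)
    return syn.simulate_movie(cfg)


class TestTrainingSamples:
    def test_jitter_bounded_by_35(self, sample_movie):
        movie, labels, tree, _ = sample_movie
        rng = np.random.default_rng(3)
        samples = make_training_samples(movie, labels, tree, "segmentor",
                                        rng, n_samples=200)
        max_shift = 0.0
        for s in samples:
            frame, cid = s.meta["frame"], s.meta["cell_id"]
            cx, cy = tree.positions_at(frame)[cid]
            c0, r0 = s.meta["offset"]
            centre = (c0 + 48, r0 + 48)
            max_shift = max(max_shift, abs(centre[0] - cx),
                            abs(centre[1] - cy))
        assert max_shift <= 36  # 35 px jitter + rounding

    def test_augmentation_is_sixfold(self, sample_movie):
        movie, labels, tree, _ = sample_movie
        rng = np.random.default_rng(4)
        base = make_training_samples(movie, labels, tree, "segmentor", rng,
                                     n_samples=10)
        augmented = make_training_samples(movie, labels, tree, "segmentor",
                                          np.random.default_rng(4),
                                          n_samples=10, augment=True)
        assert len(augmented) == 6 * len(base)
        one = augment_sample(base[0])
        assert len(one) == 6

    def test_label_is_single_component(self, sample_movie):
        from scipy import ndimage
        movie, labels, tree, _ = sample_movie
        samples = make_training_samples(movie, labels, tree, "segmentor",
                                        np.random.default_rng(5),
                                        n_samples=40)
        for s in samples:
            if s.y.any():
                assert ndimage.label(s.y > 0)[1] == 1

    def test_refiner_requires_trained_segmentor(self, sample_movie):
        movie, labels, tree, _ = sample_movie
        with pytest.raises(ValueError, match="Segmentor"):
            make_training_samples(movie, labels, tree, "refiner",
                                  np.random.default_rng(6), n_samples=5)


class TestRefineCentroid:
    def test_centered_disk_exact(self):
        mask = _disk_mask_at((96, 96), 48, 48, 15)
        cx, cy = refine_centroid(mask, (100, 200))
        assert cx == pytest.approx(148, abs=0.01)
        assert cy == pytest.approx(248, abs=0.01)

    def test_offset_disk_recovered(self):
        mask = _disk_mask_at((96, 96), 63, 40, 15)
        cx, cy = refine_centroid(mask, (0, 0))
        assert cx == pytest.approx(63, abs=0.1)
        assert cy == pytest.approx(40, abs=0.1)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            refine_centroid(np.zeros((96, 96), bool), (0, 0))


class TestTrainedEnsemble:
    def test_training_history_improves(self, toy_ensemble):
        hist = toy_ensemble["segmentor_history"]
        assert hist["train_loss"].iloc[-1] < hist["train_loss"].iloc[0]
        assert hist["val_iou"].iloc[-1] > hist["val_iou"].iloc[0]

    def test_best_checkpoint_rule(self, toy_ensemble):
        # the returned net carries the best-validation-IoU parameters
        hist = toy_ensemble["segmentor_history"]
        assert hist["val_iou"].max() >= hist["val_iou"].iloc[-1] - 1e-9

    def test_blank_patch_segments_nothing(self, toy_ensemble):
        rng = np.random.default_rng(8)
        patch = np.zeros((96, 96, 3), np.float32)
        patch[..., 0] = rng.uniform(0, 8, (96, 96))     # background only
        patch[..., 1] = rng.normal(100, 3, (96, 96))
        patch[..., 2] = make_patch_seed((48, 48), 96)
        mask, _ = segment_patch_ensemble(toy_ensemble["segmentor"],
                                         toy_ensemble["refiner"], patch)
        assert mask.sum() < 80  # at most a few speckle pixels

    def test_seeded_cell_segmented_with_good_iou(self, toy_ensemble,
                                                 heldout_patches):
        ious = []
        for patch, label in heldout_patches:
            mask, _ = segment_patch_ensemble(toy_ensemble["segmentor"],
                                             toy_ensemble["refiner"], patch)
            union = (mask | label).sum()
            ious.append((mask & label).sum() / union if union else 1.0)
        assert np.mean(ious) > 0.7

    def test_two_cell_patch_tracks_the_seed(self, toy_ensemble,
                                            two_cell_patch):
        patch, label_a, label_b = two_cell_patch
        mask, _ = segment_patch_ensemble(toy_ensemble["segmentor"],
                                         toy_ensemble["refiner"], patch)
        inter_a = (mask & label_a).sum() / max(label_a.sum(), 1)
        inter_b = (mask & label_b).sum() / max(label_b.sum(), 1)
        assert inter_a > 0.5
        assert inter_b < 0.2

    def test_refinement_reduces_centroid_error(self, toy_ensemble,
                                               heldout_movies):
        """Seeded segmentation of a patch extracted at a jittered centroid
        recovers the true centroid: the refinement loop strictly reduces
        the mean position error versus the raw (jittered) estimate."""
        rng = np.random.default_rng(11)
        raw_err, ref_err = [], []
        movie, labels, tree, _ = heldout_movies[0]
        for _ in range(60):
            frame = int(rng.integers(1, movie.n_frames))
            cands = [cid for cid in tree.alive_at(frame)
                     if cid in tree.positions_at(frame - 1)]
            cid = int(rng.choice(cands))
            cx, cy = tree.positions_at(frame)[cid]
            jx = float(np.clip(cx + rng.uniform(-20, 20), 0, 381))
            jy = float(np.clip(cy + rng.uniform(-20, 20), 0, 381))
            stack = np.stack([movie.fluor[frame], movie.bright[frame],
                              np.zeros_like(movie.fluor[frame])], axis=-1)
            patch, offset = extract_patch(stack, (jx, jy), 96)
            prev = tree.positions_at(frame - 1)[cid]
            patch[..., 2] = make_patch_seed((prev[0] - offset[0],
                                             prev[1] - offset[1]), 96)
            mask, _ = segment_patch_ensemble(toy_ensemble["segmentor"],
                                             toy_ensemble["refiner"], patch)
            if not mask.any():
                continue
            rx, ry = refine_centroid(mask, offset)
            raw_err.append(np.hypot(jx - cx, jy - cy))
            ref_err.append(np.hypot(rx - cx, ry - cy))
        assert len(ref_err) >= 50
        assert np.mean(ref_err) < np.mean(raw_err)


@pytest.fixture(scope="module")
def heldout_patches(heldout_movies):
    """Jitter-free seeded patches with labels from a held-out movie."""
    movie, labels, tree, _ = heldout_movies[1]
    rng = np.random.default_rng(9)
    out = []
    for _ in range(40):
        frame = int(rng.integers(1, movie.n_frames))
        cands = [cid for cid in tree.alive_at(frame)
                 if cid in tree.positions_at(frame - 1)]
        cid = int(rng.choice(cands))
        cx, cy = tree.positions_at(frame)[cid]
        stack = np.stack([movie.fluor[frame], movie.bright[frame],
                          np.zeros_like(movie.fluor[frame])], axis=-1)
        patch, offset = extract_patch(stack, (cx, cy), 96)
        prev = tree.positions_at(frame - 1)[cid]
        patch[..., 2] = make_patch_seed((prev[0] - offset[0],
                                         prev[1] - offset[1]), 96)
        lab, _ = extract_patch(labels[frame], (cx, cy), 96)
        out.append((patch, lab == cid))
    return out


@pytest.fixture(scope="module")
def two_cell_patch(heldout_movies):
    """A patch containing two cells, seeded on the first."""
    movie, labels, tree, _ = heldout_movies[2]
    best = None
    for frame in range(1, movie.n_frames):
        pos = tree.positions_at(frame)
        ids = sorted(pos)
        for i in ids:
            for j in ids:
                if i >= j:
                    continue
                d = np.hypot(pos[i][0] - pos[j][0], pos[i][1] - pos[j][1])
                if best is None or d < best[0]:
                    best = (d, frame, i, j)
    _, frame, a, b = best
    pos = tree.positions_at(frame)
    mid = ((pos[a][0] + pos[b][0]) / 2, (pos[a][1] + pos[b][1]) / 2)
    stack = np.stack([movie.fluor[frame], movie.bright[frame],
                      np.zeros_like(movie.fluor[frame])], axis=-1)
    patch, offset = extract_patch(stack, mid, 96)
    prev = tree.positions_at(frame - 1).get(a, pos[a])
    patch[..., 2] = make_patch_seed((prev[0] - offset[0],
                                     prev[1] - offset[1]), 96)
    lab, _ = extract_patch(labels[frame], mid, 96)
    return patch, lab == a, lab == b
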