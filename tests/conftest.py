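"""Shared fixtures: desk-scale trained networks and synthetic fixtures.

The trained models are session-scoped because CPU training, while reduced,
still takes minutes; every test that needs a trained tracker or
segmentation ensemble shares the same ones.  All randomness is seeded, so
the whole suite is reproducible.
"""

from __future__ import annotations

import numpy as np
import pytest

from seedtrack import segmentation as seg
from seedtrack import synthetic as syn
from seedtrack import tracker as trk

SEG_NET_SIDE = 48


def reduced_general_spec():
    """Reduced single-seed general tracker with a seed-centred crop."""
    return trk.TrackerSpec(
        n_cells=1, general=True, input_side=32,
        conv_stack=[8, "P", 16, "P"], fc1=64, dropout=None, fc2=None,
        crop_side=128)


def reduced_dedicated_spec(n_cells):
    """Reduced dedicated tracker; single-cell variant also crops."""
    return trk.TrackerSpec(
        n_cells=n_cells, general=False, input_side=32,
        conv_stack=[8, "P", 16, "P"], fc1=64, dropout=None, fc2=None,
        crop_side=128 if n_cells == 1 else None)


@pytest.fixture(scope="session")
def toy_general_tracker():
    """Reduced Tracker-1-general trained on ~500 synthetic seeded clips."""
    rng = np.random.default_rng(101)
    spec = reduced_general_spec()
    ds = trk.make_tracker_training_set(500, spec, rng, n_distractors=(0, 2))
    ds = trk.augment_tracker_dataset(ds)
    cfg = trk.TrainConfig(learning_rate=3e-3, batch_size=32, epochs=8,
                          seed=7, shift_augment=8, lr_milestones={6: 1e-3})
    net, history = trk.train_tracker(spec, ds, cfg)
    return net, history


@pytest.fixture(scope="session")
def toy_tracker2():
    """Reduced dedicated two-cell tracker (full frame, no crop)."""
    rng = np.random.default_rng(202)
    spec = reduced_dedicated_spec(2)
    ds = trk.make_tracker_training_set(500, spec, rng)
    ds = trk.augment_tracker_dataset(ds)
    cfg = trk.TrainConfig(learning_rate=3e-3, batch_size=32, epochs=14,
                          seed=7, shift_augment=10, lr_milestones={10: 1e-3})
    net, history = trk.train_tracker(spec, ds, cfg)
    return net, history


@pytest.fixture(scope="session")
def toy_tracker1():
    """Reduced dedicated single-cell tracker."""
    rng = np.random.default_rng(303)
    spec = reduced_dedicated_spec(1)
    ds = trk.make_tracker_training_set(150, spec, rng,
                                       n_distractors=(0, 0))
    ds = trk.augment_tracker_dataset(ds)
    cfg = trk.TrainConfig(learning_rate=3e-3, batch_size=32, epochs=5,
                          seed=7, shift_augment=8)
    net, history = trk.train_tracker(spec, ds, cfg)
    return net, history


@pytest.fixture(scope="session")
def training_movie():
    """A 2-cell movie with one division, used to build patch samples."""
    cfg = syn.SimConfig(n_frames=14, n_cells=2, divisions=[(7, 1)], seed=41)
    movie, labels, tree, table = syn.simulate_movie(cfg)
    return movie, labels, tree


@pytest.fixture(scope="session")
def toy_ensemble(training_movie):
    """Reduced Segmentor + Refiner trained on ~300 synthetic patches."""
    movie, labels, tree = training_movie
    rng = np.random.default_rng(404)
    base = seg.make_training_samples(movie, labels, tree, "segmentor", rng,
                                     n_samples=300)
    samples = [a for s in base for a in seg.augment_sample(s)]
    spec = seg.reduced_unet_spec(SEG_NET_SIDE)
    cfg = seg.SegTrainConfig(learning_rate=3e-4, batch_size=32, epochs=5,
                             seed=9)
    segmentor, seg_hist = seg.train_segmentation_net(spec, samples, cfg)

    ref_base = seg.make_training_samples(
        movie, labels, tree, "refiner", np.random.default_rng(405),
        n_samples=300, segmentor=segmentor)
    ref_samples = [a for s in ref_base for a in seg.augment_sample(s)]
    ref_cfg = seg.SegTrainConfig(learning_rate=3e-4, batch_size=32,
                                 epochs=3, seed=9)
    refiner, ref_hist = seg.train_segmentation_net(spec, ref_samples,
                                                   ref_cfg)
    return {"segmentor": segmentor, "refiner": refiner,
            "segmentor_history": seg_hist, "refiner_history": ref_hist}


@pytest.fixture(scope="session")
def heldout_movies():
    """Five held-out 2-cell movies, one division each (fixed seeds)."""
    movies = []
    for i in range(5):
        cfg = syn.SimConfig(n_frames=20, n_cells=2,
                            divisions=[(9 + i % 3, 1)], seed=1000 + i)
        movies.append(syn.simulate_movie(cfg))
    return movies
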