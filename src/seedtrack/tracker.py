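"""Seeded 3D-CNN regression trackers.

A Tracker-N maps a seeded clip — 4 consecutive fluorescent frames with a
seed channel prepended as a fifth temporal slice — to the normalized
centroids of exactly N cells in each frame.  The network is a stack of
3x3x3 convolutions and (2,2,1) max pools (never pooling along time)
followed by four parallel per-frame branches of fully connected layers,
each emitting 2N coordinates.  Identity k of the output corresponds to the
seed of rank k (intensity order) in the seed channel.

Tracker-1-general is the enlarged single-cell variant trained with exactly
one seeded cell among distractors; it learns to ignore unseeded cells, so
an N-cell movie can be tracked by running it once per cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import nn
from .core import (
    Clip, DEFAULT_SEED_SIDE, DEFAULT_TRACKER_INPUT_SIDE, Movie, SeedChannel,
    Track, make_seed_channel, normalize_clip, slice_clips,
)

logger = logging.getLogger("seedtrack")

__all__ = [
    "TrackerSpec", "TrainConfig", "build_tracker_spec", "reduced_tracker_spec",
    "proxy_box_iou", "TrackerNet", "TrackerDataset", "train_tracker",
    "track_clip", "track_movie_general",
]

#: Reference per-branch head widths: FC-1, dropout, FC-2 (None = absent).
_BRANCH_TABLE = {
    1: (256, None, None),
    2: (960, None, 512),
    3: (1024, 0.05, 512),
    4: (1024, 0.03, 512),
    5: (1024, 0.05, 512),
}

#: Reference convolutional stack shared by the dedicated trackers:
#: 3x3x3 convs with the listed filter counts, "P" = (2,2,1) pool.
_CONV_STACK = [64, 64, "P", 128, "P", 256, "P", 512]

#: Convolutional stack of the general single-cell tracker: the 64- and
#: 128-filter convolutions are doubled and a double 32-filter layer is
#: prepended.
_CONV_STACK_GENERAL = [32, 32, 64, 64, 64, 64, "P", 128, 128, "P", 256, "P", 512]

MAX_SUPPORTED_CELLS = 5


@dataclass
class TrackerSpec:
    """Architecture description of one tracker network."""

    n_cells: int
    general: bool = False
    input_side: int = DEFAULT_TRACKER_INPUT_SIDE
    n_frames: int = 4
    conv_stack: list = field(default_factory=lambda: list(_CONV_STACK))
    fc1: int = 256
    dropout: float | None = None
    fc2: int | None = None
    seed_side: int = DEFAULT_SEED_SIDE
    #: optional seed-centred crop (pixels) applied before resizing; only
    #: meaningful for single-seed trackers, where everything outside the
    #: seeded cell's neighbourhood is to be ignored anyway.  None = use
    #: the full frame (the reference full-scale configuration).
    crop_side: int | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.n_frames != 4:
            raise ValueError("trackers operate on 4-frame clips")
        if self.crop_side is not None and self.n_cells != 1:
            raise ValueError("seed-centred cropping requires a single seed")
        for entry in self.conv_stack:
            if entry == "P":
                continue
            if not isinstance(entry, int) or entry <= 0:
                raise ValueError(f"bad conv stack entry {entry!r}")

    @property
    def branch_output_width(self) -> int:
        return 2 * self.n_cells

    @property
    def output_length(self) -> int:
        """Whole-clip output size: 2 coordinates x 4 frames x N cells."""
        return 2 * self.n_frames * self.n_cells

    @property
    def n_pools(self) -> int:
        return sum(1 for e in self.conv_stack if e == "P")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrackerSpec":
        return cls(**d)


def build_tracker_spec(n_cells: int, general: bool = False,
                       input_side: int = DEFAULT_TRACKER_INPUT_SIDE
                       ) -> TrackerSpec:
    """The reference full-scale architectures: dedicated Tracker-1..5, or the enlarged
    Tracker-1-general (``general=True`` requires ``n_cells == 1``)."""
    if general:
        if n_cells != 1:
            raise ValueError("the general tracker is the single-cell variant")
        return TrackerSpec(n_cells=1, general=True, input_side=input_side,
                           conv_stack=list(_CONV_STACK_GENERAL),
                           fc1=1024, dropout=None, fc2=1024)
    if not 1 <= n_cells <= MAX_SUPPORTED_CELLS:
        raise ValueError(
            f"dedicated trackers support 1..{MAX_SUPPORTED_CELLS} cells"
        )
    fc1, drop, fc2 = _BRANCH_TABLE[n_cells]
    return TrackerSpec(n_cells=n_cells, input_side=input_side,
                       conv_stack=list(_CONV_STACK),
                       fc1=fc1, dropout=drop, fc2=fc2)


def reduced_tracker_spec(n_cells: int, general: bool = False,
                         input_side: int = 32) -> TrackerSpec:
    """A desk-scale tracker preserving the architectural contracts (4
    branches, (2,2,1) pools, seeded input) with a small conv stack, for
    CPU training."""
    spec = TrackerSpec(n_cells=n_cells, general=general,
                       input_side=input_side,
                       conv_stack=[8, "P", 16, "P"],
                       fc1=64, dropout=None, fc2=None)
    return spec


@dataclass
class TrainConfig:
    """Tracker training hyper-parameters (reference full-scale defaults)."""

    optimizer: str = "adam"
    learning_rate: float = 0.009
    batch_size: int = 32
    epochs: int = 150
    seed: int = 0
    val_fraction: float = 0.15
    #: on-the-fly translation augmentation: max |shift| in input pixels
    #: applied to every training batch (0 disables).  Teaches the
    #: fully-connected readout translation structure it cannot inherit
    #: from the convolutions, which matters at small dataset sizes.
    shift_augment: int = 0
    #: optional step decays of the learning rate: {epoch: new_lr}
    lr_milestones: dict[int, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Proxy-box IoU
# ---------------------------------------------------------------------------

def proxy_box_iou(pred, truth, side: float = DEFAULT_SEED_SIDE) -> float:
    """IoU of two axis-aligned ``side x side`` squares centred at ``pred``
    and ``truth`` — the standard trick for scoring centroid regression with
    an IoU-style metric.  Total, symmetric, 0 for disjoint boxes."""
    if side <= 0:
        raise ValueError("side must be positive")
    dx = abs(float(pred[0]) - float(truth[0]))
    dy = abs(float(pred[1]) - float(truth[1]))
    ix = max(0.0, side - dx)
    iy = max(0.0, side - dy)
    inter = ix * iy
    union = 2.0 * side * side - inter
    return inter / union


def mean_proxy_iou(pred: np.ndarray, truth: np.ndarray,
                   side: float = DEFAULT_SEED_SIDE) -> float:
    """Mean proxy-box IoU over ``(..., 2)`` arrays of centroids."""
    p = np.asarray(pred, dtype=np.float64).reshape(-1, 2)
    t = np.asarray(truth, dtype=np.float64).reshape(-1, 2)
    return float(np.mean([proxy_box_iou(a, b, side) for a, b in zip(p, t)]))


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

class TrackerNet:
    """A 3D-CNN tracker instantiated from a :class:`TrackerSpec`."""

    def __init__(self, spec: TrackerSpec, rng: np.random.Generator):
        self.spec = spec
        self.conv_layers: list = []
        c_in = 1
        side = spec.input_side
        for entry in spec.conv_stack:
            if entry == "P":
                self.conv_layers.append(MaxPoolMark())
                side //= 2
            else:
                self.conv_layers.append(nn.Conv3d(c_in, entry, rng))
                c_in = entry
        self._flat = side * side * (spec.n_frames + 1) * c_in
        self.branches = []
        for _ in range(spec.n_frames):
            layers = {"fc1": nn.Dense(self._flat, spec.fc1, rng),
                      "relu1": nn.ReLU()}
            width = spec.fc1
            if spec.dropout:
                layers["drop"] = nn.Dropout(spec.dropout)
            if spec.fc2:
                layers["fc2"] = nn.Dense(width, spec.fc2, rng)
                layers["relu2"] = nn.ReLU()
                width = spec.fc2
            layers["out"] = nn.Dense(width, spec.branch_output_width, rng)
            self.branches.append(layers)

    def params(self):
        out = []
        for layer in self.conv_layers:
            if isinstance(layer, nn.Conv3d):
                out.extend(layer.params())
        for branch in self.branches:
            for layer in branch.values():
                if isinstance(layer, nn.Dense):
                    out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """``x``: (B, side, side, T+1, 1) -> (B, 4, 2N) normalized coords."""
        h = x
        self._relus = []
        self._pools = []
        for layer in self.conv_layers:
            if isinstance(layer, MaxPoolMark):
                pool = nn.MaxPool3d221()
                h = pool.forward(h)
                self._pools.append(pool)
                self._relus.append(None)
            else:
                h = layer.forward(h)
                relu = nn.ReLU()
                h = relu.forward(h)
                self._pools.append(None)
                self._relus.append(relu)
        b = h.shape[0]
        self._conv_out_shape = h.shape
        flat = h.reshape(b, -1)
        outs = []
        for branch in self.branches:
            z = branch["relu1"].forward(branch["fc1"].forward(flat))
            if "drop" in branch:
                z = branch["drop"].forward(z, train=train, rng=rng)
            if "fc2" in branch:
                z = branch["relu2"].forward(branch["fc2"].forward(z))
            outs.append(branch["out"].forward(z))
        return np.stack(outs, axis=1)

    def backward(self, g: np.ndarray) -> None:
        """``g``: gradient of the loss wrt the (B, 4, 2N) output."""
        b = g.shape[0]
        dflat = np.zeros((b, self._flat), dtype=np.float32)
        for i, branch in enumerate(self.branches):
            gz = branch["out"].backward(g[:, i, :])
            if "fc2" in branch:
                gz = branch["fc2"].backward(branch["relu2"].backward(gz))
            if "drop" in branch:
                gz = branch["drop"].backward(gz)
            dflat += branch["fc1"].backward(branch["relu1"].backward(gz))
        h = dflat.reshape(self._conv_out_shape)
        for layer, pool, relu in zip(reversed(self.conv_layers),
                                     reversed(self._pools),
                                     reversed(self._relus)):
            if isinstance(layer, MaxPoolMark):
                h = pool.backward(h)
            else:
                h = layer.backward(relu.backward(h))

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        nn.save_arrays(path, self.spec.to_dict(), self.params())

    @classmethod
    def load(cls, path) -> "TrackerNet":
        spec_dict, arrays = nn.load_arrays(path)
        net = cls(TrackerSpec.from_dict(spec_dict), np.random.default_rng(0))
        nn.set_state(net.params(), arrays)
        return net


class MaxPoolMark:
    """Placeholder marking a pooling position in the conv stack."""


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrackerDataset:
    """Seeded clips with normalized centroid labels.

    ``clips``: (n, side, side, T+1, 1) standardized tensors (seed slice
    first); ``labels``: (n, 4, 2N) centroids in [0, 1];
    ``seed_centroids``: (n, N, 2) normalized seed positions, used for the
    pre-training identity audit; ``label_side``: the pixel side length the
    labels were normalized by (the frame side, or the crop side for
    seed-centred-crop trackers).
    """

    clips: np.ndarray
    labels: np.ndarray
    seed_centroids: np.ndarray
    label_side: float = 382.0

    def __len__(self) -> int:
        return self.clips.shape[0]


def audit_seed_labels(dataset: TrackerDataset,
                      box_frac: float | None = None) -> None:
    """Verify that each seed overlaps its cell's first-frame label within a
    proxy-box distance; a mismatch means identities were scrambled during
    dataset construction."""
    if box_frac is None:
        box_frac = DEFAULT_SEED_SIDE / dataset.label_side
    n, _, twoN = dataset.labels.shape
    n_cells = twoN // 2
    first = dataset.labels[:, 0, :].reshape(n, n_cells, 2)
    delta = np.abs(first - dataset.seed_centroids).max(axis=-1)
    bad = np.nonzero((delta > box_frac).any(axis=-1))[0]
    if bad.size:
        raise ValueError(
            f"seed/label identity mismatch in {bad.size} samples "
            f"(first: index {bad[0]}); seeds must point at the labelled cells"
        )


def train_tracker(spec: TrackerSpec, dataset: TrackerDataset,
                  cfg: TrainConfig):
    """Train a tracker by MSE on normalized centroids.

    Returns ``(net, history)`` where ``history`` is a DataFrame with
    per-epoch train/validation loss and mean proxy-box IoU (computed with
    the 40 px box on the original pixel scale).  Fully reproducible for a
    fixed ``cfg.seed``.
    """
    if np.min(dataset.labels) < 0 or np.max(dataset.labels) > 1:
        raise ValueError("labels must be normalized to [0, 1]")
    audit_seed_labels(dataset)

    rng = np.random.default_rng(cfg.seed)
    net = TrackerNet(spec, rng)
    drop_rng = np.random.default_rng(rng.integers(2 ** 31))
    opt = nn.Adam(net.params(), lr=cfg.learning_rate)

    n = len(dataset)
    n_val = max(int(round(cfg.val_fraction * n)), 1) if n > 4 else 0
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    original_side = dataset.label_side
    records = []
    for epoch in range(cfg.epochs):
        if epoch in cfg.lr_milestones:
            opt.lr = cfg.lr_milestones[epoch]
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            x = dataset.clips[idx]
            y = dataset.labels[idx]
            if cfg.shift_augment:
                x, y = _shift_batch(x, y, cfg.shift_augment, rng)
            pred = net.forward(x, train=True, rng=drop_rng)
            loss, g = nn.mse_loss(pred, y)
            opt.zero_grad()
            net.backward(g.astype(np.float32))
            opt.step()
            losses.append(loss)
        rec = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        rec.update(_evaluate_split(net, dataset, train_idx, "train",
                                   original_side))
        if n_val:
            rec.update(_evaluate_split(net, dataset, val_idx, "val",
                                       original_side))
        records.append(rec)
    return net, pd.DataFrame.from_records(records)


def _shift_batch(x: np.ndarray, y: np.ndarray, max_shift: int,
                 rng: np.random.Generator):
    """Translate each clip (all temporal slices together) by a random
    integer offset, zero-filling the exposed border, and shift labels
    accordingly.  Shifts are clamped per sample so every labelled centroid
    stays inside the frame."""
    side = x.shape[1]
    x = x.copy()
    y = y.copy()
    n = x.shape[0]
    ncells = y.shape[-1] // 2
    for i in range(n):
        lab = y[i].reshape(-1, 2)
        lo = lab.min(axis=0)
        hi = lab.max(axis=0)
        # allowed normalized shift keeps labels in (0, 1)
        max_dx = int(min(max_shift, np.floor((1 - hi[0]) * side) - 1))
        min_dx = int(max(-max_shift, -np.floor(lo[0] * side) + 1))
        max_dy = int(min(max_shift, np.floor((1 - hi[1]) * side) - 1))
        min_dy = int(max(-max_shift, -np.floor(lo[1] * side) + 1))
        dx = int(rng.integers(min_dx, max_dx + 1)) if max_dx >= min_dx else 0
        dy = int(rng.integers(min_dy, max_dy + 1)) if max_dy >= min_dy else 0
        if dx == 0 and dy == 0:
            continue
        shifted = np.zeros_like(x[i])
        rs0, rs1 = max(dy, 0), side + min(dy, 0)
        cs0, cs1 = max(dx, 0), side + min(dx, 0)
        shifted[rs0:rs1, cs0:cs1] = x[i, rs0 - dy:rs1 - dy, cs0 - dx:cs1 - dx]
        x[i] = shifted
        lab = lab + np.array([dx / side, dy / side])
        y[i] = lab.reshape(y[i].shape)
    return x, np.clip(y, 0.0, 1.0)


def _evaluate_split(net, dataset, idx, name, original_side,
                    batch: int = 64, cap: int = 256):
    if len(idx) == 0:
        return {}
    idx = idx[:cap]
    preds, losses = [], []
    for start in range(0, len(idx), batch):
        sl = idx[start:start + batch]
        pred = net.forward(dataset.clips[sl])
        loss, _ = nn.mse_loss(pred, dataset.labels[sl])
        preds.append(pred)
        losses.append(loss * len(sl))
    pred = np.concatenate(preds)
    truth = dataset.labels[idx]
    iou = mean_proxy_iou(pred * original_side, truth * original_side)
    return {f"{name}_mse": float(np.sum(losses) / len(idx)),
            f"{name}_iou": iou}


# ---------------------------------------------------------------------------
# Synthetic training data
# ---------------------------------------------------------------------------

def make_tracker_training_set(n_clips: int, spec: TrackerSpec,
                              rng: np.random.Generator,
                              n_distractors: tuple[int, int] = (0, 2),
                              sim_kwargs: dict | None = None
                              ) -> TrackerDataset:
    """Build seeded training clips from the movie simulator.

    Each sample is a fresh 5-frame simulated movie: the seed channel is
    rendered from the frame-0 positions and the clip comprises frames 1-4,
    so the seed marks "the last frame of the previous clip".  For a
    dedicated Tracker-N every cell is seeded (palette rank = identity
    rank); for the general tracker exactly one randomly chosen cell is
    seeded among ``n_distractors`` extra unseeded cells, teaching the
    network to ignore them.
    """
    from . import synthetic as syn

    sim_kwargs = dict(sim_kwargs or {})
    side = sim_kwargs.pop("side", 382)
    clips, labels, seed_cents = [], [], []
    for _ in range(n_clips):
        if spec.general:
            k = 1 + int(rng.integers(n_distractors[0], n_distractors[1] + 1))
        else:
            k = spec.n_cells
        cfg = syn.SimConfig(side=side, n_frames=5, n_cells=k,
                            seed=int(rng.integers(2 ** 31)), **sim_kwargs)
        movie, _, tree, _ = syn.simulate_movie(cfg)
        pos0 = tree.positions_at(0)
        if spec.general:
            target_ids = [int(rng.choice(sorted(pos0)))]
            palette = (255,)
        else:
            target_ids = sorted(pos0)
            palette = None
        seed = make_seed_channel(
            [(cid, pos0[cid]) for cid in target_ids],
            movie.frame_shape, side_px=spec.seed_side,
            **({"palette": palette} if palette else {}))
        clip = Clip(frames=movie.fluor[1:5], start_index=1, seed=seed)
        x, scaler, offset = clip_tensor(clip, spec)
        label = np.empty((4, len(target_ids), 2), dtype=np.float64)
        for t in range(4):
            pos = tree.positions_at(t + 1)
            for j, cid in enumerate(target_ids):
                label[t, j] = (pos[cid][0] - offset[0],
                               pos[cid][1] - offset[1])
        clips.append(x[0])
        labels.append(scaler.normalize(label).reshape(4, -1))
        seed_cents.append(scaler.normalize(np.array(
            [(pos0[cid][0] - offset[0], pos0[cid][1] - offset[1])
             for cid in target_ids])))
    return TrackerDataset(
        clips=np.stack(clips).astype(np.float32),
        labels=np.stack(labels).astype(np.float32),
        seed_centroids=np.stack(seed_cents).astype(np.float32),
        label_side=float(spec.crop_side or side),
    )


def augment_tracker_dataset(dataset: TrackerDataset,
                            side: float | None = None) -> TrackerDataset:
    """8-fold dihedral augmentation of a clip dataset.

    Each clip is rotated (3 rotations) and mirrored (2 reflections, plus
    their combinations) in the image plane, with centroid labels
    transformed accordingly; the temporal axis is untouched.  Coordinates
    follow the 0-based pixel-index convention, so a mirrored normalized
    coordinate ``x`` maps to ``(side - 1)/side - x``.
    """
    if side is None:
        side = dataset.label_side
    clips, labels, seeds = [dataset.clips], [dataset.labels], \
        [dataset.seed_centroids]
    s = (side - 1) / side
    x = dataset.labels[..., 0::2]
    y = dataset.labels[..., 1::2]
    sx = dataset.seed_centroids[..., 0]
    sy = dataset.seed_centroids[..., 1]

    def pack(lx, ly, psx, psy, arr):
        lab = np.empty_like(dataset.labels)
        lab[..., 0::2] = lx
        lab[..., 1::2] = ly
        sc = np.stack([psx, psy], axis=-1)
        clips.append(np.ascontiguousarray(arr))
        labels.append(lab)
        seeds.append(sc.astype(np.float32))

    a = dataset.clips  # (n, S, S, T, 1); axis 1 = rows (y), axis 2 = cols (x)
    pack(y, s - x, sy, s - sx, np.rot90(a, 1, axes=(1, 2)))
    pack(s - x, s - y, s - sx, s - sy, np.rot90(a, 2, axes=(1, 2)))
    pack(s - y, x, s - sy, sx, np.rot90(a, 3, axes=(1, 2)))
    pack(x, s - y, sx, s - sy, a[:, ::-1])          # flip rows
    pack(s - x, y, s - sx, sy, a[:, :, ::-1])       # flip cols
    pack(s - y, s - x, s - sy, s - sx,
         np.rot90(a, 1, axes=(1, 2))[:, :, ::-1])
    pack(y, x, sy, sx, np.rot90(a, 3, axes=(1, 2))[:, :, ::-1])
    return TrackerDataset(
        clips=np.concatenate(clips),
        labels=np.clip(np.concatenate(labels), 0.0, 1.0),
        seed_centroids=np.concatenate(seeds),
        label_side=dataset.label_side,
    )


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------

def crop_window(seed_xy, crop: int, shape) -> tuple[int, int]:
    """Top-left ``(col0, row0)`` of a ``crop x crop`` window centred on the
    seed, shifted to lie fully inside the frame."""
    h, w = shape
    if crop > min(h, w):
        raise ValueError("crop larger than the frame")
    c0 = int(round(seed_xy[0])) - crop // 2
    r0 = int(round(seed_xy[1])) - crop // 2
    return (max(0, min(c0, w - crop)), max(0, min(r0, h - crop)))


def clip_tensor(clip: Clip, spec: TrackerSpec):
    """Normalized network input for a seeded clip.

    Returns ``(x, scaler, offset)``: ``x`` shaped (1, S, S, T+1, 1) with
    the seed slice first, and ``offset`` the (col, row) of the crop origin
    (``(0, 0)`` without cropping)."""
    if clip.seed is None:
        raise ValueError("tracking requires a seeded clip")
    offset = (0, 0)
    if spec.crop_side is not None:
        s = clip.seed.seeds[0]
        c0, r0 = crop_window((s.x, s.y), spec.crop_side,
                             clip.frames.shape[1:])
        crop = spec.crop_side
        frames = clip.frames[:, r0:r0 + crop, c0:c0 + crop]
        seed_img = clip.seed.image[r0:r0 + crop, c0:c0 + crop]
        seed = SeedChannel(image=seed_img,
                           seeds=[type(s)(s.identity, s.x - c0, s.y - r0,
                                          s.intensity)],
                           side_px=clip.seed.side_px)
        clip = Clip(frames=frames, start_index=clip.start_index, seed=seed)
        offset = (c0, r0)
    tensor, scaler = normalize_clip(clip, target_side=spec.input_side)
    # (T+1, S, S) -> (1, S, S, T+1, 1)
    return tensor.transpose(1, 2, 0)[None, ..., None], scaler, offset


def track_clip(net: TrackerNet, clip: Clip) -> np.ndarray:
    """Predict per-frame centroids for each seeded identity.

    Returns a ``(4, N, 2)`` array of pixel coordinates in the original
    frame; row k corresponds to the seed of rank k.  Out-of-range
    predictions are clipped to [0, 1] before denormalization.
    """
    spec = net.spec
    n_seeds = len(clip.seed.seeds) if clip.seed else 0
    if n_seeds != spec.n_cells:
        raise ValueError(
            f"clip has {n_seeds} seeds but the model tracks "
            f"{spec.n_cells}; switch to Tracker-{n_seeds}"
            + (" or run the general tracker once per cell"
               if n_seeds > 1 else "")
        )
    x, scaler, offset = clip_tensor(clip, spec)
    pred = np.clip(net.forward(x)[0], 0.0, 1.0)  # (4, 2N)
    out = scaler.denormalize(pred).reshape(4, spec.n_cells, 2)
    out[..., 0] += offset[0]
    out[..., 1] += offset[1]
    return out


def track_movie_general(net: TrackerNet, movie: Movie, initial_seeds,
                        seed_side: int = DEFAULT_SEED_SIDE):
    """Track every seeded cell with repeated single-cell general passes.

    ``initial_seeds`` is a list of ``(cell_id, (x, y))`` start positions.
    One pass is run per cell with only that cell seeded; unseeded cells are
    ignored by construction.  Equivalent in contract to a dedicated
    Tracker-N.  Returns ``{cell_id: Track}``.
    """
    if net.spec.n_cells != 1:
        raise ValueError("track_movie_general expects a single-cell tracker")
    shape = movie.frame_shape
    tracks: dict[int, Track] = {}
    for cell_id, (x0, y0) in initial_seeds:
        track = Track(cell_id)
        pos = (float(x0), float(y0))
        for idx, frames in slice_clips(movie):
            seed = make_seed_channel([(0, pos)], shape, side_px=seed_side,
                                     palette=(255,))
            clip = Clip(frames=frames, start_index=idx[0], seed=seed)
            pred = track_clip(net, clip)  # (4, 1, 2)
            seen = set()
            for t_local, f in enumerate(idx):
                if f in seen:  # padded tail of a partial clip
                    continue
                seen.add(f)
                track.add_state(f, pred[t_local, 0, 0], pred[t_local, 0, 1])
            pos = (float(pred[-1, 0, 0]), float(pred[-1, 0, 1]))
        tracks[cell_id] = track
    return tracks
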