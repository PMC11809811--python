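"""Seeded patch segmentation: the Segmentor + Refiner U-Net ensemble.

Segmentation operates on 96 x 96 patches cropped around tracker centroids,
with three input planes — fluorescent, bright-field and a seed plane — and
returns a binary mask of the *seeded* cell only; other cells in the patch
are ignored.  Training uses a per-pixel weighted cross-entropy whose weight
map emphasises (i) the thin background ridges between close cells via a
border term ``W0 * exp(-(d1+d2)^2 / (2 sigma^2))`` (``d1``/``d2`` =
distances to the nearest and second-nearest cell borders), (ii) pixels of
unwanted cells or fragments (``Wfr``), and — for the Refiner — (iii) the
pixels the Segmentor got wrong (``Werrors``).

The Refiner consumes the Segmentor's binarized output as its seed plane
and corrects it; the final mask averages the two probability maps.  The
refined mask centroid is fed back to tracking: it repositions the patch,
the cell is re-segmented once, and the resulting centroid becomes the
recorded track position and the seed for the next frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize

from . import nn
from .core import DEFAULT_SEED_SIDE, standardize_image

logger = logging.getLogger("seedtrack")

PATCH_SIDE = 96

__all__ = [
    "PatchSample", "WeightMapParams", "UNetSpec",
    "extract_patch", "paste_patch", "make_patch_seed",
    "compute_weight_map_segmentor", "compute_difference",
    "compute_weight_map_refiner", "build_segmentor_spec",
    "build_refiner_spec", "reduced_unet_spec", "UNet",
    "make_training_samples", "augment_sample", "SegTrainConfig",
    "train_segmentation_net", "segment_patch_ensemble", "refine_centroid",
]


# ---------------------------------------------------------------------------
# Patch plumbing
# ---------------------------------------------------------------------------

def extract_patch(frame: np.ndarray, centroid, side: int = PATCH_SIDE):
    """Crop a ``side x side`` patch centred at the rounded centroid.

    ``frame`` may be ``(H, W)`` or multi-channel ``(H, W, C)``.  Regions
    outside the frame are zero-padded.  Returns ``(patch, offset)`` where
    ``offset = (col0, row0)`` maps patch to frame coordinates
    (``frame_x = patch_x + col0``).
    """
    h, w = frame.shape[:2]
    cx, cy = centroid
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError("centroid outside frame")
    r0 = int(round(cy)) - side // 2
    c0 = int(round(cx)) - side // 2
    out_shape = (side, side) + frame.shape[2:]
    patch = np.zeros(out_shape, dtype=frame.dtype)
    rs, re = max(r0, 0), min(r0 + side, h)
    cs, ce = max(c0, 0), min(c0 + side, w)
    patch[rs - r0:re - r0, cs - c0:ce - c0] = frame[rs:re, cs:ce]
    return patch, (c0, r0)


def paste_patch(canvas: np.ndarray, patch: np.ndarray, offset) -> None:
    """Paste ``patch`` into ``canvas`` at ``offset = (col0, row0)``,
    clipping at the borders (in place)."""
    c0, r0 = offset
    side = patch.shape[0]
    h, w = canvas.shape[:2]
    rs, re = max(r0, 0), min(r0 + side, h)
    cs, ce = max(c0, 0), min(c0 + side, w)
    canvas[rs:re, cs:ce] = patch[rs - r0:re - r0, cs - c0:ce - c0]


def make_patch_seed(prev_centroid, side: int = PATCH_SIDE,
                    square_side: int = DEFAULT_SEED_SIDE) -> np.ndarray:
    """The segmentation seed plane: one square of intensity 255 at the cell
    of interest's previous-frame position (patch coordinates), clipped at
    the patch borders."""
    cx, cy = prev_centroid
    plane = np.zeros((side, side), dtype=np.float32)
    r0 = int(round(cy)) - square_side // 2
    c0 = int(round(cx)) - square_side // 2
    rs, re = max(r0, 0), min(r0 + square_side, side)
    cs, ce = max(c0, 0), min(c0 + square_side, side)
    if re > rs and ce > cs:
        plane[rs:re, cs:ce] = 255.0
    return plane


# ---------------------------------------------------------------------------
# Weight maps
# ---------------------------------------------------------------------------

@dataclass
class WeightMapParams:
    """Constants of the segmentation weight maps.

    ``w0`` (border-emphasis amplitude) and ``sigma`` (border decay scale,
    px) shape the inter-cell border term; ``w_fragments`` is added on
    pixels of unwanted cells; ``w_errors`` is added, for the Refiner, on
    pixels the Segmentor misclassified.
    """

    w0: float = 10.0
    sigma: float = 5.0
    w_fragments: float = 8.0
    w_errors: float = 10.0

    def __post_init__(self) -> None:
        if min(self.w0, self.sigma, self.w_fragments, self.w_errors) < 0:
            raise ValueError("weight-map parameters must be >= 0")


def _class_balance_map(label: np.ndarray) -> np.ndarray:
    """Inverse-class-frequency weights, normalized to mean 1 per patch."""
    label = label.astype(bool)
    n = label.size
    n_fg = int(label.sum())
    w = np.empty(label.shape, dtype=np.float32)
    if n_fg == 0 or n_fg == n:
        w[...] = 1.0
        return w
    w[label] = n / (2.0 * n_fg)
    w[~label] = n / (2.0 * (n - n_fg))
    return w


def _border_distances(instances: list[np.ndarray]) -> np.ndarray:
    """Stack of per-instance Euclidean distances to the instance border,
    shape (n_instances, H, W).

    The border is the morphological gradient (dilation minus erosion), so
    it includes the one-pixel background ring around the instance: a
    background pixel wedged between two cells then has distance 0 to both
    borders, making the border term attain its maximum W0 exactly there.
    """
    out = []
    for inst in instances:
        inst = inst.astype(bool)
        if not inst.any():
            continue
        border = ndimage.binary_dilation(inst) & ~ndimage.binary_erosion(inst)
        out.append(ndimage.distance_transform_edt(~border))
    return np.stack(out) if out else np.empty((0,) + instances[0].shape)


def compute_weight_map_segmentor(label: np.ndarray, unwanted: np.ndarray,
                                 params: WeightMapParams | None = None
                                 ) -> np.ndarray:
    """Weight map for Segmentor training.

    ``label`` is the cell-of-interest mask, ``unwanted`` the union of other
    cells/fragments in the patch (disjoint from ``label``).  The border
    term uses distances to the nearest and second-nearest cell borders over
    all instances (label + connected components of ``unwanted``); with a
    single instance ``d2`` is +inf and the term vanishes.
    """
    params = params or WeightMapParams()
    label = np.asarray(label).astype(bool)
    unwanted = np.asarray(unwanted).astype(bool)
    if label.shape != unwanted.shape:
        raise ValueError("label and unwanted masks must share a shape")
    if (label & unwanted).any():
        raise ValueError("unwanted mask overlaps the label")

    instances = [label] if label.any() else []
    lab, n = ndimage.label(unwanted)
    instances += [lab == i for i in range(1, n + 1)]

    w = _class_balance_map(label).astype(np.float64)
    if len(instances) >= 2:
        dists = _border_distances(instances)
        dists.sort(axis=0)
        d1, d2 = dists[0], dists[1]
        w += params.w0 * np.exp(-((d1 + d2) ** 2) / (2.0 * params.sigma ** 2))
    w[unwanted] += params.w_fragments
    return w.astype(np.float32)


def compute_difference(output: np.ndarray, label: np.ndarray) -> np.ndarray:
    """Binary error mask: the symmetric difference |output - label|."""
    output = np.asarray(output)
    label = np.asarray(label)
    for arr, name in ((output, "output"), (label, "label")):
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{name} mask is not binary")
    return (output.astype(bool) ^ label.astype(bool)).astype(np.uint8)


def compute_weight_map_refiner(base: np.ndarray, error_mask: np.ndarray,
                               params: WeightMapParams | None = None
                               ) -> np.ndarray:
    """Refiner weight map: the Segmentor map plus ``w_errors`` on the
    pixels the Segmentor misclassified."""
    params = params or WeightMapParams()
    base = np.asarray(base, dtype=np.float32)
    error_mask = np.asarray(error_mask).astype(bool)
    if base.shape != error_mask.shape:
        raise ValueError("weight map and error mask shapes differ")
    out = base.copy()
    out[error_mask] += params.w_errors
    return out


# ---------------------------------------------------------------------------
# U-Net specs and network
# ---------------------------------------------------------------------------

@dataclass
class UNetSpec:
    """Shape of a U-Net encoder/decoder for ``side x side x in_channels``
    input and a 1-plane sigmoid output.

    ``filters`` lists the encoder block widths; the bottleneck uses
    ``2 * filters[-1]``.  ``dropouts`` maps 1-based block index (encoder
    blocks first, then the bottleneck) to a dropout rate applied at the end
    of that block.
    """

    side: int = PATCH_SIDE
    in_channels: int = 3
    filters: list[int] = field(default_factory=lambda: [64, 128, 256, 512])
    dropouts: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.side % (2 ** len(self.filters)):
            raise ValueError("side must be divisible by 2^depth")
        self.dropouts = {int(k): float(v) for k, v in self.dropouts.items()}

    @property
    def bottleneck(self) -> int:
        return 2 * self.filters[-1]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dropouts"] = {str(k): v for k, v in self.dropouts.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "UNetSpec":
        d = dict(d)
        d["dropouts"] = {int(k): v for k, v in d["dropouts"].items()}
        return cls(**d)


def build_segmentor_spec() -> UNetSpec:
    """The full-scale Segmentor: a standard 4-level U-Net for 96 x 96 x 3
    patches with dropouts Drop2 = 0.5, Drop3 = 0.3 added and Drop4/Drop5
    raised from 0.3 to 0.5."""
    return UNetSpec(side=PATCH_SIDE, in_channels=3,
                    filters=[64, 128, 256, 512],
                    dropouts={2: 0.5, 3: 0.3, 4: 0.5, 5: 0.5})


def build_refiner_spec() -> UNetSpec:
    """The full-scale Refiner: the stock U-Net (Drop4 = Drop5 = 0.3) with
    only Drop2 = 0.5 and Drop3 = 0.3 added."""
    return UNetSpec(side=PATCH_SIDE, in_channels=3,
                    filters=[64, 128, 256, 512],
                    dropouts={2: 0.5, 3: 0.3, 4: 0.3, 5: 0.3})


def reduced_unet_spec(side: int = 48) -> UNetSpec:
    """A desk-scale U-Net (two encoder levels, 8/16 filters) for CPU
    training; patches are resampled to ``side`` on the way in and the
    probability map back up on the way out."""
    return UNetSpec(side=side, in_channels=3, filters=[8, 16],
                    dropouts={2: 0.1, 3: 0.1})


class _ConvBlock:
    def __init__(self, c_in, c_out, rng, dropout=0.0):
        self.conv1 = nn.Conv2d(c_in, c_out, rng)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(c_out, c_out, rng)
        self.relu2 = nn.ReLU()
        self.drop = nn.Dropout(dropout) if dropout else None

    def params(self):
        return self.conv1.params() + self.conv2.params()

    def forward(self, x, train=False, rng=None):
        h = self.relu1.forward(self.conv1.forward(x))
        h = self.relu2.forward(self.conv2.forward(h))
        if self.drop is not None:
            h = self.drop.forward(h, train=train, rng=rng)
        return h

    def backward(self, g):
        if self.drop is not None:
            g = self.drop.backward(g)
        g = self.conv1.backward(self.relu1.backward(
            self.conv2.backward(self.relu2.backward(g))))
        return g


class UNet:
    """U-Net with nearest-neighbour upsampling and skip concatenation,
    emitting logits (apply :func:`seedtrack.nn.sigmoid` for probabilities).
    """

    def __init__(self, spec: UNetSpec, rng: np.random.Generator):
        self.spec = spec
        drops = spec.dropouts
        self.enc = []
        c_in = spec.in_channels
        for i, f in enumerate(spec.filters, start=1):
            self.enc.append(_ConvBlock(c_in, f, rng, drops.get(i, 0.0)))
            c_in = f
        bn_index = len(spec.filters) + 1
        self.bottleneck = _ConvBlock(c_in, spec.bottleneck, rng,
                                     drops.get(bn_index, 0.0))
        self.up_convs = []
        self.dec = []
        c = spec.bottleneck
        for f in reversed(spec.filters):
            self.up_convs.append(nn.Conv2d(c, f, rng))  # after upsample
            self.dec.append(_ConvBlock(2 * f, f, rng))
            c = f
        self.out_conv = nn.Conv2d(c, 1, rng, k=1)

    def params(self):
        out = []
        for block in self.enc:
            out.extend(block.params())
        out.extend(self.bottleneck.params())
        for conv, block in zip(self.up_convs, self.dec):
            out.extend(conv.params())
            out.extend(block.params())
        out.extend(self.out_conv.params())
        return out

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """(B, side, side, C) -> (B, side, side) logits."""
        skips = []
        h = x
        self._pools = []
        for block in self.enc:
            h = block.forward(h, train=train, rng=rng)
            skips.append(h)
            pool = nn.MaxPool2d22()
            h = pool.forward(h)
            self._pools.append(pool)
        h = self.bottleneck.forward(h, train=train, rng=rng)
        self._up_relus = []
        for conv, block, skip in zip(self.up_convs, self.dec,
                                     reversed(skips)):
            h = nn.upsample2x(h)
            relu = nn.ReLU()
            h = relu.forward(conv.forward(h))
            self._up_relus.append(relu)
            h = np.concatenate([skip, h], axis=-1)
            h = block.forward(h, train=train, rng=rng)
        logits = self.out_conv.forward(h)
        return logits[..., 0]

    def backward(self, g: np.ndarray) -> None:
        h = self.out_conv.backward(g[..., None])
        skip_grads = []
        for conv, block, relu in zip(reversed(self.up_convs),
                                     reversed(self.dec),
                                     reversed(self._up_relus)):
            h = block.backward(h)
            f = conv.w.value.shape[-1]
            skip_g, up_g = h[..., :f], h[..., f:]
            skip_grads.append(skip_g)
            h = nn.upsample2x_backward(conv.backward(relu.backward(up_g)))
        h = self.bottleneck.backward(h)
        for block, pool, skip_g in zip(reversed(self.enc),
                                       reversed(self._pools),
                                       reversed(skip_grads)):
            h = pool.backward(h)
            h = block.backward(h + skip_g)

    def predict_proba(self, patch: np.ndarray) -> np.ndarray:
        """Probability map for a single (side, side, C) patch."""
        return nn.sigmoid(self.forward(patch[None]))[0]

    def save(self, path) -> None:
        nn.save_arrays(path, self.spec.to_dict(), self.params())

    @classmethod
    def load(cls, path) -> "UNet":
        spec_dict, arrays = nn.load_arrays(path)
        net = cls(UNetSpec.from_dict(spec_dict), np.random.default_rng(0))
        nn.set_state(net.params(), arrays)
        return net


# ---------------------------------------------------------------------------
# Training samples
# ---------------------------------------------------------------------------

@dataclass
class PatchSample:
    """One training sample: 96 x 96 x 3 input (fluorescent, bright-field,
    seed), binary label of the cell of interest, and a weight map."""

    x: np.ndarray
    y: np.ndarray
    w: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.x.shape[:2] == self.y.shape == self.w.shape):
            raise ValueError("sample planes must share the patch shape")
        if (self.w < 0).any():
            raise ValueError("weights must be >= 0")


def normalize_patch_planes(x: np.ndarray) -> np.ndarray:
    """Standardize each channel of an (H, W, C) patch to mean 0, sd 1."""
    return np.stack([standardize_image(x[..., c])
                     for c in range(x.shape[-1])], axis=-1)


def make_training_samples(movie, mask_stack, tree, mode: str,
                          rng: np.random.Generator,
                          n_samples: int | None = None,
                          jitter: float = 35.0,
                          segmentor: "UNet | None" = None,
                          params: WeightMapParams | None = None,
                          augment: bool = False,
                          side: int = PATCH_SIDE):
    """Build Segmentor or Refiner patch samples from a simulated movie.

    Patch centres are jittered by U(-jitter, jitter) per axis around the
    true centroid to mimic tracking inaccuracy.  In ``segmentor`` mode the
    seed plane is a 40 x 40 square at the cell's previous-frame centroid;
    in ``refiner`` mode it is replaced by the trained Segmentor's binarized
    output on the same patch and the weight map gains the error term.
    ``augment=True`` expands the set 6-fold (3 rotations + 2 reflections).
    """
    if mode not in ("segmentor", "refiner"):
        raise ValueError("mode must be 'segmentor' or 'refiner'")
    if mode == "refiner" and segmentor is None:
        raise ValueError("refiner samples need a trained Segmentor")
    params = params or WeightMapParams()

    candidates = []
    for frame in range(1, movie.n_frames):
        prev = tree.positions_at(frame - 1)
        cur = tree.positions_at(frame)
        for cid in sorted(cur):
            if cid in prev:
                candidates.append((frame, cid))
    if not candidates:
        raise ValueError("movie too short to build samples")
    if n_samples is None:
        n_samples = len(candidates)
    picks = [candidates[i] for i in
             rng.integers(len(candidates), size=n_samples)]

    h, w = movie.frame_shape
    samples = []
    for frame, cid in picks:
        cx, cy = tree.positions_at(frame)[cid]
        px = float(np.clip(cx + rng.uniform(-jitter, jitter), 0, w - 1))
        py = float(np.clip(cy + rng.uniform(-jitter, jitter), 0, h - 1))
        stack = np.stack([movie.fluor[frame], movie.bright[frame],
                          np.zeros_like(movie.fluor[frame])], axis=-1)
        patch, offset = extract_patch(stack, (px, py), side)
        labels_patch, _ = extract_patch(mask_stack[frame], (px, py), side)
        label = (labels_patch == cid)
        unwanted = (labels_patch != 0) & ~label
        prev_c = tree.positions_at(frame - 1)[cid]
        seed_plane = make_patch_seed((prev_c[0] - offset[0],
                                      prev_c[1] - offset[1]), side)
        patch[..., 2] = seed_plane
        weight = compute_weight_map_segmentor(label, unwanted, params)
        sample = PatchSample(x=patch, y=label.astype(np.float32),
                             w=weight,
                             meta={"frame": frame, "cell_id": cid,
                                   "offset": offset})
        samples.append(sample)

    if mode == "refiner":
        refined = []
        for s in samples:
            prob = _apply_net(segmentor, s.x)
            seg_out = (prob > 0.5).astype(np.float32)
            x2 = s.x.copy()
            x2[..., 2] = seg_out * 255.0
            err = compute_difference(seg_out.astype(np.uint8),
                                     s.y.astype(np.uint8))
            w2 = compute_weight_map_refiner(s.w, err, params)
            refined.append(PatchSample(x=x2, y=s.y, w=w2, meta=s.meta))
        samples = refined

    if augment:
        samples = [aug for s in samples for aug in augment_sample(s)]
    return samples


def augment_sample(sample: PatchSample) -> list[PatchSample]:
    """6-fold augmentation: the original, 3 rotations and 2 reflections."""
    ops = [
        lambda a: a,
        lambda a: np.rot90(a, 1, axes=(0, 1)),
        lambda a: np.rot90(a, 2, axes=(0, 1)),
        lambda a: np.rot90(a, 3, axes=(0, 1)),
        lambda a: a[::-1],
        lambda a: a[:, ::-1],
    ]
    return [PatchSample(x=np.ascontiguousarray(op(sample.x)),
                        y=np.ascontiguousarray(op(sample.y)),
                        w=np.ascontiguousarray(op(sample.w)),
                        meta=sample.meta)
            for op in ops]


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class SegTrainConfig:
    """Segmentation training hyper-parameters (reference defaults:
    Adam, lr 9e-5, batch 32; 200 epochs for the Segmentor and 30 for the
    Refiner)."""

    learning_rate: float = 0.00009
    batch_size: int = 32
    epochs: int = 200
    seed: int = 0
    val_fraction: float = 0.15


def _mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    a, b = a.astype(bool), b.astype(bool)
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else 1.0


def _sample_tensors(samples, side):
    """Stack samples into arrays at the net's resolution."""
    xs, ys, ws = [], [], []
    for s in samples:
        x = normalize_patch_planes(s.x.astype(np.float32))
        y, w = s.y, s.w
        if s.x.shape[0] != side:
            x = resize(x, (side, side), order=1, preserve_range=True,
                       anti_aliasing=True)
            y = resize(y, (side, side), order=0, preserve_range=True,
                       anti_aliasing=False)
            w = resize(w, (side, side), order=1, preserve_range=True,
                       anti_aliasing=False)
        xs.append(x)
        ys.append(y)
        ws.append(w)
    return (np.asarray(xs, dtype=np.float32),
            np.asarray(ys, dtype=np.float32),
            np.asarray(ws, dtype=np.float32))


def train_segmentation_net(spec: UNetSpec, samples, cfg: SegTrainConfig):
    """Train a U-Net with weight-map-weighted cross-entropy.

    Returns ``(net, history)``; the parameters of the epoch with the best
    validation IoU are restored into the returned net (best-checkpoint
    rule).  History records per-epoch loss and mean mask IoU at threshold
    0.5 for both splits.
    """
    rng = np.random.default_rng(cfg.seed)
    net = UNet(spec, rng)
    drop_rng = np.random.default_rng(rng.integers(2 ** 31))
    opt = nn.Adam(net.params(), lr=cfg.learning_rate)

    x, y, w = _sample_tensors(samples, spec.side)
    n = len(samples)
    n_val = max(int(round(cfg.val_fraction * n)), 1) if n > 4 else 0
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    best_iou, best_state, best_epoch = -1.0, None, -1
    records = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = net.forward(x[idx], train=True, rng=drop_rng)
            loss, g = nn.weighted_bce_loss(logits, y[idx], w[idx])
            opt.zero_grad()
            net.backward(g.astype(np.float32))
            opt.step()
            losses.append(loss)
        rec = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        rec.update(_eval_seg(net, x, y, w, train_idx[:128], "train"))
        if n_val:
            rec.update(_eval_seg(net, x, y, w, val_idx, "val"))
            if rec["val_iou"] > best_iou:
                best_iou = rec["val_iou"]
                best_state = nn.get_state(net.params())
                best_epoch = epoch
        records.append(rec)
    if best_state is not None:
        nn.set_state(net.params(), best_state)
        logger.info("restored best checkpoint (epoch %d, val IoU %.3f)",
                    best_epoch, best_iou)
    return net, pd.DataFrame.from_records(records)


def _eval_seg(net, x, y, w, idx, name, batch: int = 32):
    if len(idx) == 0:
        return {}
    losses, ious = [], []
    for start in range(0, len(idx), batch):
        sl = idx[start:start + batch]
        logits = net.forward(x[sl])
        loss, _ = nn.weighted_bce_loss(logits, y[sl], w[sl])
        losses.append(loss * len(sl))
        pred = logits > 0
        for p, t in zip(pred, y[sl]):
            ious.append(_mask_iou(p, t > 0.5))
    return {f"{name}_loss": float(np.sum(losses) / len(idx)),
            f"{name}_iou": float(np.mean(ious))}


# ---------------------------------------------------------------------------
# Ensemble execution
# ---------------------------------------------------------------------------

def _apply_net(net: UNet, patch: np.ndarray) -> np.ndarray:
    """Run a U-Net on a raw (96, 96, 3) patch, resampling to and from the
    net's native side as needed; returns a probability map at patch size."""
    side = patch.shape[0]
    x = normalize_patch_planes(patch.astype(np.float32))
    if net.spec.side != side:
        x = resize(x, (net.spec.side, net.spec.side), order=1,
                   preserve_range=True, anti_aliasing=True
                   ).astype(np.float32)
    prob = net.predict_proba(x.astype(np.float32))
    if net.spec.side != side:
        prob = resize(prob, (side, side), order=1, preserve_range=True,
                      anti_aliasing=False)
    return prob


def segment_patch_ensemble(segmentor: UNet, refiner: UNet,
                           patch: np.ndarray, threshold: float = 0.5):
    """Segment the seeded cell in a (side, side, 3) patch.

    The Segmentor produces P1; the Refiner, fed the patch with the seed
    plane replaced by binarized P1, produces P2; the combined map is
    ``(P1 + P2) / 2`` thresholded at 0.5.  Of the resulting components the
    one with maximal seed overlap is kept (the seeded cell); the full
    thresholded union is also returned for division checking.

    Returns ``(mask, aux)`` with ``aux = {"p1", "p2", "binary_union"}``.
    """
    seed_plane = patch[..., 2]
    p1 = _apply_net(segmentor, patch)
    seg_binary = (p1 > threshold).astype(np.float32)
    patch2 = patch.copy()
    patch2[..., 2] = seg_binary * 255.0
    p2 = _apply_net(refiner, patch2)
    combined = 0.5 * (p1 + p2)
    binary = combined > threshold
    mask = _keep_seeded_component(binary, seed_plane)
    return mask, {"p1": p1, "p2": p2, "binary_union": binary}


def _keep_seeded_component(binary: np.ndarray,
                           seed_plane: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(binary)
    if n == 0:
        return np.zeros_like(binary, dtype=bool)
    seeded = seed_plane > 0
    overlaps = ndimage.sum_labels(seeded.astype(np.int64), lab,
                                  index=np.arange(1, n + 1))
    if overlaps.max() > 0:
        keep = int(np.argmax(overlaps)) + 1
    else:  # no component touches the seed; fall back to the largest
        sizes = ndimage.sum_labels(np.ones_like(lab), lab,
                                   index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
    return lab == keep


def refine_centroid(mask: np.ndarray, offset) -> tuple[float, float]:
    """Centroid of a patch mask mapped back to frame coordinates."""
    if not mask.any():
        raise ValueError("empty mask has no centroid")
    cy, cx = ndimage.center_of_mass(mask)
    return (float(cx + offset[0]), float(cy + offset[1]))
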