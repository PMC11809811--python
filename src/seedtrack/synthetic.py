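"""Synthetic two-channel movies of motile, dividing cells with ground truth.

The generator reproduces the statistical structure used to train the
trackers on lymphocyte-like cells:

* initial positions uniform over the frame,
* motion angles uniform on [0, 2pi) with step sizes drawn from the density
  ``f(t) = a * (t/b) * exp(-(t/b)^2)`` with defaults ``a = 0.25, b = 7``
  (pixels).  ``f`` is an unnormalized Rayleigh density with scale
  ``b / sqrt(2)``; sampling uses the normalized form, so ``a`` has no
  effect on the samples and is retained only for fidelity to the fitted
  empirical form,
* blob-like fluorescent cells roughly 40 px across built from a dilated
  disk with a noisy interior, Gaussian blur and background noise,
* binary-fission divisions preceded by a rendered figure-eight parent.

The bright-field channel of real instruments carries little contrast for
these cells; here it is rendered as a synthetic low-contrast annulus plus
noise and is plumbing only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import DEFAULT_FRAME_SIDE, LineageTree, Movie, Track

__all__ = [
    "MotionModel", "ShapeModel", "SimConfig", "sample_step_size",
    "sample_initial_positions", "synthesize_cell_image", "simulate_movie",
    "rayleigh_mle",
]


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

@dataclass
class MotionModel:
    """Step-size / angle model of cell motion between frames.

    ``a`` is the amplitude of the (unnormalized) empirical step-size
    density and does not affect sampling; ``b`` (pixels) sets the scale.
    Angles are uniform on [0, 2pi).
    """

    a: float = 0.25
    b: float = 7.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b < 0:
            raise ValueError("motion model requires a > 0 and b >= 0")


@dataclass
class ShapeModel:
    """Rendering model for one cell.

    The ground-truth mask is a disk of ``base_radius`` dilated by
    ``dilation_radius`` (so the equivalent diameter is about
    ``2 * (base_radius + dilation_radius)``, ~40 px at defaults).  The
    fluorescent rendering adds interior texture, Gaussian blur and
    background noise on top of the mask.
    """

    base_radius: float = 18.0
    dilation_radius: float = 2.0
    fg_intensity: float = 180.0
    interior_noise: float = 60.0
    blur_sigma: float = 1.5
    background_noise: float = 8.0

    def __post_init__(self) -> None:
        if self.base_radius <= 0:
            raise ValueError("base_radius must be positive")
        for v in (self.dilation_radius, self.interior_noise, self.blur_sigma,
                  self.background_noise):
            if v < 0:
                raise ValueError("noise amplitudes and radii must be >= 0")

    @property
    def radius(self) -> float:
        return self.base_radius + self.dilation_radius


@dataclass
class SimConfig:
    """Full simulation recipe; ``seed`` fixes all randomness."""

    side: int = DEFAULT_FRAME_SIDE
    n_frames: int = 20
    n_cells: int = 1
    divisions: list[tuple[int, int]] = field(default_factory=list)  # (frame, parent)
    motion: MotionModel = field(default_factory=MotionModel)
    shape: ShapeModel = field(default_factory=ShapeModel)
    seed: int = 0
    min_separation: float | None = None  # centre-to-centre, default 2r + 4
    n_predivision_frames: int = 2
    render: bool = True  # False: motion/lineage only (images left blank)

    def __post_init__(self) -> None:
        for frame, parent in self.divisions:
            if not (0 < frame < self.n_frames):
                raise ValueError("division frames must fall inside the movie")


# ---------------------------------------------------------------------------
# Sampling primitives
# ---------------------------------------------------------------------------

def sample_step_size(model: MotionModel, n: int, rng: np.random.Generator):
    """Draw ``n`` i.i.d. step sizes (pixels) from the normalized step-size
    density, i.e. a Rayleigh with scale ``b / sqrt(2)``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if model.b < 0:
        raise ValueError("b must be >= 0")
    if model.b == 0:
        return np.zeros(n)
    return rng.rayleigh(scale=model.b / math.sqrt(2.0), size=n)


def rayleigh_mle(steps: np.ndarray) -> float:
    """Closed-form maximum-likelihood estimate of the scale ``b`` of the
    step-size density family ``f(t) ~ (t/b) exp(-(t/b)^2)``.

    For a Rayleigh with scale ``sigma = b/sqrt(2)`` the MLE is
    ``sigma_hat^2 = mean(t^2)/2``, hence ``b_hat = sqrt(mean(t^2))``.
    """
    steps = np.asarray(steps, dtype=np.float64)
    if steps.size == 0:
        raise ValueError("no steps supplied")
    return float(np.sqrt(np.mean(steps ** 2)))


def sample_initial_positions(k: int, side: int, rng: np.random.Generator,
                             min_distance: float = 0.0,
                             max_attempts: int = 10_000):
    """Draw ``k`` centroids i.i.d. uniform on (0, side) per axis, optionally
    enforcing a minimum pairwise distance by rejection."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if min_distance <= 0:
        return rng.uniform(0, side, size=(k, 2))
    points: list[np.ndarray] = []
    attempts = 0
    while len(points) < k:
        p = rng.uniform(0, side, size=2)
        attempts += 1
        if all(np.hypot(*(p - q)) >= min_distance for q in points):
            points.append(p)
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {k} cells at min distance {min_distance} "
                f"in a {side} px frame after {max_attempts} attempts; "
                "reduce the cell count or the separation"
            )
    return np.asarray(points)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _disk_mask_at(shape, cx: float, cy: float, radius: float) -> np.ndarray:
    h, w = shape
    r0 = max(int(cy - radius) - 1, 0)
    r1 = min(int(cy + radius) + 2, h)
    c0 = max(int(cx - radius) - 1, 0)
    c1 = min(int(cx + radius) + 2, w)
    mask = np.zeros(shape, dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return mask
    yy, xx = np.mgrid[r0:r1, c0:c1]
    mask[r0:r1, c0:c1] = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2
    return mask


def _render_fluor(mask: np.ndarray, shape_model: ShapeModel,
                  rng: np.random.Generator) -> np.ndarray:
    """Fluorescent rendering of a mask: interior texture + blur, local to the
    mask's bounding window for speed.  Background noise is added per frame by
    the caller, not here."""
    img = np.zeros(mask.shape, dtype=np.float32)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return img
    pad = int(3 * shape_model.blur_sigma) + 2
    r0, r1 = max(rows.min() - pad, 0), min(rows.max() + pad + 1, mask.shape[0])
    c0, c1 = max(cols.min() - pad, 0), min(cols.max() + pad + 1, mask.shape[1])
    window = mask[r0:r1, c0:c1]
    patch = np.where(window, shape_model.fg_intensity, 0.0).astype(np.float32)
    if shape_model.interior_noise > 0:
        patch[window] += rng.uniform(-shape_model.interior_noise,
                                     shape_model.interior_noise,
                                     size=int(window.sum()))
    if shape_model.blur_sigma > 0:
        patch = gaussian_filter(patch, shape_model.blur_sigma)
    img[r0:r1, c0:c1] = patch
    return img


def synthesize_cell_image(shape_model: ShapeModel, centroid, canvas_shape,
                          rng: np.random.Generator):
    """Render one cell: returns ``(fluorescent image, ground-truth mask)``
    on a canvas of ``canvas_shape``.

    The mask is the dilated disk; the rendering adds interior texture,
    Gaussian blur and uniform background noise.  With all noise and blur set
    to zero the rendering support equals the mask exactly.
    """
    cx, cy = centroid
    h, w = canvas_shape
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError("centroid outside canvas")
    if 2 * shape_model.radius > min(canvas_shape):
        raise ValueError("cell radius larger than canvas")
    mask = _disk_mask_at(canvas_shape, cx, cy, shape_model.radius)
    img = _render_fluor(mask, shape_model, rng)
    if shape_model.background_noise > 0:
        img += rng.uniform(0, shape_model.background_noise, size=canvas_shape
                           ).astype(np.float32)
    return img, mask


def _render_bright(masks: dict[int, np.ndarray], shape,
                   rng: np.random.Generator) -> np.ndarray:
    """Synthetic bright-field stand-in: faint annulus per cell plus noise."""
    img = np.full(shape, 100.0, dtype=np.float32)
    img += rng.normal(0, 3.0, size=shape).astype(np.float32)
    for mask in masks.values():
        interior = _shrink(mask)
        ring = mask & ~interior
        img[ring] -= 20.0
        img[interior] += 5.0
    return gaussian_filter(img, 1.0)


def _shrink(mask: np.ndarray) -> np.ndarray:
    from scipy.ndimage import binary_erosion
    return binary_erosion(mask, iterations=2)


# ---------------------------------------------------------------------------
# Movie simulation
# ---------------------------------------------------------------------------

def _reflect(value: float, lo: float, hi: float) -> float:
    span = hi - lo
    if span <= 0:
        return lo
    v = (value - lo) % (2 * span)
    return lo + (v if v <= span else 2 * span - v)


@dataclass
class _CellState:
    cell_id: int
    x: float
    y: float
    radius: float
    parent_id: int | None = None
    dividing_until: int | None = None   # frame at which fission completes
    fission_axis: float = 0.0


def simulate_movie(config: SimConfig):
    """Simulate a movie under ``config``.

    Returns ``(movie, mask_stack, lineage, centroid_table)`` where
    ``mask_stack`` is a ``(T, H, W)`` uint16 label stack (0 = background,
    labels = cell ids), ``lineage`` a :class:`~seedtrack.core.LineageTree`
    and ``centroid_table`` a frame,cell_id,x,y DataFrame.  Output is
    bit-reproducible for a fixed ``config.seed``.

    Each living cell takes a step ``(R, A)`` per frame with reflection at
    the borders; steps that would bring two cells closer than the minimum
    separation are resampled (masks stay pairwise disjoint outside the
    designated pre-division frames).  At a scheduled division the parent is
    rendered as a widening figure-eight for ``n_predivision_frames`` frames
    and then replaced by two adjacent, near-equal round daughters.
    """
    rng = np.random.default_rng(config.seed)
    side = config.side
    shape = (side, side)
    radius = config.shape.radius
    min_sep = (config.min_separation if config.min_separation is not None
               else 2 * radius + 4)
    margin = radius + 1

    div_by_frame: dict[int, list[int]] = {}
    for frame, parent in config.divisions:
        div_by_frame.setdefault(frame, []).append(parent)

    positions = sample_initial_positions(
        config.n_cells, side, rng, min_distance=min_sep)
    # keep initial cells clear of the border so the full disk fits
    positions = np.clip(positions, margin, side - margin)

    cells: dict[int, _CellState] = {}
    tree = LineageTree()
    for i in range(config.n_cells):
        cid = i + 1
        cells[cid] = _CellState(cid, positions[i, 0], positions[i, 1], radius)
        tree.add_track(Track(cid))
    next_id = config.n_cells + 1

    fluor = np.zeros((config.n_frames,) + shape, dtype=np.float32)
    bright = np.zeros_like(fluor)
    labels = np.zeros((config.n_frames,) + shape, dtype=np.uint16)
    rows = []

    daughter_radius = 0.75 * radius

    for frame in range(config.n_frames):
        # the schedule is keyed on the fission frame; parents enter the
        # figure-eight phase n_predivision_frames earlier
        for parent in div_by_frame.get(frame, []):
            if parent not in cells:
                raise ValueError(
                    f"division schedule names cell {parent}, which does not "
                    f"exist (or no longer exists) at frame {frame}"
                )
            cells[parent].dividing_until = frame
        for f_div in sorted(div_by_frame):
            if frame < f_div <= frame + config.n_predivision_frames:
                for parent in div_by_frame[f_div]:
                    if parent in cells and cells[parent].dividing_until is None:
                        cells[parent].dividing_until = f_div
                        cells[parent].fission_axis = rng.uniform(0, 2 * math.pi)

        # --- execute fissions completing at this frame
        for cid in [c for c in cells
                    if cells[c].dividing_until == frame]:
            parent = cells.pop(cid)
            sep = 1.1 * daughter_radius
            # place the daughter pair along the fission axis, translated
            # as a unit to stay inside the frame (independent reflection
            # could fold them onto each other at a border); if a daughter
            # would land on another cell, try rotated axes
            placement = None
            for rot in (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5):
                axis = parent.fission_axis + rot * math.pi / 4
                dx, dy = sep * math.cos(axis), sep * math.sin(axis)
                xs = [parent.x - dx, parent.x + dx]
                ys = [parent.y - dy, parent.y + dy]
                sx = max(margin - min(xs), 0) + \
                    min(side - margin - max(xs), 0)
                sy = max(margin - min(ys), 0) + \
                    min(side - margin - max(ys), 0)
                pts = [(xs[k] + sx, ys[k] + sy) for k in range(2)]
                clear = all(
                    math.hypot(px - o.x, py - o.y)
                    >= daughter_radius + o.radius + 2
                    for px, py in pts for o in cells.values())
                if placement is None or clear:
                    placement = pts
                if clear:
                    break
            for px, py in placement:
                child = _CellState(next_id, px, py, daughter_radius,
                                   parent_id=cid)
                cells[child.cell_id] = child
                tree.add_track(Track(child.cell_id, parent_id=cid))
                next_id += 1
            c1, c2 = next_id - 2, next_id - 1
            tree.add_division(cid, frame, (c1, c2))

        # --- motion (cells in a pre-division phase stay put)
        if frame > 0:
            for cid, cell in sorted(cells.items()):
                if cell.dividing_until is not None:
                    continue
                for _ in range(50):
                    r = sample_step_size(config.motion, 1, rng)[0]
                    ang = rng.uniform(0, 2 * math.pi)
                    nx = _reflect(cell.x + r * math.cos(ang), margin, side - margin)
                    ny = _reflect(cell.y + r * math.sin(ang), margin, side - margin)
                    # accept when every pair keeps its required distance;
                    # a pair already too close may still move further apart
                    if all(np.hypot(nx - o.x, ny - o.y)
                           >= min(_required_separation(cell, o, min_sep),
                                  np.hypot(cell.x - o.x, cell.y - o.y))
                           for oc, o in cells.items() if oc != cid):
                        cell.x, cell.y = nx, ny
                        break

        # --- render
        if not config.render:
            for cid, cell in sorted(cells.items()):
                tree.tracks[cid].add_state(frame, cell.x, cell.y)
                rows.append((frame, cid, cell.x, cell.y))
            continue
        frame_masks: dict[int, np.ndarray] = {}
        frame_img = np.zeros(shape, dtype=np.float32)
        for cid, cell in cells.items():
            if cell.dividing_until is not None:
                # widening figure-eight: two lobes separating as the
                # cleavage furrow deepens (lobe separation 1.3 -> 1.9 lobe
                # radii over the pre-division frames)
                frac = 1.0 - (cell.dividing_until - frame) / max(
                    config.n_predivision_frames, 1)
                lobe_r = 1.05 * daughter_radius
                sep = (1.4 + 0.6 * frac) * lobe_r
                ax = cell.fission_axis
                dx = sep * math.cos(ax) / 2
                dy = sep * math.sin(ax) / 2
                m = (_disk_mask_at(shape, cell.x - dx, cell.y - dy, lobe_r)
                     | _disk_mask_at(shape, cell.x + dx, cell.y + dy,
                                     lobe_r))
            else:
                m = _disk_mask_at(shape, cell.x, cell.y, cell.radius)
            frame_masks[cid] = m
            frame_img += _render_fluor(m, config.shape, rng)

        if config.shape.background_noise > 0:
            frame_img += rng.uniform(0, config.shape.background_noise,
                                     size=shape).astype(np.float32)
        fluor[frame] = frame_img
        bright[frame] = _render_bright(frame_masks, shape, rng)

        label = np.zeros(shape, dtype=np.uint16)
        for cid in sorted(frame_masks):
            label[frame_masks[cid]] = cid
        labels[frame] = label

        for cid, cell in sorted(cells.items()):
            tree.tracks[cid].add_state(frame, cell.x, cell.y)
            rows.append((frame, cid, cell.x, cell.y))

    movie = Movie(fluor=fluor, bright=bright)
    table = pd.DataFrame(rows, columns=["frame", "cell_id", "x", "y"])
    tree.validate()
    return movie, labels, tree, table


def _siblings(a: _CellState, b: _CellState) -> bool:
    return a.parent_id is not None and a.parent_id == b.parent_id


def _required_separation(cell: _CellState, other: _CellState,
                         min_sep: float) -> float:
    """Centre distance another cell must keep from ``cell``.

    Freshly divided siblings only need their masks disjoint; a cell in the
    figure-eight phase has a wider footprint, so others keep extra margin.
    """
    touch = cell.radius + other.radius + 2.0
    if _siblings(cell, other):
        return touch
    if other.dividing_until is not None:
        return max(min_sep, touch) + other.radius
    return max(min_sep, touch)
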