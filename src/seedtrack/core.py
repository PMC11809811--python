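"""Domain types and seed-channel primitives shared by the whole pipeline.

Coordinate convention used throughout the package: 0-based pixel indices,
``(x, y) = (column, row)``, with sub-pixel float centroids.  Arrays are
indexed ``[row, col]``.

The *seed channel* is the central device of the pipeline: an artificial
image plane containing fixed-intensity squares, one per cell, that carries
each cell's identity and last known position between 4-frame clips and
between the tracking and segmentation stages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from skimage.transform import resize

logger = logging.getLogger("seedtrack")

#: Default physical pixel size of the instrument the pipeline was designed
#: around (20x magnification), in microns per pixel.
DEFAULT_PIXEL_SIZE_UM = 0.327

#: Default frame side in pixels (a 125 x 125 um^2 well).
DEFAULT_FRAME_SIDE = 382

#: Side of a seed square, slightly larger than a typical cell (~40 px across).
DEFAULT_SEED_SIDE = 40

#: Seed intensities by identity rank.  The first four values are the
#: standard palette; further ranks continue the halving pattern.  Override
#: by passing ``palette=`` to :func:`make_seed_channel`.
DEFAULT_SEED_PALETTE = (255, 125, 60, 30, 15, 7, 3, 1)

#: Side of the (resized) square input fed to the trackers.
DEFAULT_TRACKER_INPUT_SIDE = 100


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Movie:
    """A two-channel 2D time-lapse movie.

    Parameters
    ----------
    fluor, bright
        ``(T, H, W)`` float arrays holding the fluorescent and bright-field
        channels.  Both must share the same shape.
    pixel_size_um
        Microns per pixel; must be positive.
    frame_interval
        Seconds between consecutive frames.
    """

    fluor: np.ndarray
    bright: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval: float = 60.0

    def __post_init__(self) -> None:
        self.fluor = np.asarray(self.fluor, dtype=np.float32)
        self.bright = np.asarray(self.bright, dtype=np.float32)
        if self.fluor.ndim != 3:
            raise ValueError("movie channels must be (T, H, W) stacks")
        if self.fluor.shape != self.bright.shape:
            raise ValueError(
                "fluorescent and bright-field stacks must have identical "
                f"shapes, got {self.fluor.shape} vs {self.bright.shape}"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.fluor.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.fluor.shape[1:]


@dataclass
class Seed:
    """One identity marker: a square of fixed intensity at a centroid."""

    identity: int
    x: float
    y: float
    intensity: float


@dataclass
class SeedChannel:
    """An artificial frame of identity squares (background 0)."""

    image: np.ndarray
    seeds: list[Seed]
    side_px: int = DEFAULT_SEED_SIDE


@dataclass
class Clip:
    """Four consecutive fluorescent frames plus an optional seed channel."""

    frames: np.ndarray  # (4, H, W)
    start_index: int
    seed: SeedChannel | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.shape[0] != 4:
            raise ValueError("a clip holds exactly 4 frames")
        if self.start_index < 0:
            raise ValueError("start_index must be >= 0")


@dataclass
class Track:
    """Per-cell centroid time series with an optional parent link.

    ``states`` is an ordered list of ``(frame, x, y)`` with strictly
    increasing frame indices.
    """

    cell_id: int
    parent_id: int | None = None
    states: list[tuple[int, float, float]] = field(default_factory=list)

    def add_state(self, frame: int, x: float, y: float) -> None:
        if self.states and frame <= self.states[-1][0]:
            raise ValueError(
                f"track {self.cell_id}: frame {frame} not after "
                f"{self.states[-1][0]}"
            )
        self.states.append((int(frame), float(x), float(y)))

    @property
    def first_frame(self) -> int:
        return self.states[0][0]

    @property
    def last_frame(self) -> int:
        return self.states[-1][0]

    def position_at(self, frame: int) -> tuple[float, float] | None:
        for f, x, y in self.states:
            if f == frame:
                return (x, y)
        return None


@dataclass
class DivisionEvent:
    parent_id: int
    frame: int
    child_ids: tuple[int, int]


@dataclass
class LineageTree:
    """A forest of tracks with binary-fission division events."""

    tracks: dict[int, Track] = field(default_factory=dict)
    divisions: list[DivisionEvent] = field(default_factory=list)

    def add_track(self, track: Track) -> None:
        if track.cell_id in self.tracks:
            raise ValueError(f"duplicate cell id {track.cell_id}")
        self.tracks[track.cell_id] = track

    def add_division(self, parent_id: int, frame: int,
                     child_ids: tuple[int, int]) -> None:
        if len(child_ids) != 2:
            raise ValueError("a division produces exactly two children")
        self.divisions.append(DivisionEvent(parent_id, frame, tuple(child_ids)))

    def alive_at(self, frame: int) -> list[int]:
        return [cid for cid, tr in self.tracks.items()
                if tr.states and tr.first_frame <= frame <= tr.last_frame]

    def positions_at(self, frame: int) -> dict[int, tuple[float, float]]:
        out = {}
        for cid in self.alive_at(frame):
            pos = self.tracks[cid].position_at(frame)
            if pos is not None:
                out[cid] = pos
        return out

    def cell_count_per_frame(self, n_frames: int) -> np.ndarray:
        counts = np.zeros(n_frames, dtype=int)
        for tr in self.tracks.values():
            for f, _, _ in tr.states:
                if f < n_frames:
                    counts[f] += 1
        return counts

    def validate(self) -> None:
        """Check the forest invariants; raise ``ValueError`` on violation."""
        for ev in self.divisions:
            parent = self.tracks.get(ev.parent_id)
            if parent is None:
                raise ValueError(f"division references unknown parent {ev.parent_id}")
            for cid in ev.child_ids:
                child = self.tracks.get(cid)
                if child is None:
                    raise ValueError(f"division references unknown child {cid}")
                if child.parent_id != ev.parent_id:
                    raise ValueError(f"child {cid} does not link parent {ev.parent_id}")
                if parent.last_frame >= child.first_frame:
                    raise ValueError(
                        f"parent {ev.parent_id} outlives child {cid}"
                    )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "tracks": [
                {
                    "cell_id": tr.cell_id,
                    "parent_id": tr.parent_id,
                    "states": [[f, x, y] for f, x, y in tr.states],
                }
                for tr in self.tracks.values()
            ],
            "divisions": [
                {"parent_id": ev.parent_id, "frame": ev.frame,
                 "child_ids": list(ev.child_ids)}
                for ev in self.divisions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LineageTree":
        tree = cls()
        for td in d["tracks"]:
            tr = Track(td["cell_id"], td.get("parent_id"))
            for f, x, y in td["states"]:
                tr.add_state(f, x, y)
            tree.add_track(tr)
        for ed in d.get("divisions", []):
            tree.add_division(ed["parent_id"], ed["frame"], tuple(ed["child_ids"]))
        return tree

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LineageTree":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Seed-channel construction and identity assignment
# ---------------------------------------------------------------------------

def _square_bounds(cx: float, cy: float, side: int,
                   shape: tuple[int, int]) -> tuple[int, int, int, int]:
    """Row/col bounds of a side x side square centred at (cx, cy), clipped."""
    h, w = shape
    r0 = int(round(cy)) - side // 2
    c0 = int(round(cx)) - side // 2
    return (max(r0, 0), min(r0 + side, h), max(c0, 0), min(c0 + side, w))


def make_seed_channel(cells, shape, side_px: int = DEFAULT_SEED_SIDE,
                      palette=None) -> SeedChannel:
    """Render the seed channel for a set of cells.

    Parameters
    ----------
    cells
        Iterable of ``(identity, (x, y))`` pairs with distinct identities and
        in-bounds centroids.
    shape
        ``(H, W)`` of the output image.
    side_px
        Side of each identity square.
    palette
        Optional override of the intensity palette; rank ``k`` in ascending
        identity order receives ``palette[k]``.  The default palette is
        ``(255, 125, 60, 30)`` continued by halving.

    Lower-rank (higher-intensity) squares win where squares overlap, which
    makes rendering deterministic and the overlap tie-break well defined.
    """
    cells = list(cells)
    if palette is None:
        palette = DEFAULT_SEED_PALETTE
    ids = [c[0] for c in cells]
    if len(set(ids)) != len(ids):
        raise ValueError("cell identities must be distinct")
    if len(cells) > len(palette):
        raise ValueError(
            f"{len(cells)} cells exceed the {len(palette)}-entry seed "
            "palette; pass a longer `palette` to make_seed_channel "
            "(or extend seedtrack.core.DEFAULT_SEED_PALETTE)"
        )
    h, w = shape
    for identity, (cx, cy) in cells:
        if not (0 <= cx < w and 0 <= cy < h):
            raise ValueError(f"centroid of cell {identity} outside frame")

    image = np.zeros(shape, dtype=np.float32)
    seeds: list[Seed] = []
    # ascending identity -> rank; draw dimmest first so brighter overwrites
    ordered = sorted(cells, key=lambda c: c[0])
    for rank, (identity, (cx, cy)) in enumerate(ordered):
        seeds.append(Seed(identity, float(cx), float(cy), float(palette[rank])))
    for seed in sorted(seeds, key=lambda s: s.intensity):
        r0, r1, c0, c1 = _square_bounds(seed.x, seed.y, side_px, shape)
        image[r0:r1, c0:c1] = seed.intensity
    seeds.sort(key=lambda s: -s.intensity)
    return SeedChannel(image=image, seeds=seeds, side_px=side_px)


def assign_identities_by_overlap(masks, seed: SeedChannel):
    """Assign each binary mask the identity of the seed square it overlaps most.

    Returns a list (one entry per mask) of identities, with ``None`` for
    masks that overlap no seed square ("unseeded"; such cells are ignored
    downstream by design).  Ties break toward the lowest identity.
    """
    shape = seed.image.shape
    footprints = []
    for s in sorted(seed.seeds, key=lambda s: s.identity):
        r0, r1, c0, c1 = _square_bounds(s.x, s.y, seed.side_px, shape)
        footprints.append((s.identity, r0, r1, c0, c1))

    out = []
    for mask in masks:
        mask = np.asarray(mask)
        if mask.shape != shape:
            raise ValueError("mask and seed channel shapes differ")
        best_id, best_ov = None, 0
        # footprints are in rank order (ascending identity), so keeping the
        # first maximum realises the lowest-identity tie-break
        for identity, r0, r1, c0, c1 in footprints:
            ov = int(np.count_nonzero(mask[r0:r1, c0:c1]))
            if ov > best_ov:
                best_id, best_ov = identity, ov
        if best_id is None:
            logger.info("mask with no seed overlap flagged unseeded")
        out.append(best_id)
    return out


# ---------------------------------------------------------------------------
# Clip slicing and normalization
# ---------------------------------------------------------------------------

@dataclass
class LabelScaler:
    """Maps pixel coordinates to [0, 1] (divide by the original frame side)
    and back.  ``denormalize(normalize(p)) == p`` exactly up to float error.
    """

    original_side: int

    def normalize(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) / self.original_side

    def denormalize(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) * self.original_side


def standardize_image(img: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-sd standardization; constant images keep sd = 1."""
    img = np.asarray(img, dtype=np.float32)
    mu = float(img.mean())
    sd = float(img.std())
    if sd == 0.0:
        logger.warning("constant image in normalization; using sd = 1")
        sd = 1.0
    return (img - mu) / sd


def normalize_clip(clip: Clip,
                   target_side: int = DEFAULT_TRACKER_INPUT_SIDE):
    """Resize and standardize a (seeded) clip for the tracker.

    Each frame is resized to ``target_side`` squared (bilinear) and
    standardized to mean 0, sd 1; the seed channel, when present, is resized
    with nearest-neighbour interpolation (preserving the exact palette
    intensities) and prepended as the first temporal slice.

    Returns ``(tensor, scaler)`` where ``tensor`` has shape
    ``(T, side, side)`` with ``T = 5`` for a seeded clip and ``T = 4``
    otherwise, and ``scaler`` converts centroid labels to/from [0, 1].
    """
    h, w = clip.frames.shape[1:]
    if h != w:
        raise ValueError("normalize_clip expects square frames")
    slices = []
    if clip.seed is not None:
        seed_img = resize(clip.seed.image, (target_side, target_side),
                          order=0, preserve_range=True,
                          anti_aliasing=False).astype(np.float32)
        slices.append(standardize_image(seed_img))
    for frame in clip.frames:
        fr = resize(frame, (target_side, target_side), order=1,
                    preserve_range=True, anti_aliasing=True).astype(np.float32)
        slices.append(standardize_image(fr))
    return np.stack(slices, axis=0), LabelScaler(original_side=w)


def slice_clips(movie: Movie, start: int = 0):
    """Yield ``(frame_indices, frames)`` for consecutive non-overlapping
    4-frame clips starting at ``start``.  A final partial clip is padded by
    repeating the last frame; ``frame_indices`` then contains duplicates
    whose outputs the caller should discard.
    """
    t = movie.n_frames
    pos = start
    while pos < t:
        idx = [min(pos + i, t - 1) for i in range(4)]
        yield idx, movie.fluor[idx]
        pos += 4


# ---------------------------------------------------------------------------
# I/O: TIFF movies, CSV tracks, JSON lineage, CTC-style track file
# ---------------------------------------------------------------------------

def write_movie(path, movie: Movie) -> None:
    """Write a movie as a multi-page TIFF, channel order fluorescent then
    bright-field within each frame."""
    pages = np.empty((movie.n_frames * 2,) + movie.frame_shape, dtype=np.float32)
    pages[0::2] = movie.fluor
    pages[1::2] = movie.bright
    tifffile.imwrite(path, pages)


def read_movie(path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
               frame_interval: float = 60.0) -> Movie:
    pages = tifffile.imread(path)
    if pages.ndim != 3 or pages.shape[0] % 2:
        raise ValueError("expected an even number of single-channel pages")
    return Movie(fluor=pages[0::2], bright=pages[1::2],
                 pixel_size_um=pixel_size_um, frame_interval=frame_interval)


def write_mask_stack(path, masks: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(masks, dtype=np.uint16))


def read_mask_stack(path) -> np.ndarray:
    return tifffile.imread(path)


def tracks_to_frame(tree: LineageTree) -> pd.DataFrame:
    """Flatten a lineage tree to a frame,cell_id,parent_id,x,y table."""
    rows = []
    for tr in tree.tracks.values():
        parent = -1 if tr.parent_id is None else tr.parent_id
        for f, x, y in tr.states:
            rows.append((f, tr.cell_id, parent, x, y))
    df = pd.DataFrame(rows, columns=["frame", "cell_id", "parent_id", "x", "y"])
    return df.sort_values(["frame", "cell_id"]).reset_index(drop=True)


def write_tracks_csv(path, tree: LineageTree) -> None:
    tracks_to_frame(tree).to_csv(path, index=False)


def write_ctc_tracks(path, tree: LineageTree) -> None:
    """Write the text track format ``label begin end parent`` (0 = no parent)."""
    lines = []
    for tr in sorted(tree.tracks.values(), key=lambda t: t.cell_id):
        parent = 0 if tr.parent_id is None else tr.parent_id
        lines.append(f"{tr.cell_id} {tr.first_frame} {tr.last_frame} {parent}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
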