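"""Pipeline orchestration: the clip loop.

A movie is processed in non-overlapping 4-frame clips.  For each clip the
tracker proposes per-frame centroids for every seeded cell; each centroid
is then refined by seeded patch segmentation (segment, recentre the patch,
segment once more), the refined centroid is recorded as the track position
and seeds the next frame; the segmented patch is checked for mitosis.
When a division is confirmed the parent track is closed, two daughters are
opened, and the next clip starts at the division frame.  The seed channel
for each new clip is built from the refined centroids of the last frame of
the previous clip — segmentation correcting tracking throughout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    Clip, DEFAULT_SEED_SIDE, LineageTree, Movie, Track, make_seed_channel,
)
from .division import (
    DivisionParams, apply_division, daughter_centroids,
    detect_post_division, detect_pre_division,
)
from .segmentation import (
    PATCH_SIDE, extract_patch, make_patch_seed, paste_patch,
    refine_centroid, segment_patch_ensemble,
)
from .tracker import TrackerNet, track_clip

logger = logging.getLogger("seedtrack")

__all__ = ["PipelineConfig", "PipelineState", "PipelineResult",
           "run_pipeline", "render_overlay"]


@dataclass
class PipelineConfig:
    """Execution options of the clip loop."""

    clip_length: int = 4            # architectural constant
    patch_side: int = PATCH_SIDE
    seed_side: int = DEFAULT_SEED_SIDE
    tracker_mode: str = "general"   # "general" | "dedicated"
    #: masks produced by the (reduced-resolution) ensemble round off the
    #: cleavage furrow, so the clip loop uses a more sensitive defect
    #: threshold than the detector-level default; the pre/post fusion rule
    #: plus the daughter-plausibility gates absorb the extra sensitivity
    division: DivisionParams = field(
        default_factory=lambda: DivisionParams(depth_frac=0.12))
    #: daughters must sit closer together than this (px); unrelated
    #: neighbouring cells keep a larger separation
    max_daughter_separation: float = 48.0
    #: each daughter's equivalent radius must be below this fraction of
    #: the parent's pre-division radius
    max_daughter_radius_frac: float = 0.9
    max_restarts_per_frame: int = 4

    def __post_init__(self) -> None:
        if self.clip_length != 4:
            raise ValueError("the clip length is fixed at 4 frames")
        if self.tracker_mode not in ("general", "dedicated"):
            raise ValueError("tracker_mode must be 'general' or 'dedicated'")


@dataclass
class PipelineState:
    """Mutable state shared across the clip loop and division handling."""

    tree: LineageTree
    positions: dict[int, tuple[float, float]]  # current refined centroid
    next_id: int
    log: list[dict] = field(default_factory=list)


@dataclass
class PipelineResult:
    tree: LineageTree
    labels: np.ndarray            # (T, H, W) uint16 instance masks
    log: list[dict]

    def write(self, out_dir) -> None:
        import pathlib

        from .core import (write_ctc_tracks, write_mask_stack,
                           write_tracks_csv)
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.tree.to_json(out / "lineage.json")
        write_tracks_csv(out / "tracks.csv", self.tree)
        write_ctc_tracks(out / "tracks_ctc.txt", self.tree)
        write_mask_stack(out / "masks.tif", self.labels)
        with open(out / "run_log.jsonl", "w") as fh:
            for entry in self.log:
                fh.write(json.dumps(entry) + "\n")


def _segment_cell(movie, frame, centroid, prev_centroid, segmentor, refiner,
                  cfg):
    """Seeded two-pass segmentation of one cell in one frame.

    Returns ``(mask96, offset, refined_centroid, aux)``; the mask may be
    empty when segmentation fails (the caller falls back to the tracker
    centroid).
    """
    stack = np.stack([movie.fluor[frame], movie.bright[frame],
                      np.zeros_like(movie.fluor[frame])], axis=-1)

    def one_pass(center):
        patch, offset = extract_patch(stack, center, cfg.patch_side)
        patch[..., 2] = make_patch_seed(
            (prev_centroid[0] - offset[0], prev_centroid[1] - offset[1]),
            cfg.patch_side, cfg.seed_side)
        mask, aux = segment_patch_ensemble(segmentor, refiner, patch)
        return patch, offset, mask, aux

    _, offset, mask, aux = one_pass(centroid)
    if not mask.any():
        return mask, offset, None, aux
    refined = refine_centroid(mask, offset)
    # reposition the patch at the refined centroid and segment once more
    h, w = movie.frame_shape
    refined = (float(np.clip(refined[0], 0, w - 1)),
               float(np.clip(refined[1], 0, h - 1)))
    _, offset2, mask2, aux2 = one_pass(refined)
    if mask2.any():
        return mask2, offset2, refine_centroid(mask2, offset2), aux2
    return mask, offset, refined, aux


def run_pipeline(movie: Movie, initial_seeds, cfg: PipelineConfig,
                 tracker: TrackerNet | None = None,
                 trackers: dict[int, TrackerNet] | None = None,
                 segmentor=None, refiner=None) -> PipelineResult:
    """Track and segment a movie from frame-0 seeds.

    ``initial_seeds``: list of ``(cell_id, (x, y))`` frame-0 centroids
    (user-supplied, or from blob detection on frame 0 — see
    :func:`detect_initial_seeds`).  In ``general`` mode, ``tracker`` is the
    single-cell general model and one pass is run per cell; in
    ``dedicated`` mode, ``trackers[N]`` provides the N-cell model and the
    pipeline switches N -> N+1 at divisions.
    """
    if movie.n_frames == 0:
        raise ValueError("empty movie")
    if not initial_seeds:
        raise ValueError("no initial seeds supplied")
    if segmentor is None or refiner is None:
        raise ValueError("trained Segmentor and Refiner are required")

    n_frames = movie.n_frames
    h, w = movie.frame_shape
    tree = LineageTree()
    state = PipelineState(tree=tree, positions={}, next_id=1)
    for cid, (x, y) in initial_seeds:
        tree.add_track(Track(cid))
        state.positions[cid] = (float(x), float(y))
        state.next_id = max(state.next_id, cid + 1)

    labels = np.zeros((n_frames, h, w), dtype=np.uint16)
    seed_overlap = np.zeros((n_frames, h, w), dtype=np.int32)
    pending_pre: dict[int, tuple[int, float]] = {}  # cell -> (frame, eqr)
    restarts: dict[int, int] = {}

    def get_tracker(n: int) -> TrackerNet:
        if cfg.tracker_mode == "general":
            if tracker is None:
                raise ValueError("general mode needs the general tracker")
            return tracker
        if trackers is None or n not in trackers:
            raise ValueError(
                f"no dedicated Tracker-{n} available; supply it or run in "
                "general mode")
        return trackers[n]

    clip_start = 0
    while clip_start < n_frames:
        idx = [min(clip_start + i, n_frames - 1) for i in range(4)]
        frames = movie.fluor[idx]
        active = sorted(state.positions)
        # --- tracking
        predicted: dict[int, np.ndarray] = {}
        if cfg.tracker_mode == "general":
            net = get_tracker(1)
            for cid in active:
                seed = make_seed_channel([(0, state.positions[cid])],
                                         (h, w), side_px=cfg.seed_side,
                                         palette=(255,))
                clip = Clip(frames=frames, start_index=clip_start, seed=seed)
                predicted[cid] = track_clip(net, clip)[:, 0, :]
        else:
            net = get_tracker(len(active))
            seed = make_seed_channel(
                [(cid, state.positions[cid]) for cid in active],
                (h, w), side_px=cfg.seed_side)
            clip = Clip(frames=frames, start_index=clip_start, seed=seed)
            pred = track_clip(net, clip)  # (4, N, 2), rank order
            for rank, cid in enumerate(active):
                predicted[cid] = pred[:, rank, :]

        # --- per-frame segmentation, refinement, division checks
        division = None  # (frame, parent_id, daughters)
        done = set()
        for t_local, frame in enumerate(idx):
            if frame in done:
                continue
            done.add(frame)
            prev_positions = dict(state.positions)
            for cid in active:
                c_track = tuple(np.clip(predicted[cid][t_local],
                                        (0, 0), (w - 1, h - 1)))
                prev_c = prev_positions[cid]
                mask, offset, refined, aux = _segment_cell(
                    movie, frame, c_track, prev_c, segmentor, refiner, cfg)
                if refined is None:
                    state.log.append({"frame": frame, "cell": cid,
                                      "event": "empty-mask-fallback"})
                    refined = (float(c_track[0]), float(c_track[1]))
                    mask = None
                state.tree.tracks[cid].add_state(frame, *refined)
                state.positions[cid] = refined
                if mask is not None:
                    _paste_mask(labels[frame], seed_overlap[frame], mask,
                                offset, cid, prev_c, cfg)
                    # division checks on the segmented patch; the coarse
                    # ensemble mask rounds off the cleavage furrow, so the
                    # full-resolution intensity component under the cell is
                    # consulted as well
                    pre = detect_pre_division(mask, cfg.division)
                    ref_mask = mask
                    if not pre:
                        comp = _intensity_component(movie, frame, refined,
                                                    cfg)
                        if comp is not None and \
                                detect_pre_division(comp, cfg.division):
                            pre = True
                            ref_mask = comp
                    if pre:
                        eqr = float(np.sqrt(ref_mask.sum() / np.pi))
                        pending_pre[cid] = (frame, eqr)
                        state.log.append({"frame": frame, "cell": cid,
                                          "event": "pre-division"})
                    if (cid in pending_pre and division is None
                            and frame - pending_pre[cid][0]
                            <= cfg.division.confirm_window
                            and frame > pending_pre[cid][0]):
                        split = _post_division_split(
                            movie, frame, refined, aux, cfg,
                            parent_eqr=pending_pre[cid][1])
                        if split is not None:
                            division = (frame, cid, split)
            if division is not None:
                break

        if division is not None:
            frame, parent_id, daughters = division
            key = (frame)
            restarts[key] = restarts.get(key, 0) + 1
            if restarts[key] > cfg.max_restarts_per_frame:
                logger.warning("too many restarts at frame %d; continuing",
                               frame)
                division = None
            else:
                state.log.append({"frame": frame, "cell": parent_id,
                                  "event": "division",
                                  "daughters": [list(d) for d in daughters]})
                # wipe results from the division frame on; they are
                # recomputed by the restarted clip
                for tr in state.tree.tracks.values():
                    tr.states = [s for s in tr.states if s[0] < frame]
                labels[frame:] = 0
                seed_overlap[frame:] = 0
                apply_division(state, frame, parent_id, daughters)
                for cid in list(state.positions):
                    if cid not in state.tree.tracks:
                        continue
                    tr = state.tree.tracks[cid]
                    if tr.states:
                        state.positions[cid] = (tr.states[-1][1],
                                                tr.states[-1][2])
                pending_pre.pop(parent_id, None)
                if cfg.tracker_mode == "dedicated":
                    get_tracker(len(state.positions))  # fail fast if absent
                clip_start = frame
                continue
        clip_start += 4

    tree.validate()
    return PipelineResult(tree=tree, labels=labels, log=state.log)


def _paste_mask(label_frame, overlap_frame, mask, offset, cid, seed_centroid,
                cfg) -> None:
    """Paste a cell mask into the frame label image.

    Where two cells' refined masks overlap, pixels go to the cell whose
    seed square overlap is larger (no silent overwrite by paste order).
    """
    side = mask.shape[0]
    h, w = label_frame.shape
    c0, r0 = offset
    rs, re = max(r0, 0), min(r0 + side, h)
    cs, ce = max(c0, 0), min(c0 + side, w)
    sub = mask[rs - r0:re - r0, cs - c0:ce - c0]
    # seed-square overlap score for the incoming cell, per pixel constant
    half = cfg.seed_side // 2
    sx, sy = seed_centroid
    ov_rows = np.arange(rs, re)
    ov_cols = np.arange(cs, ce)
    in_seed = ((np.abs(ov_rows[:, None] - sy) <= half)
               & (np.abs(ov_cols[None, :] - sx) <= half)).astype(np.int32)
    score = 1 + in_seed  # inside own seed square beats outside
    target_l = label_frame[rs:re, cs:ce]
    target_o = overlap_frame[rs:re, cs:ce]
    take = sub & (score > target_o)
    target_l[take] = cid
    target_o[take] = score[take]


def _post_division_split(movie, frame, centroid, aux, cfg,
                         parent_eqr: float | None = None):
    """Confirm a post-division configuration near ``centroid``.

    First the ensemble's thresholded union is checked for two round twin
    components; failing that, a light intensity threshold of the
    fluorescent patch provides candidate components (robustness fallback
    for ensembles that segment only one daughter).  Candidate pairs must
    also be *plausible daughters*: close together and each smaller than
    the parent.  Returns the two daughter centroids in frame coordinates,
    or None.
    """
    candidates = []
    if aux is not None:
        candidates.append(aux["binary_union"])
    fg, offset = _intensity_patch_foreground(movie, frame, centroid, cfg)
    candidates.append(fg)
    for cand in candidates:
        cand = _components_near(cand, cfg.patch_side // 2, cfg.patch_side // 2,
                                radius=cfg.patch_side / 2)
        if not detect_post_division(cand, cfg.division):
            continue
        pts = daughter_centroids(cand)
        if len(pts) != 2:
            continue
        (x1, y1), (x2, y2) = pts
        if np.hypot(x1 - x2, y1 - y2) > cfg.max_daughter_separation:
            continue
        if parent_eqr is not None:
            lab, n = ndimage.label(cand)
            radii = [np.sqrt((lab == i).sum() / np.pi)
                     for i in range(1, n + 1)
                     if (lab == i).sum() >= cfg.division.min_component_px]
            if max(radii) > cfg.max_daughter_radius_frac * parent_eqr:
                continue
        return [(x + offset[0], y + offset[1]) for x, y in pts]
    return None


def _intensity_patch_foreground(movie, frame, centroid, cfg):
    """Light intensity segmentation of the fluorescent patch (threshold
    midway between the peak and the median, then binary opening)."""
    patch, offset = extract_patch(movie.fluor[frame][..., None], centroid,
                                  cfg.patch_side)
    patch = patch[..., 0]
    fg = patch > 0.5 * (patch.max() + np.median(patch))
    return ndimage.binary_opening(fg, iterations=2), offset


def _intensity_component(movie, frame, centroid, cfg):
    """The intensity-foreground component under the patch centre (None if
    the centre lies on background)."""
    fg, _ = _intensity_patch_foreground(movie, frame, centroid, cfg)
    lab, n = ndimage.label(fg)
    if n == 0:
        return None
    centre_label = lab[cfg.patch_side // 2, cfg.patch_side // 2]
    if centre_label == 0:
        # fall back to the component nearest the centre
        best, best_d = None, np.inf
        for i in range(1, n + 1):
            comp = lab == i
            if comp.sum() < cfg.division.min_component_px:
                continue
            cy, cx = ndimage.center_of_mass(comp)
            d = np.hypot(cx - cfg.patch_side / 2, cy - cfg.patch_side / 2)
            if d < best_d:
                best, best_d = comp, d
        return best if best_d < cfg.patch_side / 4 else None
    return lab == centre_label


def _components_near(binary, cx, cy, radius):
    """Keep only components whose centroid lies within ``radius`` of
    (cx, cy) in patch coordinates."""
    lab, n = ndimage.label(binary)
    keep = np.zeros_like(binary, dtype=bool)
    for i in range(1, n + 1):
        comp = lab == i
        yy, xx = ndimage.center_of_mass(comp)
        if np.hypot(xx - cx, yy - cy) <= radius:
            keep |= comp
    return keep


def detect_initial_seeds(movie: Movie, expected_radius: float = 20.0):
    """Frame-0 seeding by bright-blob detection on the fluorescent channel
    (used when no user seeds are given; flagged in the run log)."""
    frame = movie.fluor[0]
    thr = 0.5 * (frame.max() + np.median(frame))
    fg = ndimage.binary_opening(frame > thr, iterations=2)
    lab, n = ndimage.label(fg)
    seeds = []
    next_id = 1
    for i in range(1, n + 1):
        comp = lab == i
        if comp.sum() < 0.3 * np.pi * expected_radius ** 2:
            continue
        cy, cx = ndimage.center_of_mass(comp)
        seeds.append((next_id, (float(cx), float(cy))))
        next_id += 1
    return seeds


# ---------------------------------------------------------------------------
# Overlay rendering
# ---------------------------------------------------------------------------

_COLORS = np.array([
    [230, 60, 60], [60, 140, 230], [70, 200, 90], [230, 180, 50],
    [180, 90, 220], [80, 210, 210], [240, 120, 180], [160, 160, 80],
], dtype=np.uint8)


def _color(cid: int) -> np.ndarray:
    return _COLORS[(cid - 1) % len(_COLORS)]


def render_overlay(movie: Movie, result: PipelineResult,
                   panel_width: int = 96) -> np.ndarray:
    """RGB overlay movie: per-cell contours and centroid markers in stable
    per-identity colors, with the lineage tree drawn in a side panel
    (time running down, branches at divisions)."""
    t, h, w = result.labels.shape
    lo, hi = float(movie.fluor.min()), float(movie.fluor.max())
    scale = 255.0 / (hi - lo) if hi > lo else 1.0
    out = np.zeros((t, h, w + panel_width, 3), dtype=np.uint8)
    panel = _lineage_panel(result.tree, t, h, panel_width)
    for f in range(t):
        gray = ((movie.fluor[f] - lo) * scale).astype(np.uint8)
        rgb = np.stack([gray] * 3, axis=-1)
        lab = result.labels[f]
        for cid in np.unique(lab):
            if cid == 0:
                continue
            mask = lab == cid
            boundary = mask & ~ndimage.binary_erosion(mask)
            rgb[boundary] = _color(int(cid))
            pos = result.tree.tracks[int(cid)].position_at(f)
            if pos is not None:
                x, y = int(round(pos[0])), int(round(pos[1]))
                rgb[max(y - 2, 0):y + 3, max(x - 2, 0):x + 3] = \
                    _color(int(cid))
        out[f, :, :w] = rgb
        out[f, :, w:] = panel
        # time cursor on the panel
        row = int((f / max(t - 1, 1)) * (h - 1))
        out[f, row, w:] = 255 - out[f, row, w:] // 2
    return out


def _lineage_panel(tree: LineageTree, n_frames: int, height: int,
                   width: int) -> np.ndarray:
    from skimage.draw import line as draw_line

    panel = np.full((height, width, 3), 20, dtype=np.uint8)
    roots = [tr for tr in tree.tracks.values() if tr.parent_id is None]
    # assign a horizontal slot to each track by leaf ordering
    xs: dict[int, int] = {}

    def leaves_under(cid):
        kids = [ev.child_ids for ev in tree.divisions if ev.parent_id == cid]
        if not kids:
            return [cid]
        out = []
        for pair in kids:
            for c in pair:
                out.extend(leaves_under(c))
        return out

    all_leaves = []
    for root in sorted(roots, key=lambda tr: tr.cell_id):
        all_leaves.extend(leaves_under(root.cell_id))
    for i, leaf in enumerate(all_leaves):
        xs[leaf] = int((i + 1) * width / (len(all_leaves) + 1))

    def slot(cid):
        if cid in xs:
            return xs[cid]
        kids = [c for ev in tree.divisions if ev.parent_id == cid
                for c in ev.child_ids]
        vals = [slot(c) for c in kids]
        xs[cid] = int(np.mean(vals)) if vals else width // 2
        return xs[cid]

    def row_of(frame):
        return int((frame / max(n_frames - 1, 1)) * (height - 1))

    for tr in tree.tracks.values():
        if not tr.states:
            continue
        x = slot(tr.cell_id)
        r0, r1 = row_of(tr.first_frame), row_of(tr.last_frame)
        rr, cc = draw_line(r0, x, r1, x)
        panel[rr, cc] = _color(tr.cell_id)
    for ev in tree.divisions:
        r = row_of(ev.frame)
        for child in ev.child_ids:
            rr, cc = draw_line(r, slot(ev.parent_id), r, slot(child))
            panel[rr, cc] = _color(ev.parent_id)
    return panel
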