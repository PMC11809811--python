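"""Mitosis detection from segmented patches using classical geometry.

Lymphocyte divisions are stereotyped: the parent first adopts a bilobed
"figure-eight" contour, then splits into two round daughters of nearly
equal radius.  The detector therefore has two independent branches:

* a **pre-division** detector that looks for exactly two deep convexity
  defects on roughly opposite sides of a single-component contour, and
* a **post-division** detector that accepts exactly two components with
  similar equivalent radii and high circularity.

The pipeline confirms a division only when post-division evidence follows
pre-division evidence within a short frame window, which suppresses false
triggers on transiently bilobed cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

__all__ = [
    "DivisionParams", "ConvexityDefect", "ShapeDescriptor",
    "describe_shape", "detect_pre_division", "detect_post_division",
    "apply_division",
]


@dataclass
class DivisionParams:
    """Thresholds of the two detector branches (tuned on synthetic shape
    banks; all exposed in config)."""

    depth_frac: float = 0.2          # defect depth / equivalent radius
    min_angle_deg: float = 120.0     # angular separation of the two defects
    radius_tol: float = 1.25         # max daughter radius ratio
    min_circularity: float = 0.8     # per-daughter circularity floor
    min_component_px: int = 9        # ignore specks below this area
    confirm_window: int = 3          # frames from pre- to post- evidence


@dataclass
class ConvexityDefect:
    depth: float                     # px, distance from contour to hull edge
    point: tuple[float, float]       # (x, y) of the deepest contour point
    angle: float                     # direction from the shape centroid, rad


@dataclass
class ShapeDescriptor:
    area: float
    perimeter: float
    circularity: float
    equivalent_radius: float
    centroid: tuple[float, float]
    defects: list[ConvexityDefect] = field(default_factory=list)


def _longest_contour(mask: np.ndarray) -> np.ndarray:
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no contour")
    return max(contours, key=len)


def _convexity_defects(contour_xy: np.ndarray,
                       centroid: tuple[float, float]
                       ) -> list[ConvexityDefect]:
    """Deepest contour point between each pair of consecutive hull
    vertices, with its distance to the hull edge."""
    if len(contour_xy) < 4:
        return []
    try:
        hull = ConvexHull(contour_xy)
    except QhullError:
        return []
    hv = np.sort(hull.vertices)
    defects = []
    n = len(contour_xy)
    for a, b in zip(hv, np.roll(hv, -1)):
        if a < b:
            between = np.arange(a + 1, b)
        else:  # wrap around the closed contour
            between = np.concatenate([np.arange(a + 1, n), np.arange(0, b)])
        if between.size == 0:
            continue
        p0, p1 = contour_xy[a], contour_xy[b % n]
        edge = p1 - p0
        norm = np.hypot(*edge)
        if norm == 0:
            continue
        pts = contour_xy[between]
        rel = pts - p0
        dists = np.abs(edge[0] * rel[:, 1] - edge[1] * rel[:, 0]) / norm
        k = int(np.argmax(dists))
        depth = float(dists[k])
        if depth <= 0.5:  # discretization noise
            continue
        px, py = pts[k]
        defects.append(ConvexityDefect(
            depth=depth, point=(float(px), float(py)),
            angle=math.atan2(py - centroid[1], px - centroid[0])))
    defects.sort(key=lambda d: -d.depth)
    return defects


def describe_shape(mask: np.ndarray) -> ShapeDescriptor:
    """Geometric descriptor of a single-component binary mask."""
    mask = np.asarray(mask).astype(bool)
    lab, n = ndimage.label(mask)
    if n != 1:
        raise ValueError(f"expected exactly one component, found {n}")
    props = measure.regionprops(lab.astype(int))[0]
    area = float(props.area)
    perimeter = float(max(props.perimeter, 1.0))
    circularity = 4.0 * math.pi * area / perimeter ** 2
    cy, cx = props.centroid
    contour = _longest_contour(mask)[:, ::-1]  # (row, col) -> (x, y)
    defects = _convexity_defects(contour, (cx, cy))
    return ShapeDescriptor(
        area=area, perimeter=perimeter, circularity=circularity,
        equivalent_radius=math.sqrt(area / math.pi),
        centroid=(float(cx), float(cy)), defects=defects)


def detect_pre_division(mask: np.ndarray,
                        params: DivisionParams | None = None) -> bool:
    """True iff the mask is a figure-eight: exactly two convexity defects
    deeper than ``depth_frac x equivalent radius``, lying on roughly
    opposite sides of the contour."""
    params = params or DivisionParams()
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return False
    lab, n = ndimage.label(mask)
    if n != 1:
        return False
    desc = describe_shape(mask)
    threshold = params.depth_frac * desc.equivalent_radius
    deep = [d for d in desc.defects if d.depth > threshold]
    if len(deep) != 2:
        return False
    sep = abs(deep[0].angle - deep[1].angle) % (2 * math.pi)
    sep = min(sep, 2 * math.pi - sep)
    return sep > math.radians(params.min_angle_deg)


def detect_post_division(masks: np.ndarray,
                         params: DivisionParams | None = None) -> bool:
    """True iff the patch holds exactly two round components of nearly
    equal radius (twin daughters).

    ``masks`` may be a binary image (components are labelled internally)
    or an integer label image.
    """
    params = params or DivisionParams()
    arr = np.asarray(masks)
    if arr.dtype == bool or set(np.unique(arr)) <= {0, 1}:
        lab, n = ndimage.label(arr.astype(bool))
    else:
        lab, n = arr.astype(int), int(arr.max())
    comps = [lab == i for i in range(1, n + 1)
             if (lab == i).sum() >= params.min_component_px]
    if len(comps) != 2:
        return False
    descs = [describe_shape(c) for c in comps]
    r1, r2 = sorted(d.equivalent_radius for d in descs)
    if r2 / max(r1, 1e-9) > params.radius_tol:
        return False
    return all(d.circularity >= params.min_circularity for d in descs)


def daughter_centroids(masks: np.ndarray, min_px: int = 9):
    """Centroids (x, y) of the two largest components of a patch mask."""
    arr = np.asarray(masks)
    lab, n = ndimage.label(arr.astype(bool))
    sizes = ndimage.sum_labels(np.ones_like(lab), lab,
                               index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1][:2]
    out = []
    for i in order:
        if sizes[i] < min_px:
            continue
        cy, cx = ndimage.center_of_mass(lab == i + 1)
        out.append((float(cx), float(cy)))
    return out


def apply_division(state, frame: int, parent_id: int, daughters):
    """Replace a confirmed-divided parent by two daughter tracks.

    ``state`` is the pipeline's mutable state (see
    :class:`seedtrack.pipeline.PipelineState`).  The parent track is closed
    at ``frame - 1`` (its pre-division, figure-eight frames keep the parent
    identity — no retroactive relabeling), two child tracks are opened at
    ``frame`` with fresh identities seeded at the daughter centroids, and
    the caller switches tracker (dedicated N -> N+1, or one more
    general-tracker pass).  Returns ``(child_id_1, child_id_2)``.
    """
    from .core import Track

    if len(daughters) != 2:
        raise ValueError("a division needs exactly two daughter centroids")
    parent = state.tree.tracks[parent_id]
    parent.states = [s for s in parent.states if s[0] < frame]
    child_ids = []
    for cx, cy in daughters:
        cid = state.next_id
        state.next_id += 1
        state.tree.add_track(Track(cid, parent_id=parent_id))
        state.positions[cid] = (cx, cy)
        child_ids.append(cid)
    del state.positions[parent_id]
    state.tree.add_division(parent_id, frame, tuple(child_ids))
    return tuple(child_ids)
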