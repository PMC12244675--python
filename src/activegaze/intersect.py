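"""Classifying gaze rays against the arena.

Each fixation's world-frame gaze ray (origin = mean head position, a
cyclopean eye at the head-marker origin; direction = eye-in-world) is cast
against the axis-aligned tables and cages.  The nearest hit names the
look-at target; rays that miss everything are "environment" fixations.

A hit on a covered face still counts as looking AT that box — the subject
sees its surface.  Whether a target INSIDE a box can be seen is the
separate visibility operation, where covered faces and table volumes are
opaque while wire and open faces are transparent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import normalize
from .scene import Box, FaceCover, Layout, ObjectPlacement

__all__ = [
    "RayHit",
    "VisitSequence",
    "ENVIRONMENT",
    "ray_box_hits",
    "first_hit",
    "classify_fixation",
    "classify_ray",
    "visibility_from_start",
    "count_revisits",
]

ENVIRONMENT = "environment"

#: head-marker origin sits above the eyes; visibility checks lower the
#: eye point by this much (m) relative to the marker.
EYE_BELOW_MARKER = 0.10


@dataclass(frozen=True)
class RayHit:
    """One ray/box intersection; ``t`` is the ray parameter in meters."""

    box_id: str
    t: float
    face: str | None
    face_cover: FaceCover


@dataclass(frozen=True)
class VisitSequence:
    """Environment-free, duplicate-collapsed look-at sequence."""

    labels: tuple[str, ...]
    revisit_count: int
    unique_revisited: int


def _slab(origin: np.ndarray, direction: np.ndarray, box: Box):
    """Entry/exit parameters and entry face for one AABB, or None."""
    t0, t1 = -np.inf, np.inf
    entry_axis, entry_sign = None, 0.0
    for a in range(3):
        o, d = origin[a], direction[a]
        lo, hi = box.lo[a], box.hi[a]
        if abs(d) < 1e-15:
            if not (lo <= o <= hi):
                return None
            continue
        ta, tb = (lo - o) / d, (hi - o) / d
        sign = -1.0 if d > 0 else 1.0  # entering through low face if moving +
        if ta > tb:
            ta, tb = tb, ta
        if ta > t0:
            t0, entry_axis, entry_sign = ta, a, sign
        t1 = min(t1, tb)
        if t0 > t1:
            return None
    if t1 < 0.0:
        return None
    if entry_axis is None:
        # degenerate: ray parallel to all slabs it is inside of
        return 0.0, t1, None
    if t0 < 0.0:
        # origin inside the box: report entry at t = 0 with no face
        return 0.0, t1, None
    face = f"{'+' if entry_sign > 0 else '-'}{'xyz'[entry_axis]}"
    return t0, t1, face


def ray_box_hits(origin: np.ndarray, direction: np.ndarray, layout: Layout) -> list[RayHit]:
    """All boxes crossed by the ray, sorted by distance.

    The slab method is applied per box; the entry face is the slab that
    produced the largest entry parameter.  An origin inside a box yields a
    hit at t = 0 with no face.
    """
    origin = np.asarray(origin, dtype=float)
    direction = normalize(np.asarray(direction, dtype=float))
    hits = []
    for box in layout.boxes:
        res = _slab(origin, direction, box)
        if res is None:
            continue
        t0, _t1, face = res
        cover = box.faces[face] if face is not None else FaceCover.OPEN
        hits.append(RayHit(box_id=box.id, t=float(t0), face=face, face_cover=cover))
    hits.sort(key=lambda h: h.t)
    return hits


def first_hit(
    origin: np.ndarray,
    direction: np.ndarray,
    layout: Layout,
    count_covered: bool = True,
) -> RayHit | None:
    """Nearest hit, optionally skipping boxes entered through covered faces."""
    for hit in ray_box_hits(origin, direction, layout):
        if count_covered or hit.face_cover is not FaceCover.COVERED:
            return hit
    return None


def classify_ray(
    origin: np.ndarray,
    direction: np.ndarray,
    layout: Layout,
    count_covered: bool = True,
) -> str:
    hit = first_hit(origin, direction, layout, count_covered=count_covered)
    return hit.box_id if hit is not None else ENVIRONMENT


def classify_fixation(fix, layout: Layout, count_covered: bool = True) -> str:
    """Look-at label of a fixation: nearest box on its world gaze ray.

    ``count_covered=False`` switches to the alternative reading in which a
    box first met through a covered face is skipped in favour of what lies
    beyond it.
    """
    from .geometry import eye_in_world

    direction = eye_in_world(fix.mean_head_orientation, fix.mean_eye_in_head)
    return classify_ray(
        np.asarray(fix.mean_head_position, dtype=float),
        direction,
        layout,
        count_covered=count_covered,
    )


def visibility_from_start(
    layout: Layout,
    placement: ObjectPlacement,
    eye_point: np.ndarray,
    eps: float = 1e-9,
) -> bool:
    """Is the placed object visible along the straight sightline?

    True iff the eye->object segment crosses no covered cage face and does
    not pass through a table's solid volume.  Wire and open faces are
    transparent.  The segment's endpoints themselves (the object resting
    just above a surface, the eye next to a face) do not occlude.
    """
    eye = np.asarray(eye_point, dtype=float)
    target = np.asarray(placement.position, dtype=float)
    seg = target - eye
    length = np.linalg.norm(seg)
    if length < 1e-12:
        return True
    direction = seg / length
    for box in layout.boxes:
        res = _slab(eye, direction, box)
        if res is None:
            continue
        t0, t1, face = res
        if t0 > length - eps:        # box lies beyond the object
            continue
        if box.is_table:
            # solid volume: any genuine penetration blocks
            if min(t1, length) - max(t0, 0.0) > eps:
                return False
            continue
        if face is not None and t0 > eps and box.faces[face] is FaceCover.COVERED:
            return False
        if t1 < length - eps:
            # segment exits the cage before reaching the object
            exit_face = _exit_face(eye, direction, box, t1)
            if exit_face is not None and box.faces[exit_face] is FaceCover.COVERED:
                return False
    return True


def _exit_face(origin: np.ndarray, direction: np.ndarray, box: Box, t1: float) -> str | None:
    p = origin + direction * t1
    best, best_d = None, np.inf
    for a in range(3):
        for sign, bound in ((-1.0, box.lo[a]), (1.0, box.hi[a])):
            d = abs(p[a] - bound)
            if d < best_d:
                best_d = d
                best = f"{'+' if sign > 0 else '-'}{'xyz'[a]}"
    return best


def count_revisits(labels) -> VisitSequence:
    """Revisit bookkeeping over one trial's ordered look-at labels.

    Environment fixations are dropped first (they do not end a visit),
    consecutive duplicates are collapsed into single visits, and every
    compressed entry whose label appeared earlier counts as one revisit.
    """
    compressed: list[str] = []
    for lab in labels:
        if lab == ENVIRONMENT or lab is None:
            continue
        if not compressed or compressed[-1] != lab:
            compressed.append(lab)
    seen: set[str] = set()
    revisited: set[str] = set()
    revisit_count = 0
    for lab in compressed:
        if lab in seen:
            revisit_count += 1
            revisited.add(lab)
        seen.add(lab)
    return VisitSequence(
        labels=tuple(compressed),
        revisit_count=revisit_count,
        unique_revisited=len(revisited),
    )
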