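"""Arena geometry for the search environment.

The search space is a 3 x 4 m floor surrounded by curtains, furnished with
3 solid tables and 6 wireframe cages.  Cage faces are individually either
``covered`` (opaque panel), ``wire`` (see-through mesh) or ``open`` (no
panel); every cage has exactly one open face.  Tables are 1.14 x 0.70 m and
0.70 m tall; cages are 0.30 m cubes resting on tables (one stacked pair,
one side-by-side pair, two singles).  The world frame is right-handed and
z-up: x-y span the floor, z is elevation, and the origin sits at an arena
corner.  All boxes are axis-aligned; all lengths are meters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "FaceCover",
    "Box",
    "ObjectPlacement",
    "Layout",
    "FACE_NAMES",
    "CAGE_DIMS",
    "TABLE_DIMS",
    "load_layout",
    "save_layout",
    "builtin_layout",
    "validate_layout",
    "surface_elevation",
    "LayoutError",
]

FACE_NAMES = ("+x", "-x", "+y", "-y", "+z", "-z")

#: exact printed furniture dimensions (m): cages are 30 cm cubes,
#: tables 114 (w) x 70 (d) x 70 (h) cm.
CAGE_DIMS = (0.30, 0.30, 0.30)
TABLE_DIMS = (1.14, 0.70, 0.70)

ORIENTATIONS = ("upright", "front_up", "side_up", "diagonal", "upside_down")

#: object long-axis extent range (m)
EXTENT_RANGE = (0.015, 0.151)


class LayoutError(ValueError):
    """Raised when a layout file violates the documented schema."""


class FaceCover(str, Enum):
    COVERED = "covered"
    WIRE = "wire"
    OPEN = "open"


@dataclass
class Box:
    """An axis-aligned table (T1-T3) or cage (C1-C6)."""

    id: str
    center: np.ndarray
    dims: np.ndarray
    faces: dict[str, FaceCover] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.dims = np.asarray(self.dims, dtype=float)
        if not self.faces:
            # tables are solid: every face behaves as covered
            self.faces = {f: FaceCover.COVERED for f in FACE_NAMES}
        else:
            self.faces = {f: FaceCover(c) for f, c in self.faces.items()}

    @property
    def is_cage(self) -> bool:
        return self.id.startswith("C")

    @property
    def is_table(self) -> bool:
        return self.id.startswith("T")

    @property
    def lo(self) -> np.ndarray:
        return self.center - self.dims / 2.0

    @property
    def hi(self) -> np.ndarray:
        return self.center + self.dims / 2.0

    @property
    def top(self) -> float:
        """Elevation of the top face."""
        return float(self.center[2] + self.dims[2] / 2.0)

    def face_center(self, face: str) -> np.ndarray:
        axis = "xyz".index(face[1])
        sign = 1.0 if face[0] == "+" else -1.0
        c = self.center.copy()
        c[axis] += sign * self.dims[axis] / 2.0
        return c

    def face_normal(self, face: str) -> np.ndarray:
        axis = "xyz".index(face[1])
        n = np.zeros(3)
        n[axis] = 1.0 if face[0] == "+" else -1.0
        return n


@dataclass
class ObjectPlacement:
    """A stimulus object, reduced to a point with a size scalar."""

    object_id: str
    position: np.ndarray
    surface: str
    orientation: str
    extent: float
    is_target: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.orientation not in ORIENTATIONS:
            raise LayoutError(f"unknown orientation {self.orientation!r}")
        if not (EXTENT_RANGE[0] <= self.extent <= EXTENT_RANGE[1]):
            raise LayoutError(
                f"extent {self.extent} outside {EXTENT_RANGE}"
            )


@dataclass
class Layout:
    """A full arena configuration: 3 tables, 6 cages, start corner."""

    id: int
    boxes: list[Box]
    start_location: np.ndarray
    arena_bounds: tuple[float, float] = (3.0, 4.0)

    def __post_init__(self) -> None:
        self.start_location = np.asarray(self.start_location, dtype=float)

    @property
    def tables(self) -> list[Box]:
        return [b for b in self.boxes if b.is_table]

    @property
    def cages(self) -> list[Box]:
        return [b for b in self.boxes if b.is_cage]

    def box(self, box_id: str) -> Box:
        for b in self.boxes:
            if b.id == box_id:
                return b
        raise KeyError(f"no box {box_id!r} in layout {self.id}")

    @property
    def box_ids(self) -> list[str]:
        return [b.id for b in self.boxes]

    def stacked_pairs(self) -> list[tuple[Box, Box]]:
        """Cage pairs sharing an x-y footprint at different elevations."""
        pairs = []
        cages = self.cages
        for i, a in enumerate(cages):
            for b in cages[i + 1:]:
                if (
                    np.allclose(a.center[:2], b.center[:2], atol=1e-9)
                    and abs(a.center[2] - b.center[2]) > 1e-9
                ):
                    pairs.append((a, b) if a.center[2] < b.center[2] else (b, a))
        return pairs

    @property
    def surface_heights(self) -> dict[str, float]:
        heights = {t.id: t.top for t in self.tables}
        heights.update({c.id: c.top for c in self.cages})
        return heights


# ---------------------------------------------------------------------------
# serialization

def _layout_to_dict(layout: Layout) -> dict:
    return {
        "id": layout.id,
        "arena_bounds": list(layout.arena_bounds),
        "start_location": layout.start_location.tolist(),
        "boxes": [
            {
                "id": b.id,
                "center": b.center.tolist(),
                "dims": b.dims.tolist(),
                "faces": {f: c.value for f, c in b.faces.items()},
            }
            for b in layout.boxes
        ],
    }


def _layout_from_dict(data: dict) -> Layout:
    try:
        boxes = [
            Box(
                id=b["id"],
                center=b["center"],
                dims=b["dims"],
                faces=b.get("faces", {}),
            )
            for b in data["boxes"]
        ]
        return Layout(
            id=int(data["id"]),
            boxes=boxes,
            start_location=data["start_location"],
            arena_bounds=tuple(data.get("arena_bounds", (3.0, 4.0))),
        )
    except (KeyError, TypeError) as exc:
        raise LayoutError(f"malformed layout data: {exc}") from exc


def save_layout(layout: Layout, path: str | Path) -> None:
    """Write a layout to the documented JSON schema."""
    Path(path).write_text(json.dumps(_layout_to_dict(layout), indent=2))


def load_layout(path: str | Path) -> Layout:
    """Load and validate a layout from JSON.

    Raises :class:`LayoutError` on parse failure or on any violated
    structural invariant (the message names the rule).
    """
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise LayoutError(f"not valid layout JSON: {exc}") from exc
    layout = _layout_from_dict(data)
    violations = validate_layout(layout)
    if violations:
        raise LayoutError("; ".join(violations))
    return layout


def builtin_layout(layout_id: int) -> Layout:
    """One of the four shipped arena configurations (1-4).

    The shipped files satisfy the structural constraints of the study
    arena (box counts, one stacked pair, one side-by-side pair, start
    corner); exact furniture coordinates are this package's choice.
    """
    ref = resources.files("activegaze.data").joinpath(
        f"layouts/layout{layout_id}.json"
    )
    with resources.as_file(ref) as path:
        return load_layout(path)


# ---------------------------------------------------------------------------
# validation

def validate_layout(layout: Layout) -> list[str]:
    """Return all violated invariants (empty list means valid)."""
    v: list[str] = []
    tables, cages = layout.tables, layout.cages
    if len(tables) != 3:
        v.append(f"exactly 3 tables required (found {len(tables)})")
    if len(cages) != 6:
        v.append(f"exactly 6 cages required (found {len(cages)})")
    for b in layout.boxes:
        if np.any(b.dims <= 0):
            v.append(f"{b.id}: dims must be strictly positive")
        if b.is_cage and not np.allclose(b.dims, CAGE_DIMS, atol=1e-9):
            v.append(f"{b.id}: cage dims must be {CAGE_DIMS}")
        if b.is_table:
            fp = sorted(b.dims[:2])
            if not (
                np.allclose(fp, sorted(TABLE_DIMS[:2]), atol=1e-9)
                and abs(b.dims[2] - TABLE_DIMS[2]) < 1e-9
            ):
                v.append(f"{b.id}: table dims must be {TABLE_DIMS} (footprint may be rotated 90 deg)")
        if set(b.faces) != set(FACE_NAMES):
            v.append(f"{b.id}: faces must map exactly {FACE_NAMES}")
        if b.is_cage:
            n_open = sum(c is FaceCover.OPEN for c in b.faces.values())
            if n_open != 1:
                v.append(f"{b.id}: cage must have exactly one open face (found {n_open})")
    stacks = layout.stacked_pairs()
    if len(stacks) != 1:
        v.append(f"exactly one stacked cage pair required (found {len(stacks)})")
    bx, by = layout.arena_bounds
    sx, sy = layout.start_location[:2]
    if not (0.0 <= sx <= bx and 0.0 <= sy <= by):
        v.append("start location outside arena bounds")
    return v


def surface_elevation(layout: Layout, surface: str) -> float:
    """Top-face elevation (m) of a table or cage.

    Tables top out at 0.70 m, a cage resting on a table at 1.00 m, and the
    upper cage of the stacked pair at 1.30 m.
    """
    return layout.box(surface).top
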