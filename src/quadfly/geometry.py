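"""Star-shaped four-quadrant arena geometry.

The behavioral arena is a 19.5 cm x 19.5 cm Teflon frame sandwiched between
glass plates.  Odorized air enters at the four corners so that the arena is
divided, by the two axes through its center, into four quadrant sectors --
one carrying the odor, three carrying control air.  All behavioral
statistics reduce to counting tracked positions per sector, so the geometry
layer only needs: a walkable-region mask, a quadrant assignment, and the
90-degree arena rotation used in post-stimulus protocols.

Coordinate conventions
----------------------
Physical coordinates are in cm with the origin at the lower-left corner of
the bounding square, x rightward and y upward.  Image (pixel) space is
row-major with the origin at the top-left; conversion between the two is
explicit (:meth:`ArenaGeometry.cm_to_px` / :meth:`ArenaGeometry.px_to_cm`).

Quadrant naming at rotation 0: Q1 = (+,+), Q2 = (-,+), Q3 = (-,-),
Q4 = (+,-) relative to the center.  One +90 degree (counterclockwise)
arena rotation advances labels cyclically Q1 -> Q2 -> Q3 -> Q4 -> Q1: the
sector label travels with the arena, so a fixed physical point changes
label when the arena is rotated.  Which quadrant carries odor is an
experiment-configuration fact, not a geometry property.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from shapely import contains_xy as _polygon_contains
from shapely.geometry import Point, Polygon

__all__ = [
    "AXIS_TOL_CM",
    "ArenaGeometry",
    "PositionSample",
    "Quadrant",
    "assign_quadrant",
    "assign_quadrants",
    "build_arena",
    "quadrant_centroid",
    "remap_quadrant",
    "rotate_arena",
]

#: Points within this distance (cm) of a quadrant axis are labelled NONE.
AXIS_TOL_CM = 1e-12


class Quadrant(str, Enum):
    """Quadrant label; ``NONE`` marks on-axis or out-of-mask points."""

    Q1 = "Q1"
    Q2 = "Q2"
    Q3 = "Q3"
    Q4 = "Q4"
    NONE = "NONE"

    @property
    def index(self) -> int:
        """0-based sector index; raises for NONE."""
        if self is Quadrant.NONE:
            raise ValueError("NONE has no sector index")
        return int(self.value[1]) - 1


_SECTOR_LABELS = (Quadrant.Q1, Quadrant.Q2, Quadrant.Q3, Quadrant.Q4)


@dataclass(frozen=True)
class PositionSample:
    """One tracked position: frame index, time (s), position (cm), track id."""

    frame: int
    t: float
    x: float
    y: float
    fly_track_id: int | None = None


@dataclass(frozen=True)
class ArenaGeometry:
    """Four-quadrant arena: extent, mask, rotation state and pixel scale.

    Parameters
    ----------
    side_length : float
        Side of the bounding square, cm.
    px_per_cm : float
        Pixel scale used when rendering or reading video frames.
    rotation : int
        Arena rotation in degrees counterclockwise; multiple of 90.
    mask_polygon : tuple of (x, y)
        Vertices (cm) of the simple polygon bounding the walkable region.
        Defaults to the bounding square with the four corners notched off
        (isosceles right triangles of leg ``0.25 * side_length``), a simple
        stand-in for the star-shaped Teflon insert; all statistics depend
        only on quadrant sign patterns, so the exact arm shape is
        configurable rather than load-bearing.
    """

    side_length: float = 19.5
    px_per_cm: float = 10.0
    rotation: int = 0
    mask_polygon: tuple[tuple[float, float], ...] = field(default=None)  # type: ignore[assignment]
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.side_length <= 0:
            raise ValueError(f"side_length must be positive, got {self.side_length}")
        if self.px_per_cm <= 0:
            raise ValueError(f"px_per_cm must be positive, got {self.px_per_cm}")
        if self.rotation % 90 != 0:
            raise ValueError(f"rotation must be a multiple of 90, got {self.rotation}")
        object.__setattr__(self, "rotation", int(self.rotation) % 360)
        if self.mask_polygon is None:
            ox, oy = self.origin
            object.__setattr__(
                self,
                "mask_polygon",
                tuple(
                    (x + ox, y + oy) for x, y in _default_star_mask(self.side_length)
                ),
            )
        poly = Polygon(self.mask_polygon)
        if not poly.is_simple or not poly.is_valid:
            raise ValueError("mask_polygon must be a simple polygon")
        if not poly.contains(Point(self.center)):
            raise ValueError("mask_polygon must contain the arena center")

    @property
    def center(self) -> tuple[float, float]:
        return (
            self.origin[0] + self.side_length / 2.0,
            self.origin[1] + self.side_length / 2.0,
        )

    def translate(self, dx: float, dy: float) -> "ArenaGeometry":
        """The same arena shifted by (dx, dy) cm."""
        return replace(
            self,
            origin=(self.origin[0] + dx, self.origin[1] + dy),
            mask_polygon=tuple((x + dx, y + dy) for x, y in self.mask_polygon),
        )

    @property
    def mask(self) -> Polygon:
        return Polygon(self.mask_polygon)

    @property
    def image_shape(self) -> tuple[int, int]:
        """(rows, cols) of the rendered image covering the bounding square."""
        n = int(round(self.side_length * self.px_per_cm))
        return (n, n)

    # -- pixel <-> physical conversion ------------------------------------
    def cm_to_px(self, x: float | np.ndarray, y: float | np.ndarray):
        """Physical (x, y) cm -> image (row, col), float, top-left origin."""
        col = (np.asarray(x) - self.origin[0]) * self.px_per_cm
        row = (self.origin[1] + self.side_length - np.asarray(y)) * self.px_per_cm
        return row, col

    def px_to_cm(self, row: float | np.ndarray, col: float | np.ndarray):
        """Image (row, col) -> physical (x, y) cm."""
        x = self.origin[0] + np.asarray(col) / self.px_per_cm
        y = self.origin[1] + self.side_length - np.asarray(row) / self.px_per_cm
        return x, y

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "side_length_cm": self.side_length,
            "px_per_cm": self.px_per_cm,
            "rotation_deg": self.rotation,
            "origin_cm": list(self.origin),
            "mask_polygon": [list(v) for v in self.mask_polygon],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "ArenaGeometry":
        return cls(
            side_length=d["side_length_cm"],
            px_per_cm=d["px_per_cm"],
            rotation=d.get("rotation_deg", 0),
            mask_polygon=tuple(tuple(v) for v in d["mask_polygon"])
            if d.get("mask_polygon")
            else None,
            origin=tuple(d.get("origin_cm", (0.0, 0.0))),
        )

    @classmethod
    def from_json(cls, s: str) -> "ArenaGeometry":
        return cls.from_dict(json.loads(s))


def _default_star_mask(side: float) -> tuple[tuple[float, float], ...]:
    """Bounding square with corner notches of leg 0.25 * side (CCW octagon)."""
    a = 0.25 * side
    s = side
    return (
        (a, 0.0),
        (s - a, 0.0),
        (s, a),
        (s, s - a),
        (s - a, s),
        (a, s),
        (0.0, s - a),
        (0.0, a),
    )


def build_arena(
    side_length: float = 19.5, px_per_cm: float = 10.0, rotation: int = 0
) -> ArenaGeometry:
    """Construct the default arena: star mask inscribed in the square, center
    at the square center.

    Raises ``ValueError`` for non-positive dimensions or a rotation that is
    not a multiple of 90.
    """
    return ArenaGeometry(
        side_length=side_length, px_per_cm=px_per_cm, rotation=rotation
    )


def rotate_arena(arena: ArenaGeometry, degrees: int) -> ArenaGeometry:
    """Rotate the arena by ``degrees`` (multiple of 90, CCW positive).

    Returns a new arena with ``rotation`` incremented modulo 360.  Quadrant
    labels of fixed physical points are remapped by the cyclic permutation
    Q1 -> Q2 -> Q3 -> Q4 per +90 degree step (see module docstring).
    """
    if degrees % 90 != 0:
        raise ValueError(f"rotation must be a multiple of 90, got {degrees}")
    return replace(arena, rotation=(arena.rotation + int(degrees)) % 360)


def _sector_from_offsets(dx: np.ndarray, dy: np.ndarray, rotation: int) -> np.ndarray:
    """0-based sector index per point, -1 for on-axis, given arena rotation.

    The sector label travels with the arena: labelling applies the rotation
    matrix R(+rotation) to the center offset before reading the sign
    pattern, which realises the cyclic permutation Q1->Q2->Q3->Q4 per +90
    degree step.
    """
    theta = np.deg2rad(rotation % 360)
    c, s = np.cos(theta), np.sin(theta)
    u = c * dx - s * dy
    v = s * dx + c * dy
    on_axis = (np.abs(u) < AXIS_TOL_CM) | (np.abs(v) < AXIS_TOL_CM)
    # sign pattern -> sector: (+,+)=0, (-,+)=1, (-,-)=2, (+,-)=3
    sector = np.where(
        v > 0, np.where(u > 0, 0, 1), np.where(u > 0, 3, 2)
    )
    return np.where(on_axis, -1, sector)


def assign_quadrants(
    x: np.ndarray, y: np.ndarray, arena: ArenaGeometry
) -> np.ndarray:
    """Vectorized quadrant assignment.

    Returns an integer array: 0..3 for Q1..Q4, -1 for NONE (on an axis or
    outside the walkable mask).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cx, cy = arena.center
    sector = _sector_from_offsets(x - cx, y - cy, arena.rotation)
    inside = _polygon_contains(arena.mask, x, y)
    return np.where(inside, sector, -1)


def assign_quadrant(p: PositionSample, arena: ArenaGeometry) -> Quadrant:
    """Label a single position with its quadrant.

    NONE is returned for points on a quadrant axis (within
    :data:`AXIS_TOL_CM`) or outside the mask polygon; total on finite
    points.
    """
    if not (np.isfinite(p.x) and np.isfinite(p.y)):
        raise ValueError("position must be finite")
    idx = int(assign_quadrants(np.array([p.x]), np.array([p.y]), arena)[0])
    return Quadrant.NONE if idx < 0 else _SECTOR_LABELS[idx]


def remap_quadrant(label: Quadrant, degrees: int) -> Quadrant:
    """Label of the physical region that carried ``label`` before the arena
    was rotated by ``degrees`` CCW (cyclic shift by degrees/90)."""
    if degrees % 90 != 0:
        raise ValueError(f"rotation must be a multiple of 90, got {degrees}")
    if label is Quadrant.NONE:
        return label
    k = (label.index + degrees // 90) % 4
    return _SECTOR_LABELS[k]


def quadrant_centroid(
    label: Quadrant, arena: ArenaGeometry
) -> tuple[float, float]:
    """Centroid (cm) of the walkable region of one quadrant sector."""
    if label is Quadrant.NONE:
        raise ValueError("NONE has no centroid")
    cx, cy = arena.center
    # representative unit offset of the sector at rotation 0
    sign = [(1, 1), (-1, 1), (-1, -1), (1, -1)][label.index]
    theta = np.deg2rad(-arena.rotation)  # invert the labelling rotation
    c, s = np.cos(theta), np.sin(theta)
    dx, dy = sign
    u, v = c * dx - s * dy, s * dx + c * dy
    r = arena.side_length / 4.0
    return (cx + u * r, cy + v * r)
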