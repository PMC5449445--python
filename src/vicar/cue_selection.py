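"""From cue polygons to the three control points driving the affine solve.

An affine transform in the plane has six parameters, so three point
correspondences determine it exactly. How the three points are obtained
adapts to the number of cues J in the frame:

* J = 1 (scenario a): corners of the cue's minimum-area oriented
  bounding box (OBB); the first three corners are used.
* J = 2 (scenario b): the first OBB corner of each cue, plus the second
  OBB corner of the first cue as the third point (two cues alone yield
  only two points; the extra corner makes the triple non-collinear for
  any non-degenerate OBB).
* J >= 3 (scenario c): the vertex-mean centers of the first three cues.

"First" is always defined by :func:`order_cues` — a stable lexicographic
sort on the cue anchor (min y, then min x over vertices) — so the choice
is deterministic and consistent between consecutive frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .errors import DegenerateGeometryError, NoCuesError, ShiftTooLargeError, ValidationError
from .polygon_detection import Polygon

#: Minimum triangle area (px^2) for a control triple to count as non-collinear.
COLLINEARITY_TOL = 1.0


@dataclass
class ControlTriple:
    """Exactly three ordered (x, y) control points for one frame."""

    points: np.ndarray
    t: int = 1
    provenance: str = "c"  # scenario that produced the points: a, b, or c

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (3, 2):
            raise ValidationError(f"control triple must be (3, 2), got {self.points.shape}")
        if triangle_area(self.points) < COLLINEARITY_TOL:
            raise DegenerateGeometryError(
                f"control points are (near-)collinear at t={self.t}: "
                f"triangle area {triangle_area(self.points):.3g} px^2"
            )


@dataclass
class CueFrame:
    """The retained cue polygons of one frame."""

    t: int
    cues: list[Polygon] = field(default_factory=list)

    @property
    def J(self) -> int:
        return len(self.cues)

    @property
    def anchors(self) -> np.ndarray:
        """(J, 2) array of cue centers (vertex means), in cue order."""
        if not self.cues:
            return np.empty((0, 2))
        return np.array([p.centroid for p in self.cues])


def triangle_area(pts: np.ndarray) -> float:
    a, b, c = np.asarray(pts, dtype=float)
    u, v = b - a, c - a
    return float(abs(u[0] * v[1] - u[1] * v[0]) / 2.0)


def order_cues(cues: list[Polygon]) -> list[Polygon]:
    """Stable sort by anchor point: min vertex y, ties broken by min vertex x.

    The first cue under this order is the reference cue of the frame.
    """
    return sorted(cues, key=lambda p: p.anchor)


def spanning_triple_indices(centers: np.ndarray, max_pool: int = 6) -> tuple[int, int, int]:
    """Indices of the three points spanning the largest triangle.

    With more than three cues the affine solve uses only three centers;
    picking the maximum-area triangle minimizes the extrapolation
    leverage at the remaining cue positions (a point inside the control
    triangle is interpolated, not extrapolated). Only the first
    ``max_pool`` points (already in stable cue order) are considered;
    ties break lexicographically on the index triple, so the choice is
    deterministic.
    """
    from itertools import combinations

    n = min(len(centers), max_pool)
    best, best_area = (0, 1, 2), -1.0
    for idx in combinations(range(n), 3):
        a = triangle_area(centers[list(idx)])
        if a > best_area + 1e-12:
            best, best_area = idx, a
    return best


def oriented_bounding_box(p: Polygon) -> np.ndarray:
    """Minimum-area enclosing rectangle of the polygon's vertices.

    Computed by rotating calipers over the convex hull (via shapely's
    minimum rotated rectangle). Returns the 4 corners as a (4, 2) array,
    ordered counterclockwise (in x-y value terms) starting from the
    corner nearest the polygon's anchor point (min vertex x, min vertex
    y). Anchoring the start corner to the polygon's own geometry, rather
    than the image origin, makes the ordering translation-equivariant:
    moving the cue cannot change which corner comes first.
    """
    mp = shapely.multipoints(p.vertices)
    rect = shapely.minimum_rotated_rectangle(mp)
    if rect.geom_type != "Polygon":
        raise DegenerateGeometryError(
            f"polygon at t={p.t}, j={p.j} is collinear; no oriented bounding box"
        )
    corners = np.asarray(rect.exterior.coords)[:4]
    # enforce counterclockwise orientation (positive signed area)
    x, y = corners[:, 0], corners[:, 1]
    signed = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y) / 2.0
    if signed < 0:
        corners = corners[::-1]
    ref = p.vertices.min(axis=0)
    start = int(np.argmin(np.hypot(*(corners - ref).T)))
    return np.roll(corners, -start, axis=0)


def control_points(frame: CueFrame) -> ControlTriple:
    """Reduce a frame's cues to its three control points (scenarios a/b/c)."""
    if frame.J == 0:
        raise NoCuesError(f"frame t={frame.t} has no cues; it cannot be registered")
    cues = order_cues(frame.cues)
    if frame.J == 1:
        pts = oriented_bounding_box(cues[0])[:3]
        scenario = "a"
    elif frame.J == 2:
        obb0 = oriented_bounding_box(cues[0])
        obb1 = oriented_bounding_box(cues[1])
        pts = np.array([obb0[0], obb1[0], obb0[1]])
        scenario = "b"
    else:
        centers = np.array([p.centroid for p in cues])
        idx = spanning_triple_indices(centers)
        pts = centers[list(idx)]
        scenario = "c"
    return ControlTriple(points=pts, t=frame.t, provenance=scenario)


def match_cues(
    prev: CueFrame, next: CueFrame, max_displacement: float | None = None
) -> np.ndarray:
    """Bijective cue correspondence minimizing total anchor displacement.

    Returns an integer array ``perm`` with ``perm[i]`` the index in
    ``next.cues`` matched to ``prev.cues[i]`` (optimal assignment).
    Raises :class:`ShiftTooLargeError` if any matched displacement is at
    least ``max_displacement`` (callers pass half the image width: beyond
    that shift the cues found earlier may have left the visual field).
    """
    if prev.J != next.J:
        raise ValidationError(
            f"cue counts differ: J={prev.J} at t={prev.t} vs J={next.J} at t={next.t}"
        )
    if prev.J == 0:
        return np.empty(0, dtype=int)
    cost = cdist(prev.anchors, next.anchors)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(prev.J, dtype=int)
    perm[rows] = cols
    if max_displacement is not None:
        worst = float(cost[rows, cols].max())
        if worst >= max_displacement:
            raise ShiftTooLargeError(
                f"cue displacement {worst:.1f} px between t={prev.t} and t={next.t} "
                f"exceeds the limit {max_displacement:.1f} px"
            )
    return perm


def control_points_csv_row(triple: ControlTriple) -> dict:
    """Flat record for the optional per-frame control-point dump."""
    (x1, y1), (x2, y2), (x3, y3) = triple.points
    return dict(
        t=triple.t, scenario=triple.provenance,
        x1=x1, y1=y1, x2=x2, y2=y2, x3=x3, y3=y3,
    )
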