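"""Closed-polygon extraction from binary masks and the cue filter.

A connected foreground component's outer boundary is traced as an ordered
chain of 8-adjacent boundary pixels (Moore-neighbor border following with
Jacob's stopping criterion — the classic border-following approach for
binary images). Inner boundaries (holes) are deliberately not emitted:
cues are solid spacer shapes, and the area formula assumes a simple
polygon.

Each polygon is then scored by its perimeter-to-area ratio

    r_j = S_j / A_j,

a size-dependent irregularity descriptor: holding shape fixed, scaling a
polygon by s divides the ratio by s. The chamber spacers are large and
simple, so they sit below the empirical threshold r_j < 5e-2 px^-1;
small or ragged polygons (cells, noise) sit above it. If *no* polygon
passes, the full set is retained as a fallback so a frame never silently
loses all candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .errors import ValidationError
from .preprocess import BinaryMask

#: Eq. r_j < RATIO_THRESHOLD retains a polygon as a visual cue (strict).
RATIO_THRESHOLD = 5e-2

#: Components whose traced boundary has fewer pixels than this are noise.
MIN_BOUNDARY_PIXELS = 5

#: Boundary chains enclosing less than this area are degenerate (lines).
MIN_AREA = 0.5

# clockwise Moore neighborhood, starting north, as (drow, dcol)
_NB = (
    (-1, 0), (-1, 1), (0, 1), (1, 1),
    (1, 0), (1, -1), (0, -1), (-1, -1),
)
_NB_INDEX = {d: i for i, d in enumerate(_NB)}


@dataclass
class Polygon:
    """Closed vertex chain in pixel coordinates.

    ``vertices`` is an (N, 2) float array of (x, y) points, implicitly
    closed (last vertex connects back to the first). ``t`` is the frame
    index, ``j`` the polygon index within the frame.
    """

    vertices: np.ndarray
    t: int = 1
    j: int = 0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValidationError("polygon vertices must be an (N, 2) array")
        if len(self.vertices) < 3:
            raise ValidationError(
                f"polygon needs >= 3 vertices, got {len(self.vertices)}"
            )

    @property
    def anchor(self) -> tuple[float, float]:
        """(min y, min x) over vertices — the sort key for cue ordering."""
        return (float(self.vertices[:, 1].min()), float(self.vertices[:, 0].min()))

    @property
    def centroid(self) -> np.ndarray:
        """Area (shoelace) centroid of the enclosed region.

        Robust to the ragged pixel-chain boundaries border following
        produces: a noise notch contributes only its small area, whereas
        a plain vertex mean would over-weight its many boundary pixels.
        Falls back to the vertex mean for (near-)zero-area chains.
        """
        v = self.vertices
        x, y = v[:, 0], v[:, 1]
        x1, y1 = np.roll(x, -1), np.roll(y, -1)
        cross = x * y1 - x1 * y
        a = cross.sum() / 2.0
        if abs(a) < MIN_AREA:
            return v.mean(axis=0)
        cx = ((x + x1) * cross).sum() / (6.0 * a)
        cy = ((y + y1) * cross).sum() / (6.0 * a)
        return np.array([cx, cy])


@dataclass(frozen=True)
class ShapeStats:
    perimeter: float
    area: float
    ratio: float


def _trace_boundary(comp: np.ndarray) -> list[tuple[int, int]]:
    """Moore-neighbor trace of the outer boundary of a padded component.

    ``comp`` must be a boolean array with a 1-pixel false border. Returns
    boundary pixel (row, col) coordinates in order; a pixel may appear
    more than once where the component has 1-pixel-wide spurs.
    """
    rows, cols = np.nonzero(comp)
    start = (int(rows[0]), int(cols[0]))  # topmost, then leftmost
    boundary = [start]
    cur = start
    back = (start[0], start[1] - 1)  # west of start is guaranteed background
    first_state: tuple | None = None
    max_steps = 4 * len(rows) + 8
    for _ in range(max_steps):
        d0 = _NB_INDEX[(back[0] - cur[0], back[1] - cur[1])]
        nxt = None
        for k in range(1, 9):
            d = (d0 + k) % 8
            cand = (cur[0] + _NB[d][0], cur[1] + _NB[d][1])
            if comp[cand]:
                nxt = cand
                prev = (d0 + k - 1) % 8
                back = (cur[0] + _NB[prev][0], cur[1] + _NB[prev][1])
                break
        if nxt is None:  # isolated pixel
            return boundary
        state = (nxt, back)
        if first_state is None:
            first_state = state
        elif state == first_state:
            break
        boundary.append(nxt)
        cur = nxt
    if len(boundary) > 1 and boundary[-1] == boundary[0]:
        boundary.pop()
    return boundary


def find_polygons(mask: BinaryMask) -> list[Polygon]:
    """Outer-boundary polygon of every 8-connected foreground component.

    Components are visited in raster-scan discovery order, so polygon
    indices are stable across runs. Components whose boundary is shorter
    than :data:`MIN_BOUNDARY_PIXELS` or whose enclosed area is degenerate
    are discarded — they cannot form meaningful cue polygons and their
    ratio is numerically unstable.
    """
    labels = measure.label(mask.pixels, connectivity=2)
    n = int(labels.max())
    polys: list[Polygon] = []
    slices = ndimage.find_objects(labels)
    j = 0
    for lab in range(1, n + 1):
        sl = slices[lab - 1]
        if sl is None:
            continue
        comp = np.pad(labels[sl] == lab, 1)
        chain = _trace_boundary(comp)
        if len(chain) < MIN_BOUNDARY_PIXELS:
            continue
        verts = np.array(
            [(c - 1 + sl[1].start, r - 1 + sl[0].start) for r, c in chain],
            dtype=float,
        )
        if _shoelace(verts) < MIN_AREA:
            continue
        polys.append(Polygon(vertices=verts, t=mask.t, j=j))
        j += 1
    return polys


def perimeter(p: Polygon) -> float:
    """Sum of Euclidean segment lengths, including the closing segment."""
    v = p.vertices
    d = np.diff(np.vstack([v, v[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _shoelace(verts: np.ndarray) -> float:
    x, y = verts[:, 0], verts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    return float(abs(np.sum(x * y1 - x1 * y)) / 2.0)


def area(p: Polygon) -> float:
    """Absolute shoelace area (orientation-independent), wraparound included."""
    return _shoelace(p.vertices)


def ratio(p: Polygon) -> float:
    """Perimeter-to-area ratio S/A in px^-1; scales as 1/s under scaling by s."""
    a = area(p)
    if a <= 1e-12:
        raise ValidationError("degenerate polygon: area is zero")
    return perimeter(p) / a


def shape_stats(p: Polygon) -> ShapeStats:
    s, a = perimeter(p), area(p)
    if a <= 1e-12:
        raise ValidationError("degenerate polygon: area is zero")
    return ShapeStats(perimeter=s, area=a, ratio=s / a)


def filter_cues(
    polygons: list[Polygon], threshold: float = RATIO_THRESHOLD
) -> list[Polygon]:
    """Retain polygons with ratio strictly below ``threshold``.

    If none qualifies, the *full* input list is returned unchanged:
    complex polygons are retained only when no simple one is available,
    so a frame with any polygon always keeps at least one cue candidate.
    """
    retained = [p for p in polygons if ratio(p) < threshold]
    return retained if retained else list(polygons)


def polygon_table(
    polygons: list[Polygon], threshold: float = RATIO_THRESHOLD
) -> pd.DataFrame:
    """Tabular dump (frame, id, vertex count, perimeter, area, ratio, retained)."""
    kept = {id(p) for p in filter_cues(polygons, threshold)}
    rows = []
    for p in polygons:
        st = shape_stats(p)
        rows.append(
            dict(
                frame=p.t,
                polygon=p.j,
                n_vertices=len(p.vertices),
                perimeter=st.perimeter,
                area=st.area,
                ratio=st.ratio,
                retained=id(p) in kept,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["frame", "polygon", "n_vertices", "perimeter", "area", "ratio", "retained"],
    )
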