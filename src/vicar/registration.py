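"""Affine registration of a frame series to its first frame.

Registration is pairwise and adaptive. The series is partitioned into
maximal runs of frames sharing the same cue count J; within a run, the
cues of consecutive frames are matched one-to-one, reduced to control
triples, and an exact affine transform (six unknowns, three point
correspondences) is solved mapping frame t+1 coordinates onto frame t.
Composing the pairwise transforms left-to-right expresses every frame in
the coordinates of the reference frame I_1. Where J changes between t
and t+1 there is no same-J pair, so the bridging transform is estimated
from the min(J, J') nearest-matched cues reduced by the same scenario
rules — the chain stays connected across cue-count boundaries.

The module is organised around a model object,
:class:`SeriesRegistration`, whose :meth:`~SeriesRegistration.fit`
returns a :class:`RegistrationResult` with the per-frame transforms,
warped frames, per-frame diagnostics and a ``summary()`` table;
:func:`register_series` is the one-call functional wrapper.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .cue_selection import (
    ControlTriple,
    CueFrame,
    control_points,
    match_cues,
    order_cues,
    oriented_bounding_box,
    spanning_triple_indices,
)
from .errors import (
    DegenerateGeometryError,
    NoCuesError,
    ShiftTooLargeError,
    UnregistrableSeriesError,
    ValidationError,
    VicarError,
)
from .io_frames import Frame, FrameSeries, to_grayscale
from .polygon_detection import RATIO_THRESHOLD, filter_cues, find_polygons
from .preprocess import BinaryMask, PreprocessConfig, preprocess_frame


@dataclass
class AffineTransform:
    """2x3 affine matrix [[a, b, tx], [c, d, ty]] acting on (x, y) points."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 3):
            raise ValidationError(f"affine matrix must be 2x3, got {self.matrix.shape}")
        a, b, _, c, d, _ = self.matrix.ravel()
        if abs(a * d - b * c) <= 1e-12:
            raise DegenerateGeometryError("affine transform has a singular linear part")

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @classmethod
    def translation(cls, tx: float, ty: float) -> "AffineTransform":
        return cls(np.array([[1.0, 0.0, tx], [0.0, 1.0, ty]]))

    @classmethod
    def rotation_about(
        cls, angle_rad: float, center: tuple[float, float] = (0.0, 0.0)
    ) -> "AffineTransform":
        ca, sa = np.cos(angle_rad), np.sin(angle_rad)
        cx, cy = center
        tx = cx - ca * cx + sa * cy
        ty = cy - sa * cx - ca * cy
        return cls(np.array([[ca, -sa, tx], [sa, ca, ty]]))

    @classmethod
    def rigid(
        cls, angle_rad: float, tx: float, ty: float,
        center: tuple[float, float] = (0.0, 0.0),
    ) -> "AffineTransform":
        """Rotation about ``center`` followed by a translation."""
        rot = cls.rotation_about(angle_rad, center)
        m = rot.matrix.copy()
        m[:, 2] += (tx, ty)
        return cls(m)

    # -- algebra ------------------------------------------------------
    @property
    def homogeneous(self) -> np.ndarray:
        return np.vstack([self.matrix, [0.0, 0.0, 1.0]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix[:, :2].T + self.matrix[:, 2]
        return out if np.asarray(points).ndim == 2 else out[0]

    def invert(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.homogeneous)[:2])

    @property
    def params(self) -> tuple[float, float, float, float, float, float]:
        """(a, b, tx, c, d, ty)."""
        m = self.matrix
        return (m[0, 0], m[0, 1], m[0, 2], m[1, 0], m[1, 1], m[1, 2])

    @property
    def rotation_angle(self) -> float:
        """Rotation angle (rad) of the linear part, exact for rigid transforms."""
        return float(np.arctan2(self.matrix[1, 0], self.matrix[0, 0]))

    def max_corner_displacement(self, shape: tuple[int, int]) -> float:
        """Largest displacement this transform induces at the image corners."""
        r, c = shape
        corners = np.array([[0, 0], [c - 1, 0], [0, r - 1], [c - 1, r - 1]], float)
        return float(np.linalg.norm(self.apply(corners) - corners, axis=1).max())


def compose(outer: AffineTransform, inner: AffineTransform) -> AffineTransform:
    """Transform applying ``inner`` first, then ``outer``."""
    return AffineTransform((outer.homogeneous @ inner.homogeneous)[:2])


def estimate_affine(src: ControlTriple, dst: ControlTriple) -> AffineTransform:
    """Exact affine transform mapping the src triple onto the dst triple.

    Solves the 6x6 linear system built from the three correspondences
    (point i of src maps to point i of dst); the residual on the control
    points is verified to be below 1e-9 px.
    """
    s, d = src.points, dst.points
    A = np.zeros((6, 6))
    b = np.zeros(6)
    for i in range(3):
        x, y = s[i]
        A[2 * i, 0:3] = (x, y, 1.0)
        A[2 * i + 1, 3:6] = (x, y, 1.0)
        b[2 * i] = d[i, 0]
        b[2 * i + 1] = d[i, 1]
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise DegenerateGeometryError(f"singular control-point system: {exc}") from exc
    tf = AffineTransform(sol.reshape(2, 3))
    resid = np.linalg.norm(tf.apply(s) - d, axis=1).max()
    if resid > 1e-9:
        raise DegenerateGeometryError(f"affine solve residual {resid:.3g} px exceeds 1e-9")
    return tf


def estimate_affine_lsq(src: np.ndarray, dst: np.ndarray) -> AffineTransform:
    """Least-squares affine from n >= 3 point correspondences.

    For exactly three points this reproduces :func:`estimate_affine`'s
    exact solve; with more, every matched cue center constrains the fit,
    which keeps the error uniform across the field instead of
    extrapolating from a three-point subset.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    n = len(src)
    if n < 3:
        raise DegenerateGeometryError("affine estimation needs >= 3 correspondences")
    A = np.zeros((2 * n, 6))
    b = np.empty(2 * n)
    A[0::2, 0:2] = src
    A[0::2, 2] = 1.0
    A[1::2, 3:5] = src
    A[1::2, 5] = 1.0
    b[0::2] = dst[:, 0]
    b[1::2] = dst[:, 1]
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 6:
        raise DegenerateGeometryError("degenerate (collinear) correspondences")
    return AffineTransform(sol.reshape(2, 3))


# ---------------------------------------------------------------------
# interval partitioning
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class Interval:
    t_start: int
    t_end: int
    J: int

    @property
    def length(self) -> int:
        return self.t_end - self.t_start + 1

    @property
    def registrable(self) -> bool:
        """At least two consecutive frames share this J."""
        return self.length >= 2


@dataclass
class IntervalPartition:
    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = 1
        for iv in self.intervals:
            if iv.t_start != expected or iv.t_end < iv.t_start:
                raise ValidationError("intervals must be contiguous and cover 1..T")
            expected = iv.t_end + 1

    @property
    def T(self) -> int:
        return self.intervals[-1].t_end if self.intervals else 0


def partition_intervals(counts: list[int]) -> IntervalPartition:
    """Maximal runs of equal cue count J (run-length encoding of counts).

    Length-1 runs are representable but not registrable by same-J
    pairing; :class:`SeriesRegistration` bridges across them using the
    matched cue subsets of the adjacent frames.
    """
    intervals: list[Interval] = []
    start = 0
    for i in range(1, len(counts) + 1):
        if i == len(counts) or counts[i] != counts[start]:
            intervals.append(Interval(t_start=start + 1, t_end=i, J=counts[start]))
            start = i
    return IntervalPartition(intervals=intervals)


def chain_to_reference(
    pairwise: list[AffineTransform | None],
    partition: IntervalPartition | None = None,
) -> list[AffineTransform | None]:
    """Compose pairwise transforms into per-frame transforms onto frame 1.

    ``pairwise[t-1]`` maps frame t+1 onto frame t. The reference frame
    gets the exact identity. A missing pairwise transform breaks the
    chain: every downstream frame gets ``None`` (flagged, never silently
    dropped) because it can no longer be expressed in reference
    coordinates.
    """
    out: list[AffineTransform | None] = [AffineTransform.identity()]
    for tf in pairwise:
        prev = out[-1]
        out.append(None if (tf is None or prev is None) else compose(prev, tf))
    return out


# ---------------------------------------------------------------------
# warping
# ---------------------------------------------------------------------

_SWAP = np.array([[0.0, 1.0], [1.0, 0.0]])


def _rc_inverse(tf: AffineTransform) -> tuple[np.ndarray, np.ndarray]:
    """Inverse mapping in (row, col) form for scipy's affine_transform."""
    inv = tf.invert()
    lin = _SWAP @ inv.matrix[:, :2] @ _SWAP
    off = _SWAP @ inv.matrix[:, 2]
    return lin, off


def warp(frame: Frame, tf: AffineTransform) -> Frame:
    """Resample a frame under ``tf`` (inverse-mapped, bilinear, zero fill).

    RGB payloads are warped channel-wise with the same transform; the
    output keeps the input dimensions and 8-bit range.
    """
    lin, off = _rc_inverse(tf)

    def _warp_channel(ch: np.ndarray) -> np.ndarray:
        out = ndimage.affine_transform(
            np.asarray(ch, dtype=np.float64), lin, offset=off, order=1,
            mode="constant", cval=0.0,
        )
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)

    pixels = _warp_channel(frame.pixels)
    rgb = None
    if frame.rgb is not None:
        rgb = np.stack([_warp_channel(frame.rgb[..., k]) for k in range(3)], axis=-1)
    return Frame(pixels=pixels, t=frame.t, rgb=rgb)


def warp_mask(mask: BinaryMask, tf: AffineTransform) -> BinaryMask:
    """Warp a binary mask with nearest-neighbor resampling (stays binary)."""
    lin, off = _rc_inverse(tf)
    out = ndimage.affine_transform(
        mask.pixels.astype(np.uint8), lin, offset=off, order=0,
        mode="constant", cval=0,
    )
    return BinaryMask(pixels=out.astype(bool), t=mask.t)


# ---------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------

def _triples_from_matched(
    cues_a: list, cues_b: list, t_a: int, t_b: int,
    triple_idx: tuple[int, int, int] | None = None,
) -> tuple[ControlTriple, ControlTriple, str]:
    """Scenario-rule control triples from two correspondence-ordered cue lists.

    ``triple_idx`` pins which three of the matched cues form the control
    triple; keeping it fixed across all pairs of an interval makes the
    composed chain exact on the control cues (each pairwise solve maps
    them exactly, so the composition telescopes).
    """
    J = len(cues_a)
    if J == 0:
        raise NoCuesError(f"no common cues between t={t_a} and t={t_b}")
    if J == 1:
        pa = oriented_bounding_box(cues_a[0])[:3]
        pb = oriented_bounding_box(cues_b[0])[:3]
        scenario = "a"
    elif J == 2:
        oa0, oa1 = oriented_bounding_box(cues_a[0]), oriented_bounding_box(cues_a[1])
        ob0, ob1 = oriented_bounding_box(cues_b[0]), oriented_bounding_box(cues_b[1])
        pa = np.array([oa0[0], oa1[0], oa0[1]])
        pb = np.array([ob0[0], ob1[0], ob0[1]])
        scenario = "b"
    else:
        ca = np.array([p.centroid for p in cues_a])
        cb = np.array([p.centroid for p in cues_b])
        if triple_idx is None or max(triple_idx) >= len(ca):
            triple_idx = spanning_triple_indices(ca)
        idx = list(triple_idx)
        pa, pb = ca[idx], cb[idx]
        scenario = "c"
    return (
        ControlTriple(points=pa, t=t_a, provenance=scenario),
        ControlTriple(points=pb, t=t_b, provenance=scenario),
        scenario,
    )


def _min_spacing(anchors: np.ndarray) -> float:
    if len(anchors) < 2:
        return np.inf
    d = cdist(anchors, anchors)
    return float(d[np.triu_indices(len(anchors), k=1)].min())


def pair_transform(
    cf_a: CueFrame, cf_b: CueFrame, max_displacement: float | None = None,
    triple_idx: tuple[int, int, int] | None = None,
) -> tuple[AffineTransform, str]:
    """Affine transform mapping frame b's coordinates onto frame a's.

    Cues are matched by optimal assignment on their anchors; matched
    pairs are trusted only while the displacement stays below half the
    smallest inter-cue spacing — beyond that a cue that vanished in one
    frame would be paired with a *different* cue, which is exactly the
    ambiguity the cue-identity assumption rules out. The trusted common
    subset (this also bridges pairs where J changes) is reduced to
    control triples by the scenario rules and solved exactly. The
    scenario label is returned alongside.
    """
    if cf_a.J == 0 or cf_b.J == 0:
        raise NoCuesError(
            f"frame t={cf_a.t if cf_a.J == 0 else cf_b.t} has no cues"
        )
    ordered_a = order_cues(cf_a.cues)
    anchors_a = np.array([p.centroid for p in ordered_a])
    cost = cdist(anchors_a, cf_b.anchors)
    rows, cols = linear_sum_assignment(cost)
    if max_displacement is not None:
        worst = float(cost[rows, cols].max())
        if min(cf_a.J, cf_b.J) == cf_a.J == cf_b.J and worst >= max_displacement:
            raise ShiftTooLargeError(
                f"cue displacement {worst:.1f} px between t={cf_a.t} and "
                f"t={cf_b.t} exceeds the limit {max_displacement:.1f} px"
            )
    trust = min(_min_spacing(anchors_a), _min_spacing(cf_b.anchors)) / 2.0
    if max_displacement is not None:
        trust = min(trust, max_displacement)
    keep = cost[rows, cols] < trust
    if not keep.any():
        raise NoCuesError(
            f"no trustworthy cue correspondence between t={cf_a.t} and t={cf_b.t}"
        )
    rows, cols = rows[keep], cols[keep]
    order = np.argsort(rows)
    sel_a = [ordered_a[i] for i in rows[order]]
    sel_b = [cf_b.cues[k] for k in cols[order]]
    if len(sel_a) != cf_a.J or len(sel_b) != cf_b.J:
        triple_idx = None  # cue set shrank; the pinned indices no longer apply
    triple_a, triple_b, scenario = _triples_from_matched(
        sel_a, sel_b, cf_a.t, cf_b.t, triple_idx
    )
    return estimate_affine(triple_b, triple_a), scenario


@dataclass
class RegistrationResult:
    """Estimates and diagnostics of a fitted series registration.

    Attributes
    ----------
    transforms : list of AffineTransform or None
        Per-frame composed transform onto the reference frame; entry 0
        (the reference) is the exact identity, ``None`` marks frames that
        could not be chained to the reference.
    registered : FrameSeries
        Input frames warped into reference coordinates (unregistrable
        frames are passed through unwarped and flagged in ``statuses``).
    cue_frames : list of CueFrame
        The retained cue polygons per frame.
    partition : IntervalPartition
        Maximal constant-J runs of the series.
    statuses : list of str
        Per-frame "reference" / "registered" / "unregistered: <reason>".
    frame_log : pandas.DataFrame
        One row per frame: t, J, scenario, transform parameters, status,
        elapsed seconds.
    """

    transforms: list
    registered: FrameSeries
    cue_frames: list
    partition: IntervalPartition
    statuses: list
    scenarios: list
    frame_log: pd.DataFrame
    elapsed: list
    method: str = "ViCAR"

    @property
    def mean_elapsed(self) -> float:
        return float(np.mean(self.elapsed)) if self.elapsed else float("nan")

    @property
    def n_registered(self) -> int:
        return sum(tf is not None for tf in self.transforms)

    def transforms_frame(self) -> pd.DataFrame:
        """Per-frame transform parameters as a tidy table."""
        rows = []
        for i, tf in enumerate(self.transforms):
            a, b, tx, c, d, ty = tf.params if tf is not None else (np.nan,) * 6
            rows.append(
                dict(
                    t=i + 1, a=a, b=b, tx=tx, c=c, d=d, ty=ty,
                    scenario=self.scenarios[i],
                    J=self.cue_frames[i].J,
                    status=self.statuses[i],
                )
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.transforms_frame().to_csv(path, index=False)

    def summary(self) -> str:
        """Human-readable fit report."""
        df = self.transforms_frame()
        T = len(self.transforms)
        lines = [
            f"{self.method} series registration",
            "=" * 34,
            f"frames:              {T}",
            f"registered:          {self.n_registered}/{T}",
            f"constant-J runs:     "
            + ", ".join(f"[{iv.t_start}..{iv.t_end}] J={iv.J}" for iv in self.partition.intervals),
            f"mean elapsed/frame:  {self.mean_elapsed:.3f} s",
            "",
            df.to_string(
                index=False,
                float_format=lambda v: f"{v: .4f}",
            ),
        ]
        return "\n".join(lines)


class SeriesRegistration:
    """Adaptive visual-cue registration model for one frame series.

    Parameters
    ----------
    series : FrameSeries
        T >= 2 frames sharing one geometry.
    preprocess_config : PreprocessConfig, optional
        Stage (b)-(g) tunables; defaults suit 1004x1002 chamber frames.
    ratio_threshold : float
        Strict perimeter-to-area cutoff below which a polygon is a cue.
    max_shift_fraction : float
        Matching refuses cue displacements of at least this fraction of
        the image width (default 0.5: beyond half the width the original
        cues may have left the visual field).
    """

    def __init__(
        self,
        series: FrameSeries,
        preprocess_config: PreprocessConfig | None = None,
        ratio_threshold: float = RATIO_THRESHOLD,
        max_shift_fraction: float = 0.5,
    ):
        if series.T < 2:
            raise ValidationError("registration needs at least two frames")
        self.series = series
        self.preprocess_config = preprocess_config or PreprocessConfig()
        self.ratio_threshold = ratio_threshold
        self.max_shift_fraction = max_shift_fraction

    # exposed for evaluation re-use
    def detect_cues(self, frame: Frame) -> CueFrame:
        """Preprocess one frame and return its retained cue polygons."""
        mask = preprocess_frame(frame, self.preprocess_config)
        polys = find_polygons(mask)
        cues = filter_cues(polys, self.ratio_threshold) if polys else []
        return CueFrame(t=frame.t, cues=cues)

    def _refine_to_reference(self, cue_frames, transforms):
        """Re-solve each chained transform against the reference polygon.

        Pairwise chaining tracks which cue is which, but composing many
        pairwise solves lets small centroid jitter accumulate at the
        non-control cues. The reference frame's cues are visible in
        every frame, so once the chained transform has established the
        correspondence (each mapped cue is matched to the nearest
        reference cue within half the cue spacing), the transform is
        re-estimated in one exact solve frame t -> frame 1. Frames whose
        correspondence cannot be trusted keep their chained transform.
        """
        ref = cue_frames[0]
        if ref.J == 0:
            return transforms
        ref_ordered = order_cues(ref.cues)
        ref_anchors = np.array([p.centroid for p in ref_ordered])
        trust = _min_spacing(ref_anchors) / 2.0
        out = [transforms[0]]
        for t in range(1, len(transforms)):
            chained = transforms[t]
            cf = cue_frames[t]
            if chained is None or cf.J == 0:
                out.append(chained)
                continue
            mapped = chained.apply(cf.anchors)
            cost = cdist(ref_anchors, mapped)
            rows, cols = linear_sum_assignment(cost)
            keep = cost[rows, cols] < trust
            if keep.sum() < 1:
                out.append(chained)
                continue
            sel_ref = [ref_ordered[i] for i in rows[keep]]
            sel_t = [cf.cues[k] for k in cols[keep]]
            try:
                if len(sel_ref) >= 3:
                    pts_ref = np.array([p.centroid for p in sel_ref])
                    pts_t = np.array([p.centroid for p in sel_t])
                    out.append(estimate_affine_lsq(pts_t, pts_ref))
                else:
                    triple_ref, triple_t, _ = _triples_from_matched(
                        sel_ref, sel_t, 1, cf.t
                    )
                    out.append(estimate_affine(triple_t, triple_ref))
            except VicarError:
                out.append(chained)
        return out

    def fit(self) -> RegistrationResult:
        """Run the full pipeline and return the fitted result."""
        T = self.series.T
        max_disp = self.max_shift_fraction * self.series.shape[1]

        cue_frames: list[CueFrame] = []
        elapsed: list[float] = []
        for frame in self.series:
            tic = time.perf_counter()
            cue_frames.append(self.detect_cues(frame))
            elapsed.append(time.perf_counter() - tic)

        partition = partition_intervals([cf.J for cf in cue_frames])

        # pin the control-cue triple once per constant-J run (see
        # _triples_from_matched: a fixed triple makes the chain telescope)
        run_triple: dict[int, tuple[int, int, int] | None] = {}
        for iv in partition.intervals:
            idx = None
            if iv.J >= 3:
                cf0 = cue_frames[iv.t_start - 1]
                centers = np.array([p.centroid for p in order_cues(cf0.cues)])
                idx = spanning_triple_indices(centers)
            for t in range(iv.t_start, iv.t_end + 1):
                run_triple[t] = idx

        pairwise: list[AffineTransform | None] = []
        pair_scenarios: list[str | None] = []
        pair_errors: list[str | None] = []
        for t in range(T - 1):
            tic = time.perf_counter()
            try:
                same_run = cue_frames[t].J == cue_frames[t + 1].J
                tf, scenario = pair_transform(
                    cue_frames[t], cue_frames[t + 1], max_disp,
                    triple_idx=run_triple[t + 1] if same_run else None,
                )
                pairwise.append(tf)
                pair_scenarios.append(scenario)
                pair_errors.append(None)
            except VicarError as exc:
                pairwise.append(None)
                pair_scenarios.append(None)
                pair_errors.append(str(exc))
            elapsed[t + 1] += time.perf_counter() - tic

        if all(tf is None for tf in pairwise):
            raise UnregistrableSeriesError(
                "no consecutive frame pair could be registered: "
                + "; ".join(e for e in pair_errors if e)
            )

        transforms = chain_to_reference(pairwise, partition)
        transforms = self._refine_to_reference(cue_frames, transforms)

        statuses = ["reference"]
        scenarios: list[str] = ["-"]
        for t in range(1, T):
            if transforms[t] is not None:
                statuses.append("registered")
                scenarios.append(pair_scenarios[t - 1] or "-")
            else:
                reason = pair_errors[t - 1] or "broken chain upstream"
                statuses.append(f"unregistered: {reason}")
                scenarios.append("-")

        warped_frames = []
        for t, frame in enumerate(self.series):
            tic = time.perf_counter()
            if transforms[t] is None:
                warped_frames.append(Frame(pixels=frame.pixels.copy(), t=frame.t,
                                           rgb=None if frame.rgb is None else frame.rgb.copy()))
            else:
                warped_frames.append(warp(frame, transforms[t]))
            elapsed[t] += time.perf_counter() - tic

        result = RegistrationResult(
            transforms=transforms,
            registered=FrameSeries(frames=warped_frames),
            cue_frames=cue_frames,
            partition=partition,
            statuses=statuses,
            scenarios=scenarios,
            frame_log=pd.DataFrame(),
            elapsed=elapsed,
        )
        log = result.transforms_frame()
        log["elapsed_s"] = elapsed
        result.frame_log = log
        return result


def register_series(series: FrameSeries, config=None, **kwargs) -> RegistrationResult:
    """Functional wrapper: build a :class:`SeriesRegistration` and fit it.

    ``config`` may be a :class:`PreprocessConfig`; further keyword
    arguments are passed to the model constructor.
    """
    if config is not None:
        kwargs.setdefault("preprocess_config", config)
    return SeriesRegistration(series, **kwargs).fit()
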