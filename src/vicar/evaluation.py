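"""Registration quality metrics and the probabilistic-Hough baseline.

Quality is assessed on the spatial presence of the visual cues: for each
registered frame the root mean square distance (rmsd, px) between its
cue anchors and the matched anchors of the reference frame, averaged
over frames 2..T, and the derived image closeness

    Phi = 100 - rmsd * 100 / r   (percent, r = image rows),

which is 100 for a perfect registration and decreases linearly in rmsd.
Wall-clock seconds per frame are reported alongside but never used as a
quality criterion (they are hardware-dependent).

The baseline is a probabilistic Hough transform (PHT) registration:
Canny edges -> PHT line segments -> a best-fitted four-point subset
(intersections of the fitted lines, i.e. chamber corners) -> rigid
least-squares transform. It requires straight structural edges and
raises a documented :class:`~vicar.errors.BaselineFailureError` on
scenes without them — its characteristic failure mode.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from skimage import feature, transform as sk_transform

from .errors import BaselineFailureError, UnregistrableSeriesError, ValidationError
from .io_frames import Frame, FrameSeries, to_grayscale
from .registration import (
    AffineTransform,
    RegistrationResult,
    SeriesRegistration,
    chain_to_reference,
    partition_intervals,
    warp,
)


@dataclass
class EvalReport:
    """One method's metrics on one series, Table-shaped."""

    method: str
    dataset: str = ""
    per_frame_rmsd: list = field(default_factory=list)
    mean_rmsd: float = float("nan")
    closeness: float = float("nan")
    mean_elapsed: float = float("nan")
    status: str = "ok"

    def to_row(self) -> dict:
        return dict(
            dataset=self.dataset,
            method=self.method,
            mean_elapsed_s=self.mean_elapsed,
            mean_rmsd_px=self.mean_rmsd,
            closeness_pct=self.closeness,
            status=self.status,
        )


def image_closeness(mean_rmsd: float, r: int) -> float:
    """Phi = 100 - rmsd * 100 / r, the closeness score in percent."""
    if r <= 0:
        raise ValidationError(f"image row count must be positive, got {r}")
    if mean_rmsd < 0:
        raise ValidationError("rmsd cannot be negative")
    return 100.0 - mean_rmsd * 100.0 / r


def elapsed_per_frame(samples: Sequence[float]) -> float:
    """Mean wall-clock seconds per frame over the timed samples."""
    if len(samples) == 0:
        raise ValidationError("need at least one timing sample")
    return float(np.mean(samples))


def _frame_rmsd(points: np.ndarray, reference: np.ndarray) -> float | None:
    """RMS Euclidean distance under the optimal min(n, m) matching."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    if points.size == 0 or reference.size == 0:
        return None
    cost = cdist(points, reference)
    rows, cols = linear_sum_assignment(cost)
    return float(np.sqrt(np.mean(cost[rows, cols] ** 2)))


def cue_rmsd(
    registered: Sequence[np.ndarray], reference: np.ndarray
) -> tuple[list, float]:
    """Per-frame and mean rmsd of cue anchors against the reference frame.

    ``registered[t-1]`` holds frame t's cue anchor points after
    registration; matching to the reference anchors is by position
    (optimal assignment), so a relabeling of cues cannot change the
    result. Frames with no matchable cues are excluded from the mean and
    reported as None. The mean runs over frames 2..T: the reference's
    self-comparison is trivially zero and would only dilute it.
    """
    per_frame: list[float | None] = []
    for pts in registered:
        per_frame.append(_frame_rmsd(pts, reference))
    tail = [v for v in per_frame[1:] if v is not None]
    mean = float(np.mean(tail)) if tail else float("nan")
    return per_frame, mean


def ground_truth_rmsd(result: RegistrationResult, truth) -> float:
    """Mean cue-anchor error of the fitted transforms against ground truth.

    For every registered frame t the fitted transform is applied to the
    true cue anchors of frame t; the rms distance to the true reference
    anchors, matched by position, is averaged over frames 2..T.
    """
    vals = []
    ref = truth.cue_anchors[0]
    for t in range(1, len(result.transforms)):
        tf = result.transforms[t]
        if tf is None:
            continue
        v = _frame_rmsd(tf.apply(truth.cue_anchors[t]), ref)
        if v is not None:
            vals.append(v)
    if not vals:
        raise ValidationError("no registered frame has matchable ground-truth anchors")
    return float(np.mean(vals))


# ---------------------------------------------------------------------
# PHT baseline
# ---------------------------------------------------------------------

def _merge_lines(segments: list) -> list[tuple[float, float, float]]:
    """Collapse near-duplicate segments into (theta, rho, support) lines."""
    lines: list[list[float]] = []  # theta, rho, support length
    fold = np.pi - np.deg2rad(2.5)
    for (x0, y0), (x1, y1) in segments:
        dx, dy = x1 - x0, y1 - y0
        length = float(np.hypot(dx, dy))
        if length == 0:
            continue
        # canonical orientation in (-2.5 deg, 177.5 deg]: segments traced in
        # either direction land on the same (theta, rho) representation
        theta = float(np.arctan2(dy, dx)) % np.pi
        if theta > fold:
            theta -= np.pi
        # signed offset of the line x sin(theta) - y cos(theta) = rho
        rho = float(x0 * np.sin(theta) - y0 * np.cos(theta))
        merged = False
        for ln in lines:
            if abs(ln[0] - theta) < np.deg2rad(5.0) and abs(ln[1] - rho) < 12.0:
                w = ln[2] + length
                ln[0] = (ln[0] * ln[2] + theta * length) / w
                ln[1] = (ln[1] * ln[2] + rho * length) / w
                ln[2] = w
                merged = True
                break
        if not merged:
            lines.append([theta, rho, length])
    return [tuple(ln) for ln in lines]


def _line_intersections(
    lines: list[tuple[float, float, float]], shape: tuple[int, int]
) -> np.ndarray:
    """Intersection points of non-parallel line pairs, inside the image."""
    r, c = shape
    pts = []
    for i in range(len(lines)):
        for j in range(i + 1, len(lines)):
            t1, r1, w1 = lines[i]
            t2, r2, w2 = lines[j]
            if abs(np.sin(t1 - t2)) < np.sin(np.deg2rad(30.0)):
                continue  # nearly parallel: intersection is unstable
            # line k: x sin(tk) - y cos(tk) = rho_k
            A = np.array([[np.sin(t1), -np.cos(t1)], [np.sin(t2), -np.cos(t2)]])
            try:
                x, y = np.linalg.solve(A, [r1, r2])
            except np.linalg.LinAlgError:
                continue
            if 0 <= x < c and 0 <= y < r:
                pts.append((w1 + w2, x, y))
    pts.sort(key=lambda p: (-p[0], p[2], p[1]))
    return np.array([(x, y) for _, x, y in pts]) if pts else np.empty((0, 2))


def _pht_points(
    gray: np.ndarray,
    t: int,
    rng: np.random.Generator,
    canny_sigma: float,
    canny_low: float,
    canny_high: float,
    line_length: int,
    line_gap: int,
    hough_threshold: int,
    n_points: int,
) -> np.ndarray:
    edges = feature.canny(
        gray.astype(float), sigma=canny_sigma,
        low_threshold=canny_low, high_threshold=canny_high,
    )
    segments = sk_transform.probabilistic_hough_line(
        edges, threshold=hough_threshold, line_length=line_length,
        line_gap=line_gap, rng=rng,
    )
    lines = _merge_lines(segments)
    if len(lines) < 2:
        raise BaselineFailureError(t)
    pts = _line_intersections(lines, gray.shape)
    if len(pts) < n_points:
        raise BaselineFailureError(
            t, f"only {len(pts)} stable line intersections, need {n_points}"
        )
    pts = pts[:n_points]
    order = np.lexsort((pts[:, 0], pts[:, 1]))
    return pts[order]


class HoughRegistration:
    """PHT baseline registration model; ``fit()`` mirrors the cue model.

    Per frame: Canny edges, probabilistic Hough line segments, duplicate
    lines merged, the four strongest line-pair intersections retained as
    feature points. Points are matched between consecutive frames by
    optimal assignment and a rigid (rotation + translation, unit scale)
    transform is fitted by least squares, then chained to the reference.
    """

    def __init__(
        self,
        series: FrameSeries,
        canny_sigma: float = 3.0,
        canny_low: float = 6.0,
        canny_high: float = 14.0,
        line_length: int = 100,
        line_gap: int = 3,
        hough_threshold: int = 30,
        n_points: int = 4,
        seed: int = 0,
    ):
        if series.T < 2:
            raise ValidationError("registration needs at least two frames")
        self.series = series
        self.canny_sigma = canny_sigma
        self.canny_low = canny_low
        self.canny_high = canny_high
        self.line_length = line_length
        self.line_gap = line_gap
        self.hough_threshold = hough_threshold
        self.n_points = n_points
        self.seed = seed

    def fit(self) -> RegistrationResult:
        T = self.series.T
        points: list[np.ndarray] = []
        elapsed: list[float] = []
        for i, frame in enumerate(self.series):
            tic = time.perf_counter()
            gray = to_grayscale(frame).pixels
            rng = np.random.default_rng([self.seed, i])
            points.append(
                _pht_points(
                    gray, frame.t, rng, self.canny_sigma, self.canny_low,
                    self.canny_high, self.line_length, self.line_gap,
                    self.hough_threshold, self.n_points,
                )
            )
            elapsed.append(time.perf_counter() - tic)

        pairwise: list[AffineTransform | None] = []
        for t in range(T - 1):
            tic = time.perf_counter()
            a, b = points[t], points[t + 1]
            rows, cols = linear_sum_assignment(cdist(a, b))
            est = sk_transform.EuclideanTransform.from_estimate(b[cols], a[rows])
            if not est:
                raise UnregistrableSeriesError(f"rigid fit failed at pair ({t + 1}, {t + 2})")
            pairwise.append(AffineTransform(est.params[:2]))
            elapsed[t + 1] += time.perf_counter() - tic

        transforms = chain_to_reference(pairwise)
        warped = []
        for t, frame in enumerate(self.series):
            tic = time.perf_counter()
            warped.append(warp(frame, transforms[t]))
            elapsed[t] += time.perf_counter() - tic

        from .cue_selection import CueFrame

        result = RegistrationResult(
            transforms=transforms,
            registered=FrameSeries(frames=warped),
            cue_frames=[CueFrame(t=i + 1, cues=[]) for i in range(T)],
            partition=partition_intervals([self.n_points] * T),
            statuses=["reference"] + ["registered"] * (T - 1),
            scenarios=["-"] * T,
            frame_log=pd.DataFrame(),
            elapsed=elapsed,
            method="PHT",
        )
        result.frame_log = result.transforms_frame().assign(elapsed_s=elapsed)
        return result


def pht_register(series: FrameSeries, config: dict | None = None, **kwargs) -> RegistrationResult:
    """Functional wrapper over :class:`HoughRegistration`."""
    opts = dict(config or {})
    opts.update(kwargs)
    return HoughRegistration(series, **opts).fit()


# ---------------------------------------------------------------------
# benchmarking
# ---------------------------------------------------------------------

def evaluate_registration(
    result: RegistrationResult,
    model: SeriesRegistration | None = None,
    dataset: str = "",
) -> EvalReport:
    """Score a fitted registration by re-detecting cues on the warped frames.

    Cues are detected in every registered frame (the same preprocessing
    the registration used) and their anchors compared with the reference
    frame's cue anchors — the score reflects what is actually visible in
    the output images, not internal state.
    """
    model = model or SeriesRegistration(result.registered)
    anchors = [model.detect_cues(f).anchors for f in result.registered]
    per_frame, mean_rmsd = cue_rmsd(anchors, anchors[0])
    r = result.registered.shape[0]
    return EvalReport(
        method=result.method,
        dataset=dataset,
        per_frame_rmsd=per_frame,
        mean_rmsd=mean_rmsd,
        closeness=image_closeness(mean_rmsd, r),
        mean_elapsed=elapsed_per_frame(result.elapsed),
    )


def benchmark(
    series: FrameSeries,
    methods: Sequence[str] = ("vicar", "pht"),
    dataset: str = "series",
    preprocess_config=None,
    seed: int = 0,
) -> list[EvalReport]:
    """Run each method on the series and return Table-shaped reports.

    A method that raises its documented failure is recorded with status
    ``"failed: ..."`` — never as a zero score.
    """
    if not methods:
        raise ValidationError("need at least one method")
    reports = []
    for name in methods:
        name = name.lower()
        try:
            if name == "vicar":
                model = SeriesRegistration(series, preprocess_config=preprocess_config)
                reports.append(evaluate_registration(model.fit(), model, dataset))
            elif name == "pht":
                result = HoughRegistration(series, seed=seed).fit()
                model = SeriesRegistration(series, preprocess_config=preprocess_config)
                reports.append(evaluate_registration(result, model, dataset))
            else:
                raise ValidationError(f"unknown method {name!r}")
        except (BaselineFailureError, UnregistrableSeriesError) as exc:
            reports.append(
                EvalReport(method="PHT" if name == "pht" else "ViCAR",
                           dataset=dataset, status=f"failed: {exc}")
            )
    return reports


def report_frame(reports: Sequence[EvalReport]) -> pd.DataFrame:
    """Benchmark reports as one tidy table (CSV-serializable)."""
    return pd.DataFrame([r.to_row() for r in reports])


def reports_from_frame(df: pd.DataFrame) -> list[EvalReport]:
    """Inverse of :func:`report_frame` (per-frame details are not stored)."""
    out = []
    for row in df.itertuples(index=False):
        out.append(
            EvalReport(
                method=row.method, dataset=row.dataset,
                mean_rmsd=float(row.mean_rmsd_px),
                closeness=float(row.closeness_pct),
                mean_elapsed=float(row.mean_elapsed_s),
                status=row.status,
            )
        )
    return out


def format_closeness(phi: float) -> str:
    """One-decimal percent, the reporting convention for Phi."""
    return f"{phi:.1f}"


def format_rmsd(rmsd: float) -> str:
    """One-significant-digit scientific notation, the rmsd reporting style."""
    return f"{rmsd:.0e}"
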