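"""Synthetic microfluidics scenes with ground-truth drift.

The generator emulates the salient properties of real chamber series:
square-like dark spacers fixed in the chamber frame, a bacterial colony
that doubles per generation (a bright, growing, structured distractor
that plays no role in the registration ground truth), a smooth
background illumination gradient, per-frame Gaussian sensor noise, and a
slow rigid drift of the whole field modelled as a cumulative random walk
in translation and rotation (thermal drift, not i.i.d. jumps). Frame t's
content is frame 1's content mapped by the ground-truth transform of t;
noise is added after the geometric mapping, independently per frame,
because sensor noise is not transformed.

Scenes are bit-reproducible: all randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import draw

from .errors import ValidationError
from .io_frames import Frame, FrameSeries
from .registration import AffineTransform

_GOLDEN_ANGLE = 2.399963229728653


@dataclass
class SceneConfig:
    """Study conditions of a synthetic chamber scene.

    Defaults reproduce the reference imaging setup: a 1004 x 1002 px
    field, four spacers of side 115-140 px placed in the central region
    (sized so the detected cue polygon clears the 0.05 ratio filter),
    a colony growing from one cell with a doubling period of 10 frames
    capped at 300 individuals, additive Gaussian noise of sigma 8
    intensity levels, and a random-walk drift of at most 3 px translation
    and 0.3 degrees rotation per frame.
    """

    rows: int = 1004
    cols: int = 1002
    n_frames: int = 30
    # spacers (the cues)
    n_spacers: int = 4
    spacer_side_min: float = 115.0
    spacer_side_max: float = 140.0
    spacer_shape: str = "square"  # "square" | "disk"
    spacer_contrast: float = 90.0
    spacer_ring_radius: float = 165.0
    # background and noise
    background_level: float = 150.0
    gradient_amplitude: float = 12.0
    noise_sigma: float = 8.0
    edge_sigma: float = 1.0
    # colony (structured distractor)
    colony_initial_cells: int = 1
    doubling_period: int = 10
    colony_cap: int = 300
    cell_length: float = 14.0
    cell_width: float = 6.0
    colony_brightness: float = 60.0
    # drift
    drift_mode: str = "random_walk"  # "random_walk" | "linear" | "none"
    max_step_px: float = 3.0
    max_step_deg: float = 0.3
    linear_step_px: tuple[float, float] = (2.0, 1.0)
    # optional features
    cue_count_schedule: list[int] | None = None
    chamber_walls: bool = False
    wall_half_extent: float = 330.0
    wall_thickness: float = 4.0
    wall_contrast: float = 90.0
    rgb: bool = False

    def __post_init__(self) -> None:
        if min(self.rows, self.cols) < 256:
            raise ValidationError("canvas must be at least 256 x 256")
        if self.n_spacers < 1:
            raise ValidationError("need at least one spacer")
        if self.n_frames < 1:
            raise ValidationError("need at least one frame")
        if self.spacer_shape not in ("square", "disk"):
            raise ValidationError(f"unknown spacer shape {self.spacer_shape!r}")
        if self.drift_mode not in ("random_walk", "linear", "none"):
            raise ValidationError(f"unknown drift mode {self.drift_mode!r}")
        if self.cue_count_schedule is not None:
            if len(self.cue_count_schedule) != self.n_frames:
                raise ValidationError("cue_count_schedule must have one entry per frame")
            if max(self.cue_count_schedule) > self.n_spacers:
                raise ValidationError("cue_count_schedule exceeds the number of spacers")
            if min(self.cue_count_schedule) < 0:
                raise ValidationError("cue_count_schedule entries must be >= 0")


@dataclass
class Spacer:
    center: np.ndarray  # (x, y) in reference coordinates
    side: float
    angle: float  # orientation of a square spacer, radians
    shape: str = "square"

    @property
    def vertices(self) -> np.ndarray:
        """Corner coordinates (squares) or a 32-gon approximation (disks)."""
        if self.shape == "square":
            h = self.side / 2.0
            base = np.array([[-h, -h], [h, -h], [h, h], [-h, h]])
            ca, sa = np.cos(self.angle), np.sin(self.angle)
            rot = np.array([[ca, -sa], [sa, ca]])
            return base @ rot.T + self.center
        theta = np.linspace(0.0, 2 * np.pi, 32, endpoint=False)
        return self.center + (self.side / 2.0) * np.column_stack(
            [np.cos(theta), np.sin(theta)]
        )


@dataclass
class SyntheticScene:
    """A fully specified scene: geometry, trajectory and noise, from one seed."""

    config: SceneConfig
    seed: int
    spacers: list[Spacer]
    trajectory: list[AffineTransform]
    cell_offsets: np.ndarray  # (cap, 2) offsets of colony cells from center
    cell_angles: np.ndarray

    @property
    def center(self) -> tuple[float, float]:
        return (self.config.cols / 2.0, self.config.rows / 2.0)

    def visible_spacers(self, t: int) -> list[Spacer]:
        """Spacers rendered in frame t (1-based), honoring the schedule."""
        k = (
            self.config.cue_count_schedule[t - 1]
            if self.config.cue_count_schedule is not None
            else self.config.n_spacers
        )
        return self.spacers[:k]

    def colony_count(self, t: int) -> int:
        n = self.config.colony_initial_cells * 2 ** ((t - 1) // self.config.doubling_period)
        return min(n, self.config.colony_cap)


@dataclass
class GroundTruth:
    """Exact per-frame transforms, cue anchors and colony positions."""

    transforms: list[AffineTransform]
    cue_anchors: list[np.ndarray]  # per frame, (J_t, 2) spacer centers
    colony_positions: list[np.ndarray]


def make_scene(config: SceneConfig | None = None, seed: int = 0, **overrides) -> SyntheticScene:
    """Build a deterministic scene for ``(config, seed)``.

    Spacers are placed on a ring around the image center (angles evenly
    spaced with a small jitter) so they stay inside the central circular
    mask region for the whole drift trajectory; the colony seed sits at
    the center. A configuration whose spacers would overlap the colony's
    final extent is rejected.
    """
    config = replace(config, **overrides) if config is not None else SceneConfig(**overrides)
    rng = np.random.default_rng(seed)
    cx, cy = config.cols / 2.0, config.rows / 2.0

    # colony extent at the final frame, for the overlap check
    n_final = min(
        config.colony_cap,
        config.colony_initial_cells
        * 2 ** ((config.n_frames - 1) // config.doubling_period),
    )
    spacing = 1.1 * config.cell_width
    colony_radius = spacing * np.sqrt(n_final) + config.cell_length

    # spacers on a jittered ring
    spacers: list[Spacer] = []
    angles = (
        2 * np.pi * (np.arange(config.n_spacers) + 0.5) / config.n_spacers
        + rng.uniform(-0.08, 0.08, config.n_spacers)
    )
    radii = config.spacer_ring_radius + rng.uniform(-10, 10, config.n_spacers)
    sides = rng.uniform(config.spacer_side_min, config.spacer_side_max, config.n_spacers)
    tilts = rng.uniform(-0.15, 0.15, config.n_spacers)
    for ang, rad, side, tilt in zip(angles, radii, sides, tilts):
        center = np.array([cx + rad * np.cos(ang), cy + rad * np.sin(ang)])
        if rad - side / 2.0 < colony_radius:
            raise ValidationError(
                f"infeasible scene: spacer at ring radius {rad:.0f} px overlaps the "
                f"colony (final extent ~{colony_radius:.0f} px)"
            )
        spacers.append(Spacer(center=center, side=float(side), angle=float(tilt),
                              shape=config.spacer_shape))

    # rigid drift trajectory (trajectory[0] is the identity)
    trajectory = [AffineTransform.identity()]
    angle, shift = 0.0, np.zeros(2)
    max_rad = np.deg2rad(config.max_step_deg)
    for _ in range(1, config.n_frames):
        if config.drift_mode == "random_walk":
            angle += rng.uniform(-max_rad, max_rad)
            shift = shift + rng.uniform(-config.max_step_px, config.max_step_px, 2)
        elif config.drift_mode == "linear":
            shift = shift + np.asarray(config.linear_step_px, dtype=float)
        trajectory.append(
            AffineTransform.rigid(angle, shift[0], shift[1], center=(cx, cy))
        )

    # colony layout: sunflower-spiral cell packing around the center
    k = np.arange(config.colony_cap)
    cell_offsets = (
        spacing * np.sqrt(k)[:, None]
        * np.column_stack([np.cos(k * _GOLDEN_ANGLE), np.sin(k * _GOLDEN_ANGLE)])
    )
    cell_angles = rng.uniform(0.0, np.pi, config.colony_cap)

    return SyntheticScene(
        config=config, seed=seed, spacers=spacers, trajectory=trajectory,
        cell_offsets=cell_offsets, cell_angles=cell_angles,
    )


def _draw_polygon(indicator: np.ndarray, verts: np.ndarray) -> None:
    rr, cc = draw.polygon(verts[:, 1], verts[:, 0], shape=indicator.shape)
    indicator[rr, cc] = 1.0


def _render_frame(scene: SyntheticScene, t: int, noise_rng: np.random.Generator):
    cfg = scene.config
    tf = scene.trajectory[t - 1]
    shape = (cfg.rows, cfg.cols)
    cx, cy = scene.center

    # illumination gradient, fixed in chamber coordinates
    inv = tf.invert()
    yy, xx = np.mgrid[0 : cfg.rows, 0 : cfg.cols]
    u = inv.matrix[0, 0] * xx + inv.matrix[0, 1] * yy + inv.matrix[0, 2]
    v = inv.matrix[1, 0] * xx + inv.matrix[1, 1] * yy + inv.matrix[1, 2]
    img = cfg.background_level + cfg.gradient_amplitude * (
        (u / cfg.cols - 0.5) + 0.5 * (v / cfg.rows - 0.5)
    )

    # dark structures: spacers and, separately, optional chamber walls
    dark = np.zeros(shape, dtype=np.float64)
    for sp in scene.visible_spacers(t):
        _draw_polygon(dark, tf.apply(sp.vertices))
    img -= cfg.spacer_contrast * gaussian_filter(dark, cfg.edge_sigma)
    if cfg.chamber_walls:
        h, w = cfg.wall_half_extent, cfg.wall_thickness
        outer = np.array([[-h, -h], [h, -h], [h, h], [-h, h]]) + (cx, cy)
        inner = np.array([[-h + w, -h + w], [h - w, -h + w], [h - w, h - w], [-h + w, h - w]]) + (cx, cy)
        ring = np.zeros(shape, dtype=np.float64)
        _draw_polygon(ring, tf.apply(outer))
        hole = np.zeros(shape, dtype=np.float64)
        _draw_polygon(hole, tf.apply(inner))
        img -= cfg.wall_contrast * gaussian_filter(np.clip(ring - hole, 0, 1), cfg.edge_sigma)

    # bright structure: the colony
    n_cells = scene.colony_count(t)
    centers = tf.apply(scene.cell_offsets[:n_cells] + (cx, cy))
    bright = np.zeros(shape, dtype=np.float64)
    rot = tf.rotation_angle
    for (x, y), ang in zip(np.atleast_2d(centers), scene.cell_angles[:n_cells]):
        rr, cc = draw.ellipse(
            y, x, cfg.cell_width / 2.0, cfg.cell_length / 2.0,
            shape=shape, rotation=ang + rot,
        )
        bright[rr, cc] = 1.0
    bright = gaussian_filter(bright, cfg.edge_sigma)
    img += cfg.colony_brightness * bright

    if cfg.noise_sigma > 0:
        img = img + noise_rng.normal(0.0, cfg.noise_sigma, shape)
    gray = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    if not cfg.rgb:
        return Frame(pixels=gray, t=t), centers
    fluor = np.clip(np.rint(img + 40.0 * bright), 0, 255).astype(np.uint8)
    rgb = np.stack([gray, fluor, gray], axis=-1)
    from .io_frames import _luminance

    return Frame(pixels=_luminance(rgb), t=t, rgb=rgb), centers


def render_series(scene: SyntheticScene) -> tuple[FrameSeries, GroundTruth]:
    """Rasterize every frame and return the series with its ground truth.

    Geometry is transformed analytically (polygon vertices mapped by the
    true transform, then rasterized), so the recorded cue anchors are
    exact. Two renders of the same scene are bit-identical.
    """
    cfg = scene.config
    frames: list[Frame] = []
    anchors: list[np.ndarray] = []
    colony: list[np.ndarray] = []
    for t in range(1, cfg.n_frames + 1):
        noise_rng = np.random.default_rng([scene.seed, t])
        frame, centers = _render_frame(scene, t, noise_rng)
        frames.append(frame)
        tf = scene.trajectory[t - 1]
        sp_centers = np.array([sp.center for sp in scene.visible_spacers(t)])
        anchors.append(tf.apply(sp_centers) if len(sp_centers) else np.empty((0, 2)))
        colony.append(np.atleast_2d(centers))
    truth = GroundTruth(
        transforms=list(scene.trajectory),
        cue_anchors=anchors,
        colony_positions=colony,
    )
    return FrameSeries(frames=frames), truth


def ground_truth_table(truth: GroundTruth) -> "pd.DataFrame":
    """(t, rotation_rad, tx, ty) rows for the ground-truth CSV."""
    import pandas as pd

    rows = []
    for i, tf in enumerate(truth.transforms):
        rows.append(
            dict(t=i + 1, rotation_rad=tf.rotation_angle,
                 tx=tf.matrix[0, 2], ty=tf.matrix[1, 2])
        )
    return pd.DataFrame(rows)


def anchors_table(truth: GroundTruth) -> "pd.DataFrame":
    """(t, cue, x, y) rows for the spacer-anchor CSV."""
    import pandas as pd

    rows = []
    for i, pts in enumerate(truth.cue_anchors):
        for j, (x, y) in enumerate(np.atleast_2d(pts)):
            rows.append(dict(t=i + 1, cue=j, x=x, y=y))
    return pd.DataFrame(rows)
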