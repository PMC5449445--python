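"""Seven-stage preprocessing turning a raw frame into a binary cue mask.

The chamber's structural spacers are low-contrast, dark, square-like
objects sitting in a noisy, unevenly lit background. The pipeline

    (a) grayscale -> (b) bilateral denoise -> (c) CLAHE ->
    (d) adaptive mean threshold -> (e) dilation ->
    (f) border clearing -> (g) circular masking

suppresses noise while keeping edges (b), boosts local contrast (c),
binarizes against the local illumination level (d), closes small gaps in
the spacer outlines (e), and finally discards anything touching the image
border (f) or leaving the central circular region (g) — the spacers are
chamber-fixed and central, so whatever survives is a cue candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import exposure, measure

from .errors import PreprocessError, ValidationError
from .io_frames import Frame, to_grayscale


@dataclass
class BinaryMask:
    """Boolean foreground grid with the time index of its source frame."""

    pixels: np.ndarray
    t: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != bool:
            if not np.isin(self.pixels, (0, 1)).all():
                raise ValidationError("mask values must be binary")
            self.pixels = self.pixels.astype(bool)
        if self.pixels.ndim != 2:
            raise ValidationError("mask must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class PreprocessConfig:
    """Tunables of stages (b)-(g).

    Defaults are the moderate values that work on 1004x1002 px chamber
    frames: sigma_spatial = sigma_range = 75, neighborhood diameter 10 px,
    CLAHE tile 10x10 px with contrast limit 2, threshold block 11x11 px
    minus a constant 2, 3x3 dilation, and a central circle of diameter
    0.6 r. ``invert=True`` makes pixels *below* the local mean foreground,
    capturing dark spacers on a brighter background; flip it for chambers
    with bright structures.
    """

    sigma_spatial: float = 75.0
    sigma_range: float = 75.0
    bilateral_diameter: int = 10
    clahe_tile: int = 10
    clahe_clip: float = 2.0
    thresh_block: int = 11
    thresh_const: float = 2.0
    dilation_window: int = 3
    mask_diameter_fraction: float = 0.6
    invert: bool = False

    def __post_init__(self) -> None:
        if self.thresh_block < 3 or self.thresh_block % 2 == 0:
            raise ValidationError(f"thresh_block must be odd and >= 3, got {self.thresh_block}")
        if self.dilation_window < 1 or self.dilation_window % 2 == 0:
            raise ValidationError(
                f"dilation_window must be odd and >= 1, got {self.dilation_window}"
            )
        if not 0 < self.mask_diameter_fraction <= 1.5:
            raise ValidationError(
                f"mask_diameter_fraction must be in (0, 1.5], got {self.mask_diameter_fraction}"
            )
        if self.bilateral_diameter < 1:
            raise ValidationError("bilateral_diameter must be >= 1")
        if self.clahe_tile < 1:
            raise ValidationError("clahe_tile must be >= 1")


def _require_single_channel(frame: Frame) -> np.ndarray:
    if frame.rgb is not None:
        raise ValidationError("expected a single-channel frame; convert with to_grayscale first")
    return frame.pixels


def _bilateral_offsets(diameter: int) -> list[tuple[int, int]]:
    radius = diameter / 2.0
    r_int = int(np.floor(radius))
    offs = []
    for dr in range(-r_int, r_int + 1):
        for dc in range(-r_int, r_int + 1):
            if dr * dr + dc * dc <= radius * radius:
                offs.append((dr, dc))
    return offs


def denoise_bilateral(frame: Frame, cfg: PreprocessConfig) -> Frame:
    """Edge-preserving smoothing (Tomasi-Manduchi bilateral filter).

    Each output pixel is a normalized weighted mean over the circular
    neighborhood of diameter ``bilateral_diameter``; the weight of a
    neighbor is ``exp(-d^2 / 2 sigma_spatial^2) * exp(-dv^2 / 2 sigma_range^2)``
    with ``d`` the spatial distance and ``dv`` the intensity difference.
    Borders are reflect-padded. Because intensities are 8-bit, the range
    kernel is a 256-entry lookup table, which keeps the filter exact and
    fast (vectorized shift-and-accumulate over ~pi (delta/2)^2 offsets).
    """
    img = _require_single_channel(frame)
    src = np.asarray(img, dtype=np.float32)
    if src.min() < 0 or src.max() > 255:
        raise ValidationError("bilateral filter expects intensities in [0, 255]")
    u8 = np.rint(src).astype(np.int16)

    offsets = _bilateral_offsets(cfg.bilateral_diameter)
    rad = max(max(abs(dr), abs(dc)) for dr, dc in offsets)
    pad = np.pad(u8, rad, mode="reflect")

    range_lut = np.exp(
        -(np.arange(256, dtype=np.float32) ** 2) / (2.0 * cfg.sigma_range**2)
    ).astype(np.float32)

    r, c = u8.shape
    num = np.zeros((r, c), dtype=np.float32)
    den = np.zeros((r, c), dtype=np.float32)
    for dr, dc in offsets:
        sw = np.float32(np.exp(-(dr * dr + dc * dc) / (2.0 * cfg.sigma_spatial**2)))
        shifted = pad[rad + dr : rad + dr + r, rad + dc : rad + dc + c]
        w = range_lut[np.abs(shifted - u8)] * sw
        num += w * shifted
        den += w
    out = np.rint(num / den).astype(np.uint8)
    return Frame(pixels=out, t=frame.t)


def clahe(frame: Frame, cfg: PreprocessConfig) -> Frame:
    """Contrast-limited adaptive histogram equalization on small tiles.

    Histogram bins above the contrast limit are clipped and the excess
    redistributed uniformly; tile mappings are blended bilinearly. The
    contrast limit follows the bin-ceiling convention (limit x tile
    pixels / bins); a constant image is returned unchanged since it has
    no contrast to stretch.
    """
    img = _require_single_channel(frame)
    r, c = img.shape
    if cfg.clahe_tile > min(r, c):
        raise ValidationError(
            f"CLAHE tile size {cfg.clahe_tile} exceeds image dimensions {(r, c)}"
        )
    arr = np.asarray(img, dtype=np.uint8)
    if arr.max() == arr.min():
        return Frame(pixels=arr.copy(), t=frame.t)
    nbins = 256
    out = exposure.equalize_adapthist(
        arr, kernel_size=cfg.clahe_tile, clip_limit=cfg.clahe_clip / nbins, nbins=nbins
    )
    return Frame(pixels=np.rint(out * 255.0).astype(np.uint8), t=frame.t)


def adaptive_mean_threshold(frame: Frame, cfg: PreprocessConfig) -> BinaryMask:
    """Binarize against the local block mean minus a small constant.

    The threshold at each pixel is the mean over the ``thresh_block`` x
    ``thresh_block`` neighborhood (reflect-padded) minus ``thresh_const``;
    subtracting the constant keeps flat background noise out of the
    foreground. With ``invert=True`` (default) a pixel is foreground when
    *below* the threshold, which captures dark spacer outlines.
    """
    img = _require_single_channel(frame)
    if cfg.thresh_block % 2 == 0:
        raise ValidationError("threshold block size must be odd")
    local_mean = ndimage.uniform_filter(
        np.asarray(img, dtype=np.float64), size=cfg.thresh_block, mode="reflect"
    )
    thresh = local_mean - cfg.thresh_const
    fg = img < thresh if cfg.invert else img > thresh
    return BinaryMask(pixels=fg, t=frame.t)


def dilate(mask: BinaryMask, cfg: PreprocessConfig) -> BinaryMask:
    """Morphological dilation with a square window; foreground never shrinks."""
    w = cfg.dilation_window
    out = ndimage.binary_dilation(mask.pixels, structure=np.ones((w, w), dtype=bool))
    return BinaryMask(pixels=out, t=mask.t)


def clear_border(mask: BinaryMask) -> BinaryMask:
    """Remove every 8-connected component touching any image border."""
    labels = measure.label(mask.pixels, connectivity=2)
    border_labels = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    border_labels = border_labels[border_labels != 0]
    out = mask.pixels & ~np.isin(labels, border_labels)
    return BinaryMask(pixels=out, t=mask.t)


def circle_region(shape: tuple[int, int], diameter_fraction: float) -> np.ndarray:
    """Boolean disk of diameter ``diameter_fraction * rows`` centered at (r/2, c/2)."""
    r, c = shape
    radius = diameter_fraction * r / 2.0
    yy, xx = np.ogrid[:r, :c]
    return (yy - r / 2.0) ** 2 + (xx - c / 2.0) ** 2 <= radius**2


def apply_circle_mask(mask: BinaryMask, cfg: PreprocessConfig) -> BinaryMask:
    """Drop whole components that leave the central circular region.

    The decision is per component, not per pixel: a component with even one
    pixel outside the circle is removed entirely, so no artificial polygon
    fragments are created at the circle boundary. This keeps only cues in
    the central image area, where the chamber spacers live.
    """
    inside = circle_region(mask.shape, cfg.mask_diameter_fraction)
    labels = measure.label(mask.pixels, connectivity=2)
    outside_labels = np.unique(labels[~inside])
    outside_labels = outside_labels[outside_labels != 0]
    out = mask.pixels & ~np.isin(labels, outside_labels)
    return BinaryMask(pixels=out, t=mask.t)


_STAGES = (
    ("grayscale", lambda f, cfg: to_grayscale(f)),
    ("bilateral", denoise_bilateral),
    ("clahe", clahe),
    ("threshold", adaptive_mean_threshold),
    ("dilate", dilate),
    ("clear_border", lambda m, cfg: clear_border(m)),
    ("circle_mask", apply_circle_mask),
)


def preprocess_frame(
    frame: Frame,
    cfg: PreprocessConfig | None = None,
    debug_sink=None,
) -> BinaryMask:
    """Run stages (a)-(g) in order; deterministic for fixed input and config.

    ``debug_sink``, if given, is called after every stage with
    ``(stage_name, intermediate)`` so the per-stage panel can be dumped.
    Stage failures are re-raised as :class:`PreprocessError` naming the
    stage.
    """
    cfg = cfg or PreprocessConfig()
    cur: Frame | BinaryMask = frame
    for name, fn in _STAGES:
        try:
            cur = fn(cur, cfg)
        except PreprocessError:
            raise
        except Exception as exc:
            raise PreprocessError(name, str(exc)) from exc
        if debug_sink is not None:
            debug_sink(name, cur)
    return cur  # type: ignore[return-value]


def with_overrides(cfg: PreprocessConfig, **kwargs) -> PreprocessConfig:
    """Copy of ``cfg`` with the given fields replaced (validated)."""
    return replace(cfg, **kwargs)
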