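"""Reading, writing and colour conversion of ordered TIFF frame series.

Conventions used package-wide (stated once, here):

* pixel grids are indexed ``(row, col)``, 0-based, origin at the top-left;
* when interfacing with transform math, ``x ≡ col`` and ``y ≡ row``;
* grayscale intensities live in ``[0, 255]`` (8-bit-per-channel semantics);
* the caller-supplied path order is authoritative — no lexicographic
  re-sorting is applied, so ``frame_2`` vs ``frame_10`` can never be
  silently misordered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .errors import FrameIOError, ValidationError

# ITU-R 601 luminance weights for the RGB -> grayscale transformation.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class Frame:
    """One image of the series: a grayscale grid plus an optional RGB payload.

    Parameters
    ----------
    pixels : ndarray, shape (r, c)
        Grayscale intensities in [0, 255].
    t : int
        1-based time index within the series.
    rgb : ndarray, shape (r, c, 3), optional
        The original colour payload, if the source image was RGB.
    """

    pixels: np.ndarray
    t: int
    rgb: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValidationError(
                f"frame pixels must be a non-empty 2D grid, got shape {self.pixels.shape}"
            )
        if self.t < 1:
            raise ValidationError(f"time index must be >= 1, got {self.t}")
        if self.rgb is not None:
            self.rgb = np.asarray(self.rgb)
            if self.rgb.shape != self.pixels.shape + (3,):
                raise ValidationError(
                    f"rgb payload shape {self.rgb.shape} does not match "
                    f"pixel grid {self.pixels.shape}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class FrameSeries:
    """An ordered, contiguous series of frames sharing one geometry."""

    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValidationError("no frames")
        shape = self.frames[0].shape
        for i, f in enumerate(self.frames):
            if f.shape != shape:
                raise ValidationError(
                    f"frame at index {i} has shape {f.shape}, expected {shape}"
                )
            if f.t != i + 1:
                raise ValidationError(
                    f"time indices must be contiguous 1..T; frame at index {i} has t={f.t}"
                )

    @property
    def T(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]


def _as_frame(arr: np.ndarray, t: int, path=None) -> Frame:
    if arr.ndim == 2:
        return Frame(pixels=arr, t=t)
    if arr.ndim == 3 and arr.shape[-1] == 3:
        return Frame(pixels=_luminance(arr), t=t, rgb=arr)
    raise ValidationError(
        f"unsupported image shape {arr.shape}" + (f" in {path}" if path else "")
    )


def _luminance(rgb: np.ndarray) -> np.ndarray:
    wr, wg, wb = LUMA_WEIGHTS
    y = wr * rgb[..., 0] + wg * rgb[..., 1] + wb * rgb[..., 2]
    return np.rint(y).astype(np.uint8)


def read_series(paths: Sequence[str | Path]) -> FrameSeries:
    """Read an ordered list of TIFF files into a :class:`FrameSeries`.

    Frames are ordered by list position; time indices are assigned 1..T.
    A file that cannot be decoded raises :class:`FrameIOError` naming the
    path; a frame whose dimensions differ from the first raises
    :class:`ValidationError` naming the offending index.
    """
    if not paths:
        raise ValidationError("no frames")
    frames: list[Frame] = []
    for i, p in enumerate(paths):
        p = Path(p)
        try:
            arr = tifffile.imread(p)
        except (OSError, ValueError) as exc:
            raise FrameIOError(f"cannot read TIFF {p}: {exc}") from exc
        frames.append(_as_frame(np.asarray(arr), t=i + 1, path=p))
    return FrameSeries(frames=frames)


def to_grayscale(frame: Frame) -> Frame:
    """Collapse an RGB frame to luminance; identity on grayscale frames.

    Uses the ITU-R 601 weighting (0.299, 0.587, 0.114) rounded to the
    nearest integer intensity. Idempotent: applying it twice equals
    applying it once.
    """
    if frame.rgb is None:
        return frame
    return Frame(pixels=_luminance(frame.rgb), t=frame.t)


def write_series(series: FrameSeries, directory: str | Path) -> list[Path]:
    """Write one uncompressed TIFF per frame; returns the written paths.

    Filenames carry a zero-padded time index so a later ``read_series`` on
    the sorted listing reproduces the order (and the pixels, bit-exactly).
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise FrameIOError(f"cannot create output directory {directory}: {exc}") from exc
    width = max(4, len(str(series.T)))
    paths = []
    for f in series:
        data = f.rgb if f.rgb is not None else f.pixels
        p = directory / f"frame_{f.t:0{width}d}.tif"
        try:
            tifffile.imwrite(p, np.ascontiguousarray(data), compression=None)
        except OSError as exc:
            raise FrameIOError(f"cannot write TIFF {p}: {exc}") from exc
        paths.append(p)
    return paths
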