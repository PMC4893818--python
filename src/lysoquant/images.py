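"""Image containers, TIFF I/O, cell segmentation and intensity preprocessing.

The containers are deliberately thin wrappers around numpy arrays:
:class:`ImageFrame` is a single 2-D intensity grid, :class:`ImageStack` a
``(time, channel, y, x)`` array with named channels, and :class:`CellMask` a
boolean region with its binary centroid.  Coordinates are 0-based pixel
indices with ``(x, y) = (column, row)``.

Segmentation follows the common widefield practice of thresholding a
"saturated" copy of the image: intensities are clipped a fixed factor above
the image median (a robust background estimate for a single-cell field), so
that dim cytoplasmic signal and bright organelles contribute equally to the
foreground class, then Otsu-thresholded; the largest connected component is
kept with holes filled.  Background subtraction removes the median
intensity of the region outside the cell mask.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label


class ValidationError(ValueError):
    """An input object violates a documented precondition."""


class SegmentationError(RuntimeError):
    """Segmentation could not produce a non-empty cell mask."""


class ImageIOError(IOError):
    """A file could not be read as the declared image layout."""


_ALLOWED_BIT_DEPTHS = (8, 16)


@dataclass(frozen=True)
class ImageFrame:
    """A single-channel 2-D image in grey values."""

    pixels: np.ndarray
    bit_depth: int = 16
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValidationError("pixels must be a non-empty 2-D array")
        if self.bit_depth not in _ALLOWED_BIT_DEPTHS:
            raise ValidationError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if px.min() < 0 or px.max() > self.max_value:
            raise ValidationError(
                f"intensities must lie in [0, {self.max_value}] for "
                f"{self.bit_depth}-bit data"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ImageStack:
    """A ``(time, channel, y, x)`` stack with named channels."""

    data: np.ndarray
    channel_names: tuple[str, ...]
    bit_depth: int = 16
    pixel_size_um: float | None = None
    frame_interval_s: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValidationError("data must have shape (time, channel, y, x)")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[1]:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[1]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValidationError("channel names must be unique")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            try:
                return self.channel_names.index(channel)
            except ValueError:
                raise ValidationError(
                    f"channel {channel!r} not in {self.channel_names}"
                ) from None
        return int(channel)

    def frame(self, channel: int | str = 0, t: int = 0) -> ImageFrame:
        c = self.channel_index(channel)
        return ImageFrame(
            self.data[t, c], bit_depth=self.bit_depth, pixel_size_um=self.pixel_size_um
        )

    def frames(self, channel: int | str = 0) -> list[ImageFrame]:
        return [self.frame(channel, t) for t in range(self.n_frames)]


@dataclass
class CellMask:
    """A binary cell region; centroid and area are derived from the mask."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2 or not m.any():
            raise ValidationError("mask must be a 2-D boolean array with area > 0")
        self.mask = m

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def centroid(self) -> tuple[float, float]:
        """Binary centroid as (x, y) pixel coordinates."""
        rows, cols = np.nonzero(self.mask)
        return float(cols.mean()), float(rows.mean())

    @property
    def centroid_rc(self) -> tuple[float, float]:
        cx, cy = self.centroid
        return cy, cx

    def contains(self, other: "CellMask") -> bool:
        return bool(np.all(other.mask <= self.mask))


# ---------------------------------------------------------------------------
# TIFF / CSV I/O


def write_image(stack: ImageStack, path: str | Path) -> None:
    """Write a stack losslessly as an uncompressed TCYX TIFF."""
    dtype = np.uint8 if stack.bit_depth == 8 else np.uint16
    tifffile.imwrite(
        Path(path),
        stack.data.astype(dtype),
        photometric="minisblack",
        metadata={"axes": "TCYX"},
    )


def read_image(
    path: str | Path,
    layout: str = "TCYX",
    channel_names: Sequence[str] | None = None,
    bit_depth: int | None = None,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
) -> ImageStack:
    """Load a TIFF into an :class:`ImageStack`.

    ``layout`` declares the on-disk axis order using characters from
    ``T`` (time), ``C`` (channel), ``Y``, ``X``; missing axes are added with
    length one.  Raises :class:`ImageIOError` if the file cannot be read or
    its dimensionality does not match the layout.
    """
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise ImageIOError(f"cannot read {path} as TIFF: {exc}") from exc
    layout = layout.upper()
    if sorted(layout) != sorted(set(layout)) or any(a not in "TCYX" for a in layout):
        raise ValidationError(f"invalid layout {layout!r}")
    if arr.ndim != len(layout):
        raise ImageIOError(
            f"{path}: data has {arr.ndim} axes but layout {layout!r} expects "
            f"{len(layout)}"
        )
    # Reorder present axes to T, C, Y, X and insert missing ones.
    order = [layout.index(a) for a in "TCYX" if a in layout]
    arr = np.transpose(arr, order)
    present = [a for a in "TCYX" if a in layout]
    for i, a in enumerate("TCYX"):
        if a not in present:
            arr = np.expand_dims(arr, i)
    if bit_depth is None:
        bit_depth = 8 if arr.dtype == np.uint8 else 16
    if channel_names is None:
        channel_names = tuple(f"ch{i}" for i in range(arr.shape[1]))
    return ImageStack(
        data=arr,
        channel_names=tuple(channel_names),
        bit_depth=bit_depth,
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
    )


def write_mask(mask: CellMask, path: str | Path) -> None:
    tifffile.imwrite(Path(path), mask.mask.astype(np.uint8) * 255)


def read_mask(path: str | Path) -> CellMask:
    try:
        arr = tifffile.imread(Path(path))
    except (OSError, ValueError) as exc:
        raise ImageIOError(f"cannot read mask {path}: {exc}") from exc
    return CellMask(arr > 0)


def read_polygon_mask(path: str | Path, shape: tuple[int, int]) -> CellMask:
    """Rasterize an ROI polygon CSV (columns x, y; one vertex per row)."""
    xs: list[float] = []
    ys: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"x", "y"} <= set(reader.fieldnames):
            raise ImageIOError(f"{path}: polygon CSV needs 'x' and 'y' columns")
        for row in reader:
            xs.append(float(row["x"]))
            ys.append(float(row["y"]))
    if len(xs) < 3:
        raise ImageIOError(f"{path}: polygon needs at least 3 vertices")
    rr, cc = draw_polygon(np.array(ys), np.array(xs), shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return CellMask(mask)


# ---------------------------------------------------------------------------
# Segmentation and preprocessing


def segment_cell(
    frame: ImageFrame,
    saturation_quantile: float = 0.99,
    saturation_factor: float = 2.0,
) -> CellMask:
    """Define the cell perimeter by thresholding a saturated copy of the image.

    The image is saturated (clipped) at ``saturation_factor`` times its
    median — for a single-cell field the median estimates the camera
    background, so everything meaningfully above background (cytoplasm and
    bright organelles alike) collapses onto the saturation level.  The
    saturated copy is then Otsu-thresholded and the largest connected
    foreground component is returned with holes filled.  When the median is
    zero (background-free images) the clip level falls back to the
    ``saturation_quantile`` intensity quantile.

    Saturating before thresholding is what makes the threshold select the
    whole cell rather than the brightest organelles: on a punctate channel
    the raw histogram's dominant contrast is puncta-vs-everything, and a
    plain Otsu threshold would segment the puncta.
    """
    if not 0 < saturation_quantile <= 1:
        raise ValidationError("saturation_quantile must be in (0, 1]")
    if saturation_factor <= 1:
        raise ValidationError("saturation_factor must be > 1")
    px = frame.pixels.astype(np.float64)
    if px.max() == px.min():
        raise SegmentationError("constant image: no cell to segment")
    med = float(np.median(px))
    clip = saturation_factor * med if med > 0 else np.quantile(px, saturation_quantile)
    clipped = np.minimum(px, clip)
    if clipped.max() == clipped.min():
        raise SegmentationError("image constant after saturation clipping")
    thr = threshold_otsu(clipped)
    fg = clipped > thr
    if not fg.any():
        raise SegmentationError("empty foreground after thresholding")
    labels = cc_label(fg)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    largest = labels == counts.argmax()
    filled = ndimage.binary_fill_holes(largest)
    return CellMask(filled)


def subtract_background(frame: ImageFrame, mask: CellMask) -> ImageFrame:
    """Subtract the median intensity outside the mask, clamping at zero."""
    outside = ~mask.mask
    if not outside.any():
        raise ValidationError("mask covers the whole frame: no background region")
    bg = float(np.median(frame.pixels[outside]))
    out = np.clip(frame.pixels.astype(np.float64) - bg, 0, None)
    return ImageFrame(out, bit_depth=frame.bit_depth, pixel_size_um=frame.pixel_size_um)


def expression_gate(
    cells: Iterable[tuple[ImageStack, CellMask]],
    channel: int | str,
    low: float,
    high: float,
) -> tuple[list[tuple[ImageStack, CellMask]], list[dict]]:
    """Keep cells whose mean raw intensity in ``channel`` lies in [low, high].

    Returns the retained cells and a per-cell report
    (``cell_index``, ``mean_intensity``, ``retained``).  Used to select
    populations with comparable expression of a transfected marker, e.g. the
    3,000-10,000 grey-value window for a GFP-tagged construct in 16-bit data.
    """
    if not low < high:
        raise ValidationError(f"low ({low}) must be < high ({high})")
    kept: list[tuple[ImageStack, CellMask]] = []
    report: list[dict] = []
    for i, (stack, mask) in enumerate(cells):
        c = stack.channel_index(channel)
        mean = float(stack.data[0, c][mask.mask].mean())
        retained = low <= mean <= high
        report.append(
            {"cell_index": i, "mean_intensity": mean, "retained": retained}
        )
        if retained:
            kept.append((stack, mask))
    return kept, report
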