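"""Loading strip photographs and reducing them to column-sum profiles.

A lateral-flow strip is photographed in landscape orientation with the
control line — the darkest, always-present line — in the left half of the
frame.  Everything downstream works on the grayscale pixel matrix and on the
one-dimensional profile obtained by summing each pixel column, so this module
is the single place where file formats, color conversion and orientation are
dealt with.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, UnidentifiedImageError

from .exceptions import ImageTooSmallError, NotLandscapeError

__all__ = ["GrayImage", "ColumnProfile", "load_grayscale", "column_profile"]

#: Rec.601 luma weights used for RGB -> grayscale conversion.
REC601_WEIGHTS = (0.299, 0.587, 0.114)

MIN_HEIGHT = 20
MIN_WIDTH = 40


@dataclass(frozen=True)
class GrayImage:
    """An 8-bit grayscale strip image.

    Pixels are stored as a (H, W) uint8 matrix; row index runs top to
    bottom, column index left to right.  Lines on the membrane appear as
    dark (low-intensity) vertical bands.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("GrayImage requires a non-empty 2-D pixel matrix")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("pixel intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", px.astype(np.uint8, copy=False))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def inverted(self) -> np.ndarray:
        """Pixel matrix as float with lines bright (255 - intensity)."""
        return 255.0 - self.pixels.astype(np.float64)


@dataclass(frozen=True)
class ColumnProfile:
    """Per-column pixel sums S_j of a strip image plus their minimum.

    ``min_value`` is the minimum column sum divided by the image height,
    i.e. the darkest column's mean intensity on the 0-255 pixel scale.  The
    control-line threshold adds a pixel-scale offset to this value before
    scaling back by the height.
    """

    sums: np.ndarray
    height: int
    min_value: float = field(init=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.sums, dtype=np.int64)
        if s.ndim != 1 or s.size == 0:
            raise ValueError("column sums must be a non-empty 1-D sequence")
        object.__setattr__(self, "sums", s)
        object.__setattr__(self, "min_value", float(s.min()) / self.height)

    def __len__(self) -> int:
        return len(self.sums)


def _to_grayscale(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[:, :, :3].astype(np.float64)
        luma = rgb @ np.asarray(REC601_WEIGHTS)
        return np.clip(np.rint(luma), 0, 255).astype(np.uint8)
    raise ValueError(f"unsupported channel layout with shape {arr.shape}")


def _normalize_orientation(px: np.ndarray, hint: str) -> np.ndarray:
    # Portrait photos are rotated so the strip's long axis is horizontal.
    if px.shape[0] > px.shape[1]:
        px = np.rot90(px, k=-1)
    if hint == "left":
        return px
    if hint == "right":
        return px[:, ::-1]
    if hint == "auto":
        # The control line is the darkest column cluster; mirror the image
        # if it sits in the right half so it always ends up on the left.
        sums = px.astype(np.int64).sum(axis=0)
        if int(np.argmin(sums)) >= px.shape[1] / 2:
            px = px[:, ::-1]
        return px
    raise ValueError(f"orientation_hint must be auto/left/right, got {hint!r}")


def load_grayscale(path: str | os.PathLike, orientation_hint: str = "auto") -> GrayImage:
    """Load a strip photograph as a landscape grayscale image.

    Parameters
    ----------
    path
        PNG/JPEG/TIFF file, 8-bit, 1 or 3 channels (an alpha channel is
        ignored).
    orientation_hint
        ``"auto"`` mirrors the image when the darkest column cluster lies in
        the right half; ``"left"`` trusts the stored orientation; ``"right"``
        mirrors unconditionally.

    Raises
    ------
    IOError
        If the file cannot be read or decoded.
    ImageTooSmallError
        If the normalized image is smaller than 20 x 40 pixels.
    NotLandscapeError
        If the normalized image is not landscape (width < 2 x height).
    """
    try:
        with Image.open(path) as im:
            if im.mode not in ("L", "RGB", "RGBA", "P", "I;16", "1"):
                im = im.convert("RGB")
            elif im.mode in ("P", "1"):
                im = im.convert("RGB")
            elif im.mode == "I;16":
                im = im.point(lambda v: v // 256).convert("L")
            arr = np.asarray(im)
    except FileNotFoundError as exc:
        raise IOError(f"cannot read image file: {path}") from exc
    except (UnidentifiedImageError, OSError) as exc:
        raise IOError(f"cannot decode image file: {path}") from exc

    px = _normalize_orientation(_to_grayscale(arr), orientation_hint)
    h, w = px.shape
    if h < MIN_HEIGHT or w < MIN_WIDTH:
        raise ImageTooSmallError(
            f"image too small: {h}x{w} px, need at least {MIN_HEIGHT}x{MIN_WIDTH}"
        )
    if w < 2 * h:
        raise NotLandscapeError(
            f"not a landscape strip: width {w} < 2 x height {h}"
        )
    return GrayImage(px)


def column_profile(img: GrayImage) -> ColumnProfile:
    """Sum each pixel column: S_j = sum_i I_{i,j}, exact integer arithmetic."""
    sums = img.pixels.astype(np.int64).sum(axis=0)
    return ColumnProfile(sums=sums, height=img.height)
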