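"""Line signal readout and the Y1/Y2 feature values.

Each of the four line regions (control + T1..T3) is read on the inverted
image (lines bright), smoothed with a normalized Gaussian kernel, and
summarized by the peak of its per-column mean profile.  The background level
ARG is the mean inverted intensity over every column outside the four
regions; any line signal that falls below ARG is lifted to it, so a blank
test line reads exactly as background and never as a negative signal.

The two feature values normalize background-corrected line strength by the
control line::

    Y1 = (T1 + T2 + T3 - 3 * ARG) / C      (four-line read)
    Y2 = (T1 - ARG) / C                    (two-line read)

Both are dimensionless and invariant under global intensity scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import EmptyLineRegionError, InvalidControlSignalError
from .image_io import GrayImage
from .line_detection import LineLists

__all__ = [
    "BlurParams",
    "LineSignals",
    "FeatureVector",
    "gaussian_kernel_1d",
    "blur_region",
    "line_signals",
    "compute_features",
]


@dataclass(frozen=True)
class BlurParams:
    """Gaussian blur with standard deviation ``sigma`` (pixels).

    The kernel half-width defaults to ``ceil(3 * sigma)`` and the sampled
    kernel is renormalized to sum to one, so constant regions pass through
    unchanged.
    """

    sigma: float = 2.0
    radius: int | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.radius is not None and self.radius < 0:
            raise ValueError("radius must be >= 0")

    @property
    def effective_radius(self) -> int:
        return self.radius if self.radius is not None else math.ceil(3 * self.sigma)


@dataclass(frozen=True)
class LineSignals:
    """Region readouts on the inverted-intensity scale."""

    c: float
    t1: float
    t2: float
    t3: float
    arg: float

    @property
    def tests(self) -> tuple[float, float, float]:
        return (self.t1, self.t2, self.t3)


@dataclass(frozen=True)
class FeatureVector:
    y1: float
    y2: float


def gaussian_kernel_1d(params: BlurParams) -> np.ndarray:
    """Sampled Gaussian ``exp(-r^2 / (2 sigma^2))`` on -R..R, normalized to sum 1."""
    r = params.effective_radius
    x = np.arange(-r, r + 1, dtype=np.float64)
    k = np.exp(-(x**2) / (2.0 * params.sigma**2))
    return k / k.sum()


def blur_region(region: np.ndarray, params: BlurParams) -> np.ndarray:
    """Separable 2-D Gaussian convolution with reflected borders.

    A radius of zero degenerates to the identity.  Output is float64 with
    the input's shape.
    """
    reg = np.asarray(region, dtype=np.float64)
    if reg.ndim != 2 or reg.size == 0:
        raise ValueError("region must be a non-empty 2-D array")
    kernel = gaussian_kernel_1d(params)
    if kernel.size == 1:
        return reg.copy()
    out = ndimage.convolve1d(reg, kernel, axis=0, mode="reflect")
    return ndimage.convolve1d(out, kernel, axis=1, mode="reflect")


def line_signals(
    img: GrayImage, lines: LineLists, params: BlurParams | None = None
) -> LineSignals:
    """Read C, T1, T2, T3 and the background level ARG from four regions.

    The image is inverted so lines are peaks.  Each region's sub-image is
    Gaussian-blurred and collapsed to its per-column mean profile; the
    profile's maximum is the region's signal.  Columns outside all four
    regions form the background, averaged into ARG; signals below ARG are
    replaced by ARG.

    Raises
    ------
    EmptyLineRegionError
        If any region has zero width.
    ValueError
        If ``lines`` does not contain exactly four regions.
    """
    if params is None:
        params = BlurParams()
    regions = lines.regions()
    if len(regions) != 4:
        raise ValueError(f"expected exactly 4 line regions, got {len(regions)}")
    inv = img.inverted()

    signals: list[float] = []
    background = np.ones(img.width, dtype=bool)
    for reg in regions:
        if reg.end >= img.width:
            raise EmptyLineRegionError(
                f"empty line region: [{reg.head}, {reg.end}] outside image width {img.width}"
            )
        sub = inv[:, reg.head : reg.end + 1]
        if sub.size == 0:
            raise EmptyLineRegionError(f"empty line region: [{reg.head}, {reg.end}]")
        blurred = blur_region(sub, params)
        signals.append(float(blurred.mean(axis=0).max()))
        background[reg.head : reg.end + 1] = False

    arg = float(inv[:, background].mean()) if background.any() else 0.0
    c, t1, t2, t3 = (max(s, arg) for s in signals)
    return LineSignals(c=c, t1=t1, t2=t2, t3=t3, arg=arg)


def compute_features(sig: LineSignals) -> FeatureVector:
    """Y1 and Y2 from the line signals.

    Raises
    ------
    InvalidControlSignalError
        If the control signal is not positive (failed strip).
    """
    if sig.c <= 0:
        raise InvalidControlSignalError(f"invalid control signal C = {sig.c}")
    y1 = (sig.t1 + sig.t2 + sig.t3 - 3.0 * sig.arg) / sig.c
    y2 = (sig.t1 - sig.arg) / sig.c
    return FeatureVector(y1=y1, y2=y2)
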