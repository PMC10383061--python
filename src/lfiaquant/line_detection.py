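"""Locating the control line and up to three test lines on a strip image.

The detection cascade works on the grayscale strip in five stages:

1. *Control line by threshold segmentation.*  The column-sum profile is
   binarized at ``(MinValue + I) * H`` — just deep enough to keep only the
   darkest line — and the surviving run in the left half is the control line.
2. *Denoising and adaptive binarization.*  A k x k median filter removes
   speckle; the image is then binarized at ``factor * mean`` with the factor
   lowered in 0.05 steps until the mask's signal-to-noise ratio clears a
   floor, falling back to a morphological opening when it never does.
3. *Candidate test lines.*  The denoised image (inverted, so lines are
   bright) is binarized at 1.5x its mean; maximal runs of foreground columns
   yield the ``head``/``end`` edge lists.  A mirror-product convolution
   response is computed alongside as a symmetry cue.
4. *Refinement.*  Runs far from the control line's width are discarded and
   fragments separated by less than twice the gap tolerance are merged.
5. *Finalization.*  The lists are reduced/extended to exactly four regions
   (control + T1..T3); missing faint test lines are imputed at the strip's
   nominal geometry so a blank strip still yields a (zero) feature value.

Lines are darker than the membrane, so stages 3-5 and the symmetry response
work on inverted intensity (255 - pixel) where lines are peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .exceptions import ControlLineLostError, ControlLineNotFoundError
from .image_io import ColumnProfile, GrayImage, column_profile

__all__ = [
    "ThresholdParams",
    "StripGeometry",
    "LineRegion",
    "LineLists",
    "SymmetryResponse",
    "control_threshold",
    "locate_control_line",
    "median_denoise",
    "adaptive_binarize",
    "symmetry_response",
    "transition_lists",
    "refine_lists",
    "finalize_lists",
]

#: 3x3 cross structuring element for the morphological fallback.
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class ThresholdParams:
    """Tuning constants of the detection cascade.

    The defaults are the algorithm's operating point: control-threshold
    offset ``I = 30`` gray levels, minimum control-line width 5 columns,
    test-line binarization factor 1.5, SNR floor 0.75 with the binarization
    factor lowered in steps of 0.05, and a 5 x 5 median filter.
    """

    offset: float = 30.0
    min_control_width: int = 5
    mean_factor: float = 1.5
    snr_floor: float = 0.75
    factor_step: float = 0.05
    median_kernel: int = 5

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("offset must be >= 0")
        if self.mean_factor <= 0:
            raise ValueError("mean_factor must be > 0")
        if not 0 < self.snr_floor < 1:
            raise ValueError("snr_floor must lie in (0, 1)")
        if self.median_kernel < 3 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 3")


@dataclass(frozen=True)
class StripGeometry:
    """Nominal strip layout: line spacing and width in columns.

    ``expected_gap`` is the designed center-to-center distance between
    adjacent lines (the assay's physical layout, known in advance).
    ``merge_fraction`` scales the gap into the Step-4 merge tolerance:
    fragments closer than ``2 * merge_fraction * expected_gap`` are fused.
    """

    expected_gap: float
    nominal_line_width: int
    num_test_lines: int = 3
    merge_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not self.expected_gap > self.nominal_line_width > 0:
            raise ValueError("require expected_gap > nominal_line_width > 0")
        if self.num_test_lines < 1:
            raise ValueError("num_test_lines must be >= 1")

    @property
    def merge_tolerance(self) -> float:
        return self.merge_fraction * self.expected_gap


@dataclass(frozen=True)
class LineRegion:
    """An inclusive [head, end] column interval covering one line."""

    head: int
    end: int

    def __post_init__(self) -> None:
        if self.head < 0 or self.end < self.head:
            raise ValueError(f"invalid line region [{self.head}, {self.end}]")

    @property
    def width(self) -> int:
        return self.end - self.head + 1

    @property
    def center(self) -> float:
        return (self.head + self.end) / 2.0


@dataclass(frozen=True)
class LineLists:
    """Ordered left-edge (``head``) and right-edge (``end``) column lists."""

    head: tuple[int, ...]
    end: tuple[int, ...]

    def __post_init__(self) -> None:
        h, e = tuple(self.head), tuple(self.end)
        if len(h) != len(e):
            raise ValueError("head and end lists must have equal length")
        prev_end = -1
        for hk, ek in zip(h, e):
            if not prev_end < hk <= ek:
                raise ValueError(f"line lists not ordered/disjoint: {h}, {e}")
            prev_end = ek
        object.__setattr__(self, "head", h)
        object.__setattr__(self, "end", e)

    def __len__(self) -> int:
        return len(self.head)

    def regions(self) -> list[LineRegion]:
        return [LineRegion(h, e) for h, e in zip(self.head, self.end)]

    @classmethod
    def from_regions(cls, regions: Sequence[LineRegion]) -> "LineLists":
        regs = sorted(regions, key=lambda r: r.head)
        return cls(tuple(r.head for r in regs), tuple(r.end for r in regs))


@dataclass(frozen=True)
class SymmetryResponse:
    """Mirror-product image D and its per-column convolution response.

    ``d`` is the element-wise product of the inverted image restricted to
    its left half with the full horizontal mirror of the inverted image; it
    is therefore zero in all right-half columns.  ``c_vec[k]`` contracts
    column k of ``d`` against the inverted column-sum vector.
    """

    d: np.ndarray
    c_vec: np.ndarray


def control_threshold(profile: ColumnProfile, params: ThresholdParams, height: int) -> float:
    """Column-sum threshold ``(MinValue + I) * H`` for control-line segmentation."""
    if len(profile) == 0:
        raise ValueError("empty column profile")
    return (profile.min_value + params.offset) * height


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a 1-D boolean mask as inclusive (start, stop)."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0 or not m.any():
        return []
    padded = np.concatenate(([False], m, [False])).astype(np.int8)
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1) - 1
    return list(zip(starts.tolist(), stops.tolist()))


def locate_control_line(img: GrayImage, params: ThresholdParams) -> LineRegion:
    """Find the control line in the left half by threshold segmentation.

    Columns of the left half whose sum falls at or below the control
    threshold are marked; the darkest contiguous marked run is the control
    line, accepted only if it is wider than ``min_control_width`` columns
    and its right edge is positive.  A run spanning the entire left half is
    rejected: the threshold segmented nothing (contrast-free image).

    Raises
    ------
    ControlLineNotFoundError
        If no qualifying run exists — an invalid or blank strip.
    """
    profile = column_profile(img)
    thr = control_threshold(profile, params, img.height)
    half = img.width // 2
    mask = np.zeros(img.width, dtype=bool)
    mask[:half] = profile.sums[:half] <= thr

    best: tuple[int, int] | None = None
    best_depth = np.inf
    for start, stop in _runs_of(mask):
        width = stop - start + 1
        if width <= params.min_control_width or stop <= 0:
            continue
        if start == 0 and stop >= half - 1:
            continue
        mean_sum = float(profile.sums[start : stop + 1].mean())
        if mean_sum < best_depth:
            best, best_depth = (start, stop), mean_sum
    if best is None:
        raise ControlLineNotFoundError(
            "control line not found: no left-half run wider than "
            f"{params.min_control_width} columns below threshold {thr:.1f}"
        )
    return LineRegion(head=best[0], end=best[1])


def median_denoise(img: GrayImage, params: ThresholdParams) -> GrayImage:
    """k x k median filter with edge-replicated borders."""
    filtered = ndimage.median_filter(
        img.pixels, size=params.median_kernel, mode="nearest"
    )
    return GrayImage(filtered)


def _mask_snr(mask: np.ndarray, min_width: int) -> float:
    """Fraction of foreground pixels lying in column runs wider than min_width.

    Isolated speckle produces narrow column runs; a clean mask whose
    foreground all belongs to genuine lines scores 1.  An empty mask is
    treated as clean.
    """
    total = int(mask.sum())
    if total == 0:
        return 1.0
    col_fg = mask.any(axis=0)
    structured = 0
    for start, stop in _runs_of(col_fg):
        if stop - start + 1 > min_width:
            structured += int(mask[:, start : stop + 1].sum())
    return structured / total


def adaptive_binarize(img: GrayImage, params: ThresholdParams) -> np.ndarray:
    """Binarize dark pixels at ``factor * mean``, adapting the factor.

    Starting at factor 1.0, pixels below ``factor * mean`` become
    foreground.  While the mask SNR is below ``snr_floor`` and the factor is
    above 0.5, the factor is lowered by ``factor_step`` and the mask is
    recomputed.  If the SNR still misses the floor after the loop, a
    morphological opening with a 3x3 cross cleans residual speckle.

    Returns a boolean (H, W) mask; an all-background mask is legal.
    """
    mean = float(img.pixels.mean())
    factor = 1.0
    mask = img.pixels < factor * mean
    snr = _mask_snr(mask, params.min_control_width)
    while snr < params.snr_floor and factor > 0.5 + 1e-12:
        factor -= params.factor_step
        mask = img.pixels < factor * mean
        snr = _mask_snr(mask, params.min_control_width)
    if snr < params.snr_floor:
        mask = ndimage.binary_opening(mask, structure=_CROSS)
    return mask


def symmetry_response(img: GrayImage) -> SymmetryResponse:
    """Mirror-product symmetry cue on the inverted image.

    ``I_left`` keeps the inverted image in the left half and zeroes the
    right half; ``I_flipped`` is the full horizontal mirror (column x maps
    to W-1-x).  Their element-wise product is D.  The response contracts
    each column k of D against the inverted column-sum vector S:
    ``c_vec[k] = sum_x D[x, k] * S[x]`` with x running over the shared
    index range (all rows, for the landscape strips this package targets).
    """
    inv = np.rint(img.inverted()).astype(np.int64)
    h, w = inv.shape
    left = inv.copy()
    left[:, w // 2 :] = 0
    flipped = inv[:, ::-1]
    d = left * flipped
    sums = inv.sum(axis=0)
    n = min(h, w)
    c_vec = d[:n, :].T @ sums[:n]
    return SymmetryResponse(d=d, c_vec=c_vec)


def transition_lists(img: GrayImage, params: ThresholdParams) -> LineLists:
    """Head/end lists of candidate line runs from 1.5x-mean binarization.

    The denoised image is inverted so lines are bright, thresholded at
    ``mean_factor`` times its mean, and reduced to a per-column foreground
    flag (logical OR down each column).  Each maximal run of foreground
    columns contributes its first column to ``head`` and its last to
    ``end``.  Empty lists are legal (no line candidate exceeded threshold).
    """
    inv = img.inverted()
    thr = params.mean_factor * float(inv.mean())
    col_fg = (inv > thr).any(axis=0)
    runs = _runs_of(col_fg)
    return LineLists(tuple(r[0] for r in runs), tuple(r[1] for r in runs))


def _width_filter(regions: list[LineRegion], control_width: int) -> list[LineRegion]:
    lo, hi = control_width / 4.0, control_width * 4.0
    return [r for r in regions if lo <= r.width <= hi]


def refine_lists(
    lists: LineLists, control: LineRegion, geom: StripGeometry
) -> LineLists:
    """Step-4 cleanup: width filtering and fragment merging.

    Runs whose width differs from the control line's by more than a factor
    of four are discarded as noise or stains.  Adjacent runs whose gap is
    smaller than twice the geometry's merge tolerance are fused — they are
    fragments of one line split by the binarization.  Applying the function
    twice gives the same result as applying it once.
    """
    regions = _width_filter(lists.regions(), control.width)
    merged: list[LineRegion] = []
    threshold = 2.0 * geom.merge_tolerance
    for reg in regions:
        if merged and reg.head - merged[-1].end < threshold:
            merged[-1] = LineRegion(merged[-1].head, reg.end)
        else:
            merged.append(reg)
    return LineLists.from_regions(merged)


def _nominal_region(center: int, width: int, image_width: int) -> LineRegion:
    half = (width - 1) // 2
    head = max(0, min(center - half, image_width - width))
    return LineRegion(head=head, end=head + width - 1)


def _snap_center(
    nominal: int, window_half: int, c_vec: np.ndarray | None, image_width: int
) -> int:
    """Snap an imputed line center to the local symmetry-response maximum.

    Falls back to the nominal center when no response is available or the
    window is flat (ties keep the leftmost maximum only if it improves on a
    flat response).
    """
    if c_vec is None:
        return nominal
    lo = max(0, nominal - window_half)
    hi = min(image_width - 1, nominal + window_half)
    window = np.asarray(c_vec[lo : hi + 1], dtype=np.float64)
    if window.size == 0 or np.ptp(window) == 0:
        return nominal
    return lo + int(np.argmax(window))


def finalize_lists(
    lists: LineLists,
    control: LineRegion,
    geom: StripGeometry,
    img: GrayImage | None = None,
    c_vec: np.ndarray | None = None,
) -> LineLists:
    """Step-5: reduce/extend the refined runs to exactly four line regions.

    The run containing (or nearest to) the control line's right edge
    anchors the output.  Each remaining run is assigned to the nearest
    nominal test-line slot ``control_center + m * expected_gap`` (m = 1..3);
    when more than three runs compete, the strongest by mean inverted
    intensity win.  A leading fragment narrower than half the control width
    is dropped.  Slots with no detected run are imputed as nominal-width
    windows at their geometric position, searched over a window widened by
    three control widths and snapped to the local symmetry-response maximum.

    Every output region is a nominal-width window centered on the detected
    (or imputed) line center: the thresholded run width varies with line
    darkness while the printed line width is fixed by the assay, so
    normalizing the windows makes reported head/end positions comparable
    across faint and dark lines.  The result is exactly
    ``[control, T1, T2, T3]``, ordered left to right and disjoint.

    Raises
    ------
    ControlLineLostError
        If no input run overlaps or lies near the control region.
    """
    regions = lists.regions()
    if not regions:
        raise ControlLineLostError("control line lost during refinement: empty lists")

    # Anchor: the run containing the control's rightmost end, else nearest.
    containing = [r for r in regions if r.head <= control.end <= r.end]
    if containing:
        control_run = containing[0]
    else:
        control_run = min(regions, key=lambda r: abs(r.center - control.center))
        if abs(control_run.center - control.center) > geom.expected_gap / 2.0:
            raise ControlLineLostError(
                "control line lost during refinement: nearest run at "
                f"{control_run.center:.0f} is too far from control {control.center:.0f}"
            )

    others = [r for r in regions if r is not control_run]
    # Leading-fragment rule: a narrow run left of the control is an artifact.
    if others and others[0].head < control_run.head and others[0].width < control.width / 2:
        others = others[1:]

    image_width = img.width if img is not None else max(
        int(round(control_run.center + (geom.num_test_lines + 0.5) * geom.expected_gap)),
        (regions[-1].end + 1),
    )
    inv_sums = None
    if img is not None:
        inv_sums = img.inverted().sum(axis=0)

    def strength(region: LineRegion) -> float:
        if inv_sums is None:
            return -region.head  # leftmost-first tie-break only
        return float(inv_sums[region.head : region.end + 1].mean())

    ccenter = control_run.center
    slots: dict[int, LineRegion] = {}
    for reg in others:
        m = int(round((reg.center - ccenter) / geom.expected_gap))
        if not 1 <= m <= geom.num_test_lines:
            continue
        nominal_center = ccenter + m * geom.expected_gap
        if abs(reg.center - nominal_center) > geom.expected_gap / 2.0:
            continue
        if m in slots:
            incumbent = slots[m]
            if strength(reg) > strength(incumbent):
                slots[m] = reg  # stronger run wins; ties keep the leftmost
        else:
            slots[m] = reg

    window_half = (geom.nominal_line_width - 1) // 2 + (3 * control.width) // 2
    final: list[LineRegion] = []
    final.append(
        _nominal_region(
            int(round(control_run.center)), geom.nominal_line_width, image_width
        )
    )
    for m in range(1, geom.num_test_lines + 1):
        if m in slots:
            center = int(round(slots[m].center))
        else:
            nominal = int(round(ccenter + m * geom.expected_gap))
            center = _snap_center(nominal, window_half, c_vec, image_width)
        final.append(_nominal_region(center, geom.nominal_line_width, image_width))

    # Nominal windows can only collide if detection mis-centered a line;
    # shift any overlap rightward to keep the four regions disjoint.
    for i in range(1, len(final)):
        if final[i].head <= final[i - 1].end:
            shift = final[i - 1].end + 1 - final[i].head
            final[i] = replace(
                final[i], head=final[i].head + shift, end=final[i].end + shift
            )
    return LineLists.from_regions(final)
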