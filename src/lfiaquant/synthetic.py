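"""Seeded synthetic strip images with ground-truth line geometry.

Real strips are photographs of a light nitrocellulose membrane carrying one
dark control line and up to three fainter test lines at fixed spacing, whose
darkness grows with analyte concentration.  The generator emulates exactly
that: a flat background with Gaussian texture noise, Gaussian-profile
vertical lines subtracted from it, and a saturating (Hill-type) map from
concentration to line amplitude.  Every strip carries a ground-truth record
(line centers, nominal edges, amplitudes) so the whole detection pipeline is
testable without photographs.

Three image corruptions mirror the robustness protocol used on real
photographs: salt-and-pepper, additive Gaussian, and Poisson shot noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .image_io import GrayImage
from .line_detection import StripGeometry

__all__ = [
    "StripSpec",
    "ResponseCurve",
    "TEST_LINE_MULTIPLIERS",
    "generate_strip",
    "add_noise",
    "default_geometry",
]

#: Relative amplitude of T1, T2, T3 for a given concentration; T1 is the
#: strongest line, consistent with the two-line feature reading only T1.
TEST_LINE_MULTIPLIERS = (1.0, 0.8, 0.6)

#: The assay's design concentrations (ug/mL).
DESIGN_CONCENTRATIONS = (0, 5, 10, 30, 50, 80, 100, 300, 500, 800, 1000, 1300, 1500)


@dataclass(frozen=True)
class ResponseCurve:
    """Hill-type map from concentration (ug/mL) to line amplitude (gray levels).

    ``amplitude(c) = a_max * c^h / (K^h + c^h)``: zero at zero concentration,
    monotone, saturating at ``a_max``.  The defaults put synthetic Y1 values
    on the same 0-2 scale as real strip readings over 0-1500 ug/mL.
    """

    a_max: float = 110.0
    k: float = 300.0
    h: float = 1.0

    def amplitude(self, concentration: float) -> float:
        if concentration < 0:
            raise ValueError("concentration must be >= 0")
        if concentration == 0:
            return 0.0
        ch = concentration**self.h
        return self.a_max * ch / (self.k**self.h + ch)


@dataclass(frozen=True)
class StripSpec:
    """Geometry, intensity and randomness of one synthetic strip."""

    width: int = 600
    height: int = 200
    background_level: float = 220.0
    texture_sigma: float = 3.0
    control_center: int = 90
    control_amplitude: float = 120.0
    test_centers: tuple[int, int, int] = (210, 330, 450)
    line_sigma: float = 4.0
    concentration: float = 0.0
    seed: int = 0
    response: ResponseCurve = field(default_factory=ResponseCurve)

    def __post_init__(self) -> None:
        centers = (self.control_center, *self.test_centers)
        for c in centers:
            if not 0 <= c < self.width:
                raise ValueError(f"line center {c} outside image width {self.width}")
        ordered = sorted(centers)
        for a, b in zip(ordered, ordered[1:]):
            if b - a < 4 * self.line_sigma:
                raise ValueError(
                    f"overlapping lines: centers {a} and {b} closer than 4*line_sigma"
                )
        if not 0 <= self.control_amplitude <= self.background_level:
            raise ValueError("control amplitude must lie in [0, background_level]")

    def line_amplitudes(self) -> tuple[float, ...]:
        """(control, T1, T2, T3) amplitudes in gray levels."""
        base = self.response.amplitude(self.concentration)
        return (self.control_amplitude, *(base * m for m in TEST_LINE_MULTIPLIERS))


def _nominal_edges(center: int, line_sigma: float) -> tuple[int, int]:
    half = int(round(2 * line_sigma))
    return center - half, center + half


def generate_strip(spec: StripSpec) -> tuple[GrayImage, dict[str, Any]]:
    """Render a strip and its ground-truth record.

    The background is ``background_level`` plus N(0, texture_sigma^2)
    texture; each line subtracts ``amplitude * exp(-(x-center)^2 /
    (2 line_sigma^2))`` from every row.  Identical specs (same seed) render
    bit-identical images.  Ground truth lists, per line, its role, center,
    nominal head/end (center +/- 2 line_sigma) and amplitude.
    """
    rng = np.random.default_rng(spec.seed)
    base = spec.background_level + rng.normal(
        0.0, spec.texture_sigma, size=(spec.height, spec.width)
    )
    x = np.arange(spec.width, dtype=np.float64)
    amplitudes = spec.line_amplitudes()
    centers = (spec.control_center, *spec.test_centers)
    roles = ("control", "t1", "t2", "t3")
    profile = np.zeros(spec.width)
    truth_lines = []
    for role, center, amp in zip(roles, centers, amplitudes):
        profile += amp * np.exp(-((x - center) ** 2) / (2.0 * spec.line_sigma**2))
        head, end = _nominal_edges(center, spec.line_sigma)
        truth_lines.append(
            {"role": role, "center": center, "head": head, "end": end, "amplitude": amp}
        )
    pixels = np.clip(np.rint(base - profile[None, :]), 0, 255).astype(np.uint8)
    truth = {
        "concentration": spec.concentration,
        "seed": spec.seed,
        "lines": truth_lines,
    }
    return GrayImage(pixels), truth


def add_noise(img: GrayImage, kind: str, level: float, seed: int) -> GrayImage:
    """Corrupt a strip image with one of three noise models.

    ``salt_pepper``
        Each pixel independently becomes 0 or 255, with probability
        ``level / 2`` each.
    ``gaussian``
        Adds N(0, level^2), then rounds and clips to [0, 255].
    ``poisson``
        Replaces each pixel value v by ``Poisson(v * level) / level``
        (shot noise; ``level`` is the exposure scale, 1 means a Poisson
        draw with mean equal to the pixel value), clipped to [0, 255].
    """
    if level < 0:
        raise ValueError("noise level must be >= 0")
    rng = np.random.default_rng(seed)
    px = img.pixels
    if kind == "salt_pepper":
        if level == 0:
            return GrayImage(px.copy())
        u = rng.random(px.shape)
        out = px.copy()
        out[u < level / 2] = 0
        out[(u >= level / 2) & (u < level)] = 255
        return GrayImage(out)
    if kind == "gaussian":
        if level == 0:
            return GrayImage(px.copy())
        noisy = px.astype(np.float64) + rng.normal(0.0, level, size=px.shape)
        return GrayImage(np.clip(np.rint(noisy), 0, 255).astype(np.uint8))
    if kind == "poisson":
        if level <= 0:
            raise ValueError("poisson noise requires level > 0")
        draws = rng.poisson(px.astype(np.float64) * level) / level
        return GrayImage(np.clip(np.rint(draws), 0, 255).astype(np.uint8))
    raise ValueError(f"unknown noise kind: {kind!r}")


def default_geometry(spec: StripSpec) -> StripGeometry:
    """StripGeometry matching a spec's painted layout.

    The expected gap is the control-to-T1 spacing; the nominal line width
    covers the line's +/- 2 sigma extent (the same window the ground-truth
    head/end edges use).
    """
    gap = float(spec.test_centers[0] - spec.control_center)
    width = 2 * int(round(2 * spec.line_sigma)) + 1
    return StripGeometry(expected_gap=gap, nominal_line_width=width)
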