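"""Spectral conditioning: baseline, normalization, derivative, subtraction.

The conditioning chain used before band fitting is:

1. average replicate spectra,
2. resample to a uniform 1 cm⁻¹ grid over the analysis region,
3. subtract interfering component spectra (least-squares scaled),
4. multipoint linear baseline correction,
5. (for band localization only) vector-normalized Savitzky–Golay
   second derivative.

Curve fitting itself operates on the baseline-corrected absorbance; the
second derivative is used only to count and place candidate bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import interp1d
from scipy.signal import savgol_filter

from .spectra import Spectrum

__all__ = [
    "BaselineSpec",
    "DerivativeSpec",
    "baseline_correct",
    "vector_normalize",
    "second_derivative",
    "subtract_component",
]


@dataclass(frozen=True)
class BaselineSpec:
    """Multipoint linear baseline: anchors (cm⁻¹) where the baseline is pinned."""

    anchors: tuple = (1590.0, 1710.0)
    mode: str = "multipoint_linear"

    def __post_init__(self):
        anchors = tuple(float(a) for a in self.anchors)
        if len(anchors) < 2:
            raise ValueError("baseline needs at least 2 anchors")
        if any(b <= a for a, b in zip(anchors, anchors[1:])):
            raise ValueError("baseline anchors must be strictly increasing")
        if self.mode != "multipoint_linear":
            raise ValueError(f"unsupported baseline mode {self.mode!r}")
        object.__setattr__(self, "anchors", anchors)


@dataclass(frozen=True)
class DerivativeSpec:
    """Savitzky–Golay second-derivative settings (window in grid points)."""

    window_points: int = 13
    polyorder: int = 3
    order: int = 2

    def __post_init__(self):
        if self.window_points < 5 or self.window_points % 2 == 0:
            raise ValueError("window_points must be an odd integer >= 5")
        if not 2 <= self.polyorder < self.window_points:
            raise ValueError("polyorder must be >= 2 and < window_points")
        if self.order != 2:
            raise ValueError("only the second derivative is supported")


def baseline_correct(spectrum: Spectrum, baseline: BaselineSpec) -> Spectrum:
    """Subtract the piecewise-linear baseline through the spectrum's anchor values.

    The baseline passes through the (interpolated) spectrum values at each
    anchor, so the corrected spectrum is exactly zero there.  Outside the
    outer anchors the end segments are extended linearly.
    """
    lo, hi = spectrum.range
    for a in baseline.anchors:
        if not (lo <= a <= hi):
            raise ValueError(f"baseline anchor {a} outside spectrum range [{lo}, {hi}]")
    anchor_vals = np.interp(baseline.anchors, spectrum.wavenumbers, spectrum.absorbance)
    line = interp1d(
        baseline.anchors, anchor_vals, kind="linear", fill_value="extrapolate"
    )(spectrum.wavenumbers)
    return spectrum.with_absorbance(
        spectrum.absorbance - line, baseline_anchors=",".join(map(str, baseline.anchors))
    )


def vector_normalize(spectrum: Spectrum, region: tuple[float, float]) -> Spectrum:
    """Divide by the Euclidean norm of the absorbance over ``region``."""
    low, high = min(region), max(region)
    mask = (spectrum.wavenumbers >= low) & (spectrum.wavenumbers <= high)
    if mask.sum() < 2:
        raise ValueError(f"normalization region [{low}, {high}] holds fewer than 2 points")
    norm = float(np.linalg.norm(spectrum.absorbance[mask]))
    if norm == 0.0:
        raise ValueError("zero norm over normalization region")
    return spectrum.with_absorbance(spectrum.absorbance / norm, vector_norm=f"{norm:.8g}")


def _check_uniform(spectrum: Spectrum) -> float:
    steps = np.diff(spectrum.wavenumbers)
    dx = float(steps[0])
    if not np.allclose(steps, dx, rtol=1e-6, atol=1e-9):
        raise ValueError("second_derivative requires a uniform wavenumber grid; resample first")
    return dx


def second_derivative(spectrum: Spectrum, spec: DerivativeSpec = DerivativeSpec()) -> Spectrum:
    """Savitzky–Golay second derivative w.r.t. wavenumber (units AU·cm²)."""
    dx = _check_uniform(spectrum)
    if spec.window_points > len(spectrum):
        raise ValueError(
            f"derivative window ({spec.window_points}) exceeds spectrum length ({len(spectrum)})"
        )
    d2 = savgol_filter(
        spectrum.absorbance, spec.window_points, spec.polyorder, deriv=2, delta=dx
    )
    return spectrum.with_absorbance(d2, derivative_order="2")


def subtract_component(
    mixture: Spectrum,
    component: Spectrum,
    reference_region: tuple[float, float] | None = None,
    factor: float | None = None,
) -> Spectrum:
    """Remove ``k * component`` from ``mixture``.

    ``k`` is either supplied (``factor``) or chosen to minimize the squared
    residual over ``reference_region`` subject to k >= 0 — the non-negative
    least-squares projection ``max(0, <m, c> / <c, c>)``.  The factor used is
    recorded in the result's metadata under ``subtraction_factor``.
    """
    if mixture.wavenumbers.size != component.wavenumbers.size or not np.allclose(
        mixture.wavenumbers, component.wavenumbers
    ):
        raise ValueError("mixture and component must share a wavenumber grid")
    if factor is None:
        if reference_region is None:
            reference_region = mixture.range
        low, high = min(reference_region), max(reference_region)
        mask = (mixture.wavenumbers >= low) & (mixture.wavenumbers <= high)
        c = component.absorbance[mask]
        denom = float(c @ c)
        if denom == 0.0:
            raise ValueError("component has zero norm over the reference region")
        factor = max(0.0, float(mixture.absorbance[mask] @ c) / denom)
    elif factor < 0:
        raise ValueError("subtraction factor must be non-negative")
    return mixture.with_absorbance(
        mixture.absorbance - factor * component.absorbance,
        subtraction_factor=f"{factor:.8g}",
        subtracted_component=component.label,
    )
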