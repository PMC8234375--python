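"""Closed-form derivative EPR lineshapes and their integral intensities.

CW-EPR spectra are recorded as the first derivative of the microwave
absorption.  Two pure shapes cover the broadening mechanisms seen in
organic solids: a Gaussian line (inhomogeneous, dipole–dipole broadening)
and a Lorentzian line (homogeneous, exchange-narrowed).  Both are written
in the reduced variable

    x = (B − B0) / (ΔBpp / 2)

so that the derivative extrema sit exactly at x = ±1, i.e. at
B0 ± ΔBpp/2, with values ∓/±Ym:

    Gaussian:    Y(B) = e^{1/2} · Ym · x · exp(−x²/2)
    Lorentzian:  Y(B) = 16 · Ym · x / (3 + x²)²

Both are odd about B0 (so Y(B0) = 0).  The sign convention has the
positive lobe at B > B0; pass ``invert=True`` to :func:`composite` for
spectrometers phased the other way.

The integral intensity A of a component is the double integral of the
derivative (the area under the corresponding absorption line), which is
proportional to the number of contributing spins:

    A_G = (e^{1/2}·sqrt(2π)/4) · Ym · ΔBpp²
    A_L = (2π/sqrt(3))          · Ym · ΔBpp²

These closed forms are exact; Lorentzian tails make naive quadrature
inaccurate, so numeric integration lives only in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .constants import GAUSSIAN_AREA_COEFF, LORENTZIAN_AREA_COEFF
from .exceptions import InvalidParameterError

__all__ = [
    "LineComponent",
    "gaussian_derivative",
    "lorentzian_derivative",
    "evaluate",
    "composite",
    "integral_intensity",
]

Shape = Literal["gaussian", "lorentzian"]

_SHAPES = ("gaussian", "lorentzian")


@dataclass(frozen=True)
class LineComponent:
    """One pure derivative EPR line.

    Parameters
    ----------
    shape:
        ``"gaussian"`` or ``"lorentzian"``.
    B0:
        Resonance field (the zero-crossing of the derivative), mT.
    dBpp:
        Peak-to-peak linewidth ΔBpp (field separation of the derivative
        extrema), mT; must be positive.
    Ym:
        Extremum amplitude, arbitrary units; must be positive.
    """

    shape: Shape
    B0: float
    dBpp: float
    Ym: float

    def __post_init__(self):
        if self.shape not in _SHAPES:
            raise InvalidParameterError(
                f"shape must be one of {_SHAPES}, got {self.shape!r}"
            )
        if not np.isfinite(self.B0):
            raise InvalidParameterError(f"B0 must be finite, got {self.B0}")
        if not (self.dBpp > 0) or not np.isfinite(self.dBpp):
            raise InvalidParameterError(
                f"dBpp must be positive and finite, got {self.dBpp}"
            )
        if not (self.Ym > 0) or not np.isfinite(self.Ym):
            raise InvalidParameterError(
                f"Ym must be positive and finite, got {self.Ym}"
            )


def _reduced_field(B, c: LineComponent):
    return (np.asarray(B, dtype=float) - c.B0) / (c.dBpp / 2.0)


def gaussian_derivative(B, c: LineComponent):
    """Gaussian derivative line, e^{1/2}·Ym·x·exp(−x²/2)."""
    if c.shape != "gaussian":
        raise InvalidParameterError(f"expected gaussian component, got {c.shape}")
    x = _reduced_field(B, c)
    return np.e**0.5 * c.Ym * x * np.exp(-0.5 * x * x)


def lorentzian_derivative(B, c: LineComponent):
    """Lorentzian derivative line, 16·Ym·x/(3 + x²)²."""
    if c.shape != "lorentzian":
        raise InvalidParameterError(f"expected lorentzian component, got {c.shape}")
    x = _reduced_field(B, c)
    return 16.0 * c.Ym * x / (3.0 + x * x) ** 2


def evaluate(B, c: LineComponent):
    """Evaluate a component of either shape at field(s) ``B`` (mT)."""
    if c.shape == "gaussian":
        return gaussian_derivative(B, c)
    return lorentzian_derivative(B, c)


def composite(B, components: Sequence[LineComponent], *, invert: bool = False):
    """Sum of derivative components evaluated at ``B``.

    Exactly linear in each component's Ym.  ``invert`` flips the overall
    sign (opposite detection phase).
    """
    comps = list(components)
    if not comps:
        raise InvalidParameterError("composite requires at least one component")
    total = evaluate(B, comps[0])
    for c in comps[1:]:
        total = total + evaluate(B, c)
    return -total if invert else total


def integral_intensity(c: LineComponent) -> float:
    """Integral intensity A (double integral of the derivative), a.u.·mT².

    Uses the exact closed forms; scales as Ym·ΔBpp² for both shapes.
    """
    coeff = GAUSSIAN_AREA_COEFF if c.shape == "gaussian" else LORENTZIAN_AREA_COEFF
    return coeff * c.Ym * c.dBpp**2


def area_coefficient(shape: Shape) -> float:
    """Shape constant k such that A = k·Ym·ΔBpp²."""
    if shape == "gaussian":
        return GAUSSIAN_AREA_COEFF
    if shape == "lorentzian":
        return LORENTZIAN_AREA_COEFF
    raise InvalidParameterError(f"unknown shape {shape!r}")
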