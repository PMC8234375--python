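"""Microwave-power saturation analysis of deconvolved EPR components.

Recording the same sample at increasing microwave power separates the two
broadening mechanisms: a homogeneously broadened (Lorentzian) line
saturates — its peak-to-peak width grows and its intensity stops
following the incident power — while an inhomogeneously broadened
(Gaussian) line keeps a constant width and its intensity keeps growing
across the whole power range.

The analysis deconvolves every spectrum of a power series (warm-starting
each fit from the previous power so component identity is tracked by
shape label, never by width ordering), assembles per-component curves
ΔBpp(P) and A(P), and classifies each component:

``saturating``
    total width increase above ``width_slope_tol`` AND intensity growth
    that is non-monotone or clearly sub-linear (log–log exponent
    b < 0.25) in the top power decade;
``non_saturating``
    width stable within tolerance AND intensity exponent inside the
    growth band [0.4, 1.1] — wide enough to accept both the ideal CW
    amplitude law (∝ √P, b = 0.5) and growth proportional to power
    itself (b = 1);
``indeterminate``
    anything else, e.g. a series of identical spectra whose intensity
    never grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Tuple

import numpy as np

from .deconvolution import DeconvolutionResult, Spectrum, fit_deconvolution
from .exceptions import ConvergenceError, InvalidParameterError, SeriesError

__all__ = [
    "PowerSeries",
    "SaturationProfile",
    "analyze_power_series",
    "classify_saturation",
]

#: acceptable log–log intensity-growth exponents for an unsaturated line
GROWTH_BAND = (0.4, 1.1)


@dataclass
class PowerSeries:
    """Spectra of one sample recorded at ≥ 4 distinct microwave powers."""

    spectra: List[Spectrum]

    def __post_init__(self):
        if any(s.power is None for s in self.spectra):
            raise InvalidParameterError("every spectrum in a series needs power set")
        powers = [s.power for s in self.spectra]
        if len(set(powers)) < 4:
            raise SeriesError(
                f"need >= 4 distinct powers, got {sorted(set(powers))}"
            )
        freqs = {s.frequency for s in self.spectra}
        if len(freqs) > 1:
            raise InvalidParameterError(
                f"all spectra must share one microwave frequency, got {sorted(freqs)}"
            )
        self.spectra = sorted(self.spectra, key=lambda s: s.power)

    @property
    def powers(self) -> np.ndarray:
        return np.array([s.power for s in self.spectra], dtype=float)


@dataclass
class SaturationProfile:
    """Per-component saturation curves, trend statistics and labels.

    ``curves[shape]`` holds arrays over the usable power grid: ``dBpp``
    (mT), ``area`` (a.u.·mT², double integral) and ``amplitude`` (Ym).
    ``stats[shape]`` records the width change fraction over the series,
    the full-series and top-decade log–log intensity exponents, and
    whether A(P) is non-monotone.  ``classification`` maps shape →
    saturating / non_saturating / indeterminate.
    """

    powers: np.ndarray
    curves: Dict[str, Dict[str, np.ndarray]]
    fits: List[DeconvolutionResult]
    excluded_powers: List[float] = dc_field(default_factory=list)
    stats: Dict[str, dict] = dc_field(default_factory=dict)
    classification: Dict[str, str] = dc_field(default_factory=dict)


def _resample(spectra: List[Spectrum]) -> List[Spectrum]:
    """Put all spectra on the first spectrum's field axis if they differ."""
    ref = spectra[0].field
    out = []
    for s in spectra:
        if s.field.shape == ref.shape and np.allclose(s.field, ref):
            out.append(s)
        else:
            out.append(
                Spectrum(
                    field=ref.copy(),
                    intensity=np.interp(ref, s.field, s.intensity),
                    frequency=s.frequency,
                    power=s.power,
                    mass=s.mass,
                    label=s.label,
                )
            )
    return out


def analyze_power_series(
    ps: PowerSeries,
    *,
    warm_start: bool = True,
    classify: bool = True,
    **fit_kwargs,
) -> SaturationProfile:
    """Deconvolve each power and assemble per-component saturation curves.

    Individual fit failures are excluded (the power is recorded in
    ``excluded_powers``); fewer than 4 usable powers raises
    :class:`SeriesError`.
    """
    from .lineshapes import integral_intensity

    spectra = _resample(ps.spectra)
    fits: List[DeconvolutionResult] = []
    used_powers: List[float] = []
    excluded: List[float] = []
    init = None
    for s in spectra:
        try:
            r = fit_deconvolution(s, init=init, **fit_kwargs)
        except ConvergenceError:
            excluded.append(float(s.power))
            continue
        fits.append(r)
        used_powers.append(float(s.power))
        if warm_start:
            init = r.components
    if len(used_powers) < 4:
        raise SeriesError(
            f"only {len(used_powers)} usable powers after fit failures "
            f"(excluded: {excluded})"
        )

    shapes = sorted({c.shape for r in fits for c in r.components})
    curves: Dict[str, Dict[str, np.ndarray]] = {}
    for shape in shapes:
        dbpp, area, amp = [], [], []
        for r in fits:
            comps = [c for c in r.components if c.shape == shape]
            if not comps:
                dbpp.append(np.nan), area.append(np.nan), amp.append(np.nan)
                continue
            dbpp.append(sum(c.dBpp for c in comps) / len(comps))
            area.append(sum(integral_intensity(c) for c in comps))
            amp.append(sum(c.Ym for c in comps))
        curves[shape] = {
            "dBpp": np.array(dbpp),
            "area": np.array(area),
            "amplitude": np.array(amp),
        }

    profile = SaturationProfile(
        powers=np.array(used_powers),
        curves=curves,
        fits=fits,
        excluded_powers=excluded,
    )
    if classify:
        classify_saturation(profile)
    return profile


def _loglog_slope(P: np.ndarray, A: np.ndarray) -> float:
    mask = (P > 0) & (A > 0)
    if mask.sum() < 2:
        return float("nan")
    return float(np.polyfit(np.log(P[mask]), np.log(A[mask]), 1)[0])


def classify_saturation(
    profile: SaturationProfile,
    *,
    width_slope_tol: float = 0.05,
    intensity_drop_tol: float = 0.05,
    growth_band: Tuple[float, float] = GROWTH_BAND,
    sublinear_exponent: float = 0.25,
) -> Dict[str, str]:
    """Label each component saturating / non_saturating / indeterminate.

    ``width_slope_tol`` is the total fractional ΔBpp change over the
    series regarded as "constant"; ``intensity_drop_tol`` the fractional
    step-to-step drop in A(P) regarded as genuine non-monotonicity rather
    than noise.  Updates and returns ``profile.classification``.
    """
    P = profile.powers
    out: Dict[str, str] = {}
    for shape, c in profile.curves.items():
        dbpp, area = c["dBpp"], c["area"]
        ok = np.isfinite(dbpp) & np.isfinite(area)
        if ok.sum() < 4:
            out[shape] = "indeterminate"
            profile.stats[shape] = {"usable": int(ok.sum())}
            continue
        p, w, a = P[ok], dbpp[ok], area[ok]

        width_change = float((w[-1] - w[0]) / w[0])
        drops = np.diff(a) < -intensity_drop_tol * a[:-1]
        nonmonotone = bool(np.any(drops))
        b_full = _loglog_slope(p, a)
        # top-decade exponent as the log–log secant: below full saturation
        # the curve is not a power law, and a least-squares slope over
        # unevenly spaced powers is biased by that curvature
        top = p >= p[-1] / 10.0
        if top.sum() < 2:
            top = np.zeros_like(top, dtype=bool)
            top[-2:] = True
        pt, at = p[top], a[top]
        if at[0] > 0 and at[-1] > 0 and pt[-1] > pt[0]:
            b_top = float(np.log(at[-1] / at[0]) / np.log(pt[-1] / pt[0]))
        else:
            b_top = float("nan")

        width_grows = width_change > width_slope_tol
        width_stable = abs(width_change) < width_slope_tol
        saturating_intensity = nonmonotone or (
            np.isfinite(b_top) and b_top < sublinear_exponent
        )
        growing = np.isfinite(b_full) and growth_band[0] <= b_full <= growth_band[1]

        if width_grows and saturating_intensity:
            label = "saturating"
        elif width_stable and growing:
            label = "non_saturating"
        else:
            label = "indeterminate"
        out[shape] = label
        profile.stats[shape] = {
            "width_change": width_change,
            "b_full": b_full,
            "b_top": b_top,
            "nonmonotone": nonmonotone,
        }
    profile.classification = out
    return out
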