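"""Elemental maturity indices for humic acids.

The atomic ratios O/C and O/H and the internal oxidation degree

    ω = (2·O + 3·N − H) / C

computed from atomic percentages are standard indices of how oxidized —
how "mature" — a humic acid is: humification strips hydrogen-rich
aliphatics and accumulates oxygen functionality, so mature forest-soil
humic acids show higher O/C, O/H and ω than freshly incubated plant
material.

All three indices are projective: they are unchanged when (C, H, N, O)
are rescaled by a common factor, so atomic percentages need not sum to
exactly 100 (ash and minor elements account for the remainder).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import pandas as pd

from .exceptions import InvalidParameterError

__all__ = [
    "ElementalComposition",
    "MaturityIndices",
    "atomic_ratios",
    "internal_oxidation",
    "maturity_indices",
    "mass_to_atomic",
    "indices_table",
]

# IUPAC 2021 conventional atomic weights
_ATOMIC_WEIGHTS = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999}


@dataclass(frozen=True)
class ElementalComposition:
    """CHNO composition of one sample, in atomic percent.

    The four percentages must be non-negative with C strictly positive,
    and their sum must fall within ``sum_bounds`` (default 95–101 %,
    leaving room for ash and unanalyzed elements).  Set
    ``sum_bounds=None`` to skip the closure check.
    """

    C: float
    H: float
    N: float
    O: float
    label: str = ""
    sum_bounds: Optional[Tuple[float, float]] = (95.0, 101.0)

    def __post_init__(self):
        if not (self.C > 0):
            raise InvalidParameterError(f"C must be positive, got {self.C}")
        for name in ("H", "N", "O"):
            v = getattr(self, name)
            if v < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {v}")
        if self.sum_bounds is not None:
            total = self.C + self.H + self.N + self.O
            lo, hi = self.sum_bounds
            if not (lo <= total <= hi):
                raise InvalidParameterError(
                    f"atomic percentages of {self.label!r} sum to {total:.2f}, "
                    f"outside [{lo}, {hi}]"
                )


@dataclass(frozen=True)
class MaturityIndices:
    """Derived indices: O/C, O/H and internal oxidation degree ω."""

    O_C: float
    O_H: float
    omega: float
    label: str = ""

    def rounded(self, ndigits: int = 3) -> "MaturityIndices":
        """Half-even rounding for report output (full precision kept here)."""
        import decimal

        def r(v):
            q = decimal.Decimal(10) ** -ndigits
            return float(
                decimal.Decimal(repr(v)).quantize(q, rounding=decimal.ROUND_HALF_EVEN)
            )

        return MaturityIndices(r(self.O_C), r(self.O_H), r(self.omega), self.label)


def atomic_ratios(ec: ElementalComposition) -> Tuple[float, float]:
    """Atomic ratios (O/C, O/H)."""
    if not (ec.H > 0):
        raise InvalidParameterError(f"H must be positive for O/H, got {ec.H}")
    return ec.O / ec.C, ec.O / ec.H


def internal_oxidation(ec: ElementalComposition) -> float:
    """Internal oxidation degree ω = (2O + 3N − H)/C.

    Positive when oxygen (counted twice, for its two bonds) plus nitrogen
    outweigh hydrogen; grows as the material oxidizes.
    """
    return (2.0 * ec.O + 3.0 * ec.N - ec.H) / ec.C


def maturity_indices(ec: ElementalComposition) -> MaturityIndices:
    """All three indices for one composition."""
    o_c, o_h = atomic_ratios(ec)
    return MaturityIndices(o_c, o_h, internal_oxidation(ec), ec.label)


def mass_to_atomic(C: float, H: float, N: float, O: float, label: str = "") -> ElementalComposition:
    """Convert mass percentages (CHN-analyzer output) to atomic percent."""
    moles = {
        "C": C / _ATOMIC_WEIGHTS["C"],
        "H": H / _ATOMIC_WEIGHTS["H"],
        "N": N / _ATOMIC_WEIGHTS["N"],
        "O": O / _ATOMIC_WEIGHTS["O"],
    }
    total = sum(moles.values())
    if total <= 0:
        raise InvalidParameterError("mass percentages sum to zero")
    at = {k: 100.0 * v / total for k, v in moles.items()}
    return ElementalComposition(at["C"], at["H"], at["N"], at["O"], label=label)


def indices_table(df: pd.DataFrame, basis: str = "atomic") -> pd.DataFrame:
    """Compute indices for a table of samples.

    ``df`` needs columns label, C, H, N, O; ``basis`` is ``atomic`` or
    ``mass``.  Returns the input columns plus full-precision O/C, O/H, ω
    and their 3-decimal report roundings.
    """
    if basis not in ("atomic", "mass"):
        raise InvalidParameterError(f"basis must be 'atomic' or 'mass', got {basis!r}")
    rows = []
    for _, row in df.iterrows():
        label = str(row.get("label", ""))
        if basis == "mass":
            ec = mass_to_atomic(row["C"], row["H"], row["N"], row["O"], label)
        else:
            ec = ElementalComposition(row["C"], row["H"], row["N"], row["O"], label)
        mi = maturity_indices(ec)
        mr = mi.rounded(3)
        rows.append(
            {
                "label": label,
                "C": ec.C,
                "H": ec.H,
                "N": ec.N,
                "O": ec.O,
                "O_C": mi.O_C,
                "O_H": mi.O_H,
                "omega": mi.omega,
                "O_C_3dp": mr.O_C,
                "O_H_3dp": mr.O_H,
                "omega_3dp": mr.omega,
            }
        )
    return pd.DataFrame(rows)
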