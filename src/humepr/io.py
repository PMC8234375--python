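"""Readers and writers for the plain-text formats the package exchanges.

Spectra travel as two-column delimited text (field mT or G vs intensity
for EPR; wavelength nm vs intensity for fluorescence) with ``#`` comment
lines; acquisition metadata written by :func:`write_spectrum` is parsed
back from ``# key: value`` comments so files round-trip losslessly.
Separators may be commas, semicolons, tabs or whitespace; one header
line of column names is tolerated.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .deconvolution import Spectrum
from .exceptions import InvalidParameterError, ParseError
from .fluorescence import FluorescenceSpectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_elemental_csv",
    "read_manifest",
    "write_json",
]

_SPLIT = re.compile(r"[,;\t ]+")

_META_KEYS = {
    "frequency_ghz": float,
    "power_mw": float,
    "mass_g": float,
    "excitation_nm": float,
    "label": str,
}


def _parse_two_columns(path) -> Tuple[np.ndarray, np.ndarray, dict]:
    xs, ys = [], []
    meta: dict = {}
    header_allowed = True
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    key = key.strip().lower()
                    if key in _META_KEYS:
                        try:
                            meta[key] = _META_KEYS[key](value.strip())
                        except ValueError:
                            pass
                continue
            tokens = [t for t in _SPLIT.split(line) if t]
            if len(tokens) < 2:
                raise ParseError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                x, y = float(tokens[0]), float(tokens[1])
            except ValueError:
                if header_allowed:
                    header_allowed = False
                    continue
                raise ParseError(
                    f"{path}:{lineno}: non-numeric row {line!r}"
                ) from None
            header_allowed = False
            xs.append(x)
            ys.append(y)
    if not xs:
        raise ParseError(f"{path}: no numeric data rows found")
    return np.asarray(xs), np.asarray(ys), meta


def read_spectrum(
    path: Union[str, Path],
    kind: str = "epr",
    *,
    field_unit: str = "mT",
    frequency: Optional[float] = None,
    power: Optional[float] = None,
    mass: Optional[float] = None,
    excitation: Optional[float] = None,
    label: Optional[str] = None,
):
    """Read a two-column spectral file.

    ``kind`` selects the container: ``epr`` gives a :class:`Spectrum`
    (``field_unit="G"`` divides the axis by 10 to convert gauss to mT);
    ``fluorescence`` gives a :class:`FluorescenceSpectrum`.  Explicit
    keyword metadata overrides anything read from file comments.
    """
    x, y, meta = _parse_two_columns(path)
    name = label if label is not None else meta.get("label", Path(path).stem)
    if kind == "epr":
        if field_unit == "G":
            x = x / 10.0
        elif field_unit != "mT":
            raise InvalidParameterError(f"field_unit must be mT or G, got {field_unit!r}")
        freq = frequency if frequency is not None else meta.get("frequency_ghz")
        if freq is None:
            raise InvalidParameterError(
                f"{path}: microwave frequency not in file metadata; pass frequency="
            )
        return Spectrum(
            field=x,
            intensity=y,
            frequency=float(freq),
            power=power if power is not None else meta.get("power_mw"),
            mass=mass if mass is not None else meta.get("mass_g"),
            label=name,
        )
    if kind == "fluorescence":
        exc = excitation if excitation is not None else meta.get("excitation_nm", 340.0)
        return FluorescenceSpectrum(
            wavelength=x, intensity=y, excitation=float(exc), label=name
        )
    raise InvalidParameterError(f"kind must be 'epr' or 'fluorescence', got {kind!r}")


def write_spectrum(spectrum, path: Union[str, Path]) -> Path:
    """Write a spectrum as two-column text with metadata comments."""
    path = Path(path)
    lines = []
    if isinstance(spectrum, Spectrum):
        lines.append("# humepr EPR derivative spectrum (field mT, intensity a.u.)")
        lines.append(f"# frequency_GHz: {spectrum.frequency!r}")
        if spectrum.power is not None:
            lines.append(f"# power_mW: {spectrum.power!r}")
        if spectrum.mass is not None:
            lines.append(f"# mass_g: {spectrum.mass!r}")
        if spectrum.label:
            lines.append(f"# label: {spectrum.label}")
        x, y = spectrum.field, spectrum.intensity
    elif isinstance(spectrum, FluorescenceSpectrum):
        lines.append("# humepr fluorescence emission spectrum (wavelength nm, intensity a.u.)")
        lines.append(f"# excitation_nm: {spectrum.excitation!r}")
        if spectrum.label:
            lines.append(f"# label: {spectrum.label}")
        x, y = spectrum.wavelength, spectrum.intensity
    else:
        raise InvalidParameterError(f"cannot write object of type {type(spectrum)}")
    for xi, yi in zip(x, y):
        lines.append(f"{float(xi)!r}\t{float(yi)!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_elemental_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read a sample table with columns label, C, H, N, O (+ optional basis)."""
    df = pd.read_csv(path, comment="#", skipinitialspace=True)
    missing = {"C", "H", "N", "O"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    if "label" not in df.columns:
        df.insert(0, "label", [f"sample{i}" for i in range(len(df))])
    return df


def read_manifest(path: Union[str, Path]) -> List[Tuple[Path, float]]:
    """Read a power-series manifest: TSV/CSV mapping spectrum file → power mW.

    Relative file paths are resolved against the manifest's directory.
    """
    path = Path(path)
    entries: List[Tuple[Path, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = [t for t in _SPLIT.split(line) if t]
            if len(tokens) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'file power_mW'")
            try:
                p = float(tokens[-1])
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise ParseError(f"{path}:{lineno}: non-numeric power {tokens[-1]!r}") from None
            entries.append((path.parent / tokens[0], p))
    if not entries:
        raise ParseError(f"{path}: empty manifest")
    return entries


def write_json(obj, path: Union[str, Path]) -> Path:
    """Serialize a report dict to pretty-printed JSON (numpy-safe)."""
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return {k: v for k, v in vars(o).items() if not k.startswith("_")}
        return str(o)

    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")
    return path
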