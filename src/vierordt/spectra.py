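"""UV–Vis spectrum container, CSV I/O, interpolation and band-maximum detection.

A :class:`Spectrum` holds one absorbance trace on a strictly increasing
wavelength grid, as recorded by a scanning UV spectrophotometer over the
instrument range (200–400 nm by default). Absorbances are read off the grid
by linear interpolation; absorption maxima are located by parabolic
refinement of the discrete maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from os import PathLike
from typing import Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "SpectrumParseError",
    "read_spectrum",
    "write_spectrum",
    "absorbance_at",
    "find_lambda_max",
]

#: Default scanning range of the instrument, nm.
DEFAULT_INSTRUMENT_RANGE = (200.0, 400.0)


class SpectrumParseError(ValueError):
    """Raised when a spectrum CSV file cannot be parsed."""


@dataclass(frozen=True)
class Spectrum:
    """One absorbance trace on a wavelength grid.

    Parameters
    ----------
    wavelengths : array-like
        Wavelength grid in nm, strictly increasing, length >= 2, inside
        ``instrument_range``.
    absorbances : array-like
        Absorbance in AU at each grid point; all finite.
    pathlength : float
        Cell pathlength in cm (default 1 cm quartz cell).
    label : str
        Free-text sample or analyte identifier.
    concentration : float or None
        Analyte concentration in µg/ml, if the spectrum belongs to a
        single-component standard.
    instrument_range : (float, float)
        Declared scanning range in nm; grid points must lie inside it.
    """

    wavelengths: np.ndarray
    absorbances: np.ndarray
    pathlength: float = 1.0
    label: str = ""
    concentration: float | None = None
    instrument_range: tuple[float, float] = DEFAULT_INSTRUMENT_RANGE

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbances, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelength grid must be 1-D with at least 2 points")
        if ab.shape != wl.shape:
            raise ValueError(
                f"absorbances length {ab.size} != wavelengths length {wl.size}"
            )
        if not np.all(np.isfinite(wl)):
            raise ValueError("wavelengths must be finite")
        if not np.all(np.isfinite(ab)):
            raise ValueError("absorbances must be finite")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        lo, hi = self.instrument_range
        if wl[0] < lo or wl[-1] > hi:
            raise ValueError(
                f"grid [{wl[0]}, {wl[-1]}] nm outside instrument range "
                f"[{lo}, {hi}] nm"
            )
        if not (self.pathlength > 0):
            raise ValueError("pathlength must be positive")
        wl.setflags(write=False)
        ab.setflags(write=False)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbances", ab)

    def __len__(self) -> int:
        return self.wavelengths.size

    # convenience wrappers -------------------------------------------------
    def absorbance_at(self, wavelength):
        return absorbance_at(self, wavelength)

    def lambda_max(self, window: tuple[float, float] | None = None) -> float:
        return find_lambda_max(self, window)


def _parse_metadata(line: str, meta: dict) -> None:
    body = line.lstrip("#").strip()
    if "=" not in body:
        return
    key, _, value = body.partition("=")
    meta[key.strip()] = value.strip()


def read_spectrum(path: str | PathLike) -> Spectrum:
    """Read a spectrum from CSV (``wavelength_nm,absorbance``).

    Leading ``#`` comment lines may carry ``label``,
    ``concentration_ug_per_ml`` and ``pathlength_cm`` metadata. Rows are
    sorted by wavelength if the file is unordered; duplicate wavelengths or
    non-numeric fields raise :class:`SpectrumParseError` naming the line.
    """
    meta: dict[str, str] = {}
    wl: list[float] = []
    ab: list[float] = []
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                _parse_metadata(line, meta)
                continue
            if not header_seen:
                header_seen = True
                first = line.split(",")[0].strip()
                try:
                    float(first)
                except ValueError:
                    continue  # header row
            parts = line.split(",")
            if len(parts) != 2:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: expected 2 fields, got {len(parts)}"
                )
            try:
                w, a = float(parts[0]), float(parts[1])
            except ValueError:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: non-numeric value {line!r}"
                ) from None
            wl.append(w)
            ab.append(a)
    if len(wl) < 2:
        raise SpectrumParseError(f"{path}: fewer than 2 data rows")
    order = np.argsort(np.asarray(wl), kind="stable")
    wl_arr = np.asarray(wl)[order]
    ab_arr = np.asarray(ab)[order]
    dup = np.flatnonzero(np.diff(wl_arr) == 0)
    if dup.size:
        raise SpectrumParseError(
            f"{path}: duplicate wavelength {wl_arr[dup[0]]} nm"
        )
    conc = meta.get("concentration_ug_per_ml")
    return Spectrum(
        wavelengths=wl_arr,
        absorbances=ab_arr,
        pathlength=float(meta.get("pathlength_cm", 1.0)),
        label=meta.get("label", ""),
        concentration=float(conc) if conc is not None else None,
    )


def write_spectrum(spectrum: Spectrum, path: str | PathLike) -> None:
    """Write a spectrum as CSV readable by :func:`read_spectrum`.

    Values are serialized with 17 significant digits so that a read/write
    round trip is exact after float parsing.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# label={spectrum.label}\n")
        if spectrum.concentration is not None:
            fh.write(f"# concentration_ug_per_ml={spectrum.concentration!r}\n")
        fh.write(f"# pathlength_cm={spectrum.pathlength!r}\n")
        fh.write("wavelength_nm,absorbance\n")
        for w, a in zip(spectrum.wavelengths, spectrum.absorbances):
            fh.write(f"{float(w)!r},{float(a)!r}\n")


def absorbance_at(spectrum: Spectrum, wavelength) -> float | np.ndarray:
    """Absorbance at ``wavelength`` (nm) by linear interpolation.

    Exact on grid points; raises ``ValueError`` outside the grid. Accepts a
    scalar or an array of wavelengths.
    """
    wl = spectrum.wavelengths
    q = np.asarray(wavelength, dtype=float)
    if np.any(q < wl[0]) or np.any(q > wl[-1]):
        raise ValueError(
            f"wavelength {wavelength} nm outside grid [{wl[0]}, {wl[-1]}] nm"
        )
    out = np.interp(q, wl, spectrum.absorbances)
    return float(out) if np.isscalar(wavelength) else out


def find_lambda_max(
    spectrum: Spectrum, window: tuple[float, float] | None = None
) -> float:
    """Wavelength of maximum absorbance, parabolic-refined.

    The discrete maximum inside ``window`` (whole grid if absent) is refined
    by fitting a parabola through it and its two neighbours; the refined
    position is clamped to the neighbour interval. Ties break toward the
    lower wavelength. A flat trace raises ``ValueError`` (no distinct
    maximum), as does a window that misses the grid.
    """
    wl, ab = spectrum.wavelengths, spectrum.absorbances
    if window is not None:
        lo, hi = window
        mask = (wl >= lo) & (wl <= hi)
        if not mask.any():
            raise ValueError(f"window [{lo}, {hi}] nm outside grid")
        wl, ab = wl[mask], ab[mask]
    if wl.size < 3:
        raise ValueError("need at least 3 points to locate a maximum")
    if np.ptp(ab) == 0:
        raise ValueError("flat spectrum: no distinct maximum")
    i = int(np.argmax(ab))  # first occurrence == lower-wavelength tie-break
    if i == 0 or i == wl.size - 1:
        return float(wl[i])
    x0, x1, x2 = wl[i - 1], wl[i], wl[i + 1]
    y0, y1, y2 = ab[i - 1], ab[i], ab[i + 1]
    if not (y0 < y1 and y2 < y1):  # plateau: keep the lower-wavelength point
        return float(x1)
    # vertex of the interpolating parabola (general, non-uniform grid)
    d01 = (y1 - y0) / (x1 - x0)
    d12 = (y2 - y1) / (x2 - x1)
    curv = (d12 - d01) / (x2 - x0)
    if curv >= 0:  # plateau or upward kink: keep the discrete maximum
        return float(x1)
    vertex = 0.5 * (x0 + x1 - d01 / curv)
    return float(min(max(vertex, x0), x2))
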