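"""Simultaneous-equation (Vierordt) quantification of drug mixtures.

An n-component mixture measured at n wavelengths obeys, by Beer–Lambert
additivity,

    A(λ_i) = Σ_j a_ij · C_j        (C_j in g/100 ml, 1 cm cell)

where a_ij is the absorptivity A(1 g/100 ml, 1 cm) of component j at
wavelength λ_i. For two components the concentrations follow in closed form
(Cramer's rule); the general solver handles any square system with
condition-number diagnostics.

Two published coefficient sets ship as presets:

``lok-atl``
    losartan potassium / atenolol at 251.60 and 224.20 nm,
    [[320.25, 8.1], [661.75, 380.50]].
``atl-hctz``
    atenolol / hydrochlorothiazide at 224.20 and 271.60 nm,
    [[866.75, 1288], [106.0, 720]].
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from os import PathLike
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "AbsorptivityMatrix",
    "MixtureMeasurement",
    "MixtureResult",
    "SingularSystemError",
    "build_matrix",
    "preset_matrix",
    "vierordt_denominator",
    "solve_two_component",
    "solve_general",
    "condition_diagnostics",
    "convert_units",
    "read_matrix",
    "write_matrix",
    "PRESET_NAMES",
]

UG_PER_ML_PER_G_PER_100ML = 1.0e4

#: relative |det| threshold below which a system is treated as singular
SINGULAR_RTOL = 1e-12
#: condition-number thresholds for the advisory levels
COND_WARN = 1e3
COND_ERROR = 1e8


class SingularSystemError(ValueError):
    """Raised when the absorptivity matrix is singular or near-singular."""


@dataclass(frozen=True)
class AbsorptivityMatrix:
    """Per-wavelength, per-component absorptivities.

    ``values[i, j]`` is the absorptivity A(1 g/100 ml, 1 cm) of component
    ``components[j]`` at ``wavelengths[i]``. Entries must be finite and
    non-negative; wavelengths and component names must be unique.
    """

    components: tuple[str, ...]
    wavelengths: tuple[float, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        wls = tuple(float(w) for w in self.wavelengths)
        vals = np.asarray(self.values, dtype=float)
        if len(set(comps)) != len(comps):
            raise ValueError("duplicate component names")
        if len(set(wls)) != len(wls):
            raise ValueError("duplicate wavelengths")
        if vals.shape != (len(wls), len(comps)):
            raise ValueError(
                f"values shape {vals.shape} != ({len(wls)}, {len(comps)})"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("absorptivities must be finite")
        if np.any(vals < 0):
            raise ValueError("absorptivities must be non-negative")
        vals.setflags(write=False)
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "wavelengths", wls)
        object.__setattr__(self, "values", vals)

    @property
    def is_square(self) -> bool:
        return len(self.components) == len(self.wavelengths)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"AbsorptivityMatrix(components={self.components}, "
            f"wavelengths={self.wavelengths})"
        )


@dataclass(frozen=True)
class MixtureMeasurement:
    """Absorbance readings of one mixture at the analytical wavelengths."""

    wavelengths: tuple[float, ...]
    absorbances: np.ndarray
    pathlength: float = 1.0

    def __post_init__(self) -> None:
        wls = tuple(float(w) for w in self.wavelengths)
        ab = np.atleast_1d(np.asarray(self.absorbances, dtype=float))
        if ab.size != len(wls):
            raise ValueError("absorbances length != wavelengths length")
        if not np.all(np.isfinite(ab)):
            raise ValueError("absorbances must be finite")
        if not (self.pathlength > 0):
            raise ValueError("pathlength must be positive")
        ab.setflags(write=False)
        object.__setattr__(self, "wavelengths", wls)
        object.__setattr__(self, "absorbances", ab)


@dataclass(frozen=True)
class MixtureResult:
    """Solved component concentrations with solver diagnostics.

    ``concentrations_ug_per_ml`` is exactly 10^4 × the g/100 ml vector.
    ``flags`` may contain ``negative_concentration``, ``out_of_beers_range``
    and ``ill_conditioned``.
    """

    components: tuple[str, ...]
    concentrations_g_per_100ml: np.ndarray
    determinant: float
    condition_estimate: float
    flags: frozenset[str] = frozenset()

    @property
    def concentrations_ug_per_ml(self) -> np.ndarray:
        return self.concentrations_g_per_100ml * UG_PER_ML_PER_G_PER_100ML

    def as_dict(self) -> dict:
        return {
            "components": list(self.components),
            "concentrations_g_per_100ml": self.concentrations_g_per_100ml.tolist(),
            "concentrations_ug_per_ml": self.concentrations_ug_per_ml.tolist(),
            "determinant": self.determinant,
            "condition_estimate": self.condition_estimate,
            "flags": sorted(self.flags),
        }


def build_matrix(
    components: Sequence[str],
    wavelengths: Sequence[float],
    absorptivities,
) -> AbsorptivityMatrix:
    """Validated :class:`AbsorptivityMatrix`; row/column order is preserved."""
    return AbsorptivityMatrix(
        components=tuple(components),
        wavelengths=tuple(wavelengths),
        values=np.asarray(absorptivities, dtype=float),
    )


_PRESETS: dict[str, AbsorptivityMatrix] = {
    "lok-atl": build_matrix(
        ("LOK", "ATL"), (251.60, 224.20), [[320.25, 8.1], [661.75, 380.50]]
    ),
    "atl-hctz": build_matrix(
        ("ATL", "HCTZ"), (224.20, 271.60), [[866.75, 1288.0], [106.0, 720.0]]
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset_matrix(name: str) -> AbsorptivityMatrix:
    """Published absorptivity matrix by preset name (see module docstring)."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(_PRESETS)}"
        ) from None


def vierordt_denominator(matrix: AbsorptivityMatrix) -> float:
    """Signed denominator of the two-component concentration formulas.

    The classical rearrangement writes each concentration as a reversed
    numerator over the *negated* determinant, so this returns
    ``-(a11·a22 - a12·a21)``. For the ``lok-atl`` preset the value is
    -116494.95, for ``atl-hctz`` -487532.
    """
    if matrix.values.shape != (2, 2):
        raise ValueError("vierordt_denominator requires a 2x2 matrix")
    (a11, a12), (a21, a22) = matrix.values
    return -(a11 * a22 - a12 * a21)


def _flags_for(
    matrix: AbsorptivityMatrix,
    conc_g: np.ndarray,
    cond: float,
    beers_ranges: Mapping[str, tuple[float, float]] | None,
) -> frozenset[str]:
    flags = set()
    if np.any(conc_g < 0):
        flags.add("negative_concentration")
    if cond >= COND_WARN:
        flags.add("ill_conditioned")
    if beers_ranges:
        for name, c in zip(matrix.components, conc_g * UG_PER_ML_PER_G_PER_100ML):
            rng = beers_ranges.get(name)
            if rng is not None and not (rng[0] <= c <= rng[1]):
                flags.add("out_of_beers_range")
    return frozenset(flags)


def _det_tolerance(values: np.ndarray) -> float:
    row_norms = np.abs(values).max(axis=1)
    return SINGULAR_RTOL * float(np.prod(row_norms))


def _check_measurement(matrix: AbsorptivityMatrix, meas: MixtureMeasurement):
    if tuple(meas.wavelengths) != tuple(matrix.wavelengths):
        raise ValueError(
            f"measurement wavelengths {meas.wavelengths} do not match "
            f"matrix rows {matrix.wavelengths}"
        )
    # Beer–Lambert: absorbance scales with pathlength; normalise to 1 cm
    return meas.absorbances / meas.pathlength


def solve_two_component(
    matrix: AbsorptivityMatrix,
    measurement: MixtureMeasurement,
    beers_ranges: Mapping[str, tuple[float, float]] | None = None,
) -> MixtureResult:
    """Closed-form (Cramer's rule) solution of a 2×2 mixture system.

    Algebraically identical to the published rearranged formulas
    C1 = (A2·a12 − A1·a22)/D, C2 = (A1·a21 − A2·a11)/D with D the
    :func:`vierordt_denominator`. Raises :class:`SingularSystemError` when
    |det| falls below an absolute tolerance scaled to the row norms.
    """
    if matrix.values.shape != (2, 2):
        raise ValueError("solve_two_component requires a 2x2 matrix")
    a = _check_measurement(matrix, measurement)
    (a11, a12), (a21, a22) = matrix.values
    det = a11 * a22 - a12 * a21
    if abs(det) < _det_tolerance(matrix.values):
        raise SingularSystemError(f"singular system: |det| = {abs(det):.3e}")
    denom = -det
    c1 = (a[1] * a12 - a[0] * a22) / denom
    c2 = (a[0] * a21 - a[1] * a11) / denom
    conc = np.array([c1, c2])
    cond = float(np.linalg.cond(matrix.values))
    return MixtureResult(
        components=matrix.components,
        concentrations_g_per_100ml=conc,
        determinant=float(det),
        condition_estimate=cond,
        flags=_flags_for(matrix, conc, cond, beers_ranges),
    )


def solve_general(
    matrix: AbsorptivityMatrix,
    measurement: MixtureMeasurement,
    beers_ranges: Mapping[str, tuple[float, float]] | None = None,
) -> MixtureResult:
    """Direct (LU) solution of an n×n mixture system.

    Agrees with :func:`solve_two_component` on 2×2 systems to ~1e-9
    relative. Negative concentrations are returned but flagged; a condition
    number at or above 1e8 raises :class:`SingularSystemError`.
    """
    if not matrix.is_square:
        raise ValueError(
            f"need a square system, got {len(matrix.wavelengths)} wavelengths "
            f"for {len(matrix.components)} components"
        )
    a = _check_measurement(matrix, measurement)
    det = float(np.linalg.det(matrix.values))
    if abs(det) < _det_tolerance(matrix.values):
        raise SingularSystemError(f"singular system: |det| = {abs(det):.3e}")
    cond = float(np.linalg.cond(matrix.values))
    if not np.isfinite(cond) or cond >= COND_ERROR:
        raise SingularSystemError(f"ill-conditioned system: cond = {cond:.3e}")
    conc = np.linalg.solve(matrix.values, a)
    return MixtureResult(
        components=matrix.components,
        concentrations_g_per_100ml=conc,
        determinant=det,
        condition_estimate=cond,
        flags=_flags_for(matrix, conc, cond, beers_ranges),
    )


def condition_diagnostics(matrix: AbsorptivityMatrix) -> tuple[float, str]:
    """2-norm condition estimate with an advisory level.

    Levels: ``ok`` below 1e3, ``warn`` in [1e3, 1e8), ``error`` at >= 1e8
    (a singular matrix reports an infinite condition number).
    """
    if not matrix.is_square:
        raise ValueError("condition diagnostics require a square matrix")
    if abs(float(np.linalg.det(matrix.values))) < _det_tolerance(matrix.values):
        return float("inf"), "error"
    cond = float(np.linalg.cond(matrix.values))
    if not np.isfinite(cond) or cond >= COND_ERROR:
        return cond, "error"
    return cond, "warn" if cond >= COND_WARN else "ok"


_UNIT_TO_G_PER_100ML = {
    "g/100 ml": 1.0,
    "g/100ml": 1.0,
    "g_per_100ml": 1.0,
    "ug/ml": 1e-4,
    "µg/ml": 1e-4,
    "ug_per_ml": 1e-4,
    "mg/ml": 0.1,
    "mg_per_ml": 0.1,
}


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Exact concentration-unit conversion.

    1 g/100 ml = 10^4 µg/ml = 10 mg/ml. Recognised spellings:
    ``g/100 ml``, ``ug/ml`` (or ``µg/ml``), ``mg/ml`` and underscore forms.
    """
    try:
        f = _UNIT_TO_G_PER_100ML[from_unit.strip().lower()]
        t = _UNIT_TO_G_PER_100ML[to_unit.strip().lower()]
    except KeyError as exc:
        raise ValueError(f"unknown concentration unit: {exc.args[0]!r}") from None
    return value * f / t


def write_matrix(matrix: AbsorptivityMatrix, path: str | PathLike) -> None:
    """Write a matrix as CSV: header ``wavelength_nm,<comp>,...``."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["wavelength_nm", *matrix.components])
        for w, row in zip(matrix.wavelengths, matrix.values):
            writer.writerow([repr(float(w)), *[repr(float(v)) for v in row]])


def read_matrix(path: str | PathLike) -> AbsorptivityMatrix:
    """Read a matrix CSV written by :func:`write_matrix`."""
    with open(path, encoding="utf-8", newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    if len(rows) < 2:
        raise ValueError(f"{path}: matrix file needs a header and data rows")
    header = rows[0]
    if header[0].strip() != "wavelength_nm":
        raise ValueError(f"{path}: first column must be wavelength_nm")
    components = [c.strip() for c in header[1:]]
    wavelengths = [float(r[0]) for r in rows[1:]]
    values = [[float(v) for v in r[1:]] for r in rows[1:]]
    return build_matrix(components, wavelengths, values)
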