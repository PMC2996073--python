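"""Beer's-law calibration: linear regression, mean absorptivity, range checks.

Within its linearity ("Beer's law") range an analyte's absorbance at a fixed
wavelength is linear in concentration, A = slope·c + intercept. Calibration
curves are fitted by ordinary least squares of absorbance on concentration
(intercept always fitted — real curves carry small nonzero intercepts), and
the mean absorptivity A(1 g/100 ml, 1 cm) is estimated as the mean of A/c
ratios over independent dilutions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from os import PathLike
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "fit_beers_law",
    "mean_absorptivity",
    "check_beers_range",
    "read_calibration_series",
    "REFERENCE_CURVES",
]

#: µg/ml per g/100 ml — absorptivities are quoted per 1 g/100 ml.
UG_PER_ML_PER_G_PER_100ML = 1.0e4


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted Beer's-law line for one analyte at one wavelength.

    ``slope`` is in AU per (µg/ml), ``intercept`` in AU, ``correlation`` the
    Pearson r, and ``range_low``/``range_high`` the linearity range in µg/ml.
    """

    analyte: str
    wavelength: float
    slope: float
    intercept: float
    correlation: float
    range_low: float
    range_high: float
    n_points: int

    def __post_init__(self) -> None:
        if not self.range_low < self.range_high:
            raise ValueError("range_low must be < range_high")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if abs(self.correlation) > 1 + 1e-12:
            raise ValueError("|correlation| must be <= 1")

    def predict(self, concentration):
        """Absorbance predicted at ``concentration`` (µg/ml)."""
        return self.slope * np.asarray(concentration) + self.intercept

    def to_config(self) -> str:
        """Serialize as a key=value block."""
        return "".join(f"{k} = {v}\n" for k, v in asdict(self).items())

    @classmethod
    def from_config(cls, text: str) -> "CalibrationCurve":
        fields: dict[str, str] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            fields[key.strip()] = value.strip()
        return cls(
            analyte=fields["analyte"],
            wavelength=float(fields["wavelength"]),
            slope=float(fields["slope"]),
            intercept=float(fields["intercept"]),
            correlation=float(fields["correlation"]),
            range_low=float(fields["range_low"]),
            range_high=float(fields["range_high"]),
            n_points=int(fields["n_points"]),
        )


def fit_beers_law(
    concentrations: Sequence[float],
    absorbances: Sequence[float],
    analyte: str = "",
    wavelength: float = float("nan"),
) -> CalibrationCurve:
    """Ordinary least-squares fit of absorbance on concentration.

    Returns a :class:`CalibrationCurve` whose range is the [min, max] of the
    input concentrations. Raises on mismatched lengths, fewer than two
    points, or a degenerate design (all concentrations equal).
    """
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if c.shape != a.shape:
        raise ValueError("concentrations and absorbances differ in length")
    if c.size < 2:
        raise ValueError("need at least 2 calibration points")
    if np.ptp(c) == 0:
        raise ValueError("degenerate design: all concentrations identical")
    res = stats.linregress(c, a)
    r = res.rvalue
    if np.isnan(r):  # zero variance in absorbance: perfectly flat response
        r = 0.0
    return CalibrationCurve(
        analyte=analyte,
        wavelength=wavelength,
        slope=float(res.slope),
        intercept=float(res.intercept),
        correlation=float(np.clip(r, -1.0, 1.0)),
        range_low=float(c.min()),
        range_high=float(c.max()),
        n_points=int(c.size),
    )


def mean_absorptivity(
    dilutions: Sequence[tuple[float, float]], wavelength: float = float("nan")
) -> float:
    """Mean absorptivity in A(1 g/100 ml, 1 cm) units from dilution readings.

    Each dilution is a ``(concentration µg/ml, absorbance AU)`` pair; the
    estimate is the mean of A/c ratios with c converted to g/100 ml
    (1 g/100 ml = 10^4 µg/ml). Any non-positive concentration raises.
    """
    if len(dilutions) == 0:
        raise ValueError("at least one dilution required")
    ratios = []
    for c, a in dilutions:
        if c <= 0:
            raise ValueError(f"invalid dilution: concentration {c} µg/ml <= 0")
        ratios.append(a / (c / UG_PER_ML_PER_G_PER_100ML))
    return float(np.mean(ratios))


def check_beers_range(curve: CalibrationCurve, concentration: float) -> bool:
    """True iff ``concentration`` lies inside the curve's linearity range.

    The range is closed: boundary values are in range. Quantification
    outside the range should be flagged downstream.
    """
    return bool(curve.range_low <= concentration <= curve.range_high)


def read_calibration_series(path: str | PathLike):
    """Read a calibration CSV (``concentration_ug_per_ml,absorbance``).

    ``# analyte=`` and ``# wavelength_nm=`` comment lines carry metadata.
    Returns ``(concentrations, absorbances, analyte, wavelength)``.
    """
    analyte = ""
    wavelength = float("nan")
    conc: list[float] = []
    ab: list[float] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                key, _, value = body.partition("=")
                if key.strip() == "analyte":
                    analyte = value.strip()
                elif key.strip() == "wavelength_nm":
                    wavelength = float(value)
                continue
            parts = line.split(",")
            try:
                conc.append(float(parts[0]))
                ab.append(float(parts[1]))
            except ValueError:
                if lineno <= 5 and len(conc) == 0:
                    continue  # header row
                raise ValueError(f"{path}: line {lineno}: non-numeric row") from None
    return np.asarray(conc), np.asarray(ab), analyte, wavelength


#: Published calibration parameters for the three analytes: slope in
#: AU/(µg/ml), intercept in AU, Pearson r, and linearity range in µg/ml.
REFERENCE_CURVES: dict[str, CalibrationCurve] = {
    "LOK": CalibrationCurve("LOK", 251.60, 0.03315, 0.02127, 0.9991, 5.0, 30.0, 6),
    "ATL": CalibrationCurve("ATL", 224.20, 0.08503, 0.01713, 0.9995, 2.0, 12.0, 6),
    "HCTZ": CalibrationCurve("HCTZ", 271.60, 0.06673, 0.00657, 0.9993, 2.0, 14.0, 6),
}
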