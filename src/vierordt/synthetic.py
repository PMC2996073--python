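"""Synthetic UV spectrum generator — an instrument stand-in.

Pure-component spectra are emulated as sums of Gaussian absorptivity bands
whose evaluated values at the analytical wavelengths (251.60, 224.20,
271.60 nm) reproduce the published absorptivity coefficients of losartan
potassium (LOK), atenolol (ATL) and hydrochlorothiazide (HCTZ). Only those
three-wavelength anchors are constrained by data; the full curve shape is
an emulation, not a reconstruction of the real spectra.

Mixtures follow Beer–Lambert additivity; instrument noise is zero-mean
Gaussian on absorbance (default sd 0.002 AU), drawn from a seeded
generator so every dataset is reproducible.

ATL's published absorptivity at 224.20 nm differs between the two
coefficient systems (380.50 in LOK/ATL vs 866.75 in ATL/HCTZ). The
generator therefore targets the system under test:
:func:`system_band_models` returns an ATL model consistent with whichever
preset matrix will be used for solving, keeping each system's round trip
exact rather than averaging the conflicting values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import optimize

from .mixture import MixtureMeasurement, preset_matrix

__all__ = [
    "GaussianBand",
    "BandModel",
    "NoiseModel",
    "preset_band_models",
    "system_band_models",
    "simulate_pure_spectrum",
    "simulate_mixture_spectrum",
    "generate_calibration_series",
    "generate_recovery_experiment",
    "generate_assay_samples",
    "RecoveryLevel",
    "RecoveryExperiment",
    "AssaySamples",
    "DEFAULT_GRID_NM",
    "DEFAULT_RANGE_NM",
]

from .spectra import Spectrum

DEFAULT_GRID_NM = 0.2
DEFAULT_RANGE_NM = (200.0, 400.0)
UG_PER_ML_PER_G_PER_100ML = 1.0e4

#: published linearity ranges, µg/ml
BEERS_RANGES = {"LOK": (5.0, 30.0), "ATL": (2.0, 12.0), "HCTZ": (2.0, 14.0)}


@dataclass(frozen=True)
class GaussianBand:
    """One Gaussian absorptivity band: A(1 g/100 ml, 1 cm) vs wavelength."""

    center: float  # nm
    sigma: float  # nm (standard-deviation width)
    peak: float  # A(1 g/100 ml, 1 cm) at the band center

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError("band width must be positive")
        if not (190.0 <= self.center <= 410.0):
            raise ValueError("band center must lie in 190-410 nm")
        if self.peak < 0:
            raise ValueError("peak absorptivity must be non-negative")

    def __call__(self, wavelength):
        wl = np.asarray(wavelength, dtype=float)
        return self.peak * np.exp(-((wl - self.center) ** 2) / (2 * self.sigma**2))


@dataclass(frozen=True)
class BandModel:
    """Summed-Gaussian absorptivity model of one analyte."""

    analyte: str
    bands: tuple[GaussianBand, ...]
    beers_range: tuple[float, float] | None = None

    def absorptivity(self, wavelength):
        """A(1 g/100 ml, 1 cm) at ``wavelength`` (nm); scalar or array."""
        total = sum(band(wavelength) for band in self.bands)
        return float(total) if np.isscalar(wavelength) else total


@dataclass(frozen=True)
class NoiseModel:
    """Zero-mean Gaussian absorbance noise with a reproducibility seed."""

    absorbance_sd: float = 0.002  # AU
    seed: int = 0

    def __post_init__(self) -> None:
        if self.absorbance_sd < 0:
            raise ValueError("absorbance_sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _solve_peaks(centers_sigmas, anchors) -> np.ndarray:
    """Peak heights such that the band sum hits every anchor exactly."""
    design = np.array(
        [
            [math.exp(-((w - c) ** 2) / (2 * s**2)) for c, s in centers_sigmas]
            for w in anchors
        ]
    )
    peaks = np.linalg.solve(design, np.array(list(anchors.values())))
    if np.any(peaks < 0):
        raise ValueError("band layout yields a negative peak")
    return peaks


@lru_cache(maxsize=None)
def _lok_model() -> BandModel:
    # local band at the 251.60 nm maximum + a deep-UV edge band that carries
    # the larger absorptivity at 224.20 nm
    layout = ((251.60, 8.0), (203.0, 11.0))
    peaks = _solve_peaks(layout, {251.60: 320.25, 224.20: 661.75})
    return BandModel(
        "LOK",
        tuple(GaussianBand(c, s, p) for (c, s), p in zip(layout, peaks)),
        BEERS_RANGES["LOK"],
    )


@lru_cache(maxsize=None)
def _hctz_model() -> BandModel:
    layout = ((271.60, 10.0), (215.0, 13.0))
    peaks = _solve_peaks(layout, {224.20: 1288.0, 271.60: 720.0})
    return BandModel(
        "HCTZ",
        tuple(GaussianBand(c, s, p) for (c, s), p in zip(layout, peaks)),
        BEERS_RANGES["HCTZ"],
    )


@lru_cache(maxsize=None)
def _atl_model() -> BandModel:
    # main band at 224.20 nm plus a weak long-wavelength shoulder; the main
    # band's width is solved so all three anchors (866.75 @ 224.20,
    # 8.1 @ 251.60, 106.0 @ 271.60) hold simultaneously
    shoulder = (285.0, 12.0)

    def g(w, c, s):
        return math.exp(-((w - c) ** 2) / (2 * s**2))

    def residual(sigma1: float) -> float:
        layout = ((224.20, sigma1), shoulder)
        design = np.array(
            [[g(w, c, s) for c, s in layout] for w in (224.20, 271.60)]
        )
        p = np.linalg.solve(design, np.array([866.75, 106.0]))
        return p[0] * g(251.60, 224.20, sigma1) + p[1] * g(251.60, *shoulder) - 8.1

    sigma1 = optimize.brentq(residual, 7.5, 9.5, xtol=1e-12)
    layout = ((224.20, sigma1), shoulder)
    # the width solve makes the third anchor (8.1 @ 251.60) hold as well
    peaks = _solve_peaks(layout, {224.20: 866.75, 271.60: 106.0})
    return BandModel(
        "ATL",
        tuple(GaussianBand(c, s, p) for (c, s), p in zip(layout, peaks)),
        BEERS_RANGES["ATL"],
    )


@lru_cache(maxsize=None)
def _atl_model_lok_atl_variant() -> BandModel:
    # single Gaussian at 224.20 nm whose width is chosen analytically so the
    # tail at 251.60 nm equals 8.1 while the peak equals 380.50
    sigma = (251.60 - 224.20) / math.sqrt(2.0 * math.log(380.50 / 8.1))
    return BandModel(
        "ATL",
        (GaussianBand(224.20, sigma, 380.50),),
        BEERS_RANGES["ATL"],
    )


def preset_band_models() -> tuple[BandModel, BandModel, BandModel]:
    """Canonical (LOK, ATL, HCTZ) band models.

    The ATL model here satisfies all three of its published anchors
    (8.1 @ 251.60, 866.75 @ 224.20, 106.0 @ 271.60 nm); for solving against
    the LOK/ATL coefficient set use :func:`system_band_models` instead.
    """
    return _lok_model(), _atl_model(), _hctz_model()


def system_band_models(preset: str) -> tuple[BandModel, ...]:
    """Band models ordered to match :func:`~vierordt.mixture.preset_matrix`.

    ``lok-atl`` returns (LOK, ATL-consistent-with-380.50);
    ``atl-hctz`` returns (ATL-consistent-with-866.75, HCTZ).
    """
    if preset == "lok-atl":
        return _lok_model(), _atl_model_lok_atl_variant()
    if preset == "atl-hctz":
        return _atl_model(), _hctz_model()
    raise KeyError(f"unknown preset {preset!r}; available: lok-atl, atl-hctz")


def _grid(grid_nm: float, wavelength_range) -> np.ndarray:
    lo, hi = wavelength_range
    return np.arange(lo, hi + grid_nm / 2, grid_nm)


def simulate_pure_spectrum(
    model: BandModel,
    concentration_ug_per_ml: float,
    noise: NoiseModel | None = None,
    grid_nm: float = DEFAULT_GRID_NM,
    wavelength_range=DEFAULT_RANGE_NM,
) -> Spectrum:
    """Forward Beer–Lambert spectrum of one analyte at one concentration."""
    if concentration_ug_per_ml < 0:
        raise ValueError("concentration must be >= 0")
    if not (grid_nm > 0):
        raise ValueError("grid spacing must be positive")
    noise = noise or NoiseModel(absorbance_sd=0.0)
    wl = _grid(grid_nm, wavelength_range)
    c_g = concentration_ug_per_ml / UG_PER_ML_PER_G_PER_100ML
    ab = c_g * model.absorptivity(wl)
    if noise.absorbance_sd > 0:
        ab = ab + noise.rng().normal(0.0, noise.absorbance_sd, wl.size)
    return Spectrum(
        wavelengths=wl,
        absorbances=ab,
        label=model.analyte,
        concentration=concentration_ug_per_ml,
    )


def simulate_mixture_spectrum(
    models: Sequence[BandModel],
    concentrations_ug_per_ml: Sequence[float],
    noise: NoiseModel | None = None,
    grid_nm: float = DEFAULT_GRID_NM,
    wavelength_range=DEFAULT_RANGE_NM,
) -> Spectrum:
    """Additive mixture spectrum; noise added once to the summed trace."""
    if len(models) != len(concentrations_ug_per_ml):
        raise ValueError("models and concentrations differ in length")
    if any(c < 0 for c in concentrations_ug_per_ml):
        raise ValueError("concentrations must be >= 0")
    noise = noise or NoiseModel(absorbance_sd=0.0)
    wl = _grid(grid_nm, wavelength_range)
    ab = np.zeros_like(wl)
    for model, c in zip(models, concentrations_ug_per_ml):
        ab = ab + (c / UG_PER_ML_PER_G_PER_100ML) * model.absorptivity(wl)
    if noise.absorbance_sd > 0:
        ab = ab + noise.rng().normal(0.0, noise.absorbance_sd, wl.size)
    label = "+".join(m.analyte for m in models)
    return Spectrum(wavelengths=wl, absorbances=ab, label=label)


def _measure(
    models: Sequence[BandModel],
    concentrations_ug_per_ml: Sequence[float],
    wavelengths: Sequence[float],
    sd: float,
    rng: np.random.Generator,
) -> MixtureMeasurement:
    """One noisy absorbance reading set at the analytical wavelengths."""
    wl = np.asarray(wavelengths, dtype=float)
    ab = np.zeros(wl.size)
    for model, c in zip(models, concentrations_ug_per_ml):
        ab += (c / UG_PER_ML_PER_G_PER_100ML) * model.absorptivity(wl)
    if sd > 0:
        ab = ab + rng.normal(0.0, sd, wl.size)
    return MixtureMeasurement(wavelengths=tuple(wl), absorbances=ab)


def generate_calibration_series(
    model: BandModel,
    wavelength: float,
    concentrations_ug_per_ml: Sequence[float],
    noise: NoiseModel | None = None,
) -> list[tuple[float, float]]:
    """(concentration, absorbance) pairs read from simulated spectra.

    Concentrations outside the analyte's declared linearity range trigger a
    ``UserWarning`` but are still generated.
    """
    import warnings

    noise = noise or NoiseModel(absorbance_sd=0.0)
    rng = noise.rng()
    if model.beers_range is not None:
        lo, hi = model.beers_range
        for c in concentrations_ug_per_ml:
            if not (lo <= c <= hi):
                warnings.warn(
                    f"{model.analyte}: {c} µg/ml outside linearity range "
                    f"[{lo}, {hi}] µg/ml",
                    stacklevel=2,
                )
    series = []
    for c in concentrations_ug_per_ml:
        a = (c / UG_PER_ML_PER_G_PER_100ML) * model.absorptivity(wavelength)
        if noise.absorbance_sd > 0:
            a += rng.normal(0.0, noise.absorbance_sd)
        series.append((float(c), float(a)))
    return series


@dataclass(frozen=True)
class RecoveryLevel:
    """Paired spiked/unspiked measurements at one spiking level."""

    level_percent: float
    added_ug_per_ml: tuple[float, ...]  # per component
    unspiked: tuple[MixtureMeasurement, ...]
    spiked: tuple[MixtureMeasurement, ...]


@dataclass(frozen=True)
class RecoveryExperiment:
    """Simulated standard-addition experiment for one analyte system."""

    components: tuple[str, ...]
    wavelengths: tuple[float, ...]
    base_concentrations_ug_per_ml: tuple[float, ...]
    levels: tuple[RecoveryLevel, ...]


def generate_recovery_experiment(
    models: Sequence[BandModel],
    wavelengths: Sequence[float],
    base_concentrations_ug_per_ml: Sequence[float],
    spike_levels_percent: Sequence[float] = (80.0, 100.0, 120.0),
    n_replicates: int = 3,
    noise: NoiseModel | None = None,
) -> RecoveryExperiment:
    """Spiked/unspiked replicate measurements for a recovery study.

    Each spiking level adds ``level/100 × base`` of every component to the
    base mixture; ``n_replicates`` spiked and unspiked readings are
    generated per level at the given analytical wavelengths.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if any(lv <= 0 for lv in spike_levels_percent):
        raise ValueError("spike levels must be positive")
    noise = noise or NoiseModel(absorbance_sd=0.0)
    rng = noise.rng()
    base = np.asarray(base_concentrations_ug_per_ml, dtype=float)
    levels = []
    for lv in spike_levels_percent:
        added = base * (lv / 100.0)
        unspiked = tuple(
            _measure(models, base, wavelengths, noise.absorbance_sd, rng)
            for _ in range(n_replicates)
        )
        spiked = tuple(
            _measure(models, base + added, wavelengths, noise.absorbance_sd, rng)
            for _ in range(n_replicates)
        )
        levels.append(
            RecoveryLevel(
                level_percent=float(lv),
                added_ug_per_ml=tuple(added),
                unspiked=unspiked,
                spiked=spiked,
            )
        )
    return RecoveryExperiment(
        components=tuple(m.analyte for m in models),
        wavelengths=tuple(float(w) for w in wavelengths),
        base_concentrations_ug_per_ml=tuple(base),
        levels=tuple(levels),
    )


@dataclass(frozen=True)
class AssaySamples:
    """Replicate tablet-assay measurements plus the generating truth."""

    components: tuple[str, ...]
    wavelengths: tuple[float, ...]
    measurements: tuple[MixtureMeasurement, ...]
    true_concentrations_ug_per_ml: tuple[float, ...]


def generate_assay_samples(
    models: Sequence[BandModel],
    wavelengths: Sequence[float],
    label_claims_mg: Sequence[float],
    average_tablet_weight_mg: float,
    sample_weight_mg: float,
    stock_volume_ml: float,
    dilution_factor: float,
    n_replicates: int = 5,
    noise: NoiseModel | None = None,
) -> AssaySamples:
    """Replicate mixture measurements of a simulated tablet sample.

    The true solution concentration of each analyte follows the dilution
    chain (weighed powder → stock volume → working dilution); with zero
    noise the downstream assay returns the label claims exactly.
    """
    for name, val in [
        ("average_tablet_weight_mg", average_tablet_weight_mg),
        ("sample_weight_mg", sample_weight_mg),
        ("stock_volume_ml", stock_volume_ml),
        ("dilution_factor", dilution_factor),
    ]:
        if not (val > 0):
            raise ValueError(f"{name} must be positive")
    noise = noise or NoiseModel(absorbance_sd=0.0)
    rng = noise.rng()
    true_c = tuple(
        label * (sample_weight_mg / average_tablet_weight_mg) * 1000.0
        / (stock_volume_ml * dilution_factor)
        for label in label_claims_mg
    )
    measurements = tuple(
        _measure(models, true_c, wavelengths, noise.absorbance_sd, rng)
        for _ in range(n_replicates)
    )
    return AssaySamples(
        components=tuple(m.analyte for m in models),
        wavelengths=tuple(float(w) for w in wavelengths),
        measurements=measurements,
        true_concentrations_ug_per_ml=true_c,
    )
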