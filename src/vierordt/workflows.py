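"""End-to-end workflows: simulate → read → solve → validation statistics.

These functions wire the synthetic generator, the simultaneous-equation
solver and the validation statistics into the complete procedures an
analyst runs: quantifying a scanned mixture spectrum, a standard-addition
recovery study, and a tablet assay against label claim. Each accepts a
preset name (``lok-atl`` or ``atl-hctz``) and reproduces that system's
published experimental design by default.
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np

from .mixture import (
    AbsorptivityMatrix,
    MixtureMeasurement,
    MixtureResult,
    preset_matrix,
    solve_general,
    solve_two_component,
)
from .spectra import Spectrum, absorbance_at
from .synthetic import (
    BEERS_RANGES,
    NoiseModel,
    generate_assay_samples,
    generate_recovery_experiment,
    system_band_models,
)
from .validation import (
    AssayReport,
    RecoveryReport,
    assay_tablets,
    recovery_study,
)

__all__ = [
    "quantify_spectrum",
    "solve_measurement",
    "run_recovery_simulation",
    "run_assay_simulation",
    "ASSAY_DESIGNS",
    "RECOVERY_BASES",
]

#: published base mixture concentrations (µg/ml) of the recovery designs
RECOVERY_BASES = {"lok-atl": (20.0, 20.0), "atl-hctz": (8.0, 2.0)}

#: tablet assay designs: label claims (mg/tablet) and the dilution scheme
#: bringing a 50 mg-equivalent sample in 100 ml to the working range
ASSAY_DESIGNS = {
    "lok-atl": {
        "label_claims_mg": (50.0, 50.0),
        "stock_volume_ml": 100.0,
        "dilution_factor": 25.0,  # 500 µg/ml stock → 20 µg/ml working
        "average_tablet_weight_mg": 200.0,
        "sample_weight_mg": 200.0,
    },
    "atl-hctz": {
        "label_claims_mg": (50.0, 12.5),
        "stock_volume_ml": 100.0,
        "dilution_factor": 62.5,  # 500 µg/ml stock → 8 µg/ml working
        "average_tablet_weight_mg": 200.0,
        "sample_weight_mg": 200.0,
    },
}


def solve_measurement(
    matrix: AbsorptivityMatrix, measurement: MixtureMeasurement
) -> MixtureResult:
    """Solve one measurement, closed-form for 2×2 systems, LU otherwise."""
    if matrix.values.shape == (2, 2):
        return solve_two_component(matrix, measurement, BEERS_RANGES)
    return solve_general(matrix, measurement, BEERS_RANGES)


def quantify_spectrum(
    spectrum: Spectrum, matrix: AbsorptivityMatrix
) -> MixtureResult:
    """Read the analytical wavelengths off a scanned spectrum and solve."""
    absorbances = absorbance_at(spectrum, np.asarray(matrix.wavelengths))
    meas = MixtureMeasurement(
        wavelengths=matrix.wavelengths,
        absorbances=absorbances,
        pathlength=spectrum.pathlength,
    )
    return solve_measurement(matrix, meas)


def run_recovery_simulation(
    preset: str = "lok-atl",
    base_concentrations_ug_per_ml: Sequence[float] | None = None,
    spike_levels_percent: Sequence[float] = (80.0, 100.0, 120.0),
    n_replicates: int = 3,
    noise_sd: float = 0.002,
    seed: int = 0,
    baseline: Literal["preanalyzed", "paired"] = "preanalyzed",
) -> list[RecoveryReport]:
    """Simulated standard-addition recovery study for one preset system.

    With ``baseline="preanalyzed"`` (default) the unspiked replicates are
    averaged into a single preanalyzed content per level — matching the
    procedure of spiking into an already-analyzed tablet solution — and
    replicate scatter comes from the spiked readings alone. With
    ``"paired"`` each spiked replicate is differenced against its own
    unspiked partner. Returns one report per (spiking level, analyte).
    """
    matrix = preset_matrix(preset)
    models = system_band_models(preset)
    base = (
        RECOVERY_BASES[preset]
        if base_concentrations_ug_per_ml is None
        else tuple(base_concentrations_ug_per_ml)
    )
    experiment = generate_recovery_experiment(
        models,
        matrix.wavelengths,
        base,
        spike_levels_percent,
        n_replicates,
        NoiseModel(absorbance_sd=noise_sd, seed=seed),
    )
    reports: list[RecoveryReport] = []
    for level in experiment.levels:
        unspiked_c = np.array(
            [
                solve_measurement(matrix, m).concentrations_ug_per_ml
                for m in level.unspiked
            ]
        )
        spiked_c = np.array(
            [
                solve_measurement(matrix, m).concentrations_ug_per_ml
                for m in level.spiked
            ]
        )
        for j, analyte in enumerate(matrix.components):
            if baseline == "preanalyzed":
                unspiked_found = float(unspiked_c[:, j].mean())
            else:
                unspiked_found = unspiked_c[:, j]
            reports.append(
                recovery_study(
                    unspiked_found,
                    spiked_c[:, j],
                    added=level.added_ug_per_ml[j],
                    level_percent=level.level_percent,
                    analyte=analyte,
                )
            )
    return reports


def run_assay_simulation(
    preset: str = "lok-atl",
    noise_sd: float = 0.002,
    seed: int = 0,
    n_replicates: int = 5,
    **design_overrides,
) -> list[AssayReport]:
    """Simulated tablet assay: five replicate analyses vs. label claim.

    Design parameters (label claims, weights, dilution scheme) default to
    :data:`ASSAY_DESIGNS` for the preset and may be overridden by keyword.
    Returns one report per analyte.
    """
    matrix = preset_matrix(preset)
    models = system_band_models(preset)
    design = {**ASSAY_DESIGNS[preset], **design_overrides}
    samples = generate_assay_samples(
        models,
        matrix.wavelengths,
        design["label_claims_mg"],
        design["average_tablet_weight_mg"],
        design["sample_weight_mg"],
        design["stock_volume_ml"],
        design["dilution_factor"],
        n_replicates,
        NoiseModel(absorbance_sd=noise_sd, seed=seed),
    )
    solved = np.array(
        [
            solve_measurement(matrix, m).concentrations_ug_per_ml
            for m in samples.measurements
        ]
    )
    return [
        assay_tablets(
            solved[:, j],
            dilution_factor=design["dilution_factor"],
            stock_volume_ml=design["stock_volume_ml"],
            sample_weight_mg=design["sample_weight_mg"],
            average_tablet_weight_mg=design["average_tablet_weight_mg"],
            label_claim_mg=design["label_claims_mg"][j],
            analyte=analyte,
        )
        for j, analyte in enumerate(matrix.components)
    ]
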