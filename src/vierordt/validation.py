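"""Method-validation statistics: assay, recovery and precision reports.

Implements the statistics an analytical-method validation reports: tablet
assay against label claim, standard-addition recovery at 80/100/120%
spiking levels, and precision as repeatability, intra-/inter-day %RSD and
per-analyst ruggedness. Sample standard deviations use the n−1 denominator
throughout, the convention for the small replicate counts (n = 3–5) of
analytical validation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "AssayReport",
    "RecoveryReport",
    "PrecisionReport",
    "percent_rsd",
    "assay_tablets",
    "recovery_study",
    "precision_study",
]


@dataclass(frozen=True)
class AssayReport:
    """Tablet assay result for one analyte: amount found vs. label claim."""

    analyte: str
    label_claim: float  # mg/tablet
    amount_found: float  # mg/tablet, mean over replicates
    sd: float  # mg/tablet
    rsd_percent: float
    percent_label_claim: float
    n: int

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RecoveryReport:
    """Standard-addition recovery at one spiking level for one analyte."""

    analyte: str
    level_percent: float
    n: int
    mean_recovery_percent: float
    rsd_percent: float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PrecisionReport:
    """Repeatability, intra-/inter-day precision and ruggedness RSDs."""

    repeatability_rsd: float  # %RSD of one-session replicates
    intraday_rsd_range: tuple[float, float]  # (min, max) over levels × days
    interday_rsd_range: tuple[float, float]  # (min, max) over levels
    analyst_rsds: dict[str, float]  # ruggedness: %RSD per analyst

    def as_dict(self) -> dict:
        return {
            "repeatability_rsd": self.repeatability_rsd,
            "intraday_rsd_range": list(self.intraday_rsd_range),
            "interday_rsd_range": list(self.interday_rsd_range),
            "analyst_rsds": dict(self.analyst_rsds),
        }


def percent_rsd(values: Sequence[float]) -> float:
    """Relative standard deviation, 100 × sample sd (n−1) / |mean|."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError(f"need >= 2 replicates for %RSD, got {v.size}")
    mean = v.mean()
    if mean == 0:
        raise ValueError("%RSD undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / abs(mean))


def _amount_found_mg_per_tab(
    concentration_ug_per_ml: float,
    dilution_factor: float,
    stock_volume_ml: float,
    sample_weight_mg: float,
    average_tablet_weight_mg: float,
) -> float:
    # back-calculate through the dilution chain:
    # measured c × dilution = stock c (µg/ml); × volume = µg in weighed sample;
    # × (tablet weight / sample weight) = µg per tablet; /1000 → mg
    return (
        concentration_ug_per_ml
        * dilution_factor
        * stock_volume_ml
        * average_tablet_weight_mg
        / (sample_weight_mg * 1000.0)
    )


def assay_tablets(
    replicate_concentrations_ug_per_ml: Sequence[float],
    dilution_factor: float,
    stock_volume_ml: float,
    sample_weight_mg: float,
    average_tablet_weight_mg: float,
    label_claim_mg: float,
    analyte: str = "",
) -> AssayReport:
    """Tablet assay from solved replicate concentrations.

    Each replicate concentration (µg/ml, as measured in the final dilution)
    is back-calculated to mg/tablet through the dilution chain; the report
    carries the replicate mean, sd, %RSD and percentage of label claim.
    """
    for name, val in [
        ("dilution_factor", dilution_factor),
        ("stock_volume_ml", stock_volume_ml),
        ("sample_weight_mg", sample_weight_mg),
        ("average_tablet_weight_mg", average_tablet_weight_mg),
        ("label_claim_mg", label_claim_mg),
    ]:
        if not (val > 0):
            raise ValueError(f"{name} must be positive, got {val}")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    conc = np.asarray(replicate_concentrations_ug_per_ml, dtype=float)
    if conc.size < 1:
        raise ValueError("need at least one replicate")
    amounts = np.array(
        [
            _amount_found_mg_per_tab(
                c, dilution_factor, stock_volume_ml,
                sample_weight_mg, average_tablet_weight_mg,
            )
            for c in conc
        ]
    )
    mean = float(amounts.mean())
    sd = float(amounts.std(ddof=1)) if conc.size >= 2 else 0.0
    rsd = percent_rsd(amounts) if conc.size >= 2 else 0.0
    return AssayReport(
        analyte=analyte,
        label_claim=float(label_claim_mg),
        amount_found=mean,
        sd=sd,
        rsd_percent=rsd,
        percent_label_claim=100.0 * mean / float(label_claim_mg),
        n=int(conc.size),
    )


def recovery_study(
    unspiked_found,
    spiked_found: Sequence[float],
    added: float,
    level_percent: float,
    analyte: str = "",
) -> RecoveryReport:
    """Standard-addition recovery: increment over the amount added.

    ``unspiked_found`` is either a single preanalyzed baseline amount or a
    sequence paired replicate-by-replicate with ``spiked_found``. Each
    replicate recovery is 100 × (spiked − baseline)/added; negative
    recoveries are reported as-is, never clamped.
    """
    if not (added > 0):
        raise ValueError(f"added amount must be positive, got {added}")
    spiked = np.asarray(spiked_found, dtype=float)
    if spiked.size < 1:
        raise ValueError("need at least one spiked replicate")
    baseline = np.asarray(unspiked_found, dtype=float)
    if baseline.ndim == 0:
        baseline = np.full(spiked.shape, float(baseline))
    elif baseline.size == 1:
        baseline = np.full(spiked.shape, float(baseline[0]))
    elif baseline.shape != spiked.shape:
        raise ValueError(
            "unspiked_found must be scalar or match spiked_found in length"
        )
    recoveries = 100.0 * (spiked - baseline) / added
    rsd = percent_rsd(recoveries) if spiked.size >= 2 else 0.0
    return RecoveryReport(
        analyte=analyte,
        level_percent=float(level_percent),
        n=int(spiked.size),
        mean_recovery_percent=float(recoveries.mean()),
        rsd_percent=rsd,
    )


def precision_study(
    repeatability_replicates: Sequence[float],
    day_runs: Mapping[str, Sequence[Sequence[float]]],
    analyst_runs: Mapping[str, Sequence[float]],
) -> PrecisionReport:
    """Precision summary across sessions, days and analysts.

    ``day_runs`` maps a concentration level to its per-day replicate groups:
    intra-day RSDs are computed within each (level, day) group and reported
    as a (min, max) range; inter-day RSD is computed per level across the
    day *means* and likewise reported as a range over levels.
    ``analyst_runs`` maps analyst name to that analyst's replicates
    (ruggedness). Any group with fewer than 2 replicates raises.
    """
    repeatability = percent_rsd(repeatability_replicates)

    intraday: list[float] = []
    interday: list[float] = []
    for level, days in day_runs.items():
        if len(days) < 2:
            raise ValueError(f"level {level!r}: need >= 2 days")
        day_means = []
        for day in days:
            day = np.asarray(day, dtype=float)
            if day.size < 2:
                raise ValueError(
                    f"level {level!r}: each day needs >= 2 replicates"
                )
            intraday.append(percent_rsd(day))
            day_means.append(day.mean())
        interday.append(percent_rsd(day_means))
    if not intraday:
        raise ValueError("day_runs must contain at least one level")

    analyst_rsds = {
        name: percent_rsd(values) for name, values in analyst_runs.items()
    }
    return PrecisionReport(
        repeatability_rsd=repeatability,
        intraday_rsd_range=(min(intraday), max(intraday)),
        interday_rsd_range=(min(interday), max(interday)),
        analyst_rsds=analyst_rsds,
    )
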