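"""Precision summary: repeatability, intra-/inter-day RSD and ruggedness.

Simulates repeated assays of the losartan/atenolol system on two days at
two concentration levels and by two analysts, then condenses them into the
standard precision report.
"""

import numpy as np

import vierordt as v
from vierordt.synthetic import NoiseModel
from vierordt.workflows import solve_measurement


def assay_once(level_ug_per_ml, seed):
    matrix = v.preset_matrix("lok-atl")
    models = v.system_band_models("lok-atl")
    exp = v.generate_recovery_experiment(
        models, matrix.wavelengths, (level_ug_per_ml, level_ug_per_ml),
        (100.0,), 1, NoiseModel(0.002, seed),
    )
    meas = exp.levels[0].unspiked[0]
    return solve_measurement(matrix, meas).concentrations_ug_per_ml[0]


day_runs = {
    level: [[assay_once(level, 100 * day + i) for i in range(3)]
            for day in range(2)]
    for level in (10.0, 20.0)
}
analyst_runs = {
    f"analyst {k}": [assay_once(20.0, 1000 * k + i) for i in range(5)]
    for k in (1, 2)
}
repeatability = [assay_once(20.0, 9000 + i) for i in range(5)]

report = v.precision_study(repeatability, day_runs, analyst_runs)
print(f"repeatability %RSD (n=5): {report.repeatability_rsd:.3f}")
print(f"intra-day %RSD range:     {report.intraday_rsd_range[0]:.3f} - "
      f"{report.intraday_rsd_range[1]:.3f}")
print(f"inter-day %RSD range:     {report.interday_rsd_range[0]:.3f} - "
      f"{report.interday_rsd_range[1]:.3f}")
for name, rsd in report.analyst_rsds.items():
    print(f"ruggedness {name}: %RSD {rsd:.3f}")
print("Sub-percent RSDs across days and analysts indicate the method's "
      "scatter is dominated by read noise, not the operator or the day.")
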