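"""Fit a Beer's-law calibration line and estimate the mean absorptivity.

Generates a noiseless six-point atenolol series at 224.20 nm from the band
model, fits absorbance on concentration by ordinary least squares and
converts the slope into A(1 g/100 ml, 1 cm) units.
"""

import numpy as np

import vierordt as v

_, atl, _ = v.preset_band_models()
concentrations = np.linspace(2.0, 12.0, 6)  # µg/ml, the linearity range
series = v.generate_calibration_series(atl, 224.20, concentrations)

fit = v.fit_beers_law(*zip(*series), analyte="ATL", wavelength=224.20)
absorptivity = v.mean_absorptivity(series)

print(f"fit: A = {fit.slope:.5f}·c + {fit.intercept:.5f}   (r = {fit.correlation:.4f})")
print(f"mean absorptivity: {absorptivity:.2f} A(1 g/100 ml, 1 cm)")
print(f"within linearity range 5 µg/ml? {v.check_beers_range(fit, 5.0)}")
print("The slope (AU per µg/ml) × 10^4 equals the absorptivity because the "
      "noiseless series passes through the origin.")
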