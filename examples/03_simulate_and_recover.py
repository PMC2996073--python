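"""Simulate a noisy mixture scan and recover the generating concentrations.

Builds an 8 + 2 µg/ml atenolol/hydrochlorothiazide mixture spectrum on a
0.2 nm grid with 0.002 AU instrument noise, reads the two analytical
wavelengths and solves the simultaneous equations.
"""

import vierordt as v
from vierordt.synthetic import NoiseModel

models = v.system_band_models("atl-hctz")
matrix = v.preset_matrix("atl-hctz")

spectrum = v.simulate_mixture_spectrum(
    models, [8.0, 2.0], noise=NoiseModel(absorbance_sd=0.002, seed=42)
)
print(f"simulated {len(spectrum)}-point spectrum, "
      f"{spectrum.wavelengths[0]:.0f}-{spectrum.wavelengths[-1]:.0f} nm")
for w in matrix.wavelengths:
    print(f"  A({w:.2f} nm) = {spectrum.absorbance_at(w):.4f} AU")

result = v.quantify_spectrum(spectrum, matrix)
for name, c, true in zip(result.components,
                         result.concentrations_ug_per_ml, (8.0, 2.0)):
    print(f"  {name}: solved {c:.3f} µg/ml (true {true} µg/ml)")
print("Solved values differ from truth only by the propagated 0.002 AU "
      "read noise; condition estimate "
      f"{result.condition_estimate:.1f} confirms a well-posed system.")
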