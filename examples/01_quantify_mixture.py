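"""Quantify a two-drug mixture from its absorbances at two wavelengths.

The losartan/atenolol system reads absorbance at 251.60 nm (losartan's
band) and 224.20 nm (atenolol's band) and solves the 2×2 simultaneous
equations with the published absorptivity coefficients.
"""

import vierordt as v

matrix = v.preset_matrix("lok-atl")
print("absorptivity matrix, A(1 g/100 ml, 1 cm):")
for w, row in zip(matrix.wavelengths, matrix.values):
    print(f"  {w:7.2f} nm  {row}")

# absorbances of a mixture containing 20 µg/ml of each drug
measurement = v.MixtureMeasurement(
    wavelengths=matrix.wavelengths, absorbances=[0.6567, 2.0845]
)
result = v.solve_two_component(matrix, measurement)

print(f"denominator of the concentration formulas: "
      f"{v.vierordt_denominator(matrix):.2f}")
for name, c in zip(result.components, result.concentrations_ug_per_ml):
    print(f"  {name}: {c:.4f} µg/ml")
print("Each concentration is the Cramer's-rule solution of A = M·C; "
      "0.6567/2.0845 AU correspond to 20 µg/ml of each drug.")
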