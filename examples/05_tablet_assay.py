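"""Tablet assay against label claim through the dilution chain.

Simulates five replicate analyses of a 50 mg atenolol / 12.5 mg
hydrochlorothiazide tablet (powder equivalent dissolved in 100 ml, diluted
62.5-fold to the working range) and back-calculates mg per tablet.
"""

import vierordt as v

reports = v.run_assay_simulation("atl-hctz", seed=11)

print(f"{'analyte':<8}{'label mg':>10}{'found mg':>10}{'sd':>8}"
      f"{'%RSD':>8}{'% claim':>9}")
for r in reports:
    print(f"{r.analyte:<8}{r.label_claim:>10.1f}{r.amount_found:>10.2f}"
          f"{r.sd:>8.3f}{r.rsd_percent:>8.2f}{r.percent_label_claim:>9.2f}")
print("Amount found is the mean of five replicate back-calculations; "
      "% claim near 100 indicates the formulation assays at its label.")
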