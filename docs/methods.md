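# Methods

## Model

The package quantifies n-component mixtures from absorbances at n
wavelengths under two assumptions: Beer–Lambert linearity of each
component's absorbance in concentration (within its stated linearity
range) and additivity of component absorbances at every wavelength. The
working system is

    A(λᵢ) = Σⱼ aᵢⱼ Cⱼ · ℓ

with concentrations C in g/100 ml, pathlength ℓ in cm and absorptivities a
in A(1%, 1 cm) units (absorbance of a 1 g/100 ml solution in a 1 cm cell;
1 g/100 ml = 10⁴ µg/ml = 10 mg/ml, applied as exact factors). Measured
absorbances are divided by ℓ before solving, so all coefficients refer to
1 cm.

For 2×2 systems `solve_two_component` uses the classical closed form with
reversed numerators over the negated determinant, D = −(a₁₁a₂₂ − a₁₂a₂₁):

    C₁ = (A₂ a₁₂ − A₁ a₂₂) / D
    C₂ = (A₁ a₂₁ − A₂ a₁₁) / D

This is algebraically identical to textbook Cramer's rule; the sign
convention is kept because the published concentration formulas of both
preset systems are framed that way, and `vierordt_denominator` reproduces
their printed denominators (−116494.95 and −487532) exactly.
`solve_general` solves the same system by LU factorisation for any n and
serves as the cross-check for the closed form.

Two deliberate conventions in the presets:

- The LOK/ATL system uses 380.50 for atenolol's absorptivity at 224.20 nm.
  One published equation of that system prints 384.50, but the printed
  denominator −116494.95 equals 320.25×380.50 − 8.1×661.75 exactly, so
  380.50 is the internally consistent value.
- Atenolol's absorptivity at 224.20 nm is 380.50 in the LOK/ATL system but
  866.75 in the ATL/HCTZ system. These are reported as-is per system, never
  averaged or shared across systems: each preset is kept self-consistent so
  its forward/inverse round trip is exact.

## Numerical choices

- Singularity: a system is rejected when |det| < 10⁻¹² × Π(row max-norms),
  an absolute tolerance scaled to the matrix magnitude.
- Conditioning: 2-norm condition number; advisory `ok` below 10³, `warn`
  in [10³, 10⁸), `error` (refusal in `solve_general`) at ≥ 10⁸.
- Negative solved concentrations are returned and flagged
  (`negative_concentration`), never clamped — clamping would hide
  calibration or coefficient errors.
- Concentrations outside a component's linearity range are flagged
  (`out_of_beers_range`) when ranges are supplied. Note the published
  recovery design itself runs atenolol at 20 µg/ml, above its stated
  2–12 µg/ml range, so that flag is expected there.
- Spectrum interpolation is linear, not spline: the method only reads
  absorbances at fixed analytical wavelengths, and linear interpolation is
  transparent, monotone and exact on grid points.
- Band-maximum detection takes the discrete maximum (first occurrence, so
  ties and plateaus resolve toward the lower wavelength) and refines it by
  the vertex of the parabola through the maximum and its neighbours, only
  when the maximum is strict, and clamps the vertex to the neighbour
  interval.

## Calibration

Beer's-law curves are ordinary least-squares fits of absorbance on
concentration with the intercept always estimated (published curves have
nonzero intercepts); the reported correlation is Pearson r. The mean
absorptivity is the mean of A/c ratios over dilutions, which coincides with
slope × 10⁴ exactly when the data pass through the origin. The package
carries the published slope/intercept/r values and linearity ranges
(LOK 5–30, ATL 2–12, HCTZ 2–14 µg/ml) as `REFERENCE_CURVES`; the 5–30
range for losartan is used rather than a 5–35 figure that appears once in
the source procedure text, since every other statement and the calibration
table give 5–30.

## Validation statistics

All standard deviations use the n−1 denominator; %RSD = 100·s/|mean|.
Tablet assay back-calculates mg/tablet as
c(µg/ml) × dilution × stock volume × (tablet weight / sample weight) / 1000.
Recovery is increment-over-added: 100 × (found_spiked − baseline)/added.
The source material never writes its recovery formula; increment-over-added
is the standard-addition convention and matches "adding a known amount to
preanalyzed solutions". The baseline defaults to the preanalyzed content —
the mean of the unspiked determinations — because the procedure spikes into
solutions whose content was already established; a paired mode (each spiked
replicate differenced against its own unspiked partner) is available.
Inter-day precision is computed across day means (intermediate-precision
convention), intra-day within each day, and both are reported as
(min, max) ranges over concentration levels.

## Synthetic data generator

Each analyte is modelled as a sum of 1–3 Gaussian absorptivity bands.
Band positions and widths are fixed design choices; peak heights (and for
atenolol one width) are solved so that the band sum reproduces the
published absorptivity anchors at 251.60, 224.20 and 271.60 nm to machine
precision (well within the 0.5% tolerance the tests assert):

- LOK: analytical band at 251.60 nm plus a deep-UV edge band at 203 nm
  (the published data demand more absorbance at 224.20 than at the
  251.60 nm maximum, which forces a strong short-wavelength feature).
- ATL: main band at 224.20 nm plus a weak shoulder at 285 nm; the main
  width is solved by 1-D root finding so all three anchors hold. A
  single-band variant anchored to the LOK/ATL system's 380.50 value is
  used when simulating that system (`system_band_models`), mirroring the
  per-system coefficient convention above.
- HCTZ: analytical band at 271.60 nm plus an edge band at 215 nm.

Only the three-wavelength anchors are data-constrained; the full curve
shape is an emulation. Spectra are generated on a 0.2 nm grid over
200–400 nm (the instrument's scan range; the true scan step is not
documented, 0.2 nm is a typical setting). Noise is zero-mean Gaussian on
absorbance, default sd 0.002 AU, applied once per trace (or per reading
for measurement-level generators) from a `numpy` generator seeded through
`NoiseModel`; identical inputs and seed give identical output. Excipient
interference is not modelled (the source reports none).

What passing tests show — and don't: the simulator realises exactly the
additive, homoscedastic model the solver assumes, so end-to-end recovery
demonstrates correctness of the algebra and the statistics, not robustness
to real-instrument effects (baseline drift, stray light, solvent shifts,
excipient absorbance), which are out of scope.

## Simulated study designs

Defaults reproduce the published experimental designs: recovery from base
mixtures of 20 + 20 µg/ml (LOK/ATL) and 8 + 2 µg/ml (ATL/HCTZ) spiked at
80/100/120% with n = 3; assay of 50/50 and 50/12.5 mg label claims with
n = 5, a 100 ml stock and dilution factors 25 and 62.5 chosen so the
working solutions sit at those same base concentrations. Tablet and sample
weight default to 200 mg each; only their ratio matters. The recovery
envelope test runs the full design over 100 seeds (0–99) and checks
aggregate mean recovery within 98–102% and mean %RSD below 2% per analyte
and level. At 0.002 AU noise the tightest cell is hydrochlorothiazide at
the 80% level (1.6 µg/ml added), whose mean RSD sits near 1.9% — the noise
level and the small spike leave little headroom, which is a property of the
published design, not of the implementation.

## Limitations

- Coefficients are taken per system; no attempt is made to reconcile the
  conflicting atenolol values between systems or to re-derive
  absorptivities from the calibration slopes (slope × 10⁴ differs from the
  quoted matrix coefficients by a few percent; the underlying raw
  dilution data are not available).
- No weighted regression, LOD/LOQ, outlier handling, derivative or
  chemometric (PLS/PCR) methods, and no overdetermined least-squares
  quantification at more than n wavelengths.
- The point values of the published assay/recovery/precision tables depend
  on unpublished raw absorbances and are therefore checked as envelopes
  and exactness properties, not reproduced digit-for-digit.
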