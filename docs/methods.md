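# Methods

## Model

Isocratic reversed-phase retention is modelled as linear in the volume
fraction Φ of the organic modifier (methanol):

* RP-HPLC: log₁₀ k = log k_w + S·Φ, with k = t_r/t_m − 1 computed from the
  analyte retention time t_r and the dead time t_m of an unretained marker
  (uracil), both in minutes;
* RP-TLC: R_M = R_M0 + S·Φ, with R_M = log₁₀((1 − R_F)/R_F) the linearising
  transform of the plate retardation factor R_F ∈ (0, 1).

The slope S (retention units per unit volume fraction) is negative for
reversed-phase behaviour: more organic modifier elutes the analyte faster.
The intercepts log k_w and R_M0 — retention extrapolated to pure water
(Φ = 0) — are the lipophilicity indices, on the same decimal-log scale as
logP. Φ₀ = −intercept/S is the modifier fraction at which retention
vanishes; for a flat line (S = 0) it is undefined and reported as NaN
rather than raised, since a flat series is a legitimate, if uninformative,
measurement.

All logarithms in the package are base 10.

### Assumptions

* Linearity of log k (and R_M) in Φ over the measured gradient. This is the
  standard working approximation for methanol–water phases; curvature
  appears with other modifiers or very wide gradients and is not modelled.
* Homoscedastic, uncorrelated measurement error on the log-retention scale,
  so ordinary least squares is the natural estimator. No weighting or
  robust alternative is applied; the reported |r| mirrors the way such
  calibrations are judged in practice.
* Extrapolation to Φ = 0 is far outside the measured range (Φ ≥ 0.5 on the
  bench designs); the index is an extrapolated construct, and its standard
  error (reported alongside the estimate) is dominated by that leverage.

## Estimation and numerical choices

* The line is fitted per compound by OLS (delegated to
  `scipy.stats.linregress`); the results object carries the estimates,
  their standard errors, |Pearson r|, Φ₀, the residual standard deviation
  sqrt(SSR/(n−2)) and t-based confidence intervals.
* The correlation is reported as a magnitude |r|: the slope is negative, so
  the signed r would always be negative and the magnitude is what retention
  calibrations conventionally quote.
* At least three distinct Φ levels are required to fit — a correlation
  coefficient is meaningless at n = 2. A two-point escape hatch
  (`RetentionLineModel.from_points`) exists for estimator diagnostics only.
* Zero variance in Φ raises a degenerate-design error; a zero fitted slope
  yields Φ₀ = NaN without an exception.
* Replicates at the same Φ are averaged on the raw observable (t_r for
  HPLC, R_F for TLC) before the log transform; this is the standard
  reduction when replicate experiments report a single value.
* Out-of-range R_F values are errors, never silently clipped — clipping
  would bias R_M0.
* R_M is evaluated as log₁₀(1 − R_F) − log₁₀(R_F), which makes the
  antisymmetry R_M(x) = −R_M(1 − x) exact in floating point whenever x and
  1 − x are exact complements. For x below ~1e−4 the rounding of the input
  complement itself dominates; the property tests therefore quantify the
  transform over the plate-readable range R_F ∈ [0.001, 0.999].
* Printed output follows the conventions of the field's tables: intercept
  and slope to 2 decimals, Φ₀ and |r| to 3. Φ₀ in reports is always
  recomputed from the unrounded fitted parameters before rounding.

## Screening rules

* Lipinski lipophilicity: pass iff logP ≤ 5, applied to the experimental
  index (log k_w by preference). The boundary is inclusive; no compound in
  the bundled set sits exactly on it.
* Caco-2 permeability: high iff log Papp > 0.9 (Papp in 1e−6 cm/s), strict
  inequality.
* VDss: optimal within [−0.15, 0.45] log L/kg (closed interval), high
  above, low below. High VDss means predominant tissue binding.
* HIA (< 30% = poor) and blood–brain barrier (log BB > 0.3 readily crosses,
  < −1 poorly crosses) use conventional pkCSM guidance cut-offs; they are
  configurable arguments, flagged as conventions rather than
  dataset-specific findings.
* Closest-calculator concordance uses the values as printed (2 decimals)
  with no re-rounding; exact ties are credited to every attaining
  calculator, because the printed precision produces genuine ties (e.g.
  AlogPs and MLOGP both at |Δ| = 0.08 for compound 20) and any single
  assignment would need an arbitrary tie-break.

## Bundled dataset

The package ships the published study tables for 28 pseudothiohydantoin
(2-aminothiazol-4(5H)-one) derivatives in three substituent series
(isopropylamino 1–9, tert-butylamino 10–18, adamantylamino 19–28): both
techniques' fitted line parameters, seven calculated logP values and full
ADME profiles per compound. Transcription notes live in
`chromlip/datasets.py`. One caveat discovered in validation: the published
Φ₀ column is not everywhere consistent with the published rounded
(intercept, −S) pairs — recomputing −intercept/S reproduces the printed Φ₀
to 3 decimals for the HPLC column (within 0.0006) but deviates by up to
0.031 on the TLC column (compound 22), a pattern consistent with Φ₀ having
been computed from unrounded fit parameters plus one probable typo. The
package always recomputes Φ₀ rather than trusting a stored column, and the
acceptance checks report the honest deviation.

## Synthetic data generator

`simulate_hplc`/`simulate_tlc` invert the measurement pipeline: draw
log-retention from the true line plus Gaussian noise, then map back to the
raw observables (t_r = t_m(1 + 10^{log k}); R_F = 1/(1 + 10^{R_M}), always
strictly inside (0, 1)). Noise is placed on the log-retention scale — the
scale on which the model is linear — so recovery studies measure estimator
behaviour, not transform-induced misspecification. Real chromatograms
additionally contain integration error on raw times, plate-to-plate
variation and occasional non-linearity in Φ, none of which the generator
emulates; passing recovery tests therefore validate the fitting stack, not
the linearity assumption itself.

Defaults mirror the bench designs the package targets: methanol fractions
0.55–0.95 in steps of 0.05 (HPLC, 9 levels, t_m = 2 min) and 0.50–0.70 in
steps of 0.05 (TLC, 5 levels); `noise_sd` defaults to 0 (exact) and 0.02 is
used as the realistic bench level in the recovery studies, chosen to give
|r| ≈ 0.999 on the 9-point grid, matching the correlation quality of
well-behaved published calibrations. Each configuration carries one master
seed; per-simulation streams are spawned deterministically from it
(`numpy` SeedSequence), so studies reproduce across runs and platforms.
Recovery studies use 1000 replicates by default in the acceptance run —
ample for a bias check at SD ≈ 0.04/√1000 ≈ 0.001.

## Known limitations

* The package consumes calculated logP and ADME predictions as data; it
  never recomputes them from structures (no SMILES/SDF handling).
* Instrument metadata (temperature, flow rate, plate identity) is carried
  as free text only and enters no computation.
* The linear model is fitted per compound independently; no pooling or
  hierarchical shrinkage across a series.
* Extrapolated indices inherit the linearity assumption over an
  unmeasured region; they are comparative indices, not measured partition
  coefficients.
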