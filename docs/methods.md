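# Methods

This note records the models, conventions and design choices behind
`exokin`, in the order the pipeline applies them.

## Plate reduction

A fluorometric exoenzyme assay well combines 200 µL of soil homogenate
(1 g fresh soil blended in 100 mL acetate buffer) with 50 µL of substrate
solution. Free MUF or AMC fluorescence is converted to product amounts by
batch-wise controls incubated alongside the assays at each temperature:

- **Emission coefficient** ε (fluorescence per nmol in well): slope of the
  unquenched standard curve, OLS through six two-fold dilutions
  (MUF 0.625–20 µM, AMC 0.3125–10 µM in well) read in duplicate.
- **Quench coefficient** q: ratio of the quenched (homogenate-containing)
  to unquenched standard slope, per depth × temperature batch. Soil
  organic matter absorbs/scatters emission, so q ≤ 1 and is smallest at
  the surface.
- **Net fluorescence**: `net = (raw − blank_homogenate)/q −
  blank_substrate`. The homogenate blank is subtracted before unquenching
  because it is read through the same soil matrix; the substrate blank is
  a matrix-free signal and is subtracted after. Standard-curve intercepts
  are kept for diagnostics only — the blanks already measure baseline.
- **Rate**: `v = net·V_buffer / (ε·V_hom·t·m_fresh·f_dm)` in
  nmol g⁻¹ (dry soil) h⁻¹, where f_dm is the dry-matter fraction of the
  fresh soil. The homogenate protocol is stated per g *fresh* soil while
  rates are reported per g *dry* soil, so f_dm is a required input of the
  soil-context table; the conversion is explicit and testable.

Fluorescence units are arbitrary but must be consistent within a batch; no
gain normalization is attempted across batches.

## Quality control

Two well-level rules, each logged to an exclusion ledger by reason:

1. Strictly negative reduced values are analytical error and removed
   (zeros are kept).
2. Within each cell of up to 4 analytical replicates, values beyond the
   Tukey fences [Q1 − 1.5·IQR, Q3 + 1.5·IQR] are flagged and at most one —
   the flagged value farthest from the cell median — is removed. Quartiles
   use linear interpolation between order statistics (the default of
   common statistical environments); both the convention and the fence
   multiplier are configurable.

Two consequences of this convention worth knowing. First, for a 4-value
cell with k = 1.5 at most one value can ever cross a fence (an extreme
pulls its own quartile outward; the algebra excludes two simultaneous
crossings), so the "at most one removal" cap binds only for tighter
multipliers. Second, small-sample Tukey fences are aggressive: ordinary
10%-CV lognormal replicate noise gets a value flagged in roughly a fifth
to a quarter of cells. Total exclusion fractions of several percent of all
wells are therefore an intrinsic property of the rule, not evidence of bad
data. The ledger preserves conservation (`rows_in = rows_out + excluded`)
at every stage.

Filtering operates on reduced rates; since the fluorescence-to-rate map is
affine-positive, filtering before or after reduction is equivalent.

## Michaelis–Menten fitting

Per enzyme × depth × temperature × core × timepoint unit (8 substrate
concentrations × up to 4 replicates), the 2-parameter model
`µ(S) = V_max·S/(K_m+S)` is fit with a transform-both-sides (TBS) Box-Cox:
both response and model prediction pass through
`z(y) = (y^λ − 1)/λ` (λ = 0 meaning ln), sharing one λ. TBS stabilizes
the strongly mean-proportional replicate variance without
reparameterizing, so V_max and K_m stay on the original scale. λ is
profiled on a grid (−2…2, step 0.1, refined once to step 0.01 around the
optimum) by the Gaussian profile likelihood including the Jacobian term
(λ−1)·Σln v; inner fits are Levenberg–Marquardt with analytic Jacobian
and data-driven starts (V_max⁰ = max mean rate, K_m⁰ = concentration with
mean rate nearest V_max⁰/2), warm-started along the grid. Wells with
non-positive rates cannot enter a power transform and are excluded from
the fit (they are rare after QC, which already removes strict negatives).

Standard errors are the asymptotic least-squares errors at the selected λ;
p-values are two-sided t with n − 2 df. Fits with p > 0.05 on either
parameter are gated out of all downstream trait tables.

**Concentration dropping.** One substrate concentration may be removed
when (a) all of its replicates sit on the same side of the fitted curve
(uniform misfit, e.g. high-substrate inhibition) and (b) removal improves
the information criterion by more than 2. Both models are scored on the
*reduced* data at a common λ (refit RSS vs the RSS of the original
parameters), because Box-Cox likelihoods across different response sets
are not comparable — with equal parameter counts the criterion reduces to
`n·ln(RSS_base/RSS_refit) > 2`, a likelihood-ratio-style gain. Candidate
scoring fixes λ at the base fit's value for speed; the accepted drop gets
a full profile refit.

**Incubation time.** Reads at nominally 1, 4 and 24 h give three fits per
unit. Per temperature batch, each unit's V_max is normalized by its own
across-timepoint maximum (units span orders of magnitude down the
profile; raw medians would be dominated by mid-ranked units), and the
chosen time is the minimum timepoint whose median relative V_max is
within 5% (configurable) of the batch-best median — the shortest
incubation that already reaches the highest V_max. One time per batch.

**Traits.** MBC = fumigated − unfumigated extractable C (no k_EC
correction). V_max/MBC = V_max/ds ÷ MBC, CE_ds = V_max/ds ÷ K_m,
CE_MBC = V_max/MBC ÷ K_m. Non-positive MBC leaves the dry-soil basis
intact and the biomass basis undefined.

## Thermal models

- **Q10**: OLS of ln(trait) on temperature in °C; Q10 = exp(10·slope).
  Computed over the field range 4–35 °C (and optionally 4–50 °C).
- **Arrhenius**: OLS of ln(V_max) on 1/T in kelvin; E_a = −R·slope,
  reported in kJ mol⁻¹ (dimensional analysis of −R·slope gives J mol⁻¹,
  so a per-kelvin unit sometimes attached to printed E_a values is
  treated as typographical).
- **MMRT**: `ln k(T) = ln(k_B T/h) − [ΔH‡ + ΔC_p‡(T−T₀)]/(RT) + [ΔS‡ +
  ΔC_p‡·ln(T/T₀)]/R` with reference temperature T₀ = 315 K. Moving the
  `ln(k_B T/h)` pre-factor to the response side leaves a model *linear*
  in (ΔH‡, ΔS‡, ΔC_p‡), so the least-squares optimum is computed exactly
  by `lstsq` — no iteration, no multistart, no convergence failures; this
  replaces generic nonlinear optimization by construction. Any constant
  scaling of V_max is absorbed by ΔS‡, so ΔC_p‡, ΔH‡, T_opt and TS_max
  are invariant to the units of V_max.
  - T_opt (argmax of k) in closed form: `(ΔC_p‡·T₀ − ΔH‡)/(ΔC_p‡ + R)`;
    finite only for ΔC_p‡ < −R, and within that regime T_opt *increases*
    with ΔH‡ (∂T_opt/∂ΔH‡ = −1/(ΔC_p‡+R) > 0).
  - TS_max, the inflection of the rate curve k(T) (not of ln k), solves
    `g(T)² + g′(T) = 0` with g = d ln k/dT; found by bracketing scan plus
    Brent bisection below T_opt, to 0.01 K.
  - Fits whose T_opt or TS_max fall outside 0–200 °C do not describe a
    credible unimodal response over the assay range; they are flagged
    invalid and ledgered, and downstream thermal summaries use valid fits
    only.
- **Model comparison**: Gaussian log-likelihood from RSS with additive
  constants dropped (differences unaffected), parameter counts including
  the residual variance (Arrhenius k = 3, MMRT k = 4);
  AICc = AIC + 2k(k+1)/(n−k−1); relative likelihood exp(−ΔAICc/2) vs the
  best model. At n = 6 the MMRT AICc denominator is 1, a legal but severe
  penalty — AICc then rarely prefers MMRT even when it fits better;
  AIC and BIC are reported alongside for exactly this reason.

## Factorial statistics

Two-way fixed-effects ANOVA (depth × temperature, optional interaction)
and a blocked one-way ANOVA (depth tested after removing temperature-block
variation) use sequential type-I sums of squares, appropriate for the
balanced design; unbalanced tables (possible after gating) fall back to
sequential SS with a logged warning. Responses are ln-transformed when
Levene (median-centered) or Shapiro–Wilk fails at α = 0.05 on the
untransformed residuals; the decision is logged. Diagnostics are advisory:
the pipeline proceeds and warns.

Tukey HSD uses the exact studentized-range distribution on the ANOVA's
residual mean square; compact letter displays use the insert-and-absorb
algorithm (start with one letter covering all levels, split on each
significant pair, absorb subsets), with groups ordered by descending mean
for deterministic output. Two levels share a letter iff their adjusted
p > 0.05.

Percent decline of a trait is `100·(max(upper) − min(lower))/max(upper)`
per temperature, computed on depth means within temperature, then
summarized as mean ± se across temperatures; specific depth × temperature
cells can be excluded by configuration (for flagged spurious values)
rather than hard-coded. Enzyme ratios are element-wise at common
coordinates for the pairs BG:LAP, BG:AP, LAP:AP; a missing partner or zero
denominator yields a missing ratio.

## Synthetic campaign

The generator emulates the full factorial: 3 enzymes × 6 depth intervals
(0–10 … 80–90 cm) × 6 temperatures (4–50 °C) × 8 enzyme-specific
substrate concentrations × 4 analytical replicates × 3 cores × 3 read
times, which is 324 Michaelis–Menten fit units per timepoint and
10 368 sample wells per timepoint, plus all standards and blanks.

Ground truth (defaults; all configurable):

| quantity | default | rationale |
|---|---|---|
| V_max(z) | V₀·exp(−z/22.6 cm) | ~96%-class decline by 60–90 cm |
| K_m(z) | K₀·(0.15 + 0.85·exp(−z/9 cm)) | drop to ~15% of surface by 30 cm, then plateau |
| V₀ (BG/LAP/AP) | 250/120/900 nmol g⁻¹ h⁻¹ at 25 °C | AP ≫ BG > LAP ordering |
| K₀ (BG/LAP/AP) | 180/260/300 µM | LAP lowest affinity among BG-normalized series |
| ΔC_p‡ | −0.79 (BG, AP), −1.32 (LAP) kJ mol⁻¹ K⁻¹ | observed per-enzyme means |
| ΔH‡ | set so T_opt = 338.05 K | via the closed form |
| MBC(z) | 25 + 625·exp(−z/14 cm) µg g⁻¹ | steepest decline over upper 30 cm |
| quench q(z) | 0.60 (surface) → 0.90 (85 cm) | organic matter quenches |
| well noise | lognormal, CV 10% | justifies Box-Cox; sd ∝ mean |
| control-well noise | 2% relative | duplicate standards/blanks |
| negative readings | 0.8% of wells | realized analytical-error rate |
| replicate outliers | 3% of wells, ×3 | single-replicate gross errors |

Temperature scaling multiplies V_max(z) by the MMRT rate ratio
k(T)/k(25 °C), so ln V_max is exactly additive in depth and temperature.
Read-time realism: cold assays (< 16 °C) under-read at 1 h (factor 0.6)
and 4 h (0.9); 16 °C is complete by 4 h; warm assays (≥ 25 °C) are
complete at 1 h and stop accumulating product after ~4 h, so their 24 h
apparent rate collapses to 4/24. The selected timepoint in every batch has
factor 1.0, keeping recovery unbiased.

What the generator does *not* emulate — so what passing tests do not show
about real data: spatial autocorrelation between cores, seasonal dynamics,
substrate sorption/diffusion, plate-position or drift effects, and
enzyme-specific deviations from MMRT. One emergent realism is worth
noting: standards and blanks are shared per batch (as in the protocol), so
their ~1–2% sampling error shifts entire depth × temperature cells
coherently. For the weakest-signal cells (deep, short warm incubations;
LAP signals of a few fluorescence units against a 60-unit blank) this is
genuine depth × temperature variance, and a two-way ANOVA on a full
campaign can detect it as a significant interaction even though the
kinetic truth is exactly additive. The additivity calibration (interaction
rejection ≈ α) is therefore asserted on trait-level simulations where
additivity actually holds, while campaign-level tests assert the main
effects. Real assays share this property, which is one reason weak deep-
soil signals warrant cautious interaction claims.

A note on internal consistency of the reference values: the generating
MMRT truth (ΔC_p‡ = −0.79 kJ mol⁻¹ K⁻¹, T_opt = 338 K) implies a
log-linear Q10 over 4–35 °C of ≈ 1.65 for BG/AP and ≈ 2.3 for LAP —
somewhat above the observed per-enzyme Q10 means (1.44–1.78), which were
estimated from noisy per-core Arrhenius fits rather than from the mean
MMRT curve. Published summary statistics do not commute exactly through
nonlinear reductions; the recovery tests therefore compare each estimate
with the value *implied by the generating curve*, not with a printed mean.

## Problem sizes and determinism

The test suite runs a full default campaign once (324 fit units × 3
timepoints, ~90 s) shared across end-to-end checks; parameter-recovery
tests use 200 fixed-seed simulations per model; the IQR cap property runs
10⁵ draws. All randomness flows from explicit seeds; identical seeds
produce byte-identical campaign CSVs. The recovery bound for ΔC_p‡
(median |error| < 25% at σ_ln = 0.1 over six temperatures) sits at the
theoretical boundary of any unbiased estimator for this design (24.6%
theoretical median via the design covariance), which is worth remembering
when interpreting per-window fluctuations.

## Known limitations

- k_cat is deliberately absent: soil assays do not measure enzyme
  concentration, so turnover numbers cannot be inferred.
- The Box-Cox profile excludes non-positive rates; units whose wells are
  mostly at or below blank level (deepest, coldest, shortest reads) can
  lose identifiability and are reported as failed fits rather than
  guessed.
- AICc at n = 6 with k = 4 is a boundary case (denominator 1); model
  selection at these sample sizes should weigh AIC/BIC and the relative
  likelihoods together, as the comparison table reports.
- The blocked ANOVA uses a single error stratum (block effects removed,
  factor tested against the residual); variance-component estimation is
  out of scope.
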