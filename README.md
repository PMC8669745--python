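# exokin

Soil exoenzyme Michaelis–Menten kinetics and temperature sensitivity
through a soil depth profile.

Microbial communities release extracellular hydrolases — β-glucosidase
(BG, carbon acquisition), leucine aminopeptidase (LAP, nitrogen) and acid
phosphatase (AP, phosphorus) — whose kinetics set the pace of soil organic
matter decomposition. Fluorometric microplate assays (MUF/AMC substrates)
measure these kinetics, but turning raw plate fluorescence into comparable
traits across depths and temperatures takes a long chain of corrections,
exclusions and model fits. `exokin` implements that chain as a tested
pipeline, for soil ecologists and biogeochemists who run substrate-
saturation assays over factorial designs:

1. **Reduction** (`exokin.assay_data`) — raw well fluorescence to rates
   per g dry soil via batch-wise standard curves, homogenate/substrate
   blanks and quench coefficients (quenched/unquenched standard slope):
   `net = (raw − blank_hom)/quench − blank_sub`, then
   `v = net · V_buffer / (ε · V_well · t · m_dry)`.
2. **QC** (`exokin.qc_filters`) — strictly negative values removed;
   per-replicate-cell Tukey-fence outliers (1.5 × IQR, interpolated
   quartiles) with at most one removal per 4 replicates; every exclusion
   ledgered by reason.
3. **Kinetics** (`exokin.mm_kinetics`) — 2-parameter Michaelis–Menten fits
   `v(S) = V_max·S/(K_m + S)` with a transform-both-sides Box-Cox
   (shared λ by profile likelihood) to absorb heteroscedastic replicate
   variance; optional removal of one consistently misfitting substrate
   concentration; minimum-sufficient incubation time per temperature
   batch; significance gate (p ≤ 0.05 on both parameters); traits
   V_max/ds, V_max/MBC (MBC by chloroform-fumigation difference, no
   k_EC), K_m, and catalytic efficiencies CE = V_max/K_m.
4. **Thermal models** (`exokin.thermal_models`) —
   Q10 = exp(10 · slope) from ln(trait) vs T (°C); Arrhenius
   E_a = −R · slope from ln(V_max) vs 1/T (K); Macromolecular Rate Theory
   `ln k(T) = ln(k_B T/h) − [ΔH‡ + ΔC_p‡(T−T₀)]/(RT) + [ΔS‡ +
   ΔC_p‡ ln(T/T₀)]/R` (T₀ = 315 K) with closed-form
   T_opt = (ΔC_p‡T₀ − ΔH‡)/(ΔC_p‡ + R), numeric TS_max (inflection of
   k(T)), a 0–200 °C validity band, and AIC/AICc/BIC model comparison.
5. **Statistics** (`exokin.profile_stats`) — one-way/two-way/blocked
   ANOVA (type-I SS), Tukey HSD with compact letter displays,
   Levene/Shapiro/skewness diagnostics, percent-decline summaries, and
   pairwise enzyme trait ratios.
6. **Synthetic campaign** (`exokin.synthetic_data`) — a ground-truth
   profile (exponential V_max decline, K_m plateau at depth, MMRT
   temperature response, depth-dependent quenching, heteroscedastic noise,
   rare negative readings and replicate outliers) drives simulation of
   every well, standard and blank of the full factorial design
   (3 enzymes × 6 depths × 6 temperatures × 8 concentrations ×
   4 replicates × 3 cores × 3 timepoints), so the whole pipeline is
   testable against known truth.

## Worked example

The numbered drivers under `analysis/` run the pipeline on a synthetic
campaign and write their tables under `results/`:

```sh
python analysis/01_simulate_campaign.py --seed 17
python analysis/02_reduce_and_qc.py
python analysis/03_fit_michaelis_menten.py
python analysis/04_thermal_traits.py
python analysis/05_profile_statistics.py
```

prints (abridged):

```
campaign written to results/campaign
  fit units: 324 (sample wells per timepoint: 10368)
reduced 31104 sample wells -> 28290 kept
excluded 2814 (9.0%): iqr_outlier=2244, negative_value=570
incubation time per batch: 4C->24h, 10C->24h, 16C->4h, 25C->1h, 35C->1h, 50C->1h
significance gate removed 2 of 324 selected models; 322 trait rows written
54 enzyme x depth x core thermal fits; 1 MMRT fits outside the 0-200 C validity band
  AP: Q10(Vmax, 4-35C) = 1.66 +- 0.01, Ea = 36.3 +- 0.3 kJ/mol
  BG: Q10(Vmax, 4-35C) = 1.64 +- 0.01, Ea = 35.1 +- 0.3 kJ/mol
  LAP: Q10(Vmax, 4-35C) = 2.35 +- 0.02, Ea = 60.9 +- 0.6 kJ/mol
  MMRT (valid fits): Topt = 64.9 C, TSmax = 32.9 C, dCp = -0.99 kJ/mol/K
Vmax/ds percent decline (surface -> 60-90 cm):
  AP: 97.0 +- 0.1%   BG: 97.1 +- 0.1%   LAP: 97.1 +- 0.3%
```

Reading these numbers: 9.0% of sample wells fail QC (negative readings
plus replicate outliers); cold batches need the 24 h read while warm
batches saturate by 1 h; 322 of 324 enzyme × depth × temperature × core
fit units survive the significance gate. V_max per g dry soil declines
~97% from the surface to 60–90 cm — recovering the generator's 22.6 cm
e-folding truth — while the thermal traits (Q10, E_a, T_opt ≈ 65 °C,
TS_max ≈ 33 °C, ΔC_p‡ ≈ −0.8 to −1.3 kJ mol⁻¹ K⁻¹) recover the
generating MMRT parameters and are depth-invariant, the central
scientific pattern this pipeline is built to resolve.

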