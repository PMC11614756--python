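# Methods

## The measurement model

A quantum-dot-loaded reaction well reports local temperature through
fluorescence: as myosin hydrolyses ATP, dissipated heat quenches the QD
signal, so relative fluorescence F(t)/F(0) decays over the 2-minute read.
The analysis treats the *initial* decay rate of that relative trace as
the heat-release read-out. It is estimated as minus the linear
coefficient of an ordinary least-squares polynomial fit of the relative
intensity on time, i.e. the magnitude of the fitted curve's derivative at
t = 0, where the signal is most reproducible. Readings in the later part
of the window (after ~20 s) are noisier but still enter the regression;
they stabilise the curvature estimate without dominating the t = 0 slope.

The per-replicate efficiency index is

```
index = (r_ATP − r̄_blank) / c        [s⁻¹ per (mg/mL)]
```

where r̄_blank is the mean initial rate of the preparation's 0 mM ATP
wells (non-enzymatic drift) and c is the effective total-protein
concentration in the well. Extracted myosin is assumed proportional to
extracted total protein, so normalisation uses the A280 total-protein
concentration divided by the dilution factor between the A280 measurement
and the well — never a myosin-specific amount. A larger index means more
heat per unit myosin per unit time: *lower* mechanochemical efficiency.
The index is an operational statistic, not a thermodynamic efficiency in
J/J; no fluorescence-to-millikelvin calibration is modelled.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `poly_degree` | 2 | the decay is a "negative hyperbola", locally quadratic; degree 2 yields an interpretable t = 0 derivative without chasing the noisy tail |
| `window_end_s` | 120 s | full assay window enters the fit |
| `sampling_interval_s` | 5 s | plate-reader cadence; ±10 % per-step jitter tolerated |
| `sd_multiplier` | 1.0 | width of the replicate exclusion band, in sample SDs |
| `iia_stratify_threshold` | 0.10 | type IIa MyHC fraction above which a preparation is treated as a separate (high-IIa) stratum; any cutoff between the observed main-stratum (≤ 0.04) and elevated (0.16, 0.39) compositions gives the same partition |
| `a280_factor_mg_per_ml_per_AU` | 1.0 | generic-protein A280 conversion; it cancels in any within-study comparison since every sample shares it |
| `bsa_recovery_tolerance` | 0.10 | allowed relative error of a BSA internal control before the batch is flagged |
| `dilution_rate_tolerance` | 0.05 | band below the fastest net rate within which a lower concentration still counts as optimal |

All fractions are stored in [0, 1]; percentages appear only in
presentation output.

## Replicate QC

The two exclusion rules operate on the final (blank-subtracted,
concentration-normalised) index of each sextuplicate, in a fixed order:

1. negative indices — null reactions — are removed first, because they
   would corrupt the dispersion estimate;
2. on the remainder, the mean and sample SD (n − 1) are computed once and
   any value strictly more than `sd_multiplier` SDs from the mean is
   excluded. The rule is single-pass (never iterated) and a zero-SD set
   is kept whole.

This band is intentionally aggressive: on six i.i.d. normal replicates it
removes about 1.9 values in expectation and removes three or more in
roughly 15 % of sextuplicates (a property of the order statistic, checked
in the tests against an independent vectorised simulation). A
preparation whose replicates are all excluded is reported as failed, and
an animal with no surviving preparation is flagged — nothing is silently
dropped.

Aggregation is strictly hierarchical: replicate → preparation mean →
animal mean → group, and the group mean ± SD is computed over animal
means (n = animals), matching the dispersion convention for small-animal
studies.

## Group comparison

The main-stratum CON vs EXP contrast uses the classical pooled-variance
(Student) unpaired t-test, two-sided, on per-animal means; a Welch
variant is available as a sensitivity flag and does not change the
study-scale conclusion. High-IIa preparations are summarised separately
and excluded from the main test; by default stratification is
per-preparation (an animal contributes to the main test if it has at
least one main-stratum preparation), with a config flag to exclude such
animals entirely. Degenerate inputs are handled explicitly: zero pooled
variance with equal means gives t = 0, p = 1; with unequal means the
p-value is floored at 1e-300 with a note rather than reported as 0.

## The synthetic-data generator

`generate_study` draws a complete study from a hierarchical model:

* **Traces.** Relative fluorescence follows F(t) = 1/(1 + ρt), whose
  t = 0 derivative is exactly −ρ, so each well's true initial rate is
  analytic and independent of any estimator. Additive Gaussian noise is
  two-regime — SD 0.002 (relative units) up to 20 s, 0.010 after —
  reflecting the clean early window and noisy tail of the real assay.
  Raw counts are a uniform 20k–60k scale factor times the relative trace.
* **Index hierarchy.** Animal-level true indices are Normal(group mean,
  √f·σ_g) and replicates add Normal(0, √(n_rep(1 − f))·σ_g) jitter,
  with f = `animal_sd_fraction` (default 0.8) the fraction of the index
  *variance* living between animals — the standard mixed-model variance
  partition. This makes the dispersion of animal means equal σ_g by
  construction (before QC). Defaults: CON 0.47 ± 0.25, EXP 1.47 ± 0.44,
  five animals per group, one preparation per animal, sextuplicates.
* **Rates and concentrations.** ρ_ATP = ρ_blank + index · c with blank
  drift ρ_blank ≈ 2×10⁻⁴ s⁻¹ and effective in-well concentration
  c ≈ 0.002 mg/mL (stock 2.0 mg/mL measured by A280, 1000-fold combined
  dilution — about 1 µL of a series-diluted extract into a 62 µL well).
  These unpublished scales were chosen once so that ρ·120 stays in
  0.1–0.35, the regime where the degree-2 estimator's bias is small
  (see below). A280 tables include a buffer blank and BSA controls at
  1–4 mg/mL; densitometry volumes encode IIa fractions ≈ 0.03 (main) or
  ≈ 0.25 (optional high-IIa EXP animals).
* **Anomalies.** `inject_qc_anomalies` plants null reactions (net rate
  below blank) and extreme outliers (10× group mean) in chosen replicate
  wells and tags them in the ground-truth ledger, so QC recall is
  measurable.

Everything is reproducible byte-for-byte from the seed.

What the generator does **not** emulate: instrument drift and
photobleaching, well-position effects, isoform-dependent index means
(high-IIa animals draw from the same group distribution), correlated
noise, or real raw-trace magnitudes (unpublished). Passing recovery tests
therefore demonstrate correctness of the estimator and pipeline under the
stated stochastic model, not robustness to every artefact of real plates.

## Numerical choices

* Polynomial fits use a scaled-domain basis
  (`numpy.polynomial.Polynomial.fit`) and convert back to power-basis
  coefficients; tests verify agreement with an explicit normal-equations
  Vandermonde solve to 1e-8 relative for degrees ≤ 4, n ≤ 30.
* **Estimator bias.** The degree-2 OLS fit of the exact hyperbola over
  0–120 s underestimates ρ by about 0.5 % at ρ·120 = 0.1, 3.5 % at 0.3,
  5.5 % at 0.4 and 7.7 % at 0.5: the ≤ 5 % regime ends near ρ·120 ≈ 0.37.
  Under the default generator scales both groups sit inside it, but the
  recovered EXP mean still runs ~5 % low, and the negative-exclusion QC
  rule truncates the CON replicate distribution, biasing its recovered
  mean ~9 % high. Both effects are visible in the acceptance-script
  output and are properties of the specified estimator + QC, not bugs.
* r² is defined as 0 for a zero-variance trace; rank-deficient designs
  (duplicated times) are rejected.
* Times are re-based so the first reading is t = 0; any instrument
  offset between reagent addition and the first read is unrecoverable
  and ignored.
* CSV reads use round-trip float parsing and writes use shortest
  round-trip / `%.17g` formatting, so write → read preserves every value
  exactly and re-runs are byte-identical.
* Weighted fitting (inverse noise-SD weights for the late window) exists
  behind `weighted_fit` but is off by default: the reference procedure is
  plain polynomial regression.

## Problem sizes

The default test and acceptance runs use the study's own scale — 5 vs 5
animals, sextuplicate ATP and blank wells, 25 time points — and 200
independent synthetic studies for the parameter-recovery summaries; the
calibration check pools 300 studies. These sizes give Monte-Carlo
standard errors comfortably below the tolerances being checked.

## Known limitations

* The absolute units of the published indices (0.47, 1.47) are not
  stated; the pipeline's index is internally unit-consistent and the
  generator reproduces the printed numbers by construction of its scales,
  so only relative comparisons are meaningful.
* The elevated-IIa preparations' separately reported indices are not
  modelled (no isoform-dependent mean in the generator).
* The 12 % gel myosin/total-protein densitometry is consumed nowhere:
  only the two-band (I/IIa) composition enters the analysis.
* Dilution-series optimisation (`select_optimal_dilution`) is provided as
  an operation but the generator emits single-concentration studies.
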