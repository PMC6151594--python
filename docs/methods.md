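# Methods

This note documents the models and procedures implemented in `vinomics`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data generator does and does not emulate.

## The measurement model

One analytical batch consists of, in acquisition order: a six-point
natural-abundance calibration series (0, 1, 10, 50, 100, 500 µg/L), a
matching series prepared from isotopically enriched ⁶⁵Cu/²⁰⁶Pb stock,
continuing calibration blanks (two runs of six for the direct-method
matrix, eight for the microwave matrix), and the analysis sequence —
triplicate method blanks, triplicate wines, and their spiked counterparts
for each preparation method — with a 10 µg/L QC standard re-measured every
15 solutions.

The simulated response of channel *c* in solution *s* is

```
r(s,c) = S_c · conc_c(s) · matrix(m) · prep(s) · drift(s) + B_c · drift(s)
r(s,c) ← r(s,c) · LN(cv_inst)
r_IS(s,c) = S_IS · drift(s)^κ · LN(cv_inst)
```

- `conc_c(s)` sums all sources present, each weighted by that source's
  isotopic abundance at the channel mass. Only Cu (63/65) and Pb (206/208)
  are monitored at more than one mass; mono-monitored elements carry weight
  one (the abundance is absorbed into the sensitivity and cancels between
  calibration and sample). Enriched-material contributions additionally
  carry the atomic-weight ratio W_nat/W_spk because the ion current counts
  atoms, not mass: a heavier enriched material yields proportionally fewer
  ions per µg.
- `prep(s)` is a mean-one lognormal preparation factor drawn once per
  prepared solution and shared across channels: dilution, handling and
  digestion errors scale the whole element panel together. Its CV is the
  method precision parameter (defaults below). Standards, QC and
  calibration blanks are not prepared and carry factor 1.
- `drift(s)` is a bounded random walk over acquisition order (step 0.01,
  clipped to [0.8, 1.2]) shared between analyte and internal standard.
  With coupling κ = 1 the IS tracks the analyte perfectly and
  normalization cancels drift exactly; κ < 1 models imperfect tracking and
  is what makes external calibration drift-limited while the 63/65 ratio —
  internal to each solution — stays clean.
- `LN(cv)` is mean-one multiplicative lognormal noise at the instrument
  repeatability CV (default 2%); concentrations are positive and
  dispersions are reported as relative SDs, which makes the lognormal the
  natural noise family. An additive Gaussian background-noise term is not
  simulated; background enters as a constant count level `B_c`.

Internal standards (⁶Li, ⁴⁵Sc, ⁷²Ge, ⁸⁹Y, ¹¹⁵In, ¹⁵⁹Tb, ²⁰⁹Bi) are
assigned to analytes by nearest mass. The true pairing used on any given
instrument is a laboratory convention, so it is configurable; nothing in
the pipeline depends on the specific pairing because all IS channels share
the drift process.

## Preparation-method effects

Each method is described by four ingredients:

- **Dilution factor** — 3 for DD/FA/AF ("diluted 1:3" read as one part
  wine in three parts total, which maps 12–15 vol-% ethanol onto the 4%
  ethanol matrix-matched calibration solutions) and 10 for MW (2 mL wine
  + 2 mL acid, then 1:5 with water). Both are configurable for users who
  read "1:3" as 1 + 3.
- **Additive contamination**, µg/L at instrument, per channel. The
  defaults reproduce measured method-blank levels: microwave digestion is
  by far the dirtiest (e.g. ⁵⁵Mn 20.1, ²⁷Al 13.7, ⁵²Cr 5.07 µg/L), while
  the direct methods show sub-µg/L backgrounds except ⁷Li. Microwave
  contamination is drawn per replicate as a lognormal around the mean
  (CV 0.3) to emulate variable reagent/vessel carry-over; direct-method
  contamination is deterministic.
- **Filtration retention**, a multiplicative fraction on the channels
  prone to loss of organically complexed metals (⁷Li, ⁵⁹Co, ⁶³Cu/⁶⁵Cu,
  ⁸⁵Rb, ⁸⁸Sr, ⁹³Nb, ¹³³Cs, ¹⁸²W, ²⁰⁵Tl, ²⁰⁶Pb, ²⁰⁸Pb): 0.85 in both
  filtration treatments, with a further 0.92 factor in AF on the seven
  channels where acid-first filtration measures lower than filter-first
  (²⁷Al, ⁵⁵Mn, ⁶⁰Ni, ⁶⁶Zn, ⁷⁵As, ⁷⁸Se, ¹⁰¹Ru). Retention applies to the
  natural analyte only, not to the gravimetric spikes: the ionic spike
  added immediately before preparation has no time to equilibrate with
  the polyphenol/protein complexes that the filter retains.
- **Method CV** — 0.295 for MW and 0.13/0.15/0.18 for DD/FA/AF; these are
  the preparation-factor CVs above.

A note on the RSD summary: the per-cell statistic is the plain sample
RSD over n = 3 replicates, whose expectation is c₄(3) ≈ 0.886 times the
generating CV. A simulator CV of 0.295 therefore yields observed mean
RSDs near 26%, not 29.5%; the tests assert the band around the estimator's
expectation and the MW ≫ direct ordering rather than a point value.

## Truth generation

True concentrations per (wine, element) are drawn log-uniformly within
per-element ranges spanning 0.003 µg/L (rare-earth elements) to several
mg/L (Mn, Rb above 1 mg/L in every wine), independently per wine so the
four elemental fingerprints are separable. The generator emulates
magnitude structure only: it does not model inter-element correlations
(geochemical covariation), spectral interferences or cell-gas kinetics
(delegated to the collision-cell mode choice), ethanol matrix effects
(held at factor 1; matrix-matched calibration makes them unidentifiable
in this design), or real per-wine concentration values, which are not
publicly available. Passing tests therefore demonstrate correctness of
the computational chain under a realistic magnitude/noise structure, not
agreement with any particular cellar's wines.

## Quantitation rules

- Calibration is unweighted OLS of normalized response on gravimetric
  concentration (no weighting scheme is assumed); r² is reported and a
  non-positive slope marks the curve unusable.
- LOD = t·SD and LOQ = 10·SD of the calibration blanks. The t convention
  is the one-tailed 99% Student-t quantile with df = n − 1 — the MDL
  convention, which yields the customary multipliers 3.365 (n = 6) and
  2.998 (n = 8); the confidence level is configurable. Direct-method
  limits are averaged over the available CCB runs. Limits are computed at
  instrument scale (the CCBs are undiluted); for censoring they are
  scaled by each sample's dilution factor so value and limit live on the
  same (undiluted-wine) scale.
- Negative quantified concentrations pass through untouched until
  censoring; censoring replaces any value below the LOD by LOD/2 and sets
  a flag, and flagged values are never re-censored, making the operation
  idempotent even though LOD/2 < LOD.
- QC standards pass when the mean is within 20% of nominal and the
  replicate RSD is below 20%.
- Spike recoveries are computed against the *enriched-material*
  calibration (100 · (spiked − mean unspiked)/level); quantifying a
  nearly pure ⁶⁵Cu spike on a natural-abundance curve would overstate it
  by A₆₅/B₆₅ ≈ 3.2.
- Isotope dilution inverts the two-source mixing equation written so the
  atomic-weight ratio is (natural Cu)/(spike Cu), which makes the mole
  balance exact; the published symbol definitions interchange the two
  weights, and the implemented orientation is the one under which a
  forward mole-balance oracle is reproduced to machine precision. The
  response ratio fed to the equation is formed from
  background-corrected normalized responses (normalized response minus
  the natural-curve intercept), since raw count ratios are biased by the
  common background level. R values at the natural ratio raise a
  singularity error (the spiked sample is indistinguishable from
  unspiked material); values outside the [spike, natural] mixing
  interval warn, as they are inconsistent with two-source mixing. Mass
  bias is deliberately not corrected — the hook exists and defaults to
  the identity — mirroring the simplified single-ratio protocol.
- Spike abundances default to a synthetic placeholder (A₆₅ = 0.99) that
  stands in for a certificate value in simulations; real analyses must
  supply the certified abundances.

## Statistics

- The MANOVA gate uses Pillai's trace (the most robust of the standard
  multivariate statistics to covariance heterogeneity; no particular
  statistic is canonical for this design). The default response subset is
  the ten channels with >1 µg/L microwave-blank contamination, because 48
  replicate-level observations cannot support a nonsingular 43-channel
  error covariance; the subset is configurable.
- Per-channel ANOVA fits the three main effects sample, replicate and
  method with no interactions, exactly as the balanced design permits:
  the factors are orthogonal, sums of squares are computed directly from
  level means, and SS_sample + SS_replicate + SS_method + SS_residual =
  SS_total holds to machine precision. Replicate is treated as a fixed
  main effect. Unbalanced input is rejected rather than approximated. No
  multiple-testing correction is applied across the 43 channels by
  default (per-channel α = 0.05 is the reporting convention here);
  a Benjamini–Hochberg pass can be applied downstream by the user.
- Tukey letters: HSD = q(1−α; k, df)·√(MSE/n). Because a single
  threshold applies to all pairs, the mutually non-significant groups are
  contiguous runs of the sorted means; the compact letter display labels
  the maximal runs, and shared letters are exactly equivalent to
  pairwise non-significance (verified against a brute-force pairwise
  oracle in the tests).
- The blank-compromise filter includes the method blanks as a fifth
  sample level in the per-channel ANOVA (the alternative — a separate
  blanks-versus-wines test — is expressible with the same machinery, but
  blanks-as-level is the default and is what the exclusion reasons
  report). A channel is excluded when the sample effect is not
  significant or when the blank mean reaches the wine mean under any
  method, and the reason(s) are recorded per channel.
- PCA standardizes each channel and eigendecomposes the correlation
  matrix, so channels spanning five orders of magnitude contribute
  comparably; it runs on the wine × method mean profiles (16 rows), not
  on replicates. Zero-variance columns (possible after censoring) are
  dropped with a warning. The sign of each component is fixed by making
  its largest-magnitude loading positive, which makes outputs
  reproducible across linear-algebra backends.

## Numerical and design choices

- All randomness flows from one `numpy` Generator seeded explicitly;
  simulation without a seed is refused. Seeds derived internally stay
  below 2³¹.
- Concentrations are µg/L end to end; gravimetric masses are grams with
  density 1 g/mL assumed, so mass ratios equal volume ratios.
- Degenerate inputs fail loudly with typed errors: unknown method codes,
  dead internal standards (non-positive IS response), single-level
  calibration designs, missing blanks or calibration levels, singular
  MANOVA covariances, non-positive MSE in Tukey comparisons.
- Study sizes used by the validation scripts (200 batches for parameter
  recovery, 500 for the type-I calibration, 40 for MANOVA power, 20 for
  the precision summaries) put the Monte-Carlo standard errors well
  inside the asserted bands.

## Known limitations

- Lead isotope dilution is not modelled: the inversion routine is
  element-generic, but no Pb spike certificate model or Pb-specific
  protocol is provided.
- Single-point isotope dilution only; no multi-point ID calibration and
  no GUM-style uncertainty budgets.
- No vendor raw-file import; the canonical interchange format is the
  long CSV written by the simulator.
- The wine-separability of the default truth tables is an assumption of
  the generator, not a finding about real wines.
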