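# vinomics

Elemental profiling of wine by ICP-MS: a tested, fully synthetic-data-driven
implementation of the complete quantitation and method-comparison workflow —
external calibration with internal-standard normalization, blank-based
detection limits with LOD/2 censoring, quality-control gating, spike
recovery, isotope-dilution quantitation of copper, and the statistics used to
compare sample-preparation treatments (MANOVA, per-isotope ANOVA with Tukey
compact-letter displays, blank-compromise channel exclusion, and
correlation-matrix PCA).

## Who this is for

Analytical chemists and data analysts working with multi-element ICP-MS
panels — wine and other beverage/food matrices — who need a reproducible,
scriptable pipeline from raw per-channel responses to censored
concentrations and preparation-method statistics, plus a forward simulator
to validate every stage without instrument time.

The monitored panel is 43 isotope channels (⁷Li … ²³⁸U) across four wines
(Chardonnay, Pinot Noir, Syrah, Tempranillo) prepared in triplicate by four
treatments: direct dilution (DD), filtration then acidification (FA),
acidification then filtration (AF), and closed-vessel microwave-assisted
acid digestion (MW). Li, Mo and Te are acquired with no cell gas, As and Se
in high-energy helium, everything else in helium mode.

## The core calculations

**External calibration.** For each channel, an unweighted OLS line maps the
internal-standard-normalized response *y = r/r*₍IS₎ onto the gravimetric
standard concentration; sample concentrations are
*(y − b)/m ·* DF, with dilution factor DF = 3 (DD/FA/AF) or 10 (MW).

**Detection limits.** LOD = *t*·SD and LOQ = 10·SD of the calibration
blanks, with *t* the one-tailed 99% Student-t quantile at df = *n* − 1:
*t* = 3.365 for *n* = 6 (direct methods, averaged over two runs) and
*t* = 2.998 for *n* = 8 (MW). Values below the LOD are replaced by LOD/2
and flagged for the statistics.

**Isotope dilution.** Copper in spiked samples is quantified from the
measured ⁶³Cu:⁶⁵Cu response ratio *R* by inverting the two-source mixing
equation

```
c_Cu = c_spike · (m_spike/m_sample) · (W_nat/W_spk) · (R·A65 − A63)/(B63 − R·B65)
```

with natural abundances B₆₃ = 0.6915, B₆₅ = 0.3085, spike abundances
A₆₃/A₆₅ from the spike certificate, and W the atomic weights of natural and
spike copper. No instrumental mass-bias correction is applied (a hook
exists, defaulting to the identity).

**Method comparison.** A Pillai-trace MANOVA gates the overall
preparation-method effect; per-channel balanced three-way main-effects
ANOVA (sample, replicate, method) follows, with Tukey HSD compact letter
displays for the method means. Channels whose method blanks compromise the
profile (no significant sample effect with blanks included, or blank means
exceeding wine means for some method) are excluded before a
correlation-matrix PCA of the wine × method mean profiles.

## Worked example

```
vinomics report --seed 11 -o run
```

runs the full chain (simulate → quantify → compare) under the default study
conditions and prints, stage by stage:

```
simulated 159 solutions × 43 channels (6837 records), seed=11, hash=55c045b856d26934
quantified 5461 records (2010 censored), QC failures: 0
MANOVA method effect: Pillai=1.705, p=4.13e-08; 25/43 channels with a
significant method effect; 20 channels excluded by the blank filter
```

The MANOVA p-value says the preparation treatments measurably shift the
elemental profiles (driven by the microwave-digestion contamination and the
filtration losses built into the default simulation); the per-channel ANOVA
table (`run/anova.csv`) shows which channels differ and its letter columns
encode the Tukey groupings (methods sharing a letter are indistinguishable
at α = 0.05). `run/rsd_summary.csv` shows microwave digestion as the least
precise treatment, and `run/pca_scores.csv` contains the profile scores in
which the four wines separate from one another.

The same machinery is available as a library:

```python
import vinomics as v

truth = v.generate_truth(seed=42)
batch = v.simulate_batch(v.BatchDesign(), truth,
                         v.MethodEffectParams.default(),
                         v.InstrumentParams(), seed=42)
out = v.quantify_batch(batch)          # concentrations, LODs, QC, recoveries
rsds = v.summarize_rsd(out.quant)      # mean replicate RSD per prep method
```

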