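# iggfc — subclass-specific IgG Fc glycosylation profiling and association analysis

Immunoglobulin G carries a conserved biantennary *N*-glycan at Asn297 of its
Fc region whose galactosylation, sialylation, core fucosylation and
bisecting GlcNAc modulate the antibody's inflammatory capacity. Because the
tryptic Fc glycopeptides of IgG1 (EEQYNSTYR), IgG2 (EEQFNSTFR) and IgG4
(EEQFNSTYR) differ in backbone mass, LC-MS of these glycopeptides resolves
glycosylation *per subclass* — including IgG2, which released-glycan and
protein-G-based workflows cannot separate.

`iggfc` is a complete, tested implementation of that analysis for
population-scale studies of glycosylation and metabolic health:

1. **Panel** (`iggfc.panel`, `iggfc.chem`) — 20 glycoforms per subclass
   (10 for IgG4, whose afucosylated species coincide in mass with
   fucosylated IgG1 glycopeptides), with exact masses, isotope envelopes and
   2+/3+ m/z targets.
2. **Synthetic data** (`iggfc.simulate`) — family-structured cohorts with
   metabolic covariates and centroided MS1 runs (mzML) with known
   ground-truth glycoform fractions, batch effects, miscalibration and RT
   shifts.
3. **Extraction** (`iggfc.extraction`) — global m/z recalibration on the
   four most abundant glycopeptides, RT alignment, and windowed summation of
   the first three isotopologues in both charge states (±0.04 Th, ±10 s)
   with flanking-window background correction and signal-to-background
   (S/B > 3) flags.
4. **Curation** (`iggfc.curation`, `iggfc.combat`) — analyte exclusions,
   normalization to 100% per subclass, quality-fraction sample exclusion,
   parametric empirical-Bayes batch correction with 96-well plates as
   batches (verified against Bioconductor `sva::ComBat`), 5-SD
   winsorization, natural-log transforms.
5. **Derived features** (`iggfc.traits`) — fucosylation, bisection,
   galactosylation and sialylation per antenna, sialic acid per galactose,
   plus per-glycan variants.
6. **Association** (`iggfc.association`, `iggfc.report`) — GEE models
   `feature ~ β₁X + β₂age + β₃sex + β₄(age·sex)` with family clustering
   (exchangeable working correlation; binomial/independence for the
   familial-health contrast), robust SEs, t = β₁/SE(β₁), a Bonferroni
   threshold of 0.05/70 over the 14-variable × 5-feature grid, paired
   subclass t-tests, replicate Pearson correlations, and the t-statistic
   heatmap.

See `docs/methods.md` for models, assumptions, parameter defaults and
limitations.

## Worked example

The `analysis/` scripts run a deterministic 384-sample, 130-family study
(four 96-well plates) end to end:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_simulate_runs.py      # writes 3 demo mzML files to scratch/
python analysis/03_extract_quantify.py   # ~2 min: all 384 runs
python analysis/04_curate_traits.py
python analysis/05_reproducibility.py
python analysis/06_associations.py
```

Selected output (what it means in brackets):

```
cohort: 384 individuals, 130 families, 4 plates
age 59.2 +/- 6.6 y, 44.8% male
LDLC missing (TG > 4.52 mmol/L): 22          [Friedewald missingness rule]

glycoform percentage vs truth (batch effects still present):
  median |err| 0.013 pp, max |err| 5.349 pp  [extraction is accurate; the
                                              tail is plate batch effects,
                                              removed downstream]

IgG2 galactosylation plate-mean spread: 1.06 SD before ComBat -> 0.10 SD after

replicate-plate Pearson r (IgG1): fucosylation 0.991, bisection 0.956,
  galactosylation 0.979, sialylation 0.966, SA/gal 0.967

association grid: 70 analyses, Bonferroni alpha = 0.000714
17 associations below the Bonferroni threshold:
  IgG2 fucosylation ~ crp:      t = +19.6, p = 3.2e-85 [injected effect]
  IgG2 galactosylation ~ crp:   t = -9.0,  p = 1.6e-19 [injected effect]
  IgG1 galactosylation ~ crp:   t = -6.0,  p = 1.7e-09 [injected effect]
  IgG4 galactosylation ~ hdlc:  t = +5.3,  p = 1.0e-07 [injected effect]
  IgG2 galactosylation ~ age:   t = -5.4,  p = 6.1e-08 [injected age trend]
  ...
linear-model R^2 of IgG1 galactosylation on ln CRP: 0.0632
```

The generator injected lower galactosylation/sialylation and higher
fucosylation at high CRP, higher galactosylation with HDLC and lower with
TG, and negative age trends; the GEE grid recovers exactly these cells (with
their signs) below the Bonferroni threshold, while analyses without an
injected or inherited effect stay near the nominal level.

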