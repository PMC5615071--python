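# Methods

## Overview

`iggfc` implements subclass-specific IgG Fc *N*-glycosylation profiling as a
fully testable pipeline. Tryptic Fc glycopeptides of IgG1 (EEQYNSTYR), IgG2
(EEQFNSTFR) and IgG4 (EEQFNSTYR) carry a biantennary complex-type glycan at
Asn297 varying in galactose (G0/G1/G2), core fucose (F), bisecting GlcNAc (N)
and sialic acid (S1/S2). The pipeline quantifies a fixed panel of
glycopeptides from centroided MS1 LC-MS runs, normalizes to percentages per
subclass, derives five summary features, removes plate batch effects, and
tests associations with metabolic-health markers by generalized estimating
equations (GEE) with family clustering. Because no cohort raw data are
available, a synthetic-data module generates family-structured cohorts and
LC-MS runs with known ground truth; every downstream claim is validated
against that truth.

## Analyte panel

Each subclass quantifies a 20-composition grid — {G0,G1,G2} × {±N} × {±F}
plus the singly sialylated {G1S1, G2S1, G1NS1, G2NS1} × {±F}. This grid is an
explicit stand-in for the exact published composition list, consistent with
every shorthand the study names. Two rules modify it:

* **IgG4 afucosylated species are never quantified.** Because one hexose has
  the same mass as one fucose plus the Tyr/Phe oxygen difference between the
  IgG1 and IgG4 backbones, afucosylated IgG4 glycopeptides coincide in mass
  with fucosylated IgG1 glycopeptides (e.g. IgG4-G0 + Hex ≡ IgG1-G0F). The
  IgG4 panel therefore keeps only the 10 fucosylated forms, and IgG4
  fucosylation is reported as missing rather than 100%.
* **IgG2 G1FNS1 and G2FNS1** are quantified but flagged for exclusion from
  statistics (severe batch effect at <0.4% abundance in the original data).

Masses come from element-count maps (peptide via `pyteomics.mass`, glycan
residues Hex C6H10O5, HexNAc C8H13NO5, dHex C6H10O4, NeuAc C11H17NO8).
Isotope envelopes are exact convolutions of per-element isotopologue
distributions (repeated squaring, truncated beyond the first k+8 terms, which
leaves the leading k terms exact); a brute-force atom-by-atom convolution
serves as the test oracle. m/z targets use a proton mass of 1.007276 Da and
an isotopologue spacing of 1.003355 Da (the ¹³C–¹²C difference; glycopeptide
A+1 intensity is carbon-dominated). All panel targets at 2+ and 3+ fall
inside the 600–2000 m/z acquisition range.

## Synthetic cohort

`simulate_cohort` draws `n_individuals` (default 1826) in `n_families`
(default 600, sizes differing by at most one), dealt onto 96-well plates in
order. Age is Normal(59.1, 6.7) truncated to [30.2, 79.2]; sex is
Bernoulli(0.471 male). Metabolic parameters use log-normal distributions
moment-matched to the reference population for the right-skewed variables
(CRP 2.86±9.5 mg/L, IL-6 0.67±1.2 pg/mL, glucose 5.94±1.5, insulin
23.23±22.1, TG 1.82±1.2, free T3 4.12±0.8) and truncated normals for TC
(5.55±1.2) and HDLC (1.42±0.4). LDLC follows the Friedewald formula
TC − HDLC − TG/5 and is missing when TG > 4.52 mmol/L. Smoking (13.6%) and
CMV seropositivity (45.9%) are Bernoulli; long-lived family membership
(64.1%) is assigned at the family level.

Traits are generated per subclass from the marginal baselines (IgG1:
fucosylation 91.2±4.1%, bisection 19.1±3.3%, galactosylation 50.1±6.4%,
sialylation 6.8±1.4%; analogous values for IgG2/IgG4) as

    trait = mean + β₁·X + β_age·(age−59.1) + β_sex·(sex−0.471)
            + β_agesex·(age−59.1)(sex−0.471) + family effect + noise

with exchangeable within-family correlation ρ_fam (family effect variance
ρ·σ², noise (1−ρ)·σ², σ = 0.85 × marginal SD, default ρ_fam = 0.2). Default
age/sex trends (galactosylation −0.35 %/y, sialylation −0.05 %/y, bisection
+0.06 %/y; modest sex differences) reflect the well-known ageing direction of
IgG glycosylation; metabolic effects default to zero and are set through the
effect map. Log-scale variables enter the trait model on the ln scale,
centered. Sampled traits are clipped into the feasible region described next.
Traits are generated independently across subclasses; the strong
cross-subclass correlation of real IgG glycosylation is **not** emulated, so
tests validate per-subclass recovery, not cross-subclass structure.

### Trait → profile inversion

`traits_to_profile` maps target features to glycoform fractions over a
minimal spanning set in closed form: afucosylated mass on G0 (1−f), bisected
mass on G0FN (b), sialylated/galactosylated mass split between G2FS1, G1FS1
and G2F (G2FS1 alone while SA-per-gal ≤ 50%, G1FS1 entering above that), and
the G0F filler absorbing the remainder. Derived traits of the result equal
the targets exactly (round-trip tested to 1e-9). Feasibility requires
sialylation ≤ galactosylation and bisection + max(gal, 2·sial) ≤
fucosylation; infeasible targets raise.

## Synthetic LC-MS runs

Runs are centroided MS1 only: scans at 0.5 Hz across 200–460 s, m/z range
600–2000. Each analyte elutes as a Gaussian peak (σ = 4 s) at its subclass
apex (IgG2 290 s, IgG4 330 s, IgG1 370 s — co-elution of a subclass's
glycoforms with subclasses separated in time; 40 s spacing keeps the
mass-coincident IgG2/IgG4 species out of each other's ±10 s windows). Every
scan carries centroids at the first three isotopologues in 2+ and 3+ (charge
split 60:40), with the envelope renormalized over those three peaks so that
the deposited current per analyte is exactly proportional to its glycoform
fraction — this is what makes noiseless extraction an exact oracle. Baseline
noise is Poisson(4000) uniform-m/z peaks per scan with Exp(30) intensities
(a dense centroid table, ~0.3% of a major analyte's signal per window);
per-run distortions are a global m/z offset (Normal, SD 0.01 Th), a global
RT shift (SD 3 s), per-plate × per-analyte multiplicative batch factors
(log-normal, SD 0.08) and per-analyte measurement noise (log-normal, SD
0.003 — instrument-level injection variability, deliberately smaller than
full-preparation intraplate RSD; replicate-plate analyses use 0.033 to
emulate independent sample preparation). Intensity scales (10⁶/4·10⁵/10⁵ for
IgG1/2/4) are arbitrary units. One master seed drives everything;
per-sample substreams are derived by counter so any subset of runs is
reproducible.

## Extraction

Runs are first recalibrated: for the four most abundant glycopeptides (G0F,
G1F, G2F, G2FS1) in 2+ and 3+, the most intense peak within ±0.2 Th of the
monoisotopic target in each scan inside the RT window contributes one
observed−theoretical difference, and the median is subtracted globally
(fewer than two matches ⇒ offset 0 with a warning). RT alignment applies a
single global shift equalizing the calibrant's chromatographic apex with a
reference run (missing apex ⇒ shift 0 with a warning; resolution is one scan
period).

Quantification sums matching centroid intensities over the six targets
(3 isotopologues × 2 charges) within closed windows of ±0.04 Th and ±10 s.
Background per target is estimated from two flanking m/z windows
([−0.12, −0.04) and (0.04, 0.12] Th) over the same RT window as
median(flank intensity) × n_flank × (signal width / flank width), i.e. a
robust density estimate scaled to the signal window; it is homogeneous of
degree one in the intensities, so extraction is exactly linear under global
intensity scaling. Each target's background is subtracted and clamped at
zero; the analyte's signal-to-background ratio is the corrected total over
the summed background (0/0 ⇒ 0, positive/0 ⇒ ∞), and S/B > 3 marks a
quantifiable analyte. The exact background algorithm of the original
processing chain is unpublished; this estimator is an explicit stand-in.

## Curation

Fixed order, matching the processing narrative: exclude flagged analytes →
normalize to percentages summing to 100 per subclass → exclude
(sample, subclass) blocks whose fraction of intensity from S/B>3 analytes is
below the quality threshold (the original threshold value is unpublished;
default 50%, configurable) → derive features → ComBat with plates as batches
→ winsorize at mean ± 5 SD (mean/SD computed once, ddof 1, not iterated) →
natural-log transform. ComBat is applied to the derived features rather than
individual glycoform percentages (the Methods narrative corrects feature
values after derivation); a config switch applies it at the glycoform level
instead.

The ComBat implementation is the parametric empirical-Bayes location/scale
model: features standardized by grand mean and pooled (post-batch-fit)
variance; per-batch locations/scales shrunk via normal and inverse-gamma
priors with moment-matched hyperparameters, iterating the standard
fixed-point updates to relative tolerance 1e-6 (max 500 iterations). It
matches Bioconductor `sva::ComBat` to ~1e-8 on shared inputs (tested via
Rscript), which is also why the output's grand mean is preserved only
approximately (EB shrinkage moves batch means slightly; exact preservation
would deviate from the reference behaviour). A single batch returns the
input unchanged; a batch with fewer than two samples raises; with fewer than
two features the EB priors are undefined and shrinkage falls back to the raw
per-batch estimates with a warning. Note that EB shrinkage is only effective
when batch effects vary across features: if every feature in a batch shifts
by the same standardized amount, the prior variance estimate collapses and
residual batch differences of a few percent of an SD remain — inherent to
the ComBat model, and the reason batch-correction checks run on the full
15-column trait table.

Log transforms apply to the glycosylation features and CRP, IL-6, glucose,
insulin, TG and free T3. IL-6 can be 0; the default policy adds half the
smallest positive observed value (policies: `strict` error / `offset` /
`drop`).

## Derived features

With a_i the percentage of glycoform i, g_i its galactose count and s_i its
sialic-acid count: fucosylation = Σ_F a_i; bisection = Σ_N a_i;
galactosylation = 100·Σ g_i a_i / (2 Σ a_i) (two antennae per biantennary
glycan — every panel form is biantennary); sialylation analogously;
SA-per-gal = 100·Σ s_i a_i / Σ g_i a_i (undefined without galactose).
Per-glycan variants report the percentage of glycans carrying ≥1 galactose
(resp. sialic acid). All features except SA-per-gal are linear in profile
mixtures; SA-per-gal, a ratio of linear forms, is not (tested by
counterexample).

## Association analysis

Linear models `feature ~ β₁X + β₂age + β₃sex + β₄(age·sex)` are fitted by
GEE (statsmodels) with family as the cluster, exchangeable working
correlation (moment estimator), robust sandwich standard errors, and normal
reference for the Wald statistic t = β₁/SE(β₁) — standard GEE practice. The
familial-metabolic-health contrast (long-lived family membership 1 vs
partner controls 0) is a binomial GEE with independence working correlation
and the feature as exposure; robust SEs are used throughout. Sex is coded
0 = female / 1 = male and the interaction is the product of coded values.
Complete cases per model (Friedewald missingness propagates). The grid is 14
variables (12 metabolic parameters + age + sex) × 5 features = 70 analyses;
Bonferroni α = 0.05/70 ≈ 7.14×10⁻⁴, with a nominal tier at 0.05.
Collinear designs (including constant exposures) raise. With singleton
clusters or independence working correlation the fit reproduces OLS
coefficients (algebraic identity, tested to 1e-6). Reproducibility uses
Pearson correlation between replicate plate measurements; subclass contrasts
use classical paired t-tests; visualization residualizes features on age (or
age + sex) via GEE before plotting, and the heatmap colors cells by t with
point/X markers at p < 0.05 / p < α.

## Problem sizes and numerical choices

Test and analysis problem sizes are chosen so the full suite runs in a few
minutes on one core: extraction oracle checks use 50-sample batches
(noiseless agreement < 1e-6 percentage points; with default noise < 0.5
points); trait round-trips use 1000 random feasible vectors (1e-9);
batch-correction checks use 20 plates × 90 samples × 15 features with plate
effects drawn at twice the biological SD (< 0.05 SD residual); GEE checks
use n = 1000/400 families for effect recovery and 1000 null replicates at
n = 240/80 families for type-I calibration ([0.03, 0.07] at nominal 0.05);
the winsorization tail check pools thirty 10⁶-sample draws because the
expected clip count of a single draw (≈0.57) cannot resolve a factor-3
comparison against P(|Z|>5) ≈ 5.7×10⁻⁷. The analysis scripts run a
384-sample, 130-family, 4-plate study.

## Limitations

* The synthetic generator emulates isotope envelopes, co-elution, baseline,
  miscalibration, RT shifts and plate effects — not profile-mode peak
  shapes, chimeric interference beyond the IgG1/IgG4 mass coincidence,
  within-run drift, or cross-subclass trait correlation. Passing tests
  demonstrate correctness of the pipeline's operations against a known
  generative model, not performance on real instrument data.
* The 20-composition grid, background estimator, quality threshold value and
  noise magnitudes are documented stand-ins where the original study leaves
  details unpublished.
* The quality-fraction rule is relative; a blank sample whose few surviving
  spikes pass S/B could in principle evade it. An absolute intensity floor
  would be a natural extension.
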