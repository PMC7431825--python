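# Methods

This note documents the models, defaults, and numerical choices behind
`rdnameth`, and what the synthetic-data generators do and do not emulate.

## 1. Single-molecule mixture model

A deep-bisulfite amplicon read reports the methylation state of every CpG on
one sperm DNA molecule.  We model the molecule population of one
(region, variant, age class) as a two-component mixture:

* with probability `f_hyper` the molecule is *hypermethylated*: each CpG is
  methylated independently with probability `p_hyper` (default 0.85);
* otherwise it is a *background* molecule with per-CpG probability `p_bg`.

Given a published cohort pair (mean methylation m%, epimutation rate e%),
the preset is derived by `f_hyper = e/100` and the mean-reconstruction
identity `f_hyper·p_hyper + (1−f_hyper)·p_bg = m/100`.  This identifies the
mixture once `p_hyper` is fixed.  `p_hyper = 0.85` was chosen because it
keeps hypermethylated molecules unambiguously above the 50% threshold
(for 25 CpGs, P(Bin(25, 0.85) ≤ 12) ≈ 1e-5) while the background tail
P(Bin(n, p_bg) > n/2) stays below 1e-4 for every built-in preset — so the
expected ER of the simulation equals `100·f_hyper` to within Monte-Carlo
noise.  Built-in presets cover two rDNA amplicon regions (region 1 = external
transcribed spacer, 38 CpGs; region 2 = UCE + core promoter, 25 CpGs), A/G
variants, and young (26–36 y) / old (43–60 y) donor classes.

Two dispersion modes exist.  `fixed` (the default, and what the quantitative
checks use) draws every sample from the same mixture, so cohort means
converge on the calibration targets with only binomial noise.  `dispersed`
re-derives each sample's mixture from mean/ER targets jittered by the
published between-donor SDs (truncated to the feasible region); it is meant
for realism and epigenetic-drift demonstrations, not for point-recovery
tests, because ratio statistics become very noisy at cohort size 23.

## 2. Read simulation

Reads are single-end, full-length amplicons on the bisulfite-converted top
strand (amplicon PCR after conversion fixes the strand; paired-end chemistry
and read merging are sequencing details outside the model's scope).  For
each molecule: methylated CpG cytosines stay C; unmethylated CpG cytosines
and all non-CpG cytosines convert C→T, each failing independently with
probability `conversion_failure` (default 0.005); the variant position
carries the molecule's allele; independent substitution errors occur at
`seq_error` per base (default 0.001).  Qualities are constant Q37.  Not
simulated: PCR bias, chimeras, indels, and paired-end overlap artifacts —
so passing tests say nothing about robustness to those.

The default read depth (≈5,000 reads/allele/sample) was set for statistical
stability of per-sample ER estimates (SE ≈ 0.2 pp at ER ≈ 10%); published
depth per sample is not known.

Synthetic references are built deterministically from filler blocks: one
non-CpG cytosine per CpG (the conversion-QC sites), a single A/G variant
site flanked by A/T so it can never create or destroy a CpG.

## 3. Read processing rules

* **Alignment** is global (Needleman–Wunsch), since amplicon reads span the
  reference; scores: match +1 (including read T under reference C — the
  bisulfite asymmetry), mismatch −1, gap −2; traceback ties prefer diagonal,
  then up, then left.  Reads scoring below 0.5·L are dropped as unalignable
  and counted.  The batch caller short-circuits reads whose length equals
  the reference and whose substitution-only score clears the floor through
  an identity-mapping fast path; this is exact for the simulator's
  substitution-only reads and falls back to full NW otherwise.
* **Conversion QC** counts read T at non-CpG reference cytosines as
  converted and read C as unconverted; gaps and other bases are excluded
  from the denominator.  The filter is strict: conversion rate must exceed
  0.95, so a read at exactly 95% fails.  A read covering zero QC sites fails
  with an explicit `no_qc_sites` flag.
* **Calling** at reference CpGs: C → methylated, T → unmethylated, anything
  else missing.  Reads must have ≥ 90% of reference CpGs called
  (`min_cpg_call_frac`, configurable); the per-read hypermethylation
  fraction uses called CpGs as its denominator, which with the 90% floor
  differs negligibly from using all reference CpGs.
* **Allele splitting** uses the read base at the variant position; anything
  other than A/G makes the read `undetermined`, tallied separately and
  excluded from per-allele denominators.
* Quality strings are ignored; the rules reference only conversion rate.
  Coordinates are 0-based half-open internally.

Sample-level statistics are computed per sample; cohort summaries are
unweighted means over samples (not pooled reads), matching how cohort
"mean ± SD over N donors" tables are constructed.

## 4. Bulk cohort model

`simulate_bps_cohort` draws ages uniformly on the cohort's range and sets

    β_ij = clip(baseline_j + slope·age_i + u_i + ε_ij, 0, 100)

with `u_i ~ N(0, sample_sd²)` (donor offset), `ε_ij ~ N(0, cpg_sd²)`, and
missingness completely at random.  The default presets encode the published
aging slopes — human sperm 0.33 %/yr (n = 186, ages 25–66) and human blood
0.06 %/yr (n = 188, ages 1–70) — with `sample_sd = 2`, `cpg_sd = 1.5`
percentage points, a plausible magnitude for inter-donor variation in
targeted bisulfite data.  Age-0 baselines (UCE 6 / promoter 5 / 18S 4 /
28S 6 for sperm; higher for blood) are generator choices that keep values
well inside the clip range, so the linear model stays exactly linear.
Covariates (BMI, sperm concentration) are drawn independently of age; the
generator therefore cannot produce *real* confounding — tests of confounder
adjustment construct their confounders explicitly.

A note on precision: with these noise settings the OLS slope of the 9-CpG
promoter mean on age has standard error ≈ 0.013 %/yr in the sperm cohort and
≈ 0.008 %/yr in the blood cohort.  The blood slope (0.06) is therefore
recovered with ~13% relative SE — single-seed estimates scatter accordingly,
and the package's own recovery test uses the statistically calibrated
criterion |slope − truth| ≤ 3·SE rather than a fixed relative band.

## 5. Statistics

Partial correlation is computed by correlating OLS residuals of x and y on
the covariates (with intercept); p-values use the t transform with
df = n − 2 − k.  The precision-matrix form is implemented as a second public
route and used as a cross-check.  Covariates are adjusted jointly; constant
covariates are dropped.  Missing values are handled pairwise-complete and
the n used is reported.  Group comparisons default to Welch's t; the
Mann–Whitney U uses scipy's implementation.  No multiple-testing correction
is applied (documented choice: raw p-values per amplicon).  `relative_age`
divides by species life span — mouse 28 *months*, bovine 20 y, marmoset
12 y, human 80 y — and may exceed 1.

`er_ratio` takes arbitrary numerator/denominator summary sets, leaving
pooling across regions or variants to the caller.

## 6. The clock

QC removes samples with ≥ 10 missing CpGs (≤ 9 kept).  KNN imputation
(k = 10) uses the RMS difference over mutually observed CpGs as distance;
donors must have the target CpG observed; if none qualifies the CpG's
overall mean is used (approximating the cited implementation's documented
fallback).  Ties break by stable sample order, so imputation is
deterministic.

The ElasticNet objective uses the 1/(2n) convention (λ comparable across
cohort sizes).  Predictors are standardized inside each CV training fold
and for the final fit; coefficients are reported on the original scale; the
response is not standardized.  The λ path has 100 values descending
geometrically from λ_max = maxⱼ|⟨xⱼ, y−ȳ⟩|/(n·α) over four orders of
magnitude.  Folds come from a seeded permutation, as equal as possible,
unstratified.  The 1-SE rule picks the largest λ with
CV-MSE ≤ min(CV-MSE) + SE(at the minimizer), SE = SD over folds / √folds.
λ = 0 is fitted by exact least squares (lstsq) so the OLS limit is not
subject to coordinate-descent tolerance; penalized fits use scikit-learn's
coordinate descent (tol 1e-6, warm-started down the path), which the test
suite cross-checks against a brute-force coordinate-descent oracle on a tiny
instance.  Sparsity along the path is non-increasing up to a 1-feature
tolerance for solver noise.

Because the default cohort generator gives *every* CpG the same aging slope,
all 53 features are informative and the selected models are only mildly
sparse on such data; sparse-recovery tests use cohorts where age is a
function of a CpG subset.

## 7. Pipeline and formats

CSV tables carry `#`-prefixed provenance comments (package version, config
hash, seed); models and presets serialize as JSON; sequence data as
FASTA/FASTQ (Sanger quality).  The DBS driver derives one RNG stream per
(cohort, sample) from the master seed via `SeedSequence` spawn keys, so
results are bit-identical across runs and platforms for a given seed, and
fold assignment is the only thing a clock seed changes.  The study drivers
use 23 samples per cohort and 5,000 reads per allele by default — cohort
sizes matching the study design the presets were calibrated from, and a
depth chosen for stable per-sample ER estimates.

## 8. Known limitations

* The simulators are calibrated to cohort *summaries*; they do not model
  linked methylation between neighboring CpGs, allele-frequency structure,
  or donor-specific CpG profiles, so tests passing on synthetic data do not
  certify performance on real reads with indels or PCR artifacts.
* The conversion-failure channel inflates apparent methylation by roughly
  (1−p)·failure_rate; calling does not correct for it (by design — the
  published rules do not either).
* Partial correlations assume linear confounding; the clock assumes a
  linear age signal and i.i.d. noise.
* The `dispersed` mode matches published SDs only approximately (truncation
  at the feasibility boundary slightly shrinks extreme draws).
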