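# Methods

## Scope and model

`riskscreen` implements a five-stage biomarker screen — per-cohort
differential expression, direction-consistent multi-cohort intersection,
log-rank survival filtering, correlation-bin cumulative scoring, and
2^−ΔΔCt qPCR validation — together with a synthetic-cohort generator that
plants a known truth so the whole funnel can be tested end to end. The
package targets the workflow used to screen lymph-node-metastasis risk
genes in papillary thyroid carcinoma from public expression cohorts, but
nothing in it is thyroid-specific.

## Differential expression

Expression is assumed to be log2-scale (as in processed GEO series
matrices); a `log2_transform` flag applies log2(x+1) to linear input.
log2FC is the difference of group means of log2 values, tumor − normal.
Significance comes from an unmoderated Welch *t* (unequal variances,
Welch–Satterthwaite degrees of freedom), two-sided. Web DE services
typically use limma's moderated *t*; with ≥20 samples per group the
moderation matters little, and the unmoderated test keeps the stage
self-contained and exactly specified. p-values are raw by default because
the screening gate is stated as raw *P* < 0.05; Benjamini–Hochberg
adjustment is available (`p_adjust="BH"`).

Gates are strict inequalities (|log2FC| > 2, *P* < 0.05), so boundary
values are not called. Degenerate inputs are fixed by rule: zero variance
in both groups gives *p* = 1 at equal means and the smallest positive
float (with a logged warning) at unequal means. Duplicate gene symbols are
collapsed by keeping the max-mean row (microarray convention; mean-collapse
configurable); genes with missing values are excluded from that cohort with
a logged count.

## Intersection

A gene is *common* only when every cohort calls it significant with the
same direction. Genes significant everywhere with mixed directions are
surfaced as `conflicted`; genes absent from some cohort's universe are
excluded from the intersection universe with a logged count. Both choices
avoid silent loss.

## Survival screening

The Kaplan–Meier estimator and the two-group log-rank test are implemented
from first principles — they are the computation this stage exists to
provide — and are cross-checked in the test suite against lifelines to
1e-10 (KM) and 1e-8 (log-rank). Conventions: at tied times events precede
censorings; *high* expression means strictly above the cutoff. The default
cutoff is the median split, which is reproducible and unbiased; a
`scan` option (quantiles 0.25–0.75, minimum *p*) mirrors "best cutoff"
behaviour of survival web tools but its p-values are optimistic and the
package logs a warning when it is used. No multiple-testing correction is
applied across genes, matching the raw *P* < α screening convention.

## Core-gene scoring

Pairwise Pearson coefficients are computed over tumor samples by default
(the disease context the score describes); the pipeline pools tumor samples
across the discovery cohorts to stabilize the estimate (n = 60 at default
settings). Scores per pair: |r| < 0.4 → 0, 0.4 ≤ |r| < 0.6 → 1,
0.6 ≤ |r| < 0.8 → 2, 0.8 ≤ |r| ≤ 1 → 3. The published description of such
binning leaves the interval endpoints ambiguous; bins here are left-closed
and right-open with the last bin closed, which is deterministic and has
measure-zero impact on continuous data. Negative correlations score by
absolute value. Cumulative score = sum of a gene's pair scores; genes are
dense-ranked descending with ties sharing a rank (displayed
alphabetically), and the top-k ranks define the core genes, expanding past
k on a tie with an explicit flag. Zero-variance genes cannot be correlated
and are excluded with a logged warning.

## qPCR validation

ΔCt = Ct_target − Ct_reference within a tissue; ΔΔCt = ΔCt_tumor −
ΔCt_adjacent; relative expression = 2^−ΔΔCt, so ΔΔCt > 0 means the target
is down in tumor. The reference gene defaults to ACTB (β-actin); source
material for this workflow sometimes prints the symbol as "ATCB", which is
treated as a typo for the ACTB housekeeping gene — the reference symbol is
a config value, so any label can be used. The significance test is a paired
two-sided Student's *t* on per-patient ΔCt (Ct-scale values are closer to
normal than fold changes; the pairing reflects tumor/adjacent tissue from
the same patient); an unpaired option exists. Patients with incomplete
(patient, tissue) blocks are excluded with a logged count.

## Pipeline order

The funnel runs DEG → intersection → (optional) independent-cohort
direction verification → OS survival filter → scoring → (optional) qPCR →
(optional) RFS pass on the qPCR-confirmed genes, mirroring the discovery
workflow it re-implements: the risk set passed to scoring is exactly the
survival-significant subset of the verified intersection, and no stage
introduces genes a previous stage did not emit. A run missing later inputs
stops after the last feasible stage with `status="partial"` (CLI exit
code 3).

## Synthetic-data generator

The generator emulates the statistical structure the screen assumes, not
any particular platform:

* **Expression.** Gene baselines ~ N(8, 1.5²) shared across cohorts; i.i.d.
  Gaussian noise (sd 0.5 by default) within groups; planted genes shifted
  in tumor samples by a cohort-specific effect jittered N(Δ, 0.1²) around
  Δ = 4 log2 units to emulate inter-platform variability. Defaults: 3
  cohorts, 1000 genes, 20 tumor + 20 normal samples per cohort, 8 up + 15
  down planted genes — the cohort scale and up/down split of the emulated
  study design.
* **Core module.** A single latent factor shared by 4 planted genes in
  tumor samples, loading λ = 0.85 per gene, giving pairwise r ≈ λ² ≈ 0.72
  ("strong" bin). One shared factor is the simplest mechanism producing
  the block-correlation structure the scoring stage consumes.
* **Survival.** 200 patients; per-gene standardized expression with the
  same core-module factor; event times exponential with hazard
  0.02·exp(Σ β_g x_g), β = +1 for planted-up and −1 for planted-down genes
  (low expression of a down gene is the risk state); independent
  Uniform(0, q) censoring with q solved numerically so the expected
  censored fraction equals the configured rate (0.3 default).
* **qPCR.** 8 patients, paired tissues; per-gene baseline Ct ~ U(20, 30),
  a per-(patient, tissue) offset N(0, 0.3²) that cancels in ΔCt, technical
  noise sd 0.25, and a tumor-side Ct shift of +2 for planted-down and −2
  for planted-up genes.

All randomness flows from one seed through separate, independently
reproducible streams for cohorts, survival and Ct.

What the generator does **not** emulate: probe-level noise, batch and
platform annotation effects, non-Gaussian expression marginals,
non-proportional hazards, or qPCR efficiency differences. Passing recovery
tests therefore demonstrates that the pipeline's logic is correct under its
own assumptions, not that the screen has any particular power on real
microarray data.

## Problem sizes in the tests and acceptance script

Unit and acceptance runs use 1000-gene cohorts, 100 replicate worlds for
rank-recovery rates, 1000 replicates for the log-rank null calibration and
100 random datasets for oracle agreement — sizes at which the Monte-Carlo
bounds asserted (e.g. type-I error in [0.03, 0.07] at α = 0.05) have
comfortable margins while the whole suite runs in well under a minute.

## Known limitations

* Published gene lists from screens of this design depend on external
  databases and web-tool internals (moderated tests, cutoff scans, cohort
  versions) and are not reproduction targets; this package reproduces the
  procedure with every choice pinned down.
* The scan cutoff's minimum p-value is not corrected for the scan.
* The log-rank implementation loops over distinct event times in Python;
  it is ample for screening tens of genes over hundreds of patients but
  not tuned for genome-wide survival scans.
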