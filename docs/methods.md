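# Methods

## The measurement model

Each subject carries a latent DSB-repair phenotype, `intact` or
`defective`.  The phenotype fixes the expected values of the three flow
variant assays (FVAs): BRCA1 and BRCA2 nuclear localization (fraction of
marker-positive nuclei after radiomimetic challenge) and the
phospho-p53 : total-p53 fold induction.  The generator draws a per-subject
latent value for each assay from a Gaussian around the phenotype mean, then
layers multiplicative log-normal factors for cell type (PBMC vs LCL),
storage day, and replicate before sampling flow events.

Flow events are a three-part mixture per sample:

* a DAPI-low **debris** fraction (default 10%) removed by the gate;
* **marker-negative nuclei** with log-normal intensities shared between
  challenged and untreated samples;
* **marker-positive nuclei** (challenged samples only, at the subject's
  latent positive fraction) with ~10× higher median intensity.

Because the positivity threshold is estimated as the 99th percentile of the
matched untreated sample per channel, the untreated false-positive rate is
~1% by construction and the challenged positive fraction recovers the
latent value with a small (< 0.5 point) bias.  The p53 readout is the
challenged phospho:total median ratio normalized by the untreated ratio
(fold induction), making it unitless and instrument-independent; medians
are used for robustness to log-normal tails.

All randomness derives from a single seed through `numpy.random.SeedSequence`
keyed on CRC32 hashes of subject/sample identifiers, so outputs are
byte-identical for a fixed configuration regardless of generation order.

## Generator parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| intact / defective NL mean | 0.75 / 0.35 | fraction | synthetic default; intact cells respond strongly, defective cells are blunted |
| intact / defective p53 ratio | 2.5× / 1.2× | fold | synthetic default |
| between-subject SD | 0.05 (NL), 0.25 / 0.12 (p53) | — | keeps the two phenotype clusters ~4 SD apart (bimodal, interquartile ranges disjoint) |
| `events_per_sample` | 10,000 | events | stable gating fractions (binomial SE ~0.5 points); tests use 1,000–2,000 |
| `debris_fraction` | 0.10 | fraction | DAPI-low material from partial lysis |
| `measurement_cv` | 0.015 | fraction | reproduces the observed replicate behaviour: mean triplicate CV ≈ 1.5% (< 3%) with ~3–7% of individual CVs above 3%; at 0.02 the exceedance roughly triples, which overstates the measured noise |
| `day_jitter_cv` / `day4_attenuation` / `day4_noise_cv` | 0.03 / 0.5 / 0.25 | — | days 2–3 track day 1 at r² > 0.9; day 4 is attenuated toward the defective regime with inflated noise so r² falls below 0.9 (storage degradation) |
| `celltype_cv` | 0.04 | fraction | matched PBMC/LCL summaries correlate at r² > 0.9 |
| `plp_prevalence` | 0.15 (0.08 / 0.20 per clinic cohort) | fraction | carrier prevalence range of the two clinic populations |
| `vus_prevalence` | 0.35 (0.34 / 0.39) | fraction | all-gene VUS rates of the clinic populations |
| `plp_intact_leak_rate` | 0.09 | fraction | fraction of P/LP carriers whose cells behave repair-intact; equals the observed carrier false-negative fraction (2/22) and is what makes simulated sensitivity ≈ 0.91 rather than 1.0 |
| `seq_negative_defective_rate` | 0.30 | fraction | variant-free subjects with a functional defect invisible to sequencing, so the CR-B+ share of a cohort can exceed its carrier share |
| `vus_defective_rate` | 0.10 | fraction | most VUS do not disrupt the pathway |
| `transfection_efficiency` | 0.90 | fraction | gene-rescue experiments; rescued (transfected) cells behave intact only when the plasmid matches the causal gene |

Absolute intensity scales (DAPI median 1000, marker negative/positive
medians 100/1000, p53 channels 500/200) are conventions: no baseline
levels or raw units are published for these assays, and the readouts are
fractions and fold changes that are invariant to them.

## The risk classification score

The RCS is a logistic regression of the three FVA summaries on labeled
controls (carriers = pathogenic-like, negative relatives = benign-like).
Features are centered and scaled at fit time; the scaling is stored with
the coefficients so scoring is reproducible and invariant to positive
affine rescaling of any raw feature.  The reported score is the *negative*
pathogenic log-odds, so RCS = 0 exactly at model probability 0.5 ("the log
of the odds ratio of pathogenic to benign is zero at equal likelihood"),
RCS < 0 ⇔ CR-B+ and RCS > 0 ⇔ CR-B−.  A score of exactly 0 is called
CR-B+ — the tie favours sensitivity for a screening test — and the rule is
configurable (`tie_call`).  No indeterminate zone is used.

Two numerical choices matter:

* **Ridge strength.**  The default penalty is λ = 1 on standardized
  features with balanced class weights.  Because a fraction of carriers is
  phenotypically intact (the leak rate), group-labeled training data are
  near-separable with label noise; a near-maximum-likelihood fit (λ → 0)
  inflates the coefficients and drags the boundary into the intact cluster,
  costing specificity.  λ = 1 keeps the boundary near the mid-point between
  the phenotype clusters; `ridge_lambda` is a parameter for users who want
  the near-MLE behaviour.
* **Bimodality.**  One- and two-component Gaussian mixtures (k-means
  initialization, 3 restarts, fixed seed) are compared by BIC; "bimodal"
  requires BIC(2) < BIC(1) − 10, a strong-evidence margin that keeps the
  false-positive rate on unimodal data below ~5%.  Degenerate input (all
  values equal) returns `bimodal = False` with a note rather than raising.

Per-assay sensitivity/specificity in the pipeline come from single-feature
logistic fits with the same machinery, so each FVA is thresholded by the
same reproducible rule as the combined score.

## Diagnostic metrics and the all-cohort combination

Sensitivity is computed over group-1 carriers, specificity over group-3
negative relatives; group-2 subjects (VUS or no variant) have no genotype
truth and are excluded.  Empty denominators yield NA, never 0/0.

The "all cohorts" row is the weighted mean of per-cohort metric values with
weights equal to **total cohort N** (36/6/4 in the reference table),
restricted to cohorts where the metric is available (a cohort without
negative relatives drops out of specificity and accuracy, leaving N = 42).
This rule is forced by the published fractions (38.5/46 for the combined
BRCA1 sensitivity is reachable only this way) and differs from pooling the
2×2 tables: the combined numerator is an implied fraction (value × ΣN),
generally non-integer, and the sensitivity denominator is ΣN = 46 even
though only 28 subjects carry P/LP variants.  Reports carry this caveat.

Mann–Whitney p-values are exact (equivalent to full enumeration of rank
assignments) when the combined sample has ≤ 12 observations and no ties —
above that, a normal approximation with tie correction and a continuity
correction of max(|U − μ| − ½, 0), which returns p = 1 for identical
samples.  The rescue comparisons use Student's pooled-variance t test; zero
pooled variance returns p = 1 when the means agree and raises otherwise.

## Bayesian VUS reclassification

Two evidence models are computed side by side:

1. the **assay likelihood-ratio model**: LR− = (1 − sens)/spec applied to
   CR-B− results (LR+ = sens/(1 − spec) for CR-B+);
2. the **odds-of-pathogenicity framework** with base 350: strengths
   supporting/moderate/strong/very-strong carry odds 350^(1/8, 1/4, 1/2, 1)
   and benign evidence the reciprocals.

The module defaults to sensitivity 0.91 / specificity 0.96 — the operating
point the reclassification analysis applied — although the combined
validation table reports RCS specificity 1.00; both are accepted inputs and
the report records which was used (a perfect specificity yields an infinite
LR+, capped at very-strong pathogenic evidence).  Posteriors follow the
closed-form odds update and are banded at B < 0.001, LB < 0.10, LP > 0.90,
P > 0.99 (band boundaries resolve to VUS; all four configurable).  The
prior grid defaults to 0.05–0.95 in steps of 0.05.

A likelihood ratio is mapped to an evidence strength by the **nearest**
level on the log₃₅₀ scale (ratios between 1/2.08 and 2.08 are
insufficient).  LR− = 0.09375 (benign odds 10.7, log₃₅₀ = 0.40) is closest
to the strong level — matching the test's characterization as a strong BS3
classifier — whereas a floor-threshold mapping (available as
`mode="threshold"`) would call it moderate since 10.7 < √350.

Reclassification is applied per variant and only to CR-B− carriers: a
CR-B+ result never auto-upgrades a VUS, because attributing the defective
phenotype to a specific variant requires gene rescue.

## What the generator does and does not emulate

It reproduces the statistical structure the analysis relies on: bimodal
phenotype separation, triplicate CVs, day and cell-type replication,
prevalence composition, sequencing-invisible defects, and gene-specific
rescue.  It does **not** emulate spectral spillover/compensation, doublets,
instrument drift, batch effects, gene- or variant-specific effect sizes,
age or treatment covariates, or linkage between family members.  Passing
tests therefore demonstrate that the analysis code recovers known structure
under a faithful noise model — not that the assays perform identically on
real blood.

Where original per-subject data are required but not redistributable, the
package provides stand-ins that are explicitly synthetic: score columns
constructed to the published cohort splits (22/78 and 30/29 CR-B−/CR-B+)
and a matched PBMC/LCL table built by orthogonal mixing to the published
empirical correlations (r² = 0.98 / 0.93 / 0.99).  Tests against these
verify the counting and correlation code paths, not the patient data.

## Problem sizes

Production defaults simulate 10,000 events per sample and triplicates.
The test suite and stochastic checks run at 1,000–2,000 events per sample,
one to three replicates, 36-subject training panels, and 50-seed /
1,000-run batches for the operating-point and rescue-specificity checks —
sizes at which gating fractions are stable to ~1 point and a full run
completes on a single CPU in well under a minute.
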