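# crbflow

Simulation and analysis toolkit for a functional blood test of DNA
double-strand-break (DSB) repair capacity in women at elevated breast- and
ovarian-cancer risk.

Gene-panel sequencing leaves most tested women without an answer: only
15–20% carry a pathogenic or likely pathogenic (P/LP) variant in a DSB
repair gene (*BRCA1*, *BRCA2*, *PALB2*, *ATM*, ...), while ≥ 40% receive a
variant of uncertain significance (VUS) or no finding at all.  A
flow-cytometric functional test reads the pathway itself: after challenging
blood cells with a radiomimetic agent, three **flow variant assays (FVAs)**
measure BRCA1 nuclear localization, BRCA2 nuclear localization, and the
phospho-p53 : total-p53 fold induction in DAPI-gated nuclei.  Cells with
intact repair respond strongly; cells with a defective pathway are blunted,
and the phenotype is bimodal rather than continuous.

`crbflow` implements that analysis as a tested, seedable pipeline for
simulated cohorts:

* **`synthetic_data`** — cohorts (P/LP carriers, VUS / no-variant subjects,
  relatives testing negative), per-sample flow-event clouds with a
  two-component log-normal mixture, triplicate / storage-day / PBMC-vs-LCL
  replication structure, and gene-transfer rescue experiments in which only
  the causal gene's wild-type construct restores the intact phenotype.
* **`fva_quantify`** — DAPI gating, positivity thresholds from the matched
  untreated sample (99th percentile per channel), the three per-sample FVA
  summaries, and replicate CV quality control.
* **`rcs_model`** — the **risk classification score (RCS)**: a logistic
  regression of the three FVAs, reported as

  `RCS = −(β₀ + β·z) = log-odds(benign : pathogenic)`,

  normalized so the log odds of pathogenic to benign is zero at equal
  likelihood.  RCS < 0 calls the sample **CR-B+** (repair-defective),
  RCS > 0 **CR-B−** (wild-type repair).  Includes a BIC-based Gaussian
  mixture test of bimodality.
* **`performance`** — sensitivity (CR-B+ carriers / all carriers),
  specificity (CR-B− negative relatives / all negative relatives),
  accuracy, the cohort-size-weighted all-cohort combination, Pearson r²,
  Mann–Whitney (exact by enumeration for small tie-free samples), and the
  pooled two-sample t test used for rescue comparisons.
* **`vus_bayes`** — Bayesian VUS reclassification from the functional
  phenotype: likelihood ratios LR− = (1−sens)/spec and LR+ = sens/(1−spec),
  the odds-of-pathogenicity strength scale (very strong = 350,
  strong = √350 ≈ 18.7; benign directions are reciprocals), the posterior
  update `post = O·π / ((O−1)·π + 1)`, and the ACMG class bands
  (B < 0.001, LB < 0.10, LP > 0.90, P > 0.99).
* **`pipeline` / `cli`** — configuration, CSV/JSON I/O, and an end-to-end
  driver (`crbflow run`) with subcommands `simulate`, `quantify`,
  `classify`, `evaluate`, `reclassify`.

## Worked example

A CR-B− result from an assay operating at sensitivity 0.91 and specificity
0.96 carries LR− = (1 − 0.91)/0.96 = 0.09375 — benign evidence of *strong*
(BS3) magnitude on the odds-of-pathogenicity scale.  Sweeping the prior
probability of pathogenicity:

```python
>>> from crbflow import likelihood_ratios_from_assay, reclassify_over_prior_grid
>>> m = likelihood_ratios_from_assay(0.91, 0.96)
>>> out = reclassify_over_prior_grid(m, "CRB_minus")
>>> print(out.table.head(12).to_string(index=False))
 prior  posterior acmg_class
  0.05   0.004910         LB
  0.10   0.010309         LB
  0.15   0.016275         LB
  0.20   0.022901         LB
  0.25   0.030303         LB
  0.30   0.038627         LB
  0.35   0.048055         LB
  0.40   0.058824         LB
  0.45   0.071240         LB
  0.50   0.085714         LB
  0.55   0.102804        VUS
  0.60   0.123288        VUS
>>> out.max_blb_prior
0.5
```

Every VUS with a prior up to 0.50 — including the agnostic
equal-likelihood prior — is reannotated benign / likely benign, while
higher priors stay VUS.  The same sweep is available from the shell:

```sh
crbflow reclassify --sensitivity 0.91 --specificity 0.96
```

A full simulated study (a 36-subject control panel used for training plus
two clinic cohorts of 100 and 59 subjects at 8% and 20% carrier
prevalence) runs with:

```sh
crbflow run --seed 1 --out crbflow_out
```

and writes the subject table, per-replicate FVA results, RCS scores and
CR-B calls, a validation-style metrics table (per cohort and the
N-weighted "all cohorts" row, cells formatted `value (num/den)`), the
bimodality check, replicate-CV QC, and the VUS reclassification table.

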