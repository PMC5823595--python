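# Methods

## Scope and model of the data

`gliorisk` treats a case-control genotype dataset as a dosage matrix
(subjects × SNPs, entries 0/1/2 counting risk alleles, `NaN` for missing)
plus a binary outcome and optional covariates (family history of cancer
`fmc`, age, sex). All score arithmetic happens on dosages; allele letters
matter only at VCF ingestion. The statistical model throughout is the
log-additive (allelic) logistic model: each additional risk allele
multiplies the odds of disease by the SNP's allelic odds ratio, so genotype
relative risks are (1, OR, OR²).

## Synthetic cohorts

The generator reproduces the sampling structure of a retrospective
case-control study rather than a population liability model: within each
outcome group, dosages at SNP *i* are drawn i.i.d. Binomial(2, p) at that
group's risk-allele frequency (Hardy–Weinberg equilibrium within group),
independently across loci. This choice makes the published per-group
frequency tables the direct parameters of the generator, so simulated
cohorts reproduce the frequency columns, the count-score distributions and
the implied ORs by construction. The packaged panels carry the published
dataset2 (5 SNP) and dataset3 (7 SNP) frequencies and allelic ORs.

Optional features:

* **LD pairs.** Two loci can be coupled at a target squared dosage
  correlation r². Two haplotypes per subject are drawn from the two-locus
  haplotype distribution with D = r·√(p_a q_a p_b q_b); the Lewontin bound
  D ≤ min(p_a q_b, q_a p_b) is enforced and infeasible targets raise an
  error naming the attainable maximum. This is the fixture used to exercise
  the pruning stage.
* **fmc.** Sampled independently of genotype (the two were found to be
  independent predictors), Bernoulli per group with control prevalence
  `fmc_prev_ctrl` (default 0.10 — never published for these cohorts; 10% is
  a typical first-degree-relative cancer-history prevalence for a Chinese
  hospital-based control series, and the value is configurable) and case
  odds scaled by `fmc_or` (default 1.63, the published dataset2 estimate).
* **Missingness.** MCAR at a single per-entry rate; no informative
  missingness is modelled because none was reported.

What the generator does *not* emulate: population structure, relatedness,
genotyping batch effects, age/sex dependence of genotype, or LD beyond the
declared pairs. Tests that pass on these cohorts therefore validate the
statistical machinery under the stated model, not robustness to those
real-data complications.

## SNP selection

QC drops a SNP if call rate < 95%, MAF < 0.05 (computed over all genotyped
subjects), or the control-group HWE chi-square p < 0.01. The HWE test is
the 1-df goodness-of-fit chi-square at the sample allele frequency
(monomorphic SNPs return p = 1); an exact test would differ only at much
smaller counts than these panels see. Subjects genotyped at < 95% of SNPs
are flagged for removal.

Selection then proceeds in three stages:

1. univariate log-additive logistic association, keeping p < 0.05
   (Wald test; unadjusted by default, covariate adjustment optional);
2. greedy LD pruning at r² ≥ 0.35. r² is the squared Pearson correlation
   of dosages (composite LD), not EM-phased haplotype r²; at the
   frequencies involved the two are close and dosage r² is deterministic.
   Pairs are resolved in decreasing r² order and the member with the larger
   p-value is dropped (ties: the lexicographically larger id) — a
   deterministic rule that keeps the more significant member;
3. backward elimination in the joint logistic model: repeatedly refit and
   remove the SNP whose 1-df likelihood-ratio test has the largest
   p > `alpha_remove` (default 0.05, the conventional stay criterion).
   Complete-case subjects only.

A pairwise interaction scan (product term in a two-SNP logistic model,
Wald p, Benjamini–Hochberg adjustment across pairs) is provided to verify
the no-interaction assumption the scores rely on.

## Scores

* **cGRS** sums dosages.
* **wGRS1** weights dosages by the allelic ORs *themselves* (w_i = OR_i).
  This follows the defining equation of the method as published; the more
  common log-OR weighting is available via `log_weights=True` but is off by
  default. For ranking-based metrics (AUC) the two differ only through the
  nonlinearity of exp, which is small at these effect sizes.
* **wGRS2** multiplies per-SNP genotype relative risks normalised by the
  population-average risk m_i = f0 + f1·OR + f2·OR² under reference
  genotype frequencies. The reference is HWE at the control allele
  frequency (the "population" proxy; whether the original analysis used
  controls, the pooled sample or external frequencies is not documented).
  With the subject drawn from the reference distribution, each per-SNP
  factor has expectation exactly 1, which the exact oracle verifies.
* **PRFLR** is the fitted probability from the joint logistic model,
  optionally including `fmc`.

Weights for the wGRS scores are by default estimated in-sample by
univariate logistic regression on the cohort being scored — the published
odds ratios are themselves in-sample estimates, and this makes the
pipeline self-contained for data read from a bare dosage table. Panel
metadata ORs can be substituted with `weight_source="panel"`. In-sample
weighting means apparent performance is optimistic; the bootstrap optimism
correction exists precisely to quantify that.

Cumulative-effect tables group subjects either by fixed allele-count bins
(≤1, 2, …, ≥6 for a 5-SNP panel) or by quartiles computed from controls. A
score exactly equal to a cut point goes to the *lower* bin; with discrete
scores this makes the bottom quartile hold more than 25% of controls, as
observed in practice.

## Assessment statistics

* **AUC / DeLong.** AUC is the tie-corrected Mann–Whitney statistic,
  computed via midranks. The variance uses DeLong's placement values:
  Var = S₁₀/m + S₀₁/n with the empirical variances of per-case and
  per-control placements; 95% CIs are Wald, clipped to [0, 1]. The paired
  test for two scores on the same subjects uses the covariance of the
  placement differences; two identical score vectors return p = 1 rather
  than failing, so pipelines over near-duplicate models run to completion.
* **Hosmer–Lemeshow.** Ten groups by predicted-risk deciles (ties to the
  lower group), statistic Σ(O−E)²/(E(1−E/n_g)), df = G−2 (the standard
  choice). Groups with zero expected information are merged into their
  neighbour with a warning and the df reduced.
* **cNRI.** Category-free: [P(up|case) − P(down|case)] + [P(down|control)
  − P(up|control)], exact ties counting for neither direction; the SE
  treats the case and control components as independent, which is the
  standard asymptotic formula. Range −2 to 2.
* **IDI.** The change in discrimination slope (mean predicted risk in
  cases minus controls); SE from the paired differences within each group.
  The implementation is cross-checked in the tests against an independent
  two-pass slope computation to machine precision.
* **Bootstrap optimism.** Harrell's procedure: refit on each resample,
  optimism = (AUC on resample) − (resample-fitted model's AUC on the
  original data), corrected AUC = apparent − mean optimism. Resamples that
  lose a class are redrawn and counted. The default replicate count in the
  published protocol is 2000; the pipeline exposes `n_boot` and the test
  suite uses 100–200 replicates, which estimates the optimism mean to well
  under the effect sizes being corrected.
* **Binned ORs.** Cross-product odds ratios against the reference bin with
  Wald CIs on the log scale; the trend test is the Wald p of the integer
  bin index in a logistic regression (score and Wald tests agree at these
  sample sizes).

## Exact oracle

Under HWE and inter-locus independence the distribution of every score is
known in closed form. The count score's pmf is the sequential convolution
of the per-SNP genotype laws; general scores are enumerated over all 3^k
genotype vectors (capped at k = 12; the packaged panels are k = 5 and 7),
merging score values that collide within 1e-9 (wGRS2 products can collide
exactly). Exact AUC between two pmfs is Σ_j P_ctrl(v_j)[P_case(>v_j) +
½P_case(=v_j)]; exact bin masses use the same tie convention as the
binning code. The oracle is the reference against which the generator,
the scores and the AUC machinery are validated (Monte-Carlo convergence at
3 standard errors, and exact identities where they exist).

## Determinism and problem sizes

Every stochastic routine takes an explicit seed (`numpy` Generator
streams); the pipeline stamps each report with a configuration hash and
seed, and two runs with the same configuration are byte-identical,
including bootstrap summaries. The test suite and the acceptance script
use 50 simulation replicates at the published sample sizes (743/900) for
AUC summaries, 12 replicates at tenfold size for the selection-consistency
check, and 500–1000 replicates for calibration/level checks of the H-L and
HWE tests — sizes at which the Monte-Carlo error is comfortably below the
tolerances being asserted.

## Known limitations

* The generator's retrospective per-group sampling cannot express
  genotype–covariate dependence or population stratification; frequencies
  are taken as exact parameters, ignoring their own sampling error in the
  source tables.
* cNRI/IDI involving `fmc` depend on the unpublished control prevalence of
  family history and can only be matched qualitatively.
* Backward elimination explores a single deterministic path; it does not
  enumerate equally good sub-models.
* The H-L statistic's null distribution is asymptotic; with very few
  events per decile the merged-group behaviour is conservative.
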