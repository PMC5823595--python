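"""Genetic risk score construction.

Four per-subject summaries of a SNP panel are provided:

* ``cgrs`` — count GRS: the plain sum of risk-allele dosages.
* ``wgrs1`` — weighted GRS, additive form: sum of dosages weighted by the
  per-SNP allelic odds ratios themselves (w_i = OR_i, not log OR_i; a
  log-weight variant is available behind a flag).
* ``wgrs2`` — weighted GRS, multiplicative form: the product over SNPs of
  each subject's genotype relative risk (1, OR, OR^2 for 0/1/2 risk alleles)
  normalised by the population-average risk at that SNP under a reference
  genotype distribution, so a population-average subject scores 1.
* ``prflr`` — predicted risk from logistic regression: the fitted
  probability of case status from a multivariable log-additive model.

Binning utilities reproduce the two grouping schemes used for cumulative
effect tables: fixed allele-count bins and control-derived quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import statsmodels.api as sm

from .cohort import Cohort
from .panels import SnpSpec


@dataclass
class ScoreSet:
    """Per-subject values of one risk score, with its provenance."""

    method: str
    values: np.ndarray
    snp_ids: list[str]
    weights: object = None
    fit_meta: dict = field(default_factory=dict)


def _check_complete(dosages: np.ndarray) -> np.ndarray:
    d = np.asarray(dosages, float)
    if np.isnan(d).any():
        raise ValueError(
            "missing dosage encountered: apply complete-case filtering first"
        )
    return d


def cgrs(dosages: np.ndarray) -> np.ndarray:
    """Risk-allele count score: row sums of the dosage matrix."""
    d = _check_complete(dosages)
    return d.sum(axis=-1)


def wgrs1(
    dosages: np.ndarray, weights: np.ndarray, log_weights: bool = False
) -> np.ndarray:
    """Additive weighted score sum_i w_i * dosage_i with w_i = OR_i.

    ``log_weights=True`` switches to w_i = ln(OR_i) (the usual literature
    convention); the default keeps the odds ratios verbatim.
    """
    d = _check_complete(dosages)
    w = np.asarray(weights, float)
    if w.ndim != 1 or w.shape[0] != d.shape[-1]:
        raise ValueError("need exactly one weight per SNP")
    if (w <= 0).any():
        raise ValueError("weights must be positive odds ratios")
    if log_weights:
        w = np.log(w)
    return d @ w


def hwe_genotype_freqs(p: float) -> np.ndarray:
    """HWE genotype frequencies ((1-p)^2, 2p(1-p), p^2) for 0/1/2 dosage."""
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])


def wgrs2_factors(allelic_or: float, ref_freqs: np.ndarray) -> np.ndarray:
    """Per-genotype multiplicative factors for one SNP.

    Genotype relative risks under the log-additive model are (1, r, r^2);
    each is divided by the population-average risk m = f0 + f1*r + f2*r^2
    under the reference genotype distribution ``ref_freqs``.
    """
    f = np.asarray(ref_freqs, float)
    if f.shape != (3,) or abs(f.sum() - 1.0) > 1e-8 or (f < 0).any():
        raise ValueError("ref_freqs must be 3 genotype frequencies summing to 1")
    risks = np.array([1.0, allelic_or, allelic_or**2])
    m = float(f @ risks)
    if m <= 0:
        raise ValueError("population-average risk must be positive")
    return risks / m


def wgrs2(
    dosages: np.ndarray,
    allelic_ors: np.ndarray,
    ref_freqs: np.ndarray,
) -> np.ndarray:
    """Multiplicative genotypic-risk score relative to the population average.

    ``ref_freqs`` is a (k, 3) matrix of reference genotype frequencies per
    SNP (e.g. HWE frequencies at the control allele frequency).  The score
    of a subject drawn from the reference distribution has expectation 1 at
    every SNP, hence product expectation 1 under inter-locus independence.
    """
    d = _check_complete(dosages)
    d2 = np.atleast_2d(d)
    ors = np.asarray(allelic_ors, float)
    ref = np.asarray(ref_freqs, float)
    if ref.shape != (d2.shape[1], 3):
        raise ValueError("ref_freqs must be a (n_snps, 3) matrix")
    out = np.ones(d2.shape[0])
    for k in range(d2.shape[1]):
        factors = wgrs2_factors(ors[k], ref[k])
        out *= factors[d2[:, k].astype(int)]
    return out if np.ndim(d) > 1 else out[0]


def control_hwe_ref_freqs(cohort: Cohort) -> np.ndarray:
    """(k, 3) HWE genotype frequencies at the control risk-allele frequency."""
    ctrl = cohort.dosages[cohort.is_case == 0]
    freqs = []
    for k in range(cohort.n_snps):
        col = ctrl[:, k]
        col = col[~np.isnan(col)]
        freqs.append(col.sum() / (2 * col.size))
    return np.vstack([hwe_genotype_freqs(p) for p in freqs])


def prflr(
    cohort: Cohort,
    snp_ids: list[str] | None = None,
    include_fmc: bool = False,
) -> ScoreSet:
    """Predicted risks from a multivariable logistic regression.

    Fits case status on the log-additive dosages of ``snp_ids`` (all panel
    SNPs by default), optionally plus the family-history flag, on
    complete-case subjects, and returns the fitted probabilities as the
    score.  Coefficients and the complete-case count are stored in
    ``fit_meta``.  With no predictors at all the fitted risk is the case
    fraction for every subject.
    """
    ids = list(snp_ids) if snp_ids is not None else cohort.snp_ids
    sub = cohort.select_snps(ids).complete_cases() if ids else cohort
    y = sub.is_case
    cols = [sub.column(s) for s in ids]
    names = list(ids)
    if include_fmc:
        if sub.fmc is None:
            raise ValueError("cohort lacks fmc covariate")
        cols.append(np.asarray(sub.fmc, float))
        names.append("fmc")
    if cols:
        X = sm.add_constant(np.column_stack(cols))
    else:
        X = np.ones((len(y), 1))
    fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    if not fit.mle_retvals.get("converged", True):
        raise ValueError(f"logistic fit did not converge for SNPs {ids}")
    meta = dict(
        coefficients=dict(zip(["const"] + names, map(float, fit.params))),
        n_complete=int(len(y)),
        subject_ids=sub.subject_ids,
        include_fmc=include_fmc,
    )
    return ScoreSet(
        method="PRFLR",
        values=np.asarray(fit.predict(X)),
        snp_ids=ids,
        weights=np.asarray(fit.params),
        fit_meta=meta,
    )


@dataclass
class BinScheme:
    """Grouping scheme for cumulative-effect tables.

    ``count_bins`` uses fixed upper edges on an integer score (edges
    (1, 2, 3, 4, 5) give groups <=1, 2, 3, 4, 5, >=6).  ``control_quartiles``
    derives Q25/Q50/Q75 cut points from control scores.  In both schemes a
    value exactly equal to a cut point falls in the lower bin.
    """

    kind: Literal["count_bins", "control_quartiles"]
    edges: np.ndarray | None = None
    reference_bin: int = 0

    def __post_init__(self) -> None:
        if self.kind == "count_bins":
            if self.edges is None:
                raise ValueError("count_bins requires explicit edges")
            self.edges = np.asarray(self.edges, float)
            if (np.diff(self.edges) <= 0).any():
                raise ValueError("edges must be strictly increasing")


COUNT_BINS_6 = BinScheme("count_bins", edges=np.array([1, 2, 3, 4, 5]))
COUNT_BINS_7 = BinScheme("count_bins", edges=np.array([1, 2, 3, 4, 5, 6]))


def assign_bins(
    values: np.ndarray,
    scheme: BinScheme,
    control_values: np.ndarray | None = None,
) -> np.ndarray:
    """Map scores to integer bin indices under the scheme's tie convention.

    For ``control_quartiles`` the cut points are the 25/50/75 percentiles of
    ``control_values``; ties at a cut point go to the lower bin, so with
    discrete scores the bottom bin can hold more than a quarter of controls.
    """
    v = np.asarray(values, float)
    if scheme.kind == "count_bins":
        edges = scheme.edges
    else:
        if control_values is None:
            raise ValueError("control_quartiles requires control scores")
        edges = np.percentile(np.asarray(control_values, float), [25, 50, 75])
        if np.ptp(edges) == 0 and len(np.unique(control_values)) == 1:
            raise ValueError("degenerate quartiles: all control scores equal")
    return np.searchsorted(edges, v, side="left")


def _insample_ors(sub: Cohort) -> np.ndarray:
    """Per-SNP univariate allelic ORs estimated from the cohort itself."""
    out = np.empty(sub.n_snps)
    for k in range(sub.n_snps):
        X = sm.add_constant(sub.dosages[:, k])
        fit = sm.Logit(sub.is_case, X).fit(disp=0, maxiter=200)
        out[k] = np.exp(fit.params[1])
    return out


def score_cohort(
    cohort: Cohort,
    method: str,
    snp_ids: list[str] | None = None,
    wgrs2_ref: np.ndarray | None = None,
    include_fmc: bool = False,
    weight_source: Literal["insample", "panel"] = "insample",
) -> ScoreSet:
    """Compute one of cGRS / wGRS1 / wGRS2 / PRFLR on complete cases.

    The weighted scores need per-SNP allelic ORs: by default these are
    estimated in-sample by univariate logistic regression (models are
    developed and evaluated on the same dataset, with bootstrap optimism
    correction available to address the resulting overfitting);
    ``weight_source="panel"`` takes the ORs recorded in the panel metadata
    instead.  wGRS2 defaults to control-HWE reference genotype
    frequencies.  Complete-case subject ids are stored in
    ``fit_meta['subject_ids']``.
    """
    ids = list(snp_ids) if snp_ids is not None else cohort.snp_ids
    sub = cohort.select_snps(ids).complete_cases()
    if method in ("wGRS1", "wGRS2"):
        if weight_source == "panel":
            ors = np.array([s.allelic_or for s in sub.panel])
        else:
            ors = _insample_ors(sub)
    else:
        ors = None
    meta = dict(subject_ids=sub.subject_ids, n_complete=sub.n_subjects)
    if method == "cGRS":
        return ScoreSet("cGRS", cgrs(sub.dosages), ids, None, meta)
    if method == "wGRS1":
        return ScoreSet("wGRS1", wgrs1(sub.dosages, ors), ids, ors, meta)
    if method == "wGRS2":
        ref = wgrs2_ref if wgrs2_ref is not None else control_hwe_ref_freqs(sub)
        vals = wgrs2(sub.dosages, ors, ref)
        return ScoreSet("wGRS2", vals, ids, (ors, ref), meta)
    if method == "PRFLR":
        return prflr(cohort, ids, include_fmc=include_fmc)
    raise ValueError(f"unknown score method {method!r}")
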