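"""SNP quality control, association testing and panel selection.

Implements the standard candidate-SNP workflow for a case-control study:
per-SNP QC filters (call rate, minor-allele frequency, Hardy-Weinberg
equilibrium in controls), univariate log-additive logistic association,
greedy LD pruning on pairwise dosage r-squared, backward elimination by
likelihood-ratio test in a multivariate logistic model, and a pairwise
SNP x SNP interaction scan with Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import Cohort

_Z95 = stats.norm.ppf(0.975)


@dataclass
class AssocResult:
    """One logistic-regression association estimate for a SNP."""

    snp_id: str
    or_estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    model: str = "univariate"
    adjusted_for: tuple[str, ...] = ()


def hwe_test(genotype_counts: tuple[int, int, int]) -> float:
    """Chi-square (1 df) goodness-of-fit p-value for Hardy-Weinberg.

    ``genotype_counts`` are (n0, n1, n2) carriers of 0/1/2 risk alleles.
    Monomorphic SNPs return p = 1 by convention.
    """
    n0, n1, n2 = genotype_counts
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("need at least one genotyped subject")
    p = (2 * n2 + n1) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    expected = np.array([n * (1 - p) ** 2, n * 2 * p * (1 - p), n * p**2])
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = ((observed - expected) ** 2 / expected).sum()
    return float(stats.chi2.sf(chi2, df=1))


def qc_filter(
    cohort: Cohort,
    call_rate_min: float = 0.95,
    maf_min: float = 0.05,
    hwe_alpha: float = 0.01,
    subject_call_rate_min: float = 0.95,
) -> pd.DataFrame:
    """Per-SNP QC report with keep/drop decisions.

    A SNP is kept iff its call rate is >= ``call_rate_min``, its minor-allele
    frequency (over all genotyped subjects) is >= ``maf_min`` and the HWE
    chi-square p-value among controls is >= ``hwe_alpha``.  Filters are
    applied in that order for the reported ``drop_reason``.  The report also
    carries, as ``DataFrame.attrs['subjects_flagged']``, the ids of subjects
    whose genotyping rate falls below ``subject_call_rate_min``.
    """
    ctrl = cohort.is_case == 0
    if not ctrl.any():
        raise ValueError("no controls present: HWE filter undefined")
    rows = []
    for k, spec in enumerate(cohort.panel):
        col = cohort.dosages[:, k]
        obs = ~np.isnan(col)
        call_rate = obs.mean()
        vals = col[obs]
        freq = vals.sum() / (2 * vals.size) if vals.size else np.nan
        maf = min(freq, 1 - freq) if vals.size else np.nan
        cvals = col[ctrl & obs]
        counts = tuple(int((cvals == g).sum()) for g in (0, 1, 2))
        hwe_p = hwe_test(counts) if cvals.size else np.nan
        if call_rate < call_rate_min:
            reason = "call_rate"
        elif not maf >= maf_min:
            reason = "maf"
        elif not hwe_p >= hwe_alpha:
            reason = "hwe"
        else:
            reason = "none"
        rows.append(
            dict(
                snp_id=spec.snp_id,
                call_rate=call_rate,
                maf=maf,
                hwe_p=hwe_p,
                kept=reason == "none",
                drop_reason=reason,
            )
        )
    report = pd.DataFrame(rows)
    subj_rate = 1.0 - np.isnan(cohort.dosages).mean(axis=1)
    flagged = [
        cohort.subject_ids[i]
        for i in np.flatnonzero(subj_rate < subject_call_rate_min)
    ]
    report.attrs["subjects_flagged"] = flagged
    return report


def _fit_logit(y: np.ndarray, X: np.ndarray):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ValueError(f"logistic fit failed (separation?): {exc}") from exc


def univariate_assoc(
    dosage: np.ndarray,
    is_case: np.ndarray,
    covariates: np.ndarray | None = None,
    snp_id: str = "",
    covariate_names: tuple[str, ...] = (),
) -> AssocResult:
    """Log-additive logistic association of case status with one SNP.

    Fits case ~ dosage (+ covariates) on complete pairs; the per-allele OR
    is exp(beta) with a Wald 95% CI and two-sided Wald p-value.
    """
    dosage = np.asarray(dosage, float)
    is_case = np.asarray(is_case)
    keep = ~np.isnan(dosage)
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, float))
        if covariates.shape[0] != dosage.shape[0]:
            covariates = covariates.T
        keep &= ~np.isnan(covariates).any(axis=1)
    d, y = dosage[keep], is_case[keep]
    if len(set(y)) < 2:
        raise ValueError("both classes must be present")
    if np.ptp(d) == 0:
        raise ValueError(f"constant dosage for {snp_id or 'SNP'}")
    X = sm.add_constant(d)
    if covariates is not None:
        X = np.column_stack([X, covariates[keep]])
    fit = _fit_logit(y, X)
    beta, se = fit.params[1], fit.bse[1]
    return AssocResult(
        snp_id=snp_id,
        or_estimate=float(np.exp(beta)),
        ci_low=float(np.exp(beta - _Z95 * se)),
        ci_high=float(np.exp(beta + _Z95 * se)),
        p_value=float(fit.pvalues[1]),
        model="univariate",
        adjusted_for=covariate_names,
    )


def cohort_assoc(
    cohort: Cohort, adjust: tuple[str, ...] = ()
) -> list[AssocResult]:
    """Univariate association for every panel SNP, optionally adjusted.

    ``adjust`` may contain ``"age"``, ``"sex"`` and/or ``"fmc"``; the named
    covariates must be present on the cohort.
    """
    cov = None
    if adjust:
        cols = []
        for name in adjust:
            arr = getattr(cohort, name)
            if arr is None:
                raise ValueError(f"cohort lacks covariate {name!r}")
            cols.append(np.asarray(arr, float))
        cov = np.column_stack(cols)
    return [
        univariate_assoc(
            cohort.dosages[:, k],
            cohort.is_case,
            covariates=cov,
            snp_id=spec.snp_id,
            covariate_names=tuple(adjust),
        )
        for k, spec in enumerate(cohort.panel)
    ]


def pairwise_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns (composite LD)."""
    a = np.asarray(dosage_a, float)
    b = np.asarray(dosage_b, float)
    keep = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise ValueError("need at least 2 complete genotype pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("r2 undefined for a constant dosage column")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def r2_matrix(cohort: Cohort) -> pd.DataFrame:
    """Symmetric matrix of pairwise dosage r-squared over the panel."""
    ids = cohort.snp_ids
    m = np.eye(len(ids))
    for i, j in combinations(range(len(ids)), 2):
        m[i, j] = m[j, i] = pairwise_r2(
            cohort.dosages[:, i], cohort.dosages[:, j]
        )
    return pd.DataFrame(m, index=ids, columns=ids)


def ld_prune(
    assoc: list[AssocResult],
    r2_mat: pd.DataFrame,
    r2_max: float = 0.35,
) -> list[str]:
    """Greedy LD pruning: drop the less significant member of linked pairs.

    Repeatedly takes the unresolved pair with the largest r2 >= ``r2_max``
    and drops the member with the larger association p-value (tie: the
    lexicographically larger snp_id).  Deterministic; returns kept snp_ids
    in the input order.
    """
    pvals = {a.snp_id: a.p_value for a in assoc}
    order = [a.snp_id for a in assoc]
    alive = set(order)
    while True:
        best = None
        for i, j in combinations(order, 2):
            if i in alive and j in alive and r2_mat.loc[i, j] >= r2_max:
                key = (-r2_mat.loc[i, j], min(i, j), max(i, j))
                if best is None or key < best[0]:
                    best = (key, i, j)
        if best is None:
            break
        _, i, j = best
        if (pvals[i], i) >= (pvals[j], j):
            alive.discard(i)
        else:
            alive.discard(j)
    return [s for s in order if s in alive]


def backward_select(
    cohort: Cohort,
    candidate_ids: list[str],
    alpha_remove: float = 0.05,
    include_fmc: bool = False,
) -> list[str]:
    """Backward elimination by likelihood-ratio test.

    Fits a multivariate logistic model of case status on all candidate SNP
    dosages (complete-case subjects only) and iteratively removes the SNP
    whose 1-df likelihood-ratio test has the largest p > ``alpha_remove``,
    refitting until every remaining SNP is significant.  ``include_fmc``
    keeps the family-history covariate in every model without testing it.
    """
    sub = cohort.select_snps(candidate_ids).complete_cases()
    y = sub.is_case
    extra = []
    if include_fmc:
        if sub.fmc is None:
            raise ValueError("cohort lacks fmc covariate")
        extra = [np.asarray(sub.fmc, float)]
    current = list(candidate_ids)
    while current:
        cols = [sub.column(s) for s in current] + extra
        full = _fit_logit(y, sm.add_constant(np.column_stack(cols)))
        worst_p, worst_id = -1.0, None
        for drop in current:
            rest = [sub.column(s) for s in current if s != drop] + extra
            X_red = (
                sm.add_constant(np.column_stack(rest))
                if rest
                else np.ones((len(y), 1))
            )
            red = _fit_logit(y, X_red)
            lr = 2.0 * (full.llf - red.llf)
            p = float(stats.chi2.sf(max(lr, 0.0), df=1))
            # tie-break toward the lexicographically larger id, as in pruning
            if (p, drop) > (worst_p, worst_id or ""):
                worst_p, worst_id = p, drop
        if worst_p > alpha_remove:
            current.remove(worst_id)
        else:
            break
    return current


def interaction_scan(
    cohort: Cohort, snp_ids: list[str] | None = None
) -> pd.DataFrame:
    """Pairwise SNP x SNP interaction scan with BH-FDR adjustment.

    For each pair, fits case ~ snp_i + snp_j + snp_i*snp_j on complete
    pairs and reports the two-sided Wald p of the product term, plus the
    Benjamini-Hochberg adjusted p across all pairs.  Pairs whose fit fails
    (e.g. separation) are reported with missing p-values and a warning.
    """
    ids = snp_ids if snp_ids is not None else cohort.snp_ids
    if len(ids) < 2:
        raise ValueError("need at least two SNPs for an interaction scan")
    rows = []
    for a, b in combinations(ids, 2):
        da, db = cohort.column(a), cohort.column(b)
        keep = ~np.isnan(da) & ~np.isnan(db)
        X = sm.add_constant(
            np.column_stack([da[keep], db[keep], da[keep] * db[keep]])
        )
        try:
            fit = _fit_logit(cohort.is_case[keep], X)
            p = float(fit.pvalues[3])
        except ValueError as exc:
            warnings.warn(f"interaction fit failed for ({a}, {b}): {exc}")
            p = np.nan
        rows.append(dict(snp_a=a, snp_b=b, p_value=p))
    out = pd.DataFrame(rows)
    ok = out["p_value"].notna()
    adj = np.full(len(out), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = multipletests(
            out.loc[ok, "p_value"], method="fdr_bh"
        )[1]
    out["p_fdr"] = adj
    return out
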