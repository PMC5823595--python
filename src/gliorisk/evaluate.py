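"""Model assessment statistics for case-control risk prediction.

Discrimination: AUC with the DeLong structural-component variance and the
paired DeLong test for comparing two correlated AUCs.  Calibration: the
Hosmer-Lemeshow chi-square over risk-decile groups.  Reclassification:
continuous net reclassification improvement (cNRI) and integrated
discrimination improvement (IDI) with their asymptotic standard errors.
Internal validation: Harrell bootstrap optimism correction.  Cumulative
effect tables: per-bin odds ratios against a reference bin with a logistic
trend test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import Cohort

_Z95 = stats.norm.ppf(0.975)


@dataclass
class AucResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float


@dataclass
class ReclassResult:
    """cNRI or IDI estimate with Wald CI and two-sided p."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float


def _placements(scores: np.ndarray, is_case: np.ndarray):
    """DeLong structural components (placement values) and the AUC.

    V10[i] is the fraction of controls scored below case i (ties half);
    V01[j] the fraction of cases scored above control j, complemented.
    Computed with midranks in O(N log N).
    """
    s = np.asarray(scores, float)
    y = np.asarray(is_case).astype(bool)
    x, v = s[y], s[~y]
    m, n = x.size, v.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    r_all = stats.rankdata(np.r_[x, v])
    r_x = stats.rankdata(x)
    r_v = stats.rankdata(v)
    v10 = (r_all[:m] - r_x) / n
    v01 = 1.0 - (r_all[m:] - r_v) / m
    auc = float(v10.mean())
    return auc, v10, v01


def auc_delong(scores: np.ndarray, is_case: np.ndarray) -> AucResult:
    """Mann-Whitney AUC (ties half-credited) with DeLong SE and Wald CI."""
    auc, v10, v01 = _placements(scores, is_case)
    var = 0.0
    if v10.size > 1:
        var += v10.var(ddof=1) / v10.size
    if v01.size > 1:
        var += v01.var(ddof=1) / v01.size
    se = float(np.sqrt(var))
    return AucResult(
        auc=auc,
        se=se,
        ci_low=float(max(0.0, auc - _Z95 * se)),
        ci_high=float(min(1.0, auc + _Z95 * se)),
    )


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, is_case: np.ndarray
) -> tuple[float, float, float]:
    """Paired DeLong comparison of two AUCs on the same subjects.

    Returns (auc_a - auc_b, z, two-sided p).  When the two score vectors
    induce identical placements (zero variance of the difference) the
    degenerate case is reported as z = 0, p = 1.
    """
    auc_a, v10_a, v01_a = _placements(scores_a, is_case)
    auc_b, v10_b, v01_b = _placements(scores_b, is_case)
    diff = auc_a - auc_b
    var = 0.0
    if v10_a.size > 1:
        var += np.var(v10_a - v10_b, ddof=1) / v10_a.size
    if v01_a.size > 1:
        var += np.var(v01_a - v01_b, ddof=1) / v01_a.size
    if var <= 0:
        return float(diff), 0.0, 1.0
    z = diff / np.sqrt(var)
    return float(diff), float(z), float(2 * stats.norm.sf(abs(z)))


def hl_test(
    pred_risks: np.ndarray,
    is_case: np.ndarray,
    n_groups: int = 10,
) -> tuple[float, int, float]:
    """Hosmer-Lemeshow calibration chi-square over risk-quantile groups.

    Subjects are grouped by deciles (generally ``n_groups``-iles) of the
    predicted risk, ties going to the lower group; the statistic is
    sum (O - E)^2 / (E (1 - E/n_g)) over groups, with O the observed and E
    the expected case count, on G - 2 degrees of freedom.  Groups with zero
    expected information are merged into their neighbour (df reduced, with
    a warning).
    """
    p = np.asarray(pred_risks, float)
    y = np.asarray(is_case)
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("predicted risks must lie strictly in (0, 1)")
    qs = np.percentile(p, np.linspace(0, 100, n_groups + 1)[1:-1])
    grp = np.searchsorted(qs, p, side="left")
    groups = []
    for g in range(n_groups):
        mask = grp == g
        if mask.any():
            groups.append((int(mask.sum()), float(y[mask].sum()),
                           float(p[mask].sum())))
    # merge groups whose expected count carries no information
    merged: list[list[float]] = []
    for n_g, o, e in groups:
        if merged and (e <= 1e-12 or e >= n_g - 1e-12):
            warnings.warn("merged a degenerate risk group in H-L test")
            merged[-1][0] += n_g
            merged[-1][1] += o
            merged[-1][2] += e
        else:
            merged.append([n_g, o, e])
    chi2 = 0.0
    for n_g, o, e in merged:
        denom = e * (1.0 - e / n_g)
        if denom <= 0:
            continue
        chi2 += (o - e) ** 2 / denom
    df = max(len(merged) - 2, 1)
    return float(chi2), df, float(stats.chi2.sf(chi2, df))


def cnri(
    pred_old: np.ndarray, pred_new: np.ndarray, is_case: np.ndarray
) -> ReclassResult:
    """Continuous net reclassification improvement (category-free NRI).

    cNRI = [P(up|case) - P(down|case)] + [P(down|ctrl) - P(up|ctrl)], where
    "up"/"down" mean the updated model assigns a strictly higher/lower
    predicted risk; exact ties count for neither.  The asymptotic SE treats
    the case and control components as independent multinomial proportions.
    """
    old = np.asarray(pred_old, float)
    new = np.asarray(pred_new, float)
    y = np.asarray(is_case).astype(bool)
    if old.shape != new.shape or old.shape[0] != y.shape[0]:
        raise ValueError("predictions must be paired on identical subjects")
    up, down = new > old, new < old
    if not (up.any() or down.any()):
        warnings.warn("all predictions tied: cNRI variance degenerate")
        return ReclassResult(0.0, 0.0, 0.0, 0.0, 1.0)
    parts = []
    var = 0.0
    for mask in (y, ~y):
        n_g = int(mask.sum())
        pu = up[mask].mean()
        pdn = down[mask].mean()
        comp = pu - pdn
        parts.append(comp)
        var += (pu + pdn - comp**2) / n_g
    est = parts[0] - parts[1]
    se = float(np.sqrt(var))
    z = est / se if se > 0 else 0.0
    p = float(2 * stats.norm.sf(abs(z))) if se > 0 else 1.0
    return ReclassResult(
        float(est), se, float(est - _Z95 * se), float(est + _Z95 * se), p
    )


def idi(
    pred_old: np.ndarray, pred_new: np.ndarray, is_case: np.ndarray
) -> ReclassResult:
    """Integrated discrimination improvement.

    IDI is the change in discrimination slope — the difference between mean
    predicted risk in cases and controls — from the old to the updated
    model; its SE combines the paired-difference variances within cases and
    controls.
    """
    old = np.asarray(pred_old, float)
    new = np.asarray(pred_new, float)
    y = np.asarray(is_case).astype(bool)
    if old.shape != new.shape or old.shape[0] != y.shape[0]:
        raise ValueError("predictions must be paired on identical subjects")
    d = new - old
    d_case, d_ctrl = d[y], d[~y]
    est = float(d_case.mean() - d_ctrl.mean())
    var = 0.0
    if d_case.size > 1:
        var += d_case.var(ddof=1) / d_case.size
    if d_ctrl.size > 1:
        var += d_ctrl.var(ddof=1) / d_ctrl.size
    se = float(np.sqrt(var))
    z = est / se if se > 0 else 0.0
    p = float(2 * stats.norm.sf(abs(z))) if se > 0 else 1.0
    return ReclassResult(
        est, se, float(est - _Z95 * se), float(est + _Z95 * se), p
    )


def discrimination_slope(pred: np.ndarray, is_case: np.ndarray) -> float:
    """Mean predicted risk in cases minus mean predicted risk in controls."""
    p = np.asarray(pred, float)
    y = np.asarray(is_case).astype(bool)
    return float(p[y].mean() - p[~y].mean())


def bootstrap_optimism(
    fit_and_score,
    cohort: Cohort,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Harrell bootstrap optimism correction of the apparent AUC.

    ``fit_and_score(train: Cohort) -> callable`` must return a scorer
    mapping a cohort to per-subject scores.  For each bootstrap resample the
    model is refit on the resample and the optimism is the resample AUC
    minus the AUC of the same model on the original cohort; the corrected
    AUC is the apparent AUC minus the mean optimism.  Resamples missing a
    class are redrawn (counted in ``n_redrawn``).
    """
    rng = np.random.default_rng(seed)
    scorer = fit_and_score(cohort)
    apparent = auc_delong(scorer(cohort), cohort.is_case).auc
    n = cohort.n_subjects
    optimism = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if len(set(cohort.is_case[idx])) == 2:
                break
            n_redrawn += 1
        boot = cohort.subset(idx)
        scorer_b = fit_and_score(boot)
        auc_boot = auc_delong(scorer_b(boot), boot.is_case).auc
        auc_orig = auc_delong(scorer_b(cohort), cohort.is_case).auc
        optimism[b] = auc_boot - auc_orig
    mean_opt = float(optimism.mean())
    return dict(
        apparent_auc=apparent,
        optimism=mean_opt,
        corrected_auc=apparent - mean_opt,
        n_boot=n_boot,
        n_redrawn=n_redrawn,
        seed=seed,
    )


def binned_or_from_counts(
    case_counts: np.ndarray,
    ctrl_counts: np.ndarray,
    reference_bin: int = 0,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Per-bin odds ratios versus a reference bin from case/control counts.

    ORs are cross-products against the reference bin with Wald CIs on the
    log scale and two-sided Wald p-values.  Bins with an empty cell are
    reported with missing OR and a warning.
    """
    a = np.asarray(case_counts, float)
    b = np.asarray(ctrl_counts, float)
    if a.shape != b.shape:
        raise ValueError("count vectors must align")
    if a[reference_bin] == 0 or b[reference_bin] == 0:
        raise ValueError("reference bin must be non-empty in both classes")
    rows = []
    for g in range(len(a)):
        row = dict(
            bin=labels[g] if labels else g,
            n_case=int(a[g]),
            n_ctrl=int(b[g]),
            or_estimate=np.nan,
            ci_low=np.nan,
            ci_high=np.nan,
            p_value=np.nan,
        )
        if g == reference_bin:
            row["or_estimate"] = 1.0
        elif a[g] == 0 or b[g] == 0:
            warnings.warn(f"empty cell in bin {g}: OR undefined")
        else:
            log_or = np.log(a[g] * b[reference_bin] / (b[g] * a[reference_bin]))
            se = np.sqrt(
                1 / a[g] + 1 / b[g] + 1 / a[reference_bin] + 1 / b[reference_bin]
            )
            row.update(
                or_estimate=float(np.exp(log_or)),
                ci_low=float(np.exp(log_or - _Z95 * se)),
                ci_high=float(np.exp(log_or + _Z95 * se)),
                p_value=float(2 * stats.norm.sf(abs(log_or / se))),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def binned_or(
    bins: np.ndarray,
    is_case: np.ndarray,
    reference_bin: int = 0,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Cumulative-effect table: per-bin ORs plus a logistic trend test.

    The trend p-value (stored in ``DataFrame.attrs['trend_p']``) is the
    two-sided Wald p of the integer bin index in a logistic regression of
    case status.
    """
    bins = np.asarray(bins)
    y = np.asarray(is_case)
    n_bins = int(bins.max()) + 1
    case_counts = np.bincount(bins[y == 1], minlength=n_bins)
    ctrl_counts = np.bincount(bins[y == 0], minlength=n_bins)
    out = binned_or_from_counts(case_counts, ctrl_counts, reference_bin, labels)
    fit = sm.Logit(y, sm.add_constant(bins.astype(float))).fit(disp=0)
    out.attrs["trend_p"] = float(fit.pvalues[1])
    return out
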