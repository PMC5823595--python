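"""Exact score distributions under HWE and inter-locus independence.

Closed-form reference computations used to validate the stochastic parts of
the pipeline: the exact probability mass function of the risk-allele count
(by sequential convolution of per-SNP Binomial(2, p) genotype laws), exact
pmfs of any of the score constructions (by 3^k genotype enumeration), the
exact AUC between two score pmfs, and exact bin probabilities under the
same tie convention as the binning code.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .panels import SnpSpec
from .scores import hwe_genotype_freqs, wgrs2_factors

_MERGE_TOL = 1e-9
_ENUM_MAX_K = 12


@dataclass
class ExactPmf:
    """Discrete pmf: strictly increasing support with matching probabilities."""

    support: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, float)
        self.probs = np.asarray(self.probs, float)
        if self.support.shape != self.probs.shape:
            raise ValueError("support and probs must align")
        if (np.diff(self.support) <= 0).any():
            raise ValueError("support must be strictly increasing")
        if (self.probs < -1e-15).any() or abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be nonnegative and sum to 1")

    @property
    def mean(self) -> float:
        return float(self.support @ self.probs)

    @property
    def var(self) -> float:
        return float((self.support - self.mean) ** 2 @ self.probs)

    def cdf(self, x: float) -> float:
        return float(self.probs[self.support <= x + _MERGE_TOL].sum())


def _merge(values: np.ndarray, probs: np.ndarray) -> ExactPmf:
    order = np.argsort(values)
    v, p = values[order], probs[order]
    out_v, out_p = [v[0]], [p[0]]
    for vi, pi in zip(v[1:], p[1:]):
        if vi - out_v[-1] <= _MERGE_TOL:
            out_p[-1] += pi
        else:
            out_v.append(vi)
            out_p.append(pi)
    return ExactPmf(np.array(out_v), np.array(out_p))


def count_pmf(freqs: list[float]) -> ExactPmf:
    """Exact pmf of the summed risk-allele count sum_i Binomial(2, p_i)."""
    pmf = np.array([1.0])
    for p in freqs:
        if not 0.0 <= p <= 1.0:
            raise ValueError("frequencies must lie in [0, 1]")
        pmf = np.convolve(pmf, hwe_genotype_freqs(p))
    return ExactPmf(np.arange(pmf.size, dtype=float), pmf)


def score_pmf(
    panel: list[SnpSpec],
    group: str,
    scorer: str,
    ref_freqs: np.ndarray | None = None,
) -> ExactPmf:
    """Exact pmf of a score over one outcome group by genotype enumeration.

    Enumerates all 3^k genotype vectors with probability the product of the
    per-SNP HWE genotype frequencies at the group's risk-allele frequency;
    merges score values colliding within 1e-9.  ``ref_freqs`` (a (k, 3)
    matrix) is required for wGRS2 and defaults to HWE frequencies at the
    control allele frequencies.  Panels beyond k = 12 are rejected; use
    :func:`count_pmf` for the count score instead.
    """
    k = len(panel)
    if k > _ENUM_MAX_K:
        raise ValueError(
            f"enumeration capped at k={_ENUM_MAX_K}; for cGRS use count_pmf"
        )
    if group not in ("case", "control"):
        raise ValueError("group must be 'case' or 'control'")
    freqs = [s.freq_case if group == "case" else s.freq_ctrl for s in panel]
    geno = np.vstack([hwe_genotype_freqs(p) for p in freqs])
    ors = np.array([s.allelic_or for s in panel])
    if scorer == "cGRS":
        per_snp_vals = np.tile(np.arange(3.0), (k, 1))
    elif scorer == "wGRS1":
        per_snp_vals = np.outer(ors, np.arange(3.0))
    elif scorer == "wGRS2":
        if ref_freqs is None:
            ref_freqs = np.vstack(
                [hwe_genotype_freqs(s.freq_ctrl) for s in panel]
            )
        per_snp_vals = np.vstack(
            [wgrs2_factors(ors[i], ref_freqs[i]) for i in range(k)]
        )
    else:
        raise ValueError(f"unknown scorer {scorer!r}")
    vals = np.empty(3**k)
    probs = np.empty(3**k)
    for idx, g in enumerate(product(range(3), repeat=k)):
        gi = np.array(g)
        vs = per_snp_vals[np.arange(k), gi]
        vals[idx] = vs.prod() if scorer == "wGRS2" else vs.sum()
        probs[idx] = geno[np.arange(k), gi].prod()
    return _merge(vals, probs)


def exact_auc(pmf_case: ExactPmf, pmf_ctrl: ExactPmf) -> float:
    """Exact P(case score > control score) + 0.5 P(equal)."""
    auc = 0.0
    for v, q in zip(pmf_ctrl.support, pmf_ctrl.probs):
        gt = pmf_case.probs[pmf_case.support > v + _MERGE_TOL].sum()
        eq = pmf_case.probs[np.abs(pmf_case.support - v) <= _MERGE_TOL].sum()
        auc += q * (gt + 0.5 * eq)
    return float(auc)


def exact_bin_prob(
    pmf: ExactPmf, low: float | None = None, high: float | None = None
) -> float:
    """Mass of the half-open bin (low, high]; ``None`` leaves a side open.

    Matches the binning tie convention: a value exactly at a cut point
    belongs to the bin whose upper edge it equals.
    """
    mask = np.ones(pmf.support.size, bool)
    if low is not None:
        mask &= pmf.support > low + _MERGE_TOL
    if high is not None:
        mask &= pmf.support <= high + _MERGE_TOL
    return float(pmf.probs[mask].sum())
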