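"""Case-control cohort container and synthetic-cohort generator.

The generator inverts the descriptive model of a retrospective case-control
study: within each outcome group, genotype dosages at each SNP are drawn as
Binomial(2, p_group) under Hardy-Weinberg equilibrium at that group's
risk-allele frequency, independently across loci except for explicitly
declared linkage-disequilibrium (LD) pairs.  A binary family-history-of-cancer
covariate (fmc) is sampled per group so that its case/control odds ratio
matches a target in expectation, independently of genotype.  Missingness is
missing-completely-at-random.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .panels import SnpSpec, validate_panel


@dataclass
class Cohort:
    """Genotype dosages plus phenotype for one case-control dataset.

    ``dosages`` is a float matrix (subjects x SNPs) of risk-allele counts in
    {0, 1, 2} with ``NaN`` marking missing genotypes.  ``is_case`` is a 0/1
    integer vector; ``fmc``, ``age`` and ``sex`` are optional covariates.
    """

    dosages: np.ndarray
    is_case: np.ndarray
    panel: list[SnpSpec]
    fmc: np.ndarray | None = None
    age: np.ndarray | None = None
    sex: np.ndarray | None = None
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.is_case = np.asarray(self.is_case, dtype=int)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix (subjects x SNPs)")
        if self.dosages.shape[1] != len(self.panel):
            raise ValueError("dosage columns must match panel length")
        if self.dosages.shape[0] != self.is_case.shape[0]:
            raise ValueError("dosage rows must match is_case length")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosage entries must be 0, 1, 2 or missing")
        if len(set(self.is_case)) < 2:
            raise ValueError("is_case must contain both cases and controls")
        if self.subject_ids is None:
            self.subject_ids = [f"S{i + 1:05d}" for i in range(self.n_subjects)]

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.panel]

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.snp_ids.index(snp_id)]

    def subset(self, rows: np.ndarray) -> "Cohort":
        """Row-subset (e.g. bootstrap resample); panel is shared."""
        rows = np.asarray(rows)
        ids = [self.subject_ids[i] for i in rows]
        return Cohort(
            dosages=self.dosages[rows],
            is_case=self.is_case[rows],
            panel=self.panel,
            fmc=None if self.fmc is None else self.fmc[rows],
            age=None if self.age is None else self.age[rows],
            sex=None if self.sex is None else self.sex[rows],
            subject_ids=ids,
        )

    def select_snps(self, snp_ids: list[str]) -> "Cohort":
        """Column-subset to the given SNPs, preserving order of ``snp_ids``."""
        idx = [self.snp_ids.index(s) for s in snp_ids]
        return Cohort(
            dosages=self.dosages[:, idx],
            is_case=self.is_case,
            panel=[self.panel[i] for i in idx],
            fmc=self.fmc,
            age=self.age,
            sex=self.sex,
            subject_ids=self.subject_ids,
        )

    def complete_cases(self) -> "Cohort":
        """Subjects with no missing dosage on any panel SNP."""
        keep = ~np.isnan(self.dosages).any(axis=1)
        return self.subset(np.flatnonzero(keep))


@dataclass
class SimConfig:
    """Simulation settings for :func:`simulate_cohort`.

    ``ld_pairs`` couples pairs of panel SNPs at a target squared dosage
    correlation; each entry is ``((i, j), r2)`` with column indices into the
    panel.  ``fmc_or`` anchors the family-history odds ratio; its control
    prevalence is a free parameter of the generator (default 0.10).
    """

    n_case: int
    n_ctrl: int
    seed: int
    fmc_prev_ctrl: float = 0.10
    fmc_or: float = 1.63
    missing_rate: float = 0.0
    ld_pairs: list[tuple[tuple[int, int], float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_ctrl < 1:
            raise ValueError("n_case and n_ctrl must be >= 1")
        if not (0.0 < self.fmc_prev_ctrl < 1.0):
            raise ValueError("fmc_prev_ctrl must lie in (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        for (_, r2) in self.ld_pairs:
            if not (0.0 <= r2 <= 1.0):
                raise ValueError("ld_pair r2 targets must lie in [0, 1]")


def _d_from_r2(freq_a: float, freq_b: float, r2: float) -> float:
    """Positive-sign disequilibrium coefficient D matching a target r2.

    Raises ``ValueError`` when the target exceeds the Lewontin feasibility
    bound D_max = min(p_a q_b, q_a p_b) for the given allele frequencies.
    """
    qa, qb = 1.0 - freq_a, 1.0 - freq_b
    if min(freq_a, qa, freq_b, qb) <= 0.0:
        if r2 == 0.0:
            return 0.0
        raise ValueError("r2 > 0 infeasible for a monomorphic locus")
    d = math.sqrt(r2 * freq_a * qa * freq_b * qb)
    d_max = min(freq_a * qb, qa * freq_b)
    if d > d_max + 1e-12:
        r2_max = d_max**2 / (freq_a * qa * freq_b * qb)
        raise ValueError(
            f"target r2={r2:.4g} infeasible for frequencies "
            f"({freq_a:.3g}, {freq_b:.3g}): Lewontin bound gives "
            f"max attainable r2={r2_max:.4g}"
        )
    return min(d, d_max)


def _sample_ld_dosages(
    freq_a: float, freq_b: float, r2: float, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    d = _d_from_r2(freq_a, freq_b, r2)
    qa, qb = 1.0 - freq_a, 1.0 - freq_b
    # Haplotypes ordered (AB, Ab, aB, ab); A/B are the risk alleles.
    hap = np.array(
        [freq_a * freq_b + d, freq_a * qb - d, qa * freq_b - d, qa * qb + d]
    )
    hap = np.clip(hap, 0.0, None)
    hap /= hap.sum()
    draws = rng.choice(4, size=(n, 2), p=hap)
    dos_a = (draws <= 1).sum(axis=1)  # haplotypes carrying A
    dos_b = ((draws == 0) | (draws == 2)).sum(axis=1)
    return dos_a.astype(float), dos_b.astype(float)


def simulate_ld_pair(
    freq_a: float, freq_b: float, r2: float, n_subjects: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sample two dosage columns with a target squared dosage correlation.

    Two haplotypes per subject are drawn from the two-locus haplotype
    distribution with marginal risk-allele frequencies ``(freq_a, freq_b)``
    and disequilibrium D = sqrt(r2 * p_a q_a p_b q_b); dosages are haplotype
    sums.  Infeasible targets raise ``ValueError`` naming the bound.
    """
    rng = np.random.default_rng(seed)
    return _sample_ld_dosages(freq_a, freq_b, r2, n_subjects, rng)


def simulate_cohort(panel: list[SnpSpec], config: SimConfig) -> Cohort:
    """Generate a case-control cohort under per-group HWE sampling.

    Controls receive dosages ~ Binomial(2, freq_ctrl_i) and cases
    ~ Binomial(2, freq_case_i), independently across SNPs except for the
    declared ``ld_pairs``.  Cases are the first ``n_case`` rows.  Fully
    reproducible from ``config.seed``.
    """
    validate_panel(panel)
    for (i, j), _ in config.ld_pairs:
        if not (0 <= i < len(panel) and 0 <= j < len(panel)) or i == j:
            raise ValueError(f"invalid ld_pair indices ({i}, {j})")
    rng = np.random.default_rng(config.seed)
    n = config.n_case + config.n_ctrl
    is_case = np.r_[np.ones(config.n_case, int), np.zeros(config.n_ctrl, int)]

    dosages = np.empty((n, len(panel)))
    ld_members = {i for pair, _ in config.ld_pairs for i in pair}
    for grp, n_grp, sl in (
        (1, config.n_case, slice(0, config.n_case)),
        (0, config.n_ctrl, slice(config.n_case, n)),
    ):
        freqs = [s.freq_case if grp else s.freq_ctrl for s in panel]
        for k, p in enumerate(freqs):
            if k not in ld_members:
                dosages[sl, k] = rng.binomial(2, p, size=n_grp)
        for (i, j), r2 in config.ld_pairs:
            da, db = _sample_ld_dosages(freqs[i], freqs[j], r2, n_grp, rng)
            dosages[sl, i] = da
            dosages[sl, j] = db

    # fmc: control odds o scaled by fmc_or for cases; independent of genotype
    o = config.fmc_prev_ctrl / (1.0 - config.fmc_prev_ctrl)
    p_case = config.fmc_or * o / (1.0 + config.fmc_or * o)
    p_fmc = np.where(is_case == 1, p_case, config.fmc_prev_ctrl)
    fmc = (rng.random(n) < p_fmc).astype(int)

    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan

    return Cohort(dosages=dosages, is_case=is_case, panel=list(panel), fmc=fmc)
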