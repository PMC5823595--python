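"""SNP panel metadata.

A panel is an ordered list of :class:`SnpSpec` records, one per SNP, holding
the risk/non-risk alleles, the per-group risk-allele frequencies and the
per-allele (allelic) odds ratio estimated under a log-additive model.  Two
panels from published glioma case-control work in Han Chinese populations are
packaged as module constants: a five-SNP replication panel
(:data:`DATASET2_PANEL`) and a seven-SNP tag-SNP panel
(:data:`DATASET3_PANEL`).  These supply the frequencies and odds-ratio
weights used throughout the simulation and scoring machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class SnpSpec:
    """Per-SNP metadata for panel definition and cohort simulation.

    Parameters
    ----------
    snp_id : str
        rs identifier; must be unique within a panel.
    chrom : str
        Chromosome label.
    risk_allele, nonrisk_allele : str
        Single-letter alleles; dosage counts copies of ``risk_allele``.
    freq_case, freq_ctrl : float
        Risk-allele frequency among cases / controls, in [0, 1].
    allelic_or : float
        Per-risk-allele odds ratio (> 0) under the log-additive model;
        genotype relative risks are (1, OR, OR**2).
    """

    snp_id: str
    chrom: str
    risk_allele: str
    nonrisk_allele: str
    freq_case: float
    freq_ctrl: float
    allelic_or: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.freq_case <= 1.0 and 0.0 <= self.freq_ctrl <= 1.0):
            raise ValueError(
                f"{self.snp_id}: allele frequencies must lie in [0, 1]"
            )
        if self.allelic_or <= 0:
            raise ValueError(f"{self.snp_id}: allelic OR must be positive")


def validate_panel(panel: list[SnpSpec]) -> None:
    """Raise ``ValueError`` if SNP ids within the panel are not unique."""
    ids = [s.snp_id for s in panel]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate snp_id in panel")


# Five consistently replicated glioma GWAS SNPs (dataset2 frequencies/ORs).
DATASET2_PANEL: list[SnpSpec] = [
    SnpSpec("rs2736100", "5", "G", "T", 0.482, 0.418, 1.29),
    SnpSpec("rs1077236", "8", "C", "A", 0.725, 0.688, 1.20),
    SnpSpec("rs2157719", "9", "C", "T", 0.141, 0.111, 1.32),
    SnpSpec("rs498872", "11", "G", "A", 0.349, 0.285, 1.35),
    SnpSpec("rs6010620", "20", "C", "T", 0.330, 0.267, 1.35),
]

# Seven independent tag SNPs covering the replicated regions (dataset3).
# The published OR for rs494560 (0.73) contradicts its own confidence
# interval (1.18-1.60) and the allele-frequency cross-product (~1.37); the
# CI-consistent value 1.37 is used here.
DATASET3_PANEL: list[SnpSpec] = [
    SnpSpec("rs2853677", "5", "C", "T", 0.449, 0.375, 1.36),
    SnpSpec("rs2735948", "5", "T", "C", 0.170, 0.146, 1.20),
    SnpSpec("rs6589664", "11", "A", "G", 0.310, 0.271, 1.21),
    SnpSpec("rs494560", "11", "G", "A", 0.801, 0.746, 1.37),
    SnpSpec("rs17748", "11", "T", "C", 0.327, 0.263, 1.36),
    SnpSpec("rs3761121", "20", "G", "A", 0.269, 0.202, 1.45),
    SnpSpec("rs1058319", "20", "C", "T", 0.354, 0.256, 1.59),
]
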