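"""File formats: dosage tables, panel metadata, minimal VCF ingestion.

The native genotype format is a tab-separated dosage table in a PLINK
.raw-style dialect: comment lines starting ``#`` (carrying provenance such
as the simulation seed), then a header ``subject_id  is_case  fmc  <snp>...``
and one row per subject with dosages 0/1/2 or ``NA`` for missing.  Panel
metadata round-trips as a TSV with one row per SNP.  VCF files can be
ingested read-only given a risk-allele declaration per site.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort
from .panels import SnpSpec

_PHENO_COLS = ("subject_id", "is_case", "fmc")


def write_dosage_table(
    cohort: Cohort, path: str | Path, header_comments: list[str] | None = None
) -> None:
    """Write a cohort as a tab-separated dosage table (missing coded NA)."""
    path = Path(path)
    with path.open("w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        fh.write("\t".join(list(_PHENO_COLS) + cohort.snp_ids) + "\n")
        fmc = (
            cohort.fmc
            if cohort.fmc is not None
            else np.full(cohort.n_subjects, -9)
        )
        for i in range(cohort.n_subjects):
            cells = [cohort.subject_ids[i], str(cohort.is_case[i]), str(fmc[i])]
            for v in cohort.dosages[i]:
                cells.append("NA" if np.isnan(v) else str(int(v)))
            fh.write("\t".join(cells) + "\n")


def read_dosage_table(
    path: str | Path, panel: list[SnpSpec] | None = None
) -> Cohort:
    """Read the dosage-table dialect back into a :class:`Cohort`.

    Dosage cells must be 0, 1, 2 or ``NA``; anything else raises a
    ``ValueError`` naming the offending line.  If ``panel`` is omitted a
    minimal placeholder panel (alleles/frequencies unknown) is constructed
    from the header SNP ids.
    """
    path = Path(path)
    header: list[str] | None = None
    ids, case, fmc, rows = [], [], [], []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
                if tuple(header[:3]) != _PHENO_COLS:
                    raise ValueError(
                        f"line {lineno}: header must start with "
                        f"{' '.join(_PHENO_COLS)}"
                    )
                continue
            if len(cells) != len(header):
                raise ValueError(
                    f"line {lineno}: expected {len(header)} fields, "
                    f"got {len(cells)}"
                )
            ids.append(cells[0])
            case.append(int(cells[1]))
            fmc.append(int(cells[2]))
            row = []
            for col, cell in zip(header[3:], cells[3:]):
                if cell == "NA":
                    row.append(np.nan)
                elif cell in ("0", "1", "2"):
                    row.append(float(cell))
                else:
                    raise ValueError(
                        f"line {lineno}: invalid dosage {cell!r} for {col} "
                        "(must be 0, 1, 2 or NA)"
                    )
            rows.append(row)
    if header is None:
        raise ValueError(f"{path}: no header found")
    snp_ids = header[3:]
    if panel is None:
        panel = [
            SnpSpec(s, "?", "N", "N", 0.5, 0.5, 1.0) for s in snp_ids
        ]
    else:
        if [s.snp_id for s in panel] != snp_ids:
            raise ValueError("panel snp_ids do not match table header")
    fmc_arr = np.array(fmc)
    return Cohort(
        dosages=np.array(rows, dtype=float),
        is_case=np.array(case),
        panel=panel,
        fmc=None if (fmc_arr == -9).all() else fmc_arr,
        subject_ids=ids,
    )


def write_panel(panel: list[SnpSpec], path: str | Path) -> None:
    pd.DataFrame([vars(s) for s in panel]).to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path) -> list[SnpSpec]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        SnpSpec(
            snp_id=r.snp_id,
            chrom=str(r.chrom),
            risk_allele=r.risk_allele,
            nonrisk_allele=r.nonrisk_allele,
            freq_case=float(r.freq_case),
            freq_ctrl=float(r.freq_ctrl),
            allelic_or=float(r.allelic_or),
        )
        for r in df.itertuples()
    ]


def read_vcf_minimal(
    path: str | Path,
    risk_alleles: dict[str, str],
    is_case: np.ndarray,
    fmc: np.ndarray | None = None,
) -> Cohort:
    """Build a cohort from a VCF's GT fields and declared risk alleles.

    Only biallelic sites with an entry in ``risk_alleles`` are ingested;
    the dosage is the per-genotype count of the declared risk allele, which
    must match REF or ALT (otherwise ``ValueError``).  Multi-allelic sites
    are skipped with a warning; missing genotypes become missing dosages.
    Case status is supplied separately, aligned to the VCF sample order.
    """
    from cyvcf2 import VCF  # deferred: optional dependency

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    cols, specs = [], []
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        if vid not in risk_alleles:
            continue
        if len(var.ALT) != 1:
            warnings.warn(f"{vid}: multi-allelic site skipped")
            continue
        risk = risk_alleles[vid]
        if risk == var.ALT[0]:
            nonrisk, flip = var.REF, False
        elif risk == var.REF:
            nonrisk, flip = var.ALT[0], True
        else:
            raise ValueError(
                f"{vid}: risk allele {risk!r} matches neither REF "
                f"{var.REF!r} nor ALT {var.ALT[0]!r}"
            )
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt (with gts012), 3=missing
        vcf_gts = var.gt_types.astype(float)
        alt_dosage = np.where(vcf_gts == 3, np.nan, vcf_gts)
        col = 2.0 - alt_dosage if flip else alt_dosage
        cols.append(col)
        specs.append(
            SnpSpec(vid, str(var.CHROM), risk, nonrisk, 0.5, 0.5, 1.0)
        )
    if not cols:
        raise ValueError("no usable biallelic sites found in VCF")
    return Cohort(
        dosages=np.column_stack(cols),
        is_case=np.asarray(is_case),
        panel=specs,
        fmc=None if fmc is None else np.asarray(fmc),
        subject_ids=samples,
    )
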