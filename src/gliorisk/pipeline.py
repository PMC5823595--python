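"""End-to-end workflow: simulate/load -> QC -> select -> score -> evaluate.

``run_pipeline`` wires the stage functions together in the order a
case-control risk-model study runs them and writes one tab-separated report
per stage, each stamped with the configuration hash and seed so that two
runs with the same configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate, io, qc, scores
from .cohort import Cohort, SimConfig
from .panels import DATASET2_PANEL, SnpSpec


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run.

    Exactly one of ``dosage_table`` (with optional ``panel_table``) or
    ``simulate`` must be provided.  Threshold defaults follow the standard
    candidate-SNP protocol: per-SNP call rate >= 0.95, MAF >= 0.05, HWE
    alpha 0.01 in controls, univariate p < 0.05, LD r2 < 0.35, backward
    elimination at 0.05.
    """

    dosage_table: str | None = None
    panel_table: str | None = None
    simulate: SimConfig | None = None
    panel: list[SnpSpec] = field(default_factory=lambda: list(DATASET2_PANEL))
    call_rate_min: float = 0.95
    maf_min: float = 0.05
    hwe_alpha: float = 0.01
    p_max: float = 0.05
    r2_max: float = 0.35
    alpha_remove: float = 0.05
    score_methods: tuple[str, ...] = ("cGRS", "wGRS1", "wGRS2", "PRFLR")
    include_fmc: bool = False
    n_boot: int = 0
    hl_groups: int = 10
    seed: int = 1

    def __post_init__(self) -> None:
        if (self.dosage_table is None) == (self.simulate is None):
            raise ValueError(
                "exactly one of dosage_table or simulate must be given"
            )
        for name in ("call_rate_min", "maf_min", "p_max", "r2_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0.0 < self.hwe_alpha < 1.0 and 0.0 < self.alpha_remove <= 1.0):
            raise ValueError("hwe_alpha and alpha_remove must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        panel = raw.pop("panel", None)
        cfg = cls(
            simulate=SimConfig(**sim) if sim else None,
            panel=[SnpSpec(**s) for s in panel] if panel else list(
                DATASET2_PANEL
            ),
            **raw,
        )
        return cfg

    def digest(self) -> str:
        payload = {
            k: v
            for k, v in asdict(self).items()
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _write_report(df: pd.DataFrame, path: Path, stamp: list[str]) -> None:
    with path.open("w") as fh:
        for line in stamp:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full workflow and write stage reports under ``outdir``.

    Returns a dict of in-memory results: the cohort, QC report, association
    table, selected SNP ids, score sets and the evaluation tables.  Raises
    at the first failing stage, naming it.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = [f"config_hash: {config.digest()}", f"seed: {config.seed}"]

    if config.simulate is not None:
        from .cohort import simulate_cohort

        cohort = simulate_cohort(config.panel, config.simulate)
    else:
        panel = (
            io.read_panel(config.panel_table) if config.panel_table else None
        )
        cohort = io.read_dosage_table(config.dosage_table, panel=panel)
    io.write_dosage_table(cohort, outdir / "cohort.tsv", stamp)

    qc_report = qc.qc_filter(
        cohort, config.call_rate_min, config.maf_min, config.hwe_alpha
    )
    _write_report(qc_report, outdir / "qc_report.tsv", stamp)
    kept = qc_report.loc[qc_report.kept, "snp_id"].tolist()
    if not kept:
        (outdir / "selected_snps.txt").write_text("# no SNPs selected\n")
        return dict(cohort=cohort, qc=qc_report, selected=[])

    cohort_qc = cohort.select_snps(kept)
    assoc = qc.cohort_assoc(cohort_qc)
    assoc_df = pd.DataFrame([vars(a) for a in assoc])
    _write_report(assoc_df, outdir / "association.tsv", stamp)

    sig = [a for a in assoc if a.p_value < config.p_max]
    if not sig:
        (outdir / "selected_snps.txt").write_text("# no SNPs selected\n")
        return dict(
            cohort=cohort, qc=qc_report, assoc=assoc_df, selected=[]
        )
    sig_ids = [a.snp_id for a in sig]
    r2 = qc.r2_matrix(cohort_qc.select_snps(sig_ids))
    pruned = qc.ld_prune(sig, r2, config.r2_max)
    selected = qc.backward_select(cohort_qc, pruned, config.alpha_remove)
    (outdir / "selected_snps.txt").write_text(
        "".join(f"# {s}\n" for s in stamp)
        + "\n".join(selected)
        + ("\n" if selected else "")
    )
    if not selected:
        return dict(
            cohort=cohort, qc=qc_report, assoc=assoc_df, selected=[]
        )

    score_sets = {
        m: scores.score_cohort(
            cohort_qc, m, selected, include_fmc=config.include_fmc
        )
        for m in config.score_methods
    }
    score_rows = []
    for m, ss in score_sets.items():
        for sid, v in zip(ss.fit_meta["subject_ids"], ss.values):
            score_rows.append(dict(subject_id=sid, method=m, score=v))
    _write_report(
        pd.DataFrame(score_rows), outdir / "scores.tsv", stamp
    )

    complete = cohort_qc.select_snps(selected).complete_cases()
    y = complete.is_case
    eval_rows, pair_rows = [], []
    methods = list(score_sets)
    for m in methods:
        ss = score_sets[m]
        res = evaluate.auc_delong(ss.values, y)
        row = dict(
            model=m,
            auc=res.auc,
            ci_low=res.ci_low,
            ci_high=res.ci_high,
            hl_p=np.nan,
        )
        if m == "PRFLR":
            row["hl_p"] = evaluate.hl_test(ss.values, y, config.hl_groups)[2]
        if config.n_boot and m == "PRFLR":
            boot = evaluate.bootstrap_optimism(
                lambda train, ids=tuple(ss.snp_ids): _prflr_scorer(
                    train, list(ids)
                ),
                complete,
                n_boot=config.n_boot,
                seed=config.seed,
            )
            row["corrected_auc"] = boot["corrected_auc"]
        eval_rows.append(row)
    for i, a in enumerate(methods):
        for b in methods[i + 1 :]:
            diff, z, p = evaluate.delong_test(
                score_sets[a].values, score_sets[b].values, y
            )
            pair_rows.append(
                dict(model_a=a, model_b=b, auc_diff=diff, z=z, p_value=p)
            )
    _write_report(pd.DataFrame(eval_rows), outdir / "evaluation.tsv", stamp)
    _write_report(pd.DataFrame(pair_rows), outdir / "auc_pairs.tsv", stamp)
    return dict(
        cohort=cohort,
        qc=qc_report,
        assoc=assoc_df,
        selected=selected,
        scores=score_sets,
        evaluation=pd.DataFrame(eval_rows),
        auc_pairs=pd.DataFrame(pair_rows),
    )


def _prflr_scorer(train: Cohort, snp_ids: list[str]):
    """Fit PRFLR on ``train``; return a scorer applying it to any cohort."""
    ss = scores.prflr(train, snp_ids)
    coefs = ss.fit_meta["coefficients"]

    def scorer(c: Cohort) -> np.ndarray:
        X = np.column_stack([c.column(s) for s in snp_ids])
        eta = coefs["const"] + X @ np.array(
            [coefs[s] for s in snp_ids]
        )
        return 1.0 / (1.0 + np.exp(-eta))

    return scorer
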