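"""End-to-end screen orchestration.

Stage funnel (mirroring the discovery workflow the package implements):

1. per-cohort DEG screen (fold-change + p gates);
2. direction-consistent intersection across discovery cohorts;
3. optional direction verification against an independent (large) cohort;
4. survival screen — the survival-significant subset of the verified
   intersection becomes the *risk set*;
5. correlation-bin cumulative scoring of the risk set -> core genes;
6. optional qPCR ΔΔCt validation of the risk set;
7. optional relapse-free-survival pass on the qPCR-confirmed genes.

A run is reproducible from its config + seed; the report records every
stage's parameters and outputs and serializes losslessly to JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import (ExpressionDataset, SurvivalRecord, CtRecord,
                       read_expression_table, read_survival_table,
                       read_ct_table)
from .deg import compute_deg, DegScreenResult
from .intersect import intersect_degs, IntersectionResult
from .survival import screen_survival
from .score import pearson_matrix, cumulative_scores, rank_core_genes
from .qpcr import validate_gene_set

logger = logging.getLogger(__name__)


@dataclass
class PipelineReport:
    """Consolidated, JSON-serializable record of one pipeline run."""

    parameters: dict
    status: str = "partial"                     # partial | complete
    stages_run: list[str] = field(default_factory=list)
    deg_counts: dict[str, int] = field(default_factory=dict)
    intersection: dict = field(default_factory=dict)
    verification: list[dict] = field(default_factory=list)
    survival: dict = field(default_factory=dict)
    risk_set: list[str] = field(default_factory=list)
    scores: list[dict] = field(default_factory=list)
    core_genes: list[str] = field(default_factory=list)
    core_tie_expanded: bool = False
    qpcr: list[dict] = field(default_factory=list)
    rfs: dict = field(default_factory=dict)
    version: str = __version__

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "PipelineReport":
        with open(path) as fh:
            return cls(**json.load(fh))


def verify_directions(discovery: IntersectionResult,
                      validation: DegScreenResult) -> list[dict]:
    """Check each intersected gene against an independent validation screen.

    A gene is confirmed when the validation cohort calls it significant in
    the same direction.  Genes absent from the validation universe are
    marked unverifiable, not dropped.
    """
    table = []
    for gene in sorted(discovery.common):
        disc_dir = discovery.direction_of(gene)
        val_dir = validation.direction_of(gene)
        if val_dir is None:
            table.append({"gene": gene, "discovery": disc_dir,
                          "validation": "absent", "confirmed": False,
                          "unverifiable": True})
        else:
            table.append({"gene": gene, "discovery": disc_dir,
                          "validation": val_dir,
                          "confirmed": val_dir == disc_dir,
                          "unverifiable": False})
    return table


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_screen(
    cohorts: list[ExpressionDataset],
    validation: ExpressionDataset | None = None,
    survival_records: list[SurvivalRecord] | None = None,
    rfs_records: list[SurvivalRecord] | None = None,
    ct_records: list[CtRecord] | None = None,
    *,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    p_adjust: str = "none",
    alpha: float = 0.05,
    cutoff: str = "median",
    n_core: int = 4,
    reference_gene: str = "ACTB",
    paired: bool = True,
    correlation_group: str = "tumor",
    seed: int = 0,
) -> PipelineReport:
    """Run the screen on in-memory inputs; see module docstring for stages.

    Stops with a partial report after the last stage whose inputs exist
    (e.g. no survival table -> report ends at the intersection/verification).
    """
    params = dict(fc_threshold=fc_threshold, p_threshold=p_threshold,
                  p_adjust=p_adjust, alpha=alpha, cutoff=cutoff,
                  n_core=n_core, reference_gene=reference_gene,
                  paired=paired, correlation_group=correlation_group,
                  seed=seed,
                  cohorts=[c.dataset_id for c in cohorts],
                  validation=validation.dataset_id if validation else None)
    report = PipelineReport(parameters=params)

    if len(cohorts) < 2:
        raise StageError("deg", ValueError("need at least 2 discovery cohorts"))

    try:
        screens = [compute_deg(c, fc_threshold, p_threshold, p_adjust)
                   for c in cohorts]
    except Exception as e:                                  # noqa: BLE001
        raise StageError("deg", e) from e
    report.deg_counts = {s.dataset_id: s.n_significant for s in screens}
    report.stages_run.append("deg")

    try:
        inter = intersect_degs(screens)
    except Exception as e:                                  # noqa: BLE001
        raise StageError("intersect", e) from e
    report.intersection = {
        "up_common": sorted(inter.up_common),
        "down_common": sorted(inter.down_common),
        "conflicted": sorted(inter.conflicted),
    }
    report.stages_run.append("intersect")

    candidates = inter.common
    if validation is not None:
        try:
            val_screen = compute_deg(validation, fc_threshold, p_threshold,
                                     p_adjust)
            report.verification = verify_directions(inter, val_screen)
        except Exception as e:                              # noqa: BLE001
            raise StageError("verify", e) from e
        candidates = {row["gene"] for row in report.verification
                      if row["confirmed"]}
        report.stages_run.append("verify")

    if survival_records is None or not candidates:
        logger.info("stopping after %s: no survival table or no candidates",
                    report.stages_run[-1])
        return report

    try:
        os_screen = screen_survival(sorted(candidates), survival_records,
                                    endpoint="OS", alpha=alpha, cutoff=cutoff)
    except Exception as e:                                  # noqa: BLE001
        raise StageError("survival", e) from e
    report.survival = {
        s.gene: {"p_value": s.logrank.p_value,
                 "chi_square": s.logrank.chi_square,
                 "cutoff": s.cutoff_value, "significant": s.significant}
        for s in os_screen
    }
    risk_set = sorted(s.gene for s in os_screen if s.significant)
    report.risk_set = risk_set
    report.stages_run.append("survival")

    if len(risk_set) >= 2:
        try:
            pooled = _pool_tumor_samples(cohorts, risk_set)
            corr = pearson_matrix(pooled, risk_set, group=correlation_group)
            table = cumulative_scores(corr)
            core, expanded = rank_core_genes(table,
                                             min(n_core, len(table.genes)))
        except Exception as e:                              # noqa: BLE001
            raise StageError("score", e) from e
        report.scores = table.to_frame().to_dict(orient="records")
        report.core_genes = core
        report.core_tie_expanded = expanded
        report.stages_run.append("score")

    if ct_records is None:
        return report

    try:
        qpcr_results = validate_gene_set(ct_records, risk_set,
                                         reference=reference_gene,
                                         alpha=alpha, paired=paired)
    except Exception as e:                                  # noqa: BLE001
        raise StageError("qpcr", e) from e
    report.qpcr = [
        {"gene": r.gene, "mean_delta_delta_ct": r.mean_delta_delta_ct,
         "mean_fold_change": r.mean_fold_change, "p_value": r.p_value,
         "significant": r.significant, "n_patients": len(r.patients)}
        for r in qpcr_results
    ]
    report.stages_run.append("qpcr")
    confirmed = [row["gene"] for row in report.qpcr if row["significant"]]

    if rfs_records is not None and confirmed:
        try:
            rfs_screen = screen_survival(confirmed, rfs_records,
                                         endpoint="RFS", alpha=alpha,
                                         cutoff=cutoff)
        except Exception as e:                              # noqa: BLE001
            raise StageError("rfs", e) from e
        report.rfs = {
            s.gene: {"p_value": s.logrank.p_value,
                     "significant": s.significant}
            for s in rfs_screen
        }
        report.stages_run.append("rfs")

    report.status = "complete"
    return report


def _pool_tumor_samples(cohorts: list[ExpressionDataset],
                        genes: list[str]) -> ExpressionDataset:
    """Concatenate cohort samples for the correlation stage (GEPIA-like
    large-sample correlation); sample ids are prefixed by cohort."""
    frames, group = [], {}
    for c in cohorts:
        sub = c.submatrix(genes=genes)
        sub = sub.rename(columns={s: f"{c.dataset_id}:{s}" for s in sub.columns})
        frames.append(sub)
        group.update({f"{c.dataset_id}:{s}": g for s, g in c.group.items()})
    return ExpressionDataset(dataset_id="pooled",
                             values=pd.concat(frames, axis=1), group=group)


# ---------------------------------------------------------------------------
# config-driven entry point
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _read_group_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "group"}.issubset(df.columns):
        raise ValueError("group map needs columns: sample, group")
    return dict(zip(df["sample"].astype(str), df["group"].astype(str)))


def _load_cohort(entry: dict) -> ExpressionDataset:
    gm = entry["group_map"]
    group_map = gm if isinstance(gm, dict) else _read_group_map(gm)
    return read_expression_table(
        entry["path"], group_map, dataset_id=entry.get("id"),
        log2_transform=entry.get("log2_transform", False),
        duplicate_rule=entry.get("duplicate_rule", "max-mean"),
    )


def run_pipeline(config: dict | str) -> PipelineReport:
    """File-based wrapper over :func:`run_screen` driven by one YAML config."""
    if not isinstance(config, dict):
        config = load_config(config)

    cohorts = [_load_cohort(e) for e in config["discovery_cohorts"]]
    validation = (_load_cohort(config["validation_cohort"])
                  if config.get("validation_cohort") else None)
    survival_records = (read_survival_table(config["survival_table"])
                        if config.get("survival_table") else None)
    rfs_records = (read_survival_table(config["rfs_table"])
                   if config.get("rfs_table") else None)
    ct_records = (read_ct_table(config["ct_table"],
                                reference_gene=config.get("reference_gene",
                                                          "ACTB"))
                  if config.get("ct_table") else None)

    report = run_screen(
        cohorts, validation, survival_records, rfs_records, ct_records,
        fc_threshold=float(config.get("fc_threshold", 2.0)),
        p_threshold=float(config.get("p_threshold", 0.05)),
        p_adjust=config.get("p_adjust", "none"),
        alpha=float(config.get("alpha", 0.05)),
        cutoff=config.get("cutoff", "median"),
        n_core=int(config.get("n_core", 4)),
        reference_gene=config.get("reference_gene", "ACTB"),
        paired=bool(config.get("paired", True)),
        correlation_group=config.get("correlation_group", "tumor"),
        seed=int(config.get("seed", 0)),
    )
    if config.get("report_path"):
        report.to_json(config["report_path"])
    return report
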