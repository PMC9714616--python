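"""Relative quantification of qPCR Ct values by the 2^−ΔΔCt method.

For each patient: ΔCt = Ct(target) − Ct(reference) within a tissue, and
ΔΔCt = ΔCt(tumor) − ΔCt(adjacent); the fold change is 2^−ΔΔCt, so ΔΔCt > 0
means the target is down in tumor relative to the adjacent tissue.
Significance is a two-sided Student's t-test on the per-patient ΔCt values
(paired by default — the tissues come from the same patient).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datasets import CtRecord

logger = logging.getLogger(__name__)


@dataclass
class RelativeExpression:
    """Per-gene ΔΔCt summary over patients with complete paired blocks."""

    gene: str
    reference: str
    patients: list[str]
    delta_ct_tumor: np.ndarray = field(repr=False)
    delta_ct_adjacent: np.ndarray = field(repr=False)
    p_value: float | None = None
    alpha: float = 0.05

    @property
    def delta_delta_ct(self) -> np.ndarray:
        return self.delta_ct_tumor - self.delta_ct_adjacent

    @property
    def fold_change(self) -> np.ndarray:
        """Per-patient relative expression 2^−ΔΔCt."""
        return fold_change(self.delta_delta_ct)

    @property
    def mean_fold_change(self) -> float:
        return float(np.mean(self.fold_change))

    @property
    def mean_delta_delta_ct(self) -> float:
        return float(np.mean(self.delta_delta_ct))

    @property
    def se_fold_change(self) -> float:
        fc = self.fold_change
        return float(np.std(fc, ddof=1) / np.sqrt(fc.size))

    @property
    def significant(self) -> bool:
        if self.p_value is None:
            raise ValueError("run test_relative_expression first")
        return self.p_value < self.alpha


def fold_change(delta_delta_ct):
    """Relative expression 2^−ΔΔCt; 1 iff ΔΔCt = 0."""
    return np.exp2(-np.asarray(delta_delta_ct, dtype=float))


def delta_delta_ct(records: list[CtRecord], target: str,
                   reference: str) -> RelativeExpression:
    """Per-patient ΔΔCt of ``target`` against ``reference``.

    Patients lacking target or reference Ct in either tissue are excluded
    with a logged count.  Multiple Ct entries for one (patient, tissue, gene)
    are averaged (technical replicates).
    """
    if target == reference:
        raise ValueError("target and reference gene must differ")
    ct: dict[tuple[str, str, str], list[float]] = {}
    patients: list[str] = []
    for r in records:
        if r.gene not in (target, reference):
            continue
        ct.setdefault((r.patient_id, r.tissue, r.gene), []).append(r.ct)
        if r.patient_id not in patients:
            patients.append(r.patient_id)

    if not any(g == reference for (_, _, g) in ct):
        raise ValueError(f"reference gene {reference!r} absent from Ct table")

    def mean_ct(pid, tissue, gene):
        vals = ct.get((pid, tissue, gene))
        return float(np.mean(vals)) if vals else None

    complete, d_tumor, d_adj = [], [], []
    for pid in patients:
        block = [mean_ct(pid, tissue, gene)
                 for tissue in ("tumor", "adjacent")
                 for gene in (target, reference)]
        if any(v is None for v in block):
            continue
        tt, tr, at, ar = block
        complete.append(pid)
        d_tumor.append(tt - tr)
        d_adj.append(at - ar)

    n_dropped = len(patients) - len(complete)
    if n_dropped:
        logger.warning("%s: excluded %d patient(s) with incomplete "
                       "tumor/adjacent Ct blocks", target, n_dropped)
    if not complete:
        raise ValueError(f"no patient has complete Ct data for {target!r}")
    return RelativeExpression(gene=target, reference=reference,
                              patients=complete,
                              delta_ct_tumor=np.array(d_tumor),
                              delta_ct_adjacent=np.array(d_adj))


def test_relative_expression(expr: RelativeExpression, alpha: float = 0.05,
                             paired: bool = True) -> RelativeExpression:
    """Two-sided Student's t-test of tumor vs adjacent ΔCt.

    Paired by default (per-patient differences); the p-value and alpha are
    stored on the returned object.  All-zero differences give p = 1.
    """
    if len(expr.patients) < 2:
        raise ValueError("need at least 2 patients with complete data")
    if paired:
        diff = expr.delta_delta_ct
        if np.all(diff == 0.0):
            p = 1.0
        else:
            n = diff.size
            se = np.std(diff, ddof=1) / np.sqrt(n)
            if se == 0.0:
                p = float(np.finfo(float).tiny)
            else:
                t = np.mean(diff) / se
                p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    else:
        res = stats.ttest_ind(expr.delta_ct_tumor, expr.delta_ct_adjacent)
        p = float(res.pvalue)
    expr.p_value = max(min(p, 1.0), float(np.finfo(float).tiny))
    expr.alpha = alpha
    return expr


def validate_gene_set(records: list[CtRecord], genes: list[str],
                      reference: str = "ACTB", alpha: float = 0.05,
                      paired: bool = True) -> list[RelativeExpression]:
    """ΔΔCt + significance test for each gene in the risk set."""
    return [
        test_relative_expression(
            delta_delta_ct(records, g, reference), alpha=alpha, paired=paired)
        for g in genes
    ]
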