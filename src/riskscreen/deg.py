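"""Per-cohort differential expression with fold-change and p-value gates.

log2FC is the difference of group means of log2 expression (tumor − normal);
the test is an unmoderated Welch t on the log2 values, two-sided, with raw
p-values by default (Benjamini–Hochberg adjustment available via
``p_adjust="BH"``).  A gene is called up if log2FC > fc_threshold and
p < p_threshold, down if log2FC < −fc_threshold and p < p_threshold —
strict inequalities, so a gene sitting exactly on a threshold is not called.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datasets import ExpressionDataset

logger = logging.getLogger(__name__)

TINY_P = float(np.finfo(float).tiny)


def _welch_arrays(mean_a, var_a, n_a, mean_b, var_b, n_b):
    """Vectorized Welch t statistic and two-sided p with Welch–Satterthwaite
    degrees of freedom.  ``var`` are ddof=1 sample variances.

    Degenerate rule: zero variance in both groups -> p = 1 if the means are
    equal, else the smallest positive probability (logged).
    """
    mean_a, var_a = np.asarray(mean_a, float), np.asarray(var_a, float)
    mean_b, var_b = np.asarray(mean_b, float), np.asarray(var_b, float)
    se2_a, se2_b = var_a / n_a, var_b / n_b
    denom2 = se2_a + se2_b
    diff = mean_a - mean_b
    degenerate = denom2 == 0.0

    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(denom2)
        df = denom2 ** 2 / (se2_a ** 2 / (n_a - 1) + se2_b ** 2 / (n_b - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.minimum(p, 1.0)
    p = np.where(p == 0.0, TINY_P, p)

    if np.any(degenerate):
        equal = degenerate & (diff == 0.0)
        unequal = degenerate & (diff != 0.0)
        t = np.where(equal, 0.0, t)
        p = np.where(equal, 1.0, p)
        if np.any(unequal):
            logger.warning(
                "%d zero-variance comparison(s) with unequal means: "
                "p underflows, reported as smallest positive probability",
                int(np.sum(unequal)))
            p = np.where(unequal, TINY_P, p)
            t = np.where(unequal, np.sign(diff) * np.inf, t)
    return t, p


def welch_t_pvalue(a, b) -> float:
    """Two-sided p from the unequal-variance two-sample t test."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in input")
    _, p = _welch_arrays(a.mean(), a.var(ddof=1), a.size,
                         b.mean(), b.var(ddof=1), b.size)
    return float(p)


def classify_direction(log2fc: float, p: float,
                       fc_threshold: float, p_threshold: float) -> str:
    """``up`` / ``down`` / ``not_significant`` under strict gates."""
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if p < p_threshold:
        if log2fc > fc_threshold:
            return "up"
        if log2fc < -fc_threshold:
            return "down"
    return "not_significant"


@dataclass
class DegRecord:
    gene: str
    log2fc: float
    p_value: float
    direction: str


@dataclass
class DegScreenResult:
    """One cohort's screen: per-gene log2FC, p, direction under the gates."""

    dataset_id: str
    fc_threshold: float
    p_threshold: float
    records: list[DegRecord] = field(repr=False)

    @property
    def n_significant(self) -> int:
        return sum(r.direction != "not_significant" for r in self.records)

    def genes_with_direction(self, direction: str) -> set[str]:
        return {r.gene for r in self.records if r.direction == direction}

    @property
    def up_genes(self) -> set[str]:
        return self.genes_with_direction("up")

    @property
    def down_genes(self) -> set[str]:
        return self.genes_with_direction("down")

    def direction_of(self, gene: str) -> str | None:
        for r in self.records:
            if r.gene == gene:
                return r.direction
        return None

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(
            [{"gene": r.gene, "log2fc": r.log2fc, "p_value": r.p_value,
              "direction": r.direction} for r in self.records]
        )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def compute_deg(dataset: ExpressionDataset, fc_threshold: float = 2.0,
                p_threshold: float = 0.05,
                p_adjust: str = "none") -> DegScreenResult:
    """Screen one cohort: Welch t per gene, gates applied, sorted by |log2FC|.

    Requires at least 2 samples per group.  ``p_adjust="BH"`` applies
    Benjamini–Hochberg before gating.
    """
    tumor = dataset.submatrix(group="tumor").to_numpy()
    normal = dataset.submatrix(group="normal").to_numpy()
    if tumor.shape[1] < 2 or normal.shape[1] < 2:
        raise ValueError(
            f"{dataset.dataset_id}: each group needs at least 2 samples "
            f"(got {tumor.shape[1]} tumor, {normal.shape[1]} normal)"
        )
    log2fc = tumor.mean(axis=1) - normal.mean(axis=1)
    _, p = _welch_arrays(tumor.mean(axis=1), tumor.var(axis=1, ddof=1),
                         tumor.shape[1],
                         normal.mean(axis=1), normal.var(axis=1, ddof=1),
                         normal.shape[1])
    if p_adjust == "BH":
        p = _bh_adjust(p)
    elif p_adjust != "none":
        raise ValueError(f"p_adjust must be 'none' or 'BH', got {p_adjust!r}")

    records = [
        DegRecord(gene=g, log2fc=float(fc), p_value=float(pv),
                  direction=classify_direction(fc, pv, fc_threshold,
                                               p_threshold))
        for g, fc, pv in zip(dataset.genes, log2fc, p)
    ]
    records.sort(key=lambda r: -abs(r.log2fc))
    return DegScreenResult(dataset_id=dataset.dataset_id,
                           fc_threshold=fc_threshold,
                           p_threshold=p_threshold, records=records)
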