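"""Core-risk-gene scoring: binned pairwise Pearson correlations, summed.

Each gene pair in the risk set gets an integer score from the absolute
Pearson correlation of their expression across samples:

    |r| < 0.4            -> 0   (very weak)
    0.4 <= |r| < 0.6     -> 1   (weak)
    0.6 <= |r| < 0.8     -> 2   (strong)
    0.8 <= |r| <= 1      -> 3   (very strong)

Bins are left-closed, right-open (last bin closed) so boundary values are
deterministic.  A gene's cumulative score is the sum of its pair scores
against every other gene in the set; the genes with the highest cumulative
scores are the core risk genes.  Correlations are computed on tumor samples
by default — the disease context the score describes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset

logger = logging.getLogger(__name__)

BIN_EDGES = (0.4, 0.6, 0.8)


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson matrix over an ordered gene list."""

    genes: list[str]
    r: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.genes)
        if self.r.shape != (n, n):
            raise ValueError("matrix shape does not match gene list")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix not symmetric")
        if not np.allclose(np.diag(self.r), 1.0):
            raise ValueError("correlation diagonal must be 1")
        if np.any(np.abs(self.r) > 1.0 + 1e-12):
            raise ValueError("correlations outside [-1, 1]")


@dataclass
class ScoreTable:
    """Pairwise bin scores, per-gene cumulative scores, and dense ranks."""

    genes: list[str]
    pair_scores: np.ndarray = field(repr=False)
    cumulative: dict[str, int] = field(default_factory=dict)
    rank: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "gene": self.genes,
            "cumulative_score": [self.cumulative[g] for g in self.genes],
            "rank": [self.rank[g] for g in self.genes],
        })
        return df.sort_values(["rank", "gene"]).reset_index(drop=True)


def pearson_matrix(dataset: ExpressionDataset, genes: list[str],
                   group: str = "tumor") -> CorrelationMatrix:
    """Sample Pearson coefficients between the given genes over a group.

    Zero-variance genes cannot be correlated; they are excluded with a
    logged warning (scoring then proceeds on the remainder).
    """
    sub = dataset.submatrix(genes=genes, group=group)
    if sub.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    arr = sub.to_numpy()
    sd = arr.std(axis=1)
    flagged = [g for g, s in zip(genes, sd) if s == 0.0]
    if flagged:
        logger.warning("excluding %d zero-variance gene(s) from "
                       "correlation: %s", len(flagged), flagged[:5])
        keep = [g for g in genes if g not in set(flagged)]
        if len(keep) < 2:
            raise ValueError("fewer than 2 genes with variance")
        arr = sub.loc[keep].to_numpy()
        genes = keep
    r = np.corrcoef(arr)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return CorrelationMatrix(genes=list(genes), r=r)


def bin_correlation(r: float) -> int:
    """Map a Pearson coefficient to its integer bin score via |r|."""
    a = abs(r)
    if a > 1.0:
        raise ValueError(f"|r| must be <= 1, got {r}")
    # left-closed bins: 0.4 -> 1, 0.6 -> 2, 0.8 -> 3
    return int(np.searchsorted(BIN_EDGES, a, side="right"))


def cumulative_scores(matrix: CorrelationMatrix) -> ScoreTable:
    """Bin every off-diagonal pair and sum per gene; dense-rank descending."""
    n = len(matrix.genes)
    if n < 2:
        raise ValueError("need at least 2 genes to score")
    pair = np.searchsorted(BIN_EDGES, np.abs(matrix.r), side="right")
    np.fill_diagonal(pair, 0)
    totals = pair.sum(axis=1)

    cumulative = {g: int(t) for g, t in zip(matrix.genes, totals)}
    distinct = sorted(set(totals), reverse=True)
    score_rank = {s: i + 1 for i, s in enumerate(distinct)}
    rank = {g: score_rank[t] for g, t in zip(matrix.genes, totals)}
    return ScoreTable(genes=list(matrix.genes), pair_scores=pair,
                      cumulative=cumulative, rank=rank)


def rank_core_genes(table: ScoreTable, k: int) -> tuple[list[str], bool]:
    """Genes occupying the top-k dense ranks, alphabetical within a rank.

    Ties can expand the list beyond k; the returned flag says whether they
    did.
    """
    n = len(table.genes)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    ordered = sorted(table.genes, key=lambda g: (table.rank[g], g))
    top = [g for g in ordered if table.rank[g] <= table.rank[ordered[k - 1]]]
    return top, len(top) > k
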