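"""Core data containers and tabular I/O.

Three table kinds flow through the pipeline:

* expression matrices — genes (rows) x samples (columns), log2 scale,
  tab-separated, first column gene symbol, plus a companion sample->group map
  (``tumor`` / ``normal``);
* survival tables — one row per patient: ``patient_id``, ``time`` (months),
  ``event`` (0 censored / 1 event), then one column of log2 expression per gene;
* Ct tables — long format: ``patient_id``, ``tissue`` (``tumor`` /
  ``adjacent``), ``gene``, ``ct``.

GEO series-matrix files are accepted for expression input: comment/metadata
lines starting with ``!`` are skipped.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("tumor", "normal")
TISSUES = ("tumor", "adjacent")


class ValidationError(ValueError):
    """Raised when an input table violates a contract of the pipeline."""


@dataclass
class ExpressionDataset:
    """One cohort's log2 expression matrix with tumor/normal labels.

    Parameters
    ----------
    dataset_id : str
        Cohort label (e.g. a GEO accession).
    values : pandas.DataFrame
        Genes x samples matrix of finite log2-scale expression values.
        Row index = gene symbols, columns = sample ids, both unique.
    group : dict
        Maps every sample id to ``"tumor"`` or ``"normal"``.
    """

    dataset_id: str
    values: pd.DataFrame
    group: dict[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if v.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")
        missing = [s for s in v.columns if s not in self.group]
        if missing:
            raise ValidationError(
                f"samples without a group label: {missing[:5]}"
            )
        bad = {s: g for s, g in self.group.items()
               if s in v.columns and g not in GROUPS}
        if bad:
            raise ValidationError(f"group labels must be tumor/normal, got {bad}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("non-numeric expression values")
        if not np.all(np.isfinite(arr)):
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite expression at gene {v.index[r]!r}, "
                f"sample {v.columns[c]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        if group == "all":
            return self.samples
        if group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS} or 'all'")
        return [s for s in self.samples if self.group[s] == group]

    def submatrix(self, genes=None, group: str = "all") -> pd.DataFrame:
        """Genes x samples view restricted to ``genes`` and a sample group."""
        cols = self.samples_in_group(group)
        out = self.values.loc[:, cols]
        if genes is not None:
            missing = [g for g in genes if g not in out.index]
            if missing:
                raise KeyError(f"genes absent from {self.dataset_id}: {missing[:5]}")
            out = out.loc[list(genes)]
        return out


@dataclass
class SurvivalRecord:
    """One patient's follow-up: time in months, event indicator, expression."""

    patient_id: str
    time: float
    event: int
    expression: dict[str, float] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time <= 0:
            raise ValidationError(
                f"patient {self.patient_id}: time must be > 0, got {self.time}"
            )
        if self.event not in (0, 1):
            raise ValidationError(
                f"patient {self.patient_id}: event must be 0 or 1, got {self.event}"
            )


@dataclass
class CtRecord:
    """One qPCR measurement: mean cycle threshold for (patient, tissue, gene)."""

    patient_id: str
    tissue: str
    gene: str
    ct: float

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValidationError(
                f"tissue must be one of {TISSUES}, got {self.tissue!r}"
            )
        if not np.isfinite(self.ct) or self.ct <= 0:
            raise ValidationError(
                f"ct must be finite and > 0, got {self.ct} "
                f"({self.patient_id}/{self.tissue}/{self.gene})"
            )


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _strip_series_matrix_comments(source) -> io.StringIO:
    """Drop GEO series-matrix metadata lines (prefixed '!')."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "rt", encoding="utf-8") as fh:
            text = fh.read()
    kept = [ln for ln in text.splitlines() if not ln.startswith("!")]
    return io.StringIO("\n".join(kept))


def read_expression_table(
    source,
    group_map: dict[str, str],
    dataset_id: str | None = None,
    *,
    sep: str = "\t",
    log2_transform: bool = False,
    duplicate_rule: str = "max-mean",
) -> ExpressionDataset:
    """Read a genes x samples expression table.

    First column holds gene symbols; the header row holds sample ids.
    ``group_map`` must label every sample ``tumor`` or ``normal``.

    ``log2_transform=True`` applies log2(x+1) for linear-scale input (the
    pipeline otherwise assumes values are already log2, as in processed GEO
    series matrices).  Duplicate gene symbols are collapsed by
    ``duplicate_rule``: ``"max-mean"`` keeps the row with the highest mean
    (common microarray convention), ``"mean"`` averages the rows.  Genes with
    any missing value are excluded (logged).
    """
    if dataset_id is None:
        dataset_id = os.path.basename(str(source)) if not hasattr(source, "read") else "dataset"
    buf = _strip_series_matrix_comments(source)
    df = pd.read_csv(buf, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    missing_group = [s for s in df.columns if s not in group_map]
    if missing_group:
        raise ValidationError(
            f"{dataset_id}: samples absent from group map: {missing_group[:5]}"
        )

    # non-numeric cells -> hard error naming row/column
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                gene = df.index[bad.to_numpy().nonzero()[0][0]]
                raise ValidationError(
                    f"{dataset_id}: non-numeric value at gene {gene!r}, "
                    f"sample {col!r}"
                )
            df[col] = coerced

    n_na = int(df.isna().any(axis=1).sum())
    if n_na:
        logger.warning("%s: excluding %d gene(s) with missing values",
                       dataset_id, n_na)
        df = df.dropna(axis=0)

    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        if duplicate_rule == "max-mean":
            means = df.mean(axis=1)
            # stable: keep the first occurrence of the max-mean row per symbol
            order = np.arange(len(df))
            pick = (
                pd.DataFrame({"mean": means.to_numpy(), "order": order},
                             index=df.index)
                .groupby(level=0, sort=False)
                .apply(lambda g: g["order"].iloc[int(np.argmax(g["mean"].to_numpy()))])
            )
            df = df.iloc[np.sort(pick.to_numpy())]
        elif duplicate_rule == "mean":
            df = df.groupby(level=0, sort=False).mean()
        else:
            raise ValueError(f"unknown duplicate_rule {duplicate_rule!r}")
        logger.info("%s: collapsed %d duplicate gene row(s) by %s",
                    dataset_id, n_dup, duplicate_rule)

    if log2_transform:
        if (df.to_numpy() < 0).any():
            raise ValidationError(
                f"{dataset_id}: negative values under log2_transform"
            )
        df = np.log2(df + 1.0)

    return ExpressionDataset(
        dataset_id=dataset_id,
        values=df,
        group={s: group_map[s] for s in df.columns},
    )


def write_expression_table(dataset: ExpressionDataset, path, *, sep: str = "\t") -> None:
    """Write the matrix back out; round-trips clean input bit-identically."""
    dataset.values.to_csv(path, sep=sep, index_label="gene")


# ---------------------------------------------------------------------------
# survival tables
# ---------------------------------------------------------------------------

def read_survival_table(source, *, sep: str = "\t") -> list[SurvivalRecord]:
    """Read a survival table: patient_id, time, event, one column per gene.

    Rows with missing time or event are dropped with a logged count;
    a negative time is a hard error.
    """
    df = pd.read_csv(source, sep=sep)
    required = {"patient_id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"survival table must have columns {sorted(required)}, "
            f"got {list(df.columns)[:6]}"
        )
    gene_cols = [c for c in df.columns if c not in required]

    neg = pd.to_numeric(df["time"], errors="coerce") < 0
    if neg.any():
        raise ValidationError(
            f"negative follow-up time for patient "
            f"{df.loc[neg, 'patient_id'].iloc[0]!r}"
        )

    incomplete = df["time"].isna() | df["event"].isna()
    if incomplete.any():
        logger.warning("survival table: dropped %d row(s) with missing "
                       "time/event", int(incomplete.sum()))
        df = df.loc[~incomplete]

    records = []
    for _, row in df.iterrows():
        records.append(SurvivalRecord(
            patient_id=str(row["patient_id"]),
            time=float(row["time"]),
            event=int(row["event"]),
            expression={g: float(row[g]) for g in gene_cols},
        ))
    return records


def write_survival_table(records: list[SurvivalRecord], path, *, sep: str = "\t") -> None:
    genes = sorted({g for r in records for g in r.expression})
    rows = [
        {"patient_id": r.patient_id, "time": r.time, "event": r.event,
         **{g: r.expression.get(g, np.nan) for g in genes}}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------

def read_ct_table(source, *, sep: str = "\t",
                  reference_gene: str | None = None) -> list[CtRecord]:
    """Read a long-format qPCR table: patient_id, tissue, gene, ct.

    If ``reference_gene`` is given, (patient, tissue) blocks lacking it are
    flagged with a warning here; the hard error is raised at ΔΔCt time.
    """
    df = pd.read_csv(source, sep=sep)
    required = ["patient_id", "tissue", "gene", "ct"]
    if not set(required).issubset(df.columns):
        raise ValidationError(
            f"Ct table must have columns {required}, got {list(df.columns)}"
        )
    ct_num = pd.to_numeric(df["ct"], errors="coerce")
    bad = ct_num.isna() & df["ct"].notna()
    if bad.any():
        i = bad.to_numpy().nonzero()[0][0]
        raise ValidationError(
            f"non-numeric ct value {df['ct'].iloc[i]!r} "
            f"({df['patient_id'].iloc[i]}/{df['gene'].iloc[i]})"
        )

    records = [
        CtRecord(patient_id=str(r.patient_id), tissue=str(r.tissue),
                 gene=str(r.gene), ct=float(ct))
        for r, ct in zip(df.itertuples(index=False), ct_num)
    ]

    if reference_gene is not None:
        have_ref = {(r.patient_id, r.tissue) for r in records
                    if r.gene == reference_gene}
        blocks = {(r.patient_id, r.tissue) for r in records}
        lacking = sorted(blocks - have_ref)
        if lacking:
            logger.warning(
                "Ct table: %d (patient, tissue) block(s) lack reference "
                "gene %r: %s", len(lacking), reference_gene, lacking[:5])
    return records


def write_ct_table(records: list[CtRecord], path, *, sep: str = "\t") -> None:
    pd.DataFrame(
        [{"patient_id": r.patient_id, "tissue": r.tissue,
          "gene": r.gene, "ct": r.ct} for r in records]
    ).to_csv(path, sep=sep, index=False)
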