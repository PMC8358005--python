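"""Differential-expression table intake, overlaps, and fold-change correlation.

DE fitting itself is out of scope; tables arrive as TSV with columns
``gene_id``, ``log2FC``, ``pvalue`` and a nominal significance threshold
(default p < 0.05).  Direction is derived from the sign of the fold
change; an exact zero is assigned "up" by convention and logged, and such
genes are excluded from direction-stratified enrichments downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from recipase.errors import UserInputError

logger = logging.getLogger(__name__)

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"


@dataclass
class DeTable:
    """One DE contrast: per-gene log2 fold change and p-value."""

    contrast_label: str
    records: pd.DataFrame = field(repr=False)
    significance_threshold: float = 0.05

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, contrast_label: str, significance_threshold: float = 0.05
    ) -> "DeTable":
        required = {"gene_id", "log2_fold_change", "p_value"}
        missing = required - set(frame.columns)
        if missing:
            raise UserInputError(f"DE table missing columns: {sorted(missing)}")
        df = frame[["gene_id", "log2_fold_change", "p_value"]].copy()
        dup = df["gene_id"][df["gene_id"].duplicated()]
        if len(dup):
            raise UserInputError(
                f"duplicate gene ids in DE table '{contrast_label}': {sorted(set(dup))[:5]}"
            )
        p = df["p_value"].to_numpy(dtype=float)
        if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
            raise UserInputError(f"p-values outside (0, 1] in DE table '{contrast_label}'")
        n_zero = int((df["log2_fold_change"] == 0).sum())
        if n_zero:
            logger.info(
                "DE table %s: %d genes with log2FC == 0 assigned direction 'up'",
                contrast_label, n_zero,
            )
        df["direction"] = np.where(
            df["log2_fold_change"].to_numpy(dtype=float) >= 0, DIRECTION_UP, DIRECTION_DOWN
        )
        df = df.reset_index(drop=True)
        return cls(contrast_label, df, significance_threshold)

    @property
    def significant_genes(self) -> set:
        mask = self.records["p_value"] < self.significance_threshold
        return set(self.records.loc[mask, "gene_id"])

    def significant_by_direction(self, direction: str, exclude_zero_fc: bool = True) -> set:
        mask = (self.records["p_value"] < self.significance_threshold) & (
            self.records["direction"] == direction
        )
        if exclude_zero_fc:
            mask &= self.records["log2_fold_change"] != 0
        return set(self.records.loc[mask, "gene_id"])

    def to_tsv(self, path) -> None:
        out = self.records.rename(
            columns={"log2_fold_change": "log2FC", "p_value": "pvalue"}
        )
        out[["gene_id", "log2FC", "pvalue"]].to_csv(path, sep="\t", index=False)


def read_de_table(tsv_path, contrast_label: str, significance_threshold: float = 0.05) -> DeTable:
    """Load a DE TSV (gene_id, log2FC, pvalue); duplicate ids are an error."""
    path = Path(tsv_path)
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2FC", "pvalue"}
    missing = required - set(df.columns)
    if missing:
        raise UserInputError(f"{path}: missing DE columns {sorted(missing)}")
    for col in ("log2FC", "pvalue"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise UserInputError(f"{path}: non-numeric values in column {col}")
    df = df.rename(columns={"log2FC": "log2_fold_change", "pvalue": "p_value"})
    return DeTable.from_frame(df, contrast_label, significance_threshold)


def overlapping_de_genes(table_x: DeTable, table_y: DeTable) -> list:
    """Gene ids significant (under each table's own threshold) in both."""
    return sorted(table_x.significant_genes & table_y.significant_genes)


def correlate_fold_changes(
    table_x: DeTable,
    table_y: DeTable,
    genes=None,
    exclude_ids=(),
):
    """Pearson correlation of log2 fold changes over shared genes.

    Parameters
    ----------
    genes
        Optional id set restricting the correlation; defaults to all genes
        present in both tables.
    exclude_ids
        Explicit outlier ids removed before computing (never automatic).

    Returns
    -------
    (pearson_r, p_value, n_used) with p from the t-distribution transform.
    """
    merged = table_x.records.merge(
        table_y.records, on="gene_id", suffixes=("_x", "_y")
    )
    if genes is not None:
        merged = merged[merged["gene_id"].isin(set(genes))]
    if exclude_ids:
        merged = merged[~merged["gene_id"].isin(set(exclude_ids))]
    n = len(merged)
    if n < 3:
        raise UserInputError(f"correlation needs >= 3 genes after exclusions, got {n}")
    r, p = stats.pearsonr(
        merged["log2_fold_change_x"].to_numpy(), merged["log2_fold_change_y"].to_numpy()
    )
    return float(r), float(p), n


def overlap_counts(tables) -> dict:
    """Exact counts of every non-empty membership pattern of significant genes.

    Returns a dict mapping a sorted tuple of contrast labels to the number
    of genes significant in exactly those tables (upset-style exclusive
    patterns); values sum to the size of the union.
    """
    tables = list(tables)
    if len(tables) < 2:
        raise UserInputError("overlap_counts requires at least two tables")
    labels = [t.contrast_label for t in tables]
    if len(set(labels)) != len(labels):
        raise UserInputError("contrast labels must be unique")
    sig = {t.contrast_label: t.significant_genes for t in tables}
    union = set().union(*sig.values())
    counts: dict = {}
    for gene in union:
        pattern = tuple(sorted(lab for lab in labels if gene in sig[lab]))
        counts[pattern] = counts.get(pattern, 0) + 1
    return dict(sorted(counts.items()))
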