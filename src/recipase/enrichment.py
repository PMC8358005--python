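"""Fisher-exact gene-set enrichment and the AIE x DE crosswalk battery.

All tests are laid out as 2x2 tables against an explicit expressed-gene
universe (never silently the whole annotation):

===========  ============  ================
             in annotation  not in annotation
in query          a               b
not in query      c               d
===========  ============  ================

Fold enrichment is the in-query proportion over the background proportion;
reported values round half away from zero to one decimal (reporting only —
stored values are unrounded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from recipase.aie_core import CAT_DECREASING, CAT_INCREASING, bh_fdr
from recipase.de_integration import DIRECTION_DOWN, DIRECTION_UP
from recipase.errors import UserInputError

ENRICHMENT_COLUMNS = [
    "query_name",
    "set_name",
    "a",
    "b",
    "c",
    "d",
    "odds_ratio",
    "fold_enrichment",
    "p_value",
    "q_fdr",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    gene_ids: frozenset = field(default_factory=frozenset)
    description: str = ""

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", frozenset(self.gene_ids))

    def __len__(self):
        return len(self.gene_ids)


def read_gene_sets(path) -> list:
    """Read 2-column TSV (set_name, gene_id) into a list of GeneSet."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"set_name", "gene_id"} <= set(df.columns):
        raise UserInputError(f"{path}: gene-set TSV needs columns set_name, gene_id")
    return [
        GeneSet(name, frozenset(sub["gene_id"]))
        for name, sub in df.groupby("set_name", sort=True)
    ]


def read_universe(path) -> GeneSet:
    """Universe file: either one gene id per line or a TSV with a gene_id column."""
    path = Path(path)
    first = path.read_text().splitlines()
    if first and "\t" in first[0] or (first and first[0] == "gene_id"):
        df = pd.read_csv(path, sep="\t", dtype=str)
        if "gene_id" not in df.columns:
            raise UserInputError(f"{path}: universe TSV needs a gene_id column")
        ids = df["gene_id"]
    else:
        ids = [line.strip() for line in first if line.strip()]
    return GeneSet("universe", frozenset(ids))


def round_reported(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention used in reports)."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def fold_enrichment(overlap: int, query_size: int, background_proportion: float) -> float:
    """(overlap/query_size) / background_proportion, unrounded."""
    if query_size < 1:
        raise UserInputError("query_size must be >= 1")
    if overlap > query_size:
        raise UserInputError("overlap cannot exceed query_size")
    if background_proportion <= 0:
        raise UserInputError("background_proportion must be > 0")
    return (overlap / query_size) / background_proportion


def _fisher_table(query_ids, annotation_ids, universe_ids):
    q = set(query_ids) & universe_ids
    ann = set(annotation_ids) & universe_ids
    a = len(q & ann)
    b = len(q - ann)
    c = len(ann - q)
    d = len(universe_ids) - a - b - c
    return a, b, c, d


def _fisher_row(query_name, set_name, a, b, c, d, alternative="two-sided"):
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    n = a + b + c + d
    if a + b > 0 and a + c > 0 and n > 0:
        fold = (a / (a + b)) / ((a + c) / n)
    elif a == 0:
        fold = 0.0
    else:
        fold = float("nan")
    return {
        "query_name": query_name,
        "set_name": set_name,
        "a": a, "b": b, "c": c, "d": d,
        "odds_ratio": float(odds) if np.isfinite(odds) else float("inf"),
        "fold_enrichment": fold,
        "p_value": max(float(p), np.finfo(float).tiny),
    }


def fisher_enrichment(
    query: GeneSet, annotation: GeneSet, universe: GeneSet, alternative="two-sided"
) -> pd.DataFrame:
    """Two-sided Fisher exact test of annotation membership within a query.

    Genes outside the universe are discarded before tabulation.  Returns a
    single-row frame with the 2x2 counts, odds ratio, fold enrichment and
    p-value (``q_fdr`` equals p for a lone test).
    """
    if not universe.gene_ids:
        raise UserInputError("universe is empty")
    if not set(query.gene_ids) & universe.gene_ids:
        raise UserInputError("query is empty after intersecting with universe")
    a, b, c, d = _fisher_table(query.gene_ids, annotation.gene_ids, universe.gene_ids)
    row = _fisher_row(query.name, annotation.name, a, b, c, d, alternative)
    row["q_fdr"] = row["p_value"]
    return pd.DataFrame([row], columns=ENRICHMENT_COLUMNS)


def gene_set_battery(query_sets, annotation_sets, universe: GeneSet, alternative="two-sided") -> pd.DataFrame:
    """Full cross of query x annotation Fisher tests, BH across the battery.

    Rows are ordered (query_name, set_name); BH is computed over all cells
    and is invariant to row order.
    """
    if not universe.gene_ids:
        raise UserInputError("universe is empty")
    rows = []
    for query in query_sets:
        for ann in annotation_sets:
            a, b, c, d = _fisher_table(query.gene_ids, ann.gene_ids, universe.gene_ids)
            rows.append(_fisher_row(query.name, ann.name, a, b, c, d, alternative))
    df = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-1])
    df = df.sort_values(["query_name", "set_name"], kind="mergesort").reset_index(drop=True)
    df["q_fdr"] = bh_fdr(df["p_value"].to_numpy()) if len(df) else []
    return df[ENRICHMENT_COLUMNS]


def crosswalk_aie_de_enrichment(
    gene_aie: pd.DataFrame,
    de_tables,
    universe: GeneSet,
    alternative="two-sided",
) -> pd.DataFrame:
    """AIE-category x DE-direction enrichment battery.

    For each tissue in ``gene_aie`` and each DE contrast, tests every
    {increasing, decreasing} AIE gene category against {up, down}
    regulated significant DE genes with Fisher's exact test over the
    expressed-gene universe; BH across all cells.  Empty queries yield
    p = 1 rows (a = 0) rather than errors.
    """
    if not universe.gene_ids:
        raise UserInputError("universe is empty")
    rows = []
    tissues = sorted(gene_aie["tissue"].unique()) if len(gene_aie) else []
    for tissue in tissues:
        sub = gene_aie[gene_aie["tissue"] == tissue]
        for category in (CAT_INCREASING, CAT_DECREASING):
            aie_genes = set(sub.loc[sub["category"] == category, "gene_id"])
            for table in de_tables:
                for direction in (DIRECTION_UP, DIRECTION_DOWN):
                    de_genes = table.significant_by_direction(direction)
                    a, b, c, d = _fisher_table(aie_genes, de_genes, universe.gene_ids)
                    query_name = f"{tissue}:{category}"
                    set_name = f"{table.contrast_label}:{direction}"
                    if a + b == 0:
                        rows.append(
                            {
                                "query_name": query_name, "set_name": set_name,
                                "a": 0, "b": 0, "c": c, "d": d,
                                "odds_ratio": float("nan"),
                                "fold_enrichment": 0.0,
                                "p_value": 1.0,
                            }
                        )
                    else:
                        rows.append(
                            _fisher_row(query_name, set_name, a, b, c, d, alternative)
                        )
    df = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-1])
    df = df.sort_values(["query_name", "set_name"], kind="mergesort").reset_index(drop=True)
    df["q_fdr"] = bh_fdr(df["p_value"].to_numpy()) if len(df) else []
    return df[ENRICHMENT_COLUMNS]
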