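"""Core AIE statistics for reciprocal-cross subgroups.

Counts are always subgroup-pooled: per-sample allelic depths are summed
within each cross subgroup before any test is applied.  The reference
allele is the allele matching the reference genome build, so ``ref_frac``
is the reference-copy fraction throughout.

Main entry points:

- :func:`aggregate_by_subgroup` -- pool per-sample depths into AggregatedSite rows
- :func:`call_subgroup_aie` -- exact binomial AIE calls per (tissue, subgroup)
- :func:`call_differential_aie` -- pooled two-proportion test A vs B with
  delta threshold, categories, and the strong-imprinting flag
- :func:`gene_level_aie` -- collapse SNP-level differential results to genes
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from recipase.errors import UserInputError

#: differential-AIE categories
CAT_INCREASING = "increasing_ref_frac"
CAT_DECREASING = "decreasing_ref_frac"
CAT_NONE = "none"

AGGREGATED_COLUMNS = [
    "snp_id",
    "tissue",
    "subgroup",
    "ref_depth_sum",
    "alt_depth_sum",
    "ref_frac",
]

DIFFERENTIAL_COLUMNS = [
    "snp_id",
    "tissue",
    "ref_frac_a",
    "ref_frac_b",
    "delta",
    "z_stat",
    "p_value",
    "q_fdr",
    "category",
    "strong_imprinting",
]

GENE_VERDICT_COLUMNS = [
    "gene_id",
    "tissue",
    "category",
    "best_snp_id",
    "best_q_fdr",
    "best_delta",
]

_TINY = np.finfo(float).tiny


# ---------------------------------------------------------------------------
# primitive tests
# ---------------------------------------------------------------------------

def exact_binomial_test(ref_depth, alt_depth):
    """Two-sided exact binomial p-value against a 0.5 success probability.

    Uses the doubled-tail form ``min(1, 2*min(P(X<=k), P(X>=k)))`` which,
    for a symmetric null (p0 = 0.5), is identical to the minimum-likelihood
    two-sided test.  Accepts scalars or arrays; vectorized over sites.

    Raises
    ------
    UserInputError
        if any total depth is zero.
    """
    ref = np.asarray(ref_depth, dtype=np.int64)
    alt = np.asarray(alt_depth, dtype=np.int64)
    if np.any(ref < 0) or np.any(alt < 0):
        raise UserInputError("allele depths must be non-negative")
    total = ref + alt
    if np.any(total < 1):
        raise UserInputError("exact_binomial_test requires total depth >= 1")
    lower = stats.binom.cdf(ref, total, 0.5)
    upper = stats.binom.sf(ref - 1, total, 0.5)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    p = np.maximum(p, _TINY)
    if np.isscalar(ref_depth) and np.isscalar(alt_depth):
        return float(p)
    return p


def bh_fdr(p_values):
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved).

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the sorted p-values, capped
    at 1.  All inputs must lie in (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise UserInputError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def two_proportion_test(ref_a, tot_a, ref_b, tot_b, continuity_correction=False):
    """Pooled two-sample proportion z test, two-tailed.

    Tests equality of the reference-allele fraction between subgroups using
    the score statistic with the pooled proportion.  No continuity
    correction by default; set ``continuity_correction=True`` for the Yates
    variant.  Accepts scalars or arrays.

    Returns
    -------
    (z_stat, p_value)
        z is signed (A minus B); p from the doubled standard-normal tail,
        floored at the smallest positive float.
    """
    ra = np.asarray(ref_a, dtype=float)
    na = np.asarray(tot_a, dtype=float)
    rb = np.asarray(ref_b, dtype=float)
    nb = np.asarray(tot_b, dtype=float)
    if np.any(na < 1) or np.any(nb < 1):
        raise UserInputError("two_proportion_test requires totals >= 1")
    pa = ra / na
    pb = rb / nb
    pooled = (ra + rb) / (na + nb)
    var = pooled * (1.0 - pooled) * (1.0 / na + 1.0 / nb)
    diff = pa - pb
    if continuity_correction:
        cc = 0.5 * (1.0 / na + 1.0 / nb)
        diff = np.sign(diff) * np.maximum(np.abs(diff) - cc, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, diff / np.sqrt(var), 0.0)
    p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), _TINY)
    if np.isscalar(ref_a) and np.isscalar(tot_a):
        return float(z), float(p)
    return z, p


# ---------------------------------------------------------------------------
# aggregation and filtering
# ---------------------------------------------------------------------------

def aggregate_by_subgroup(records: pd.DataFrame) -> pd.DataFrame:
    """Sum per-sample allelic depths across samples within each subgroup.

    Parameters
    ----------
    records
        Long-format allele-depth table with columns ``snp_id``, ``tissue``,
        ``subgroup``, ``ref_depth``, ``alt_depth`` (one row per sample/SNP).
        All rows must share a single tissue.

    Returns
    -------
    One row per (snp_id, subgroup) with summed depths and ``ref_frac``
    (NaN when the pooled total is zero).
    """
    required = {"snp_id", "tissue", "subgroup", "ref_depth", "alt_depth"}
    missing = required - set(records.columns)
    if missing:
        raise UserInputError(f"records missing columns: {sorted(missing)}")
    tissues = records["tissue"].unique()
    if len(tissues) > 1:
        raise UserInputError(
            f"aggregate_by_subgroup expects a single tissue per call, got {sorted(tissues)}"
        )
    if records.empty:
        return pd.DataFrame(columns=AGGREGATED_COLUMNS)
    agg = (
        records.groupby(["snp_id", "tissue", "subgroup"], sort=True, observed=True)[
            ["ref_depth", "alt_depth"]
        ]
        .sum()
        .reset_index()
        .rename(columns={"ref_depth": "ref_depth_sum", "alt_depth": "alt_depth_sum"})
    )
    total = agg["ref_depth_sum"] + agg["alt_depth_sum"]
    with np.errstate(invalid="ignore"):
        agg["ref_frac"] = np.where(total > 0, agg["ref_depth_sum"] / total, np.nan)
    return agg[AGGREGATED_COLUMNS]


def filter_sites(ref_a, alt_a, ref_b, alt_b, min_depth=20, min_allele_depth=2):
    """Depth filter on pooled counts: keep a site iff *each* subgroup has
    total >= ``min_depth`` and both alleles >= ``min_allele_depth``.

    Vectorized; scalars return a bool, arrays return a boolean mask.
    """
    ra, aa = np.asarray(ref_a), np.asarray(alt_a)
    rb, ab = np.asarray(ref_b), np.asarray(alt_b)
    keep = (
        (ra + aa >= min_depth)
        & (rb + ab >= min_depth)
        & (ra >= min_allele_depth)
        & (aa >= min_allele_depth)
        & (rb >= min_allele_depth)
        & (ab >= min_allele_depth)
    )
    if np.isscalar(ref_a):
        return bool(keep)
    return keep


def _filter_single(ref, alt, min_depth, min_allele_depth):
    ref, alt = np.asarray(ref), np.asarray(alt)
    return (ref + alt >= min_depth) & (ref >= min_allele_depth) & (alt >= min_allele_depth)


def pair_subgroups(aggregated: pd.DataFrame) -> pd.DataFrame:
    """Pivot an aggregated table to wide form with one row per SNP present
    in both subgroups (columns ``ref_a``, ``alt_a``, ``ref_b``, ``alt_b``)."""
    a = aggregated[aggregated["subgroup"] == "A"]
    b = aggregated[aggregated["subgroup"] == "B"]
    wide = a.merge(
        b, on=["snp_id", "tissue"], suffixes=("_a", "_b"), how="inner"
    ).rename(
        columns={
            "ref_depth_sum_a": "ref_a",
            "alt_depth_sum_a": "alt_a",
            "ref_depth_sum_b": "ref_b",
            "alt_depth_sum_b": "alt_b",
        }
    )
    return wide[["snp_id", "tissue", "ref_a", "alt_a", "ref_b", "alt_b"]]


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def call_subgroup_aie(
    aggregated: pd.DataFrame,
    fdr: float = 0.05,
    min_depth: int = 20,
    min_allele_depth: int = 2,
) -> pd.DataFrame:
    """Flag pooled sites as allelically imbalanced by exact binomial test.

    The depth filter is applied to each subgroup's own pooled counts; BH
    correction is applied within each (tissue, subgroup) family.
    ``is_aie`` is ``q_fdr < fdr``.
    """
    agg = aggregated.copy()
    keep = _filter_single(
        agg["ref_depth_sum"], agg["alt_depth_sum"], min_depth, min_allele_depth
    )
    agg = agg.loc[keep].reset_index(drop=True)
    if agg.empty:
        out = pd.DataFrame(columns=AGGREGATED_COLUMNS + ["p_binomial", "q_fdr", "is_aie"])
        return out
    agg["p_binomial"] = exact_binomial_test(
        agg["ref_depth_sum"].to_numpy(), agg["alt_depth_sum"].to_numpy()
    )
    agg["q_fdr"] = 1.0
    for _, idx in agg.groupby(["tissue", "subgroup"], observed=True).groups.items():
        agg.loc[idx, "q_fdr"] = bh_fdr(agg.loc[idx, "p_binomial"].to_numpy())
    agg["is_aie"] = agg["q_fdr"] < fdr
    return agg.sort_values(["tissue", "subgroup", "snp_id"], kind="mergesort").reset_index(
        drop=True
    )


def call_differential_aie(
    aggregated: pd.DataFrame,
    fdr: float = 0.05,
    min_delta: float = 0.1,
    strong_delta: float = 0.7,
    min_depth: int = 20,
    min_allele_depth: int = 2,
    continuity_correction: bool = False,
) -> pd.DataFrame:
    """Differential AIE between subgroups A and B.

    For every SNP passing :func:`filter_sites` in both subgroups, runs the
    pooled two-proportion test on reference-allele fractions, corrects with
    BH within each tissue, and categorises:

    - ``increasing_ref_frac``: q < fdr and delta > min_delta
    - ``decreasing_ref_frac``: q < fdr and delta < -min_delta
    - ``none`` otherwise

    where ``delta = ref_frac_A - ref_frac_B`` on unrounded fractions.
    ``strong_imprinting`` is ``|delta| > strong_delta`` regardless of q.
    """
    wide = pair_subgroups(aggregated)
    keep = filter_sites(
        wide["ref_a"], wide["alt_a"], wide["ref_b"], wide["alt_b"],
        min_depth=min_depth, min_allele_depth=min_allele_depth,
    )
    wide = wide.loc[keep].reset_index(drop=True)
    if wide.empty:
        return pd.DataFrame(columns=DIFFERENTIAL_COLUMNS)
    tot_a = (wide["ref_a"] + wide["alt_a"]).to_numpy(dtype=float)
    tot_b = (wide["ref_b"] + wide["alt_b"]).to_numpy(dtype=float)
    frac_a = wide["ref_a"].to_numpy(dtype=float) / tot_a
    frac_b = wide["ref_b"].to_numpy(dtype=float) / tot_b
    z, p = two_proportion_test(
        wide["ref_a"].to_numpy(dtype=float), tot_a,
        wide["ref_b"].to_numpy(dtype=float), tot_b,
        continuity_correction=continuity_correction,
    )
    out = pd.DataFrame(
        {
            "snp_id": wide["snp_id"],
            "tissue": wide["tissue"],
            "ref_frac_a": frac_a,
            "ref_frac_b": frac_b,
            "delta": frac_a - frac_b,
            "z_stat": z,
            "p_value": p,
        }
    )
    out["q_fdr"] = 1.0
    for _, idx in out.groupby("tissue", observed=True).groups.items():
        out.loc[idx, "q_fdr"] = bh_fdr(out.loc[idx, "p_value"].to_numpy())
    qualifies = (out["q_fdr"] < fdr) & (out["delta"].abs() > min_delta)
    out["category"] = CAT_NONE
    out.loc[qualifies & (out["delta"] > 0), "category"] = CAT_INCREASING
    out.loc[qualifies & (out["delta"] < 0), "category"] = CAT_DECREASING
    out["strong_imprinting"] = out["delta"].abs() > strong_delta
    return out.sort_values(["tissue", "snp_id"], kind="mergesort").reset_index(drop=True)


def gene_level_aie(
    differential: pd.DataFrame, assignments: pd.DataFrame
) -> pd.DataFrame:
    """Collapse SNP-level differential-AIE results to gene verdicts.

    A gene's category is the category of its best *qualifying* SNP
    (minimum q, ties broken by larger \\|delta\\|, then lexicographic
    snp_id); genes whose assigned SNPs are all category ``none`` get
    ``none`` (best SNP chosen by the same rule among them).
    """
    if differential.empty or assignments.empty:
        return pd.DataFrame(columns=GENE_VERDICT_COLUMNS)
    merged = differential.merge(assignments[["snp_id", "gene_id"]], on="snp_id")
    if merged.empty:
        return pd.DataFrame(columns=GENE_VERDICT_COLUMNS)
    merged["_qualifies"] = merged["category"] != CAT_NONE
    merged["_absdelta"] = merged["delta"].abs()
    # qualifying SNPs sort strictly before non-qualifying ones
    merged = merged.sort_values(
        ["_qualifies", "q_fdr", "_absdelta", "snp_id"],
        ascending=[False, True, False, True],
        kind="mergesort",
    )
    best = merged.groupby(["gene_id", "tissue"], sort=True, observed=True).head(1)
    out = pd.DataFrame(
        {
            "gene_id": best["gene_id"],
            "tissue": best["tissue"],
            "category": best["category"],
            "best_snp_id": best["snp_id"],
            "best_q_fdr": best["q_fdr"],
            "best_delta": best["delta"],
        }
    )
    return out.sort_values(["tissue", "gene_id"], kind="mergesort").reset_index(drop=True)
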