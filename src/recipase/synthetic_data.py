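"""Seeded simulators for reciprocal-cross allele counts and DE tables.

Ground truth is planted at the gene level: a gene is null, cis-shifted, or
imprinted (paternally or maternally expressed).  Subgroup A is the cross
whose *father* carries the non-reference strain, so at a paternally
expressed gene the expressed allele in A is the alternate allele and the
true reference fraction drops below 0.5, while in subgroup B it rises
symmetrically.  Cis effects shift both subgroups the same way; mapping
bias is a single additive shift toward (or away from) the reference
allele applied to every site.

Per-site total depth is negative binomial; reference depth is
beta-binomial with intra-class correlation ``overdispersion_rho``
(``rho = 0`` degenerates to binomial draws).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from recipase.de_integration import DeTable
from recipase.errors import UserInputError

EFFECT_NULL = "null"
EFFECT_CIS = "cis"
EFFECT_IMPRINTED_PATERNAL = "imprinted_paternal"
EFFECT_IMPRINTED_MATERNAL = "imprinted_maternal"

TRUTH_COLUMNS = [
    "snp_id",
    "gene_id",
    "effect_class",
    "true_ref_frac_a",
    "true_ref_frac_b",
]

COUNT_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "sample_id",
    "subgroup",
    "tissue",
    "ref_depth",
    "alt_depth",
]

_BASES = np.array(list("ACGT"))
_CLAMP = 1e-6
_GENE_SPAN = 10_000
_GENE_SPACING = 25_000
_GENES_PER_CHROM = 200


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for :func:`simulate_allele_counts`; defaults give a mixed
    null/cis/imprinted fixture at realistic bulk depths (n = 8 per cross)."""

    n_genes: int = 100
    snps_per_gene_mean: float = 3.0
    n_samples_per_subgroup: int = 8
    depth_mean: float = 30.0
    depth_dispersion: float = 5.0
    overdispersion_rho: float = 0.01
    frac_imprinted_paternal: float = 0.05
    frac_imprinted_maternal: float = 0.05
    frac_cis_effect: float = 0.10
    imprint_delta: float = 0.2
    cis_delta: float = 0.2
    mapping_bias: float = 0.0
    tissue: str = "NAcc"
    seed: int = 0

    def validate(self) -> None:
        c = self
        checks = [
            (c.n_genes >= 1, "n_genes must be >= 1"),
            (c.snps_per_gene_mean > 0, "snps_per_gene_mean must be > 0"),
            (c.n_samples_per_subgroup >= 1, "n_samples_per_subgroup must be >= 1"),
            (c.depth_mean > 0, "depth_mean must be > 0"),
            (c.depth_dispersion > 0, "depth_dispersion must be > 0"),
            (0 <= c.overdispersion_rho < 1, "overdispersion_rho must be in [0, 1)"),
            (0 <= c.frac_imprinted_paternal <= 1, "frac_imprinted_paternal in [0, 1]"),
            (0 <= c.frac_imprinted_maternal <= 1, "frac_imprinted_maternal in [0, 1]"),
            (0 <= c.frac_cis_effect <= 1, "frac_cis_effect in [0, 1]"),
            (
                c.frac_imprinted_paternal + c.frac_imprinted_maternal + c.frac_cis_effect
                <= 1 + 1e-12,
                "effect fractions must sum to <= 1",
            ),
            (0 < c.imprint_delta <= 0.5, "imprint_delta must be in (0, 0.5]"),
            (0 < c.cis_delta <= 0.5, "cis_delta must be in (0, 0.5]"),
            (-0.2 <= c.mapping_bias <= 0.2, "mapping_bias must be in [-0.2, 0.2]"),
            (c.seed is not None, "seed is required"),
        ]
        numeric = [
            c.snps_per_gene_mean, c.depth_mean, c.depth_dispersion,
            c.overdispersion_rho, c.frac_imprinted_paternal,
            c.frac_imprinted_maternal, c.frac_cis_effect, c.imprint_delta,
            c.cis_delta, c.mapping_bias,
        ]
        if not all(math.isfinite(v) for v in numeric):
            raise UserInputError("SimulationConfig contains non-finite values")
        for ok, msg in checks:
            if not ok:
                raise UserInputError(msg)


def simulated_gene_models(n_genes: int) -> pd.DataFrame:
    """Deterministic gene layout used by :func:`simulate_allele_counts`.

    Genes are tiled along chr1, chr2, ... with fixed spans, so the layout
    depends only on ``n_genes`` (not the seed).
    """
    width = max(4, len(str(n_genes)))
    rows = []
    for g in range(n_genes):
        start = (g % _GENES_PER_CHROM) * _GENE_SPACING + 1
        rows.append(
            (
                f"gene{g + 1:0{width}d}",
                f"chr{g // _GENES_PER_CHROM + 1}",
                start,
                start + _GENE_SPAN - 1,
                "+",
                "autosome",
            )
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "chromosome_class"]
    )


def _beta_binomial(rng, n, theta, rho):
    """Draw beta-binomial counts; rho=0 falls back to plain binomial."""
    if rho == 0:
        return rng.binomial(n, theta)
    alpha = theta * (1.0 - rho) / rho
    beta = (1.0 - theta) * (1.0 - rho) / rho
    p = rng.beta(alpha, beta)
    return rng.binomial(n, p)


def simulate_allele_counts(config: SimulationConfig):
    """Generate a per-sample allele-depth table plus its truth table.

    Returns
    -------
    (counts, truth)
        ``counts`` is long-format with :data:`COUNT_COLUMNS`; ``truth``
        has one row per SNP with the planted effect class and the true
        reference fractions per subgroup (after mapping bias and
        clamping).  Deterministic for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_genes = config.n_genes
    classes = np.full(n_genes, EFFECT_NULL, dtype=object)
    n_pat = int(round(config.frac_imprinted_paternal * n_genes))
    n_mat = int(round(config.frac_imprinted_maternal * n_genes))
    n_cis = int(round(config.frac_cis_effect * n_genes))
    picked = rng.permutation(n_genes)[: n_pat + n_mat + n_cis]
    classes[picked[:n_pat]] = EFFECT_IMPRINTED_PATERNAL
    classes[picked[n_pat : n_pat + n_mat]] = EFFECT_IMPRINTED_MATERNAL
    classes[picked[n_pat + n_mat :]] = EFFECT_CIS
    cis_sign = rng.choice([-1.0, 1.0], size=n_genes)

    width = max(4, len(str(n_genes)))
    theta_a = np.full(n_genes, 0.5)
    theta_b = np.full(n_genes, 0.5)
    for g in range(n_genes):
        cls = classes[g]
        if cls == EFFECT_IMPRINTED_PATERNAL:
            # A's father carries the alt strain: paternal expression
            # depletes the reference copy in A and enriches it in B.
            theta_a[g] = 0.5 - config.imprint_delta
            theta_b[g] = 0.5 + config.imprint_delta
        elif cls == EFFECT_IMPRINTED_MATERNAL:
            theta_a[g] = 0.5 + config.imprint_delta
            theta_b[g] = 0.5 - config.imprint_delta
        elif cls == EFFECT_CIS:
            shift = cis_sign[g] * config.cis_delta
            theta_a[g] = 0.5 + shift
            theta_b[g] = 0.5 + shift
    theta_a = np.clip(theta_a + config.mapping_bias, _CLAMP, 1 - _CLAMP)
    theta_b = np.clip(theta_b + config.mapping_bias, _CLAMP, 1 - _CLAMP)

    snp_rows = []
    truth_rows = []
    for g in range(n_genes):
        gene_id = f"gene{g + 1:0{width}d}"
        chrom = f"chr{g // _GENES_PER_CHROM + 1}"
        start = (g % _GENES_PER_CHROM) * _GENE_SPACING + 1
        n_snps = rng.poisson(config.snps_per_gene_mean)
        offsets = np.sort(rng.choice(_GENE_SPAN, size=n_snps, replace=False)) if n_snps else []
        for s, off in enumerate(offsets):
            pos = start + int(off)
            ref_i = rng.integers(4)
            alt_i = (ref_i + 1 + rng.integers(3)) % 4
            snp_rows.append(
                (
                    f"{gene_id}_snp{s + 1}",
                    chrom,
                    pos,
                    _BASES[ref_i],
                    _BASES[alt_i],
                    g,
                )
            )
            truth_rows.append(
                (
                    f"{gene_id}_snp{s + 1}",
                    gene_id,
                    classes[g],
                    theta_a[g],
                    theta_b[g],
                )
            )

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)

    n_per = config.n_samples_per_subgroup
    samples = [("A", f"A{i + 1:02d}") for i in range(n_per)] + [
        ("B", f"B{i + 1:02d}") for i in range(n_per)
    ]
    p_nb = config.depth_dispersion / (config.depth_dispersion + config.depth_mean)

    records = []
    for snp_id, chrom, pos, ref, alt, g in snp_rows:
        for subgroup, sample_id in samples:
            theta = theta_a[g] if subgroup == "A" else theta_b[g]
            depth = int(rng.negative_binomial(config.depth_dispersion, p_nb))
            ref_depth = int(_beta_binomial(rng, depth, theta, config.overdispersion_rho))
            records.append(
                (
                    snp_id, chrom, pos, ref, alt,
                    sample_id, subgroup, config.tissue,
                    ref_depth, depth - ref_depth,
                )
            )
    counts = pd.DataFrame(records, columns=COUNT_COLUMNS)
    counts["pos"] = counts["pos"].astype(np.int64) if len(counts) else counts["pos"]
    return counts, truth


def simulate_de_tables(
    n_genes: int,
    frac_shared_de: float,
    target_correlation: float,
    seed: int,
    frac_private_de: float = 0.1,
    significance_threshold: float = 0.05,
    labels=("contrastX", "contrastY"),
):
    """Two correlated DE tables with a planted shared-significant subset.

    Shared-DE genes get log2 fold changes drawn from a bivariate normal
    with population correlation ``target_correlation`` and p-values below
    the significance threshold in *both* tables; a ``frac_private_de``
    slice of the remaining genes is significant in exactly one table;
    all other genes are non-significant in both.  The intersection of
    significant genes is therefore exactly the returned shared list.

    Returns ``(table_x, table_y, shared_gene_ids)``.
    """
    if n_genes < 3:
        raise UserInputError("n_genes must be >= 3")
    if not -1.0 <= target_correlation <= 1.0:
        raise UserInputError("target_correlation must be in [-1, 1]")
    if not 0.0 <= frac_shared_de <= 1.0:
        raise UserInputError("frac_shared_de must be in [0, 1]")
    rng = np.random.default_rng(seed)

    width = max(4, len(str(n_genes)))
    gene_ids = np.array([f"gene{i + 1:0{width}d}" for i in range(n_genes)])
    n_shared = int(round(frac_shared_de * n_genes))
    perm = rng.permutation(n_genes)
    shared_idx = perm[:n_shared]
    rest = perm[n_shared:]
    n_private = min(int(round(frac_private_de * n_genes)), len(rest) // 2)
    private_x = rest[:n_private]
    private_y = rest[n_private : 2 * n_private]

    rho = target_correlation
    x_fc = rng.normal(0.0, 1.0, n_genes)
    noise = rng.normal(0.0, 1.0, n_genes)
    y_fc = rng.normal(0.0, 1.0, n_genes)
    # exact population correlation on the shared subset
    y_fc[shared_idx] = rho * x_fc[shared_idx] + math.sqrt(max(0.0, 1 - rho * rho)) * noise[
        shared_idx
    ]

    thr = significance_threshold
    p_x = rng.uniform(thr, 1.0, n_genes)
    p_y = rng.uniform(thr, 1.0, n_genes)
    p_x[shared_idx] = rng.uniform(1e-8, thr * 0.999, n_shared)
    p_y[shared_idx] = rng.uniform(1e-8, thr * 0.999, n_shared)
    p_x[private_x] = rng.uniform(1e-8, thr * 0.999, len(private_x))
    p_y[private_y] = rng.uniform(1e-8, thr * 0.999, len(private_y))

    def _table(label, fc, p):
        df = pd.DataFrame({"gene_id": gene_ids, "log2_fold_change": fc, "p_value": p})
        return DeTable.from_frame(df, label, significance_threshold=thr)

    shared_ids = sorted(gene_ids[shared_idx].tolist())
    return _table(labels[0], x_fc, p_x), _table(labels[1], y_fc, p_y), shared_ids


def write_fixture_bundle(
    records: pd.DataFrame,
    truth: pd.DataFrame,
    out_dir,
    de_tables=(),
) -> dict:
    """Write a simulation to plain-text fixtures that round-trip through
    the readers in :mod:`recipase.allele_io`.

    Emits the allele-count TSV, a matching multi-sample VCF (one per
    tissue, per-sample AD fields), a sample->subgroup map, the truth
    TSV, and one DE TSV per table.  Returns a dict of logical name ->
    path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    counts_path = out_dir / "allele_counts.tsv"
    records.to_csv(counts_path, sep="\t", index=False, columns=COUNT_COLUMNS)
    paths["counts_tsv"] = counts_path

    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False, columns=TRUTH_COLUMNS)
    paths["truth_tsv"] = truth_path

    samples = (
        records[["sample_id", "subgroup", "tissue"]].drop_duplicates().sort_values(
            ["tissue", "subgroup", "sample_id"]
        )
        if len(records)
        else pd.DataFrame(columns=["sample_id", "subgroup", "tissue"])
    )
    samples_path = out_dir / "samples.tsv"
    samples.to_csv(samples_path, sep="\t", index=False)
    paths["samples_tsv"] = samples_path

    tissues = sorted(records["tissue"].unique()) if len(records) else []
    vcf_paths = {}
    for tissue in tissues or [None]:
        sub = records if tissue is None else records[records["tissue"] == tissue]
        name = "allele_counts.vcf" if tissue is None else f"allele_counts.{tissue}.vcf"
        vcf_path = out_dir / name
        _write_vcf(sub, vcf_path)
        vcf_paths[tissue if tissue is not None else ""] = vcf_path
    paths["vcf"] = vcf_paths

    if len(truth):
        # regenerate deterministic layout covering every gene in the truth table
        max_index = max(int(g.lstrip("gene")) for g in truth["gene_id"].unique())
        models = simulated_gene_models(max_index)
        genes_path = out_dir / "genes.bed"
        with open(genes_path, "w") as fh:
            for row in models.itertuples():
                fh.write(
                    f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.gene_id}\t0\t{row.strand}\n"
                )
        paths["genes_bed"] = genes_path

    for table in de_tables:
        de_path = out_dir / f"de_{table.contrast_label}.tsv"
        table.to_tsv(de_path)
        paths[f"de_{table.contrast_label}"] = de_path
    return paths


def _write_vcf(records: pd.DataFrame, path: Path) -> None:
    """Minimal VCF v4.2 with GT:AD per sample for one tissue's counts."""
    if len(records):
        sample_ids = sorted(records["sample_id"].unique())
        sites = (
            records[["chrom", "pos", "snp_id", "ref", "alt"]]
            .drop_duplicates()
            .sort_values(["chrom", "pos", "snp_id"])
        )
        depth = {
            (r.snp_id, r.sample_id): (r.ref_depth, r.alt_depth)
            for r in records.itertuples()
        }
    else:
        sample_ids, sites, depth = [], pd.DataFrame(), {}

    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    ]
    if len(records):
        for chrom in sites["chrom"].unique():
            length = int(sites.loc[sites["chrom"] == chrom, "pos"].max()) + _GENE_SPAN
            lines.append(f"##contig=<ID={chrom},length={length}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    lines.append("\t".join(header + sample_ids))
    for site in sites.itertuples() if len(records) else []:
        fields = [
            site.chrom, str(site.pos), site.snp_id, site.ref, site.alt,
            ".", "PASS", ".", "GT:AD",
        ]
        for sid in sample_ids:
            rd, ad = depth.get((site.snp_id, sid), (0, 0))
            fields.append(f"0/1:{rd},{ad}")
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")
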