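"""Config-driven orchestration of the full AIE analysis.

A single YAML config names the inputs (allele counts, gene models, DE
tables, gene sets, universe) and the thresholds; :func:`run_pipeline`
executes extract -> aggregate -> binomial AIE -> differential AIE ->
SNP/gene mapping -> gene verdicts -> enrichment crosswalk/battery ->
DE overlaps/correlations, writes TSV/JSON outputs and a manifest with
sha256 hashes.  Re-running on identical inputs is bit-identical (the
manifest carries no timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from recipase import __version__, allele_io, de_integration, enrichment
from recipase import aie_core
from recipase.errors import UserInputError

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "fdr": 0.05,
    "min_delta": 0.1,
    "strong_delta": 0.7,
    "min_depth": 20,
    "min_allele_depth": 2,
    "de_p": 0.05,
}

_THRESHOLD_RANGES = {
    "fdr": (0.0, 1.0),
    "min_delta": (0.0, 1.0),
    "strong_delta": (0.0, 1.0),
    "min_depth": (0, 10**9),
    "min_allele_depth": (0, 10**9),
    "de_p": (0.0, 1.0),
}


@dataclass
class PipelineConfig:
    output_dir: Path
    counts_tsv: Path | None = None
    vcf: Path | None = None
    samples_tsv: Path | None = None  # sample_id, subgroup, tissue (for VCF input)
    vcf_tissue: str = "tissue"
    gene_models: Path | None = None
    flank_bp: int = 0
    de_tables: dict = field(default_factory=dict)  # label -> path
    gene_sets: Path | None = None
    universe: Path | None = None
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    correlate: list = field(default_factory=list)  # [{x, y, exclude: [...]}]
    seed: int = 0


def validate_config(path) -> tuple[PipelineConfig | None, list[str]]:
    """Parse and validate a YAML config; collects all errors (no fail-fast)."""
    errors: list[str] = []
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except Exception as exc:  # unreadable/unparsable file
        return None, [f"cannot read config: {exc}"]
    if not isinstance(raw, dict):
        return None, ["config must be a mapping"]

    base = Path(path).parent

    def _resolve(key):
        value = raw.get(key)
        if value is None:
            return None
        p = Path(value)
        return p if p.is_absolute() else base / p

    cfg = PipelineConfig(output_dir=_resolve("output_dir") or base / "out")
    cfg.counts_tsv = _resolve("counts_tsv")
    cfg.vcf = _resolve("vcf")
    cfg.samples_tsv = _resolve("samples_tsv")
    cfg.vcf_tissue = raw.get("vcf_tissue", "tissue")
    cfg.gene_models = _resolve("gene_models")
    cfg.flank_bp = raw.get("flank_bp", 0)
    cfg.gene_sets = _resolve("gene_sets")
    cfg.universe = _resolve("universe")
    cfg.seed = raw.get("seed", 0)
    cfg.correlate = raw.get("correlate", [])

    for label, p in (raw.get("de_tables") or {}).items():
        pp = Path(p)
        cfg.de_tables[str(label)] = pp if pp.is_absolute() else base / pp

    thresholds = dict(DEFAULT_THRESHOLDS)
    for key, value in (raw.get("thresholds") or {}).items():
        if key not in DEFAULT_THRESHOLDS:
            errors.append(f"thresholds: unknown key {key!r}")
            continue
        thresholds[key] = value
    for key, (lo, hi) in _THRESHOLD_RANGES.items():
        v = thresholds[key]
        if not isinstance(v, (int, float)) or not lo <= v <= hi:
            errors.append(f"thresholds.{key}={v!r} outside [{lo}, {hi}]")
    cfg.thresholds = thresholds

    if cfg.counts_tsv is None and cfg.vcf is None:
        errors.append("one of counts_tsv or vcf is required")
    if cfg.vcf is not None and cfg.samples_tsv is None:
        errors.append("samples_tsv is required with vcf input")
    for key in ("counts_tsv", "vcf", "samples_tsv", "gene_models", "gene_sets", "universe"):
        p = getattr(cfg, key)
        if p is not None and not Path(p).exists():
            errors.append(f"{key}: path does not exist: {p}")
    for label, p in cfg.de_tables.items():
        if not Path(p).exists():
            errors.append(f"de_tables.{label}: path does not exist: {p}")
    for spec in cfg.correlate:
        if not isinstance(spec, dict) or "x" not in spec or "y" not in spec:
            errors.append(f"correlate entries need x and y labels: {spec!r}")
        else:
            for side in ("x", "y"):
                if spec[side] not in cfg.de_tables:
                    errors.append(f"correlate: unknown DE label {spec[side]!r}")
    if errors:
        return None, errors
    return cfg, []


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage whose inputs are configured; returns the manifest."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    outputs: dict[str, Path] = {}

    # --- extract ---
    if config.counts_tsv is not None:
        counts = allele_io.read_allele_counts_tsv(config.counts_tsv)
    else:
        samples = pd.read_csv(config.samples_tsv, sep="\t", dtype=str)
        subgroup_map = dict(zip(samples["sample_id"], samples["subgroup"]))
        tissue = (
            samples["tissue"].iloc[0] if "tissue" in samples.columns and len(samples)
            else config.vcf_tissue
        )
        counts = allele_io.read_vcf_allele_depths(config.vcf, subgroup_map, tissue)
    logger.info("loaded %d allele-depth records", len(counts))

    # --- aggregate + AIE per tissue ---
    agg_frames, aie_frames, diff_frames = [], [], []
    for tissue in sorted(counts["tissue"].unique()):
        sub = counts[counts["tissue"] == tissue]
        agg = aie_core.aggregate_by_subgroup(sub)
        agg_frames.append(agg)
        aie_frames.append(
            aie_core.call_subgroup_aie(
                agg, fdr=thr["fdr"], min_depth=thr["min_depth"],
                min_allele_depth=thr["min_allele_depth"],
            )
        )
        diff_frames.append(
            aie_core.call_differential_aie(
                agg, fdr=thr["fdr"], min_delta=thr["min_delta"],
                strong_delta=thr["strong_delta"], min_depth=thr["min_depth"],
                min_allele_depth=thr["min_allele_depth"],
            )
        )
    aggregated = pd.concat(agg_frames, ignore_index=True) if agg_frames else pd.DataFrame(
        columns=aie_core.AGGREGATED_COLUMNS
    )
    aie_calls = pd.concat(aie_frames, ignore_index=True) if aie_frames else pd.DataFrame()
    differential = pd.concat(diff_frames, ignore_index=True) if diff_frames else pd.DataFrame(
        columns=aie_core.DIFFERENTIAL_COLUMNS
    )
    _write_tsv(aggregated, out_dir / "aggregated.tsv")
    _write_tsv(aie_calls, out_dir / "aie_calls.tsv")
    _write_tsv(differential, out_dir / "differential_aie.tsv")
    outputs["aggregated"] = out_dir / "aggregated.tsv"
    outputs["aie_calls"] = out_dir / "aie_calls.tsv"
    outputs["differential_aie"] = out_dir / "differential_aie.tsv"

    # --- gene mapping + verdicts ---
    gene_aie = pd.DataFrame(columns=aie_core.GENE_VERDICT_COLUMNS)
    if config.gene_models is not None:
        models = allele_io.read_gene_models(config.gene_models)
        snp_pos = counts[["snp_id", "chrom", "pos"]].drop_duplicates("snp_id")
        assignments = allele_io.map_snps_to_genes(snp_pos, models, flank_bp=config.flank_bp)
        _write_tsv(assignments, out_dir / "snp_gene_assignments.tsv")
        outputs["snp_gene_assignments"] = out_dir / "snp_gene_assignments.tsv"
        gene_aie = aie_core.gene_level_aie(differential, assignments)
        _write_tsv(gene_aie, out_dir / "gene_aie.tsv")
        outputs["gene_aie"] = out_dir / "gene_aie.tsv"

    # --- DE tables ---
    de_tables = {
        label: de_integration.read_de_table(path, label, significance_threshold=thr["de_p"])
        for label, path in sorted(config.de_tables.items())
    }

    # --- enrichment ---
    if config.universe is not None:
        universe = enrichment.read_universe(config.universe)
        if de_tables and len(gene_aie):
            crosswalk = enrichment.crosswalk_aie_de_enrichment(
                gene_aie, list(de_tables.values()), universe
            )
            _write_tsv(crosswalk, out_dir / "crosswalk_enrichment.tsv")
            outputs["crosswalk_enrichment"] = out_dir / "crosswalk_enrichment.tsv"
        if config.gene_sets is not None:
            annotation_sets = enrichment.read_gene_sets(config.gene_sets)
            query_sets = []
            for (tissue, category), sub in gene_aie.groupby(["tissue", "category"]):
                if category == aie_core.CAT_NONE:
                    continue
                query_sets.append(
                    enrichment.GeneSet(f"{tissue}:{category}", frozenset(sub["gene_id"]))
                )
            if query_sets:
                battery = enrichment.gene_set_battery(query_sets, annotation_sets, universe)
                _write_tsv(battery, out_dir / "gene_set_enrichment.tsv")
                outputs["gene_set_enrichment"] = out_dir / "gene_set_enrichment.tsv"

    # --- DE overlaps and correlations ---
    if len(de_tables) >= 2:
        counts_by_pattern = de_integration.overlap_counts(de_tables.values())
        overlap_json = {
            "+".join(pattern): count for pattern, count in counts_by_pattern.items()
        }
        (out_dir / "de_overlaps.json").write_text(
            json.dumps(overlap_json, indent=2, sort_keys=True) + "\n"
        )
        outputs["de_overlaps"] = out_dir / "de_overlaps.json"
    if config.correlate:
        rows = []
        for spec in config.correlate:
            r, p, n = de_integration.correlate_fold_changes(
                de_tables[spec["x"]], de_tables[spec["y"]],
                exclude_ids=spec.get("exclude", []),
            )
            rows.append({"x": spec["x"], "y": spec["y"], "pearson_r": r, "p_value": p, "n": n})
        _write_tsv(pd.DataFrame(rows), out_dir / "correlations.tsv")
        outputs["correlations"] = out_dir / "correlations.tsv"

    manifest = {
        "recipase_version": __version__,
        "seed": config.seed,
        "thresholds": thr,
        "outputs": {name: {"path": p.name, "sha256": _sha256(p)} for name, p in sorted(outputs.items())},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
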