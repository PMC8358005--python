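"""File-format boundary: VCF/TSV allele depths, FASTA masking, gene models.

Coordinates are 1-based inclusive internally (VCF/GFF3 convention); BED is
converted on read and write.  Multi-allelic and indel VCF records are
dropped, not decomposed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from recipase.errors import UserInputError
from recipase.synthetic_data import COUNT_COLUMNS

logger = logging.getLogger(__name__)

GENE_MODEL_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "chromosome_class"]
ASSIGNMENT_COLUMNS = ["snp_id", "gene_id", "distance"]

CLASS_AUTOSOME = "autosome"
CLASS_X = "X"
CLASS_Y = "Y"
CLASS_MT = "MT"


# ---------------------------------------------------------------------------
# allele-depth tables
# ---------------------------------------------------------------------------

def read_allele_counts_tsv(path) -> pd.DataFrame:
    """Read a long-format allele-count TSV (the fixture-bundle schema)."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "snp_id": str, "chrom": str, "ref": str, "alt": str,
            "sample_id": str, "subgroup": str, "tissue": str,
        },
    )
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise UserInputError(f"{path}: missing columns {sorted(missing)}")
    df = df[COUNT_COLUMNS]
    if len(df):
        if (df["ref_depth"] < 0).any() or (df["alt_depth"] < 0).any():
            raise UserInputError(f"{path}: negative depths")
        bad = df["subgroup"][~df["subgroup"].isin(["A", "B"])]
        if len(bad):
            raise UserInputError(f"{path}: subgroup must be A or B, got {sorted(set(bad))}")
    return df


def read_vcf_allele_depths(vcf_path, subgroup_map: dict, tissue: str) -> pd.DataFrame:
    """Extract per-sample ref/alt depths at bi-allelic SNPs from a VCF.

    Parameters
    ----------
    subgroup_map
        sample_id -> "A" | "B"; every VCF sample must be present.
    tissue
        Label stamped on every record.

    Multi-allelic and indel records are skipped; the skip count is logged
    and stored in ``result.attrs["n_skipped"]``.  A record without an AD
    field is a hard error naming the site.
    """
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in subgroup_map]
    if unknown:
        raise UserInputError(f"samples missing from subgroup_map: {unknown}")
    subgroups = [subgroup_map[s] for s in samples]

    rows = []
    n_skipped = 0
    for variant in vcf:
        alts = variant.ALT
        if len(alts) != 1 or len(variant.REF) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            continue
        ad = variant.format("AD")
        if ad is None:
            raise UserInputError(
                f"record {variant.CHROM}:{variant.POS} has no AD (allele depth) field"
            )
        snp_id = variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}:{variant.POS}"
        ref_d = np.maximum(ad[:, 0], 0)
        alt_d = np.maximum(ad[:, 1], 0)
        for i, sample in enumerate(samples):
            rows.append(
                (
                    snp_id, variant.CHROM, variant.POS, variant.REF, alts[0],
                    sample, subgroups[i], tissue, int(ref_d[i]), int(alt_d[i]),
                )
            )
    if n_skipped:
        logger.info("%s: skipped %d non-bi-allelic-SNP records", vcf_path, n_skipped)
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    df.attrs["n_skipped"] = n_skipped
    return df


# ---------------------------------------------------------------------------
# FASTA masking
# ---------------------------------------------------------------------------

def mask_reference_fasta(fasta_path, sites, out_path):
    """Write a copy of a FASTA with the base at each (chrom, 1-based pos) set to N.

    Headers, sequence order, and all other bases are unchanged; masking is
    idempotent.  Out-of-bounds or unknown-chromosome sites are errors.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    seqs = {rec.id: bytearray(str(rec.seq), "ascii") for rec in records}
    for chrom, pos in sites:
        if chrom not in seqs:
            raise UserInputError(f"chromosome {chrom!r} not found in {fasta_path}")
        if not 1 <= pos <= len(seqs[chrom]):
            raise UserInputError(
                f"position {pos} out of bounds for {chrom} (length {len(seqs[chrom])})"
            )
        seqs[chrom][pos - 1] = ord("N")
    masked = [
        SeqRecord(Seq(seqs[rec.id].decode("ascii")), id=rec.id, description=rec.description)
        for rec in records
    ]
    SeqIO.write(masked, str(out_path), "fasta")
    return Path(out_path)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def _chromosome_class(chrom: str, x_label="X", y_label="Y", mt_labels=("MT", "M")) -> str:
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name == x_label:
        return CLASS_X
    if name == y_label:
        return CLASS_Y
    if name in mt_labels:
        return CLASS_MT
    return CLASS_AUTOSOME


def read_gene_models(path, x_label="X", y_label="Y", feature_type="gene") -> pd.DataFrame:
    """Read gene intervals from GFF3 (1-based inclusive) or BED (converted).

    Format chosen by extension (.bed vs anything else = GFF3).  Returns a
    frame with :data:`GENE_MODEL_COLUMNS`; malformed lines raise with the
    line number.
    """
    path = Path(path)
    rows = []
    if path.suffix.lower() == ".bed":
        for ln, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise UserInputError(f"{path}:{ln}: BED line needs >= 4 columns")
            try:
                chrom, start0, end0, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            except ValueError as exc:
                raise UserInputError(f"{path}:{ln}: {exc}") from None
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            rows.append((name, chrom, start0 + 1, end0, strand))
    else:
        for ln, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise UserInputError(f"{path}:{ln}: GFF3 line needs 9 columns")
            if fields[2] != feature_type:
                continue
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise UserInputError(f"{path}:{ln}: {exc}") from None
            strand = fields[6] if fields[6] in "+-" else "."
            gene_id = None
            for kv in fields[8].split(";"):
                kv = kv.strip()
                for key in ("ID=", "gene_id="):
                    if kv.startswith(key):
                        gene_id = kv[len(key):].strip('"')
                        break
                if gene_id:
                    break
            if gene_id is None:
                raise UserInputError(f"{path}:{ln}: no ID/gene_id attribute")
            rows.append((gene_id, fields[0], start, end, strand))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    if len(df) and (df["start"] > df["end"]).any():
        bad = df.loc[df["start"] > df["end"], "gene_id"].iloc[0]
        raise UserInputError(f"{path}: start > end for gene {bad}")
    df["chromosome_class"] = [
        _chromosome_class(c, x_label=x_label, y_label=y_label) for c in df["chrom"]
    ]
    return df[GENE_MODEL_COLUMNS]


def write_gene_models_bed(gene_models: pd.DataFrame, path) -> Path:
    """Write gene models as 6-column BED (0-based half-open on disk)."""
    with open(path, "w") as fh:
        for row in gene_models.itertuples():
            fh.write(
                f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.gene_id}\t0\t{row.strand}\n"
            )
    return Path(path)


def map_snps_to_genes(snps: pd.DataFrame, gene_models: pd.DataFrame, flank_bp: int = 0) -> pd.DataFrame:
    """Assign each SNP to every gene whose flank-extended interval contains it.

    ``snps`` needs columns snp_id, chrom, pos (1-based).  The interval is
    ``[start - flank_bp, end + flank_bp]``, 1-based inclusive; distance is
    0 inside the gene body, else the gap to the nearest gene edge.  SNPs
    covered by no interval produce no rows.
    """
    if flank_bp < 0:
        raise UserInputError("flank_bp must be non-negative")
    snps = snps[["snp_id", "chrom", "pos"]].drop_duplicates("snp_id")
    out = []
    for chrom, gsub in gene_models.groupby("chrom"):
        ssub = snps[snps["chrom"] == chrom]
        if ssub.empty:
            continue
        pos = ssub["pos"].to_numpy()[:, None]
        start = gsub["start"].to_numpy()[None, :]
        end = gsub["end"].to_numpy()[None, :]
        hit = (pos >= start - flank_bp) & (pos <= end + flank_bp)
        si, gi = np.nonzero(hit)
        if len(si) == 0:
            continue
        p = ssub["pos"].to_numpy()[si]
        s = gsub["start"].to_numpy()[gi]
        e = gsub["end"].to_numpy()[gi]
        dist = np.maximum(np.maximum(s - p, p - e), 0)
        out.append(
            pd.DataFrame(
                {
                    "snp_id": ssub["snp_id"].to_numpy()[si],
                    "gene_id": gsub["gene_id"].to_numpy()[gi],
                    "distance": dist,
                }
            )
        )
    if not out:
        return pd.DataFrame(columns=ASSIGNMENT_COLUMNS)
    result = pd.concat(out, ignore_index=True)
    return result.sort_values(["snp_id", "gene_id"], kind="mergesort").reset_index(drop=True)
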