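"""Readers and writers for every on-disk format the pipeline touches.

TSV count/score matrices, BED intervals, minimal VCF (GT only), JASPAR text
PFMs, FASTA and Newick. Heavy lifting for the standard formats is delegated
to pysam (VCF), Biopython (FASTA, JASPAR) and dendropy (Newick); the TSV/BED
readers enforce this pipeline's stricter contracts directly.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    ElementClass,
    Genotype,
    GenomicInterval,
    GlandSide,
    Motif,
    SampleMeta,
    ScoreMatrix,
    Variant,
    validate_counts,
)

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# counts / score TSV matrices


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a genes x samples raw-count matrix (first column gene ids)."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: no header (empty file)")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns")
    arr = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, (gene, cell) in enumerate(df[col].items()):
            try:
                arr[i, j] = int(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: non-integer count {cell!r} at gene {gene!r}, sample {col!r}"
                ) from None
    out = pd.DataFrame(arr, index=df.index, columns=df.columns)
    try:
        return validate_counts(out)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a real-valued feature x sample matrix (scores, protein abundances...)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)


def write_matrix_tsv(df: pd.DataFrame, path, index_label: str = "feature") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")


# ---------------------------------------------------------------------------
# BED

_strand_logged = False


def read_bed(path, class_map: Optional[dict] = None, gene_map: Optional[dict] = None
             ) -> list[GenomicInterval]:
    """Read BED3+ intervals (0-based, half-open).

    ``class_map``/``gene_map`` are sidecar annotations keyed by interval name:
    element class and target gene are assigned from them, falling back to a
    5th/6th column when present (name-convention class in column 5).
    """
    global _strand_logged
    out = []
    class_map = class_map or {}
    gene_map = gene_map or {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{ln}: expected at least 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{ln}: non-numeric coordinates") from None
            if start >= end:
                raise ParseError(f"{path}:{ln}: start >= end ({start} >= {end})")
            name = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
            cls = ElementClass.OTHER
            if name in class_map:
                cls = ElementClass(class_map[name])
            elif len(fields) > 4 and fields[4] in ElementClass._value2member_map_:
                cls = ElementClass(fields[4])
            elif len(fields) > 4 and fields[4] in ("+", "-"):
                if not _strand_logged:
                    logger.info("BED strand column ignored (interval-level analyses are strand-free)")
                    _strand_logged = True
            if len(fields) > 5 and fields[5] in ("+", "-") and not _strand_logged:
                logger.info("BED strand column ignored (interval-level analyses are strand-free)")
                _strand_logged = True
            gene = gene_map.get(name)
            out.append(GenomicInterval(chrom, start, end, name, cls, gene))
    return out


def write_bed(intervals: list[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.element_class.value}\n")


def read_score_tsv(path, intervals: list[GenomicInterval]) -> ScoreMatrix:
    """Read a per-interval score matrix keyed to BED intervals by name."""
    df = read_matrix_tsv(path)
    by_name = {iv.name: iv for iv in intervals}
    missing = [n for n in df.index if n not in by_name]
    if missing:
        raise ParseError(f"{path}: rows not present in BED annotation: {missing[:5]}")
    return ScoreMatrix([by_name[n] for n in df.index], df)


# ---------------------------------------------------------------------------
# VCF


def _gt_to_genotype(gt: tuple, alt_index: int) -> Genotype:
    if gt is None or any(a is None for a in gt):
        return Genotype.MISSING
    n_alt = sum(1 for a in gt if a == alt_index)
    if n_alt == len(gt) and n_alt > 0:
        return Genotype.HOM_ALT
    if n_alt > 0:
        return Genotype.HET
    return Genotype.HOM_REF


def read_vcf_minimal(path, region: Optional[GenomicInterval] = None) -> list[Variant]:
    """Read GT calls from a VCF; multiallelic records are split per alt allele."""
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vf = pysam.VariantFile(str(path))
        if not list(vf.header.samples):
            raise ParseError(f"{path}: VCF has no sample columns")
        for rec in vf:
            alts = rec.alts or ()
            for k, alt in enumerate(alts, start=1):
                if alt is None or not set(alt) <= set("ACGT"):
                    continue  # symbolic / spanning-deletion alleles out of scope
                genos = {}
                for s in rec.samples:
                    try:
                        gt = rec.samples[s].get("GT")
                        genos[s] = _gt_to_genotype(gt, k)
                    except (KeyError, ValueError):
                        logger.warning("%s: malformed GT at %s:%d sample %s", path, rec.chrom, rec.pos, s)
                        genos[s] = Genotype.MISSING
                var = Variant(rec.chrom, rec.pos, rec.ref, alt, genos)
                if region is not None and not var.interval.overlaps(region):
                    continue
                out.append(var)
        vf.close()
    return out


def write_vcf_minimal(variants: list[Variant], samples: list[str], path,
                      contigs: Optional[dict[str, int]] = None) -> None:
    """Write a minimal VCF 4.2 with GT-only FORMAT."""
    gt_code = {Genotype.HOM_REF: "0/0", Genotype.HET: "0/1",
               Genotype.HOM_ALT: "1/1", Genotype.MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt_allele)):
            gts = "\t".join(gt_code[v.genotypes.get(s, Genotype.MISSING)] for s in samples)
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# JASPAR PFM


def read_jaspar_pfm(path) -> list[Motif]:
    """Read motifs from JASPAR text PFM format (4 labeled count rows per motif)."""
    try:
        with open(path) as fh:
            parsed = bio_motifs.parse(fh, "jaspar")
            out = []
            for m in parsed:
                pfm = np.array([list(m.counts[b]) for b in "ACGT"], dtype=float)
                out.append(Motif(m.matrix_id or m.name, m.name or m.matrix_id, pfm))
    except (KeyError, ValueError, IndexError) as exc:
        raise ParseError(f"{path}: malformed JASPAR PFM ({exc})") from None
    if not out:
        raise ParseError(f"{path}: no motifs found")
    return out


def write_jaspar_pfm(motif_list: list[Motif], path) -> None:
    with open(path, "w") as fh:
        for m in motif_list:
            fh.write(f">{m.motif_id}\t{m.tf_name}\n")
            for i, base in enumerate("ACGT"):
                row = " ".join(f"{int(c):6d}" if float(c).is_integer() else f"{c:8.2f}"
                               for c in m.pfm[i])
                fh.write(f"{base}  [ {row} ]\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Newick


def read_newick(path) -> dendropy.Tree:
    """Read a rooted weighted tree; every non-root edge must carry a length."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from None
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ParseError(f"{path}: branch lengths required on every edge "
                             "(independent contrasts need them)")
        if edge.length < 0:
            raise ParseError(f"{path}: negative branch length")
    labels = [t.taxon.label for t in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ParseError(f"{path}: duplicate tip labels")
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


# ---------------------------------------------------------------------------
# sample metadata


def read_sample_meta(path) -> list[SampleMeta]:
    """Read sample metadata TSV: sample_id, individual, lineage, population, gland_side."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "lineage"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: metadata needs columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        out.append(SampleMeta(
            sample_id=row["sample_id"],
            lineage=row["lineage"],
            population=row.get("population", ""),
            gland_side=GlandSide(row.get("gland_side", "NA") or "NA"),
            individual=row.get("individual", "") or row["sample_id"],
        ))
    ids = [m.sample_id for m in out]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate sample ids")
    return out


def write_sample_meta(meta: list[SampleMeta], path) -> None:
    pd.DataFrame([{
        "sample_id": m.sample_id, "individual": m.individual, "lineage": m.lineage,
        "population": m.population, "gland_side": m.gland_side.value,
    } for m in meta]).to_csv(path, sep="\t", index=False)


def validate_labels(counts: Optional[pd.DataFrame], meta: list[SampleMeta],
                    matrices: Optional[list[ScoreMatrix]] = None) -> None:
    """Cross-file consistency: every sample referenced by a matrix exists in metadata."""
    known = {m.sample_id for m in meta}
    if counts is not None:
        unknown = set(counts.columns) - known
        if unknown:
            raise ParseError(f"counts samples missing from metadata: {sorted(unknown)}")
    for sm in matrices or []:
        unknown = set(sm.samples) - known
        if unknown:
            raise ParseError(f"score-matrix samples missing from metadata: {sorted(unknown)}")
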