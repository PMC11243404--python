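"""End-to-end orchestration over an input bundle.

Chains the per-module operations into the full analysis: normalization,
variance tables, TF-venom correlations, CLR mRNA-protein coupling, per-CRE
nucleotide diversity and TFBS changes, footprint occupancy, deletion calls,
and the per-gene regulatory-correlate matrix. ``full_pipeline`` writes every
table as TSV so a fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import cre as cre_mod
from . import io as rio
from .depth import DepthProfile, call_deletion, depth_ratio
from .expression import NormalizedMatrix, normalize, tf_venom_correlation
from .footprints import OccupancyMatrix, binarize_footprints, intersect_bound_variants
from .phylo import (
    ContrastTransformer,
    GeneModelResult,
    assemble_feature_table,
    fit_feature_table,
)
from .proteo import mrna_protein_fit, pair_abundances
from .simulate import Bundle, CreAnnotation, build_bundle  # noqa: F401 (re-export)
from .types import ElementClass, GenomicInterval, Variant

logger = logging.getLogger(__name__)


def load_bundle_inputs(bundle_dir) -> dict:
    """Read a written bundle back as the raw pipeline inputs."""
    d = Path(bundle_dir)
    ann = json.loads((d / "annotation.json").read_text())
    intervals = rio.read_bed(d / "peaks.bed", class_map=ann["class_map"],
                             gene_map=ann["gene_map"])
    tfbs_intervals = []
    tfbs_motif, tf_of = {}, {}
    with open(d / "tfbs.bed") as fh:
        for line in fh:
            c, s, e, name, motif_id, tf = line.rstrip("\n").split("\t")
            gene = None
            tfbs_intervals.append(GenomicInterval(c, int(s), int(e), name,
                                                  ElementClass.OTHER, gene))
            tfbs_motif[name] = motif_id
            tf_of[name] = tf
    out = {
        "counts": rio.read_counts_tsv(d / "counts.tsv"),
        "meta": rio.read_sample_meta(d / "meta.tsv"),
        "tree": rio.read_newick(d / "tree.nwk"),
        "intervals": intervals,
        "accessibility": rio.read_score_tsv(d / "accessibility.tsv", intervals),
        "footprint_scores": rio.read_score_tsv(d / "footprints.tsv", tfbs_intervals),
        "tfbs_motif": tfbs_motif,
        "tf_of": tf_of,
        "variants": rio.read_vcf_minimal(d / "variants.vcf"),
        "cre_sequences": rio.read_fasta(d / "cres.fa"),
        "motifs": rio.read_jaspar_pfm(d / "motifs.jaspar"),
        "venom_genes": ann["venom_genes"],
        "tf_genes": ann["tf_genes"],
    }
    if (d / "protein.tsv").exists():
        out["protein"] = rio.read_matrix_tsv(d / "protein.tsv")
    if (d / "depth.tsv").exists():
        raw = pd.read_csv(d / "depth.tsv", sep="\t", index_col=0)
        windows = [GenomicInterval(r.chrom, int(r.start), int(r.end), name)
                   for name, r in raw.iterrows()]
        out["depth"] = DepthProfile(windows, raw.drop(columns=["chrom", "start", "end"]))
    return out


def normalized_expression(bundle: Bundle, transform: str = "log2p1") -> NormalizedMatrix:
    return normalize(bundle.counts, transform=transform)


def run_fig4_matrix(bundle: Bundle, genes: Optional[list[str]] = None,
                    norm: Optional[NormalizedMatrix] = None,
                    occupancy: Optional[OccupancyMatrix] = None,
                    transformer: Optional[ContrastTransformer] = None,
                    **fit_kwargs) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene, per-feature-class coefficient/p-value matrix.

    Genes without annotated CREs are ineligible and listed with a reason
    instead of being fit. Returns (results table, exclusions table).
    """
    genes = list(genes) if genes is not None else list(bundle.venom_genes)
    norm = norm or normalized_expression(bundle)
    occupancy = occupancy or binarize_footprints(bundle.footprint_scores)
    transformer = transformer or ContrastTransformer(bundle.tree)

    # pre-bucket variants and TFBS rows by gene for speed on large bundles
    cres_by_gene = {g: bundle.annotation.cres_of(g) for g in genes}
    variants_by_gene: dict[str, list[Variant]] = {g: [] for g in genes}
    for v in bundle.variants:
        for g in genes:
            if any(v.interval.overlaps(c) for c in cres_by_gene[g]):
                variants_by_gene[g].append(v)
                break

    rows, excluded = [], []
    for g in genes:
        if not cres_by_gene[g]:
            excluded.append({"gene": g, "reason": "no annotated CREs (genomic context unresolved)"})
            continue
        cre_names = {c.name for c in cres_by_gene[g]}
        fp_names = [iv.name for iv in bundle.footprint_scores.intervals
                    if any(c.start <= iv.start and iv.end <= c.end and c.chrom == iv.chrom
                           for c in cres_by_gene[g])]
        occ_sub = OccupancyMatrix(
            [iv for iv in occupancy.intervals if iv.name in set(fp_names)],
            occupancy.scores.loc[fp_names], occupancy.thresholds,
            occupancy.bound.loc[fp_names], occupancy.tf_names)
        acc_sub_names = [iv.name for iv in bundle.accessibility.intervals
                         if iv.gene == g or iv.name in cre_names]
        acc_sub = bundle.accessibility.subset(acc_sub_names)
        try:
            ft = assemble_feature_table(
                g, norm.values, acc_sub, occ_sub, variants_by_gene[g],
                bundle.tf_genes, bundle.annotation.intervals)
            res = fit_feature_table(ft, transformer, **fit_kwargs)
        except (ValueError, KeyError) as exc:
            excluded.append({"gene": g, "reason": str(exc)})
            continue
        for cls, row in res.table.iterrows():
            rows.append({"gene": g, "class": cls, "coefficient": row["coefficient"],
                         "abs_coefficient": row["abs_coefficient"], "p": row["p"],
                         "r2": res.r2, "n_contrasts": res.n_contrasts,
                         "pc1_var_explained": row["pc1_var_explained"],
                         "significant": bool(row["p"] < 0.05)})
    results = pd.DataFrame(rows)
    exclusions = pd.DataFrame(excluded, columns=["gene", "reason"])
    return results, exclusions


def fit_single_gene(bundle: Bundle, gene: str,
                    norm: Optional[NormalizedMatrix] = None,
                    occupancy: Optional[OccupancyMatrix] = None,
                    transformer: Optional[ContrastTransformer] = None,
                    **fit_kwargs) -> GeneModelResult:
    norm = norm or normalized_expression(bundle)
    occupancy = occupancy or binarize_footprints(bundle.footprint_scores)
    transformer = transformer or ContrastTransformer(bundle.tree)
    ft = assemble_feature_table(gene, norm.values, bundle.accessibility, occupancy,
                                bundle.variants, bundle.tf_genes,
                                bundle.annotation.intervals)
    return fit_feature_table(ft, transformer, **fit_kwargs)


def cre_diversity_table(bundle: Bundle, het_policy: str = "alt") -> pd.DataFrame:
    """Per-CRE nucleotide diversity over projected consensus sequences."""
    rows = []
    for name, seq in sorted(bundle.cre_sequences.items()):
        interval = next(iv for iv in bundle.annotation.intervals if iv.name == name)
        cons = cre_mod.build_consensus_set(seq, bundle.variants, bundle.samples,
                                           interval, het_policy)
        res = cre_mod.nucleotide_diversity(cons, cre_name=name)
        rows.append({"cre": name, "element_class": interval.element_class.value,
                     "gene": interval.gene, "pi": res.pi,
                     "n_sequences": res.n_sequences,
                     "mean_compared_sites": res.n_compared_sites})
    return pd.DataFrame(rows).set_index("cre")


def tfbs_change_table(bundle: Bundle) -> pd.DataFrame:
    rows = []
    for name, seq in sorted(bundle.cre_sequences.items()):
        interval = next(iv for iv in bundle.annotation.intervals if iv.name == name)
        overlapping = [v for v in bundle.variants if v.interval.overlaps(interval)]
        for ch in cre_mod.classify_tfbs_changes(seq, overlapping, bundle.motifs, interval):
            rows.append({"cre": name,
                         "variant": f"{ch.variant.chrom}:{ch.variant.pos}:"
                                    f"{ch.variant.ref_allele}>{ch.variant.alt_allele}",
                         "motif_id": ch.motif_id, "change": ch.change,
                         "samples_with_alt": ",".join(ch.samples_with_alt)})
    return pd.DataFrame(rows, columns=["cre", "variant", "motif_id", "change",
                                       "samples_with_alt"])


def tfbs_presence_from_changes(bundle: Bundle,
                               changes: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Per-sample presence matrix of variant-modified TFBSs.

    For a 'lost' change the motif match is present in samples NOT carrying the
    alt allele; for a 'gained' change it is present in carriers. Rows are
    (cre, variant, motif) combinations; input to the sharing spectrum.
    """
    if changes is None:
        changes = tfbs_change_table(bundle)
    key_to_var = {f"{v.chrom}:{v.pos}:{v.ref_allele}>{v.alt_allele}": v
                  for v in bundle.variants}
    rows = {}
    for _, rec in changes.iterrows():
        if rec["change"] not in ("lost", "gained"):
            continue
        var = key_to_var[rec["variant"]]
        carriers = set(var.carriers())
        present_if_carrier = rec["change"] == "gained"
        rows[f"{rec['cre']}|{rec['variant']}|{rec['motif_id']}"] = [
            int((s in carriers) == present_if_carrier) for s in bundle.samples]
    return pd.DataFrame.from_dict(rows, orient="index", columns=bundle.samples)


def deletion_calls(bundle: Bundle) -> pd.DataFrame:
    if bundle.depth is None or bundle.truth.deletion_interval is None:
        return pd.DataFrame(columns=["sample", "call", "run_length", "mean_ratio"])
    query = bundle.truth.deletion_interval
    ratios = depth_ratio(bundle.depth, exclude=query)
    calls = call_deletion(ratios, bundle.depth.windows, query)
    return pd.DataFrame([{"sample": c.sample, "call": c.call,
                          "run_length": c.run_length, "mean_ratio": c.mean_ratio}
                         for c in calls]).set_index("sample")


def full_pipeline(bundle: Bundle, outdir) -> dict:
    """Run every stage on a bundle and write all result tables under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    norm = normalized_expression(bundle)
    rio.write_matrix_tsv(norm.values, out / "normalized_expression.tsv", "gene")

    var_all = norm.values.var(axis=1, ddof=1)
    var_all.rename("variance").to_frame().to_csv(out / "expression_variance.tsv", sep="\t",
                                                 float_format="%.10g")
    corr = tf_venom_correlation(norm, bundle.tf_genes, bundle.venom_genes)
    rio.write_matrix_tsv(corr.rho, out / "tf_venom_rho.tsv", "tf")
    rio.write_matrix_tsv(corr.q, out / "tf_venom_q.tsv", "tf")
    corr.significant.astype(int).to_csv(out / "tf_venom_significant.tsv", sep="\t",
                                        index_label="tf")

    results = {"norm": norm, "correlations": corr}

    if bundle.protein is not None:
        counts_scale = bundle.counts.div(norm.size_factors, axis=1).loc[bundle.venom_genes]
        paired = pair_abundances(counts_scale, bundle.protein)
        slope, intercept, r2 = mrna_protein_fit(paired)
        pd.DataFrame([{"slope": slope, "intercept": intercept, "r2": r2}]).to_csv(
            out / "mrna_protein_fit.tsv", sep="\t", index=False, float_format="%.10g")
        results["mrna_protein_r2"] = r2

    div = cre_diversity_table(bundle)
    div.to_csv(out / "cre_pi.tsv", sep="\t", float_format="%.10g")
    results["pi_table"] = div

    changes = tfbs_change_table(bundle)
    changes.to_csv(out / "tfbs_changes.tsv", sep="\t", index=False)
    results["tfbs_changes"] = changes

    occupancy = binarize_footprints(bundle.footprint_scores)
    occupancy.bound.to_csv(out / "footprint_bound.tsv", sep="\t", index_label="tfbs")
    inter = intersect_bound_variants(occupancy, bundle.variants)
    if not inter.empty:
        inter.assign(
            bound_alt_carriers=inter["bound_alt_carriers"].map(",".join),
            bound_ref_carriers=inter["bound_ref_carriers"].map(",".join),
        ).to_csv(out / "bound_variant_intersection.tsv", sep="\t", index=False)
    results["occupancy"] = occupancy
    results["bound_variants"] = inter

    presence = tfbs_presence_from_changes(bundle, changes)
    spectrum, frac_unique = cre_mod.tfbs_sharing_spectrum(
        presence if len(presence) else occupancy.bound)
    pd.DataFrame({"n_individuals": list(spectrum), "n_tfbs": list(spectrum.values())}
                 ).to_csv(out / "tfbs_sharing_spectrum.tsv", sep="\t", index=False)
    results["sharing_spectrum"] = (spectrum, frac_unique)

    dels = deletion_calls(bundle)
    dels.to_csv(out / "deletion_calls.tsv", sep="\t", float_format="%.10g")
    results["deletions"] = dels

    fig4, excl = run_fig4_matrix(bundle, norm=norm, occupancy=occupancy)
    fig4.to_csv(out / "gene_model_matrix.tsv", sep="\t", index=False,
                float_format="%.10g")
    excl.to_csv(out / "gene_model_exclusions.tsv", sep="\t", index=False)
    results["fig4"] = fig4
    results["fig4_excluded"] = excl
    return results
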