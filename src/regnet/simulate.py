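"""Synthetic multi-omic bundles with known ground truth.

Emulates the structure of the study system: ~12 venom-gland samples from 4
closely related lineages on a known tree; negative-binomial mRNA counts whose
log-means evolve by Brownian motion on that tree; ATAC accessibility and
footprint-score matrices over an annotated CRE set; CRE sequences, variants
(including motif-destroying ones), a planted multi-kb deletion visible in
windowed depth; and protein abundances proportional to mRNA. Every layer is
internally consistent (variants match sequences, footprints match genotypes)
and fully determined by the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

from . import io as rio
from .depth import DepthProfile
from .phylo import ContrastTransformer, bm_sample
from .types import (
    ElementClass,
    Genotype,
    GenomicInterval,
    GlandSide,
    Motif,
    SampleMeta,
    ScoreMatrix,
    Variant,
)

logger = logging.getLogger(__name__)

_DEFAULT_LINEAGES = ("viridis", "concolor", "lutosus", "cerberus")
_BASES = "ACGT"

#: Default planted-driver strength: a regulatory driver whose swing across
#: lineages produces order-of-magnitude expression differences, matching the
#: scale of venom-gene variation the system is known for.
DEFAULT_EFFECT_SIZE = 4.0
#: Grid used when tracking recovery as a function of effect size.
EFFECT_SIZE_GRID = (1.0, 2.0, 4.0, 6.0)


@dataclass
class PlantedEffect:
    gene: str
    feature_class: str  # 'cre_accessibility' or 'tf_expression'
    effect_size: float


@dataclass
class SimulationConfig:
    """Study-scale defaults: 4 lineages x 3 samples, ~50 venom genes, ~40
    enhancers + 50 promoters, NB dispersion 0.1, ~50x depth."""

    n_lineages: int = 4
    samples_per_lineage: int = 3
    n_genes: int = 50  # venom genes
    n_tfs: int = 40  # venom-regulating TFs
    n_background_genes: int = 400  # stable genes anchoring size-factor estimation
    enhancer_prob: float = 0.8  # ~41 enhancers for 50 genes
    dispersion: float = 0.1
    base_mean: float = 500.0
    bm_rate: float = 1.0  # residual BM rate of log venom-gene expression per unit height
    driver_rate: float = 0.5  # BM rate of planted regulatory drivers
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    n_motifs: int = 8
    motif_length: int = 6
    tfbs_per_cre: int = 3
    variants_per_cre: float = 3.0  # Poisson mean, outside TFBSs
    n_breaking_variants: int = 2  # first is a SNP, second an indel
    deletion: bool = True
    deletion_hom_samples: int = 1
    deletion_het_samples: int = 1
    depth_mean: float = 50.0
    depth_window: int = 500
    protein_noise_sd: float = 0.5
    protein_factor_sd: float = 0.3
    footprint_mu0: float = 1.0
    footprint_mu1: float = 8.0
    footprint_sd: float = 1.0
    bound_prob: float = 0.8
    accessibility_log_mean: float = np.log(50.0)
    accessibility_bm_rate: float = 0.1  # heritable (BM) variation of log accessibility
    accessibility_noise_sd: float = 0.02  # iid technical noise on log accessibility
    epsilon_frac: float = 0.01  # sample-branch length as fraction of tree height
    glands: bool = True
    single_gland_individual: bool = True  # first individual has right gland only
    promoter_len: int = 600
    enhancer_len: int = 800

    def lineage_names(self) -> list[str]:
        if self.n_lineages == len(_DEFAULT_LINEAGES):
            return list(_DEFAULT_LINEAGES)
        return [f"lineage{i + 1}" for i in range(self.n_lineages)]


# ---------------------------------------------------------------------------
# tree


def simulate_tree(n_lineages: int, samples_per_lineage: int, seed: int,
                  epsilon_frac: float = 0.01) -> dendropy.Tree:
    """Pure-birth lineage tree with each sample attached to its lineage tip.

    Sample branches have length epsilon_frac x tree height, so samples within
    a lineage are nearly (but not exactly) exchangeable under BM, keeping the
    contrast covariance model exactly satisfiable.
    """
    if n_lineages < 2 or samples_per_lineage < 1:
        raise ValueError("need n_lineages >= 2 and samples_per_lineage >= 1")
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(n_lineages=n_lineages)
    lineages = cfg.lineage_names()

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    # Yule process: split a random active tip at Exp(k)-distributed waits.
    root = tree.seed_node
    active = [root]
    birth_time = {root: 0.0}
    t = 0.0
    while len(active) < n_lineages:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(rng.integers(len(active)))
        node.edge.length = t - birth_time[node]
        for _ in range(2):
            child = node.new_child()
            birth_time[child] = t
            active.append(child)
    t_final = t + rng.exponential(1.0 / max(len(active), 1))
    height = t_final if t_final > 0 else 1.0
    eps = epsilon_frac * height
    for node, lin in zip(active, lineages):
        node.edge.length = t_final - birth_time[node]
        for k in range(samples_per_lineage):
            child = node.new_child(edge_length=eps)
            child.taxon = taxa.new_taxon(label=f"{lin}_{k + 1}")
    tree.is_rooted = True
    return tree


def random_binary_tree(n_tips: int, rng: np.random.Generator,
                       min_len: float = 0.1, max_len: float = 1.0) -> dendropy.Tree:
    """Random binary tree with uniform branch lengths (for oracle checks)."""
    if n_tips < 2:
        raise ValueError("need >= 2 tips")
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    leaves = [tree.seed_node]
    while len(leaves) < n_tips:
        node = leaves.pop(rng.integers(len(leaves)))
        for _ in range(2):
            child = node.new_child(edge_length=float(rng.uniform(min_len, max_len)))
            leaves.append(child)
    for i, leaf in enumerate(leaves):
        leaf.taxon = taxa.new_taxon(label=f"t{i + 1}")
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# expression


def simulate_expression(tree: dendropy.Tree, n_genes: int,
                        planted: list[PlantedEffect],
                        config: SimulationConfig, seed: int,
                        drivers: Optional[pd.DataFrame] = None):
    """Latent BM log-means plus planted driver contributions -> NB counts.

    Returns (counts, latents, gland_counts): ``latents`` holds per-gene tip
    log-mean deviations; ``gland_counts`` is a dict of left/right replicate
    matrices (summing, per individual, to independent draws around the same
    latent) when ``config.glands`` is set, else None. ``dispersion <= 0``
    collapses the NB noise to deterministic rounding of the mean.
    """
    rng = np.random.default_rng(seed)
    tr = ContrastTransformer(tree)
    tips = tr.tips
    genes = [f"VEN{i + 1:02d}" for i in range(n_genes)]
    for eff in planted:
        if eff.gene not in genes:
            raise ValueError(f"planted effect references unknown gene {eff.gene!r}")
    lat = pd.DataFrame(
        bm_sample(tr, config.bm_rate, rng, size=n_genes).T, index=genes, columns=tips
    )
    if drivers is not None:
        for eff in planted:
            key = f"{eff.feature_class}:{eff.gene}"
            lat.loc[eff.gene] += eff.effect_size * drivers.loc[key].reindex(tips).to_numpy()
    mean = config.base_mean * np.exp(lat)

    def draw(mu: np.ndarray) -> np.ndarray:
        if config.dispersion <= 0:
            return np.rint(mu).astype(np.int64)
        r = 1.0 / config.dispersion
        return rng.negative_binomial(r, r / (r + mu)).astype(np.int64)

    counts = pd.DataFrame(draw(mean.to_numpy()), index=genes, columns=tips)
    gland = None
    if config.glands:
        left = pd.DataFrame(draw(mean.to_numpy() / 2), index=genes, columns=tips)
        right = pd.DataFrame(draw(mean.to_numpy() / 2), index=genes, columns=tips)
        gland = {"left": left, "right": right}
        counts = left + right
    return counts, lat, gland


# ---------------------------------------------------------------------------
# genome layout


@dataclass
class CreAnnotation:
    genes: list[str]
    intervals: list[GenomicInterval]  # promoters, enhancers, ctcf, denovo peaks
    gene_spans: dict[str, GenomicInterval]
    chrom: str = "chrV"

    def cres_of(self, gene: str) -> list[GenomicInterval]:
        return [iv for iv in self.intervals if iv.gene == gene and
                iv.element_class in (ElementClass.PROMOTER, ElementClass.ENHANCER)]


def make_cre_annotation(genes: list[str], config: SimulationConfig,
                        rng: np.random.Generator,
                        must_have_enhancer: frozenset = frozenset()) -> CreAnnotation:
    """Lay genes on one chromosome: promoter + (probable) enhancer + CTCF site
    + a handful of unannotated peaks per 100-kb gene array."""
    intervals = []
    spans = {}
    chrom = "chrV"
    for i, g in enumerate(genes):
        a = i * 100_000
        spans[g] = GenomicInterval(chrom, a + 50_000, a + 53_000, f"SPAN_{g}", gene=g)
        intervals.append(GenomicInterval(chrom, a + 49_200, a + 49_200 + config.promoter_len,
                                         f"PRO_{g}", ElementClass.PROMOTER, g))
        if g in must_have_enhancer or rng.random() < config.enhancer_prob:
            intervals.append(GenomicInterval(chrom, a + 40_000, a + 40_000 + config.enhancer_len,
                                             f"ENH_{g}", ElementClass.ENHANCER, g))
        intervals.append(GenomicInterval(chrom, a + 45_000, a + 45_400,
                                         f"CTCF_{g}", ElementClass.CTCF, g))
        for k in range(4):
            s = a + 30_000 + int(rng.integers(0, 18_000))
            intervals.append(GenomicInterval(chrom, s, s + 400,
                                             f"PEAK_{g}_{k + 1}", ElementClass.OTHER, g))
    return CreAnnotation(genes, intervals, spans, chrom)


def _random_motifs(config: SimulationConfig, rng: np.random.Generator) -> list[Motif]:
    out = []
    for m in range(config.n_motifs):
        L = config.motif_length
        pfm = np.ones((4, L))
        for j in range(L):
            pfm[rng.integers(4), j] = 18.0
        out.append(Motif(f"MA{m + 1:04d}.1", f"TF{m + 1:02d}", pfm))
    return out


# ---------------------------------------------------------------------------
# regulatory layers


@dataclass
class SyntheticTruth:
    planted_effects: list[PlantedEffect]
    motif_breaking: list[dict]  # {'variant', 'motif_id', 'tfbs'}
    deletion_interval: Optional[GenomicInterval]
    deletion_samples: dict[str, str]  # sample -> 'hom' | 'het'
    bound_truth: Optional[pd.DataFrame]  # TFBS x samples binary
    dispersion: float
    depth_mean: float
    seed: int


@dataclass
class Bundle:
    """A complete in-memory input set plus its ground truth."""

    config: SimulationConfig
    seed: int
    tree: dendropy.Tree
    meta: list[SampleMeta]
    gland_meta: list[SampleMeta]
    counts: pd.DataFrame  # combined per individual
    gland_counts: Optional[dict[str, pd.DataFrame]]
    latents: pd.DataFrame
    annotation: CreAnnotation
    accessibility: ScoreMatrix
    footprint_scores: ScoreMatrix
    tfbs_motif: dict[str, str]  # TFBS name -> motif_id
    tf_of: dict[str, str]  # TFBS name -> TF name
    variants: list[Variant]
    cre_sequences: dict[str, str]  # CRE name -> reference sequence
    motifs: list[Motif]
    depth: DepthProfile
    protein: pd.DataFrame
    tf_genes: list[str]
    venom_genes: list[str]
    truth: SyntheticTruth

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _lineage_of(sample: str) -> str:
    return sample.rsplit("_", 1)[0]


def simulate_regulatory_layers(tree: dendropy.Tree, annotation: CreAnnotation,
                               config: SimulationConfig, seed: int,
                               drivers: Optional[pd.DataFrame] = None,
                               norm_expression: Optional[pd.DataFrame] = None):
    """Accessibility, footprints, variants, sequences, depth and protein layers.

    See :class:`SimulationConfig` for the knobs. Returns a dict of layers plus
    the partial truth record.
    """
    from .cre import scan_motifs  # local import to avoid a cycle at module load

    rng = np.random.default_rng(seed)
    tr = ContrastTransformer(tree)
    samples = tr.tips
    lineages = sorted({_lineage_of(s) for s in samples})
    motifs = _random_motifs(config, rng)
    by_id = {m.motif_id: m for m in motifs}

    # ---- CRE sequences with planted TFBS consensi ----
    cre_seqs: dict[str, str] = {}
    tfbs_intervals: list[GenomicInterval] = []
    tfbs_motif: dict[str, str] = {}
    tf_of: dict[str, str] = {}
    cres = [iv for iv in annotation.intervals
            if iv.element_class in (ElementClass.PROMOTER, ElementClass.ENHANCER)]
    for cre in cres:
        seq = list(_random_seq(len(cre), rng))
        L = config.motif_length
        slots = np.linspace(10, len(cre) - L - 10, config.tfbs_per_cre).astype(int)
        for k, off in enumerate(slots):
            motif = motifs[int(rng.integers(len(motifs)))]
            seq[off:off + L] = list(motif.consensus())
            name = f"TFBS_{cre.name}_{k + 1}"
            tfbs_intervals.append(GenomicInterval(cre.chrom, cre.start + off,
                                                  cre.start + off + L, name,
                                                  ElementClass.OTHER, cre.gene))
            tfbs_motif[name] = motif.motif_id
            tf_of[name] = motif.tf_name
        cre_seqs[cre.name] = "".join(seq)

    # ---- variants (outside TFBSs), lineage-structured genotypes ----
    variants: list[Variant] = []
    tfbs_by_cre: dict[str, list[GenomicInterval]] = {}
    for iv in tfbs_intervals:
        cre = next(c for c in cres if c.contains_point(iv.start))
        tfbs_by_cre.setdefault(cre.name, []).append(iv)

    def random_genotypes() -> dict[str, Genotype]:
        mode = rng.random()
        if mode < 0.4:  # singleton
            carrier = samples[int(rng.integers(len(samples)))]
            return {s: (Genotype.HET if s == carrier else Genotype.HOM_REF) for s in samples}
        lin = lineages[int(rng.integers(len(lineages)))]
        out = {}
        for s in samples:
            if _lineage_of(s) == lin:
                out[s] = Genotype.HOM_ALT if rng.random() < 0.5 else Genotype.HET
            else:
                out[s] = Genotype.HOM_REF
        return out

    for cre in cres:
        seq = cre_seqs[cre.name]
        blocked = [(iv.start - cre.start, iv.end - cre.start) for iv in
                   tfbs_by_cre.get(cre.name, [])]
        n_var = int(rng.poisson(config.variants_per_cre))
        taken: list[tuple[int, int]] = list(blocked)
        placed = 0
        attempts = 0
        while placed < n_var and attempts < 50 * max(n_var, 1):
            attempts += 1
            off = int(rng.integers(0, len(seq)))
            if any(a <= off < b for a, b in taken):
                continue
            ref = seq[off]
            alt = _BASES[(_BASES.index(ref) + 1 + int(rng.integers(3))) % 4]
            variants.append(Variant(cre.chrom, cre.start + off + 1, ref, alt,
                                    random_genotypes()))
            taken.append((off, off + 1))
            placed += 1

    # ---- motif-breaking variants inside TFBSs ----
    breaking: list[dict] = []
    breaking_var: dict[str, Variant] = {}
    candidates = list(tfbs_intervals)
    rng.shuffle(candidates)
    breaking_tfbs: list[GenomicInterval] = []
    for idx in range(config.n_breaking_variants):
        want_indel = idx % 2 == 1
        made = None
        for iv in candidates:
            if iv in breaking_tfbs:
                continue
            cre = next(c for c in cres if c.contains_point(iv.start))
            seq = cre_seqs[cre.name]
            motif = by_id[tfbs_motif[iv.name]]
            off = iv.start - cre.start + motif.length // 2
            lin = lineages[(idx + 1) % len(lineages)]
            genos = {s: (Genotype.HOM_ALT if _lineage_of(s) == lin else Genotype.HOM_REF)
                     for s in samples}
            if want_indel:
                if off + 3 > len(seq):
                    continue
                ref, alt = seq[off:off + 3], seq[off]
            else:
                ref = seq[off]
                col = motif.pfm[:, motif.length // 2]
                alt = _BASES[int(col.argmin())]
                if alt == ref:
                    alt = _BASES[(int(col.argmin()) + 1) % 4]
            var = Variant(cre.chrom, cre.start + off + 1, ref, alt, genos)
            # verify the alt allele really destroys the motif hit in its window
            w0 = max(0, (off) - (motif.length - 1))
            w1 = min(len(seq), off + len(ref) + motif.length - 1)
            alt_win = seq[w0:off] + alt + seq[off + len(ref):w1]
            ref_hits = scan_motifs(seq[w0:w1], [motif])
            alt_hits = scan_motifs(alt_win, [motif])
            if ref_hits and not alt_hits:
                made = (var, iv, motif)
                break
        if made is None:
            raise ValueError("could not place a motif-breaking variant inside any motif hit")
        var, iv, motif = made
        variants.append(var)
        breaking_tfbs.append(iv)
        breaking_var[iv.name] = var
        breaking.append({"variant": f"{var.chrom}:{var.pos}:{var.ref_allele}>{var.alt_allele}",
                         "motif_id": motif.motif_id, "tfbs": iv.name})

    # ---- accessibility scores: heritable (BM) log-variation + technical noise ----
    planted_by_peak: dict[str, str] = {}
    if drivers is not None:
        for key in drivers.index:
            cls, gene = key.split(":", 1)
            if cls == "cre_accessibility":
                planted_by_peak[f"ENH_{gene}"] = key
    n_peaks = len(annotation.intervals)
    acc_bm = bm_sample(tr, config.accessibility_bm_rate, rng, n_peaks).T  # peaks x samples
    acc_log = (config.accessibility_log_mean + acc_bm
               + rng.normal(0.0, config.accessibility_noise_sd, (n_peaks, len(samples))))
    acc_df = pd.DataFrame(np.exp(acc_log),
                          index=[iv.name for iv in annotation.intervals], columns=samples)
    for name, key in planted_by_peak.items():
        # the driver latent is the log-accessibility of the planted enhancer
        z = drivers.loc[key].reindex(samples).to_numpy()
        acc_df.loc[name] = np.exp(config.accessibility_log_mean + z)
    accessibility = ScoreMatrix(list(annotation.intervals), acc_df)

    # ---- footprint scores coupled to genotype ----
    bound = pd.DataFrame(0, index=[iv.name for iv in tfbs_intervals],
                         columns=samples, dtype=np.int8)
    breaking_names = set(breaking_var)
    for iv in tfbs_intervals:
        if iv.name in breaking_names:
            carriers = set(breaking_var[iv.name].carriers())
            bound.loc[iv.name] = [0 if s in carriers else 1 for s in samples]
            continue
        lin_state = {lin: int(rng.random() < config.bound_prob) for lin in lineages}
        bound.loc[iv.name] = [lin_state[_lineage_of(s)] for s in samples]
    mu = np.where(bound.to_numpy() == 1, config.footprint_mu1, config.footprint_mu0)
    fp_vals = rng.normal(mu, config.footprint_sd)
    footprint_scores = ScoreMatrix(list(tfbs_intervals),
                                   pd.DataFrame(fp_vals, index=bound.index, columns=samples))

    # ---- deletion + depth ----
    deletion_interval = None
    deletion_samples: dict[str, str] = {}
    enhancers = [iv for iv in annotation.intervals if iv.element_class == ElementClass.ENHANCER]
    depth = None
    if config.deletion and enhancers:
        target = enhancers[len(enhancers) // 2]
        deletion_interval = GenomicInterval(target.chrom, target.start - 1500,
                                            target.end + 1500, f"DEL_{target.name}")
        pool = [s for s in samples]
        for k in range(config.deletion_hom_samples):
            deletion_samples[pool[k]] = "hom"
        for k in range(config.deletion_het_samples):
            deletion_samples[pool[config.deletion_hom_samples + k]] = "het"
        region_start = (deletion_interval.start // config.depth_window - 10) * config.depth_window
        region_end = ((deletion_interval.end // config.depth_window) + 11) * config.depth_window
        windows = [GenomicInterval(target.chrom, s, s + config.depth_window,
                                   f"W{(s - region_start) // config.depth_window + 1:03d}")
                   for s in range(max(0, region_start), region_end, config.depth_window)]
        dep = np.empty((len(windows), len(samples)))
        for j, s in enumerate(samples):
            factor = np.ones(len(windows))
            state = deletion_samples.get(s)
            if state:
                hit = np.array([w.overlaps(deletion_interval) for w in windows])
                factor[hit] = 0.02 if state == "hom" else 0.5
            dep[:, j] = rng.poisson(config.depth_mean * factor)
        depth = DepthProfile(windows, pd.DataFrame(dep, index=[w.name for w in windows],
                                                   columns=samples))

    # ---- protein abundances ----
    protein = None
    if norm_expression is not None:
        factors = np.exp(rng.normal(0.0, config.protein_factor_sd, norm_expression.shape[0]))
        noise = np.exp(rng.normal(0.0, config.protein_noise_sd, norm_expression.shape))
        protein = norm_expression.mul(factors, axis=0) * noise

    truth = SyntheticTruth(
        planted_effects=list(config.planted_effects),
        motif_breaking=breaking,
        deletion_interval=deletion_interval,
        deletion_samples=deletion_samples,
        bound_truth=bound,
        dispersion=config.dispersion,
        depth_mean=config.depth_mean,
        seed=seed,
    )
    return {
        "motifs": motifs,
        "cre_sequences": cre_seqs,
        "tfbs_intervals": tfbs_intervals,
        "tfbs_motif": tfbs_motif,
        "tf_of": tf_of,
        "variants": variants,
        "accessibility": accessibility,
        "footprint_scores": footprint_scores,
        "depth": depth,
        "protein": protein,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# full bundle


def build_bundle(config: Optional[SimulationConfig] = None, seed: int = 0) -> Bundle:
    """Generate a complete, internally consistent input bundle."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    tree_seed, expr_seed, layer_seed = (int(x) for x in
                                        rng.integers(0, 2**31 - 1, size=3))
    tree = simulate_tree(config.n_lineages, config.samples_per_lineage, tree_seed,
                         config.epsilon_frac)
    tr = ContrastTransformer(tree)
    samples = tr.tips

    genes = [f"VEN{i + 1:02d}" for i in range(config.n_genes)]
    tf_genes = [f"TFG{i + 1:02d}" for i in range(config.n_tfs)]
    bg_genes = [f"BG{i + 1:03d}" for i in range(config.n_background_genes)]

    # planted regulatory drivers evolve by BM on the tree
    drng = np.random.default_rng(expr_seed + 1)
    driver_rows = {}
    for eff in config.planted_effects:
        key = f"{eff.feature_class}:{eff.gene}"
        driver_rows[key] = bm_sample(tr, config.driver_rate, drng, 1)[:, 0]
    drivers = (pd.DataFrame(driver_rows, index=samples).T
               if driver_rows else None)

    counts, latents, gland = simulate_expression(tree, config.n_genes,
                                                 config.planted_effects, config,
                                                 expr_seed, drivers)
    # TF + background expression
    aux_rng = np.random.default_rng(expr_seed + 2)
    tf_lat = pd.DataFrame(bm_sample(tr, config.bm_rate, aux_rng, len(tf_genes)).T,
                          index=tf_genes, columns=samples)
    if drivers is not None:
        for eff in config.planted_effects:
            if eff.feature_class == "tf_expression":
                # surface the driver as the first TF's expression
                tf_lat.iloc[0] = drivers.loc[f"tf_expression:{eff.gene}"]
    bg_lat = pd.DataFrame(aux_rng.normal(0, 0.1, (len(bg_genes), len(samples))),
                          index=bg_genes, columns=samples)
    aux_lat = pd.concat([tf_lat, bg_lat])
    aux_mean = config.base_mean * np.exp(aux_lat)
    if config.dispersion <= 0:
        aux_counts = pd.DataFrame(np.rint(aux_mean.to_numpy()).astype(np.int64),
                                  index=aux_lat.index, columns=samples)
        if gland is not None:
            aux_l = pd.DataFrame(np.rint(aux_mean.to_numpy() / 2).astype(np.int64),
                                 index=aux_lat.index, columns=samples)
            aux_r = aux_counts - aux_l
    else:
        r = 1.0 / config.dispersion
        if gland is not None:
            aux_l = pd.DataFrame(aux_rng.negative_binomial(
                r, r / (r + aux_mean.to_numpy() / 2)).astype(np.int64),
                index=aux_lat.index, columns=samples)
            aux_r = pd.DataFrame(aux_rng.negative_binomial(
                r, r / (r + aux_mean.to_numpy() / 2)).astype(np.int64),
                index=aux_lat.index, columns=samples)
            aux_counts = aux_l + aux_r
        else:
            aux_counts = pd.DataFrame(aux_rng.negative_binomial(
                r, r / (r + aux_mean.to_numpy())).astype(np.int64),
                index=aux_lat.index, columns=samples)
    counts = pd.concat([counts, aux_counts])
    if gland is not None:
        gland = {"left": pd.concat([gland["left"], aux_l]),
                 "right": pd.concat([gland["right"], aux_r])}
        if config.single_gland_individual:
            solo = samples[0]
            gland["left"] = gland["left"].drop(columns=[solo])
            counts = counts.copy()
            counts[solo] = gland["right"][solo]

    forced = frozenset(e.gene for e in config.planted_effects
                       if e.feature_class == "cre_accessibility")
    annotation = make_cre_annotation(genes, config, np.random.default_rng(layer_seed + 1),
                                     must_have_enhancer=forced)
    # normalized (count-scale) expression feeds the protein layer
    sf = counts.sum(axis=0) / counts.sum(axis=0).median()
    norm_counts = counts.div(sf, axis=1)
    layers = simulate_regulatory_layers(tree, annotation, config, layer_seed,
                                        drivers, norm_counts.loc[genes])

    meta = []
    lin_names = config.lineage_names()
    populations = {lin: f"pop{i + 1}" for i, lin in enumerate(lin_names)}
    for s in samples:
        lin = _lineage_of(s)
        meta.append(SampleMeta(s, lin, populations.get(lin, ""), GlandSide.COMBINED, s))
    gland_meta = []
    if gland is not None:
        for side, mat in (("left", gland["left"]), ("right", gland["right"])):
            for s in mat.columns:
                lin = _lineage_of(s)
                gland_meta.append(SampleMeta(f"{s}_{side[0].upper()}", lin,
                                             populations.get(lin, ""),
                                             GlandSide(side), s))

    return Bundle(
        config=config, seed=seed, tree=tree, meta=meta, gland_meta=gland_meta,
        counts=counts, gland_counts=gland, latents=latents, annotation=annotation,
        accessibility=layers["accessibility"],
        footprint_scores=layers["footprint_scores"],
        tfbs_motif=layers["tfbs_motif"], tf_of=layers["tf_of"],
        variants=layers["variants"], cre_sequences=layers["cre_sequences"],
        motifs=layers["motifs"], depth=layers["depth"], protein=layers["protein"],
        tf_genes=tf_genes, venom_genes=genes, truth=layers["truth"],
    )


# ---------------------------------------------------------------------------
# bundle persistence


def write_bundle(bundle: Bundle, outdir) -> None:
    """Write the bundle as plain-text files (TSV/BED/VCF/FASTA/Newick/JSON)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rio.write_counts_tsv(bundle.counts, out / "counts.tsv")
    if bundle.gland_counts:
        rio.write_counts_tsv(bundle.gland_counts["left"], out / "counts_left.tsv")
        rio.write_counts_tsv(bundle.gland_counts["right"], out / "counts_right.tsv")
    rio.write_sample_meta(bundle.meta, out / "meta.tsv")
    if bundle.gland_meta:
        rio.write_sample_meta(bundle.gland_meta, out / "meta_glands.tsv")
    rio.write_newick(bundle.tree, out / "tree.nwk")
    rio.write_bed(bundle.annotation.intervals, out / "peaks.bed")
    rio.write_matrix_tsv(bundle.accessibility.values, out / "accessibility.tsv", "peak")
    fp_ivs = bundle.footprint_scores.intervals
    with open(out / "tfbs.bed", "w") as fh:
        for iv in fp_ivs:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t"
                     f"{bundle.tfbs_motif[iv.name]}\t{bundle.tf_of[iv.name]}\n")
    rio.write_matrix_tsv(bundle.footprint_scores.values, out / "footprints.tsv", "tfbs")
    contigs = {bundle.annotation.chrom: (len(bundle.annotation.genes) + 1) * 100_000}
    rio.write_vcf_minimal(bundle.variants, bundle.samples, out / "variants.vcf", contigs)
    rio.write_fasta(bundle.cre_sequences, out / "cres.fa")
    rio.write_jaspar_pfm(bundle.motifs, out / "motifs.jaspar")
    if bundle.depth is not None:
        dep = bundle.depth.depth.copy()
        meta_cols = pd.DataFrame({
            "chrom": [w.chrom for w in bundle.depth.windows],
            "start": [w.start for w in bundle.depth.windows],
            "end": [w.end for w in bundle.depth.windows],
        }, index=dep.index)
        pd.concat([meta_cols, dep], axis=1).to_csv(out / "depth.tsv", sep="\t",
                                                   index_label="window",
                                                   float_format="%.10g")
    if bundle.protein is not None:
        rio.write_matrix_tsv(bundle.protein, out / "protein.tsv", "gene")
    ann = {
        "venom_genes": bundle.venom_genes,
        "tf_genes": bundle.tf_genes,
        "class_map": {iv.name: iv.element_class.value for iv in bundle.annotation.intervals},
        "gene_map": {iv.name: iv.gene for iv in bundle.annotation.intervals},
    }
    (out / "annotation.json").write_text(json.dumps(ann, indent=1, sort_keys=True))
    truth = bundle.truth
    truth_json = {
        "planted_effects": [dataclasses.asdict(e) for e in truth.planted_effects],
        "motif_breaking": truth.motif_breaking,
        "deletion_interval": (None if truth.deletion_interval is None else
                              [truth.deletion_interval.chrom, truth.deletion_interval.start,
                               truth.deletion_interval.end]),
        "deletion_samples": truth.deletion_samples,
        "dispersion": truth.dispersion,
        "depth_mean": truth.depth_mean,
        "seed": truth.seed,
    }
    (out / "truth.json").write_text(json.dumps(truth_json, indent=1, sort_keys=True))
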