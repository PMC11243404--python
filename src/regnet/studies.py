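"""Validation studies quantifying the pipeline's statistical behavior.

Each study regenerates its inputs from a seed, runs the relevant pipeline
stage end to end, and measures agreement with an independent oracle or with
the generator's ground truth:

* contrast-operator exactness against the Brownian-motion covariance model;
* calibration of standardized-contrast variance and of the per-gene model's
  type-I error;
* recovery of planted regulatory drivers as a function of effect size;
* nucleotide diversity and motif scanning against brute-force oracles;
* genotype-footprint consistency, deletion recovery, CLR/FDR limit checks;
* byte-level determinism of the full pipeline.

The oracles here are deliberately naive re-implementations (per-window loops,
pairwise column counting, dense linear algebra) kept independent of the
production code paths they check.
"""

from __future__ import annotations

import filecmp
import tempfile
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .cre import nucleotide_diversity, scan_motifs
from .expression import benjamini_hochberg, normalize
from .footprints import binarize_footprints, intersect_bound_variants
from .phylo import ContrastTransformer, bm_sample
from .pipeline import deletion_calls, fit_single_gene, full_pipeline, run_fig4_matrix
from .proteo import clr_transform, mrna_protein_fit, pair_abundances
from .simulate import (
    DEFAULT_EFFECT_SIZE,
    EFFECT_SIZE_GRID,
    Motif,
    PlantedEffect,
    SimulationConfig,
    build_bundle,
    random_binary_tree,
    simulate_tree,
    write_bundle,
)


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.default_rng([seed, k]).integers(0, 2**31 - 1))


# ---------------------------------------------------------------------------
# 1. contrast operator exactness


def pic_whitening_study(seed: int, n_trees: int = 200, max_tips: int = 12) -> dict:
    """Max deviation of T C T' from identity and of the contrast sum of squares
    from the GLS quadratic form, over random trees."""
    rng = np.random.default_rng(_sub_seed(seed, 1))
    max_gram = 0.0
    max_qf = 0.0
    for _ in range(n_trees):
        tree = random_binary_tree(int(rng.integers(3, max_tips + 1)), rng)
        tr = ContrastTransformer(tree)
        C = tr.bm_covariance()
        gram = tr.matrix @ C @ tr.matrix.T
        max_gram = max(max_gram, float(np.abs(gram - np.eye(gram.shape[0])).max()))
        x = rng.normal(size=C.shape[0])
        Cinv = np.linalg.inv(C)
        one = np.ones(C.shape[0])
        mu = one @ Cinv @ x / (one @ Cinv @ one)
        qf = (x - mu) @ Cinv @ (x - mu)
        max_qf = max(max_qf, float(abs((tr.transform(x) ** 2).sum() - qf)))
    return {"max_whitening_dev": max_gram, "max_quadform_dev": max_qf, "n": n_trees}


# ---------------------------------------------------------------------------
# 2. BM contrast variance calibration


def bm_calibration_study(seed: int, n_reps: int = 1000, rate: float = 0.7) -> dict:
    """Pooled variance of standardized contrasts under BM with known rate."""
    rng = np.random.default_rng(_sub_seed(seed, 2))
    tree = simulate_tree(4, 3, seed=_sub_seed(seed, 20))
    tr = ContrastTransformer(tree)
    contrasts = tr.matrix @ bm_sample(tr, rate, rng, size=n_reps)
    n = contrasts.size
    var = float(contrasts.var(ddof=1))
    se = rate * np.sqrt(2.0 / (n - 1))
    return {"variance": var, "rate": rate, "z": (var - rate) / se, "n": n}


# ---------------------------------------------------------------------------
# 3. null calibration of the per-gene model


def null_calibration_study(seed: int, n_genes: int = 1000,
                           genes_per_bundle: int = 100) -> dict:
    """Per-class false-positive rate of the end-to-end per-gene model on null
    bundles whose traits follow the BM model exactly (measurement noise off)."""
    per_class_hits: dict[str, int] = {}
    per_class_n: dict[str, int] = {}
    n_bundles = int(np.ceil(n_genes / genes_per_bundle))
    for b in range(n_bundles):
        cfg = SimulationConfig(n_genes=genes_per_bundle, dispersion=0.0, deletion=False)
        bundle = build_bundle(cfg, seed=_sub_seed(seed, 100 + b))
        fig4, _ = run_fig4_matrix(bundle)
        for cls, grp in fig4.groupby("class"):
            per_class_hits[cls] = per_class_hits.get(cls, 0) + int((grp["p"] < 0.05).sum())
            per_class_n[cls] = per_class_n.get(cls, 0) + len(grp)
    fpr = {cls: per_class_hits[cls] / per_class_n[cls] for cls in per_class_hits}
    pooled = sum(per_class_hits.values()) / sum(per_class_n.values())
    return {"per_class_fpr": fpr, "per_class_n": per_class_n, "pooled_fpr": pooled}


# ---------------------------------------------------------------------------
# 4. planted-effect recovery


def effect_recovery_study(seed: int, n_reps: int = 200,
                          effect_sizes=EFFECT_SIZE_GRID,
                          gene: str = "VEN05") -> dict:
    """Fraction of replicates in which the planted class has the smallest p.

    The same replicate seeds are reused across effect sizes (common random
    numbers), so the recovery-vs-effect-size curve is a paired comparison.
    """
    rates = {}
    for beta in effect_sizes:
        wins = 0
        for r in range(n_reps):
            cfg = SimulationConfig(
                n_genes=8, n_background_genes=200, deletion=False,
                planted_effects=[PlantedEffect(gene, "cre_accessibility", float(beta))])
            bundle = build_bundle(cfg, seed=_sub_seed(seed, 1000 + r))
            res = fit_single_gene(bundle, gene)
            wins += int(res.table["p"].idxmin() == "cre_accessibility")
        rates[float(beta)] = wins / n_reps
    return {"recovery_by_effect": rates,
            "default_effect": float(DEFAULT_EFFECT_SIZE),
            "default_recovery": rates[float(DEFAULT_EFFECT_SIZE)],
            "n_reps": n_reps}


# ---------------------------------------------------------------------------
# 5. nucleotide diversity oracle


def _pi_brute_force(seqs: dict[str, str]) -> float:
    names = sorted(seqs)
    total = 0.0
    for a, b in combinations(names, 2):
        d = L = 0
        for x, y in zip(seqs[a], seqs[b]):
            if x in "ACGT" and y in "ACGT":
                L += 1
                d += x != y
        total += d / L if L else 0.0
    n = len(names)
    return total / (n * (n - 1) / 2)


def pi_oracle_study(seed: int, n_alignments: int = 100) -> dict:
    rng = np.random.default_rng(_sub_seed(seed, 5))
    max_dev = 0.0
    done = 0
    while done < n_alignments:
        n = int(rng.integers(2, 9))
        L = int(rng.integers(5, 101))
        seqs = {f"s{i}": "".join(rng.choice(list("ACGTN"), p=[.24, .24, .24, .24, .04],
                                            size=L)) for i in range(n)}
        try:
            res = nucleotide_diversity(seqs)
        except ValueError:
            continue
        max_dev = max(max_dev, abs(res.pi - _pi_brute_force(seqs)))
        done += 1
    return {"max_abs_dev": max_dev, "n": n_alignments}


# ---------------------------------------------------------------------------
# 6. motif scanner oracle


def _naive_scan(seq: str, motif: Motif, threshold: float = 0.15, pseudo: float = 0.8):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    L = motif.length
    probs = (motif.pfm + pseudo) / (motif.pfm.sum(axis=0) + 4 * pseudo)
    lo = np.log(probs / motif.background[:, None])
    max_s, min_s = lo.max(axis=0).sum(), lo.min(axis=0).sum()
    hits = []
    for off in range(len(seq) - L + 1):
        window = seq[off:off + L]
        if "N" in window:
            continue
        for strand in "+-":
            w = window if strand == "+" else "".join(comp[c] for c in reversed(window))
            s = sum(lo["ACGT".index(c), j] for j, c in enumerate(w))
            if (s - min_s) / (max_s - min_s) >= 1 - threshold:
                hits.append((off, strand, s))
    return hits


def scanner_oracle_study(seed: int, n_pairs: int = 100) -> dict:
    rng = np.random.default_rng(_sub_seed(seed, 6))
    max_dev = 0.0
    mismatches = 0
    planted_missed = 0
    for _ in range(n_pairs):
        L = int(rng.integers(4, 10))
        pfm = rng.uniform(0.5, 4.0, (4, L))
        for j in range(L):
            pfm[rng.integers(4), j] += rng.uniform(2.0, 12.0)
        motif = Motif("M1", "TF", pfm)
        seq = "".join(rng.choice(list("ACGTN"), p=[.24, .24, .24, .24, .04], size=60))
        ours = sorted((h.offset, h.strand, h.score) for h in scan_motifs(seq, [motif]))
        oracle = sorted(_naive_scan(seq, motif))
        if [(o, s) for o, s, _ in ours] != [(o, s) for o, s, _ in oracle]:
            mismatches += 1
            continue
        if ours:
            max_dev = max(max_dev, max(abs(a[2] - b[2]) for a, b in zip(ours, oracle)))
        # planted consensus must always be hit
        bg = "".join(rng.choice(list("ACGT"), size=40))
        planted = bg[:15] + motif.consensus() + bg[15 + L:]
        hits = scan_motifs(planted, [motif])
        planted_missed += int(not any(h.offset == 15 and h.strand == "+" for h in hits))
    return {"max_score_dev": max_dev, "hit_set_mismatches": mismatches,
            "planted_missed": planted_missed, "n": n_pairs}


# ---------------------------------------------------------------------------
# 7. genotype-footprint consistency


def variant_footprint_study(seed: int, n_tfbs: int = 1000) -> dict:
    bundle = build_bundle(SimulationConfig(
        n_genes=10, n_background_genes=200,
        planted_effects=[PlantedEffect("VEN04", "cre_accessibility",
                                       DEFAULT_EFFECT_SIZE)]),
        seed=_sub_seed(seed, 7))
    occ = binarize_footprints(bundle.footprint_scores)
    inter = intersect_bound_variants(occ, bundle.variants)
    flagged = set(inter.loc[inter["differentially_bound"], "tfbs"])
    planted = {rec["tfbs"] for rec in bundle.truth.motif_breaking}
    # misclassification of the binarization at default mixture separation
    rng = np.random.default_rng(_sub_seed(seed, 70))
    truth = rng.integers(0, 2, size=(n_tfbs, 12))
    scores = rng.normal(np.where(truth == 1, 8.0, 1.0), 1.0)
    from .types import GenomicInterval, ScoreMatrix
    ivs = [GenomicInterval("c", 10 * i, 10 * i + 6, f"t{i}") for i in range(n_tfbs)]
    df = pd.DataFrame(scores, index=[iv.name for iv in ivs],
                      columns=[f"s{j}" for j in range(12)])
    occ2 = binarize_footprints(ScoreMatrix(ivs, df))
    mis = float((occ2.bound.to_numpy() != truth).mean())
    return {"flagged_equals_planted": float(flagged == planted),
            "n_flagged": len(flagged), "n_planted": len(planted),
            "misclassification_rate": mis, "n_scored": int(truth.size)}


# ---------------------------------------------------------------------------
# 8. deletion recovery


def deletion_recovery_study(seed: int) -> dict:
    bundle = build_bundle(SimulationConfig(n_genes=10, n_background_genes=200),
                          seed=_sub_seed(seed, 8))
    calls = deletion_calls(bundle)
    truth = bundle.truth.deletion_samples
    expected = {s: {"hom": "hom_del", "het": "het_del"}.get(truth.get(s), "none")
                for s in calls.index}
    correct = sum(calls.loc[s, "call"] == expected[s] for s in calls.index)
    query = bundle.truth.deletion_interval
    n_del_windows = sum(w.overlaps(query) for w in bundle.depth.windows)
    hom = next(s for s, st in truth.items() if st == "hom")
    boundary_dev = abs(int(calls.loc[hom, "run_length"]) - n_del_windows)
    return {"call_accuracy": correct / len(calls.index),
            "boundary_dev_windows": boundary_dev, "n_samples": len(calls.index)}


# ---------------------------------------------------------------------------
# 9. CLR / BH limit checks


def clr_bh_study(seed: int, n_compositions: int = 200) -> dict:
    rng = np.random.default_rng(_sub_seed(seed, 9))
    max_zero_sum = 0.0
    max_scale_dev = 0.0
    for _ in range(n_compositions):
        x = rng.uniform(0.01, 100.0, size=int(rng.integers(2, 30)))
        out = clr_transform(x)
        max_zero_sum = max(max_zero_sum, abs(float(out.sum())))
        alpha = float(rng.uniform(0.01, 50.0))
        max_scale_dev = max(max_scale_dev,
                            float(np.abs(clr_transform(alpha * x) - out).max()))
    # zero-noise bundle: mRNA and protein compositions coincide exactly
    cfg = SimulationConfig(n_genes=12, n_background_genes=100, dispersion=0.0,
                           protein_noise_sd=0.0, protein_factor_sd=0.0, deletion=False)
    bundle = build_bundle(cfg, seed=_sub_seed(seed, 90))
    norm = normalize(bundle.counts)
    mrna = bundle.counts.div(norm.size_factors, axis=1).loc[bundle.venom_genes]
    _, _, r2 = mrna_protein_fit(pair_abundances(mrna, bundle.protein))
    # BH step-up oracle
    max_bh_dev = 0.0
    for _ in range(50):
        p = rng.uniform(size=int(rng.integers(1, 60)))
        ours = benjamini_hochberg(p)
        m = len(p)
        order = np.argsort(p, kind="stable")
        ref = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            running = min(running, p[order[rank - 1]] * m / rank)
            ref[order[rank - 1]] = running
        max_bh_dev = max(max_bh_dev, float(np.abs(ours - ref).max()))
    return {"clr_max_zero_sum_dev": max_zero_sum,
            "clr_max_scale_dev": max_scale_dev,
            "zero_noise_r2": float(r2),
            "bh_max_dev": max_bh_dev,
            "n": n_compositions}


# ---------------------------------------------------------------------------
# 10. determinism


def determinism_study(seed: int, workdir=None) -> dict:
    """Full pipeline on the default bundle, twice; outputs must be identical."""
    base = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="regnet_det_"))
    identical = True
    n_files = 0
    dirs = []
    for run in ("run1", "run2"):
        bundle = build_bundle(SimulationConfig(), seed=_sub_seed(seed, 10))
        out = base / run
        write_bundle(bundle, out / "bundle")
        full_pipeline(bundle, out / "results")
        dirs.append(out)
    for sub in ("bundle", "results"):
        a, b = dirs[0] / sub, dirs[1] / sub
        names = sorted(p.name for p in a.iterdir())
        if names != sorted(p.name for p in b.iterdir()):
            identical = False
            continue
        for name in names:
            n_files += 1
            if not filecmp.cmp(a / name, b / name, shallow=False):
                identical = False
    return {"identical": float(identical), "n_files_compared": n_files}
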