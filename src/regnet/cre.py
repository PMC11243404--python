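"""Cis-regulatory element sequence analyses.

Projects per-sample variants onto reference CRE sequences, computes
nucleotide diversity (pi) over the resulting consensus set, scans sequences
against PFM motif models on both strands, classifies variant-induced TFBS
gains/losses, and summarizes variable TFBS sharing across individuals in a
site-frequency-spectrum style histogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import edlib
import numpy as np
import pandas as pd

from .types import GenomicInterval, Genotype, Motif, Variant

logger = logging.getLogger(__name__)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP = str.maketrans("ACGTN", "TGCAN")


# ---------------------------------------------------------------------------
# consensus projection


def project_consensus(cre_sequence: str, variants: list[Variant], sample: str,
                      cre: GenomicInterval, het_policy: str = "alt") -> str:
    """Apply one sample's variant alleles to a reference CRE sequence.

    hom_alt substitutes the alt allele; heterozygotes substitute alt as well
    under the default policy ("alt" maximizes sensitivity for TFBS-change
    detection; pass ``het_policy="ref"`` to keep the reference base).
    Missing genotypes leave the reference. Indels shift later coordinates.
    """
    if het_policy not in ("alt", "ref"):
        raise ValueError("het_policy must be 'alt' or 'ref'")
    seq = cre_sequence.upper()
    if len(seq) != len(cre):
        raise ValueError(f"sequence length {len(seq)} != CRE span {len(cre)}")
    apply_gts = {Genotype.HOM_ALT}
    if het_policy == "alt":
        apply_gts.add(Genotype.HET)
    chosen = []
    for v in variants:
        if not v.interval.overlaps(cre):
            continue
        if v.interval.start < cre.start or v.interval.end > cre.end:
            logger.warning("variant %s:%d extends past CRE %s; skipped", v.chrom, v.pos, cre.name)
            continue
        if v.genotypes.get(sample, Genotype.MISSING) in apply_gts:
            chosen.append(v)
    chosen.sort(key=lambda v: v.pos)
    for a, b in zip(chosen, chosen[1:]):
        if a.interval.end > b.interval.start:
            raise ValueError(
                f"overlapping variants with conflicting ref alleles at positions "
                f"{a.pos} and {b.pos}"
            )
    out = []
    cursor = cre.start
    for v in chosen:
        off = v.interval.start - cre.start
        if seq[off:off + len(v.ref_allele)] != v.ref_allele:
            raise ValueError(
                f"ref allele mismatch at {v.chrom}:{v.pos}: sequence has "
                f"{seq[off:off + len(v.ref_allele)]!r}, variant says {v.ref_allele!r}"
            )
        out.append(seq[cursor - cre.start:off])
        out.append(v.alt_allele)
        cursor = v.interval.end
    out.append(seq[cursor - cre.start:])
    return "".join(out)


def build_consensus_set(cre_sequence: str, variants: list[Variant], samples: list[str],
                        cre: GenomicInterval, het_policy: str = "alt") -> dict[str, str]:
    """Per-sample projected sequences, with the reference included as 'reference'."""
    out = {"reference": cre_sequence.upper()}
    for s in samples:
        out[s] = project_consensus(cre_sequence, variants, s, cre, het_policy)
    return out


# ---------------------------------------------------------------------------
# alignment + nucleotide diversity


def _pairwise_aligned(query: str, ref: str) -> tuple[str, str]:
    res = edlib.align(query, ref, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, query, ref)
    return nice["query_aligned"], nice["target_aligned"]


def anchor_msa(seqs: dict[str, str], ref_key: str) -> dict[str, str]:
    """Reference-anchored multiple alignment for near-identical sequences.

    Each sequence is globally aligned to the reference; insertion columns are
    merged across sequences at their reference slot. Adequate for consensus
    sets that differ by a handful of small variants; not a general MSA.
    """
    ref = seqs[ref_key]
    L = len(ref)
    # per sequence: char at each ref position, plus insertions before each slot
    per_ref: dict[str, list[str]] = {}
    inserts: dict[str, list[str]] = {}
    max_ins = [0] * (L + 1)
    for name, s in seqs.items():
        if name == ref_key:
            per_ref[name] = list(ref)
            inserts[name] = [""] * (L + 1)
            continue
        qa, ta = _pairwise_aligned(s, ref)
        chars = []
        ins = [""] * (L + 1)
        ref_i = 0
        for qc, tc in zip(qa, ta):
            if tc == "-":
                ins[ref_i] += qc
            else:
                chars.append(qc)
                ref_i += 1
        per_ref[name] = chars
        inserts[name] = ins
        max_ins = [max(a, len(b)) for a, b in zip(max_ins, ins)]
    out = {}
    for name in seqs:
        parts = []
        for i in range(L + 1):
            block = inserts[name][i]
            parts.append(block + "-" * (max_ins[i] - len(block)))
            if i < L:
                parts.append(per_ref[name][i])
        out[name] = "".join(parts)
    return out


@dataclass
class DiversityResult:
    cre_name: str
    n_sequences: int
    pi: float
    n_compared_sites: float  # mean comparable columns over included pairs
    n_pairs: int = 0


def nucleotide_diversity(sequences: dict[str, str], cre_name: str = "",
                         ref_key: str = "reference") -> DiversityResult:
    """Average per-site pairwise difference over a consensus set.

    pi = [sum_{i<j} d_ij / L_ij] / C(n,2), where d_ij counts mismatches over
    columns where both sequences carry a non-gap, non-N base and L_ij is the
    number of such columns. Unequal-length inputs are aligned first
    (reference-anchored). Pairs with no comparable column are excluded with a
    warning; all pairs excluded is an error.
    """
    if len(sequences) < 2:
        raise ValueError("nucleotide diversity needs >= 2 sequences")
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) > 1:
        anchor = ref_key if ref_key in sequences else next(iter(sequences))
        aligned = anchor_msa(sequences, anchor)
    else:
        aligned = sequences
    names = sorted(aligned)
    arrs = {n: np.frombuffer(aligned[n].encode(), dtype=np.uint8) for n in names}
    ok_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    total = 0.0
    n_pairs = 0
    sites = []
    for a, b in combinations(names, 2):
        xa, xb = arrs[a], arrs[b]
        comparable = np.isin(xa, ok_codes) & np.isin(xb, ok_codes)
        L = int(comparable.sum())
        if L == 0:
            logger.warning("pair (%s, %s) has no comparable sites; excluded", a, b)
            continue
        d = int((xa[comparable] != xb[comparable]).sum())
        total += d / L
        sites.append(L)
        n_pairs += 1
    n_all = len(names) * (len(names) - 1) // 2
    if n_pairs == 0:
        raise ValueError("all sequence pairs lacked comparable sites")
    pi = total / n_all
    return DiversityResult(cre_name, len(names), pi, float(np.mean(sites)), n_pairs)


# ---------------------------------------------------------------------------
# motif scanning


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    offset: int  # 0-based window start on the forward sequence
    strand: str  # '+' or '-'
    score: float  # log-odds
    rel_score: float  # (score - min) / (max - min) in [0, 1]


def _log_odds(motif: Motif, pseudo: float) -> np.ndarray:
    col_tot = motif.pfm.sum(axis=0)
    probs = (motif.pfm + pseudo) / (col_tot + 4.0 * pseudo)
    return np.log(probs / motif.background[:, None])


def encode_sequence(seq: str) -> np.ndarray:
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    return np.frombuffer(seq.encode().translate(bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))),
                         dtype=np.uint8)


def scan_motifs(sequence: str, motifs: list[Motif],
                similarity_threshold: float = 0.15,
                pseudo: float = 0.8) -> list[MotifHit]:
    """Scan both strands for motif matches above the relative-score cutoff.

    Windows score the PFM log-odds against the background; the relative score
    rescales between the worst and best achievable window, and hits with
    relative score >= 1 - similarity_threshold (0.85 at the default) are
    retained. Windows containing N are skipped; degenerate motifs whose best
    and worst scores coincide are skipped with a warning.
    """
    codes = encode_sequence(sequence)
    hits: list[MotifHit] = []
    for motif in motifs:
        L = motif.length
        if len(codes) < L:
            continue
        lo = _log_odds(motif, pseudo)
        max_s, min_s = lo.max(axis=0).sum(), lo.min(axis=0).sum()
        if max_s - min_s <= 0:
            logger.warning("motif %s is degenerate (uniform columns); skipped", motif.motif_id)
            continue
        windows = np.lib.stride_tricks.sliding_window_view(codes, L)
        valid = ~(windows == 4).any(axis=1)
        lo_rc = lo[::-1, ::-1]  # reverse-complement strand
        for strand, mat in (("+", lo), ("-", lo_rc)):
            padded = np.vstack([mat, np.zeros(L)])  # row 4 = N placeholder
            scores = padded[windows, np.arange(L)].sum(axis=1)
            rel = (scores - min_s) / (max_s - min_s)
            for off in np.nonzero(valid & (rel >= 1.0 - similarity_threshold))[0]:
                hits.append(MotifHit(motif.motif_id, int(off), strand,
                                     float(scores[off]), float(rel[off])))
    hits.sort(key=lambda h: (h.offset, h.motif_id, h.strand))
    return hits


# ---------------------------------------------------------------------------
# variant-induced TFBS changes


@dataclass
class TFBSChange:
    variant: Variant
    motif_id: str
    change: str  # 'gained' | 'lost' | 'retained_changed_score'
    samples_with_alt: list[str] = field(default_factory=list)


def classify_tfbs_changes(cre_sequence: str, variants: list[Variant],
                          motifs: list[Motif], cre: GenomicInterval,
                          similarity_threshold: float = 0.15,
                          pseudo: float = 0.8,
                          score_delta: float = 1e-9) -> list[TFBSChange]:
    """Classify each variant's effect on motif matches around it.

    A window of +/-(max motif length - 1) around the variant is scanned on the
    reference-allele and alternate-allele sequences; motifs hit only on the
    reference are 'lost', only on the alternate 'gained', and hit on both with
    a best-score change >= ``score_delta`` 'retained_changed_score'.
    """
    if not motifs:
        return []
    seq = cre_sequence.upper()
    max_l = max(m.length for m in motifs)
    out: list[TFBSChange] = []
    for v in variants:
        if not v.interval.overlaps(cre):
            continue
        off = v.interval.start - cre.start
        if off < 0 or off + len(v.ref_allele) > len(seq):
            continue
        if seq[off:off + len(v.ref_allele)] != v.ref_allele:
            raise ValueError(f"ref allele mismatch at {v.chrom}:{v.pos}")
        w0 = max(0, off - (max_l - 1))
        w1 = min(len(seq), off + len(v.ref_allele) + (max_l - 1))
        ref_win = seq[w0:w1]
        alt_win = seq[w0:off] + v.alt_allele + seq[off + len(v.ref_allele):w1]
        ref_hits = scan_motifs(ref_win, motifs, similarity_threshold, pseudo)
        alt_hits = scan_motifs(alt_win, motifs, similarity_threshold, pseudo)
        ref_best = _best_by_motif(ref_hits)
        alt_best = _best_by_motif(alt_hits)
        for mid in sorted(set(ref_best) | set(alt_best)):
            if mid in ref_best and mid not in alt_best:
                change = "lost"
            elif mid in alt_best and mid not in ref_best:
                change = "gained"
            elif abs(ref_best[mid] - alt_best[mid]) >= score_delta:
                change = "retained_changed_score"
            else:
                continue
            out.append(TFBSChange(v, mid, change, sorted(v.carriers())))
    return out


def _best_by_motif(hits: list[MotifHit]) -> dict[str, float]:
    best: dict[str, float] = {}
    for h in hits:
        if h.motif_id not in best or h.score > best[h.motif_id]:
            best[h.motif_id] = h.score
    return best


# ---------------------------------------------------------------------------
# TFBS sharing spectrum


def tfbs_sharing_spectrum(presence: pd.DataFrame):
    """Site-frequency-spectrum-style summary of variable TFBS sharing.

    ``presence`` is a binary TFBS x individuals matrix. TFBSs shared by all or
    by none are excluded as non-variable; the histogram counts TFBSs by the
    number of individuals sharing them (1..n-1). Returns (spectrum dict,
    fraction_unique).
    """
    arr = presence.to_numpy()
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("presence matrix must be binary 0/1")
    n = presence.shape[1]
    shared = arr.sum(axis=1)
    variable = (shared > 0) & (shared < n)
    counts = shared[variable]
    spectrum = {k: int((counts == k).sum()) for k in range(1, n)}
    total = int(variable.sum())
    frac_unique = spectrum.get(1, 0) / total if total else float("nan")
    return spectrum, frac_unique
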