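"""CRE sequence analyses: consensus projection, pi, scanning, TFBS changes."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from regnet.cre import (
    anchor_msa,
    build_consensus_set,
    classify_tfbs_changes,
    nucleotide_diversity,
    project_consensus,
    scan_motifs,
    tfbs_sharing_spectrum,
)
from regnet.types import Genotype, GenomicInterval, Motif, Variant


def _var(pos, ref, alt, gt, sample="s1", chrom="chr1"):
    return Variant(chrom, pos, ref, alt, {sample: Genotype(gt)})


CRE = GenomicInterval("chr1", 0, 10, "cre1")


class TestProjectConsensus:
    def test_hom_alt_snp_substituted(self):
        out = project_consensus("AAAAACAAAA", [_var(6, "C", "T", "hom_alt")], "s1", CRE)
        assert out == "AAAAATAAAA"

    def test_two_bp_deletion_shortens(self):
        out = project_consensus("AAAAACTGAA", [_var(6, "CTG", "C", "hom_alt")], "s1", CRE)
        assert out == "AAAAACAA"
        assert len(out) == 10 - 2

    def test_missing_genotype_leaves_reference(self):
        out = project_consensus("AAAAACAAAA", [_var(6, "C", "T", "missing")], "s1", CRE)
        assert out == "AAAAACAAAA"

    def test_het_policy(self):
        v = _var(6, "C", "T", "het")
        assert project_consensus("AAAAACAAAA", [v], "s1", CRE)[5] == "T"
        assert project_consensus("AAAAACAAAA", [v], "s1", CRE, het_policy="ref")[5] == "C"

    def test_overlapping_variants_rejected(self):
        vs = [_var(5, "ACA", "A", "hom_alt"), _var(6, "C", "G", "hom_alt")]
        with pytest.raises(ValueError, match="overlapping"):
            project_consensus("AAAAACAAAA", vs, "s1", CRE)

    def test_ref_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            project_consensus("AAAAACAAAA", [_var(6, "G", "T", "hom_alt")], "s1", CRE)

    def test_coordinate_shift_after_indel(self):
        # deletion at offset 2 shifts the later SNP left by 2 in the output
        vs = [_var(3, "AAA", "A", "hom_alt", sample="s1"),
              _var(8, "A", "G", "hom_alt", sample="s1")]
        out = project_consensus("AAAAAAAAAA", vs, "s1", CRE)
        assert out == "AAAAAGAA"


def _pi_oracle(seqs: dict) -> float:
    """Independent O(n^2 L) brute force over aligned sequences."""
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


class TestNucleotideDiversity:
    def test_identical_sequences(self):
        res = nucleotide_diversity({"a": "ACGT", "b": "ACGT"})
        assert res.pi == 0.0

    def test_three_sequence_closed_form(self):
        res = nucleotide_diversity({"a": "AAAA", "b": "AAAT", "c": "AATT"})
        assert res.pi == pytest.approx((0.25 + 0.5 + 0.25) / 3)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            n = rng.integers(2, 8)
            L = rng.integers(5, 100)
            seqs = {f"s{i}": "".join(rng.choice(list("ACGTN"), p=[.24, .24, .24, .24, .04],
                                                size=L)) for i in range(n)}
            try:
                res = nucleotide_diversity(seqs)
            except ValueError:
                continue  # all pairs incomparable
            assert res.pi == pytest.approx(_pi_oracle(seqs), abs=1e-12)

    def test_indel_only_variation_gives_zero_pi(self):
        cre = GenomicInterval("chr1", 0, 20, "c")
        ref = "ACGTACGTACGTACGTACGT"
        v = Variant("chr1", 5, "ACG", "A", {"s1": Genotype.HOM_ALT, "s2": Genotype.HOM_REF})
        cons = build_consensus_set(ref, [v], ["s1", "s2"], cre)
        res = nucleotide_diversity(cons)
        assert res.pi == pytest.approx(0.0)

    def test_anchor_msa_places_gaps(self):
        seqs = {"reference": "AACCGGTT", "del": "AAGGTT", "ins": "AACCTTGGTT"}
        aligned = anchor_msa(seqs, "reference")
        assert len({len(s) for s in aligned.values()}) == 1
        # "del" carries its own 2-bp deletion plus the 2-column insertion slot
        assert aligned["del"].count("-") == 4
        assert aligned["reference"].count("-") == 2
        assert aligned["ins"].count("-") == 0 and len(aligned["ins"]) == 10


def _naive_scan(seq, motif, threshold=0.15, pseudo=0.8):
    """Independent per-window scanner used as the oracle."""
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
            rel = (s - min_s) / (max_s - min_s)
            if rel >= 1 - threshold:
                hits.append((motif.motif_id, off, strand, s))
    return hits


def _random_motif(rng, L=6, sharp=12.0):
    pfm = rng.uniform(0.5, 4.0, (4, L))
    for j in range(L):
        pfm[rng.integers(4), j] += sharp
    return Motif(f"M{rng.integers(1e6)}", "TF", pfm)


class TestScanMotifs:
    def test_consensus_sequence_scores_one(self, rng):
        m = _random_motif(rng)
        hits = scan_motifs(m.consensus(), [m])
        assert any(h.offset == 0 and h.strand == "+" and h.rel_score == pytest.approx(1.0)
                   for h in hits)

    def test_degenerate_motif_skipped(self):
        m = Motif("MU", "TF", np.ones((4, 5)))
        assert scan_motifs("ACGTACGTA", [m]) == []

    def test_non_acgtn_rejected_and_n_windows_skipped(self, rng):
        m = _random_motif(rng)
        with pytest.raises(ValueError, match="non-ACGTN"):
            scan_motifs("ACGTX", [m])
        seq = m.consensus()
        assert scan_motifs(seq[:2] + "N" + seq[3:], [m]) == []

    def test_planted_consensus_found_on_each_strand(self, rng):
        comp = str.maketrans("ACGT", "TGCA")
        for _ in range(10):
            m = _random_motif(rng)
            bg = "".join(rng.choice(list("ACGT"), size=40))
            fwd = bg[:17] + m.consensus() + bg[17 + m.length:]
            hits = scan_motifs(fwd, [m])
            assert any(h.offset == 17 and h.strand == "+" for h in hits)
            rc = m.consensus().translate(comp)[::-1]
            rev = bg[:17] + rc + bg[17 + m.length:]
            hits = scan_motifs(rev, [m])
            assert any(h.offset == 17 and h.strand == "-" for h in hits)

    def test_agrees_with_naive_oracle(self, rng):
        for _ in range(30):
            m = _random_motif(rng, L=int(rng.integers(4, 9)), sharp=float(rng.uniform(2, 12)))
            seq = "".join(rng.choice(list("ACGTN"), p=[.24, .24, .24, .24, .04], size=60))
            ours = [(h.motif_id, h.offset, h.strand, h.score) for h in scan_motifs(seq, [m])]
            oracle = _naive_scan(seq, m)
            assert len(ours) == len(oracle)
            for (mid, off, strand, s), (mid2, off2, strand2, s2) in zip(
                    sorted(ours, key=lambda h: (h[1], h[2])),
                    sorted(oracle, key=lambda h: (h[1], h[2]))):
                assert (mid, off, strand) == (mid2, off2, strand2)
                assert s == pytest.approx(s2, abs=1e-9)


class TestClassifyChanges:
    def _setup(self, rng):
        m = _random_motif(rng)
        cre = GenomicInterval("chr1", 100, 160, "cre")
        bg = "".join(rng.choice(list("ACGT"), size=60))
        seq = bg[:20] + m.consensus() + bg[20 + m.length:]
        return m, cre, seq

    def test_core_snp_reports_loss(self, rng):
        m, cre, seq = self._setup(rng)
        core = 20 + m.length // 2
        ref = seq[core]
        alt = "ACGT"[int(m.pfm[:, m.length // 2].argmin())]
        if alt == ref:
            alt = "ACGT"[(int(m.pfm[:, m.length // 2].argmin()) + 1) % 4]
        v = Variant("chr1", cre.start + core + 1, ref, alt, {"s1": Genotype.HOM_ALT})
        changes = classify_tfbs_changes(seq, [v], [m], cre)
        assert any(c.motif_id == m.motif_id and c.change == "lost" for c in changes)
        assert changes[0].samples_with_alt == ["s1"]

    def test_variant_far_from_motif_reports_nothing(self, rng):
        m, cre, seq = self._setup(rng)
        off = 45  # > motif length away from the planted hit
        alt = "A" if seq[off] != "A" else "C"
        v = Variant("chr1", cre.start + off + 1, seq[off], alt, {"s1": Genotype.HOM_ALT})
        changes = classify_tfbs_changes(seq, [v], [m], cre)
        assert all(c.change != "lost" or c.motif_id != m.motif_id for c in changes) \
            or changes == []

    def test_deletion_restoring_consensus_reports_gain(self, rng):
        m = _random_motif(rng)
        cons = m.consensus()
        cre = GenomicInterval("chr1", 0, 40, "cre")
        # consensus interrupted by 2 inserted bases; deleting them restores it
        seq = "TTTTT" + cons[:3] + "CA" + cons[3:] + "T" * (40 - 5 - m.length - 2 - 1) + "G"
        seq = seq[:40].ljust(40, "T")
        pos = 5 + 3  # 1-based pos of base before the insertion, 0-based offset 7
        v = Variant("chr1", pos, seq[pos - 1] + "CA", seq[pos - 1], {"s1": Genotype.HOM_ALT})
        changes = classify_tfbs_changes(seq, [v], [m], cre)
        assert any(c.motif_id == m.motif_id and c.change == "gained" for c in changes)

    def test_symmetry_under_allele_swap(self, rng):
        m, cre, seq = self._setup(rng)
        core = 20 + m.length // 2
        ref = seq[core]
        alt = "ACGT"[int(m.pfm[:, m.length // 2].argmin())]
        if alt == ref:
            alt = "ACGT"[(int(m.pfm[:, m.length // 2].argmin()) + 1) % 4]
        fwd = classify_tfbs_changes(seq, [Variant("chr1", cre.start + core + 1, ref, alt,
                                                  {"s1": Genotype.HOM_ALT})], [m], cre)
        swapped_seq = seq[:core] + alt + seq[core + 1:]
        rev = classify_tfbs_changes(swapped_seq, [Variant("chr1", cre.start + core + 1,
                                                          alt, ref,
                                                          {"s1": Genotype.HOM_ALT})], [m], cre)
        lost_fwd = {c.motif_id for c in fwd if c.change == "lost"}
        gained_rev = {c.motif_id for c in rev if c.change == "gained"}
        assert lost_fwd == gained_rev


class TestSharingSpectrum:
    def test_singletons(self):
        mat = pd.DataFrame(np.eye(3, 12, dtype=int))
        spectrum, frac = tfbs_sharing_spectrum(mat)
        assert spectrum[1] == 3 and frac == 1.0

    def test_fixed_rows_excluded(self):
        mat = pd.DataFrame([[1] * 5, [0] * 5, [1, 1, 0, 0, 0]])
        spectrum, _ = tfbs_sharing_spectrum(mat)
        assert sum(spectrum.values()) == 1 and spectrum[2] == 1

    def test_total_equals_variable_rows(self, rng):
        mat = pd.DataFrame(rng.integers(0, 2, (40, 8)))
        spectrum, _ = tfbs_sharing_spectrum(mat)
        variable = ((mat.sum(axis=1) > 0) & (mat.sum(axis=1) < 8)).sum()
        assert sum(spectrum.values()) == variable

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            tfbs_sharing_spectrum(pd.DataFrame([[0, 2]]))


def test_consensus_round_trip_recovers_snps(null_bundle):
    """Differences between a projected sequence and the reference are exactly
    the applied SNP alleles at the applied offsets."""
    b = null_bundle
    cre = next(iv for iv in b.annotation.intervals if iv.name in b.cre_sequences)
    seq = b.cre_sequences[cre.name]
    snps = [v for v in b.variants if v.is_snp and v.interval.overlaps(cre)]
    sample = b.samples[0]
    out = project_consensus(seq, b.variants, sample, cre)
    if len(out) == len(seq):
        diffs = {i for i, (a, c) in enumerate(zip(seq, out)) if a != c}
        expected = {v.pos - 1 - cre.start for v in snps
                    if v.genotypes.get(sample) in (Genotype.HET, Genotype.HOM_ALT)}
        assert diffs == expected
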