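"""IUPAC matching, sequence extraction, and Fisher-with-erasure discovery."""

import math

import numpy as np
import pytest

from meripdiff.genome import GenomicInterval, Peak
from meripdiff.motif import (
    IUPAC,
    _erase,
    _pattern_regex,
    default_candidates,
    dinucleotide_shuffle,
    discover_motifs,
    extract_peak_sequences,
    fisher_enrichment_p,
    iupac_match_sites,
    make_background,
)


def random_seq(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


def plant(seq, word, at):
    return seq[:at] + word + seq[at + len(word):]


def hypergeom_tail_by_summation(k, N, K, n):
    """P(X >= k) by explicit summation of the hypergeometric pmf."""
    total = 0
    denom = math.comb(N, n)
    for j in range(k, min(n, K) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / denom


class TestIupacMatching:
    def test_exact_word(self):
        assert iupac_match_sites("GGACT", "GGAC") == [(0, "GGAC")]

    def test_degenerate_letter(self):
        assert iupac_match_sites("AGACT", "RRAC") == [(0, "AGAC")]

    def test_overlapping_matches_reported(self):
        assert iupac_match_sites("AAAA", "AA") == [(0, "AA"), (1, "AA"), (2, "AA")]

    def test_erased_lowercase_never_matches(self):
        assert iupac_match_sites("ggact", "GGAC") == []
        assert iupac_match_sites("GgACT", "GGAC") == []

    def test_illegal_letter_rejected(self):
        with pytest.raises(ValueError):
            iupac_match_sites("ACGT", "AXGT")

    def test_random_pairs_match_brute_force(self):
        """100 random (sequence, pattern) pairs vs per-offset set membership."""
        rng = np.random.default_rng(13)
        letters = list(IUPAC)
        for _ in range(100):
            seq = random_seq(rng, int(rng.integers(10, 60)))
            pattern = "".join(
                letters[i] for i in rng.integers(0, len(letters), int(rng.integers(2, 6)))
            )
            expected = []
            for off in range(len(seq) - len(pattern) + 1):
                window = seq[off : off + len(pattern)]
                if all(b in IUPAC[p] for b, p in zip(window, pattern)):
                    expected.append((off, window))
            assert iupac_match_sites(seq, pattern) == expected


class TestExtraction:
    def make_genome(self, rng, length=1000):
        return {"chr1": random_seq(rng, length)}

    def test_flank_widening(self):
        rng = np.random.default_rng(0)
        genome = self.make_genome(rng)
        peak = Peak(GenomicInterval("chr1", 100, 200), name="p", score=1.0)
        (seq,) = extract_peak_sequences([peak], genome, flank=100)
        assert len(seq) == 300
        assert seq == genome["chr1"][0:300]

    def test_clipping_at_chromosome_start(self):
        rng = np.random.default_rng(0)
        genome = self.make_genome(rng)
        peak = Peak(GenomicInterval("chr1", 0, 50), name="p")
        (seq,) = extract_peak_sequences([peak], genome, flank=100)
        assert len(seq) == 150

    def test_minus_strand_reverse_complemented(self):
        rng = np.random.default_rng(0)
        genome = self.make_genome(rng)
        peak = Peak(GenomicInterval("chr1", 300, 400, "-"), name="p")
        (seq,) = extract_peak_sequences([peak], genome, flank=10)
        fwd = genome["chr1"][290:410]
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        assert seq == "".join(comp[b] for b in reversed(fwd))

    def test_top_n_selects_by_score(self):
        rng = np.random.default_rng(0)
        genome = self.make_genome(rng)
        peaks = [
            Peak(GenomicInterval("chr1", 100 * i, 100 * i + 50), name=f"p{i}", score=i)
            for i in range(1, 6)
        ]
        seqs = extract_peak_sequences(peaks, genome, top_n=2, flank=0)
        assert seqs == [genome["chr1"][500:550], genome["chr1"][400:450]]

    def test_missing_chromosome_named(self):
        with pytest.raises(KeyError, match="chrX"):
            extract_peak_sequences(
                [Peak(GenomicInterval("chrX", 0, 10), name="p")], {"chr1": "ACGT"}
            )


class TestFisher:
    def test_fisher_equals_hypergeometric_summation(self):
        # table: pos 40/100 with, background 10/100 with
        p = fisher_enrichment_p(40, 100, 10, 100)
        expected = hypergeom_tail_by_summation(40, 200, 50, 100)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_no_enrichment_is_p_near_one(self):
        assert fisher_enrichment_p(0, 50, 50, 50) == pytest.approx(1.0)

    def test_agrees_with_scipy_fisher_exact(self):
        """Independent route: scipy's 2x2 Fisher test on random tables."""
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(19)
        for _ in range(200):
            pt = int(rng.integers(1, 80))
            bt = int(rng.integers(1, 80))
            pw = int(rng.integers(0, pt + 1))
            bw = int(rng.integers(0, bt + 1))
            ours = fisher_enrichment_p(pw, pt, bw, bt)
            ref = fisher_exact(
                [[pw, pt - pw], [bw, bt - bw]], alternative="greater"
            )[1]
            assert ours == pytest.approx(ref, rel=1e-9)


class TestShuffle:
    def test_dinucleotide_counts_preserved(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            seq = random_seq(rng, int(rng.integers(20, 200)))
            shuf = dinucleotide_shuffle(seq, rng)
            assert len(shuf) == len(seq)
            assert shuf[0] == seq[0] and shuf[-1] == seq[-1]

            def dinucs(s):
                counts = {}
                for a, b in zip(s, s[1:]):
                    counts[a + b] = counts.get(a + b, 0) + 1
                return counts

            assert dinucs(shuf) == dinucs(seq)


class TestDiscovery:
    def planted_sets(self, n=200, length=300, seed=5):
        rng = np.random.default_rng(seed)
        pos = [
            plant(random_seq(rng, length), "GGACT", int(rng.integers(0, length - 5)))
            for _ in range(n)
        ]
        bg = [random_seq(rng, length) for _ in range(n)]
        return pos, bg

    def test_planted_motif_recovered(self):
        pos, bg = self.planted_sets()
        results = discover_motifs(pos, bg, candidates=default_candidates())
        assert results, "no motif discovered"
        top = results[0]
        # the winning pattern is an instance of the planted GGAC-family word
        assert iupac_match_sites("GGACT", top.name), top.name
        assert top.pos_with == len(pos)

    def test_e_value_relation_exact(self):
        pos, bg = self.planted_sets(n=80)
        candidates = default_candidates()
        results = discover_motifs(pos, bg, candidates=candidates)
        for r in results:
            assert r.e_value == r.p_value * len(candidates)
        assert [r.rank for r in results] == list(range(1, len(results) + 1))

    def test_first_motif_unerased_equals_e(self):
        pos, bg = self.planted_sets(n=80)
        results = discover_motifs(pos, bg)
        assert results[0].unerased_e == results[0].e_value

    def test_null_case_emits_nothing(self):
        rng = np.random.default_rng(8)
        seqs = [random_seq(rng, 100) for _ in range(50)]
        results = discover_motifs(seqs, list(seqs), candidates=["GGAC", "AAAA", "DRAC"])
        assert results == []

    def test_erasure_removes_all_sites_of_emitted_motif(self):
        pos, bg = self.planted_sets(n=60)
        results = discover_motifs(pos, bg)
        top = results[0]
        rx = _pattern_regex(top.name)
        erased = [_erase(s, rx, top.width) for s in pos]
        assert all(not iupac_match_sites(s, top.name) for s in erased)

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            discover_motifs(["ACGT"], ["ACGT"], candidates=[])

    def test_background_defaults_are_seeded(self):
        pos, _ = self.planted_sets(n=10)
        assert make_background(pos, seed=1) == make_background(pos, seed=1)
        assert make_background(pos, seed=1) != make_background(pos, seed=2)
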