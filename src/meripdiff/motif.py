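"""IUPAC motif enrichment around top peaks, with erasure and E-values.

Sequences are extracted around the highest-scoring peaks (100 bp of flank on
each side by default). Discovery is a greedy loop over a fixed candidate set
of degenerate IUPAC patterns: each round scores every remaining candidate by
a one-sided Fisher's exact test on the 2x2 table of sequences with/without at
least one unerased match (positive vs background), emits the candidate with
the smallest E-value (Fisher P times the number of candidates tested), and
erases its matched sites in both sequence sets so later motifs rest on
independent evidence. Each emitted motif also carries the "unerased" E-value
computed on the pristine sequences.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genome import Peak, reverse_complement

IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}


@dataclass
class MotifResult:
    name: str
    width: int
    pos_with: int
    pos_total: int
    bg_with: int
    bg_total: int
    p_value: float
    e_value: float
    unerased_e: float
    rank: int


def default_candidates(width: int = 4) -> list[str]:
    """All fixed-width ACGT words plus the canonical degenerate m6A family."""
    words = ["".join(w) for w in itertools.product("ACGT", repeat=width)]
    extra = ["RRAC", "DRAC", "RRACH", "DRACH"]
    return words + [e for e in extra if e not in words]


def extract_peak_sequences(
    peaks: list[Peak],
    genome: dict[str, str],
    top_n: int = 5000,
    flank: int = 100,
) -> list[str]:
    """Sequences around the top-scoring peaks, widened by ``flank`` bp each side.

    Spans are clipped to chromosome bounds; minus-strand peaks are
    reverse-complemented so motifs read in transcript orientation.
    """
    ranked = sorted(peaks, key=lambda p: (-p.score, p.name))[: max(top_n, 0)]
    seqs: list[str] = []
    for p in ranked:
        if p.chrom not in genome:
            raise KeyError(f"chromosome {p.chrom} missing from FASTA")
        chrom_seq = genome[p.chrom]
        lo = max(0, p.start - flank)
        hi = min(len(chrom_seq), p.end + flank)
        seq = chrom_seq[lo:hi]
        if p.strand == "-":
            seq = reverse_complement(seq)
        seqs.append(seq)
    return seqs


def _pattern_regex(pattern: str) -> re.Pattern:
    parts = []
    for letter in pattern.upper():
        if letter not in IUPAC:
            raise ValueError(f"illegal IUPAC letter {letter!r} in {pattern!r}")
        bases = IUPAC[letter]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    # lookahead makes overlapping matches visible; lowercase (erased) bases
    # fall outside the uppercase classes and can never match
    return re.compile(f"(?=({''.join(parts)}))")


def iupac_match_sites(seq: str, pattern: str) -> list[tuple[int, str]]:
    """All (possibly overlapping) match offsets of an IUPAC pattern.

    Erased positions are lowercase-masked and never match.
    """
    rx = _pattern_regex(pattern)
    return [(m.start(), m.group(1)) for m in rx.finditer(seq)]


def _contains(seq: str, rx: re.Pattern) -> bool:
    return rx.search(seq) is not None


def fisher_enrichment_p(pos_with, pos_total, bg_with, bg_total):
    """One-sided (enrichment) Fisher's exact P for the 2x2 sequence table.

    Computed as the hypergeometric upper tail P(X >= pos_with) with
    X ~ Hypergeom(N=pos_total+bg_total, K=pos_with+bg_with, n=pos_total),
    which is exactly the one-sided Fisher P. Accepts scalars or arrays.
    """
    pos_with = np.asarray(pos_with)
    p = stats.hypergeom.sf(
        pos_with - 1,
        np.asarray(pos_total) + np.asarray(bg_total),
        pos_with + np.asarray(bg_with),
        pos_total,
    )
    p = np.minimum(p, 1.0)
    return float(p) if p.ndim == 0 else p


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erikson doublet-preserving shuffle of an ACGT string."""
    if len(seq) < 3:
        return seq
    first, last = seq[0], seq[-1]
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    vertices = list(edges)
    for _ in range(1000):
        # pick a random terminal edge per vertex; accept when they form a
        # tree oriented toward the last character (Eulerian-path condition)
        terminal = {
            v: edges[v][int(rng.integers(len(edges[v])))]
            for v in vertices
            if v != last
        }
        ok = True
        for v in terminal:
            seen = {v}
            cur = v
            while cur != last:
                cur = terminal.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - tiny alphabet, rejection terminates fast
        return seq
    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v != last:
            rest.remove(terminal[v])
        perm = [rest[i] for i in rng.permutation(len(rest))]
        if v != last:
            perm.append(terminal[v])
        shuffled[v] = perm
    out = [first]
    counters = {v: 0 for v in vertices}
    cur = first
    for _ in range(len(seq) - 1):
        nxt = shuffled[cur][counters[cur]]
        counters[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def make_background(pos_seqs: list[str], seed: int = 0) -> list[str]:
    """Default background: one dinucleotide shuffle of each positive sequence."""
    rng = np.random.default_rng(seed)
    return [dinucleotide_shuffle(s, rng) for s in pos_seqs]


def discover_motifs(
    pos_seqs: list[str],
    bg_seqs: list[str],
    candidates: list[str] | None = None,
    max_motifs: int = 5,
) -> list[MotifResult]:
    """Greedy Fisher-with-erasure motif discovery over a fixed candidate set.

    Stops after ``max_motifs`` motifs or when the best remaining E-value is
    at least 1.
    """
    if candidates is None:
        candidates = default_candidates()
    if not candidates:
        raise ValueError("empty candidate set")
    if not bg_seqs:
        raise ValueError("empty background set")
    n_candidates = len(candidates)
    regexes = {c: _pattern_regex(c) for c in candidates}

    pristine_pos, pristine_bg = list(pos_seqs), list(bg_seqs)
    pos, bg = list(pos_seqs), list(bg_seqs)
    remaining = list(candidates)
    results: list[MotifResult] = []
    while remaining and len(results) < max_motifs:
        best: tuple[float, str, int, int] | None = None
        for cand in remaining:
            rx = regexes[cand]
            pw = sum(1 for s in pos if _contains(s, rx))
            bw = sum(1 for s in bg if _contains(s, rx))
            p = fisher_enrichment_p(pw, len(pos), bw, len(bg))
            e = p * n_candidates
            if best is None or (e, cand) < (best[0], best[1]):
                best = (e, cand, pw, bw)
        e, cand, pw, bw = best
        if e >= 1.0:
            break
        p = e / n_candidates
        rx = regexes[cand]
        upw = sum(1 for s in pristine_pos if _contains(s, rx))
        ubw = sum(1 for s in pristine_bg if _contains(s, rx))
        unerased_e = (
            fisher_enrichment_p(upw, len(pristine_pos), ubw, len(pristine_bg))
            * n_candidates
        )
        results.append(
            MotifResult(
                name=cand,
                width=len(cand),
                pos_with=pw,
                pos_total=len(pos),
                bg_with=bw,
                bg_total=len(bg),
                p_value=p,
                e_value=e,
                unerased_e=unerased_e,
                rank=len(results) + 1,
            )
        )
        pos = [_erase(s, rx, len(cand)) for s in pos]
        bg = [_erase(s, rx, len(cand)) for s in bg]
        remaining.remove(cand)
    return results


def _erase(seq: str, rx: re.Pattern, width: int) -> str:
    chars = list(seq)
    for m in rx.finditer(seq):
        for i in range(m.start(), m.start() + width):
            chars[i] = chars[i].lower()
    return "".join(chars)


def write_motif_table(results: list[MotifResult], path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "name": [r.name for r in results],
            "width": [r.width for r in results],
            "pos_with": [r.pos_with for r in results],
            "pos_total": [r.pos_total for r in results],
            "bg_with": [r.bg_with for r in results],
            "bg_total": [r.bg_total for r in results],
            "p_value": [r.p_value for r in results],
            "e_value": [r.e_value for r in results],
            "unerased_e": [r.unerased_e for r in results],
            "rank": [r.rank for r in results],
        }
    ).to_csv(path, sep="\t", index=False)
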