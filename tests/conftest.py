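"""Shared fixtures: the default simulated experiment and small helpers.

The default scenario (seed 42, 170 mRNAs + 80 lncRNAs, one peak each, 8x
baseline IP enrichment, 20% of peaks differential at 4-fold) is expensive
enough to build once per session; tests that need planted truth share it.
"""

from types import SimpleNamespace

import numpy as np
import pytest

from meripdiff import diffmeth
from meripdiff import peaks as peaks_mod
from meripdiff.genome import GenomicInterval, TranscriptModel
from meripdiff.simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def default_sim():
    cfg = SimulationConfig()
    genome, models = simulate_annotation(cfg)
    tracks, infos, truth, genome = simulate_experiment(cfg, models, genome)
    return SimpleNamespace(
        cfg=cfg, genome=genome, models=models, tracks=tracks, infos=infos, truth=truth
    )


@pytest.fixture(scope="session")
def default_calls(default_sim):
    """Called peaks per group, the between-group union, and the signal matrix."""
    s = default_sim
    merged = {}
    for group in ("A", "B"):
        ip = s.tracks["HAEC_IP" if group == "A" else "SCC25_IP"]
        inp = s.tracks["HAEC_input" if group == "A" else "SCC25_input"]
        called = peaks_mod.call_peaks(ip, inp)
        merged[group] = peaks_mod.intersect_within_group([called])
    union = peaks_mod.union_between_groups(merged["A"], merged["B"])
    matrix = peaks_mod.count_signal(
        union, [s.tracks[i.sample_id] for i in s.infos], s.infos
    )
    records = diffmeth.call_differential(matrix)
    return SimpleNamespace(merged=merged, union=union, matrix=matrix, records=records)


@pytest.fixture(scope="session")
def small_sim():
    """A quick scenario for IO and CLI tests."""
    cfg = SimulationConfig(n_mrna=12, n_lncrna=8, chrom_length=250_000, seed=7)
    genome, models = simulate_annotation(cfg)
    tracks, infos, truth, genome = simulate_experiment(cfg, models, genome)
    return SimpleNamespace(
        cfg=cfg, genome=genome, models=models, tracks=tracks, infos=infos, truth=truth
    )


def random_transcript(
    rng: np.random.Generator,
    chrom: str = "chr1",
    mrna: bool = True,
    name: str = "t",
) -> TranscriptModel:
    """A random valid transcript for oracle tests."""
    n_exons = int(rng.integers(1, 5))
    strand = "+" if rng.integers(2) == 0 else "-"
    at = int(rng.integers(0, 500))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(30, 200))
        exons.append(GenomicInterval(chrom, at, at + length, strand))
        at += length + int(rng.integers(10, 100))
    cds_start = cds_end = None
    model = TranscriptModel(
        transcript_id=name,
        gene_id=f"g_{name}",
        gene_name=f"G_{name}",
        chrom=chrom,
        strand=strand,
        exons=exons,
    )
    if mrna:
        L = model.spliced_length
        lo = int(rng.integers(1, L - 1))
        hi = int(rng.integers(lo + 1, L))
        g1 = model.transcript_to_genomic(lo)
        g2 = model.transcript_to_genomic(hi - 1)
        cds_start, cds_end = min(g1, g2), max(g1, g2) + 1
    return TranscriptModel(
        transcript_id=name,
        gene_id=f"g_{name}",
        gene_name=f"G_{name}",
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
    )


def exonic_bases_oriented(model: TranscriptModel) -> list[int]:
    """Exonic genomic positions in 5'->3' transcript order (oracle helper)."""
    positions = [p for e in model.exons for p in range(e.start, e.end)]
    return positions if model.strand == "+" else positions[::-1]
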