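"""Assignment of each peak to one of seven functional categories.

The peak's representative point (summit when present, else midpoint) is
tested against every overlapping transcript; each (transcript, point) pair
yields one candidate category and the highest-priority category wins. UTR
categories outrank exon categories because a UTR base is also exonic but the
seven reported classes are disjoint. Exon and intron ordinals are counted in
transcript orientation (the 1st exon is the 5'-most).
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .genome import MRNA, Peak, TranscriptIndex, TranscriptModel

FIVE_PRIME_UTR = "five_prime_utr"
THREE_PRIME_UTR = "three_prime_utr"
FIRST_EXON = "first_exon"
OTHER_EXON = "other_exon"
FIRST_INTRON = "first_intron"
OTHER_INTRON = "other_intron"
DISTAL_INTERGENIC = "distal_intergenic"

CATEGORIES = (
    FIVE_PRIME_UTR,
    THREE_PRIME_UTR,
    FIRST_EXON,
    OTHER_EXON,
    FIRST_INTRON,
    OTHER_INTRON,
    DISTAL_INTERGENIC,
)
DEFAULT_PRIORITY = CATEGORIES  # highest first


@dataclass
class PeakAnnotation:
    peak: Peak
    category: str
    gene_id: str
    distance: int  # signed bp from the point to the host/nearest TSS; 0 when genic


def _signed_tss_distance(t: TranscriptModel, pos: int) -> int:
    """Positive downstream of the TSS in transcript orientation."""
    return pos - t.tss if t.strand == "+" else t.tss - pos


def _classify(t: TranscriptModel, pos: int) -> list[str]:
    """All categories one transcript offers for a position.

    A UTR base is also exonic, so it yields both the UTR category and its
    exon-ordinal category; the caller's priority order picks the winner.
    """
    if not t.span.contains(pos):
        return []
    offset = t.genomic_to_transcript(pos)
    if offset is None:
        ordinal = t.intron_ordinal(pos)
        if ordinal is None:
            return []
        return [FIRST_INTRON if ordinal == 1 else OTHER_INTRON]
    cats = []
    if t.biotype == MRNA:
        region = t.region_of(offset)
        if region == "utr5":
            cats.append(FIVE_PRIME_UTR)
        elif region == "utr3":
            cats.append(THREE_PRIME_UTR)
    ordinal = t.exon_ordinal(pos)
    cats.append(FIRST_EXON if ordinal == 1 else OTHER_EXON)
    return cats


def annotate_peak(
    peak: Peak,
    transcripts: list[TranscriptModel] | TranscriptIndex,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> PeakAnnotation:
    """Annotate one peak; among overlapping transcripts the best category wins.

    When several transcripts tie on the winning category, the one whose TSS is
    nearest to the point provides the gene id. Peaks overlapping no transcript
    are distal_intergenic with the nearest gene recorded and the signed TSS
    distance reported.
    """
    if set(priority) != set(CATEGORIES):
        raise ValueError("priority must be a total order over the seven categories")
    rank = {c: i for i, c in enumerate(priority)}
    index = (
        transcripts
        if isinstance(transcripts, TranscriptIndex)
        else TranscriptIndex(transcripts)
    )
    pos = peak.point()
    candidates: list[tuple[int, int, str, TranscriptModel]] = []
    for t in index.overlapping(peak.chrom, pos):
        for cat in _classify(t, pos):
            candidates.append((rank[cat], abs(_signed_tss_distance(t, pos)), cat, t))
    if candidates:
        candidates.sort(key=lambda c: (c[0], c[1], c[3].transcript_id))
        _, _, cat, t = candidates[0]
        return PeakAnnotation(peak=peak, category=cat, gene_id=t.gene_id, distance=0)
    nearest = index.nearest_tss(peak.chrom, pos)
    if nearest is None:
        return PeakAnnotation(
            peak=peak, category=DISTAL_INTERGENIC, gene_id="", distance=0
        )
    return PeakAnnotation(
        peak=peak,
        category=DISTAL_INTERGENIC,
        gene_id=nearest.gene_id,
        distance=_signed_tss_distance(nearest, pos),
    )


def annotate_peaks(
    peaks: list[Peak],
    transcripts: list[TranscriptModel],
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> list[PeakAnnotation]:
    index = TranscriptIndex(transcripts)
    return [annotate_peak(p, index, priority) for p in peaks]


def category_proportions(annotations: list[PeakAnnotation]) -> dict[str, float]:
    """Fraction of peaks per category; all seven categories always present."""
    if not annotations:
        raise ValueError("no annotations")
    counts = Counter(a.category for a in annotations)
    n = len(annotations)
    return {c: counts.get(c, 0) / n for c in CATEGORIES}


def write_annotations(
    annotations: list[PeakAnnotation], path: str | os.PathLike
) -> None:
    pd.DataFrame(
        {
            "peak": [a.peak.name for a in annotations],
            "category": [a.category for a in annotations],
            "gene_id": [a.gene_id for a in annotations],
            "distance": [a.distance for a in annotations],
        }
    ).to_csv(path, sep="\t", index=False)


def write_proportions(proportions: dict[str, float], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"category": list(proportions), "fraction": list(proportions.values())}
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")
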