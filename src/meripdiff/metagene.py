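"""Metagene peak-frequency profiles over scaled transcript regions.

Each peak is reduced to a single representative point (summit when present,
otherwise the interval midpoint). The point is projected onto every
overlapping transcript of the requested biotype; on mRNA it is classified
into 5'UTR/CDS/3'UTR by the CDS bounds in transcript coordinates and
expressed as a fraction of that region, on lncRNA as a fraction of the
spliced body. Fractions are histogrammed into region-local bins and
normalized to a density. A peak mapping onto k transcripts contributes total
weight 1/k, so annotation redundancy does not distort the profile.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import LNCRNA, MRNA, Peak, TranscriptIndex, TranscriptModel

MRNA_REGIONS = ("utr5", "cds", "utr3")
DEFAULT_MRNA_BINS = {"utr5": 20, "cds": 40, "utr3": 40}
DEFAULT_LNCRNA_BINS = 100


@dataclass
class MetageneProfile:
    """Per-bin peak frequency; density sums to 1 when any peak maps."""

    kind: str  # mRNA or lncRNA
    regions: list[str]  # region label per bin
    bin_index: list[int]  # region-local bin index per bin
    density: np.ndarray

    def __post_init__(self) -> None:
        total = float(self.density.sum())
        if np.any(self.density < 0):
            raise ValueError("negative density")
        if total > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError(f"density sums to {total}, expected 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kind": self.kind,
                "region": self.regions,
                "bin_index": self.bin_index,
                "density": self.density,
            }
        )

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def peak_metagene_positions(
    peak: Peak,
    transcripts: list[TranscriptModel] | TranscriptIndex,
) -> list[tuple[str, str, float]]:
    """Map the peak's representative point onto overlapping transcripts.

    Returns (transcript_id, region, fractional position within region) for
    every transcript whose exons contain the point; intronic hits are dropped.
    """
    index = (
        transcripts
        if isinstance(transcripts, TranscriptIndex)
        else TranscriptIndex(transcripts)
    )
    pos = peak.point()
    out: list[tuple[str, str, float]] = []
    for t in index.overlapping(peak.chrom, pos):
        offset = t.genomic_to_transcript(pos)
        if offset is None:
            continue
        if t.biotype == MRNA:
            lo, hi = t.cds_tx_bounds()
            region = t.region_of(offset)
            if region == "utr5":
                frac = offset / lo
            elif region == "cds":
                frac = (offset - lo) / (hi - lo)
            else:
                frac = (offset - hi) / (t.spliced_length - hi)
        else:
            region = "body"
            frac = offset / t.spliced_length
        out.append((t.transcript_id, region, frac))
    return out


def build_profile(
    peaks: list[Peak],
    transcripts: list[TranscriptModel],
    kind: str,
    mrna_bins: dict[str, int] | None = None,
    lncrna_bins: int = DEFAULT_LNCRNA_BINS,
) -> MetageneProfile:
    """Histogram mapped peak positions into region-local bins, normalized.

    ``kind`` selects which biotype's transcripts receive peaks. Bin counts
    default to 20/40/40 across 5'UTR/CDS/3'UTR and 100 over lncRNA bodies.
    """
    if kind not in (MRNA, LNCRNA):
        raise ValueError(f"kind must be {MRNA} or {LNCRNA}")
    mrna_bins = dict(DEFAULT_MRNA_BINS if mrna_bins is None else mrna_bins)

    if kind == MRNA:
        regions: list[str] = []
        bin_index: list[int] = []
        offsets = {}
        at = 0
        for region in MRNA_REGIONS:
            offsets[region] = at
            regions += [region] * mrna_bins[region]
            bin_index += list(range(mrna_bins[region]))
            at += mrna_bins[region]
        nbins = at
    else:
        regions = ["body"] * lncrna_bins
        bin_index = list(range(lncrna_bins))
        offsets = {"body": 0}
        nbins = lncrna_bins

    selected = [t for t in transcripts if t.biotype == kind]
    index = TranscriptIndex(selected)
    weights = np.zeros(nbins, dtype=float)
    for peak in peaks:
        hits = peak_metagene_positions(peak, index)
        if not hits:
            continue
        w = 1.0 / len(hits)
        for _, region, frac in hits:
            if kind == MRNA:
                rbins = mrna_bins[region]
            else:
                rbins = lncrna_bins
            b = min(int(frac * rbins), rbins - 1)
            weights[offsets[region] + b] += w

    total = weights.sum()
    density = weights / total if total > 0 else weights
    return MetageneProfile(
        kind=kind, regions=regions, bin_index=bin_index, density=density
    )


def cds_utr3_boundary_bin(mrna_bins: dict[str, int] | None = None) -> int:
    """Global bin index of the first 3'UTR bin (the stop-codon boundary)."""
    mrna_bins = dict(DEFAULT_MRNA_BINS if mrna_bins is None else mrna_bins)
    return mrna_bins["utr5"] + mrna_bins["cds"]
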