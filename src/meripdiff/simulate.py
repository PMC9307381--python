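"""Synthetic MeRIP-Seq data with planted ground truth.

The generator emulates a two-condition MeRIP-Seq design (a tumor-like case
group and a control group, each with one IP and one input sample): a random
genome carrying non-overlapping multi-exon transcripts on both strands, flat
per-transcript expression with Poisson counting noise, one methylation peak
per transcript where IP coverage is amplified over input, peak placement
biased toward the CDS/3'UTR junction on mRNAs (the stop-codon hotspot) and
uniform over lncRNA bodies, a consensus motif written into the genome under
every peak center, a planted fraction of peaks with a between-group
enrichment difference, and a term->gene map with one term enriched for the
genes hosting differential peaks.

Coverage is simulated directly (no reads, no aligner): the pipeline consumes
coverage, and a read model would add scope without exercising any of the
downstream computations.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass

import numpy as np

from .enrich import GeneSet
from .genome import (
    GenomicInterval,
    LNCRNA,
    MRNA,
    Peak,
    TranscriptModel,
)
from .peaks import CoverageTrack, SampleInfo

GROUP_A = "A"  # control-like (HAEC)
GROUP_B = "B"  # case-like (SCC25)
SAMPLE_NAMES = {
    ("A", "input"): "HAEC_input",
    ("A", "IP"): "HAEC_IP",
    ("B", "input"): "SCC25_input",
    ("B", "IP"): "SCC25_IP",
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    ``peak_enrichment`` is the baseline IP-over-input fold inside a peak;
    ``frac_differential`` of peaks additionally differ between groups by
    ``diff_fold`` (half stronger in the case group, half in the control).
    ``stop_codon_bias`` concentrates mRNA peak centers at the CDS/3'UTR
    junction: the placement SD is ``250 / stop_codon_bias`` bp in transcript
    coordinates.
    """

    seed: int = 42
    n_mrna: int = 170
    n_lncrna: int = 80
    chrom: str = "chr1"
    chrom_length: int = 2_000_000
    peak_enrichment: float = 8.0
    frac_differential: float = 0.2
    diff_fold: float = 4.0
    stop_codon_bias: float = 5.0
    motif: str = "GGACT"
    expression_low: float = 5.0
    expression_high: float = 20.0
    background_coverage: float = 1.0
    peak_width_min: int = 100
    peak_width_max: int = 200
    n_terms: int = 50
    planted_term_size: int = 20
    term_enrichment_fold: float = 10.0

    def __post_init__(self) -> None:
        if self.n_mrna < 1 or self.n_lncrna < 1:
            raise ValueError("transcript counts must be >= 1")
        if not 0 <= self.frac_differential <= 1:
            raise ValueError("frac_differential must lie in [0, 1]")
        if self.diff_fold <= 1:
            raise ValueError("diff_fold must exceed 1")
        if self.peak_enrichment <= 0 or self.stop_codon_bias <= 0:
            raise ValueError("fold and bias parameters must be positive")
        if set(self.motif) - set("ACGT"):
            raise ValueError("planted motif must be a plain ACGT word")


@dataclass
class PlantedPeak:
    name: str
    chrom: str
    start: int
    end: int
    transcript_id: str
    gene_id: str
    fold_a: float
    fold_b: float
    direction: str | None  # "up" (case higher), "down", or None
    center: int


@dataclass
class GroundTruth:
    peaks: list[PlantedPeak]
    motif_positions: list[tuple[str, int]]
    planted_term_id: str | None = None

    @property
    def differential(self) -> list[PlantedPeak]:
        return [p for p in self.peaks if p.direction is not None]

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "peaks": [asdict(p) for p in self.peaks],
            "motif_positions": [list(m) for m in self.motif_positions],
            "planted_term_id": self.planted_term_id,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            peaks=[PlantedPeak(**p) for p in payload["peaks"]],
            motif_positions=[tuple(m) for m in payload["motif_positions"]],
            planted_term_id=payload.get("planted_term_id"),
        )


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[TranscriptModel]]:
    """Random genome plus non-overlapping multi-exon transcripts.

    mRNAs receive a CDS leaving non-empty UTRs on both sides; lncRNAs carry
    no CDS. Transcripts are packed left to right with intergenic gaps.
    """
    rng = np.random.default_rng([config.seed, 0])
    bases = np.array(list("ACGT"))
    genome_arr = bases[rng.integers(0, 4, config.chrom_length)]

    biotypes = [MRNA] * config.n_mrna + [LNCRNA] * config.n_lncrna
    order = rng.permutation(len(biotypes))
    biotypes = [biotypes[i] for i in order]

    models: list[TranscriptModel] = []
    cursor = 1000
    for i, biotype in enumerate(biotypes):
        n_exons = int(rng.integers(2, 5))
        exon_lens = rng.integers(250, 701, n_exons)
        intron_lens = rng.integers(150, 501, n_exons - 1)
        strand = "+" if rng.integers(2) == 0 else "-"
        span = int(exon_lens.sum() + intron_lens.sum())
        if cursor + span > config.chrom_length - 1000:
            raise ValueError(
                f"chrom_length {config.chrom_length} too small to pack "
                f"{len(biotypes)} transcripts"
            )
        exons = []
        at = cursor
        for j in range(n_exons):
            exons.append(
                GenomicInterval(config.chrom, at, at + int(exon_lens[j]), strand)
            )
            at += int(exon_lens[j])
            if j < n_exons - 1:
                at += int(intron_lens[j])
        cursor = at + int(rng.integers(400, 1201))

        cds_start = cds_end = None
        tmp = TranscriptModel(
            transcript_id=f"tx{i:04d}",
            gene_id=f"gene{i:04d}",
            gene_name=f"GENE{i:04d}",
            chrom=config.chrom,
            strand=strand,
            exons=exons,
        )
        if biotype == MRNA:
            L = tmp.spliced_length
            utr5_len = max(80, int(0.15 * L))
            utr3_len = max(150, int(0.30 * L))
            lo, hi = utr5_len, L - utr3_len  # CDS transcript-coordinate bounds
            g1 = tmp.transcript_to_genomic(lo)
            g2 = tmp.transcript_to_genomic(hi - 1)
            cds_start, cds_end = min(g1, g2), max(g1, g2) + 1
        models.append(
            TranscriptModel(
                transcript_id=tmp.transcript_id,
                gene_id=tmp.gene_id,
                gene_name=tmp.gene_name,
                chrom=config.chrom,
                strand=strand,
                exons=exons,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    genome = {config.chrom: "".join(genome_arr)}
    return genome, models


# ---------------------------------------------------------------------------
# experiment


def _place_peak(
    model: TranscriptModel, config: SimulationConfig, rng: np.random.Generator
) -> tuple[int, int, int]:
    """Choose one exonic peak interval on a transcript; returns (start, end, center)."""
    L = model.spliced_length
    width = int(rng.integers(config.peak_width_min, config.peak_width_max + 1))
    if model.biotype == MRNA:
        _, cds_hi = model.cds_tx_bounds()
        sigma = 250.0 / config.stop_codon_bias
        center_tx = int(round(cds_hi + rng.normal(0.0, sigma)))
        center_tx = min(max(center_tx, 0), L - 1)
    else:
        center_tx = int(rng.integers(0, L))
    center = model.transcript_to_genomic(center_tx)
    exon = next(e for e in model.exons if e.contains(center))
    if exon.length() <= width:
        return exon.start, exon.end, center
    start = min(max(center - width // 2, exon.start), exon.end - width)
    return start, start + width, center


def simulate_experiment(
    config: SimulationConfig,
    models: list[TranscriptModel],
    genome: dict[str, str] | None = None,
) -> tuple[dict[str, CoverageTrack], list[SampleInfo], GroundTruth, dict[str, str]]:
    """Coverage tracks for two groups x {IP, input} plus planted ground truth.

    Input tracks are Poisson noise around flat per-transcript expression on a
    low intergenic background; IP tracks amplify the input rate by
    ``peak_enrichment`` inside each planted peak, with the differential subset
    amplified by ``diff_fold`` in one group only (alternating directions).
    The planted motif is written into the genome under every peak center.
    """
    rng = np.random.default_rng([config.seed, 1])
    n = config.chrom_length
    base = np.full(n, config.background_coverage, dtype=float)
    for m in models:
        expr = float(rng.uniform(config.expression_low, config.expression_high))
        for e in m.exons:
            base[e.start : e.end] = expr

    n_peaks = len(models)
    n_diff = math.ceil(config.frac_differential * n_peaks)
    diff_idx = sorted(rng.choice(n_peaks, size=n_diff, replace=False).tolist())
    direction_of = {
        idx: ("up" if j % 2 == 0 else "down") for j, idx in enumerate(diff_idx)
    }

    ip_a = base.copy()
    ip_b = base.copy()
    planted: list[PlantedPeak] = []
    for i, m in enumerate(models):
        start, end, center = _place_peak(m, config, rng)
        fold_a = fold_b = config.peak_enrichment
        direction = direction_of.get(i)
        if direction == "up":
            fold_b *= config.diff_fold
        elif direction == "down":
            fold_a *= config.diff_fold
        ip_a[start:end] *= fold_a
        ip_b[start:end] *= fold_b
        planted.append(
            PlantedPeak(
                name=f"planted_{i:04d}",
                chrom=m.chrom,
                start=start,
                end=end,
                transcript_id=m.transcript_id,
                gene_id=m.gene_id,
                fold_a=fold_a,
                fold_b=fold_b,
                direction=direction,
                center=center,
            )
        )

    tracks: dict[str, CoverageTrack] = {}
    infos: list[SampleInfo] = []
    for group, lam_ip in (("A", ip_a), ("B", ip_b)):
        for kind, lam in (("input", base), ("IP", lam_ip)):
            name = SAMPLE_NAMES[(group, kind)]
            values = rng.poisson(lam).astype(float)
            track = CoverageTrack(sample_id=name, values={config.chrom: values})
            tracks[name] = track
            infos.append(SampleInfo(name, group, kind, track.library_size))

    motif_positions: list[tuple[str, int]] = []
    if genome is not None:
        arr = np.array(list(genome[config.chrom]))
        half = len(config.motif) // 2
        for p in planted:
            at = min(max(p.center - half, 0), n - len(config.motif))
            arr[at : at + len(config.motif)] = list(config.motif)
            motif_positions.append((p.chrom, at))
        genome = {config.chrom: "".join(arr)}
    truth = GroundTruth(peaks=planted, motif_positions=motif_positions)
    return tracks, infos, truth, genome if genome is not None else {}


# ---------------------------------------------------------------------------
# term maps


def simulate_term_map(
    genes: list[str],
    study_genes: list[str] | set[str],
    n_terms: int = 50,
    planted_term_size: int = 20,
    enrichment_fold: float = 10.0,
    seed: int = 0,
) -> tuple[list[GeneSet], str]:
    """Random flat term->gene sets plus one term enriched for study genes.

    Members of the planted term are drawn with ``enrichment_fold`` times the
    sampling weight for study genes; a fold of 1 makes the planted term
    statistically indistinguishable from the background terms.
    """
    genes = sorted(set(genes))
    study = set(study_genes)
    if planted_term_size < 1:
        raise ValueError("planted_term_size must be >= 1")
    if planted_term_size > len(genes):
        raise ValueError("planted_term_size exceeds the gene universe")
    if not study <= set(genes):
        raise ValueError("study genes outside the gene list")
    rng = np.random.default_rng(seed)
    namespaces = ("BP", "MF", "CC")

    sets: list[GeneSet] = []
    weights = np.array(
        [enrichment_fold if g in study else 1.0 for g in genes], dtype=float
    )
    members = rng.choice(
        genes, size=planted_term_size, replace=False, p=weights / weights.sum()
    )
    planted_id = "T_planted"
    sets.append(
        GeneSet(
            term_id=planted_id,
            term_name="planted term",
            namespace="BP",
            genes=frozenset(members.tolist()),
        )
    )
    for t in range(n_terms - 1):
        size = int(rng.integers(10, min(41, len(genes) + 1)))
        bg_members = rng.choice(genes, size=size, replace=False)
        sets.append(
            GeneSet(
                term_id=f"T{t:04d}",
                term_name=f"background term {t}",
                namespace=namespaces[t % len(namespaces)],
                genes=frozenset(bg_members.tolist()),
            )
        )
    return sets, planted_id


# ---------------------------------------------------------------------------
# planted-truth evaluation


def peak_recovery(truth: GroundTruth, called: list[Peak]) -> float:
    """Fraction of planted peak centers falling inside a called peak."""
    if not truth.peaks:
        return 0.0
    spans: dict[str, list[tuple[int, int]]] = {}
    for p in called:
        spans.setdefault(p.chrom, []).append((p.start, p.end))
    hit = 0
    for t in truth.peaks:
        if any(s <= t.center < e for s, e in spans.get(t.chrom, [])):
            hit += 1
    return hit / len(truth.peaks)


def differential_performance(records, truth: GroundTruth) -> tuple[float, float]:
    """(sensitivity, precision) of up/down calls against planted truth.

    A planted differential peak is recovered when some record with the
    matching call overlaps it; a call is correct when it overlaps a planted
    differential peak with the matching direction.
    """
    calls = [r for r in records if r.call in ("up", "down")]
    diff = truth.differential
    if not diff:
        return 0.0, 0.0

    def overlaps(rec, t: PlantedPeak) -> bool:
        return (
            rec.peak.chrom == t.chrom
            and rec.peak.start < t.end
            and t.start < rec.peak.end
        )

    recovered = sum(
        1 for t in diff if any(r.call == t.direction and overlaps(r, t) for r in calls)
    )
    sensitivity = recovered / len(diff)
    if not calls:
        return sensitivity, 0.0
    correct = sum(
        1 for r in calls if any(r.call == t.direction and overlaps(r, t) for t in diff)
    )
    precision = correct / len(calls)
    return sensitivity, precision
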