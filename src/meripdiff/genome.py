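"""Coordinate system, transcript models, and plain-text genomics IO.

All internal coordinates are 0-based half-open (the BED convention). GTF,
which is 1-based closed, is shifted on read and unshifted on write. Transcript
offsets always run 5'->3' of the transcript, so minus-strand arithmetic is
confined to :meth:`TranscriptModel.genomic_to_transcript` and its inverse.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_STRANDS = ("+", "-", ".")

MRNA = "mRNA"
LNCRNA = "lncRNA"


class FormatError(ValueError):
    """A file violates its declared plain-text format."""


class ModelError(ValueError):
    """A transcript model violates its structural invariants."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ModelError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ModelError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ModelError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class Peak:
    """A scored interval; ``summit`` is an offset from ``start`` when known."""

    interval: GenomicInterval
    name: str = ""
    score: float = 0.0
    summit: int | None = None

    def __post_init__(self) -> None:
        if self.summit is not None and not 0 <= self.summit < self.interval.length():
            raise ModelError(
                f"summit {self.summit} outside peak of length {self.interval.length()}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def strand(self) -> str:
        return self.interval.strand

    def point(self) -> int:
        """Representative genomic position: summit when present, else midpoint."""
        if self.summit is not None:
            return self.start + self.summit
        return self.start + self.interval.length() // 2


@dataclass
class TranscriptModel:
    """Exon structure plus optional CDS span; biotype follows CDS presence.

    Transcript coordinates count spliced (exonic) bases from the transcript's
    5' end, which for minus-strand transcripts is the genomically rightmost
    exonic base.
    """

    transcript_id: str
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    cds_start: int | None = None
    cds_end: int | None = None
    _exon_offsets: list[int] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ModelError(
                f"{self.transcript_id}: transcript strand must be + or -, got {self.strand!r}"
            )
        if not self.exons:
            raise ModelError(f"{self.transcript_id}: no exons")
        for e in self.exons:
            if e.chrom != self.chrom:
                raise ModelError(
                    f"{self.transcript_id}: exon on {e.chrom}, transcript on {self.chrom}"
                )
        starts = [e.start for e in self.exons]
        if starts != sorted(starts):
            raise ModelError(f"{self.transcript_id}: exons not sorted by start")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ModelError(f"{self.transcript_id}: overlapping exons")
        if (self.cds_start is None) != (self.cds_end is None):
            raise ModelError(f"{self.transcript_id}: partial CDS bounds")
        # cumulative exonic length in genomic order, for offset arithmetic
        off = 0
        self._exon_offsets = []
        for e in self.exons:
            self._exon_offsets.append(off)
            off += e.length()
        if self.cds_start is not None:
            lo, hi = self.cds_tx_bounds()
            if lo <= 0 or hi >= self.spliced_length:
                raise ModelError(
                    f"{self.transcript_id}: CDS leaves an empty UTR "
                    f"(tx bounds [{lo},{hi}) of {self.spliced_length})"
                )

    @property
    def biotype(self) -> str:
        return MRNA if self.cds_start is not None else LNCRNA

    @property
    def spliced_length(self) -> int:
        return sum(e.length() for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def tss(self) -> int:
        """Genomic position of the transcription start site."""
        return self.exons[0].start if self.strand == "+" else self.exons[-1].end - 1

    def genomic_to_transcript(self, pos: int) -> int | None:
        """Transcript offset of genomic ``pos``; None when intronic/outside.

        The offset is the number of exonic bases strictly 5' of ``pos`` in
        transcript orientation.
        """
        for e, off in zip(self.exons, self._exon_offsets):
            if e.start <= pos < e.end:
                plus_off = off + (pos - e.start)
                if self.strand == "+":
                    return plus_off
                return self.spliced_length - 1 - plus_off
        return None

    def transcript_to_genomic(self, offset: int) -> int:
        """Genomic position of transcript ``offset`` (inverse of the above)."""
        L = self.spliced_length
        if not 0 <= offset < L:
            raise ModelError(
                f"{self.transcript_id}: offset {offset} outside [0,{L})"
            )
        plus_off = offset if self.strand == "+" else L - 1 - offset
        for e, off in zip(self.exons, self._exon_offsets):
            if off <= plus_off < off + e.length():
                return e.start + (plus_off - off)
        raise AssertionError("unreachable: offset inside spliced length")

    def cds_tx_bounds(self) -> tuple[int, int]:
        """Half-open CDS bounds in transcript coordinates (mRNA only)."""
        if self.cds_start is None or self.cds_end is None:
            raise ModelError(f"{self.transcript_id}: no CDS on a {self.biotype}")
        a = self.genomic_to_transcript(self.cds_start)
        b = self.genomic_to_transcript(self.cds_end - 1)
        if a is None or b is None:
            raise ModelError(
                f"{self.transcript_id}: CDS bounds fall outside the exon union"
            )
        lo, hi = min(a, b), max(a, b)
        return lo, hi + 1

    def region_of(self, offset: int) -> str:
        """Classify a transcript offset: utr5/cds/utr3 for mRNA, body otherwise."""
        if self.biotype == LNCRNA:
            return "body"
        lo, hi = self.cds_tx_bounds()
        if offset < lo:
            return "utr5"
        if offset < hi:
            return "cds"
        return "utr3"

    def exon_ordinal(self, pos: int) -> int | None:
        """1-based exon number of an exonic genomic position, 5'-most first."""
        for i, e in enumerate(self.exons):
            if e.contains(pos):
                return i + 1 if self.strand == "+" else len(self.exons) - i
        return None

    def intron_ordinal(self, pos: int) -> int | None:
        """1-based intron number of an intronic genomic position, 5'-most first."""
        n = len(self.exons) - 1
        for i, (a, b) in enumerate(zip(self.exons, self.exons[1:])):
            if a.end <= pos < b.start:
                return i + 1 if self.strand == "+" else n - i
        return None


class TranscriptIndex:
    """Interval-tree lookup of transcripts overlapping a genomic position."""

    def __init__(self, models: list[TranscriptModel]):
        from intervaltree import IntervalTree

        self.models = list(models)
        self._trees: dict[str, "IntervalTree"] = {}
        for m in models:
            tree = self._trees.setdefault(m.chrom, IntervalTree())
            tree[m.span.start : m.span.end] = m

    def overlapping(self, chrom: str, pos: int) -> list[TranscriptModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree[pos]]
        hits.sort(key=lambda m: m.transcript_id)
        return hits

    def nearest_tss(self, chrom: str, pos: int) -> TranscriptModel | None:
        """Transcript with the TSS closest to ``pos`` on ``chrom``."""
        candidates = [m for m in self.models if m.chrom == chrom]
        if not candidates:
            return None
        return min(candidates, key=lambda m: (abs(m.tss - pos), m.transcript_id))


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | os.PathLike) -> list[Peak]:
    """Read a BED3+ file into Peaks (score column 5, strand column 6)."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start or start < 0:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval {start}-{end}"
                )
            name = fields[3] if len(fields) > 3 else f"peak_{lineno}"
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in VALID_STRANDS:
                raise FormatError(f"{path}:{lineno}: invalid strand {strand!r}")
            peaks.append(
                Peak(GenomicInterval(chrom, start, end, strand), name=name, score=score)
            )
    return peaks


def write_bed(peaks: list[Peak], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:.6g}\t{p.strand}\n"
            )


# ---------------------------------------------------------------------------
# GTF


def read_gtf(path: str | os.PathLike) -> list[TranscriptModel]:
    """Read exon/CDS features of a GTF2.2 file into transcript models.

    Biotype is inferred: a transcript with at least one CDS feature is mRNA,
    otherwise lncRNA. GTF's 1-based closed coordinates are converted to
    0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, dict] = {}
    for f in db.all_features():
        if f.featuretype not in ("exon", "CDS"):
            continue
        tid = f.attributes["transcript_id"][0]
        gid = f.attributes["gene_id"][0]
        gname = f.attributes.get("gene_name", [gid])[0]
        rec = meta.setdefault(
            tid, {"gene_id": gid, "gene_name": gname, "chrom": f.seqid, "strand": f.strand}
        )
        if rec["chrom"] != f.seqid or rec["strand"] != f.strand:
            raise ModelError(
                f"{tid}: features on multiple chromosomes or strands"
            )
        iv = GenomicInterval(f.seqid, f.start - 1, f.end, f.strand)
        (exons if f.featuretype == "exon" else cds).setdefault(tid, []).append(iv)

    models = []
    for tid, rec in meta.items():
        if tid not in exons:
            raise ModelError(f"{tid}: CDS features without exons")
        exon_list = sorted(exons[tid], key=lambda e: e.start)
        cds_start = cds_end = None
        if tid in cds:
            cds_start = min(c.start for c in cds[tid])
            cds_end = max(c.end for c in cds[tid])
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                gene_name=rec["gene_name"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=exon_list,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    models.sort(key=lambda m: (m.chrom, m.span.start, m.transcript_id))
    return models


def write_gtf(models: list[TranscriptModel], path: str | os.PathLike) -> None:
    """Write exon and CDS features (CDS clipped to exons) in GTF2.2."""
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda m: (m.chrom, m.span.start, m.transcript_id)):
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                f'gene_name "{m.gene_name}";'
            )
            for e in m.exons:
                fh.write(
                    f"{m.chrom}\tmeripdiff\texon\t{e.start + 1}\t{e.end}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            if m.cds_start is not None:
                for e in m.exons:
                    lo = max(e.start, m.cds_start)
                    hi = min(e.end, m.cds_end)
                    if lo < hi:
                        fh.write(
                            f"{m.chrom}\tmeripdiff\tCDS\t{lo + 1}\t{hi}\t.\t{m.strand}\t0\t{attrs}\n"
                        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
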