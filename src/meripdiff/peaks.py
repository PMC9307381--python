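"""Enrichment-based peak calling, replicate merging, and signal counting.

The caller tiles each chromosome into fixed windows and keeps maximal runs of
windows whose library-normalized IP/input ratio clears a threshold. Replicate
peak sets within a group are intersected base-wise (a base survives only if
every replicate covers it); the two groups' merged sets are then unioned, and
per-sample signal is summed over the union intervals.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .genome import FormatError, GenomicInterval, Peak


@dataclass(frozen=True)
class SampleInfo:
    """Role tags for one coverage track inside a signal matrix."""

    sample_id: str
    group: str  # "A" (control) or "B" (case)
    kind: str  # "IP" or "input"
    library_size: float


@dataclass
class CoverageTrack:
    """Per-base signal for one sample, one numpy array per chromosome."""

    sample_id: str
    values: dict[str, np.ndarray]
    library_size: float = field(init=False)

    def __post_init__(self) -> None:
        total = 0.0
        for chrom, arr in self.values.items():
            if np.any(arr < 0):
                raise ValueError(f"{self.sample_id}: negative signal on {chrom}")
            total += float(arr.sum())
        self.library_size = total

    def interval_sum(self, iv: GenomicInterval) -> float:
        arr = self.values.get(iv.chrom)
        if arr is None:
            return 0.0
        return float(arr[iv.start : min(iv.end, len(arr))].sum())

    @classmethod
    def from_bedgraph(
        cls,
        path: str | os.PathLike,
        sample_id: str,
        chrom_sizes: dict[str, int] | None = None,
    ) -> "CoverageTrack":
        """Load a bedGraph TSV (chrom, start, end, value; 0-based half-open)."""
        spans: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise FormatError(f"{path}:{lineno}: fewer than 4 columns")
                chrom = fields[0]
                try:
                    start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad fields") from exc
                if end <= start or value < 0:
                    raise FormatError(f"{path}:{lineno}: invalid span or value")
                spans.setdefault(chrom, []).append((start, end, value))
        values: dict[str, np.ndarray] = {}
        for chrom, items in spans.items():
            size = max(e for _, e, _ in items)
            if chrom_sizes and chrom in chrom_sizes:
                size = max(size, chrom_sizes[chrom])
            arr = np.zeros(size, dtype=float)
            for s, e, v in items:
                arr[s:e] = v
            values[chrom] = arr
        if chrom_sizes:
            for chrom, size in chrom_sizes.items():
                values.setdefault(chrom, np.zeros(size, dtype=float))
        return cls(sample_id=sample_id, values=values)

    def to_bedgraph(self, path: str | os.PathLike) -> None:
        """Write run-length-encoded coverage; zero runs are omitted."""
        with open(path, "w") as fh:
            for chrom in sorted(self.values):
                arr = self.values[chrom]
                if len(arr) == 0:
                    continue
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(arr)]))
                for s, e in zip(starts, ends):
                    v = arr[s]
                    if v != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


@dataclass
class SignalMatrix:
    """Summed coverage per merged peak (rows) per sample (columns)."""

    peaks: list[Peak]
    samples: list[SampleInfo]
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.peaks), len(self.samples)):
            raise ValueError("counts shape inconsistent with peaks x samples")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for s in self.samples:
                fh.write(
                    f"#sample\t{s.sample_id}\t{s.group}\t{s.kind}\t{s.library_size:.6f}\n"
                )
            header = ["peak", "chrom", "start", "end"] + [s.sample_id for s in self.samples]
            fh.write("\t".join(header) + "\n")
            for i, p in enumerate(self.peaks):
                row = [p.name, p.chrom, str(p.start), str(p.end)]
                row += [f"{self.counts[i, j]:.6f}" for j in range(len(self.samples))]
                fh.write("\t".join(row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "SignalMatrix":
        samples: list[SampleInfo] = []
        peaks: list[Peak] = []
        rows: list[list[float]] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#sample\t"):
                    _, sid, group, kind, lib = line.split("\t")
                    samples.append(SampleInfo(sid, group, kind, float(lib)))
                    continue
                if line.startswith("peak\t") or not line:
                    continue
                fields = line.split("\t")
                name, chrom, start, end = fields[:4]
                peaks.append(
                    Peak(GenomicInterval(chrom, int(start), int(end)), name=name)
                )
                rows.append([float(x) for x in fields[4:]])
        counts = np.array(rows, dtype=float).reshape(len(peaks), len(samples))
        return cls(peaks=peaks, samples=samples, counts=counts)


# ---------------------------------------------------------------------------
# interval set algebra (sorted, half-open)


def _merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not spans:
        return []
    spans = sorted(spans)
    out = [spans[0]]
    for s, e in spans[1:]:
        ls, le = out[-1]
        if s <= le:
            out[-1] = (ls, max(le, e))
        else:
            out.append((s, e))
    return out


def _intersect_spans(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _by_chrom(peaks: list[Peak]) -> dict[str, list[tuple[int, int]]]:
    d: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        d.setdefault(p.chrom, []).append((p.start, p.end))
    return d


# ---------------------------------------------------------------------------
# operations


def call_peaks(
    ip: CoverageTrack,
    input_track: CoverageTrack,
    window: int = 25,
    min_enrichment: float = 2.0,
    min_length: int = 50,
    pseudocount: float = 1.0,
) -> list[Peak]:
    """Call IP-over-input enriched regions on non-overlapping windows.

    A window is enriched when
    ``(ip_w / ip_lib) / ((input_w + pseudocount) / input_lib) >= min_enrichment``.
    Maximal runs of adjacent enriched windows whose total span is at least
    ``min_length`` bp become peaks; the score is the run's mean enrichment and
    the summit is the offset of the center of its strongest window.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if min_enrichment <= 1:
        raise ValueError("min_enrichment must be > 1")
    if ip.library_size <= 0 or input_track.library_size <= 0:
        raise ValueError("zero library size")

    peaks: list[Peak] = []
    idx = 0
    for chrom in sorted(ip.values):
        ip_arr = ip.values[chrom]
        in_arr = input_track.values.get(chrom, np.zeros(0))
        n = len(ip_arr)
        if len(in_arr) < n:
            in_arr = np.concatenate([in_arr, np.zeros(n - len(in_arr))])
        nwin = (n + window - 1) // window
        edges = np.arange(nwin + 1) * window
        edges[-1] = n
        ip_w = np.add.reduceat(ip_arr, edges[:-1])
        in_w = np.add.reduceat(in_arr[:n], edges[:-1])
        enr = (ip_w / ip.library_size) / (
            (in_w + pseudocount) / input_track.library_size
        )
        enriched = enr >= min_enrichment
        # maximal runs of enriched windows
        w = 0
        while w < nwin:
            if not enriched[w]:
                w += 1
                continue
            w2 = w
            while w2 + 1 < nwin and enriched[w2 + 1]:
                w2 += 1
            start, end = int(edges[w]), int(edges[w2 + 1])
            if end - start >= min_length:
                run = enr[w : w2 + 1]
                best = int(np.argmax(run)) + w
                summit = int(edges[best]) + (int(edges[best + 1]) - int(edges[best])) // 2 - start
                idx += 1
                peaks.append(
                    Peak(
                        GenomicInterval(chrom, start, end, "."),
                        name=f"peak_{idx}",
                        score=float(run.mean()),
                        summit=summit,
                    )
                )
            w = w2 + 1
    return peaks


def intersect_within_group(replicate_peak_sets: list[list[Peak]]) -> list[Peak]:
    """Base-wise intersection of replicate peak sets, merged per replicate first.

    A base survives only when every replicate set covers it; the surviving
    bases are re-assembled into maximal strandless intervals.
    """
    if not replicate_peak_sets:
        raise ValueError("empty replicate set")
    per_rep = [
        {c: _merge_spans(v) for c, v in _by_chrom(reps).items()}
        for reps in replicate_peak_sets
    ]
    chroms = set(per_rep[0])
    for rep in per_rep[1:]:
        chroms &= set(rep)
    out: list[Peak] = []
    idx = 0
    for chrom in sorted(chroms):
        spans = per_rep[0][chrom]
        for rep in per_rep[1:]:
            spans = _intersect_spans(spans, rep[chrom])
        for s, e in spans:
            idx += 1
            out.append(
                Peak(GenomicInterval(chrom, s, e, "."), name=f"common_{idx}")
            )
    return out


def union_between_groups(
    group_a_peaks: list[Peak], group_b_peaks: list[Peak]
) -> list[Peak]:
    """Base-wise union of the two groups' peaks with group provenance.

    Output names carry the contributing group(s) as a suffix: ``A``, ``B``,
    or ``AB``; the score is the maximum score among contributing peaks.
    """
    a_by, b_by = _by_chrom(group_a_peaks), _by_chrom(group_b_peaks)
    a_merged = {c: _merge_spans(v) for c, v in a_by.items()}
    b_merged = {c: _merge_spans(v) for c, v in b_by.items()}
    score_of: dict[str, list[tuple[int, int, float]]] = {}
    for p in list(group_a_peaks) + list(group_b_peaks):
        score_of.setdefault(p.chrom, []).append((p.start, p.end, p.score))

    out: list[Peak] = []
    idx = 0
    for chrom in sorted(set(a_merged) | set(b_merged)):
        merged = _merge_spans(a_merged.get(chrom, []) + b_merged.get(chrom, []))
        for s, e in merged:
            prov = ""
            if any(rs < e and s < re_ for rs, re_ in a_merged.get(chrom, [])):
                prov += "A"
            if any(rs < e and s < re_ for rs, re_ in b_merged.get(chrom, [])):
                prov += "B"
            score = max(
                (sc for rs, re_, sc in score_of.get(chrom, []) if rs < e and s < re_),
                default=0.0,
            )
            idx += 1
            out.append(
                Peak(
                    GenomicInterval(chrom, s, e, "."),
                    name=f"merged_{idx}.{prov}",
                    score=score,
                )
            )
    return out


def count_signal(
    merged_peaks: list[Peak],
    tracks: list[CoverageTrack],
    sample_info: list[SampleInfo] | None = None,
) -> SignalMatrix:
    """Sum each track over each merged peak interval (no normalization).

    ``sample_info`` supplies group/kind tags per track; when omitted, tags are
    left blank and must be filled before differential calling.
    """
    if sample_info is None:
        sample_info = [
            SampleInfo(t.sample_id, "", "", t.library_size) for t in tracks
        ]
    if len(sample_info) != len(tracks):
        raise ValueError("sample_info length mismatch")
    # prefix sums give O(1) interval sums per track
    csums = [
        {c: np.concatenate(([0.0], np.cumsum(arr))) for c, arr in t.values.items()}
        for t in tracks
    ]
    counts = np.zeros((len(merged_peaks), len(tracks)), dtype=float)
    for i, p in enumerate(merged_peaks):
        for j, cs in enumerate(csums):
            arr = cs.get(p.chrom)
            if arr is None:
                continue
            lo = min(p.start, len(arr) - 1)
            hi = min(p.end, len(arr) - 1)
            counts[i, j] = arr[hi] - arr[lo]
    return SignalMatrix(peaks=list(merged_peaks), samples=list(sample_info), counts=counts)
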