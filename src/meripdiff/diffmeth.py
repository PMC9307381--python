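"""E-score differential methylation calls between two groups.

Each merged peak receives one enrichment score (E-score) per group: the
library-normalized IP signal divided by the library-normalized input signal,
with a pseudocount on both, after pooling replicates within the group.
Differential peaks are those whose mean E-score across groups exceeds
``t_mean`` (default 6) and whose log2 E-score ratio (case over control)
exceeds ``t_diff`` in magnitude (default 1).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import pandas as pd

from .genome import Peak, write_bed
from .peaks import SignalMatrix

CALL_UP = "up"
CALL_DOWN = "down"
CALL_NS = "ns"

_CALL_ORDER = {CALL_UP: 0, CALL_DOWN: 1, CALL_NS: 2}


class ConfigurationError(ValueError):
    """A group is missing an IP or input sample."""


@dataclass
class EScoreRecord:
    """Per-peak enrichment scores and the differential call."""

    peak: Peak
    e_a: float
    e_b: float
    mean_e: float
    log2_diff: float
    call: str


def compute_escore(
    ip_signal: float,
    input_signal: float,
    ip_lib: float,
    input_lib: float,
    pseudo: float = 1.0,
) -> float:
    """Library-normalized linear IP/input enrichment ratio.

    ``((ip_signal + pseudo) / ip_lib) / ((input_signal + pseudo) / input_lib)``
    """
    for v in (ip_signal, input_signal, ip_lib, input_lib, pseudo):
        if not math.isfinite(v):
            raise ValueError("non-finite E-score input")
    if ip_lib <= 0 or input_lib <= 0:
        raise ValueError("library sizes must be positive")
    if pseudo <= 0:
        raise ValueError("pseudocount must be positive")
    return ((ip_signal + pseudo) / ip_lib) / ((input_signal + pseudo) / input_lib)


def _pooled(matrix: SignalMatrix, group: str, kind: str) -> tuple[list[int], float]:
    cols = [
        j
        for j, s in enumerate(matrix.samples)
        if s.group == group and s.kind == kind
    ]
    lib = sum(matrix.samples[j].library_size for j in cols)
    return cols, lib


def call_differential(
    matrix: SignalMatrix,
    t_mean: float = 6.0,
    t_diff: float = 1.0,
    pseudo: float = 1.0,
) -> list[EScoreRecord]:
    """One E-score record per peak with the threshold-rule differential call.

    ``up`` means higher enrichment in group B (case) than group A (control).
    Replicates within a group are pooled (signals and libraries summed) before
    the ratio. Records are ordered up, down, ns; within each call by
    descending |log2_diff|, ties broken by peak name.
    """
    pools = {}
    for group in ("A", "B"):
        for kind in ("IP", "input"):
            cols, lib = _pooled(matrix, group, kind)
            if not cols:
                raise ConfigurationError(f"group {group} lacks an {kind} sample")
            pools[(group, kind)] = (cols, lib)

    records: list[EScoreRecord] = []
    for i, peak in enumerate(matrix.peaks):
        scores = {}
        for group in ("A", "B"):
            ip_cols, ip_lib = pools[(group, "IP")]
            in_cols, in_lib = pools[(group, "input")]
            ip_sig = float(matrix.counts[i, ip_cols].sum())
            in_sig = float(matrix.counts[i, in_cols].sum())
            scores[group] = compute_escore(ip_sig, in_sig, ip_lib, in_lib, pseudo)
        e_a, e_b = scores["A"], scores["B"]
        mean_e = (e_a + e_b) / 2.0
        # difference of logs (not log of ratio) so that swapping the group
        # labels negates the value exactly in floating point
        log2_diff = math.log2(e_b) - math.log2(e_a)
        if mean_e > t_mean and log2_diff > t_diff:
            call = CALL_UP
        elif mean_e > t_mean and log2_diff < -t_diff:
            call = CALL_DOWN
        else:
            call = CALL_NS
        records.append(
            EScoreRecord(
                peak=peak, e_a=e_a, e_b=e_b, mean_e=mean_e, log2_diff=log2_diff, call=call
            )
        )
    records.sort(
        key=lambda r: (_CALL_ORDER[r.call], -abs(r.log2_diff), r.peak.name)
    )
    return records


def volcano_table(records: list[EScoreRecord]) -> pd.DataFrame:
    """The volcano-plot table: mean E-score vs log2 E-score difference."""
    return pd.DataFrame(
        {
            "peak": [r.peak.name for r in records],
            "mean_e": [r.mean_e for r in records],
            "log2_diff": [r.log2_diff for r in records],
            "call": [r.call for r in records],
        }
    )


def write_volcano(records: list[EScoreRecord], path: str | os.PathLike) -> None:
    volcano_table(records).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_volcano(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_differential_bed(
    records: list[EScoreRecord], path: str | os.PathLike
) -> None:
    """Differential peaks as BED6; score = log2_diff, name suffixed .up/.down."""
    peaks = [
        Peak(
            r.peak.interval,
            name=f"{r.peak.name}.{r.call}",
            score=r.log2_diff,
        )
        for r in records
        if r.call in (CALL_UP, CALL_DOWN)
    ]
    write_bed(peaks, path)
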