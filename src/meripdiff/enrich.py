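"""Gene-set enrichment with Fisher's exact test, BH-FDR, and rich factors.

For every term, a one-sided Fisher's exact test (hypergeometric tail) asks
whether study genes hit the term more often than expected from the universe;
P values are Benjamini-Hochberg adjusted within each namespace. The rich
factor k/K (study genes in the term over all universe genes in the term)
summarizes enrichment magnitude. Term maps are GMT files; no ontology DAG
propagation is performed (flat sets).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GeneSet:
    term_id: str
    term_name: str
    namespace: str
    genes: frozenset[str]


@dataclass
class GeneSetResult:
    term_id: str
    term_name: str
    namespace: str
    k: int  # study genes in term
    K: int  # universe genes in term
    n: int  # study size
    N: int  # universe size
    p_value: float
    fdr: float
    rich_factor: float


def read_gmt(path: str | os.PathLike) -> list[GeneSet]:
    """GMT rows: term_id, "namespace|term_name", gene ids (tab-separated)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            desc = fields[1]
            if "|" in desc:
                namespace, name = desc.split("|", 1)
            else:
                namespace, name = "pathway", desc
            sets.append(
                GeneSet(
                    term_id=fields[0],
                    term_name=name,
                    namespace=namespace,
                    genes=frozenset(g for g in fields[2:] if g),
                )
            )
    return sets


def write_gmt(sets: list[GeneSet], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s in sets:
            genes = "\t".join(sorted(s.genes))
            fh.write(f"{s.term_id}\t{s.namespace}|{s.term_name}\t{genes}\n")


def bh_fdr(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def fisher_enrichment(
    study_genes: set[str] | list[str],
    term_sets: list[GeneSet],
    universe: set[str] | None = None,
) -> list[GeneSetResult]:
    """Per-term hypergeometric enrichment with BH-FDR within each namespace.

    The universe defaults to all genes carrying at least one annotation. Term
    gene sets are intersected with the universe before testing; terms with no
    universe gene are dropped. Results are sorted by P ascending (term_id
    breaks ties).
    """
    study = set(study_genes)
    if universe is None:
        universe = set().union(*(s.genes for s in term_sets)) if term_sets else set()
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not study:
        raise ValueError("empty study set")
    if not study <= universe:
        missing = sorted(study - universe)[:5]
        raise ValueError(f"study genes outside universe, e.g. {missing}")

    N, n = len(universe), len(study)
    rows: list[GeneSetResult] = []
    for s in term_sets:
        term_genes = s.genes & universe
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & study)
        # P(X >= k) for X ~ Hypergeom(N, K, n): one-sided Fisher enrichment P
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            GeneSetResult(
                term_id=s.term_id,
                term_name=s.term_name,
                namespace=s.namespace,
                k=k,
                K=K,
                n=n,
                N=N,
                p_value=min(p, 1.0),
                fdr=1.0,
                rich_factor=k / K,
            )
        )
    for namespace in {r.namespace for r in rows}:
        members = [r for r in rows if r.namespace == namespace]
        adjusted = bh_fdr([r.p_value for r in members])
        for r, q in zip(members, adjusted):
            r.fdr = float(max(q, r.p_value))
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    return rows


def top_n_report(
    results: list[GeneSetResult],
    n_bar: int = 15,
    n_bubble: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic top-N tables per namespace (smallest P, tie on term_id).

    Returns the bar table (term, -log10 P) and the bubble table
    (term, rich factor, gene count, P).
    """
    bar_rows, bubble_rows = [], []
    for namespace in sorted({r.namespace for r in results}):
        members = sorted(
            (r for r in results if r.namespace == namespace),
            key=lambda r: (r.p_value, r.term_id),
        )
        for r in members[:n_bar]:
            neglog = -math.log10(r.p_value) if r.p_value > 0 else math.inf
            bar_rows.append(
                {
                    "namespace": namespace,
                    "term_id": r.term_id,
                    "term_name": r.term_name,
                    "minus_log10_p": neglog,
                }
            )
        for r in members[:n_bubble]:
            bubble_rows.append(
                {
                    "namespace": namespace,
                    "term_id": r.term_id,
                    "term_name": r.term_name,
                    "rich_factor": r.rich_factor,
                    "k": r.k,
                    "p_value": r.p_value,
                }
            )
    return pd.DataFrame(bar_rows), pd.DataFrame(bubble_rows)


def write_results(results: list[GeneSetResult], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "term_name": [r.term_name for r in results],
            "namespace": [r.namespace for r in results],
            "k": [r.k for r in results],
            "K": [r.K for r in results],
            "n": [r.n for r in results],
            "N": [r.N for r in results],
            "p_value": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
            "rich_factor": [r.rich_factor for r in results],
        }
    ).to_csv(path, sep="\t", index=False)
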