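"""Gene-set enrichment: hypergeometric over-representation and ranked
running-sum (GSEA-style) analysis with leading-edge extraction."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .data import GeneSetCollection
from .de_stats import bh_fdr


def hypergeometric_test(query, gene_set, universe) -> float:
    """Upper-tail hypergeometric p-value P(X >= overlap).

    The gene set is intersected with the universe before testing; the
    query must be a subset of the universe.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query)
    if not q:
        raise ValueError("empty query")
    if not q <= uni:
        raise ValueError("query is not a subset of the universe")
    gs = set(gene_set) & uni
    k = len(q & gs)
    return float(hypergeom.sf(k - 1, len(uni), len(gs), len(q)))


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p: float
    q: float = np.nan
    members: list[str] = field(default_factory=list)
    significant: bool = False


def ora_collection(
    query,
    collection: GeneSetCollection,
    universe,
    fdr_threshold: float = 0.10,
    min_set: int = 5,
) -> list[EnrichmentResult]:
    """Over-representation analysis of a gene list against a collection.

    Sets with fewer than ``min_set`` in-universe members are skipped;
    BH correction runs across the tested sets; enriched means
    q <= ``fdr_threshold`` (the boundary value counts as enriched).
    """
    uni = set(universe)
    q_set = set(query)
    if not q_set:
        raise ValueError("empty query")
    if not q_set <= uni:
        raise ValueError("query is not a subset of the universe")
    results: list[EnrichmentResult] = []
    for name in collection.names():
        members_in = [g for g in collection.members(name) if g in uni]
        if len(members_in) < min_set:
            continue
        overlap = [g for g in members_in if g in q_set]
        p = float(
            hypergeom.sf(len(overlap) - 1, len(uni), len(members_in), len(q_set))
        )
        results.append(
            EnrichmentResult(
                name, len(overlap), len(members_in), len(q_set), len(uni), p,
                members=overlap,
            )
        )
    if not results:
        warnings.warn("no gene set passed the min_set filter; empty result")
        return results
    qvals = bh_fdr([r.p for r in results])
    for r, qv in zip(results, qvals):
        r.q = float(qv)
        r.significant = qv <= fdr_threshold
    return results


@dataclass
class GseaResult:
    set_name: str
    es: float
    leading_edge: list[str]
    p: float
    q: float = np.nan


def _running_es(
    in_set: np.ndarray, scores: np.ndarray, weight_exponent: float
) -> tuple[float, int, np.ndarray]:
    """Enrichment score, extremum index and running sum of a ranked list."""
    n = in_set.size
    nh = int(in_set.sum())
    weights = np.abs(scores) ** weight_exponent
    hit_w = np.where(in_set, weights, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit scores zero: fall back to unweighted hits
        hit_w = in_set.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~in_set) / (n - nh)
    running = np.cumsum(steps)
    ext = int(np.argmax(np.abs(running)))
    return float(running[ext]), ext, running


def gsea_ranked(
    ranked_genes: list[str],
    scores,
    gene_set,
    n_perm: int = 999,
    weight_exponent: float = 1.0,
    seed: int = 0,
) -> GseaResult:
    """Weighted Kolmogorov-Smirnov enrichment of a set in a ranked list.

    ``ranked_genes`` must be ordered by decreasing score with no
    duplicates. Hits advance the running sum proportionally to
    |score|**weight_exponent (normalized); misses retreat by
    1/(N - set size). ES is the extremum of the running sum; the
    leading edge contains the hits at or before a positive extremum
    (at or after a negative one). The p-value permutes gene labels and
    is two-sided on |ES|.
    """
    if len(set(ranked_genes)) != len(ranked_genes):
        raise ValueError("ranked list contains duplicate gene IDs")
    scores_arr = np.asarray(scores, dtype=float)
    if scores_arr.size != len(ranked_genes):
        raise ValueError("scores do not match ranked list")
    gs = set(gene_set)
    in_set = np.array([g in gs for g in ranked_genes])
    nh = int(in_set.sum())
    if nh == 0:
        raise ValueError("gene set is disjoint from the ranked list")
    if nh == len(ranked_genes):
        raise ValueError("gene set covers the whole ranked list; ES undefined")
    es, ext, _ = _running_es(in_set, scores_arr, weight_exponent)
    if es >= 0:
        leading = [g for k, g in enumerate(ranked_genes) if in_set[k] and k <= ext]
    else:
        leading = [g for k, g in enumerate(ranked_genes) if in_set[k] and k >= ext]

    rng = np.random.default_rng(seed)
    exceed = 0
    labels = in_set.copy()
    for _ in range(n_perm):
        rng.shuffle(labels)
        es_null, _, _ = _running_es(labels, scores_arr, weight_exponent)
        if abs(es_null) >= abs(es):
            exceed += 1
    p = (1.0 + exceed) / (n_perm + 1.0)
    return GseaResult(gene_set_name(gene_set), es, leading, p)


def gene_set_name(gene_set) -> str:
    return getattr(gene_set, "name", "gene_set")


def write_enrichment(results: list[EnrichmentResult], path) -> None:
    rows = [
        (r.set_name, r.overlap, r.set_size, r.query_size, r.universe_size, r.p, r.q,
         int(r.significant), ",".join(r.members))
        for r in results
    ]
    pd.DataFrame(
        rows,
        columns=["set", "overlap", "set_size", "query_size", "universe_size",
                 "p", "q", "significant", "members"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
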