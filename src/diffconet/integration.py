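"""Regulator-pathway-phenotype integration networks.

Builds the tripartite graph that links candidate regulator genes to
pathways (enrichment of the regulator's differentially co-expressed
neighborhood) and to physiological phenotypes (regression of the
training-induced phenotype change on baseline regulator expression),
ranks nodes by degree, and constructs condition-specific seed-gene
pathway neighborhoods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

from .data import PRE, POST, GeneSetCollection, PairedExpressionSet, PhenotypeTable
from .de_stats import bh_fdr
from .enrichment import ora_collection

EVIDENCE_ENRICHMENT = "enrichment"
EVIDENCE_REGRESSION = "regression"
EVIDENCE_CORRELATION = "correlation"


def _corr_with_row(matrix: np.ndarray, row: int) -> np.ndarray:
    """Pearson correlation of one gene against every row, vectorized."""
    x = matrix - matrix.mean(axis=1, keepdims=True)
    norms = np.sqrt((x**2).sum(axis=1))
    if norms[row] == 0:
        raise ValueError("regulator gene has zero variance")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x @ x[row]) / (norms * norms[row])
    return np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)


@dataclass
class RegulatorScores:
    """Differential co-expression of every gene with one regulator."""

    regulator: str
    table: pd.DataFrame  # gene, score, p, q, significant
    fdr_threshold: float

    @property
    def significant_genes(self) -> list[str]:
        return self.table.loc[self.table["significant"], "gene"].tolist()


def regulator_diffcoex_scores(
    eset: PairedExpressionSet,
    regulator: str,
    n_perm: int = 999,
    fdr_threshold: float = 0.10,
    seed: int = 0,
) -> RegulatorScores:
    """Score every gene by |corr_pre - corr_post| with the regulator.

    The permutation null swaps each subject's pre/post assignment
    independently (the same paired scheme as the gene-pair filter) and
    recomputes the regulator-restricted correlation changes; BH across
    all genes.
    """
    reg_idx = eset.gene_index(regulator)
    pre, post = eset.paired_matrices()
    observed = np.abs(_corr_with_row(pre, reg_idx) - _corr_with_row(post, reg_idx))
    rng = np.random.default_rng(seed)
    n_subj = pre.shape[1]
    exceed = np.zeros_like(observed)
    for _ in range(n_perm):
        flip = rng.random(n_subj) < 0.5
        pre_p = np.where(flip[None, :], post, pre)
        post_p = np.where(flip[None, :], pre, post)
        null = np.abs(_corr_with_row(pre_p, reg_idx) - _corr_with_row(post_p, reg_idx))
        exceed += null >= observed
    keep = np.arange(len(eset.gene_ids)) != reg_idx
    p = (1.0 + exceed[keep]) / (n_perm + 1.0)
    q = bh_fdr(p)
    genes = [g for g in eset.gene_ids if g != regulator]
    table = pd.DataFrame(
        {
            "gene": genes,
            "score": observed[keep],
            "p": p,
            "q": q,
            "significant": q <= fdr_threshold,
        }
    )
    return RegulatorScores(regulator, table, fdr_threshold)


@dataclass
class Edge:
    source: str
    target: str
    q: float
    evidence: str


def regulator_pathway_edges(
    scores: RegulatorScores,
    collection: GeneSetCollection,
    universe,
    fdr_threshold: float = 0.10,
    min_set: int = 5,
) -> list[Edge]:
    """One edge per gene set enriched in the regulator's rewired neighborhood."""
    sig = scores.significant_genes
    if not sig:
        warnings.warn(f"regulator {scores.regulator}: no significant neighbors, no edges")
        return []
    uni = [g for g in universe if g != scores.regulator]
    results = ora_collection(sig, collection, uni, fdr_threshold=fdr_threshold, min_set=min_set)
    return [
        Edge(scores.regulator, r.set_name, r.q, EVIDENCE_ENRICHMENT)
        for r in results
        if r.significant
    ]


def regulator_phenotype_edges(
    eset: PairedExpressionSet,
    phenotypes: PhenotypeTable,
    regulators: list[str],
    fdr_threshold: float = 0.10,
    response: str = "delta",
) -> tuple[list[Edge], pd.DataFrame]:
    """Regression of each phenotype's training response on baseline expression.

    For every (regulator, phenotype) pair the per-subject response
    (post - pre by default, percent change with ``response="percent"``)
    is regressed on the subject's baseline (pre) expression of the
    regulator; slope p-values are BH-corrected across the whole grid
    and pairs with q <= ``fdr_threshold`` become edges.
    """
    if response not in ("delta", "percent"):
        raise ValueError(f"unknown response transform {response!r}")
    pre = eset.condition_matrix(PRE)
    subjects = eset.subject_ids
    common = [s for s in subjects if s in set(phenotypes.subject_ids)]
    if len(common) < 4:
        raise ValueError("need >= 4 subjects shared between expression and phenotypes")
    col_of = {s: j for j, s in enumerate(subjects)}
    cols = [col_of[s] for s in common]
    rows = []
    for reg in regulators:
        x_all = pre[eset.gene_index(reg), cols]
        if np.std(x_all) == 0:
            warnings.warn(f"regulator {reg}: zero baseline variance, skipped")
            continue
        for name in phenotypes.names():
            df = phenotypes.measurements[name].loc[common]
            y = (df["post"] - df["pre"]).to_numpy(dtype=float)
            if response == "percent":
                y = 100.0 * y / df["pre"].to_numpy(dtype=float)
            ok = np.isfinite(y)
            if ok.sum() < 4:
                warnings.warn(f"({reg}, {name}): fewer than 4 complete cases, skipped")
                continue
            fit = stats.linregress(x_all[ok], y[ok])
            rows.append((reg, name, fit.slope, fit.stderr, fit.pvalue))
    grid = pd.DataFrame(rows, columns=["regulator", "phenotype", "slope", "stderr", "p"])
    if grid.empty:
        return [], grid
    grid["q"] = bh_fdr(grid["p"].to_numpy())
    edges = [
        Edge(r.regulator, r.phenotype, float(r.q), EVIDENCE_REGRESSION)
        for r in grid.itertuples()
        if r.q <= fdr_threshold
    ]
    return edges, grid


NODE_TYPES = {"regulator_gene", "gene_set", "phenotype"}


def assemble_graph(
    edges: list[Edge],
    node_types: dict[str, str],
) -> nx.Graph:
    """Merge typed edge lists into one simple graph, keeping the best q
    for duplicate edges. Self edges are rejected; every edge must join a
    regulator gene to a non-regulator node."""
    g = nx.Graph()
    for node, t in node_types.items():
        if t not in NODE_TYPES:
            raise ValueError(f"unknown node type {t!r} for {node!r}")
        g.add_node(node, type=t)
    for e in edges:
        if e.source == e.target:
            raise ValueError(f"self edge on {e.source!r}")
        for n in (e.source, e.target):
            if n not in g:
                raise ValueError(f"edge references undeclared node {n!r}")
        ts, tt = g.nodes[e.source]["type"], g.nodes[e.target]["type"]
        if "regulator_gene" not in (ts, tt) or ts == tt:
            raise ValueError(
                f"edge {e.source!r}-{e.target!r} must join a regulator gene to another node type"
            )
        if g.has_edge(e.source, e.target):
            if e.q < g.edges[e.source, e.target]["q"]:
                g.edges[e.source, e.target].update(q=e.q, evidence=e.evidence)
        else:
            g.add_edge(e.source, e.target, q=e.q, evidence=e.evidence)
    return g


def node_degrees(g: nx.Graph) -> pd.DataFrame:
    """Degree table ranked by descending degree, ties broken by node name."""
    rows = sorted(
        ((n, g.nodes[n].get("type", ""), d) for n, d in g.degree()),
        key=lambda t: (-t[2], t[0]),
    )
    df = pd.DataFrame(rows, columns=["node", "type", "degree"])
    df["rank"] = np.arange(1, len(df) + 1)
    return df


@dataclass
class SeedNetwork:
    """Star graph of gene sets enriched among genes correlated with a seed."""

    seed_gene: str
    condition: str
    correlations: pd.DataFrame  # gene, r, p, q, significant
    enrichment: list
    graph: nx.Graph

    @property
    def degree(self) -> int:
        return self.graph.degree(self.seed_gene)


def seed_condition_network(
    eset: PairedExpressionSet,
    seed_gene: str,
    condition: str,
    collection: GeneSetCollection,
    corr_fdr: float = 0.05,
    enrich_fdr: float = 0.10,
    min_set: int = 5,
) -> SeedNetwork:
    """Pathways enriched among genes correlated with the seed in one condition.

    Per-gene correlation p-values come from the exact t transform
    t = r sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom, BH-corrected;
    the significant genes (q <= ``corr_fdr``) are tested for set
    over-representation, and the output star graph connects the seed to
    each enriched set.
    """
    m = eset.condition_matrix(condition)
    n = m.shape[1]
    if n < 4:
        raise ValueError(f"condition {condition!r} has fewer than 4 samples")
    seed_idx = eset.gene_index(seed_gene)
    r = _corr_with_row(m, seed_idx)
    keep = np.arange(len(eset.gene_ids)) != seed_idx
    r = r[keep]
    genes = [g for g in eset.gene_ids if g != seed_gene]
    sat = np.isclose(np.abs(r), 1.0)
    if sat.any():
        warnings.warn("correlation of +/-1 encountered; p set to minimum representable")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[sat] = np.finfo(float).tiny
    q = bh_fdr(p)
    sig = q <= corr_fdr
    corr_table = pd.DataFrame(
        {"gene": genes, "r": r, "p": p, "q": q, "significant": sig}
    )
    sig_genes = corr_table.loc[sig, "gene"].tolist()
    graph = nx.Graph()
    graph.add_node(seed_gene, type="regulator_gene")
    results = []
    if sig_genes:
        results = ora_collection(
            sig_genes, collection, genes, fdr_threshold=enrich_fdr, min_set=min_set
        )
        for res in results:
            if res.significant:
                graph.add_node(res.set_name, type="gene_set")
                graph.add_edge(seed_gene, res.set_name, q=res.q,
                               evidence=EVIDENCE_CORRELATION)
    return SeedNetwork(seed_gene, condition, corr_table, results, graph)


def write_integration_graph(g: nx.Graph, graphml_path=None, degree_path=None) -> None:
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)
    if degree_path is not None:
        node_degrees(g).to_csv(degree_path, sep="\t", index=False)
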