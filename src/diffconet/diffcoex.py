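"""Differential co-expression network inference.

The pipeline scores every gene pair by the change of its expression
correlation between the two conditions, raises the half-change to a
soft-threshold power to obtain an adjacency, converts the adjacency to
a topological-overlap similarity, clusters genes on the corresponding
dissimilarity, and then applies two permutation filters:

* a gene-pair filter that removes within-module pairs whose correlation
  change is not significant against a paired condition-shuffle null
  (Benjamini-Hochberg FDR, default 1%), and
* a module-level test of the dispersion statistic (root-mean-square of
  half correlation differences) against a null of size-matched random
  clusters (default 1,000), keeping module-module edges below a 10% FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .data import PairedExpressionSet
from .de_stats import bh_fdr

PEARSON = "pearson"
SPEARMAN = "spearman"


# ---------------------------------------------------------------------------
# correlation substrate


def _corr(matrix: np.ndarray, method: str = PEARSON) -> np.ndarray:
    if method == SPEARMAN:
        matrix = np.apply_along_axis(rankdata, 1, matrix)
    elif method != PEARSON:
        raise ValueError(f"unknown correlation method {method!r}")
    sd = matrix.std(axis=1)
    if (sd == 0).any():
        raise ValueError(f"zero-variance gene rows at indices {np.flatnonzero(sd == 0)[:5].tolist()}")
    c = np.corrcoef(matrix)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return c


def pairwise_correlation(
    eset: PairedExpressionSet, condition: str, method: str = PEARSON
) -> np.ndarray:
    """Gene-gene correlation matrix within one condition.

    Raises if a gene has zero variance (its name is reported) or if the
    condition has fewer than three samples.
    """
    m = eset.condition_matrix(condition)
    if m.shape[1] < 3:
        raise ValueError(f"need >=3 samples in condition {condition!r}")
    sd = m.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [eset.gene_ids[i] for i in dead[:5]]
        raise ValueError(f"zero-variance genes in condition {condition!r}: {names}")
    return _corr(m, method)


@dataclass
class CorrelationPair:
    """Pre/post correlation matrices over a common gene ordering."""

    corr_pre: np.ndarray
    corr_post: np.ndarray
    method: str = PEARSON

    def __post_init__(self) -> None:
        for name, c in (("corr_pre", self.corr_pre), ("corr_post", self.corr_post)):
            if c.shape != self.corr_pre.shape or c.shape[0] != c.shape[1]:
                raise ValueError(f"{name} is not square / shapes differ")
            if not np.allclose(c, c.T, atol=1e-12):
                raise ValueError(f"{name} not symmetric")
            if not np.allclose(np.diag(c), 1.0):
                raise ValueError(f"{name} diagonal not unit")

    @classmethod
    def from_expression(
        cls, eset: PairedExpressionSet, method: str = PEARSON
    ) -> "CorrelationPair":
        return cls(
            pairwise_correlation(eset, "pre", method),
            pairwise_correlation(eset, "post", method),
            method,
        )

    @property
    def half_delta(self) -> np.ndarray:
        """(corr_pre - corr_post) / 2, the substrate of adjacency and dispersion."""
        return (self.corr_pre - self.corr_post) / 2.0


# ---------------------------------------------------------------------------
# adjacency / topological overlap


def differential_adjacency(cp: CorrelationPair, beta: float = 6.0) -> np.ndarray:
    """a_ij = (|corr_pre_ij - corr_post_ij| / 2) ** beta, zero diagonal."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    a = np.abs(cp.half_delta) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap similarity of an adjacency in [0, 1].

    T_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j, with unit diagonal. Genes sharing many strong neighbors get
    high overlap even if their direct edge is noisy.
    """
    a = np.asarray(adjacency, dtype=float)
    if (a < 0).any() or (a > 1).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1)
    numer = a @ a + a  # zero diagonal makes the u=i, u=j terms vanish
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        t = numer / denom
    t = np.clip(np.nan_to_num(t, nan=0.0), 0.0, 1.0)
    np.fill_diagonal(t, 1.0)
    return t


@dataclass
class DifferentialNetwork:
    """Adjacency + topological overlap of the differential network."""

    adjacency: np.ndarray
    tom: np.ndarray
    beta: float

    @classmethod
    def from_correlations(cls, cp: CorrelationPair, beta: float = 6.0) -> "DifferentialNetwork":
        a = differential_adjacency(cp, beta)
        return cls(a, topological_overlap(a), beta)


# ---------------------------------------------------------------------------
# module detection


@dataclass
class ModulePartition:
    """Gene -> module labels; 0 marks unassigned genes.

    Labels are contiguous positive integers ordered by decreasing
    module size (ties broken by first gene index).
    """

    gene_ids: list[str]
    labels: np.ndarray
    min_module_size: int = 10

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.gene_ids) != self.labels.size:
            raise ValueError("labels do not match gene_ids")

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.labels) - {0})

    def module_sizes(self) -> dict[int, int]:
        return {m: int((self.labels == m).sum()) for m in self.module_ids}

    def genes_in(self, module: int) -> list[str]:
        return [g for g, l in zip(self.gene_ids, self.labels) if l == module]

    def indices_in(self, module: int) -> np.ndarray:
        return np.flatnonzero(self.labels == module)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.gene_ids, "module": self.labels})


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Renumber nonzero labels 1..K by decreasing size, stable for ties."""
    out = np.zeros_like(labels)
    sizes = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        idx = np.flatnonzero(labels == lab)
        sizes.append((-idx.size, idx[0], lab))
    for new, (_, _, old) in enumerate(sorted(sizes), start=1):
        out[labels == old] = new
    return out


def cluster_modules(
    tom: np.ndarray,
    gene_ids: list[str],
    min_module_size: int = 10,
    cut_height: float = 0.99,
    method: str = "average",
) -> ModulePartition:
    """Detect modules by average-linkage clustering of 1 - TOM.

    The tree is cut at an absolute dissimilarity ``cut_height`` (the
    sensitivity knob of the procedure: lower cuts split more
    aggressively); clusters smaller than ``min_module_size`` are left
    unassigned (label 0).
    """
    n = len(gene_ids)
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    if n < min_module_size:
        warnings.warn("fewer genes than min_module_size; all genes unassigned")
        return ModulePartition(gene_ids, np.zeros(n, dtype=int), min_module_size)
    dissim = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(dissim, 0.0)
    if method != "average":
        raise ValueError("only average linkage is supported")
    link = average(squareform(dissim, checks=False))
    raw = fcluster(link, t=cut_height, criterion="distance")
    labels = np.asarray(raw, dtype=int)
    for lab in np.unique(labels):
        if (labels == lab).sum() < min_module_size:
            labels[labels == lab] = 0
    return ModulePartition(gene_ids, _relabel_by_size(labels), min_module_size)


# ---------------------------------------------------------------------------
# gene-pair permutation filter


@dataclass
class PairFilterResult:
    """Per within-module gene pair: observed |delta corr|, permutation p, BH q."""

    table: pd.DataFrame  # columns: gene_i, gene_j, module, delta, p, q, retained
    filtered_partition: ModulePartition
    n_perm: int
    fdr_threshold: float


def _condition_swap_half_delta(
    pre: np.ndarray, post: np.ndarray, flip: np.ndarray, method: str
) -> np.ndarray:
    """Half correlation difference after swapping pre/post for flipped subjects."""
    pre_p = np.where(flip[None, :], post, pre)
    post_p = np.where(flip[None, :], pre, post)
    return (_corr(pre_p, method) - _corr(post_p, method)) / 2.0


def filter_gene_pairs(
    eset: PairedExpressionSet,
    partition: ModulePartition,
    n_perm: int = 999,
    fdr_threshold: float = 0.01,
    seed: int = 0,
    method: str = PEARSON,
    drop_isolated_genes: bool = True,
) -> PairFilterResult:
    """Permutation filter on within-module correlation changes.

    For every within-module gene pair the observed statistic is
    |corr_pre - corr_post|. The null swaps each subject's pre/post
    labels independently (the paired-design analogue of a condition
    permutation) and recomputes the statistic; p-values use the +1
    correction, are BH-adjusted across all tested pairs, and pairs with
    q above ``fdr_threshold`` are removed. Genes that lose every
    within-module edge are dropped from their module (label 0) unless
    ``drop_isolated_genes`` is False.
    """
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} gives coarse p-value resolution (min p = {1/(n_perm+1):.3g})")
    modules = partition.module_ids
    if not modules:
        raise ValueError("partition has no modules to filter")
    rng = np.random.default_rng(seed)
    pre, post = eset.paired_matrices()

    rows_i: list[int] = []
    rows_j: list[int] = []
    mod_of_pair: list[int] = []
    for m in modules:
        idx = partition.indices_in(m)
        ii, jj = np.triu_indices(idx.size, k=1)
        rows_i.extend(idx[ii])
        rows_j.extend(idx[jj])
        mod_of_pair.extend([m] * ii.size)
    rows_i_arr = np.asarray(rows_i)
    rows_j_arr = np.asarray(rows_j)

    # restrict to module genes: permutation correlations only needed there
    used = np.unique(np.concatenate([rows_i_arr, rows_j_arr]))
    pos = {g: k for k, g in enumerate(used)}
    pre_u, post_u = pre[used], post[used]
    pi = np.array([pos[g] for g in rows_i_arr])
    pj = np.array([pos[g] for g in rows_j_arr])

    obs_half = (_corr(pre_u, method) - _corr(post_u, method)) / 2.0
    observed = 2.0 * np.abs(obs_half[pi, pj])  # |delta corr|

    exceed = np.zeros(observed.size)
    n_subj = pre_u.shape[1]
    for _ in range(n_perm):
        flip = rng.random(n_subj) < 0.5
        null_half = _condition_swap_half_delta(pre_u, post_u, flip, method)
        null_stat = 2.0 * np.abs(null_half[pi, pj])
        exceed += null_stat >= observed
    p = (1.0 + exceed) / (n_perm + 1.0)
    q = bh_fdr(p)
    retained = q <= fdr_threshold

    labels = partition.labels.copy()
    if drop_isolated_genes:
        keeps_edge = set(rows_i_arr[retained]) | set(rows_j_arr[retained])
        for g in used:
            if g not in keeps_edge:
                labels[g] = 0
    table = pd.DataFrame(
        {
            "gene_i": [eset.gene_ids[g] for g in rows_i_arr],
            "gene_j": [eset.gene_ids[g] for g in rows_j_arr],
            "module": mod_of_pair,
            "delta": observed,
            "p": p,
            "q": q,
            "retained": retained,
        }
    )
    filtered = ModulePartition(
        partition.gene_ids, _relabel_by_size(labels), partition.min_module_size
    )
    return PairFilterResult(table, filtered, n_perm, fdr_threshold)


# ---------------------------------------------------------------------------
# module-module dispersion


def module_dispersion(
    cp: CorrelationPair, genes_a: np.ndarray, genes_b: np.ndarray
) -> float:
    """Root-mean-square half correlation change over a module pair.

    For a module against itself the mean runs over unordered
    within-module pairs (i < j); a singleton module has no such pairs
    and raises.
    """
    a = np.asarray(genes_a)
    b = np.asarray(genes_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty module in dispersion computation")
    hd = cp.half_delta
    same = a.size == b.size and np.array_equal(np.sort(a), np.sort(b))
    if same:
        if a.size < 2:
            raise ValueError("within-module dispersion needs >= 2 genes")
        block = hd[np.ix_(a, a)]
        ii, jj = np.triu_indices(a.size, k=1)
        vals = block[ii, jj]
    else:
        vals = hd[np.ix_(a, b)].ravel()
    return float(np.sqrt(np.mean(vals**2)))


@dataclass
class DispersionResult:
    module_a: int
    module_b: int
    d: float
    p: float
    q: float = np.nan
    significant: bool = False


def _block_stats(hd2: np.ndarray, indicator: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Dispersion d for every module pair at once via indicator matmuls.

    ``hd2`` is the squared half-delta matrix (zero diagonal irrelevant:
    handled for the within case), ``indicator`` is genes x modules 0/1.
    Returns a modules x modules matrix of d values.
    """
    s = indicator.T @ hd2 @ indicator  # block sums including diagonal terms
    counts = np.outer(sizes, sizes).astype(float)
    # within-module: unordered pairs, subtract the (zero) diagonal and halve
    diag_sums = np.einsum("gm,g,gm->m", indicator, np.diag(hd2), indicator)
    np.fill_diagonal(s, (np.diag(s) - diag_sums) / 2.0)
    within_counts = sizes * (sizes - 1) / 2.0
    np.fill_diagonal(counts, within_counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt(s / counts)
    return d


def dispersion_significance(
    eset: PairedExpressionSet,
    partition: ModulePartition,
    n_random: int = 1000,
    fdr_threshold: float = 0.10,
    seed: int = 0,
    method: str = PEARSON,
    null_mode: str = "size_matched",
) -> list[DispersionResult]:
    """Permutation test of the dispersion statistic for every module pair.

    The null draws ``n_random`` random partitions with the observed
    module-size multiset (genes sampled without replacement from the
    analyzed universe) and recomputes d for every random module pair.
    Each observed pair is compared against null values for pairs with
    the same (unordered) size pair (``null_mode="size_matched"``,
    default) or against the pooled null (``null_mode="pooled"``).
    Edges are pairs with BH q <= ``fdr_threshold``.
    """
    modules = partition.module_ids
    if len(modules) < 2:
        raise ValueError("need >= 2 modules for dispersion significance")
    if n_random < 100:
        warnings.warn(f"n_random={n_random} gives coarse p-value resolution")
    if null_mode not in ("size_matched", "pooled"):
        raise ValueError(f"unknown null_mode {null_mode!r}")
    rng = np.random.default_rng(seed)

    # universe = genes assigned to any module
    universe = np.flatnonzero(partition.labels > 0)
    cp = CorrelationPair.from_expression(eset, method)
    hd2 = cp.half_delta**2

    sizes = np.array([partition.module_sizes()[m] for m in modules])
    k = len(modules)
    indicator = np.zeros((len(partition.gene_ids), k))
    for col, m in enumerate(modules):
        indicator[partition.indices_in(m), col] = 1.0
    observed = _block_stats(hd2, indicator, sizes)

    # null: random partitions with the same size multiset over the universe
    null_d = np.empty((n_random, k, k))
    for r in range(n_random):
        perm = rng.permutation(universe)
        ind = np.zeros((len(partition.gene_ids), k))
        start = 0
        for col, sz in enumerate(sizes):
            ind[perm[start : start + sz], col] = 1.0
            start += sz
        null_d[r] = _block_stats(hd2, ind, sizes)

    results: list[DispersionResult] = []
    pvals: list[float] = []
    pairs: list[tuple[int, int]] = []
    for ai in range(k):
        for bi in range(ai, k):
            d_obs = observed[ai, bi]
            if null_mode == "pooled":
                null_vals = null_d.ravel()
            else:
                size_pair = tuple(sorted((sizes[ai], sizes[bi])))
                cols = [
                    (x, y)
                    for x in range(k)
                    for y in range(x, k)
                    if tuple(sorted((sizes[x], sizes[y]))) == size_pair
                    and (x == y) == (ai == bi)  # within vs cross are different statistics
                ]
                null_vals = np.concatenate([null_d[:, x, y] for x, y in cols])
            p = (1.0 + np.sum(null_vals >= d_obs)) / (null_vals.size + 1.0)
            pairs.append((modules[ai], modules[bi]))
            pvals.append(p)
            results.append(DispersionResult(modules[ai], modules[bi], float(d_obs), p))
    qvals = bh_fdr(np.asarray(pvals))
    for res, q in zip(results, qvals):
        res.q = float(q)
        res.significant = q <= fdr_threshold
    return results


def build_module_graph(
    partition: ModulePartition, results: list[DispersionResult]
) -> nx.Graph:
    """Module-level graph: nodes are modules (size attribute), edges are
    significant dispersion pairs with d and q attributes."""
    g = nx.Graph()
    for m, size in partition.module_sizes().items():
        g.add_node(m, size=size)
    for res in results:
        if res.significant and res.module_a != res.module_b:
            g.add_edge(res.module_a, res.module_b, d=res.d, p=res.p, q=res.q)
        elif res.significant:
            g.nodes[res.module_a]["within_d"] = res.d
            g.nodes[res.module_a]["within_q"] = res.q
    return g


def write_module_graph(g: nx.Graph, graphml_path=None, sif_path=None) -> None:
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)
    if sif_path is not None:
        with open(sif_path, "w") as fh:
            fh.write("module_a\tinteraction\tmodule_b\td\tp\tq\n")
            for a, b, attrs in g.edges(data=True):
                fh.write(
                    f"{a}\tdiffcoex\t{b}\t{attrs['d']:.6g}\t{attrs['p']:.6g}\t{attrs['q']:.6g}\n"
                )
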