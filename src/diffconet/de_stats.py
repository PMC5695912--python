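"""Paired differential expression: SAM-style permutation statistic,
fold-change/p filtering, and the shared Benjamini-Hochberg utility."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data import PairedExpressionSet


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SamResult:
    """Per-gene paired SAM output.

    ``d = r / (s + s0)`` where r is the mean paired difference, s its
    standard error and s0 the variance-stabilizing fudge factor shared
    across genes.
    """

    table: pd.DataFrame  # gene, r, s, d, p, q, significant
    s0: float
    n_perm: int
    fdr_threshold: float

    @property
    def significant_genes(self) -> list[str]:
        return self.table.loc[self.table["significant"], "gene"].tolist()


def _fudge_factor(r: np.ndarray, s: np.ndarray, rule) -> float:
    """Choose s0 per the stated rule.

    The default ``"cv"`` rule scans s0 over percentiles of {s_i} and
    picks the value minimizing the coefficient of variation of the
    median absolute deviation of d across bins of s_i — the classic SAM
    tuning heuristic. ``"median"`` uses the median of s; a float is a
    fixed value.
    """
    if isinstance(rule, (int, float)) and not isinstance(rule, bool):
        if rule < 0:
            raise ValueError("fixed s0 must be nonnegative")
        return float(rule)
    if rule == "median":
        return float(np.median(s))
    if rule != "cv":
        raise ValueError(f"unknown s0 rule {rule!r}")
    n_bins = min(10, max(2, s.size // 10))
    # bin genes by s quantile once
    edges = np.quantile(s, np.linspace(0, 1, n_bins + 1))
    bin_of = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_bins - 1)
    best_s0, best_cv = 0.0, np.inf
    for alpha in np.linspace(0.0, 1.0, 21):
        s0 = float(np.quantile(s, alpha))
        d = r / (s + s0)
        mads = []
        for b in range(n_bins):
            sel = bin_of == b
            if sel.sum() < 2:
                continue
            db = d[sel]
            mads.append(np.median(np.abs(db - np.median(db))))
        mads_arr = np.asarray(mads)
        if mads_arr.size < 2 or mads_arr.mean() == 0:
            continue
        cv = mads_arr.std() / mads_arr.mean()
        if cv < best_cv:
            best_cv, best_s0 = cv, s0
    return best_s0


def sam_paired(
    eset: PairedExpressionSet,
    n_perm: int = 999,
    s0_rule="cv",
    fdr_threshold: float = 0.05,
    seed: int = 0,
) -> SamResult:
    """Paired two-class SAM with a sign-flip permutation null.

    For each gene, r is the mean post - pre difference over subjects
    and s its standard error. The null flips the sign of each subject's
    difference vector independently; the two-sided p-value compares
    |d_null| to |d_obs| with the +1 correction, and significance is
    BH q <= ``fdr_threshold``.
    """
    if eset.n_subjects < 4:
        raise ValueError("paired SAM needs >= 4 subjects")
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} gives coarse p-value resolution")
    pre, post = eset.paired_matrices()
    diffs = post - pre  # genes x subjects
    n = diffs.shape[1]
    r = diffs.mean(axis=1)
    s = diffs.std(axis=1, ddof=1) / np.sqrt(n)
    s0 = _fudge_factor(r, s, s0_rule)
    if s0 == 0 and (s == 0).any():
        dead = np.flatnonzero(s == 0)[:5]
        names = [eset.gene_ids[i] for i in dead]
        raise ValueError(f"zero-variance paired differences with s0=0: {names}")
    d = r / (s + s0)

    rng = np.random.default_rng(seed)
    # sign flips change the mean but not sum of squares: vectorized null
    sq_sum = (diffs**2).sum(axis=1)
    exceed = np.zeros(d.size)
    abs_d = np.abs(d)
    signs = rng.choice([-1.0, 1.0], size=(n, n_perm))
    means = diffs @ signs / n  # genes x n_perm
    var = (sq_sum[:, None] - n * means**2) / (n - 1)
    se = np.sqrt(np.maximum(var, 0.0)) / np.sqrt(n)
    d_null = means / (se + s0)
    exceed = (np.abs(d_null) >= abs_d[:, None]).sum(axis=1)
    p = (1.0 + exceed) / (n_perm + 1.0)
    q = bh_fdr(p)
    table = pd.DataFrame(
        {
            "gene": eset.gene_ids,
            "r": r,
            "s": s,
            "d": d,
            "p": p,
            "q": q,
            "significant": q <= fdr_threshold,
        }
    )
    return SamResult(table, s0, n_perm, fdr_threshold)


def fc_p_filter(
    log2fc: pd.Series,
    p: pd.Series,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> list[str]:
    """Genes with |log2 fold change| strictly above ``fc_threshold`` and
    p strictly below ``p_threshold``. Indices must match exactly."""
    if not log2fc.index.equals(p.index):
        raise ValueError("log2fc and p are not aligned on the same gene IDs")
    sel = (log2fc.abs() > fc_threshold) & (p < p_threshold)
    return log2fc.index[sel].tolist()


def write_sam_result(result: SamResult, path) -> None:
    result.table.to_csv(path, sep="\t", index=False, float_format="%.6g")
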