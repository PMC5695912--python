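"""Shared fixtures: small synthetic datasets and brute-force oracles."""

import numpy as np
import pytest

from diffconet import PairedExpressionSet, SyntheticConfig, generate_paired_expression
from diffconet.simulate import PhenotypeSpec


def make_eset(values: np.ndarray, gene_ids=None, subjects=None) -> PairedExpressionSet:
    """Wrap a genes x (2 * n_subjects) matrix, columns alternating pre/post."""
    n_genes, n_samples = values.shape
    assert n_samples % 2 == 0
    n_subj = n_samples // 2
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    subjects = subjects or [f"s{j}" for j in range(n_subj)]
    sample_subjects = []
    sample_conditions = []
    for s in subjects:
        sample_subjects += [s, s]
        sample_conditions += ["pre", "post"]
    return PairedExpressionSet(gene_ids, sample_subjects, sample_conditions, values)


def null_eset(n_genes: int, n_subjects: int, seed: int) -> PairedExpressionSet:
    """Global-null paired data: every gene independent standard normal."""
    rng = np.random.default_rng(seed)
    return make_eset(rng.standard_normal((n_genes, 2 * n_subjects)))


@pytest.fixture
def small_synthetic():
    """300 genes, 40 subjects, 5 rewired modules, a hub, one phenotype."""
    cfg = SyntheticConfig(
        n_genes=300,
        n_subjects=40,
        seed=11,
        phenotype_specs=[PhenotypeSpec(n_driver_genes=1, effect_size=2.0, noise_sd=1.0)],
    )
    eset, truth = generate_paired_expression(cfg)
    return cfg, eset, truth


def tom_triple_loop(a: np.ndarray) -> np.ndarray:
    """Naive O(n^3) topological overlap used as the independent oracle."""
    n = a.shape[0]
    k = a.sum(axis=1)
    t = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            t[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return t


def bh_step_up(p: np.ndarray) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up definition."""
    n = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * n / rank_from_top)
        q[idx] = running_min
    return q
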