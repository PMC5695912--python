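"""Synthetic paired-design expression data with planted network structure.

The generator emulates the kind of data a paired endurance-training
transcriptome study produces: one pre- and one post-training sample per
subject, groups of genes whose mutual correlation differs between the
two states (rewired modules), a hub regulator whose neighborhood is
condition specific, pathway annotations that overlap the planted
modules, and physiological phenotypes whose training response depends
linearly on baseline expression of driver genes.

Module genes are generated from a per-subject latent factor with
loading sqrt(rho) plus independent Gaussian noise of variance (1-rho),
so the expected pairwise correlation inside a module equals the target
rho exactly. Latent factors are drawn independently per condition, so
pre/post pairing induces no cross-condition structure unless planted.
A negative target rho is realized as a two-arm module: half the genes
load +sqrt(|rho|) and half load -sqrt(|rho|), the strongest mutual
anti-correlation realizable for more than two genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import PRE, POST, PairedExpressionSet, GeneSetCollection, PhenotypeTable

import pandas as pd


class ConfigError(ValueError):
    """Raised for an inconsistent synthetic-data configuration."""


@dataclass
class ModuleSpec:
    """One planted co-expression module.

    ``rewired`` modules change their within-module correlation between
    conditions; non-rewired modules keep it fixed. Modules given the
    same ``group`` share one latent factor per condition, so they are
    co-rewired: their cross-module correlations change together with
    the within-module ones.
    """

    size: int = 30
    rewired: bool = True
    within_corr_pre: float = 0.85
    within_corr_post: float = -0.85
    group: int | None = None

    def __post_init__(self) -> None:
        for rho in (self.within_corr_pre, self.within_corr_post):
            if not -1.0 <= rho <= 1.0:
                raise ConfigError(f"target correlation {rho} outside [-1, 1]")
        if self.size < 2:
            raise ConfigError("module size must be >= 2")
        if not self.rewired and self.within_corr_pre != self.within_corr_post:
            raise ConfigError("non-rewired module must have equal pre/post correlation")


@dataclass
class PhenotypeSpec:
    """One synthetic physiological measurement.

    The training-induced change (post - pre) of the measurement is a
    linear function of the baseline expression of ``n_driver_genes``
    driver genes (each with coefficient ``effect_size``) plus Gaussian
    noise. Drivers are sampled from the gene universe unless given
    explicitly.
    """

    n_driver_genes: int = 1
    effect_size: float = 2.0
    noise_sd: float = 1.0
    drivers: list[str] | None = None
    name: str | None = None


def default_modules() -> list[ModuleSpec]:
    """Five strongly rewired modules of 30 genes (sign-flip rewiring)."""
    return [ModuleSpec() for _ in range(5)]


@dataclass
class SyntheticConfig:
    n_genes: int = 2000
    n_subjects: int = 40
    modules: list[ModuleSpec] = field(default_factory=default_modules)
    hub_gene_neighbors_pre: int = 30
    hub_gene_neighbors_post: int = 30
    hub_corr: float = 0.7
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    phenotype_specs: list[PhenotypeSpec] = field(default_factory=list)
    seed: int = 0

    @property
    def has_hub(self) -> bool:
        return self.hub_gene_neighbors_pre + self.hub_gene_neighbors_post > 0

    def validate(self) -> None:
        planted = sum(m.size for m in self.modules)
        if self.has_hub:
            planted += 1 + self.hub_gene_neighbors_pre + self.hub_gene_neighbors_post
        if planted > self.n_genes:
            raise ConfigError(
                f"planted structure needs {planted} genes but n_genes={self.n_genes}"
            )
        if self.n_subjects < 4:
            raise ConfigError("n_subjects must be >= 4")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        if not 0.0 <= self.hub_corr <= 1.0:
            raise ConfigError("hub_corr must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic dataset.

    ``module_of_gene`` maps every gene to its planted module label
    (0 = background); hub neighborhoods and planted pathway sets are
    recorded so downstream recovery can be scored.
    """

    module_of_gene: dict[str, int]
    hub_gene_id: str | None
    planted_sets: dict[str, list[str]]
    phenotype_drivers: dict[str, tuple[list[str], list[float]]]

    def module_labels(self, gene_ids: list[str]) -> np.ndarray:
        return np.array([self.module_of_gene.get(g, 0) for g in gene_ids])

    def background_genes(self, gene_ids: list[str]) -> list[str]:
        planted = {g for members in self.planted_sets.values() for g in members}
        if self.hub_gene_id is not None:
            planted.add(self.hub_gene_id)
        return [g for g in gene_ids if g not in planted]


def _module_block(
    rng: np.random.Generator,
    size: int,
    rho: float,
    n_subjects: int,
    factor: np.ndarray | None = None,
) -> np.ndarray:
    """size x n_subjects block with expected pairwise correlation rho."""
    if factor is None:
        factor = rng.standard_normal(n_subjects)
    eps = rng.standard_normal((size, n_subjects))
    a = abs(rho)
    signs = np.ones(size)
    if rho < 0:
        signs[size // 2:] = -1.0
    return signs[:, None] * np.sqrt(a) * factor[None, :] + np.sqrt(1.0 - a) * eps


def generate_paired_expression(
    config: SyntheticConfig,
) -> tuple[PairedExpressionSet, SyntheticTruth]:
    """Simulate a paired pre/post expression matrix with planted structure.

    Returns the expression set together with the ground truth needed to
    score module recovery, hub detection, enrichment, and phenotype
    regression downstream. Identical config (including seed) gives
    bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, s = config.n_genes, config.n_subjects
    gene_ids = [f"G{i:05d}" for i in range(n)]
    subject_ids = [f"subj{j:03d}" for j in range(s)]

    baseline = config.baseline_mean + config.baseline_sd * rng.standard_normal(n)
    mats = {PRE: rng.standard_normal((n, s)), POST: rng.standard_normal((n, s))}

    module_of_gene: dict[str, int] = {}
    planted_sets: dict[str, list[str]] = {}
    group_factors: dict[tuple[int, str], np.ndarray] = {}
    cursor = 0
    for k, spec in enumerate(config.modules, start=1):
        idx = np.arange(cursor, cursor + spec.size)
        cursor += spec.size
        members = [gene_ids[i] for i in idx]
        for g in members:
            module_of_gene[g] = k
        planted_sets[f"module_{k}"] = members
        for cond, rho in ((PRE, spec.within_corr_pre), (POST, spec.within_corr_post)):
            factor = None
            if spec.group is not None:
                key = (spec.group, cond)
                if key not in group_factors:
                    group_factors[key] = rng.standard_normal(s)
                factor = group_factors[key]
            mats[cond][idx, :] = _module_block(rng, spec.size, rho, s, factor)

    hub_gene_id: str | None = None
    if config.has_hub:
        hub_idx = cursor
        hub_gene_id = gene_ids[hub_idx]
        cursor += 1
        nb = {PRE: config.hub_gene_neighbors_pre, POST: config.hub_gene_neighbors_post}
        hc = config.hub_corr
        for cond in (PRE, POST):
            factor = rng.standard_normal(s)
            mats[cond][hub_idx, :] = (
                np.sqrt(hc) * factor + np.sqrt(1 - hc) * rng.standard_normal(s)
            )
            if nb[cond] == 0:
                continue
            idx = np.arange(cursor, cursor + nb[cond])
            cursor += nb[cond]
            members = [gene_ids[i] for i in idx]
            planted_sets[f"hub_neighbors_{cond}"] = members
            mats[cond][idx, :] = np.sqrt(hc) * factor[None, :] + np.sqrt(
                1 - hc
            ) * rng.standard_normal((nb[cond], s))

    # assemble: scale by noise_sd, add per-gene baseline, interleave samples
    values = np.empty((n, 2 * s))
    sample_subjects: list[str] = []
    sample_conditions: list[str] = []
    for j, subj in enumerate(subject_ids):
        for c_off, cond in enumerate((PRE, POST)):
            values[:, 2 * j + c_off] = config.noise_sd * mats[cond][:, j] + baseline
            sample_subjects.append(subj)
            sample_conditions.append(cond)

    eset = PairedExpressionSet(gene_ids, sample_subjects, sample_conditions, values)

    phenotype_drivers: dict[str, tuple[list[str], list[float]]] = {}
    for p, spec in enumerate(config.phenotype_specs):
        name = spec.name or f"pheno_{p}"
        if spec.drivers is not None:
            drivers = list(spec.drivers)
            unknown = [g for g in drivers if g not in module_of_gene and g not in gene_ids]
            if unknown:
                raise ConfigError(f"phenotype {name!r} names unknown drivers {unknown}")
        else:
            drivers = [gene_ids[i] for i in rng.choice(n, size=spec.n_driver_genes, replace=False)]
        phenotype_drivers[name] = (drivers, [spec.effect_size] * len(drivers))

    truth = SyntheticTruth(module_of_gene, hub_gene_id, planted_sets, phenotype_drivers)
    return eset, truth


def generate_phenotypes(
    truth: SyntheticTruth,
    eset: PairedExpressionSet,
    config: SyntheticConfig,
) -> PhenotypeTable:
    """Simulate pre/post phenotype measurements from the planted drivers.

    Each phenotype's per-subject training delta is the planted linear
    combination of baseline (pre) driver expression plus Gaussian noise;
    the pre value is an independent baseline level.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    pre = eset.condition_matrix(PRE)
    subjects = eset.subject_ids
    specs = {(sp.name or f"pheno_{p}"): sp for p, sp in enumerate(config.phenotype_specs)}
    measurements: dict[str, pd.DataFrame] = {}
    for name, (drivers, coeffs) in truth.phenotype_drivers.items():
        missing = [g for g in drivers if g not in eset.gene_ids]
        if missing:
            raise ConfigError(f"phenotype {name!r}: driver genes not in matrix: {missing}")
        rows = np.array([eset.gene_index(g) for g in drivers])
        delta = np.asarray(coeffs) @ pre[rows, :]
        sd = specs[name].noise_sd if name in specs else 1.0
        if sd > 0:
            delta = delta + sd * rng.standard_normal(len(subjects))
        base = 100.0 + 10.0 * rng.standard_normal(len(subjects))
        measurements[name] = pd.DataFrame(
            {"pre": base, "post": base + delta}, index=subjects
        )
    return PhenotypeTable(list(subjects), measurements)


def generate_gene_sets(
    truth: SyntheticTruth,
    gene_ids: list[str],
    n_decoy_sets: int,
    set_size: int,
    seed: int,
) -> GeneSetCollection:
    """Planted pathway sets plus uniform decoy sets from background genes.

    Planted sets are exact copies of the planted modules and hub
    neighborhoods; decoys are drawn without replacement from background
    genes, so any overlap with planted structure is purely
    hypergeometric.
    """
    if not gene_ids:
        raise ConfigError("empty gene universe")
    background = truth.background_genes(gene_ids)
    if n_decoy_sets > 0 and set_size > len(background):
        raise ConfigError(
            f"decoy set_size {set_size} exceeds background universe {len(background)}"
        )
    rng = np.random.default_rng(seed)
    sets: dict[str, tuple[str, list[str]]] = {}
    for name, members in truth.planted_sets.items():
        sets[name] = ("planted", list(members))
    for d in range(n_decoy_sets):
        picks = rng.choice(len(background), size=set_size, replace=False)
        sets[f"decoy_{d}"] = ("decoy", [background[i] for i in sorted(picks)])
    return GeneSetCollection(sets)


def write_truth(truth: SyntheticTruth, path) -> None:
    """Serialize ground truth as a simple sectioned key-value text file."""
    with open(path, "w") as fh:
        fh.write("[hub]\n")
        fh.write(f"hub_gene_id\t{truth.hub_gene_id or ''}\n")
        fh.write("[modules]\n")
        for g, m in truth.module_of_gene.items():
            fh.write(f"{g}\t{m}\n")
        fh.write("[planted_sets]\n")
        for name, members in truth.planted_sets.items():
            fh.write("\t".join([name, *members]) + "\n")
        fh.write("[phenotype_drivers]\n")
        for name, (drivers, coeffs) in truth.phenotype_drivers.items():
            fh.write(
                "\t".join([name, ",".join(drivers), ",".join(str(c) for c in coeffs)])
                + "\n"
            )
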