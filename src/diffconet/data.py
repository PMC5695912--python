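"""Core data containers and plain-text readers/writers.

The pipeline operates on three kinds of input: a paired two-condition
expression matrix (genes x samples, log2 scale), gene-set collections in
GMT format, and per-subject phenotype tables with a pre- and a
post-training measurement. Everything is tab-delimited text; values are
validated (finite, complete pairing, unique identifiers) at load time
rather than imputed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

PRE = "pre"
POST = "post"
CONDITIONS = (PRE, POST)


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass
class PairedExpressionSet:
    """Genes x samples log2 expression with subject pairing.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per matrix row.
    sample_subjects
        Subject identifier of each column.
    sample_conditions
        Condition label of each column, one of ``"pre"`` / ``"post"``.
        Each subject must appear exactly once per condition.
    values
        Real matrix of shape (n_genes, n_samples); all entries finite.
    """

    gene_ids: list[str]
    sample_subjects: list[str]
    sample_conditions: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("expression values must be a 2-D matrix")
        n_genes, n_samples = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise DataError("gene_ids length does not match matrix rows")
        if len(self.sample_subjects) != n_samples or len(self.sample_conditions) != n_samples:
            raise DataError("sample annotations do not match matrix columns")
        if len(set(self.gene_ids)) != n_genes:
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise DataError(f"duplicate gene IDs: {dupes[:5]}")
        bad = ~np.isfinite(self.values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataError(
                f"non-finite expression value at gene {self.gene_ids[i]!r}, "
                f"sample column {j}"
            )
        for c in self.sample_conditions:
            if c not in CONDITIONS:
                raise DataError(f"unknown condition label {c!r}; expected 'pre' or 'post'")
        # pairing: every subject exactly once per condition
        seen: dict[tuple[str, str], int] = {}
        for subj, cond in zip(self.sample_subjects, self.sample_conditions):
            key = (subj, cond)
            if key in seen:
                raise DataError(f"subject {subj!r} appears more than once in condition {cond!r}")
            seen[key] = 1
        subjects = self.subject_ids
        for subj in subjects:
            for cond in CONDITIONS:
                if (subj, cond) not in seen:
                    raise DataError(f"subject {subj!r} lacks a {cond!r} sample")

    @property
    def subject_ids(self) -> list[str]:
        """Subjects in first-appearance order."""
        out: list[str] = []
        for s in self.sample_subjects:
            if s not in out:
                out.append(s)
        return out

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise DataError(f"gene {gene!r} not in expression set") from None

    def condition_matrix(self, condition: str) -> np.ndarray:
        """Genes x subjects matrix for one condition, columns in subject order."""
        if condition not in CONDITIONS:
            raise DataError(f"unknown condition {condition!r}")
        order = self.subject_ids
        cols = {
            (subj, cond): j
            for j, (subj, cond) in enumerate(zip(self.sample_subjects, self.sample_conditions))
        }
        idx = [cols[(s, condition)] for s in order]
        return self.values[:, idx]

    def paired_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """(pre, post) matrices with identical subject column order."""
        return self.condition_matrix(PRE), self.condition_matrix(POST)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{s}:{c}" for s, c in zip(self.sample_subjects, self.sample_conditions)]
        return pd.DataFrame(self.values, index=self.gene_ids, columns=cols)


def write_expression(eset: PairedExpressionSet, path: str | Path) -> None:
    """Write matrix as TSV with ``subject:condition`` column headers."""
    df = eset.to_frame()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_expression(
    path: str | Path,
    condition_map: Mapping[str, tuple[str, str]] | str | Path | None = None,
) -> PairedExpressionSet:
    """Read a tab-delimited genes x samples matrix.

    ``condition_map`` maps each sample ID in the header to a
    ``(subject, condition)`` pair; it may be a dict or a path to a
    3-column TSV (sample, subject, condition). When omitted, sample IDs
    are expected to follow the ``subject:condition`` convention used by
    :func:`write_expression`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate gene IDs in {path.name}: {dupes[:5]}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for gene, row in df.iterrows():
            for col, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise DataError(
                        f"non-numeric cell {cell!r} at gene {gene!r}, sample {col!r}"
                    ) from None
        raise
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise DataError(
            f"missing value at gene {df.index[i]!r}, sample {df.columns[j]!r}"
        )

    if condition_map is None:
        mapping = {}
        for col in df.columns:
            if ":" not in col:
                raise DataError(
                    f"sample {col!r} not in 'subject:condition' form and no condition map given"
                )
            subj, cond = col.rsplit(":", 1)
            mapping[col] = (subj, cond)
    elif isinstance(condition_map, (str, Path)):
        cm = pd.read_csv(condition_map, sep="\t", dtype=str)
        if cm.shape[1] < 3:
            raise DataError("condition map needs columns: sample, subject, condition")
        mapping = {r.iloc[0]: (r.iloc[1], r.iloc[2]) for _, r in cm.iterrows()}
    else:
        mapping = dict(condition_map)

    missing = [c for c in df.columns if c not in mapping]
    if missing:
        raise DataError(f"samples missing from condition map: {missing[:5]}")
    subjects = [mapping[c][0] for c in df.columns]
    conditions = [mapping[c][1] for c in df.columns]
    return PairedExpressionSet(list(df.index), subjects, conditions, values)


# ---------------------------------------------------------------------------
# gene sets


@dataclass
class GeneSetCollection:
    """Named gene sets with free-text descriptions (GMT semantics)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise DataError(f"gene set {name!r} is empty")

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        return GeneSetCollection({n: self.sets[n] for n in names})


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name, description, then member IDs, tab-separated.

    Member order is preserved; duplicate members within a set are
    collapsed to their first occurrence.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"GMT line {lineno}: expected >=3 tab-separated fields")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise DataError(f"GMT line {lineno}: duplicate set name {name!r}")
            members: list[str] = []
            for g in fields[2:]:
                if g and g not in members:
                    members.append(g)
            sets[name] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# phenotypes


@dataclass
class PhenotypeTable:
    """Per-subject pre/post physiological measurements.

    ``measurements`` maps a measurement name to a DataFrame indexed by
    subject with columns ``pre`` and ``post``; ``delta`` is post - pre.
    """

    subject_ids: list[str]
    measurements: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        for name, df in self.measurements.items():
            if not {"pre", "post"} <= set(df.columns):
                raise DataError(f"measurement {name!r} lacks pre/post columns")
            missing = set(self.subject_ids) - set(df.index)
            if missing:
                raise DataError(
                    f"measurement {name!r} missing subjects: {sorted(missing)[:5]}"
                )

    def names(self) -> list[str]:
        return list(self.measurements)

    def delta(self, name: str) -> pd.Series:
        df = self.measurements[name].loc[self.subject_ids]
        return df["post"] - df["pre"]


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    rows = []
    for name, df in table.measurements.items():
        for subj in table.subject_ids:
            rows.append((subj, name, df.loc[subj, "pre"], df.loc[subj, "post"]))
    out = pd.DataFrame(rows, columns=["subject", "measurement", "pre", "post"])
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"subject": str, "measurement": str})
    required = {"subject", "measurement", "pre", "post"}
    if not required <= set(df.columns):
        raise DataError(f"phenotype table needs columns {sorted(required)}")
    subjects: list[str] = []
    for s in df["subject"]:
        if s not in subjects:
            subjects.append(s)
    measurements = {}
    for name, grp in df.groupby("measurement", sort=False):
        measurements[name] = grp.set_index("subject")[["pre", "post"]].astype(float)
    return PhenotypeTable(subjects, measurements)
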