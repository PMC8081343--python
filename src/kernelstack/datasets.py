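"""Domain containers and I/O for multi-omic feature tables and gene-set priors.

A dataset is a collection of per-data-type numeric tables (samples x features)
sharing one canonical sample ordering, a label vector (binary class or real
response), and an optional list of "global" features (e.g. clinical variables)
that are appended to every feature set before forest training.

Feature identifiers are qualified as ``gene::datatype`` so that a gene-level
set fans out to its measurements in every data type; global features keep
their raw names and by construction never collide with qualified locals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("kernelstack")

QUALIFIER = "::"

CLASSIFICATION = "classification"
REGRESSION = "regression"


class GmtParseError(ValueError):
    """Raised on a malformed GMT line (fewer than 3 tab-separated fields)."""


@dataclass
class FeatureSetCollection:
    """Named groups of gene identifiers (prior knowledge, e.g. pathways)."""

    sets: dict[str, list[str]]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"feature set {name!r} is empty")
            deduped = list(dict.fromkeys(members))
            self.sets[name] = deduped

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def subset(self, names: Sequence[str]) -> "FeatureSetCollection":
        return FeatureSetCollection(
            {n: list(self.sets[n]) for n in names},
            {n: self.provenance[n] for n in names if n in self.provenance},
        )


def read_gmt(path: str | Path) -> FeatureSetCollection:
    """Parse a GMT file (name, description, members...) into a collection.

    Duplicate member genes within a line are collapsed; empty member fields
    are skipped. A line with fewer than 3 fields or a duplicate set name is an
    error.
    """
    sets: dict[str, list[str]] = {}
    provenance: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc = fields[0], fields[1]
            if name in sets:
                raise GmtParseError(f"{path}: line {lineno}: duplicate set name {name!r}")
            members = list(dict.fromkeys(m for m in fields[2:] if m))
            if not members:
                raise GmtParseError(f"{path}: line {lineno}: set {name!r} has no members")
            sets[name] = members
            provenance[name] = desc
    return FeatureSetCollection(sets, provenance)


def write_gmt(collection: FeatureSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            desc = collection.provenance.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


@dataclass
class OmicsDataset:
    """Aligned multi-data-type sample x feature tables with labels.

    ``X`` is the combined samples x features matrix; local features carry
    qualified names (``gene::datatype``), globals keep raw names.
    """

    sample_ids: list[str]
    data_types: list[str]
    X: pd.DataFrame                    # samples x all features
    feature_types: pd.Series           # feature -> data-type name
    feature_genes: pd.Series           # feature -> raw gene identifier
    labels: pd.Series                  # indexed by sample id
    task: str                          # CLASSIFICATION or REGRESSION
    global_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.task not in (CLASSIFICATION, REGRESSION):
            raise ValueError(f"unknown task {self.task!r}")
        if list(self.X.index) != self.sample_ids:
            raise ValueError("X row order does not match sample_ids")
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("labels length does not match sample count")
        if self.X.columns.has_duplicates:
            dups = self.X.columns[self.X.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature identifiers: {dups}")
        missing = set(self.global_features) - set(self.X.columns)
        if missing:
            raise ValueError(f"global features absent from tables: {sorted(missing)}")
        if self.task == CLASSIFICATION:
            classes = np.unique(self.labels.to_numpy())
            if len(classes) != 2:
                raise ValueError(
                    f"classification labels must take exactly two values, got {classes}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def classes(self) -> np.ndarray:
        """Sorted pair of class labels (classification only)."""
        return np.unique(self.labels.to_numpy())

    def y_numeric(self) -> np.ndarray:
        """Labels as floats; classification mapped to 0/1 (positive = larger)."""
        y = self.labels.to_numpy()
        if self.task == CLASSIFICATION:
            return (y == self.classes[1]).astype(float)
        return y.astype(float)

    def gene_universe(self, data_type: str) -> set[str]:
        mask = (self.feature_types == data_type).to_numpy()
        return set(self.feature_genes[mask])


@dataclass
class AvailableFeatures:
    """A feature set mapped onto the dataset's qualified feature space."""

    set_name: str
    local_features: list[str]
    global_features: list[str]

    @property
    def all_features(self) -> list[str]:
        return self.local_features + self.global_features

    @property
    def usable(self) -> bool:
        return len(self.local_features) > 0


def qualify(gene: str, data_type: str) -> str:
    return f"{gene}{QUALIFIER}{data_type}"


def split_qualified(feature: str) -> tuple[str, str | None]:
    """Return (gene, data_type); data_type is None for unqualified globals."""
    if QUALIFIER in feature:
        gene, dtype = feature.rsplit(QUALIFIER, 1)
        return gene, dtype
    return feature, None


def assemble_dataset(
    tables: Mapping[str, pd.DataFrame],
    labels: pd.Series,
    global_features: Sequence[str] = (),
    task: str | None = None,
) -> OmicsDataset:
    """Build an :class:`OmicsDataset` from per-data-type tables.

    Rows are reordered to a single canonical sample order (lexicographic by
    sample id, fixed before any randomized step so seeds reproduce). Feature
    identifiers are qualified ``gene::datatype`` except for globals, which
    keep their raw names. Task is inferred from label arity (two distinct
    values -> classification) unless overridden.
    """
    if not tables:
        raise ValueError("at least one data-type table is required")
    ids_per_table = {name: set(t.index) for name, t in tables.items()}
    common = set.intersection(*ids_per_table.values())
    union = set.union(*ids_per_table.values())
    if common != union:
        missing = {
            name: sorted(union - ids) for name, ids in ids_per_table.items() if union - ids
        }
        raise ValueError(f"sample-id mismatch across tables; missing ids: {missing}")
    if not common <= set(labels.index):
        raise ValueError(
            f"labels missing for samples: {sorted(common - set(labels.index))}"
        )
    sample_ids = sorted(common)

    globals_set = set(global_features)
    blocks: list[pd.DataFrame] = []
    ftypes: dict[str, str] = {}
    fgenes: dict[str, str] = {}
    data_types = sorted(tables)
    for dtype in data_types:
        table = tables[dtype].loc[sample_ids]
        bad = table.columns[~table.apply(
            lambda c: pd.api.types.is_numeric_dtype(c), axis=0
        )]
        if len(bad):
            raise ValueError(f"non-numeric columns in table {dtype!r}: {list(bad)}")
        if table.isna().to_numpy().any():
            r, c = np.argwhere(table.isna().to_numpy())[0]
            raise ValueError(
                f"missing value in table {dtype!r} at sample "
                f"{table.index[r]!r}, feature {table.columns[c]!r}; "
                "missing values are not supported"
            )
        renamed = {}
        for col in table.columns:
            name = col if col in globals_set else qualify(col, dtype)
            renamed[col] = name
            ftypes[name] = dtype
            fgenes[name] = col
        blocks.append(table.rename(columns=renamed).astype(float))
    X = pd.concat(blocks, axis=1)

    resolved_globals = [g for g in global_features if g in set(X.columns)]
    if set(global_features) - set(resolved_globals):
        raise ValueError(
            "global features absent from all tables: "
            f"{sorted(set(global_features) - set(resolved_globals))}"
        )

    y = labels.loc[sample_ids]
    if task is None:
        task = CLASSIFICATION if len(pd.unique(y)) == 2 else REGRESSION

    return OmicsDataset(
        sample_ids=sample_ids,
        data_types=data_types,
        X=X,
        feature_types=pd.Series(ftypes),
        feature_genes=pd.Series(fgenes),
        labels=y,
        task=task,
        global_features=list(resolved_globals),
    )


def map_feature_set(
    set_name: str, genes: Sequence[str], dataset: OmicsDataset
) -> AvailableFeatures:
    """Intersect a gene set with every data type's gene universe.

    For each data type, genes present in that table contribute their qualified
    feature; all global features are appended. An empty local intersection
    flags the set unusable (dropped upstream with a warning) -- never an
    exception. Idempotent and order-independent in the input gene list.
    """
    gene_set = set(genes)
    globals_set = set(dataset.global_features)
    local = [
        f
        for f in dataset.X.columns
        if f not in globals_set and dataset.feature_genes[f] in gene_set
    ]
    return AvailableFeatures(
        set_name=set_name,
        local_features=local,
        global_features=list(dataset.global_features),
    )


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """TSV with a header row of feature names and first column of sample ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="sample")


def read_labels(path: str | Path) -> pd.Series:
    """Two-column TSV (sample id, label)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.shape[1] != 1:
        raise ValueError(f"{path}: expected exactly one label column, got {frame.shape[1]}")
    return frame.iloc[:, 0]


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.rename("label").to_csv(path, sep="\t", index_label="sample")
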