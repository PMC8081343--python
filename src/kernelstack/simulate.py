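"""Synthetic multi-omic datasets with planted pathway signal.

The generator emulates the statistical structures the stacked learner relies
on: one (or more) "planted" gene set whose member genes carry label signal in
the expression-like data type, a compendium of disjoint pure-noise sets,
optional near-collinear decoy genes (a passenger gene whose expression tracks
a causal driver, present in fewer sets), and optional clinical-style global
features with tunable informativeness.

Continuous data types are standard Gaussians; causal features shift their
class mean by ``effect_size`` standard deviations (classification, Cohen's d)
or contribute linearly to the response (regression). Everything is
reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import (
    CLASSIFICATION,
    REGRESSION,
    FeatureSetCollection,
    OmicsDataset,
    assemble_dataset,
    qualify,
    write_feature_table,
    write_gmt,
    write_labels,
)

PLANTED_SET = "planted_set"
DECOY_GENE = "DECOYGENE"

_DATATYPES = ("expr", "cnv", "prot")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset."""

    planted_sets: list[str]
    causal_features: dict[str, float]          # qualified name -> effect size
    decoy_map: dict[str, str] = field(default_factory=dict)   # causal -> decoy
    noise_model: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def generate(
    n_samples: int = 120,
    n_sets: int = 50,
    set_size_range: tuple[int, int] = (10, 50),
    n_datatypes: int = 2,
    n_causal: int = 10,
    effect_size: float = 1.0,
    collinearity: float | None = None,
    causal_set_multiplicity: int = 5,
    task: str = CLASSIFICATION,
    class_balance: float = 0.5,
    seed: int = 0,
    data_seed: int | None = None,
) -> tuple[OmicsDataset, FeatureSetCollection, SyntheticTruth]:
    """Generate a dataset, a feature-set compendium and its ground truth.

    One planted set carries ``n_causal`` causal genes whose expression
    features drive the labels. With the defaults (10 causal genes at Cohen's
    d = 1 each) the combined latent effect is ~sqrt(10) standard deviations,
    so the planted signal is essentially Bayes-separable while every single
    feature stays only moderately informative -- the set, not any one gene,
    carries the signal; the remaining ``n_sets - 1`` sets hold
    disjoint noise genes. With ``collinearity`` set, a decoy gene whose
    expression column correlates with the first causal gene at that level is
    added to the planted set only, while the first causal gene is also
    injected into ``causal_set_multiplicity`` noise sets (pathway overlap for
    the driver, not the passenger).

    ``seed`` fixes the compendium structure (set sizes, gene assignment);
    ``data_seed`` (default: derived from ``seed``) fixes the sampled values
    and labels, so a fresh draw from the same population is obtained by
    changing ``data_seed`` alone.
    """
    if n_samples < 20:
        raise ValueError("n_samples must be >= 20")
    if n_sets < 1:
        raise ValueError("need at least one (planted) set")
    lo, hi = set_size_range
    if not 1 <= lo <= hi:
        raise ValueError(f"bad set_size_range {set_size_range}")
    if hi < n_causal or n_causal < 1:
        raise ValueError("n_causal must be in [1, set_size_range[1]]")
    if not 1 <= n_datatypes <= len(_DATATYPES):
        raise ValueError(f"n_datatypes must be in [1, {len(_DATATYPES)}]")

    srng = np.random.default_rng(seed)                    # compendium structure
    rng = np.random.default_rng(seed + 104729 if data_seed is None else data_seed)
    dtypes = list(_DATATYPES[:n_datatypes])

    # --- gene sets -----------------------------------------------------
    counter = 0

    def fresh_genes(k: int) -> list[str]:
        nonlocal counter
        genes = [f"GENE{counter + i:05d}" for i in range(k)]
        counter += k
        return genes

    planted_size = max(int(srng.integers(lo, hi + 1)), n_causal)
    planted_genes = fresh_genes(planted_size)
    causal_genes = planted_genes[:n_causal]

    sets: dict[str, list[str]] = {PLANTED_SET: list(planted_genes)}
    for i in range(n_sets - 1):
        size = int(srng.integers(lo, hi + 1))
        sets[f"noise_set_{i:04d}"] = fresh_genes(size)

    decoy_map: dict[str, str] = {}
    if collinearity is not None:
        if not 0 <= collinearity < 1:
            raise ValueError("collinearity must be in [0, 1)")
        sets[PLANTED_SET] = sets[PLANTED_SET] + [DECOY_GENE]
        driver = causal_genes[0]
        noise_names = [n for n in sets if n != PLANTED_SET]
        overlap_sets = noise_names[:causal_set_multiplicity]
        for name in overlap_sets:
            extra = fresh_genes(2)          # complementary signal genes
            causal_genes = causal_genes + extra
            sets[name] = sets[name] + [driver] + extra
        decoy_map[qualify(driver, "expr")] = qualify(DECOY_GENE, "expr")

    all_genes = sorted({g for members in sets.values() for g in members})

    # --- labels --------------------------------------------------------
    if task == CLASSIFICATION:
        y01 = rng.binomial(1, class_balance, size=n_samples)
        labels = pd.Series(y01, index=_sample_ids(n_samples), name="label")
    elif task == REGRESSION:
        y01 = None
        labels = None  # filled after causal columns are drawn
    else:
        raise ValueError(f"unknown task {task!r}")

    # --- tables --------------------------------------------------------
    ids = _sample_ids(n_samples)
    tables: dict[str, pd.DataFrame] = {}
    causal_cols: dict[str, np.ndarray] = {}
    for dtype in dtypes:
        data = rng.standard_normal((n_samples, len(all_genes)))
        table = pd.DataFrame(data, index=ids, columns=all_genes)
        if dtype == "expr":
            for g in causal_genes:
                if task == CLASSIFICATION:
                    table[g] = table[g] + effect_size * y01
                causal_cols[g] = table[g].to_numpy().copy()
        tables[dtype] = table

    if task == REGRESSION:
        signal = np.sum([causal_cols[g] for g in causal_genes], axis=0)
        signal *= effect_size / np.sqrt(n_causal)
        y = signal + rng.standard_normal(n_samples)
        labels = pd.Series(y, index=ids, name="label")
        for g in causal_genes:  # columns unchanged; record post-hoc
            causal_cols[g] = tables["expr"][g].to_numpy()

    if collinearity is not None:
        driver_col = causal_cols[causal_genes[0]]
        z = (driver_col - driver_col.mean()) / driver_col.std()
        decoy = collinearity * z + np.sqrt(1 - collinearity**2) * rng.standard_normal(
            n_samples
        )
        for dtype in dtypes:
            tables[dtype][DECOY_GENE] = (
                decoy if dtype == "expr" else rng.standard_normal(n_samples)
            )

    dataset = assemble_dataset(tables, labels, task=task)
    collection = FeatureSetCollection(
        sets, {name: "synthetic" for name in sets}
    )
    signal_sets = [PLANTED_SET]
    if collinearity is not None:
        signal_sets = signal_sets + [
            n for n in sets
            if n != PLANTED_SET and causal_genes[0] in sets[n]
        ]
    truth = SyntheticTruth(
        planted_sets=signal_sets,
        causal_features={qualify(g, "expr"): effect_size for g in causal_genes},
        decoy_map=decoy_map,
        noise_model={
            "distribution": "standard_normal",
            "n_samples": n_samples,
            "n_sets": n_sets,
            "set_size_range": list(set_size_range),
            "data_types": dtypes,
            "task": task,
            "class_balance": class_balance,
            "collinearity": collinearity,
        },
        seed=seed,
    )
    return dataset, collection, truth


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(n)]


def generate_global_features(
    dataset: OmicsDataset,
    n_globals: int,
    informativeness: float,
    seed: int,
) -> OmicsDataset:
    """Append clinical-style global features to every feature set's view.

    Each global column is ``rho * latent + sqrt(1 - rho^2) * noise`` with
    ``rho = informativeness`` and the latent score the standardized label
    signal; informativeness 0 gives pure noise, 1 a perfectly informative
    composite (an NPI-like index). Returns a rebuilt dataset; ``n_globals=0``
    returns the input unchanged.
    """
    if n_globals == 0:
        return dataset
    if not 0 <= informativeness <= 1:
        raise ValueError("informativeness must be in [0, 1]")
    rng = np.random.default_rng(seed)
    y = dataset.y_numeric()
    latent = (y - y.mean()) / (y.std() if y.std() > 0 else 1.0)
    cols = {}
    for i in range(n_globals):
        noise = rng.standard_normal(dataset.n_samples)
        cols[f"global_var_{i:02d}"] = (
            informativeness * latent + np.sqrt(1 - informativeness**2) * noise
        )
    clinical = pd.DataFrame(cols, index=dataset.sample_ids)

    tables = dataset_tables(dataset)
    tables["clinical"] = clinical
    return assemble_dataset(
        tables,
        dataset.labels,
        global_features=list(clinical.columns) + list(dataset.global_features),
        task=dataset.task,
    )


def dataset_tables(dataset: OmicsDataset) -> dict[str, pd.DataFrame]:
    """Recover per-data-type tables with raw gene column names."""
    out = {}
    for dtype in dataset.data_types:
        mask = (dataset.feature_types == dtype).to_numpy()
        feats = dataset.feature_types.index[mask]
        table = dataset.X[feats].copy()
        table.columns = [dataset.feature_genes[f] for f in feats]
        out[dtype] = table
    return out


def write_dataset_dir(
    dataset: OmicsDataset,
    collection: FeatureSetCollection,
    truth: SyntheticTruth | None,
    outdir: str | Path,
) -> None:
    """Write tables, labels, GMT, global list and truth JSON to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for dtype, table in dataset_tables(dataset).items():
        write_feature_table(table, outdir / f"{dtype}.tsv")
    write_labels(dataset.labels, outdir / "labels.tsv")
    write_gmt(collection, outdir / "feature_sets.gmt")
    with open(outdir / "global_features.txt", "w") as fh:
        for g in dataset.global_features:
            fh.write(g + "\n")
    if truth is not None:
        truth.to_json(outdir / "truth.json")
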