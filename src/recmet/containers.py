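"""Core data containers shared across the pipeline stages.

The pipeline operates on a genes x samples expression matrix with per-sample
covariates, a gene-set collection (pathway -> member genes), a module
partition of the gene set, and a four-way receptor label state
(positive / inferred-negative / known-negative / unlabeled).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "FilterReport",
    "GeneSetCollection",
    "ModulePartition",
    "LabelSet",
]


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2-scale expression values.

    Parameters
    ----------
    values : DataFrame
        Rows indexed by gene id, columns by sample id. Values are
        log2-transformed abundances (e.g. ``log2(RPKM + 1)``).
    covariates : DataFrame, optional
        One row per sample (index = sample id). Expected columns when
        present: ``batch``, ``ischemic_time_min``, ``sex``, ``age``,
        ``death_class``.
    """

    values: pd.DataFrame
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated gene ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicated sample ids: {dups[:5]}")
        if self.covariates is not None:
            missing = self.values.columns.difference(self.covariates.index)
            if len(missing):
                raise ValueError(
                    f"covariate table does not cover samples: {missing.tolist()[:5]}"
                )
            # keep covariates aligned to the sample order of the matrix
            self.covariates = self.covariates.loc[self.values.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[gene_ids], self.covariates)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        cov = self.covariates.loc[sample_ids] if self.covariates is not None else None
        return ExpressionMatrix(self.values[list(sample_ids)], cov)

    def copy(self) -> "ExpressionMatrix":
        cov = self.covariates.copy() if self.covariates is not None else None
        return ExpressionMatrix(self.values.copy(), cov)


@dataclass
class FilterReport:
    """Counts of entities removed during preprocessing."""

    genes_removed_low_expression: int = 0
    genes_removed_zero_variance: int = 0
    samples_removed_outlier: int = 0
    batches_removed_singleton: int = 0
    samples_removed_death_class: int = 0
    genes_removed_batch_zero_variance: int = 0

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    def merged(self, other: "FilterReport") -> "FilterReport":
        return FilterReport(
            **{k: getattr(self, k) + getattr(other, k) for k in vars(self)}
        )

    def to_dict(self) -> dict:
        return dict(vars(self))


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways) over a gene universe."""

    pathways: dict[str, frozenset]
    universe: frozenset

    def __post_init__(self) -> None:
        self.pathways = {k: frozenset(v) for k, v in self.pathways.items()}
        self.universe = frozenset(self.universe)

    def restrict(self, universe) -> "GeneSetCollection":
        """Intersect every pathway with ``universe``; drop emptied pathways."""
        universe = frozenset(universe)
        restricted = {}
        for name, genes in self.pathways.items():
            kept = genes & universe
            if kept:
                restricted[name] = kept
        return GeneSetCollection(restricted, universe)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)


@dataclass
class ModulePartition:
    """Gene -> module assignment with module eigengenes and kME.

    Module labels are positive integers numbered by decreasing module size
    (module 1 is the largest); label 0 marks genes not assigned to any
    module.
    """

    module_of_gene: pd.Series
    eigengenes: pd.DataFrame  # samples x modules, columns are module labels
    kme: pd.DataFrame  # genes x modules

    def __post_init__(self) -> None:
        labels = sorted(set(self.module_of_gene) - {0})
        if labels != list(range(1, len(labels) + 1)):
            raise ValueError(f"module labels must be contiguous from 1, got {labels}")

    @property
    def module_labels(self) -> list[int]:
        return sorted(set(self.module_of_gene) - {0})

    def members(self, label: int) -> pd.Index:
        return self.module_of_gene.index[self.module_of_gene == label]

    def module_sizes(self) -> pd.Series:
        return self.module_of_gene[self.module_of_gene > 0].value_counts().sort_index()


@dataclass
class LabelSet:
    """Receptor supervision state: four pairwise-disjoint id sets."""

    positives: frozenset = field(default_factory=frozenset)
    negatives_inferred: frozenset = field(default_factory=frozenset)
    negatives_known: frozenset = field(default_factory=frozenset)
    unlabeled: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        sets = [
            frozenset(self.positives),
            frozenset(self.negatives_inferred),
            frozenset(self.negatives_known),
            frozenset(self.unlabeled),
        ]
        self.positives, self.negatives_inferred, self.negatives_known, self.unlabeled = sets
        total = sum(len(s) for s in sets)
        if total != len(frozenset().union(*sets)):
            raise ValueError("label sets must be pairwise disjoint")

    @property
    def all_labeled(self) -> frozenset:
        return self.positives | self.negatives_inferred | self.negatives_known

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, ids in [
            ("pos", self.positives),
            ("neg_inferred", self.negatives_inferred),
            ("neg_known", self.negatives_known),
            ("unlabeled", self.unlabeled),
        ]:
            rows.extend({"receptor": r, "label": label} for r in sorted(ids))
        return pd.DataFrame(rows, columns=["receptor", "label"])


def as_float_array(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in input")
    return arr
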