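"""Module-pathway over-representation scoring and the receptor feature space.

Each detected module is tested against each pathway with the one-sided
(upper-tail) hypergeometric test over the analysis universe; p-values are
Benjamini-Hochberg adjusted within each module across its pathways. A
receptor inherits its module's pathway score vector: the feature is
``-log10(p_adj)`` where the module-pathway pair is significant at ``alpha``
and 0 elsewhere, so two receptors in the same module have identical rows
and receptors in no module (label 0) have none.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .containers import GeneSetCollection, ModulePartition

logger = logging.getLogger(__name__)

__all__ = [
    "hypergeom_enrich",
    "bh_adjust",
    "enrich_modules",
    "FeatureMatrix",
    "build_feature_matrix",
]


def hypergeom_enrich(module_genes, pathway_genes, universe) -> float:
    """Upper-tail hypergeometric p-value P[X >= k] for the overlap.

    Drawing ``n = |module|`` genes from a universe of ``N`` containing
    ``K = |pathway|`` successes, with observed overlap ``k``.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    module_genes = frozenset(module_genes) & universe
    pathway_genes = frozenset(pathway_genes) & universe
    N, K, n = len(universe), len(pathway_genes), len(module_genes)
    k = len(module_genes & pathway_genes)
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order kept."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_modules(
    partition: ModulePartition,
    gene_sets: GeneSetCollection,
    universe=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score every (module, pathway) pair; BH-adjust within each module.

    ``universe`` defaults to all genes assigned to any module; pathway
    gene sets are restricted to it (emptied pathways are dropped with a
    log message but keep their column downstream via the collection).

    Returns a DataFrame with columns
    ``module, pathway, overlap, module_size, pathway_size, p_raw, p_adj``.
    """
    if universe is None:
        universe = frozenset(
            partition.module_of_gene.index[partition.module_of_gene > 0]
        )
    restricted = gene_sets.restrict(universe)
    dropped = set(gene_sets.pathways) - set(restricted.pathways)
    if dropped:
        logger.warning("%d pathways empty after universe restriction", len(dropped))
    rows = []
    for m in partition.module_labels:
        members = frozenset(partition.members(m)) & frozenset(universe)
        pvals = []
        for pw, genes in restricted.pathways.items():
            k = len(members & genes)
            pvals.append(
                (pw, k, len(genes), hypergeom_enrich(members, genes, universe))
            )
        adj = bh_adjust([p for _, _, _, p in pvals])
        for (pw, k, psize, p_raw), p_adj in zip(pvals, adj):
            rows.append(
                {
                    "module": m,
                    "pathway": pw,
                    "overlap": k,
                    "module_size": len(members),
                    "pathway_size": psize,
                    "p_raw": p_raw,
                    "p_adj": p_adj,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["module", "pathway", "overlap", "module_size", "pathway_size", "p_raw", "p_adj"],
    )


@dataclass
class FeatureMatrix:
    """Receptors x pathways enrichment-score feature space.

    ``values[r, p] = -log10(p_adj(module(r), p))`` when that pair is
    significant, else 0. Receptors unassigned to a module or absent from
    the expression data are excluded and listed.
    """

    values: pd.DataFrame
    receptor_module: pd.Series
    excluded_unassigned: list = field(default_factory=list)
    excluded_missing: list = field(default_factory=list)

    @property
    def receptor_ids(self) -> pd.Index:
        return self.values.index


def build_feature_matrix(
    partition: ModulePartition,
    enrichment: pd.DataFrame,
    receptors,
    alpha: float = 0.05,
) -> FeatureMatrix:
    """Assemble per-receptor feature rows from module enrichment scores."""
    pathways = sorted(enrichment["pathway"].unique())
    sig = enrichment[enrichment["p_adj"] < alpha]
    score_by_module = {}
    for m in partition.module_labels:
        row = pd.Series(0.0, index=pathways)
        msig = sig[sig["module"] == m]
        row[msig["pathway"].to_numpy()] = -np.log10(msig["p_adj"].to_numpy())
        score_by_module[m] = row
        if msig.empty:
            logger.info("module %d has no significant pathway; all-zero rows", m)

    rows, modules, missing, unassigned = {}, {}, [], []
    for r in receptors:
        if r not in partition.module_of_gene.index:
            missing.append(r)
            continue
        m = int(partition.module_of_gene[r])
        if m == 0:
            unassigned.append(r)
            continue
        rows[r] = score_by_module[m]
        modules[r] = m
    if missing:
        logger.warning("%d receptors absent from expression data; excluded", len(missing))
    if unassigned:
        logger.info("%d receptors not in any module; excluded from features", len(unassigned))
    values = pd.DataFrame(rows).T if rows else pd.DataFrame(columns=pathways)
    values.index.name = "receptor"
    return FeatureMatrix(
        values=values.loc[sorted(rows)] if rows else values,
        receptor_module=pd.Series(modules, dtype=int).sort_index(),
        excluded_unassigned=sorted(unassigned),
        excluded_missing=sorted(missing),
    )
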