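"""Signed weighted co-expression network construction and module detection.

Pipeline: robust correlation (biweight midcorrelation) -> signed soft
adjacency ``a_ij = (0.5 * (1 + cor(i, j)))**beta`` -> topological overlap
matrix (TOM) -> average-linkage hierarchical clustering of the TOM
dissimilarity -> static tree cut with a minimum module size -> iterative
merging of modules with correlated eigengenes. Modules are labeled by
decreasing size (module 1 is the largest); label 0 marks unassigned genes.

An eigengene is the first principal component of a module's
gene-standardized expression submatrix, sign-oriented to correlate
positively with the module's mean expression profile; kME is a gene's
correlation with a module eigengene (eigengene-based connectivity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .containers import ExpressionMatrix, ModulePartition

__all__ = [
    "bicor",
    "pearson",
    "soft_adjacency",
    "tom_similarity",
    "module_eigengene",
    "kme",
    "detect_modules",
    "CoexpressionModules",
    "scale_free_fit_r2",
]


def _bicor_rows(X: np.ndarray) -> np.ndarray:
    """Per-gene robust deviation rows for biweight midcorrelation.

    For gene row x: u_i = (x_i - med) / (9 * MAD), weight
    w_i = (1 - u_i^2)^2 * 1[|u_i| < 1], deviation d_i = (x_i - med) * w_i.
    A gene with MAD = 0 falls back to Pearson deviations (x - mean);
    a gene that is fully constant has no defined correlation.
    """
    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1, keepdims=True)
    zero_mad = mad[:, 0] == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (X - med) / (9.0 * mad)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    D = (X - med) * w
    if zero_mad.any():
        D[zero_mad] = X[zero_mad] - X[zero_mad].mean(axis=1, keepdims=True)
    norms = np.sqrt((D**2).sum(axis=1))
    degenerate = norms == 0
    if degenerate.any():
        raise ValueError(
            f"{int(degenerate.sum())} gene(s) have zero MAD and zero variance; "
            "correlation is undefined — filter constant genes first"
        )
    return D / norms[:, None]


def bicor(X, gene_ids=None) -> pd.DataFrame:
    """Biweight midcorrelation matrix of the rows of ``X`` (genes x samples).

    Robust to outliers: points far from the per-gene median get weight
    zero. Requires >= 4 samples.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 4:
        raise ValueError("bicor needs a 2-D matrix with >= 4 samples")
    D = _bicor_rows(X)
    C = np.clip(D @ D.T, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    C = (C + C.T) / 2.0
    ids = gene_ids if gene_ids is not None else range(X.shape[0])
    return pd.DataFrame(C, index=ids, columns=ids)


def pearson(X, gene_ids=None) -> pd.DataFrame:
    """Pearson correlation matrix of the rows of ``X`` (genes x samples)."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1)
    if (sd == 0).any():
        raise ValueError("constant gene(s); correlation undefined")
    C = np.clip(np.corrcoef(X), -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    ids = gene_ids if gene_ids is not None else range(X.shape[0])
    return pd.DataFrame(C, index=ids, columns=ids)


def soft_adjacency(cor, beta: float = 12.0, signed: bool = True):
    """Soft-threshold a correlation matrix into a weighted adjacency.

    Signed (default): ``a_ij = (0.5 * (1 + cor_ij))**beta``, so perfectly
    anticorrelated genes get adjacency 0. Unsigned: ``|cor_ij|**beta``.
    """
    if beta < 1:
        raise ValueError(f"beta must be >= 1, got {beta}")
    arr = np.asarray(cor, dtype=float)
    adj = (0.5 * (1.0 + arr)) ** beta if signed else np.abs(arr) ** beta
    if isinstance(cor, pd.DataFrame):
        return pd.DataFrame(adj, index=cor.index, columns=cor.columns)
    return adj


def tom_similarity(adj):
    """Topological overlap matrix of a weighted adjacency.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` for i != j,
    with shared-neighbor weight ``l_ij = sum_u a_iu * a_uj`` (u != i, j)
    and connectivity ``k_i = sum_u a_iu`` (u != i); diagonal set to 1.
    """
    A = np.asarray(adj, dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    L = A @ A  # diag(A)=0 already excludes u=i and u=j terms
    k = A.sum(axis=1)
    min_k = np.minimum.outer(k, k)
    denom = min_k + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        T = (L + A) / denom
    T = np.nan_to_num(T, nan=0.0)
    np.fill_diagonal(T, 1.0)
    T = np.clip((T + T.T) / 2.0, 0.0, 1.0)
    if isinstance(adj, pd.DataFrame):
        return pd.DataFrame(T, index=adj.index, columns=adj.columns)
    return T


def module_eigengene(expr_values, member_genes=None) -> np.ndarray:
    """First principal component of the gene-standardized member submatrix.

    Returns a unit-norm per-sample score vector, sign-oriented so its
    correlation with the members' mean expression profile is >= 0. A
    single-gene module returns that gene's standardized (unit-norm)
    profile.
    """
    if isinstance(expr_values, pd.DataFrame) and member_genes is not None:
        sub = expr_values.loc[member_genes].to_numpy(dtype=float)
    else:
        sub = np.asarray(expr_values, dtype=float)
        if member_genes is not None:
            sub = sub[np.asarray(member_genes)]
    if sub.ndim != 2 or sub.shape[0] < 1:
        raise ValueError("module must have at least one member gene")
    sd = sub.std(axis=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("constant gene in module; filter first")
    Z = (sub - sub.mean(axis=1, keepdims=True)) / sd
    if Z.shape[0] == 1:
        v = Z[0]
    else:
        # first right singular vector = per-sample eigengene scores
        _, _, vt = np.linalg.svd(Z, full_matrices=False)
        v = vt[0]
    v = v / np.linalg.norm(v)
    mean_profile = Z.mean(axis=0)
    if np.dot(v, mean_profile - mean_profile.mean()) < 0:
        v = -v
    return v


def _corr_with_vector(X: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of X with vector v."""
    Xc = X - X.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (vc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = Xc @ vc / denom
    return np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)


def kme(expr: ExpressionMatrix, partition: ModulePartition) -> pd.DataFrame:
    """Eigengene-based connectivity: cor(gene expression, module eigengene)."""
    X = expr.values.to_numpy(dtype=float)
    out = {}
    for m in partition.eigengenes.columns:
        out[m] = _corr_with_vector(X, partition.eigengenes[m].to_numpy())
    return pd.DataFrame(out, index=expr.gene_ids)


class CoexpressionModules(BaseEstimator, ClusterMixin):
    """Detect co-expression modules from a signed weighted network.

    sklearn-style clusterer over ``X`` of shape ``(n_samples, n_genes)``
    (samples are observations, genes are the clustered features). After
    ``fit``: ``labels_`` (per gene; 0 = unassigned), ``eigengenes_``
    (samples x modules), ``kme_`` (genes x modules), ``linkage_``.

    Parameters
    ----------
    beta : float
        Soft-threshold power (default 12).
    signed : bool
        Use the signed adjacency transform (default True).
    corr_method : {'bicor', 'pearson'}
        Gene-gene correlation measure.
    cut_height : float
        Static dendrogram cut height on TOM dissimilarity.
    min_module_size : int
        Clusters below this size are unassigned (label 0).
    merge_height : float
        Modules whose eigengene dissimilarity (1 - cor) is below this are
        merged iteratively; 0 disables merging.
    """

    def __init__(
        self,
        beta: float = 12.0,
        signed: bool = True,
        corr_method: str = "bicor",
        cut_height: float = 0.995,
        min_module_size: int = 30,
        merge_height: float = 0.25,
    ):
        self.beta = beta
        self.signed = signed
        self.corr_method = corr_method
        self.cut_height = cut_height
        self.min_module_size = min_module_size
        self.merge_height = merge_height

    def fit(self, X, y=None):
        X = check_array(X)
        G = X.T  # genes x samples
        if self.corr_method == "bicor":
            C = bicor(G).to_numpy()
        elif self.corr_method == "pearson":
            C = pearson(G).to_numpy()
        else:
            raise ValueError(f"unknown corr_method {self.corr_method!r}")
        A = soft_adjacency(C, self.beta, self.signed)
        T = tom_similarity(A)
        diss = 1.0 - T
        np.fill_diagonal(diss, 0.0)
        self.linkage_ = linkage(squareform(diss, checks=False), method="average")
        raw = fcluster(self.linkage_, t=self.cut_height, criterion="distance")

        labels = np.zeros(G.shape[0], dtype=int)
        sizes = pd.Series(raw).value_counts()
        kept = [c for c in sizes.index if sizes[c] >= self.min_module_size]
        for new, c in enumerate(kept, start=1):
            labels[raw == c] = new
        if not kept:
            warnings.warn("tree cut produced no module of min_module_size; all genes unassigned",
                          stacklevel=2)
        labels = self._merge_modules(G, labels)
        labels = self._relabel_by_size(labels)
        self.labels_ = labels
        self.eigengenes_ = self._eigengenes(G, labels)
        self.kme_ = pd.DataFrame(
            {m: _corr_with_vector(G, self.eigengenes_[m].to_numpy())
             for m in self.eigengenes_.columns}
        )
        return self

    def _eigengenes(self, G: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
        cols = {}
        for m in sorted(set(labels) - {0}):
            cols[m] = module_eigengene(G[labels == m])
        return pd.DataFrame(cols, index=range(G.shape[1]))

    def _merge_modules(self, G: np.ndarray, labels: np.ndarray) -> np.ndarray:
        if self.merge_height <= 0:
            return labels
        labels = labels.copy()
        while True:
            mods = sorted(set(labels) - {0})
            if len(mods) < 2:
                return labels
            eig = {m: module_eigengene(G[labels == m]) for m in mods}
            best, best_diss = None, None
            for i, mi in enumerate(mods):
                for mj in mods[i + 1 :]:
                    r = float(np.clip(np.corrcoef(eig[mi], eig[mj])[0, 1], -1, 1))
                    d = 1.0 - r
                    if d < self.merge_height and (best_diss is None or d < best_diss):
                        best, best_diss = (mi, mj), d
            if best is None:
                return labels
            labels[labels == best[1]] = best[0]

    @staticmethod
    def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
        sizes = pd.Series(labels[labels > 0]).value_counts()
        # decreasing size; ties broken by original label for determinism
        order = sorted(sizes.index, key=lambda m: (-sizes[m], m))
        mapping = {old: new for new, old in enumerate(order, start=1)}
        return np.array([mapping.get(l, 0) for l in labels], dtype=int)


def detect_modules(
    tom,
    min_module_size: int = 30,
    cut_height: float = 0.995,
    merge_height: float = 0.25,
    expr: ExpressionMatrix = None,
) -> ModulePartition:
    """Cut a precomputed TOM into modules and attach eigengenes and kME.

    ``tom`` and ``expr`` must cover identical gene sets in the same order.
    """
    T = tom.to_numpy() if isinstance(tom, pd.DataFrame) else np.asarray(tom, float)
    if expr is None:
        raise ValueError("detect_modules requires the expression matrix for eigengenes")
    if T.shape[0] != expr.n_genes:
        raise ValueError("TOM and expression matrix cover different gene sets")
    if isinstance(tom, pd.DataFrame) and not tom.index.equals(expr.gene_ids):
        raise ValueError("TOM gene ids do not match expression gene ids")
    diss = 1.0 - T
    np.fill_diagonal(diss, 0.0)
    lk = linkage(squareform(diss, checks=False), method="average")
    raw = fcluster(lk, t=cut_height, criterion="distance")
    labels = np.zeros(expr.n_genes, dtype=int)
    sizes = pd.Series(raw).value_counts()
    kept = [c for c in sizes.index if sizes[c] >= min_module_size]
    for new, c in enumerate(kept, start=1):
        labels[raw == c] = new
    if not kept:
        warnings.warn("tree cut produced no module of min_module_size; all genes unassigned",
                      stacklevel=2)
    est = CoexpressionModules(min_module_size=min_module_size,
                              cut_height=cut_height, merge_height=merge_height)
    G = expr.values.to_numpy(dtype=float)
    labels = est._merge_modules(G, labels)
    labels = CoexpressionModules._relabel_by_size(labels)
    eig = {}
    for m in sorted(set(labels) - {0}):
        eig[m] = module_eigengene(G[labels == m])
    eigengenes = pd.DataFrame(eig, index=expr.sample_ids, dtype=float)
    partition = ModulePartition(
        module_of_gene=pd.Series(labels, index=expr.gene_ids, name="module"),
        eigengenes=eigengenes,
        kme=pd.DataFrame(index=expr.gene_ids),
    )
    partition.kme = kme(expr, partition)
    return partition


def scale_free_fit_r2(adj, n_bins: int = 10) -> float:
    """Diagnostic R^2 of the log-log degree-distribution fit.

    Measures how well the weighted connectivity distribution follows a
    power law; used to sanity-check the soft-threshold power, not to
    select it automatically.
    """
    A = np.asarray(adj, dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    k = k[k > 0]
    if len(k) < n_bins:
        raise ValueError("too few connected nodes for the degree fit")
    counts, edges = np.histogram(k, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mask = counts > 0
    x = np.log10(centers[mask])
    y = np.log10(counts[mask] / counts.sum())
    if mask.sum() < 3:
        raise ValueError("degenerate degree histogram")
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)
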