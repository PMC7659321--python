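"""Expression-matrix preprocessing: filtering, normalization, batch adjustment.

The stage mirrors a standard bulk RNA-seq cleanup for co-expression work:

1. keep genes expressed at >= ``min_value`` (raw scale) in >= ``min_fraction``
   of samples, and drop zero-variance genes;
2. drop outlier samples whose standardized mean inter-sample correlation
   falls below a cutoff (default z < -3);
3. quantile-normalize samples to the common rank-mean distribution;
4. subset to one death-classification group and discretize covariates
   (ischemic time into 300-minute bins capped at 5, age into decades);
5. iteratively location-scale adjust each known factor (batch, ischemic
   bin, sex, age bin), removing singleton factor levels and genes with
   zero within-level variance.

Core steps are sklearn-style estimators on ``(n_samples, n_genes)`` arrays;
the module-level functions wrap them for the genes x samples
:class:`~recmet.containers.ExpressionMatrix` used by the pipeline.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .containers import ExpressionMatrix, FilterReport

logger = logging.getLogger(__name__)

__all__ = [
    "LowExpressionFilter",
    "SampleOutlierFilter",
    "QuantileNormalizer",
    "BatchAdjuster",
    "filter_genes",
    "remove_outlier_samples",
    "quantile_normalize",
    "discretize_covariates",
    "subset_death_class",
    "adjust_batches",
    "preprocess_expression",
]


class LowExpressionFilter(BaseEstimator, TransformerMixin):
    """Select genes expressed above ``min_value`` (raw scale) in enough samples.

    Input values are log2-scale with pseudocount: stored ``v = log2(x + c)``,
    so the raw-scale test ``x >= min_value`` becomes
    ``v >= log2(min_value + c)``. Zero-variance genes are always dropped.

    Parameters
    ----------
    min_value : float
        Raw-scale expression threshold (e.g. 0.1 RPKM).
    min_fraction : float
        Fraction of samples required to meet the threshold, in (0, 1].
    pseudocount : float
        Pseudocount used in the log transform of the stored values.
    """

    def __init__(self, min_value: float = 0.1, min_fraction: float = 0.8, pseudocount: float = 1.0):
        self.min_value = min_value
        self.min_fraction = min_fraction
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        if not 0.0 < self.min_fraction <= 1.0:
            raise ValueError(f"min_fraction must be in (0, 1], got {self.min_fraction}")
        X = check_array(X)
        log_threshold = np.log2(self.min_value + self.pseudocount)
        frac_expressed = np.mean(X >= log_threshold, axis=0)
        expressed = frac_expressed >= self.min_fraction
        nonconstant = X.std(axis=0) > 0
        self.support_ = expressed & nonconstant
        self.n_low_expression_ = int(np.sum(~expressed))
        self.n_zero_variance_ = int(np.sum(expressed & ~nonconstant))
        if not self.support_.any():
            raise ValueError(
                "no genes survive the expression filter "
                f"(min_value={self.min_value}, min_fraction={self.min_fraction})"
            )
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        return check_array(X)[:, self.support_]


class SampleOutlierFilter(BaseEstimator):
    """Flag outlier samples by standardized network connectivity.

    Each sample's connectivity score is its mean Pearson correlation with
    all other samples (``metric='correlation'``) or minus its mean
    Euclidean distance (``metric='euclidean'``); scores are z-standardized
    and samples with z below ``sd_cutoff`` are outliers. A degenerate score
    vector (zero variance) yields no outliers.
    """

    def __init__(self, sd_cutoff: float = -3.0, metric: str = "correlation"):
        self.sd_cutoff = sd_cutoff
        self.metric = metric

    def fit(self, X, y=None):
        X = check_array(X)
        n = X.shape[0]
        if n < 3:
            raise ValueError(f"need >= 3 samples to score outliers, got {n}")
        if self.metric == "correlation":
            with np.errstate(invalid="ignore"):
                c = np.corrcoef(X)
            c = np.nan_to_num(c, nan=0.0)
            scores = (c.sum(axis=1) - 1.0) / (n - 1)
        elif self.metric == "euclidean":
            from scipy.spatial.distance import squareform, pdist

            d = squareform(pdist(X))
            scores = -d.sum(axis=1) / (n - 1)
        else:
            raise ValueError(f"unknown outlier metric {self.metric!r}")
        sd = scores.std()
        if sd == 0:
            self.z_scores_ = np.zeros(n)
        else:
            self.z_scores_ = (scores - scores.mean()) / sd
        self.outlier_mask_ = self.z_scores_ < self.sd_cutoff
        return self

    def transform(self, X):
        check_is_fitted(self, "outlier_mask_")
        return check_array(X)[~self.outlier_mask_]


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Map every sample (row) onto the common rank-mean distribution.

    ``fit`` stores the reference: the across-sample mean of the sorted
    per-sample value vectors. ``transform`` replaces each value by the
    reference value at its rank; ties receive the mean of the reference
    values at their (averaged) rank positions.
    """

    def fit(self, X, y=None):
        X = check_array(X)
        self.reference_ = np.sort(X, axis=1).mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_")
        X = check_array(X)
        ref = self.reference_
        if X.shape[1] != ref.shape[0]:
            # interpolate the reference onto this gene count
            q_ref = np.linspace(0, 1, ref.shape[0])
            q_new = np.linspace(0, 1, X.shape[1])
            ref = np.interp(q_new, q_ref, ref)
        out = np.empty_like(X, dtype=float)
        for i, row in enumerate(X):
            ranks = rankdata(row, method="average")  # 1-based, .5 on ties
            lo = np.floor(ranks).astype(int) - 1
            hi = np.ceil(ranks).astype(int) - 1
            out[i] = 0.5 * (ref[lo] + ref[hi])
        return out


class BatchAdjuster(BaseEstimator, TransformerMixin):
    """Per-gene location-scale adjustment over ordered categorical factors.

    For each factor in turn, every level's values are re-centered to the
    gene's grand mean and rescaled so the within-level standard deviation
    equals the pooled (across-level residual) standard deviation. Factor
    levels with a single sample are removed before adjusting; genes with
    zero variance within any level of the current factor are dropped. This
    removes known-factor location and scale effects exactly; it applies no
    empirical-Bayes shrinkage across genes.

    ``fit_transform(X, factors=...)`` expects ``factors`` as a DataFrame of
    categorical columns aligned to the rows (samples) of X, adjusted in
    column order.
    """

    def __init__(self, min_level_size: int = 2):
        self.min_level_size = min_level_size

    def fit_transform(self, X, y=None, *, factors: pd.DataFrame):
        X = check_array(X).astype(float)
        factors = factors.reset_index(drop=True)
        if len(factors) != X.shape[0]:
            raise ValueError("factors must have one row per sample")
        sample_mask = np.ones(X.shape[0], dtype=bool)
        gene_mask = np.ones(X.shape[1], dtype=bool)
        n_singleton = 0

        for name in factors.columns:
            fac = factors[name].astype(str).to_numpy()
            # drop singleton levels among currently kept samples
            kept_idx = np.flatnonzero(sample_mask)
            levels, counts = np.unique(fac[kept_idx], return_counts=True)
            for lev, cnt in zip(levels, counts):
                if cnt < self.min_level_size:
                    sample_mask[kept_idx[fac[kept_idx] == lev]] = False
                    n_singleton += int(cnt)
                    logger.warning("factor %s: removed singleton level %s", name, lev)
            kept_idx = np.flatnonzero(sample_mask)
            levels = np.unique(fac[kept_idx])
            if len(levels) < 2:
                warnings.warn(f"factor {name!r} has a single level; skipped", stacklevel=2)
                continue

            sub = X[np.ix_(kept_idx, np.flatnonzero(gene_mask))]
            grand_mean = sub.mean(axis=0)
            resid = np.empty_like(sub)
            level_rows = {lev: np.flatnonzero(fac[kept_idx] == lev) for lev in levels}
            zero_var = np.zeros(sub.shape[1], dtype=bool)
            for lev, rows in level_rows.items():
                block = sub[rows]
                lev_sd = block.std(axis=0, ddof=0)
                zero_var |= lev_sd == 0
                resid[rows] = block - block.mean(axis=0)
            pooled_sd = resid.std(axis=0, ddof=0)
            zero_var |= pooled_sd == 0
            if zero_var.any():
                gene_cols = np.flatnonzero(gene_mask)
                gene_mask[gene_cols[zero_var]] = False
                logger.warning(
                    "factor %s: dropped %d genes with zero within-level variance",
                    name,
                    int(zero_var.sum()),
                )
                sub = sub[:, ~zero_var]
                resid = resid[:, ~zero_var]
                grand_mean = grand_mean[~zero_var]
                pooled_sd = pooled_sd[~zero_var]
            for lev, rows in level_rows.items():
                lev_sd = sub[rows].std(axis=0, ddof=0)
                sub[rows] = grand_mean + resid[rows] * (pooled_sd / lev_sd)
            X[np.ix_(kept_idx, np.flatnonzero(gene_mask))] = sub

        self.sample_mask_ = sample_mask
        self.gene_mask_ = gene_mask
        self.n_singleton_samples_removed_ = n_singleton
        self.n_genes_removed_ = int(np.sum(~gene_mask))
        return X[np.ix_(sample_mask, gene_mask)]

    def fit(self, X, y=None, **kwargs):  # pragma: no cover - fit_transform is the API
        self.fit_transform(X, y, **kwargs)
        return self


# ---------------------------------------------------------------------------
# ExpressionMatrix-level wrappers


def filter_genes(
    expr: ExpressionMatrix,
    min_value: float = 0.1,
    min_fraction: float = 0.8,
    pseudocount: float = 1.0,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Retain genes with raw value >= ``min_value`` in >= ``min_fraction``
    of samples and nonzero variance. Gene order is preserved."""
    f = LowExpressionFilter(min_value, min_fraction, pseudocount).fit(expr.values.T.to_numpy())
    kept = expr.gene_ids[f.support_]
    report = FilterReport(
        genes_removed_low_expression=f.n_low_expression_,
        genes_removed_zero_variance=f.n_zero_variance_,
    )
    return expr.subset_genes(kept), report


def remove_outlier_samples(
    expr: ExpressionMatrix, sd_cutoff: float = -3.0, metric: str = "correlation"
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop samples whose standardized connectivity z-score < ``sd_cutoff``."""
    f = SampleOutlierFilter(sd_cutoff, metric).fit(expr.values.T.to_numpy())
    kept = expr.sample_ids[~f.outlier_mask_]
    return expr.subset_samples(kept), FilterReport(
        samples_removed_outlier=int(f.outlier_mask_.sum())
    )


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize all samples to the rank-mean reference."""
    out = QuantileNormalizer().fit_transform(expr.values.T.to_numpy()).T
    return ExpressionMatrix(
        pd.DataFrame(out, index=expr.gene_ids, columns=expr.sample_ids), expr.covariates
    )


def discretize_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Discretize continuous covariates for categorical batch adjustment.

    Ischemic time (minutes, >= 0) goes into five 300-minute bins labeled
    1-5, capped at 5: ``bin = min(5, time // 300 + 1)``. Age goes into
    decade bins labeled like ``"30-39"``. Other columns pass through.
    """
    out = covariates.copy()
    if "ischemic_time_min" in out:
        t = out["ischemic_time_min"].to_numpy()
        if (t < 0).any():
            raise ValueError("negative ischemic times")
        out["ischemic_bin"] = np.minimum(5, t // 300 + 1).astype(int)
    if "age" in out:
        decade = (out["age"].to_numpy() // 10) * 10
        out["age_bin"] = [f"{d}-{d + 9}" for d in decade]
    return out


def subset_death_class(
    expr: ExpressionMatrix, death_class: str | None = "ventilator"
) -> tuple[ExpressionMatrix, FilterReport]:
    """Keep only samples of one death-classification group (None keeps all)."""
    if death_class is None or expr.covariates is None or "death_class" not in expr.covariates:
        return expr, FilterReport()
    keep = expr.covariates["death_class"] == death_class
    if not keep.any():
        raise ValueError(f"no samples with death_class={death_class!r}")
    return expr.subset_samples(expr.sample_ids[keep]), FilterReport(
        samples_removed_death_class=int((~keep).sum())
    )


def adjust_batches(
    expr: ExpressionMatrix, factors: list[str] = ("batch", "ischemic_bin", "sex", "age_bin")
) -> tuple[ExpressionMatrix, FilterReport]:
    """Iteratively adjust each known factor by per-level location-scale
    correction, in the given order. Preserves each gene's grand mean."""
    if expr.covariates is None:
        raise ValueError("adjust_batches requires sample covariates")
    missing = [f for f in factors if f not in expr.covariates.columns]
    if missing:
        raise ValueError(f"covariate columns not found: {missing}")
    adj = BatchAdjuster()
    out = adj.fit_transform(expr.values.T.to_numpy(), factors=expr.covariates[list(factors)])
    kept_samples = expr.sample_ids[adj.sample_mask_]
    kept_genes = expr.gene_ids[adj.gene_mask_]
    cov = expr.covariates.loc[kept_samples] if expr.covariates is not None else None
    new = ExpressionMatrix(
        pd.DataFrame(out.T, index=kept_genes, columns=kept_samples), cov
    )
    return new, FilterReport(
        batches_removed_singleton=adj.n_singleton_samples_removed_,
        genes_removed_batch_zero_variance=adj.n_genes_removed_,
    )


def preprocess_expression(
    expr: ExpressionMatrix,
    min_value: float = 0.1,
    min_fraction: float = 0.8,
    pseudocount: float = 1.0,
    sd_cutoff: float = -3.0,
    death_class: str | None = "ventilator",
    factors: list[str] = ("batch", "ischemic_bin", "sex", "age_bin"),
    adjust: bool = True,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Full preprocessing chain: death-class subset -> gene filter ->
    outlier removal -> quantile normalization -> covariate discretization
    -> iterative factor adjustment."""
    expr, report = subset_death_class(expr, death_class)
    expr, r = filter_genes(expr, min_value, min_fraction, pseudocount)
    report = report.merged(r)
    expr, r = remove_outlier_samples(expr, sd_cutoff)
    report = report.merged(r)
    expr = quantile_normalize(expr)
    if expr.covariates is not None:
        expr = ExpressionMatrix(expr.values, discretize_covariates(expr.covariates))
    if adjust and expr.covariates is not None:
        usable = [f for f in factors if f in expr.covariates.columns]
        expr, r = adjust_batches(expr, usable)
        report = report.merged(r)
    return expr, report
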