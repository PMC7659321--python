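"""Preprocessing: gene/sample filters, quantile normalization, batch adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from recmet.containers import ExpressionMatrix
from recmet import preprocessing as pp


def _expr(values, gene_ids=None, sample_ids=None, covariates=None):
    values = np.asarray(values, dtype=float)
    genes = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    samples = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), covariates)


# --- filter_genes -----------------------------------------------------------

def test_filter_removes_gene_below_sample_fraction():
    # raw >= 0.1 in 79/100 samples only -> removed at min_fraction 0.8
    n = 100
    low = np.log2(0.05 + 1)
    high = np.log2(5.0 + 1)
    gene_bad = np.array([high] * 79 + [low] * 21) + np.linspace(0, 1e-3, n)
    gene_good = np.array([high] * 80 + [low] * 20) + np.linspace(0, 1e-3, n)
    expr = _expr([gene_bad, gene_good])
    out, report = pp.filter_genes(expr, min_value=0.1, min_fraction=0.8)
    assert list(out.gene_ids) == ["g1"]
    assert report.genes_removed_low_expression == 1


def test_vacuous_filter_keeps_all_varying_genes():
    rng = np.random.default_rng(0)
    expr = _expr(rng.normal(5, 1, (10, 20)))
    out, report = pp.filter_genes(expr, min_value=0.0, min_fraction=1e-9)
    assert out.n_genes == 10
    assert report.genes_removed_low_expression == 0


def test_constant_gene_removed_and_counted():
    expr = _expr([[5, 5, 5, 5, 5], [1, 2, 3, 4, 5], [2, 4, 6, 8, 10]])
    out, report = pp.filter_genes(expr, min_value=0.0, min_fraction=0.5)
    assert list(out.gene_ids) == ["g1", "g2"]
    assert report.genes_removed_zero_variance == 1
    assert report.genes_removed_low_expression == 0


def test_filter_is_idempotent():
    rng = np.random.default_rng(1)
    vals = rng.normal(2, 2, (30, 40))
    expr = _expr(vals)
    once, _ = pp.filter_genes(expr, 0.1, 0.8)
    twice, report2 = pp.filter_genes(once, 0.1, 0.8)
    pd.testing.assert_frame_equal(once.values, twice.values)
    assert report2.genes_removed_low_expression == 0


def test_filter_all_genes_removed_is_fatal():
    expr = _expr([[0.0, 0.0, 0.0], [0.01, 0.01, 0.01]])
    with pytest.raises(ValueError, match="min_value"):
        pp.filter_genes(expr, min_value=10.0, min_fraction=0.8)


# --- remove_outlier_samples -------------------------------------------------

def test_identical_samples_yield_no_outliers():
    col = np.arange(10.0)
    expr = _expr(np.tile(col[:, None], (1, 8)))
    out, report = pp.remove_outlier_samples(expr)
    assert out.n_samples == 8
    assert report.samples_removed_outlier == 0


def test_anticorrelated_sample_is_removed():
    rng = np.random.default_rng(1)
    base = rng.normal(0, 1, 50)
    cols = [base + rng.normal(0, 0.05, 50) for _ in range(20)] + [-base]
    expr = _expr(np.column_stack(cols))
    out, report = pp.remove_outlier_samples(expr, sd_cutoff=-3.0)
    assert report.samples_removed_outlier == 1
    assert "s20" not in out.sample_ids


def test_infinite_cutoff_removes_nothing():
    rng = np.random.default_rng(2)
    expr = _expr(rng.normal(0, 1, (20, 10)))
    out, report = pp.remove_outlier_samples(expr, sd_cutoff=-np.inf)
    assert out.n_samples == 10


def test_too_few_samples_error():
    with pytest.raises(ValueError, match="3 samples"):
        pp.remove_outlier_samples(_expr([[1, 2], [3, 4]]))


# --- quantile_normalize -----------------------------------------------------

def test_quantile_normalize_hand_example():
    expr = _expr(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
    out = pp.quantile_normalize(expr)
    expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
    np.testing.assert_allclose(out.values.to_numpy(), expected)


def test_quantile_normalize_fixed_point_and_single_sample():
    col = np.array([3.0, 1.0, 2.0, 5.0])
    same = _expr(np.tile(col[:, None], (1, 5)))
    np.testing.assert_allclose(
        pp.quantile_normalize(same).values.to_numpy(), same.values.to_numpy()
    )
    single = _expr(col[:, None])
    np.testing.assert_allclose(
        pp.quantile_normalize(single).values.to_numpy(), single.values.to_numpy()
    )


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.integers(0, 2**31 - 1), st.integers(3, 12), st.integers(2, 6))
def test_quantile_normalize_equalizes_sorted_vectors(seed, n_genes, n_samples):
    rng = np.random.default_rng(seed)
    expr = _expr(rng.normal(0, 3, (n_genes, n_samples)))
    out = pp.quantile_normalize(expr).values.to_numpy()
    sorted_cols = np.sort(out, axis=0)
    reference = np.tile(sorted_cols[:, [0]], (1, sorted_cols.shape[1]))
    np.testing.assert_allclose(sorted_cols, reference, atol=1e-12)


def test_quantile_normalize_handles_ties_with_rank_mean():
    expr = _expr(np.array([[1.0, 10.0], [1.0, 20.0], [2.0, 30.0]]))
    out = pp.quantile_normalize(expr).values.to_numpy()
    # tied pair shares the mean of the two lowest reference values
    assert out[0, 0] == out[1, 0]
    ref = np.sort(expr.values.to_numpy(), axis=0).mean(axis=1)
    np.testing.assert_allclose(out[0, 0], 0.5 * (ref[0] + ref[1]))


# --- discretize_covariates --------------------------------------------------

@pytest.mark.parametrize(
    "minutes,expected", [(0, 1), (299, 1), (300, 2), (1499, 5), (10000, 5)]
)
def test_ischemic_bins(minutes, expected):
    cov = pd.DataFrame({"ischemic_time_min": [minutes], "age": [40]}, index=["s0"])
    assert pp.discretize_covariates(cov)["ischemic_bin"].iloc[0] == expected


def test_age_decade_bins():
    cov = pd.DataFrame({"ischemic_time_min": [0, 0], "age": [34, 70]}, index=["a", "b"])
    out = pp.discretize_covariates(cov)
    assert list(out["age_bin"]) == ["30-39", "70-79"]


def test_negative_ischemic_time_rejected():
    cov = pd.DataFrame({"ischemic_time_min": [-1], "age": [40]}, index=["s0"])
    with pytest.raises(ValueError, match="negative"):
        pp.discretize_covariates(cov)


def test_death_class_subsetting(standard_dataset):
    out, report = pp.subset_death_class(standard_dataset.expression, "ventilator")
    assert (out.covariates["death_class"] == "ventilator").all()
    assert report.samples_removed_death_class == (
        standard_dataset.expression.n_samples - out.n_samples
    )


# --- adjust_batches ---------------------------------------------------------

def _two_batch_expr(shift=2.0, n_per_batch=10, n_genes=6, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.normal(5, 1, (n_genes, 2 * n_per_batch))
    base[:, n_per_batch:] += shift
    cov = pd.DataFrame(
        {"batch": ["A"] * n_per_batch + ["B"] * n_per_batch},
        index=[f"s{j}" for j in range(2 * n_per_batch)],
    )
    return _expr(base, covariates=cov)


def test_constant_shift_batches_equalize_means():
    expr = _two_batch_expr()
    out, _ = pp.adjust_batches(expr, ["batch"])
    means = out.values.T.groupby(out.covariates["batch"]).mean()
    np.testing.assert_allclose(means.iloc[0], means.iloc[1], atol=1e-9)


def test_adjustment_preserves_grand_mean():
    expr = _two_batch_expr(seed=3)
    before = expr.values.mean(axis=1)
    out, _ = pp.adjust_batches(expr, ["batch"])
    np.testing.assert_allclose(out.values.mean(axis=1), before, atol=1e-9)


def test_single_level_factor_is_skipped_with_warning():
    expr = _two_batch_expr()
    cov = expr.covariates.assign(batch="A")
    expr = ExpressionMatrix(expr.values, cov)
    with pytest.warns(UserWarning, match="single level"):
        out, _ = pp.adjust_batches(expr, ["batch"])
    pd.testing.assert_frame_equal(out.values, expr.values)


def test_singleton_batch_samples_removed():
    expr = _two_batch_expr()
    cov = expr.covariates.copy()
    cov.iloc[0, 0] = "C"  # lone sample in batch C
    expr = ExpressionMatrix(expr.values, cov)
    out, report = pp.adjust_batches(expr, ["batch"])
    assert report.batches_removed_singleton == 1
    assert "s0" not in out.sample_ids


def test_full_preprocess_removes_planted_batch_effect(standard_dataset):
    """Preprocessing the batch-shifted fixture differs from preprocessing
    its shift-free twin by only a global constant: the planted batch
    effect is removed exactly (rank-based normalization is invariant to a
    per-sample additive shift)."""
    from recmet.datasets import SyntheticConfig, generate_dataset

    twin = generate_dataset(SyntheticConfig(rng_seed=7, batch_shift_sd=0.0))
    shifted, _ = pp.preprocess_expression(standard_dataset.expression)
    clean, _ = pp.preprocess_expression(twin.expression)
    delta = shifted.values.to_numpy() - clean.values.to_numpy()
    assert delta.std() < 1e-9
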