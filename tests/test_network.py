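"""Network stage: bicor, signed adjacency, TOM, module detection, eigengenes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from recmet import network
from recmet.datasets import SyntheticConfig, generate_dataset


# --- independent scalar oracles --------------------------------------------

def bicor_pair_oracle(x, y):
    """Direct scalar transcription of the biweight midcorrelation formula."""
    def dev(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            return v - v.mean()
        u = (v - med) / (9 * mad)
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        return (v - med) * w

    dx, dy = dev(np.asarray(x, float)), dev(np.asarray(y, float))
    return float(np.sum(dx * dy) / np.sqrt(np.sum(dx**2) * np.sum(dy**2)))


def tom_oracle(A):
    """Brute-force triple-loop TOM."""
    A = np.asarray(A, float).copy()
    np.fill_diagonal(A, 0.0)
    n = A.shape[0]
    T = np.eye(n)
    k = A.sum(axis=1)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            T[i, j] = (l + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


# --- bicor ------------------------------------------------------------------

def test_bicor_self_and_affine():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 10)
    C = network.bicor(np.vstack([x, 2 * x + 3]))
    assert C.iloc[0, 0] == pytest.approx(1.0)
    assert C.iloc[0, 1] == pytest.approx(1.0)


def test_bicor_downweights_outlier_more_than_pearson():
    x = np.arange(1.0, 11.0)
    y = x.copy()
    y[-1] = 1000.0
    X = np.vstack([x, y])
    b = network.bicor(X).iloc[0, 1]
    p = network.pearson(X).iloc[0, 1]
    assert b == pytest.approx(bicor_pair_oracle(x, y), abs=1e-12)
    assert b > p
    assert b == pytest.approx(0.8750764673845515, abs=1e-10)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_bicor_matches_pairwise_oracle(seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (4, 8))
    C = network.bicor(X).to_numpy()
    for i in range(4):
        for j in range(4):
            expected = 1.0 if i == j else bicor_pair_oracle(X[i], X[j])
            assert C[i, j] == pytest.approx(expected, abs=1e-10)


def test_bicor_constant_gene_is_an_error():
    X = np.vstack([np.ones(6), np.arange(6.0)])
    with pytest.raises(ValueError, match="zero MAD and zero variance"):
        network.bicor(X)


def test_bicor_mad_zero_falls_back_to_pearson():
    # heavy central tie mass: MAD 0 but nonzero variance
    x = np.array([5.0, 5.0, 5.0, 5.0, 5.0, 9.0, 1.0])
    y = np.arange(7.0)
    got = network.bicor(np.vstack([x, y])).iloc[0, 1]
    assert got == pytest.approx(bicor_pair_oracle(x, y), abs=1e-12)


# --- soft adjacency ---------------------------------------------------------

def test_signed_adjacency_spot_values():
    C = np.array([[1.0, -1.0, 0.0], [-1.0, 1.0, 0.5], [0.0, 0.5, 1.0]])
    A = network.soft_adjacency(C, beta=12, signed=True)
    assert A[0, 0] == pytest.approx(1.0, abs=1e-12)
    assert A[0, 1] == pytest.approx(0.0, abs=1e-12)
    assert A[0, 2] == pytest.approx(0.5**12, abs=1e-12)
    assert A[1, 2] == pytest.approx(0.75**12, abs=1e-12)


def test_unsigned_adjacency_uses_absolute_value():
    C = np.array([[1.0, -0.5], [-0.5, 1.0]])
    A = network.soft_adjacency(C, beta=6, signed=False)
    assert A[0, 1] == pytest.approx(0.5**6)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    st.floats(-1, 1), st.floats(-1, 1),
    st.floats(1, 20), st.floats(1, 20),
)
def test_signed_adjacency_monotone(c1, c2, b1, b2):
    lo, hi = sorted([c1, c2])
    a_lo = network.soft_adjacency(np.array([[lo]]), beta=b1)[0, 0]
    a_hi = network.soft_adjacency(np.array([[hi]]), beta=b1)[0, 0]
    assert a_lo <= a_hi + 1e-15  # monotone in correlation
    b_lo, b_hi = sorted([b1, b2])
    if hi < 1:
        assert (
            network.soft_adjacency(np.array([[hi]]), beta=b_hi)[0, 0]
            <= network.soft_adjacency(np.array([[hi]]), beta=b_lo)[0, 0] + 1e-15
        )


def test_beta_below_one_rejected():
    with pytest.raises(ValueError):
        network.soft_adjacency(np.eye(2), beta=0.5)


# --- TOM --------------------------------------------------------------------

def test_tom_hand_example_complete_triangle():
    A = np.ones((3, 3))
    T = network.tom_similarity(A)
    assert np.allclose(T, 1.0)


def test_tom_empty_network():
    T = network.tom_similarity(np.zeros((4, 4)))
    assert np.allclose(T - np.eye(4), 0.0)


@settings(deadline=None, derandomize=True, max_examples=100)
@given(st.integers(0, 2**31 - 1))
def test_tom_matches_triple_loop_oracle(seed):
    rng = np.random.default_rng(seed)
    A = rng.uniform(0, 1, (6, 6))
    A = (A + A.T) / 2
    T = network.tom_similarity(A)
    assert np.max(np.abs(T - tom_oracle(A))) < 1e-12
    assert np.allclose(T, T.T)
    assert T.min() >= 0.0 and T.max() <= 1.0


# --- eigengenes and kME -----------------------------------------------------

def test_eigengene_rank_one_module():
    profile = np.sin(np.linspace(0, 6, 40))
    X = np.tile(profile, (5, 1))
    v = network.module_eigengene(X)
    r = np.corrcoef(v, profile)[0, 1]
    assert abs(r) == pytest.approx(1.0, abs=1e-10)
    assert r > 0  # oriented with the mean member profile


def test_eigengene_sign_flips_with_negated_members():
    rng = np.random.default_rng(5)
    X = rng.normal(0, 1, (6, 30)) + rng.normal(0, 1, 30)
    v = network.module_eigengene(X)
    v_neg = network.module_eigengene(-X)
    assert np.corrcoef(v, v_neg)[0, 1] == pytest.approx(-1.0, abs=1e-10)


def test_eigengene_tracks_latent_factor():
    """On a confounder-free planted module the eigengene is almost the
    latent factor itself."""
    ds = generate_dataset(SyntheticConfig(rng_seed=7, batch_shift_sd=0.0))
    module1 = [g for g, m in ds.truth.module_of_gene.items() if m == 1]
    eig = network.module_eigengene(ds.expression.values, module1)
    planted = ds.truth.latent_factors[1].to_numpy()
    assert abs(np.corrcoef(eig, planted)[0, 1]) > 0.95


def test_detected_eigengene_still_tracks_factor_after_preprocessing(
    standard_dataset, pipeline_run
):
    """Through the full chain (normalization slightly blurs the signal)
    the detected metabolic module's eigengene stays close to the factor."""
    part = pipeline_run.partition
    factors = standard_dataset.truth.latent_factors.loc[
        list(pipeline_run.expression.sample_ids)
    ]
    met = list(standard_dataset.truth.metabolic_receptors)
    detected = part.module_of_gene[met].mode()[0]
    eig = part.eigengenes[detected].to_numpy()
    assert abs(np.corrcoef(eig, factors[1].to_numpy())[0, 1]) > 0.85


def test_kme_of_eigengene_like_gene_and_bounds(pipeline_run):
    part = pipeline_run.partition
    assert ((part.kme >= -1) & (part.kme <= 1)).all().all()
    # genes of a module have high own-module kME
    for m in part.module_labels:
        own = part.kme.loc[part.members(m), m]
        assert own.mean() > 0.6


def test_background_gene_kme_is_small_at_large_n():
    cfg = SyntheticConfig(
        n_genes=300, n_samples=200, module_sizes=(80, 80, 80),
        batch_shift_sd=0.0, rng_seed=13,
    )
    ds = generate_dataset(cfg)
    expr = ds.expression
    corr = network.bicor(expr.values.to_numpy(), gene_ids=expr.gene_ids)
    tom = network.tom_similarity(network.soft_adjacency(corr))
    part = network.detect_modules(tom, expr=expr)
    bg = [g for g, m in ds.truth.module_of_gene.items() if m == 0]
    assert part.kme.loc[bg].abs().to_numpy().mean() < 0.3


# --- module detection -------------------------------------------------------

def test_detect_modules_recovers_planted_partition(standard_dataset, pipeline_run):
    truth = np.array(
        [standard_dataset.truth.module_of_gene[g]
         for g in pipeline_run.expression.gene_ids]
    )
    found = pipeline_run.partition.module_of_gene.to_numpy()
    assert adjusted_rand_score(truth, found) > 0.9


def test_labels_numbered_by_decreasing_size(pipeline_run):
    sizes = pipeline_run.partition.module_sizes()
    assert list(sizes.index) == sorted(sizes.index)
    assert (sizes.diff().dropna() <= 0).all()


def test_metabolic_receptors_colocate(standard_dataset, pipeline_run):
    labels = pipeline_run.partition.module_of_gene[
        list(standard_dataset.truth.metabolic_receptors)
    ]
    majority = labels.mode()[0]
    assert (labels == majority).mean() >= 0.9


def test_oversized_min_module_size_unassigns_everything(pipeline_run):
    with pytest.warns(UserWarning, match="no module"):
        part = network.detect_modules(
            pipeline_run.tom,
            min_module_size=10_000,
            expr=pipeline_run.expression,
        )
    assert (part.module_of_gene == 0).all()


def test_merge_height_zero_keeps_partition(pipeline_run):
    part = network.detect_modules(
        pipeline_run.tom, merge_height=0.0, expr=pipeline_run.expression
    )
    base = pipeline_run.partition.module_of_gene
    assert adjusted_rand_score(base.to_numpy(), part.module_of_gene.to_numpy()) == 1.0
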