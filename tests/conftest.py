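"""Shared fixtures: the standard synthetic dataset and one full pipeline run.

The standard fixture plants 3 modules of 100 genes in a 600-gene,
150-sample matrix with eigengene loading 1.5 against unit noise, 60
receptors (24 metabolic, all in module 1), and 30 pathways of which 6 are
module-enriched. Seed 7 throughout.
"""

from types import SimpleNamespace

import pytest

from recmet import classify, enrichment, network, preprocessing, pu
from recmet.datasets import SyntheticConfig, generate_dataset

STANDARD_SEED = 7


@pytest.fixture(scope="session")
def standard_config():
    return SyntheticConfig(rng_seed=STANDARD_SEED)


@pytest.fixture(scope="session")
def standard_dataset(standard_config):
    return generate_dataset(standard_config)


@pytest.fixture(scope="session")
def pipeline_run(standard_dataset):
    """One in-memory run of every stage on the standard dataset."""
    ds = standard_dataset
    expr, report = preprocessing.preprocess_expression(ds.expression)
    corr = network.bicor(expr.values.to_numpy(), gene_ids=expr.gene_ids)
    adj = network.soft_adjacency(corr, beta=12.0, signed=True)
    tom = network.tom_similarity(adj)
    partition = network.detect_modules(tom, expr=expr)

    enr = enrichment.enrich_modules(partition, ds.gene_sets)
    features = enrichment.build_feature_matrix(partition, enr, ds.receptors)

    seed_positives = [r for r in ds.seed_positives if r in features.values.index]
    known_negatives = [r for r in ds.known_negatives if r in features.values.index]
    rates = pu.pu_bagging(features.values, seed_positives, rng_seed=STANDARD_SEED)
    labels = pu.derive_labels(
        rates,
        accept_list=ds.accept_list,
        seed_positives=seed_positives,
        known_negatives=known_negatives,
    )

    groups = {"inferred": labels.negatives_inferred, "known": labels.negatives_known}
    evaluation = classify.evaluate_label_sets(
        features.values, labels.positives, groups, rng_seed=STANDARD_SEED
    )
    specs = {
        g: {"svm_cost": evaluation[g]["svm_cost"], "knn_k": evaluation[g]["knn_k"]}
        for g in groups
    }
    models = classify.fit_final_models(
        features.values, labels.positives, groups, specs=specs
    )
    unlabeled = [r for r in features.values.index if r in labels.unlabeled]
    consensus, votes = classify.consensus_predict(features.values.loc[unlabeled], models)

    return SimpleNamespace(
        dataset=ds,
        expression=expr,
        filter_report=report,
        correlation=corr,
        adjacency=adj,
        tom=tom,
        partition=partition,
        enrichment=enr,
        features=features,
        rates=rates,
        labels=labels,
        evaluation=evaluation,
        models=models,
        unlabeled=unlabeled,
        consensus=consensus,
        votes=votes,
    )
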