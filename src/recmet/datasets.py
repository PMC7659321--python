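"""Synthetic expression datasets with planted co-expression modules.

The generator emulates the data regime the pipeline assumes: a latent-factor
expression model with a handful of co-expressed gene modules (one of them
"metabolic", holding most of the planted metabolic receptors), additive
per-batch shifts, background genes with no shared structure, pathway gene
sets enriched for designated modules, and a receptor subset with known
positive / negative / unlabeled status.

Model per gene g and sample s::

    x[g, s] = mu[g] + loading[g] * F[module(g), s] + shift[batch(s)] + eps[g, s]

with one standard-normal latent factor F per module per sample,
``loading = module_signal`` for module members and 0 for background genes,
and ``eps ~ N(0, noise_sd^2)``. Under this model the expected within-module
correlation is ``signal^2 / (signal^2 + noise_sd^2)``, which is what makes
weighted-correlation-network module detection and guilt-by-association
classification provably recoverable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSetCollection

__all__ = ["SyntheticConfig", "SyntheticTruth", "SyntheticDataset", "generate_dataset", "write_dataset"]

DEATH_CLASSES = ("ventilator", "violent_fast", "fast_natural", "slow")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic data generator.

    Defaults define the "standard fixture": 600 genes, three planted
    modules of 100 genes, 60 receptors of which 40% are metabolic,
    eigengene loading 1.5 against unit noise, 150 samples in 4 batches.
    """

    n_genes: int = 600
    n_samples: int = 150
    n_modules: int = 3
    module_sizes: tuple[int, ...] = (100, 100, 100)
    n_receptors: int = 60
    frac_metabolic_receptors: float = 0.4
    module_signal: float = 1.5
    noise_sd: float = 1.0
    n_batches: int = 4
    batch_shift_sd: float = 0.5
    n_pathways: int = 30
    pathway_purity: float = 0.8
    pathway_size_range: tuple[int, int] = (10, 50)
    pathways_per_module: int = 2
    seed_positive_fraction: float = 1 / 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_samples": self.n_samples,
            "n_receptors": self.n_receptors,
            "n_batches": self.n_batches,
            "n_pathways": self.n_pathways,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.n_modules < 0:
            raise ValueError("n_modules must be >= 0")
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes must have n_modules entries")
        if any(s <= 0 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError(
                f"sum of module sizes {sum(self.module_sizes)} exceeds n_genes {self.n_genes}"
            )
        if self.n_receptors > self.n_genes:
            raise ValueError("receptor count exceeds gene count")
        for name in ("frac_metabolic_receptors", "pathway_purity", "seed_positive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.module_signal < 0:
            raise ValueError("module_signal must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass
class SyntheticTruth:
    """Planted ground truth backing every downstream test."""

    module_of_gene: dict[str, int]
    metabolic_receptors: frozenset
    nonmetabolic_receptors: frozenset
    pathway_target_module: dict[str, int]
    latent_factors: pd.DataFrame | None = None  # samples x modules

    def __post_init__(self) -> None:
        self.metabolic_receptors = frozenset(self.metabolic_receptors)
        self.nonmetabolic_receptors = frozenset(self.nonmetabolic_receptors)
        if self.metabolic_receptors & self.nonmetabolic_receptors:
            raise ValueError("metabolic and nonmetabolic receptor sets overlap")
        modules = set(self.module_of_gene.values())
        for pw, m in self.pathway_target_module.items():
            if m not in modules:
                raise ValueError(f"pathway {pw} targets nonexistent module {m}")

    def to_json(self, path) -> None:
        payload = {
            "module_of_gene": self.module_of_gene,
            "metabolic_receptors": sorted(self.metabolic_receptors),
            "nonmetabolic_receptors": sorted(self.nonmetabolic_receptors),
            "pathway_target_module": self.pathway_target_module,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            module_of_gene=payload["module_of_gene"],
            metabolic_receptors=frozenset(payload["metabolic_receptors"]),
            nonmetabolic_receptors=frozenset(payload["nonmetabolic_receptors"]),
            pathway_target_module=payload["pathway_target_module"],
        )


@dataclass
class SyntheticDataset:
    """Everything one pipeline run needs, plus the planted truth."""

    expression: ExpressionMatrix
    gene_sets: GeneSetCollection
    receptors: list[str]
    seed_positives: list[str]
    known_negatives: list[str]
    accept_list: list[str]
    truth: SyntheticTruth
    config: SyntheticConfig = field(repr=False, default=SyntheticConfig())


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset; deterministic given ``rng_seed``.

    The metabolic module is module 1; planted metabolic receptors are all
    members of it. Nonmetabolic receptors are spread over the remaining
    modules and the background: roughly 40% go to module 2 and are emitted
    as the known-negative list (playing the role an independent negative
    receptor family — e.g. cytokine receptors — plays on real data), 30%
    to module 3 (or module 2 when fewer modules exist), and the rest to
    background genes.
    """
    rng = np.random.default_rng(config.rng_seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    samples = [f"S{j:04d}" for j in range(config.n_samples)]

    # --- module assignment: random permutation carved into blocks
    perm = rng.permutation(config.n_genes)
    module_of = np.zeros(config.n_genes, dtype=int)
    offset = 0
    for m, size in enumerate(config.module_sizes, start=1):
        module_of[perm[offset : offset + size]] = m
        offset += size

    # --- receptors
    n_metabolic = int(round(config.n_receptors * config.frac_metabolic_receptors))
    if config.n_modules >= 1 and config.module_signal > 0:
        module1_genes = np.flatnonzero(module_of == 1)
        if n_metabolic > len(module1_genes):
            raise ValueError("metabolic receptor count exceeds module 1 size")
        metabolic_idx = rng.choice(module1_genes, size=n_metabolic, replace=False)
    else:
        metabolic_idx = rng.choice(config.n_genes, size=n_metabolic, replace=False)

    n_nonmet = config.n_receptors - n_metabolic
    n_known_neg = int(round(0.4 * n_nonmet))
    n_other_module = int(round(0.3 * n_nonmet))
    n_background = n_nonmet - n_known_neg - n_other_module

    taken = set(metabolic_idx.tolist())

    def _draw(pool: np.ndarray, size: int) -> np.ndarray:
        pool = np.array([g for g in pool if g not in taken])
        if size > len(pool):
            size = len(pool)
        picked = rng.choice(pool, size=size, replace=False) if size else np.array([], dtype=int)
        taken.update(picked.tolist())
        return picked

    if config.n_modules >= 2:
        known_neg_idx = _draw(np.flatnonzero(module_of == 2), n_known_neg)
        other_mod = 3 if config.n_modules >= 3 else 2
        other_idx = _draw(np.flatnonzero(module_of == other_mod), n_other_module)
    else:
        known_neg_idx = _draw(np.flatnonzero(module_of == 0), n_known_neg)
        other_idx = _draw(np.flatnonzero(module_of == 0), n_other_module)
    bg_idx = _draw(np.flatnonzero(module_of == 0), n_background)
    nonmet_idx = np.concatenate([known_neg_idx, other_idx, bg_idx])

    receptor_idx = np.concatenate([metabolic_idx, nonmet_idx])
    receptors = sorted(genes[i] for i in receptor_idx)
    metabolic = frozenset(genes[i] for i in metabolic_idx)
    nonmetabolic = frozenset(genes[i] for i in nonmet_idx)
    known_negatives = sorted(genes[i] for i in known_neg_idx)

    # seed positives + accept list (accept list stands in for manual
    # literature verification: seeds plus half of the remaining metabolic)
    met_sorted = sorted(metabolic)
    n_seed = max(2, int(round(config.seed_positive_fraction * len(met_sorted)))) if met_sorted else 0
    seed_positives = sorted(rng.choice(met_sorted, size=min(n_seed, len(met_sorted)), replace=False))
    remaining = sorted(set(met_sorted) - set(seed_positives))
    n_accept_extra = len(remaining) // 2
    accept_extra = sorted(rng.choice(remaining, size=n_accept_extra, replace=False)) if remaining else []
    accept_list = sorted(set(seed_positives) | set(accept_extra))

    # --- expression values
    mu = rng.uniform(2.0, 8.0, size=config.n_genes)
    factors = rng.standard_normal((max(config.n_modules, 1), config.n_samples))
    batch_of = rng.integers(0, config.n_batches, size=config.n_samples)
    shifts = rng.normal(0.0, config.batch_shift_sd, size=config.n_batches)
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_genes, config.n_samples))

    values = mu[:, None] + noise
    member = module_of > 0
    if config.n_modules > 0 and member.any():
        values[member] += config.module_signal * factors[module_of[member] - 1]
    values += shifts[batch_of][None, :]

    covariates = pd.DataFrame(
        {
            "batch": [f"B{b}" for b in batch_of],
            "ischemic_time_min": rng.integers(0, 1500, size=config.n_samples),
            "sex": rng.choice(["M", "F"], size=config.n_samples),
            "age": rng.integers(20, 80, size=config.n_samples),
            "death_class": rng.choice(
                DEATH_CLASSES, size=config.n_samples, p=[0.9, 0.04, 0.03, 0.03]
            ),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples),
        covariates,
    )

    # --- pathways
    pathways: dict[str, frozenset] = {}
    target: dict[str, int] = {}
    background_genes = [genes[i] for i in np.flatnonzero(module_of == 0)]
    all_genes = list(genes)
    lo, hi = config.pathway_size_range
    n_planted = min(config.n_pathways, config.pathways_per_module * config.n_modules)
    for p in range(config.n_pathways):
        name = f"PW{p:03d}"
        size = int(rng.integers(lo, hi + 1))
        if p < n_planted:
            m = (p % config.n_modules) + 1
            mod_genes = [genes[i] for i in np.flatnonzero(module_of == m)]
            n_from_mod = min(int(round(config.pathway_purity * size)), len(mod_genes))
            picked = list(rng.choice(mod_genes, size=n_from_mod, replace=False))
            n_bg = min(size - n_from_mod, len(background_genes))
            if n_bg > 0:
                picked += list(rng.choice(background_genes, size=n_bg, replace=False))
            target[name] = m
        else:
            picked = list(rng.choice(all_genes, size=min(size, len(all_genes)), replace=False))
        pathways[name] = frozenset(picked)
    gene_sets = GeneSetCollection(pathways, frozenset(genes))

    truth = SyntheticTruth(
        module_of_gene={g: int(m) for g, m in zip(genes, module_of)},
        metabolic_receptors=metabolic,
        nonmetabolic_receptors=nonmetabolic,
        pathway_target_module=target,
        latent_factors=pd.DataFrame(
            factors.T, index=samples, columns=range(1, max(config.n_modules, 1) + 1)
        ),
    )
    return SyntheticDataset(
        expression=expr,
        gene_sets=gene_sets,
        receptors=receptors,
        seed_positives=list(seed_positives),
        known_negatives=known_negatives,
        accept_list=accept_list,
        truth=truth,
        config=config,
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write every artifact of a synthetic dataset as plain-text files."""
    from . import io  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "metadata": outdir / "metadata.tsv",
        "pathways": outdir / "pathways.gmt",
        "receptors": outdir / "receptors.txt",
        "seed_positives": outdir / "seed_positives.txt",
        "known_negatives": outdir / "known_negatives.txt",
        "accept_list": outdir / "accept_list.txt",
        "truth": outdir / "truth.json",
        "config": outdir / "generator_config.json",
    }
    io.write_expression_tsv(dataset.expression, paths["expression"])
    io.write_metadata_tsv(dataset.expression.covariates, paths["metadata"])
    io.write_gmt(dataset.gene_sets, paths["pathways"])
    io.write_gene_list(dataset.receptors, paths["receptors"])
    io.write_gene_list(dataset.seed_positives, paths["seed_positives"])
    io.write_gene_list(dataset.known_negatives, paths["known_negatives"])
    io.write_gene_list(dataset.accept_list, paths["accept_list"])
    dataset.truth.to_json(paths["truth"])
    cfg = asdict(dataset.config)
    cfg = {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()}
    paths["config"].write_text(json.dumps(cfg, indent=1))
    return paths
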