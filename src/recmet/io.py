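"""Readers and writers for the pipeline's plain-text formats.

Expression matrices and metadata travel as TSV (gzip transparently
supported via the ``.gz`` suffix), pathways as GMT, receptor lists as
one-gene-per-line text. Readers validate shape and id uniqueness and fail
with the offending identifier or line.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import pandas as pd

from .containers import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
]


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_expression_tsv(path, metadata_path=None) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column = gene ids, header = sample
    ids); optionally attach a metadata TSV indexed by sample id."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    bad = df.columns[[not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]]
    if len(bad):
        for col in bad:
            nonnum = pd.to_numeric(df[col], errors="coerce")
            row = nonnum.index[nonnum.isna() & df[col].notna()]
            line = df.index.get_loc(row[0]) + 2 if len(row) else "?"
            raise ValueError(f"{path}: non-numeric cell in sample {col!r} near line {line}")
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"{path}: missing/ragged value at gene {gene!r}")
    cov = read_metadata_tsv(metadata_path) if metadata_path else None
    return ExpressionMatrix(df.astype(float), cov)


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    df = expr.values.copy()
    df.index.name = "gene_id"
    # no float_format: full repr precision so write/read round-trips exactly
    df.to_csv(path, sep="\t")


def read_metadata_tsv(path) -> pd.DataFrame:
    cov = pd.read_csv(path, sep="\t", index_col=0)
    if cov.index.has_duplicates:
        dup = cov.index[cov.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    return cov


def write_metadata_tsv(covariates: pd.DataFrame, path) -> None:
    out = covariates.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_gmt(path, universe=None) -> GeneSetCollection:
    """Read a GMT gene-set file: name, description, then member genes.

    Duplicate genes within a line are collapsed. When ``universe`` is
    given, genes outside it are dropped (count logged) and pathways
    emptied by the restriction are dropped with a warning.
    """
    pathways: dict[str, frozenset] = {}
    n_outside = 0
    universe_set = frozenset(universe) if universe is not None else None
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, genes = fields[0], frozenset(g for g in fields[2:] if g)
            if name in pathways:
                raise ValueError(f"{path}:{lineno}: duplicate pathway {name!r}")
            if universe_set is not None:
                kept = genes & universe_set
                n_outside += len(genes) - len(kept)
                if not kept:
                    logger.warning("pathway %s empty after universe restriction; dropped", name)
                    continue
                genes = kept
            pathways[name] = genes
    if n_outside:
        logger.info("dropped %d pathway genes outside the expression universe", n_outside)
    if universe_set is None:
        universe_set = frozenset().union(*pathways.values()) if pathways else frozenset()
    return GeneSetCollection(pathways, universe_set)


def write_gmt(gene_sets: GeneSetCollection, path) -> None:
    with _open_text(path, "wt") as fh:
        for name, genes in gene_sets.pathways.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


def read_gene_list(path) -> list[str]:
    with _open_text(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path) -> None:
    with _open_text(path, "wt") as fh:
        for g in genes:
            fh.write(f"{g}\n")
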