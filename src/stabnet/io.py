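"""Readers and writers for counts, designs, gene sets and result tables.

TSV is the canonical interchange format. MatrixMarket is accepted for count
matrices only, with sidecar ``<stem>.genes.txt`` / ``<stem>.samples.txt`` id
files. All writers round-trip exactly through their paired readers.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import (
    CountMatrix,
    DesignTable,
    GeneSetMap,
    ExpressionMatrix,
    ValidationError,
)

log = logging.getLogger("stabnet")


def _mtx_sidecars(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}.genes.txt"), Path(f"{stem}.samples.txt")


def read_counts(path, fmt: str | None = None) -> CountMatrix:
    """Read a count matrix from TSV or MatrixMarket.

    TSV layout: header row of sample ids, first column of gene ids. MTX files
    must sit next to ``<stem>.genes.txt`` and ``<stem>.samples.txt`` id lists
    (one id per line, matrix rows = genes).
    """
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "tsv"
    if fmt == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except pd.errors.EmptyDataError:
            raise ValidationError("no genes parsed") from None
        if df.shape[0] == 0:
            raise ValidationError("no genes parsed")
        return CountMatrix(df)
    if fmt == "mtx":
        genes_path, samples_path = _mtx_sidecars(path)
        for p in (genes_path, samples_path):
            if not p.exists():
                raise ValidationError(f"missing MTX sidecar id file: {p}")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = genes_path.read_text().split()
        samples = samples_path.read_text().split()
        if mat.shape != (len(genes), len(samples)):
            raise ValidationError(
                f"MTX shape {mat.shape} does not match id files "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        return CountMatrix(pd.DataFrame(mat, index=genes, columns=samples))
    raise ValueError(f"unknown counts format {fmt!r}")


def write_counts(cm: CountMatrix, path, fmt: str | None = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "tsv"
    if fmt == "tsv":
        cm.counts.to_csv(path, sep="\t", index_label="gene_id")
    elif fmt == "mtx":
        genes_path, samples_path = _mtx_sidecars(path)
        scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(cm.counts.to_numpy()))
        genes_path.write_text("\n".join(cm.gene_ids) + "\n")
        samples_path.write_text("\n".join(cm.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown counts format {fmt!r}")


def read_design(path, populations=None, stages=None) -> DesignTable:
    """Read the sample design TSV (sample_id, population, infestation)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "population", "infestation"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"design table missing column(s): {sorted(missing)}")
    df = df.set_index("sample_id")
    kwargs = {}
    if populations is not None:
        kwargs["populations"] = tuple(populations)
    if stages is not None:
        kwargs["stages"] = tuple(stages)
    return DesignTable(df, **kwargs)


def write_design(design: DesignTable, path) -> None:
    design.table.to_csv(path, sep="\t", index_label="sample_id")


def read_gene_sets(path) -> GeneSetMap:
    """Read gene sets from TSV with columns term_id, term_name, gene_id."""
    df = pd.read_csv(path, sep="\t")
    required = {"term_id", "term_name", "gene_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"gene set table missing column(s): {sorted(missing)}")
    return GeneSetMap.from_records(
        df[["term_id", "term_name", "gene_id"]].itertuples(index=False)
    )


def write_gene_sets(gsm: GeneSetMap, path) -> None:
    rows = [
        (gs.term_id, gs.term_name, g)
        for gs in sorted(gsm, key=lambda s: s.term_id)
        for g in sorted(gs.gene_ids)
    ]
    pd.DataFrame(rows, columns=["term_id", "term_name", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_expression(path, prior_count: float = 0.5) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, prior_count)


def write_expression(em: ExpressionMatrix, path) -> None:
    em.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def write_table(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
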