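"""TSV loaders for the pipeline's tabular inputs.

Sample naming convention: the strain label is the first ``_``-separated token
of the sample id (e.g. ``ILS_saline_2`` or ``LXS014_1``), which is how the
bundle writer encodes per-sample strain membership in plain TSV headers.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .mirna_de import CountMatrix
from .mrna_assoc import ExpressionTable, PhenotypeTable
from .target_pairs import aggregate_long_table, validate_target_db


def strain_of(sample_id: str) -> str:
    return sample_id.split("_")[0]


def read_counts(path: str | Path, study: str) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(
        feature_ids=[str(i) for i in df.index],
        sample_ids=list(df.columns),
        strain=[strain_of(c) for c in df.columns],
        study=study,
        counts=df.to_numpy(),
    )


def read_expression(path: str | Path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionTable(
        gene_ids=[str(i) for i in df.index],
        sample_ids=list(df.columns),
        strain=[strain_of(c) for c in df.columns],
        values=df.to_numpy(),
    )


def read_phenotype(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t")
    if not {"strain", "lorr_minutes"} <= set(df.columns):
        raise ValueError(f"phenotype table {path} needs columns strain, lorr_minutes")
    return PhenotypeTable(
        strain=[str(s) for s in df["strain"]],
        lorr_minutes=df["lorr_minutes"].to_numpy(),
    )


def read_target_db(path: str | Path) -> pd.DataFrame:
    """Read a target-DB snapshot; accepts the aggregated-count dialect
    (validated_db_count / predicted_db_count columns) or the long dialect
    (one row per mirna/gene/database/evidence)."""
    df = pd.read_csv(path, sep="\t")
    if {"database", "evidence"} <= set(df.columns):
        df = aggregate_long_table(df)
    return validate_target_db(df)
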