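"""Candidate miRNA-mRNA pair construction from a multi-database snapshot.

Interaction evidence comes from target databases of two kinds: experimentally
validated interactions and sequence-based predictions.  The consensus filter
keeps a pair if it is validated in at least one database, or predicted in at
least five of the eight prediction databases.  A pair qualifying both ways is
labelled "validated" (validation evidence dominates), so the retained set
partitions cleanly into validated and predicted interactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

REQUIRED_COLUMNS = ("mirna_id", "gene_id", "validated_db_count", "predicted_db_count")


@dataclass(frozen=True)
class CandidatePair:
    mirna_id: str
    gene_id: str
    interaction_type: str  # "validated" | "predicted"
    support: int


def validate_target_db(db: pd.DataFrame) -> pd.DataFrame:
    """Check the target-DB table; raises with a row number on malformed input."""
    for col in REQUIRED_COLUMNS:
        if col not in db.columns:
            raise ValueError(f"target DB table missing column {col!r}")
    dup = db.duplicated(subset=["mirna_id", "gene_id"])
    if dup.any():
        raise ValueError(f"duplicate (mirna, gene) pair at row {int(dup.idxmax())}")
    for col in ("validated_db_count", "predicted_db_count"):
        bad = (db[col] < 0) | db[col].isna()
        if bad.any():
            raise ValueError(f"invalid {col} at row {int(bad.idxmax())}")
    return db


def aggregate_long_table(long: pd.DataFrame) -> pd.DataFrame:
    """Collapse a long-format table (one row per mirna/gene/database/evidence
    type) into per-pair validated and predicted database counts."""
    for col in ("mirna_id", "gene_id", "database", "evidence"):
        if col not in long.columns:
            raise ValueError(f"long-format target table missing column {col!r}")
    dedup = long.drop_duplicates(subset=["mirna_id", "gene_id", "database", "evidence"])
    counts = (
        dedup.pivot_table(
            index=["mirna_id", "gene_id"],
            columns="evidence",
            values="database",
            aggfunc="nunique",
            fill_value=0,
        )
        .reset_index()
    )
    counts.columns.name = None
    out = counts.rename(
        columns={"validated": "validated_db_count", "predicted": "predicted_db_count"}
    )
    for col in ("validated_db_count", "predicted_db_count"):
        if col not in out.columns:
            out[col] = 0
    return out[list(REQUIRED_COLUMNS)]


def filter_pairs(
    db: pd.DataFrame, validated_min: int = 1, predicted_min: int = 5
) -> list[CandidatePair]:
    """Apply the consensus filter; validated evidence takes precedence."""
    db = validate_target_db(db)
    out: list[CandidatePair] = []
    for row in db.itertuples(index=False):
        v = int(row.validated_db_count)
        p = int(row.predicted_db_count)
        if v >= validated_min:
            out.append(CandidatePair(row.mirna_id, row.gene_id, "validated", v))
        elif p >= predicted_min:
            out.append(CandidatePair(row.mirna_id, row.gene_id, "predicted", p))
    return out


def restrict_to_measured(
    pairs: list[CandidatePair], mirna_ids: set[str], gene_ids: set[str]
) -> list[CandidatePair]:
    """Keep pairs whose miRNA passed the expression filter and whose gene was
    measured in the expression table."""
    return [p for p in pairs if p.mirna_id in mirna_ids and p.gene_id in gene_ids]


def pairs_frame(pairs: list[CandidatePair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mirna_id": [p.mirna_id for p in pairs],
            "gene_id": [p.gene_id for p in pairs],
            "interaction_type": [p.interaction_type for p in pairs],
            "support": [p.support for p in pairs],
        }
    )
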