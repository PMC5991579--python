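"""Genomic interval overlap between miRNA loci and QTL regions.

Coordinates follow the BED convention: 0-based, half-open [start, end).
Strand is ignored; only physical colocation matters here.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"malformed interval {self.name or ''}: "
                f"{self.chrom}:{self.start}-{self.end}"
            )


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Half-open intersection test."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def read_bed(path) -> list[GenomicInterval]:
    """Read a BED3+ file (tab-separated, no header)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"BED file {path} has fewer than 3 columns")
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        name = str(row[3]) if df.shape[1] > 3 else f"interval_{i}"
        out.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2]), name))
    return out


def annotate_overlaps(
    features: list[GenomicInterval], regions: list[GenomicInterval]
) -> pd.DataFrame:
    """All overlapping (feature, region) pairs via a per-chromosome sorted sweep."""
    by_chrom_f: dict[str, list[GenomicInterval]] = {}
    by_chrom_r: dict[str, list[GenomicInterval]] = {}
    for f in features:
        by_chrom_f.setdefault(f.chrom, []).append(f)
    for r in regions:
        by_chrom_r.setdefault(r.chrom, []).append(r)

    hits = []
    for chrom in sorted(set(by_chrom_f) & set(by_chrom_r)):
        fs = sorted(by_chrom_f[chrom], key=lambda x: x.start)
        rs = sorted(by_chrom_r[chrom], key=lambda x: x.start)
        j0 = 0
        for f in fs:
            # drop regions that end at or before this feature's start
            while j0 < len(rs) and rs[j0].end <= f.start:
                j0 += 1
            j = j0
            while j < len(rs) and rs[j].start < f.end:
                if overlaps(f, rs[j]):
                    hits.append(
                        {
                            "feature": f.name,
                            "region": rs[j].name,
                            "chrom": chrom,
                            "feature_start": f.start,
                            "feature_end": f.end,
                            "region_start": rs[j].start,
                            "region_end": rs[j].end,
                        }
                    )
                j += 1
    return pd.DataFrame(
        hits,
        columns=[
            "feature", "region", "chrom",
            "feature_start", "feature_end", "region_start", "region_end",
        ],
    )
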