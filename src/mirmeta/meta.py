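"""Direction-aware Stouffer Z-score combination and FDR control.

Evidence from several independent analyses of the same biological question is
combined per feature (or per miRNA-mRNA pair) by converting each two-sided
p-value to a signed standard-normal z-score,

    z = direction * Phi^{-1}(1 - p / 2),

summing with weights, renormalising (Stouffer's method), and converting the
combined Z back to a two-sided p-value.  Concordant evidence (all sources
pointing the same way under the repression-oriented sign convention) adds
constructively; discordant evidence cancels.

Two combinations are used in the pipeline:

* the two-study miRNA meta-analysis (saline-treated and naive count studies,
  each giving a strain-effect p and direction), and
* the per-pair integrative meta-analysis over four sources: the two miRNA
  strain tests, the mRNA parental-strain test, and the mRNA-phenotype rank
  correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: smallest p-value accepted before conversion to z; keeps Phi^{-1} finite.
P_CLAMP = 1e-300

#: canonical evidence-source labels, in pipeline order.
SOURCES_4 = ("saline_mirna_de", "naive_mirna_de", "mrna_de", "lorr_corr")

#: orientation of each source's z in the repression-concordant configuration:
#: miRNA up in ISS, target mRNA up in ILS (strain effect opposite in sign),
#: and mRNA expression positively correlated with LORR (ILS being the
#: high-LORR, i.e. long-sleep, strain).
ORIENTATION_4 = {
    "saline_mirna_de": +1.0,
    "naive_mirna_de": +1.0,
    "mrna_de": -1.0,
    "lorr_corr": +1.0,
}

PATTERN_CONCORDANT = "ISS-up-miRNA/ILS-up-mRNA/positive-corr"
PATTERN_MIRROR = "mirror"
PATTERN_DISCORDANT = "discordant"
PATTERN_DEGENERATE = "degenerate"


@dataclass(frozen=True)
class SignedEvidence:
    """One evidence source for one pair: a two-sided p and an effect sign.

    ``direction`` is the sign of the ISS-vs-ILS effect for expression sources
    and the sign of the Spearman rho for the phenotype-correlation source.
    """

    source: str
    p: float
    direction: int

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise ValueError(
                f"direction must be -1 or +1, got {self.direction!r} "
                f"for source {self.source!r}"
            )
        if not (self.p <= 1.0):
            raise ValueError(f"p must be <= 1, got {self.p!r}")


@dataclass
class PairMetaResult:
    """Combined evidence for one miRNA-mRNA pair."""

    mirna_id: str
    gene_id: str
    component_z: dict[str, float]
    combined_Z: float
    p: float
    pattern: str
    q: float = field(default=np.nan)


def signed_z(p: float, direction: int) -> float:
    """Convert a two-sided p-value and an effect sign to a signed z-score.

    p is clamped into [1e-300, 1]; p = 1 maps to z = 0 regardless of sign.
    """
    if direction not in (-1, 1):
        raise ValueError(f"direction must be -1 or +1, got {direction!r}")
    p = float(np.clip(p, P_CLAMP, 1.0))
    return float(direction) * float(stats.norm.isf(p / 2.0))


def stouffer_combine(
    zs: Sequence[float], weights: Sequence[float] | None = None
) -> tuple[float, float]:
    """Combine signed z-scores: Z = sum(w_i z_i) / sqrt(sum(w_i^2)).

    Returns ``(Z, p)`` with p two-sided.  Equal weights by default.
    """
    z = np.asarray(zs, dtype=float)
    if z.size == 0:
        raise ValueError("stouffer_combine requires at least one z-score")
    if weights is None:
        w = np.ones_like(z)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != z.shape:
            raise ValueError("weights must match zs in length")
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
    Z = float(np.dot(w, z) / np.sqrt(np.dot(w, w)))
    p = float(2.0 * stats.norm.sf(abs(Z)))
    return Z, min(p, 1.0)


def combine_two_sided(ps: Sequence[float], directions: Sequence[int]) -> tuple[float, float]:
    """Equal-weight Stouffer combination of two-sided p-values with signs."""
    zs = [signed_z(p, d) for p, d in zip(ps, directions, strict=True)]
    return stouffer_combine(zs)


def _classify_pattern(oriented: np.ndarray) -> str:
    if np.all(oriented == 0):
        return PATTERN_DEGENERATE
    if np.all(oriented > 0):
        return PATTERN_CONCORDANT
    if np.all(oriented < 0):
        return PATTERN_MIRROR
    return PATTERN_DISCORDANT


def pair_meta(
    mirna_id: str,
    gene_id: str,
    evidence: Iterable[SignedEvidence],
    sources: Sequence[str] = SOURCES_4,
    orientation: dict[str, float] | None = None,
    weights: Sequence[float] | None = None,
) -> PairMetaResult:
    """Integrative meta-analysis for one miRNA-mRNA pair.

    Each source's signed z enters with a fixed orientation so that the
    repression-concordant configuration (miRNA and mRNA strain effects of
    opposite sign, mRNA-phenotype correlation concordant with the mRNA strain
    effect) accumulates, regardless of which strain the miRNA is up in.  The
    pattern label reports which concordance class (if any) the pair falls in.
    """
    orientation = ORIENTATION_4 if orientation is None else orientation
    by_source = {e.source: e for e in evidence}
    missing = [s for s in sources if s not in by_source]
    if missing:
        raise ValueError(f"missing evidence source(s): {', '.join(missing)}")

    component_z: dict[str, float] = {}
    oriented = np.empty(len(sources))
    for i, s in enumerate(sources):
        z = signed_z(by_source[s].p, by_source[s].direction)
        component_z[s] = z
        oriented[i] = orientation[s] * z

    Z, p = stouffer_combine(oriented, weights)
    return PairMetaResult(
        mirna_id=mirna_id,
        gene_id=gene_id,
        component_z=component_z,
        combined_Z=Z,
        p=p,
        pattern=_classify_pattern(oriented),
    )


def bh_adjust(ps: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(ps, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_q(results: Sequence[PairMetaResult]) -> list[PairMetaResult]:
    """Fill in BH q-values across a collection of pair results (in place)."""
    if not results:
        return list(results)
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return list(results)


def declare_significant(
    results: Sequence[PairMetaResult], fdr_threshold: float = 0.10
) -> list[PairMetaResult]:
    """Pairs with q < threshold, sorted by p then (mirna_id, gene_id)."""
    hits = [r for r in results if r.q < fdr_threshold]
    hits.sort(key=lambda r: (r.p, r.mirna_id, r.gene_id))
    return hits


def results_frame(results: Sequence[PairMetaResult]) -> pd.DataFrame:
    """Flatten pair results to a table (one row per pair)."""
    rows = []
    for r in results:
        row = {"mirna_id": r.mirna_id, "gene_id": r.gene_id}
        for s, z in r.component_z.items():
            row[f"z_{s}"] = z
        row.update(combined_Z=r.combined_Z, p=r.p, q=r.q, pattern=r.pattern)
        rows.append(row)
    return pd.DataFrame(rows)
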