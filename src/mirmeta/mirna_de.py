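"""miRNA differential expression from small count-based strain studies.

Counts from each study (features x samples, two parental strains ILS/ISS at
n = 3 replicates each in the designs this emulates) are filtered on counts
per million, normalised by the per-sample upper quartile, and tested for a
strain effect with a negative-binomial quasi-likelihood F-test comparing the
strain model to an intercept-only model.

The quasi-likelihood framework treats the NB variance function mu + phi*mu^2
as known up to a multiplicative quasi-dispersion estimated from the
full-model deviance, so the test statistic

    F = (D_null - D_full) / (D_full / (n - 2))

is referred to an F(1, n - 2) distribution.  This absorbs over- or
under-dispersion relative to the working NB model, which matters at the tiny
replicate numbers typical of small-RNA strain comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

DISPERSION_FLOOR = 1e-8
DISPERSION_CAP = 1e3


@dataclass
class CountMatrix:
    """Integer count matrix with per-sample strain and study labels."""

    feature_ids: list[str]
    sample_ids: list[str]
    strain: list[str]
    study: str
    counts: np.ndarray  # features x samples, non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match feature/sample ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.strain) != len(self.sample_ids):
            raise ValueError("strain labels must match sample ids")

    def subset(self, feature_ids) -> "CountMatrix":
        idx = [self.feature_ids.index(f) for f in feature_ids]
        return CountMatrix(
            feature_ids=list(feature_ids),
            sample_ids=list(self.sample_ids),
            strain=list(self.strain),
            study=self.study,
            counts=self.counts[idx, :],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class DEResult:
    """Per-feature strain-effect test result.

    ``log_fc`` is the natural-log ISS-over-ILS effect; ``direction`` its sign.
    """

    feature_id: str
    log_fc: float
    direction: int
    statistic: float
    p: float
    q: float = np.nan
    degenerate: bool = False


def cpm(counts: CountMatrix) -> np.ndarray:
    """Counts per million: each column rescaled to sum to 1e6."""
    totals = counts.counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"sample(s) with zero total count: "
            f"{', '.join(counts.sample_ids[j] for j in zero)}"
        )
    return counts.counts / totals * 1e6


def filter_expressed(
    counts_by_study: list[CountMatrix],
    min_cpm: float = 1.0,
    min_samples: int = 3,
) -> set[str]:
    """Features with CPM strictly > min_cpm in >= min_samples samples in EVERY study.

    Feature universes are joined by intersection before filtering, so a
    feature absent from any study cannot pass.
    """
    if not counts_by_study:
        raise ValueError("at least one study required")
    common = set(counts_by_study[0].feature_ids)
    for cm in counts_by_study[1:]:
        common &= set(cm.feature_ids)
    keep = common
    for cm in counts_by_study:
        x = cpm(cm)
        idx = {f: i for i, f in enumerate(cm.feature_ids)}
        n_pass = (x > min_cpm).sum(axis=1)
        keep = {f for f in keep if n_pass[idx[f]] >= min_samples}
    return keep


def uq_factors(counts: CountMatrix) -> np.ndarray:
    """Per-sample 75th percentile of raw counts (linear-interpolation percentile)."""
    q = np.percentile(counts.counts, 75, axis=0, method="linear")
    zero = np.flatnonzero(q == 0)
    if zero.size:
        raise ValueError(
            f"zero 75th percentile in sample(s): "
            f"{', '.join(counts.sample_ids[j] for j in zero)}"
        )
    return q


def normalize_uq_log(counts: CountMatrix, pseudocount: float = 1.0) -> np.ndarray:
    """Upper-quartile-scaled, natural-log-transformed counts.

    entry(i, j) = ln(counts(i, j) / Q75(j) + pseudocount).  The pseudocount is
    added after scaling, which keeps the transform invariant to rescaling all
    counts in a sample and avoids ln(0).
    """
    q = uq_factors(counts)
    return np.log(counts.counts / q + pseudocount)


# ---------------------------------------------------------------------------
# NB fitting.  With a two-level factor the design is group-saturated, so each
# group's fitted mean solves a one-dimensional score equation
#   sum_j (y_j - s_j * m) / (1 + phi * s_j * m) = 0
# in the mean-per-unit-offset m = exp(beta); no IRLS needed.


def _nb_group_mean(y: np.ndarray, s: np.ndarray, phi: float) -> float:
    """MLE of the per-unit-offset mean for NB(mu = s*m, var = mu + phi*mu^2)."""
    if np.all(y == 0):
        return 0.0
    if phi < 1e-12:
        return float(y.sum() / s.sum())

    def score(m: float) -> float:
        mu = s * m
        return float(np.sum((y - mu) / (1.0 + phi * mu)))

    lo = max(y.sum() / s.sum() * 1e-6, 1e-12)
    hi = y.sum() / s.sum() * 1e6 + 1.0
    # score is decreasing in m; bracket then solve
    if score(lo) <= 0:
        return lo
    return float(optimize.brentq(score, lo, hi, xtol=1e-12, rtol=1e-12))


def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """Negative-binomial deviance (mean-dispersion form, var = mu + phi*mu^2)."""
    mu = np.maximum(mu, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    if phi < 1e-12:
        # Poisson limit
        return float(2.0 * np.sum(term1 - (y - mu)))
    a = 1.0 / phi
    term2 = (y + a) * np.log((1.0 + phi * y) / (1.0 + phi * mu))
    return float(2.0 * np.sum(term1 - term2))


def _moment_dispersion(y: np.ndarray, s: np.ndarray, groups: np.ndarray) -> float:
    """Method-of-moments NB dispersion from the group-saturated Poisson fit.

    phi_hat = sum((y - mu)^2 - mu) / sum(mu^2) with mu the Poisson group fit,
    clipped into [DISPERSION_FLOOR, DISPERSION_CAP].
    """
    mu = np.empty_like(y, dtype=float)
    for g in np.unique(groups):
        m = groups == g
        mu[m] = s[m] * (y[m].sum() / s[m].sum())
    denom = np.sum(mu**2)
    if denom == 0:
        return DISPERSION_FLOOR
    phi = np.sum((y - mu) ** 2 - mu) / denom
    return float(np.clip(phi, DISPERSION_FLOOR, DISPERSION_CAP))


def ql_strain_test(
    counts: CountMatrix,
    filtered_ids: set[str] | None = None,
    ref_strain: str = "ILS",
) -> list[DEResult]:
    """Per-feature NB quasi-likelihood F-test of a strain effect.

    For each feature a negative-binomial log-linear model with the per-sample
    upper-quartile scaling factor as offset is fitted twice: with a strain
    effect (group-saturated) and intercept-only.  The quasi-dispersion is the
    full-model deviance over its residual df (n - 2); the statistic
    (D_null - D_full) / quasi-dispersion is referred to F(1, n - 2).

    ``log_fc`` is ln(mean_ISS / mean_ILS) when ref_strain is "ILS".
    """
    strains = np.asarray(counts.strain)
    levels = np.unique(strains)
    if levels.size != 2:
        raise ValueError(f"expected exactly two strain levels, got {list(levels)}")
    other = [g for g in levels if g != ref_strain]
    if len(other) != 1:
        raise ValueError(f"reference strain {ref_strain!r} not present")
    alt_strain = other[0]
    for g in levels:
        if (strains == g).sum() < 2:
            raise ValueError(f"need >= 2 samples per strain, strain {g!r} has fewer")

    s = uq_factors(counts)
    n = len(counts.sample_ids)
    df_den = n - 2
    if df_den < 1:
        raise ValueError("need at least 3 samples for the quasi-likelihood F-test")
    is_ref = strains == ref_strain

    order = counts.feature_ids if filtered_ids is None else [
        f for f in counts.feature_ids if f in filtered_ids
    ]
    idx = {f: i for i, f in enumerate(counts.feature_ids)}

    results: list[DEResult] = []
    for fid in order:
        y = counts.counts[idx[fid]].astype(float)
        if np.all(y == 0):
            results.append(DEResult(fid, 0.0, 0, 0.0, 1.0, degenerate=True))
            continue
        phi = _moment_dispersion(y, s, is_ref)
        m_ref = _nb_group_mean(y[is_ref], s[is_ref], phi)
        m_alt = _nb_group_mean(y[~is_ref], s[~is_ref], phi)
        m_all = _nb_group_mean(y, s, phi)
        mu_full = np.where(is_ref, s * m_ref, s * m_alt)
        d_full = _nb_deviance(y, mu_full, phi)
        d_null = _nb_deviance(y, s * m_all, phi)
        if m_ref <= 0 or m_alt <= 0:
            # one strain entirely zero: effect direction defined, scale not
            log_fc = np.inf if m_ref <= 0 else -np.inf
            direction = int(np.sign(log_fc))
        else:
            log_fc = float(np.log(m_alt / m_ref))
            direction = int(np.sign(log_fc))
        qdisp = d_full / df_den
        if qdisp <= 0 or not np.isfinite(qdisp):
            results.append(
                DEResult(fid, 0.0 if not np.isfinite(log_fc) else log_fc,
                         direction, 0.0, 1.0, degenerate=True)
            )
            continue
        f_stat = max(d_null - d_full, 0.0) / qdisp
        p = float(stats.f.sf(f_stat, 1, df_den))
        results.append(DEResult(fid, log_fc, direction, f_stat, p))

    from .meta import bh_adjust

    qs = bh_adjust([r.p for r in results]) if results else []
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


def de_frame(results: list[DEResult]) -> pd.DataFrame:
    """Tabulate DE results; pct_of_ILS = 100 * exp(log_fc)."""
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "log_fc": [r.log_fc for r in results],
            "pct_of_ILS": [100.0 * np.exp(r.log_fc) for r in results],
            "direction": [r.direction for r in results],
            "statistic": [r.statistic for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )
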