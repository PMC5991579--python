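"""mRNA association analyses: parental-strain DE and phenotype correlation.

Two independent lines of evidence per gene:

* a two-group moderated t-test between the parental strains (ILS vs ISS) on
  log-scale expression, with empirical-Bayes variance shrinkage in the style
  of Smyth (2004): gene-wise residual variances s_g^2 on d df are shrunk
  toward a prior s_0^2 with d_0 prior df, giving moderated variances
  (d_0 s_0^2 + d s_g^2) / (d_0 + d) and t-statistics on d_0 + d df;

* a Spearman rank correlation between panel strain-mean expression and the
  strain-level phenotype (LORR minutes), parental strains excluded.  The
  correlation p is exact (full permutation enumeration) for small panels
  (n <= 8) and uses the usual t-approximation on n - 2 df otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .meta import bh_adjust
from .mirna_de import DEResult

EXACT_SPEARMAN_MAX_N = 8


@dataclass
class ExpressionTable:
    """Continuous log-scale expression matrix with per-sample strain labels."""

    gene_ids: list[str]
    sample_ids: list[str]
    strain: list[str]
    values: np.ndarray  # genes x samples

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match gene/sample ids")
        if len(self.strain) != len(self.sample_ids):
            raise ValueError("strain labels must match sample ids")
        if any(s is None or s == "" for s in self.strain):
            raise ValueError("missing strain labels")


@dataclass
class PhenotypeTable:
    """Strain-level phenotype: LORR duration in minutes (non-negative)."""

    strain: list[str]
    lorr_minutes: np.ndarray

    def __post_init__(self) -> None:
        self.lorr_minutes = np.asarray(self.lorr_minutes, dtype=float)
        if len(set(self.strain)) != len(self.strain):
            raise ValueError("one row per strain required")
        if np.any(self.lorr_minutes < 0):
            raise ValueError("LORR must be non-negative")


@dataclass
class CorrelationResult:
    gene_id: str
    rho: float
    n: int
    p: float
    q: float = np.nan
    direction: int = 0
    degenerate: bool = False


def strain_means(
    expr: ExpressionTable, exclude: set[str] = frozenset()
) -> pd.DataFrame:
    """Per-gene arithmetic mean over samples of each retained strain."""
    keep = [s for s in dict.fromkeys(expr.strain) if s not in exclude]
    if not keep:
        raise ValueError("no strains left after exclusion")
    strains = np.asarray(expr.strain)
    cols = {s: expr.values[:, strains == s].mean(axis=1) for s in keep}
    return pd.DataFrame(cols, index=expr.gene_ids)


# -- empirical-Bayes variance shrinkage -------------------------------------


def fit_f_dist_moments(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match s_g^2 ~ s_0^2 F(d, d_0): estimate (d_0, s_0^2).

    Works on e_g = ln s_g^2; under the scaled-F model
      E[e] = ln s_0^2 + psi(d/2) - ln(d/2) - (psi(d_0/2) - ln(d_0/2))
      Var[e] = psi'(d/2) + psi'(d_0/2),
    so d_0 solves psi'(d_0/2) = Var_hat[e] - psi'(d/2) (trigamma inversion by
    Newton steps), and s_0^2 follows from the mean equation.  Returns
    d_0 = inf when the excess variance is non-positive (no evidence of
    gene-to-gene variance heterogeneity beyond chi-square noise).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive gene variances")
    e = np.log(s2[ok])
    e_mean = e.mean()
    # unbiased-ish sample variance of e
    e_var = e.var(ddof=1)
    target = e_var - special.polygamma(1, df / 2.0)
    if target <= 0:
        # no excess spread in the gene variances: infinite prior df, and the
        # prior term psi(d0/2) - ln(d0/2) vanishes in the mean equation
        s0_2 = float(np.exp(e_mean - special.digamma(df / 2.0) + np.log(df / 2.0)))
        return np.inf, s0_2
    # invert trigamma: solve polygamma(1, x) = target for x = d0/2 by Newton
    # steps on 1/polygamma(1, .), which is nearly linear
    x = 0.5 + 1.0 / target
    for _ in range(60):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / target) / special.polygamma(2, x)
        x = x + step
        if abs(step) < 1e-10 * x:
            break
    d0 = 2.0 * x
    s0_2 = float(
        np.exp(
            e_mean
            - special.digamma(df / 2.0)
            + np.log(df / 2.0)
            + special.digamma(d0 / 2.0)
            - np.log(d0 / 2.0)
        )
    )
    return float(d0), s0_2


def moderated_de(
    expr: ExpressionTable,
    strain_a: str = "ILS",
    strain_b: str = "ISS",
    d0_override: float | None = None,
) -> list[DEResult]:
    """Gene-wise moderated t-test of strain_b minus strain_a expression.

    ``d0_override`` forces the prior df (0 recovers the ordinary t-test;
    numpy.inf replaces every gene's variance by the prior).
    """
    strains = np.asarray(expr.strain)
    a = expr.values[:, strains == strain_a]
    b = expr.values[:, strains == strain_b]
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per parental strain")
    df = n1 + n2 - 2
    if df < 1:
        raise ValueError("zero residual degrees of freedom")

    effect = b.mean(axis=1) - a.mean(axis=1)  # ISS minus ILS on log scale
    ss = a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df
    se_factor = np.sqrt(1.0 / n1 + 1.0 / n2)

    if d0_override is not None:
        d0 = float(d0_override)
        if d0 > 0:
            _, s0_2 = fit_f_dist_moments(s2, df)
        else:
            s0_2 = 0.0
    else:
        d0, s0_2 = fit_f_dist_moments(s2, df)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = d0 + df

    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / (np.sqrt(s2_post) * se_factor)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isnan(t), 1.0, p)

    results = [
        DEResult(
            feature_id=g,
            log_fc=float(effect[i]),
            direction=int(np.sign(effect[i])),
            statistic=float(t[i]) if np.isfinite(t[i]) else 0.0,
            p=float(p[i]),
            degenerate=bool(np.isnan(t[i])),
        )
        for i, g in enumerate(expr.gene_ids)
    ]
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


# -- phenotype correlation ---------------------------------------------------


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho with average ranks (Pearson correlation of ranks)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    if denom == 0:
        return np.nan
    return float(np.sum(rx * ry) / denom)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by enumerating all n! orderings of y against x."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    ry_sorted = np.sort(ry)
    sx2 = np.sum(rx_c**2)
    count = 0
    total = 0
    thresh = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(ry_sorted):
        ryp = np.asarray(perm) - ry.mean()
        denom = np.sqrt(sx2 * np.sum(ryp**2))
        rho = np.sum(rx_c * ryp) / denom
        if abs(rho) >= thresh:
            count += 1
        total += 1
    return count / total


def spearman_test(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float, bool]:
    """Spearman rho and two-sided p; exact enumeration when n <= 8.

    Returns (rho, n, p, degenerate).  Constant input gives rho = nan, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    rho = _spearman_rho(x, y)
    if np.isnan(rho):
        return np.nan, n, 1.0, True
    if n <= EXACT_SPEARMAN_MAX_N:
        return rho, n, _exact_spearman_p(x, y, rho), False
    if abs(rho) >= 1.0:
        return rho, n, 0.0, False
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return rho, n, float(2.0 * stats.t.sf(abs(t), n - 2)), False


def lorr_correlation(
    means: pd.DataFrame, pheno: PhenotypeTable
) -> list[CorrelationResult]:
    """Spearman correlation of gene strain-mean expression with LORR.

    Strains are joined by label; at least 4 common strains required.
    """
    pheno_map = dict(zip(pheno.strain, pheno.lorr_minutes))
    common = [s for s in means.columns if s in pheno_map]
    if len(common) < 4:
        raise ValueError(
            f"need >= 4 strains common to expression and phenotype, got {len(common)}"
        )
    y = np.array([pheno_map[s] for s in common])
    sub = means[common]
    results = []
    for gene, row in zip(sub.index, sub.to_numpy()):
        rho, n, p, degen = spearman_test(row, y)
        results.append(
            CorrelationResult(
                gene_id=gene,
                rho=rho,
                n=n,
                p=p,
                direction=0 if np.isnan(rho) else int(np.sign(rho)) or 0,
                degenerate=degen,
            )
        )
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


def correlation_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "rho": [r.rho for r in results],
            "n": [r.n for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )
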