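"""Synthetic data generator for the integrative miRNA-mRNA pipeline.

Emulates the full input surface of the analysis: two small negative-binomial
miRNA count studies (two parental strains, three replicates each), a
log-scale mRNA expression table covering the two parental strains plus a
recombinant-inbred panel, a strain-level phenotype (ethanol-induced loss of
righting reflex, LORR, in minutes), a multi-database miRNA-target snapshot,
and BED interval files for miRNA loci and QTL regions.

Planted signal pairs follow the repression-concordant configuration that
dominates real inbred-strain data: miRNA up in the short-sleep strain (ISS),
target mRNA up in the long-sleep strain (ILS), and mRNA expression
positively correlated with LORR across the panel.  The phenotype
correlation is planted through a Gaussian copula: for a target Spearman
correlation rho_s, the latent Pearson correlation is 2*sin(pi*rho_s/6), so
the panel strain means hit the requested rank correlation in expectation.

All randomness flows from a single seed; identical config + seed gives
bit-identical output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genomics import GenomicInterval
from .mirna_de import CountMatrix
from .mrna_assoc import ExpressionTable, PhenotypeTable


class ConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass
class SimConfig:
    n_mirna: int = 100
    n_gene: int = 500
    n_signal_pairs: int = 10
    replicates_per_strain_per_study: int = 3
    n_panel_strains: int = 60
    mirna_fc_signal: float = 2.0       # ISS/ILS mean ratio for signal miRNAs
    mrna_effect_signal: float = -0.5   # ISS minus ILS log-scale shift
    lorr_corr_signal: float = 0.4      # target Spearman magnitude, [0, 1)
    nb_dispersion: float = 0.05        # var = mu + phi mu^2
    library_size_range: tuple[float, float] = (2_000_000.0, 7_000_000.0)
    n_pred_db: int = 8
    n_db_pairs: int = 4000             # rows in the simulated target-DB snapshot
    n_parental_mrna_reps: int = 3
    mrna_resid_sd: float = 0.25
    seed: int = 0

    def validate(self) -> "SimConfig":
        for f in ("n_mirna", "n_gene", "replicates_per_strain_per_study",
                  "n_panel_strains", "n_pred_db", "n_db_pairs",
                  "n_parental_mrna_reps"):
            if getattr(self, f) <= 0:
                raise ConfigError(f"{f} must be positive")
        if self.n_signal_pairs < 0:
            raise ConfigError("n_signal_pairs must be >= 0")
        if self.n_signal_pairs > min(self.n_mirna, self.n_gene):
            raise ConfigError("n_signal_pairs must be <= n_mirna and <= n_gene")
        if self.mirna_fc_signal <= 0:
            raise ConfigError("mirna_fc_signal must be a positive ratio")
        if not (0.0 <= abs(self.lorr_corr_signal) < 1.0):
            raise ConfigError("lorr_corr_signal magnitude must lie in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ConfigError("library_size_range must be an increasing positive pair")
        if self.mrna_resid_sd <= 0:
            raise ConfigError("mrna_resid_sd must be positive")
        return self


@dataclass
class SimBundle:
    counts_study1: CountMatrix
    counts_study2: CountMatrix
    panel_expression: ExpressionTable
    phenotype: PhenotypeTable
    target_db: pd.DataFrame
    mirna_loci: list[GenomicInterval]
    qtl_regions: list[GenomicInterval]
    truth: pd.DataFrame
    config: SimConfig = field(repr=False, default=None)


STUDIES = ("saline", "naive")
GENOME_CHROMS = [f"chr{i}" for i in range(1, 20)]
CHROM_LEN = 100_000_000


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mu, var = mu + phi mu^2) via the gamma-Poisson mixture."""
    if phi < 1e-12:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
    return rng.poisson(lam)


def _simulate_counts(
    rng: np.random.Generator, cfg: SimConfig, study: str,
    mirna_ids: list[str], base_prop: np.ndarray, signal_mask: np.ndarray,
) -> CountMatrix:
    reps = cfg.replicates_per_strain_per_study
    strains = ["ILS"] * reps + ["ISS"] * reps
    sample_ids = [f"{s}_{study}_{i + 1}" for i, s in enumerate(strains)]
    lo, hi = cfg.library_size_range
    libs = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(strains)))
    # split the fold change symmetrically so signal features keep their
    # overall abundance: ILS gets fc^-1/2, ISS gets fc^+1/2
    half = np.sqrt(cfg.mirna_fc_signal)
    fc = np.ones((len(mirna_ids), len(strains)))
    iss = np.asarray(strains) == "ISS"
    fc[np.ix_(signal_mask, iss)] = half
    fc[np.ix_(signal_mask, ~iss)] = 1.0 / half
    mean = base_prop[:, None] * libs[None, :] * fc
    counts = _nb_draw(rng, mean, cfg.nb_dispersion)
    return CountMatrix(
        feature_ids=list(mirna_ids), sample_ids=sample_ids,
        strain=strains, study=study, counts=counts,
    )


def simulate(config: SimConfig) -> SimBundle:
    """Generate a complete, internally consistent input bundle."""
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)

    mirna_ids = [f"sim-miR-{i + 1:04d}" for i in range(cfg.n_mirna)]
    gene_ids = [f"Gene{i + 1:04d}" for i in range(cfg.n_gene)]
    signal_mirna = np.zeros(cfg.n_mirna, dtype=bool)
    signal_mirna[: cfg.n_signal_pairs] = True
    signal_gene = np.zeros(cfg.n_gene, dtype=bool)
    signal_gene[: cfg.n_signal_pairs] = True

    # relative miRNA abundances: heavy-tailed, like real small-RNA libraries
    w = np.exp(rng.normal(0.0, 1.5, size=cfg.n_mirna))
    base_prop = w / w.sum()

    counts1 = _simulate_counts(rng, cfg, STUDIES[0], mirna_ids, base_prop, signal_mirna)
    counts2 = _simulate_counts(rng, cfg, STUDIES[1], mirna_ids, base_prop, signal_mirna)

    # --- phenotype and panel expression (Gaussian copula for the rank corr)
    panel = [f"LXS{i + 1:03d}" for i in range(cfg.n_panel_strains)]
    z = rng.normal(size=cfg.n_panel_strains)
    lorr = np.maximum(0.0, 60.0 + 15.0 * z)
    # parental phenotype: ILS long-sleep, ISS short-sleep
    pheno = PhenotypeTable(
        strain=panel + ["ILS", "ISS"],
        lorr_minutes=np.concatenate([lorr, [110.0, 10.0]]),
    )

    rho_s = float(cfg.lorr_corr_signal)
    rho_pearson = 2.0 * np.sin(np.pi * rho_s / 6.0)
    gene_base = rng.normal(8.0, 1.0, size=cfg.n_gene)
    spread = 0.5  # strain-to-strain biological spread on the log scale

    eps = rng.normal(size=(cfg.n_gene, cfg.n_panel_strains))
    panel_vals = gene_base[:, None] + spread * eps
    if cfg.n_signal_pairs:
        sig = np.flatnonzero(signal_gene)
        panel_vals[sig, :] = gene_base[sig, None] + spread * (
            rho_pearson * z[None, :]
            + np.sqrt(1.0 - rho_pearson**2) * eps[sig, :]
        )

    # parental samples: strain shift for signal genes, iid residual noise
    reps = cfg.n_parental_mrna_reps
    par_strains = ["ILS"] * reps + ["ISS"] * reps
    par_vals = np.tile(gene_base[:, None], (1, 2 * reps)) + rng.normal(
        0.0, cfg.mrna_resid_sd, size=(cfg.n_gene, 2 * reps)
    )
    iss_cols = np.asarray(par_strains) == "ISS"
    par_vals[np.ix_(signal_gene, iss_cols)] += cfg.mrna_effect_signal

    sample_ids = [f"{s}_{i + 1}" for i, s in enumerate(par_strains)] + [
        f"{s}_1" for s in panel
    ]
    expr = ExpressionTable(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        strain=par_strains + panel,
        values=np.hstack([par_vals, panel_vals]),
    )

    # --- target-DB snapshot
    target_db, truth = _simulate_target_db(
        rng, cfg, mirna_ids, gene_ids, signal_mirna, signal_gene
    )

    # --- genomic intervals
    mirna_loci = []
    for mid in mirna_ids:
        chrom = GENOME_CHROMS[rng.integers(len(GENOME_CHROMS))]
        start = int(rng.integers(0, CHROM_LEN - 200))
        mirna_loci.append(GenomicInterval(chrom, start, start + 100, mid))
    qtl_regions = []
    for k in range(6):
        chrom = GENOME_CHROMS[rng.integers(len(GENOME_CHROMS))]
        start = int(rng.integers(0, CHROM_LEN - 10_000_000))
        qtl_regions.append(
            GenomicInterval(chrom, start, start + 10_000_000, f"LORR_QTL_{k + 1}")
        )

    return SimBundle(
        counts_study1=counts1,
        counts_study2=counts2,
        panel_expression=expr,
        phenotype=pheno,
        target_db=target_db,
        mirna_loci=mirna_loci,
        qtl_regions=qtl_regions,
        truth=truth,
        config=cfg,
    )


def _simulate_target_db(rng, cfg, mirna_ids, gene_ids, signal_mirna, signal_gene):
    n_planted = cfg.n_signal_pairs
    planted = [(mirna_ids[i], gene_ids[i]) for i in range(n_planted)]

    rows = []
    for k, (m, g) in enumerate(planted):
        if k % 2 == 0:  # alternate evidence class so both paths are exercised
            v, p = 1 + int(rng.integers(0, 3)), int(rng.integers(0, cfg.n_pred_db + 1))
        else:
            v, p = 0, 5 + int(rng.integers(0, cfg.n_pred_db - 4))
        rows.append((m, g, v, p, True))

    # null pairs: skewed predicted-support distribution so the 5-of-8 filter
    # removes a realistic majority; a minority carry validation evidence.
    # Pairs are drawn without replacement from the miRNA x gene universe
    # (capped at its size), excluding the planted diagonal.
    universe = cfg.n_mirna * cfg.n_gene
    n_null = min(max(cfg.n_db_pairs - n_planted, 0), universe - n_planted)
    flat_planted = np.array([i * cfg.n_gene + i for i in range(n_planted)], dtype=np.int64)
    avail = np.setdiff1d(np.arange(universe, dtype=np.int64), flat_planted)
    chosen = rng.choice(avail, size=n_null, replace=False)
    has_validation = rng.random(n_null) < 0.30
    v_null = np.where(has_validation, 1 + rng.integers(0, 2, n_null), 0)
    p_null = np.clip(rng.geometric(0.45, n_null) - 1, 0, cfg.n_pred_db)
    for flat, v, p in zip(chosen, v_null, p_null):
        rows.append((mirna_ids[flat // cfg.n_gene], gene_ids[flat % cfg.n_gene],
                     int(v), int(p), False))

    db = pd.DataFrame(
        rows, columns=["mirna_id", "gene_id", "validated_db_count",
                       "predicted_db_count", "planted"],
    )
    # per-database boolean flags consistent with the counts
    for j in range(cfg.n_pred_db):
        db[f"pred_db_{j + 1}"] = db["predicted_db_count"] > j
    db["val_db_1"] = db["validated_db_count"] > 0

    truth = pd.DataFrame(
        {
            "mirna_id": [m for m, _ in planted],
            "gene_id": [g for _, g in planted],
            "mirna_direction": 1,            # up in ISS
            "mrna_direction": int(np.sign(cfg.mrna_effect_signal)) or 0,
            "corr_sign": int(np.sign(cfg.lorr_corr_signal)) or 0,
        }
    )
    return db, truth


# --- persistence ------------------------------------------------------------


def _counts_tsv(cm: CountMatrix) -> pd.DataFrame:
    return pd.DataFrame(cm.counts, index=pd.Index(cm.feature_ids, name="feature_id"),
                        columns=cm.sample_ids)


def write_bundle(bundle: SimBundle, directory: str | Path) -> dict:
    """Write the bundle as TSV/BED files; returns a manifest with checksums."""
    d = Path(directory)
    try:
        d.mkdir(parents=True, exist_ok=True)
        probe = d / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"directory {d} is not writable: {exc}") from exc

    files: dict[str, Path] = {}

    def _write(name: str, writer) -> None:
        path = d / name
        writer(path)
        files[name] = path

    _write("counts_saline.tsv",
           lambda p: _counts_tsv(bundle.counts_study1).to_csv(p, sep="\t"))
    _write("counts_naive.tsv",
           lambda p: _counts_tsv(bundle.counts_study2).to_csv(p, sep="\t"))
    expr = bundle.panel_expression
    _write("expression.tsv", lambda p: pd.DataFrame(
        expr.values, index=pd.Index(expr.gene_ids, name="gene_id"),
        columns=expr.sample_ids).to_csv(p, sep="\t"))
    _write("phenotype.tsv", lambda p: pd.DataFrame(
        {"strain": bundle.phenotype.strain,
         "lorr_minutes": bundle.phenotype.lorr_minutes}).to_csv(p, sep="\t", index=False))
    _write("target_db.tsv", lambda p: bundle.target_db.to_csv(p, sep="\t", index=False))
    _write("truth.tsv", lambda p: bundle.truth.to_csv(p, sep="\t", index=False))

    def _bed(path: Path, intervals) -> None:
        with open(path, "w") as fh:
            for iv in intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")

    _write("mirna_loci.bed", lambda p: _bed(p, bundle.mirna_loci))
    _write("qtl_regions.bed", lambda p: _bed(p, bundle.qtl_regions))

    manifest = {
        "config": asdict(bundle.config) if bundle.config else None,
        "files": {
            name: {
                "path": str(path),
                "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
            }
            for name, path in files.items()
        },
    }
    with open(d / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
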