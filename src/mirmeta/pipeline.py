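"""End-to-end orchestration of the integrative miRNA-mRNA meta-analysis.

Stage order: CPM filter -> per-study miRNA DE -> two-study miRNA meta ->
parental-strain mRNA DE -> panel phenotype correlation -> target-pair
filtering -> per-pair integrative meta -> BH FDR -> network summaries and
QTL-interval overlap.  The in-memory entry point is :func:`integrate`;
:func:`run` adds file IO around it for the command-line interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genomics import GenomicInterval, annotate_overlaps, read_bed
from .io import read_counts, read_expression, read_phenotype, read_target_db
from .meta import (
    PairMetaResult,
    SignedEvidence,
    attach_q,
    combine_two_sided,
    declare_significant,
    pair_meta,
    results_frame,
    bh_adjust,
)
from .mirna_de import CountMatrix, DEResult, de_frame, filter_expressed, ql_strain_test
from .mrna_assoc import (
    CorrelationResult,
    ExpressionTable,
    PhenotypeTable,
    correlation_frame,
    lorr_correlation,
    moderated_de,
    strain_means,
)
from .network import build_network, degree_summary, edge_list_frame, find_hubs, write_graphml
from .target_pairs import CandidatePair, filter_pairs, pairs_frame, restrict_to_measured

PARENTAL_STRAINS = {"ILS", "ISS"}

SOURCES_3 = ("mirna_meta", "mrna_de", "lorr_corr")
ORIENTATION_3 = {"mirna_meta": +1.0, "mrna_de": -1.0, "lorr_corr": +1.0}


@dataclass
class Thresholds:
    min_cpm: float = 1.0
    min_samples: int = 3
    predicted_min: int = 5
    validated_min: int = 1
    fdr_pairs: float = 0.10
    fdr_top: float = 0.05
    hub_min_degree: int = 5
    meta_sources: int = 4  # 4 = the two miRNA studies enter separately


@dataclass
class IntegrationResult:
    filtered_mirnas: set[str]
    mirna_de: dict[str, list[DEResult]]      # study -> results
    mirna_meta: pd.DataFrame
    mrna_de: list[DEResult]
    correlation: list[CorrelationResult]
    candidate_pairs: list[CandidatePair]
    pair_results: list[PairMetaResult]
    significant: list[PairMetaResult]
    top: list[PairMetaResult]
    network: object
    degree: dict
    hubs: list[str]
    overlap_hits: pd.DataFrame = field(default=None)


def _dir(d: int) -> int:
    """Coerce a possibly-zero effect sign to a valid evidence direction."""
    return d if d in (-1, 1) else 1


def mirna_meta_table(
    de_by_study: dict[str, list[DEResult]], feature_order: list[str]
) -> pd.DataFrame:
    """Two-study signed Stouffer meta-analysis per miRNA."""
    studies = list(de_by_study)
    maps = {s: {r.feature_id: r for r in de_by_study[s]} for s in studies}
    rows = []
    for fid in feature_order:
        rs = [maps[s][fid] for s in studies if fid in maps[s]]
        if len(rs) != len(studies):
            continue
        Z, p = combine_two_sided([r.p for r in rs], [_dir(r.direction) for r in rs])
        row = {"feature_id": fid}
        for s, r in zip(studies, rs):
            row[f"p_{s}"] = r.p
            row[f"direction_{s}"] = r.direction
            row[f"pct_of_ILS_{s}"] = 100.0 * np.exp(r.log_fc)
        row.update(combined_Z=Z, p=p)
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = bh_adjust(df["p"].to_numpy())
    return df


def integrate(
    counts_saline: CountMatrix,
    counts_naive: CountMatrix,
    expression: ExpressionTable,
    phenotype: PhenotypeTable,
    target_db: pd.DataFrame,
    thresholds: Thresholds | None = None,
    mirna_loci: list[GenomicInterval] | None = None,
    qtl_regions: list[GenomicInterval] | None = None,
) -> IntegrationResult:
    """Run the full integrative analysis in memory."""
    th = thresholds or Thresholds()

    # 1. expression filter, applied independently in both studies
    filtered = filter_expressed(
        [counts_saline, counts_naive], min_cpm=th.min_cpm, min_samples=th.min_samples
    )

    # 2. per-study strain tests + 3. two-study meta
    de_by_study = {
        counts_saline.study: ql_strain_test(counts_saline, filtered),
        counts_naive.study: ql_strain_test(counts_naive, filtered),
    }
    order = [f for f in counts_saline.feature_ids if f in filtered]
    meta_tbl = mirna_meta_table(de_by_study, order)

    # 4. parental-strain mRNA DE and 5. panel phenotype correlation
    mrna_results = moderated_de(expression)
    means = strain_means(expression, exclude=PARENTAL_STRAINS)
    corr_results = lorr_correlation(means, phenotype)

    # 6. candidate pairs from the database snapshot
    cand = filter_pairs(
        target_db, validated_min=th.validated_min, predicted_min=th.predicted_min
    )
    cand = restrict_to_measured(cand, filtered, set(expression.gene_ids))

    # 7. per-pair integrative meta
    de_maps = {s: {r.feature_id: r for r in rs} for s, rs in de_by_study.items()}
    mrna_map = {r.feature_id: r for r in mrna_results}
    corr_map = {r.gene_id: r for r in corr_results}
    meta_map = (
        {row.feature_id: row for row in meta_tbl.itertuples(index=False)}
        if not meta_tbl.empty else {}
    )

    pair_results: list[PairMetaResult] = []
    for cp in cand:
        if cp.gene_id not in corr_map or cp.gene_id not in mrna_map:
            continue
        mr = mrna_map[cp.gene_id]
        cr = corr_map[cp.gene_id]
        if th.meta_sources == 4:
            ev = [
                SignedEvidence("saline_mirna_de",
                               de_maps[counts_saline.study][cp.mirna_id].p,
                               _dir(de_maps[counts_saline.study][cp.mirna_id].direction)),
                SignedEvidence("naive_mirna_de",
                               de_maps[counts_naive.study][cp.mirna_id].p,
                               _dir(de_maps[counts_naive.study][cp.mirna_id].direction)),
                SignedEvidence("mrna_de", mr.p, _dir(mr.direction)),
                SignedEvidence("lorr_corr", cr.p, _dir(cr.direction)),
            ]
            res = pair_meta(cp.mirna_id, cp.gene_id, ev)
        elif th.meta_sources == 3:
            m = meta_map.get(cp.mirna_id)
            if m is None:
                continue
            ev = [
                SignedEvidence("mirna_meta", m.p, _dir(int(np.sign(m.combined_Z)))),
                SignedEvidence("mrna_de", mr.p, _dir(mr.direction)),
                SignedEvidence("lorr_corr", cr.p, _dir(cr.direction)),
            ]
            res = pair_meta(cp.mirna_id, cp.gene_id, ev,
                            sources=SOURCES_3, orientation=ORIENTATION_3)
        else:
            raise ValueError("meta_sources must be 3 or 4")
        pair_results.append(res)

    # 8. FDR + significance calls
    attach_q(pair_results)
    significant = declare_significant(pair_results, th.fdr_pairs)
    top = declare_significant(pair_results, th.fdr_top)

    # 9. network summaries
    mirna_ann = _mirna_annotations(de_by_study)
    gene_ann = _gene_annotations(mrna_map, corr_map, {p.gene_id for p in significant})
    net = build_network(significant, mirna_ann, gene_ann)
    deg = degree_summary(net)
    hubs = find_hubs(net, th.hub_min_degree)

    # 10. optional miRNA-locus vs QTL-interval overlap
    hits = None
    if mirna_loci is not None and qtl_regions is not None:
        sig_mirnas = {p.mirna_id for p in significant}
        loci = [iv for iv in mirna_loci if iv.name in sig_mirnas]
        hits = annotate_overlaps(loci, qtl_regions)

    return IntegrationResult(
        filtered_mirnas=filtered,
        mirna_de=de_by_study,
        mirna_meta=meta_tbl,
        mrna_de=mrna_results,
        correlation=corr_results,
        candidate_pairs=cand,
        pair_results=pair_results,
        significant=significant,
        top=top,
        network=net,
        degree=deg,
        hubs=hubs,
        overlap_hits=hits,
    )


def _mirna_annotations(de_by_study):
    ann = {}
    for rs in de_by_study.values():
        for r in rs:
            a = ann.setdefault(r.feature_id, {"direction": 0, "mean_abs_log_fc": 0.0, "_n": 0})
            if np.isfinite(r.log_fc):
                a["mean_abs_log_fc"] += abs(r.log_fc)
            a["direction"] += r.direction
            a["_n"] += 1
    for a in ann.values():
        n = a.pop("_n")
        a["mean_abs_log_fc"] /= max(n, 1)
        a["direction"] = int(np.sign(a["direction"]))
    return ann


def _gene_annotations(mrna_map, corr_map, genes):
    ann = {}
    for g in genes:
        a = {}
        if g in mrna_map:
            a["direction"] = mrna_map[g].direction
            a["abs_log_fc"] = abs(mrna_map[g].log_fc) if np.isfinite(mrna_map[g].log_fc) else 0.0
        if g in corr_map and not np.isnan(corr_map[g].rho):
            a["corr_sign"] = int(np.sign(corr_map[g].rho))
        ann[g] = a
    return ann


# --- file-based runner ------------------------------------------------------


@dataclass
class PipelineConfig:
    counts_saline: str
    counts_naive: str
    expression: str
    phenotype: str
    target_db: str
    mirna_loci: str | None = None
    qtl_regions: str | None = None
    out_dir: str = "results"
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        th = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=th, **raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run(config: PipelineConfig) -> dict:
    """Load inputs, run :func:`integrate`, write all stage tables.

    Returns a manifest of written artifacts.  Deterministic: identical
    config + inputs give identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise StageError(name, exc) from exc

    cs = _stage("load_counts_saline", lambda: read_counts(config.counts_saline, "saline"))
    cn = _stage("load_counts_naive", lambda: read_counts(config.counts_naive, "naive"))
    expr = _stage("load_expression", lambda: read_expression(config.expression))
    pheno = _stage("load_phenotype", lambda: read_phenotype(config.phenotype))
    tdb = _stage("load_target_db", lambda: read_target_db(config.target_db))
    loci = regions = None
    if config.mirna_loci and config.qtl_regions:
        loci = _stage("load_mirna_loci", lambda: read_bed(config.mirna_loci))
        regions = _stage("load_qtl_regions", lambda: read_bed(config.qtl_regions))

    res = _stage("integrate", lambda: integrate(
        cs, cn, expr, pheno, tdb,
        thresholds=config.thresholds, mirna_loci=loci, qtl_regions=regions,
    ))

    artifacts = {}

    def _save(name, df):
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        artifacts[name] = str(path)

    _save("filtered_mirnas.tsv", pd.DataFrame({"feature_id": sorted(res.filtered_mirnas)}))
    for study, rs in res.mirna_de.items():
        _save(f"mirna_de_{study}.tsv", de_frame(rs))
    _save("mirna_meta.tsv", res.mirna_meta)
    _save("mrna_de.tsv", de_frame(res.mrna_de))
    _save("lorr_correlation.tsv", correlation_frame(res.correlation))
    _save("candidate_pairs.tsv", pairs_frame(res.candidate_pairs))
    _save("pair_meta.tsv", results_frame(res.pair_results))
    _save("significant_pairs.tsv", results_frame(res.significant))
    _save("top_pairs.tsv", results_frame(res.top))
    _save("network_edges.tsv", edge_list_frame(res.network))
    _save("hubs.tsv", pd.DataFrame({"mirna_id": res.hubs,
                                    "degree": [res.network.degree(h) for h in res.hubs]}))
    if res.overlap_hits is not None:
        _save("qtl_overlap.tsv", res.overlap_hits)
    write_graphml(res.network, out / "network.graphml")
    artifacts["network.graphml"] = str(out / "network.graphml")

    log = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": vars(config.thresholds),
        "inputs": {
            k: getattr(config, k)
            for k in ("counts_saline", "counts_naive", "expression",
                      "phenotype", "target_db", "mirna_loci", "qtl_regions")
        },
        "summary": {
            "n_filtered_mirnas": len(res.filtered_mirnas),
            "n_candidate_pairs": len(res.candidate_pairs),
            "n_significant_pairs": len(res.significant),
            "n_top_pairs": len(res.top),
            "hubs": res.hubs,
            "max_mirna_degree": res.degree["max_mirna_degree"],
            "max_gene_degree": res.degree["max_gene_degree"],
        },
        "artifacts": artifacts,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    artifacts["run_log.json"] = str(out / "run_log.json")
    return log
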