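"""Bipartite miRNA-mRNA network over significant pairs.

Nodes are miRNAs and genes; an edge is a significant pair, weighted by
-log10(combined p) so stronger pairs draw heavier edges.  Hubs are miRNAs
connected to at least five target mRNAs.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .meta import PairMetaResult

EDGE_WEIGHT_CAP = 300.0


def build_network(
    sig_pairs: list[PairMetaResult],
    mirna_annotations: dict[str, dict] | None = None,
    gene_annotations: dict[str, dict] | None = None,
) -> nx.Graph:
    """Bipartite graph: one node per unique id, one edge per pair."""
    mirna_annotations = mirna_annotations or {}
    gene_annotations = gene_annotations or {}
    g = nx.Graph()
    seen = set()
    for r in sig_pairs:
        key = (r.mirna_id, r.gene_id)
        if key in seen:
            raise ValueError(f"duplicate pair {key}")
        seen.add(key)
        for node, part, anns in (
            (r.mirna_id, "mirna", mirna_annotations),
            (r.gene_id, "gene", gene_annotations),
        ):
            if node not in g:
                attrs = anns.get(node)
                if attrs is None and anns:
                    warnings.warn(f"no annotation for node {node!r}; using defaults")
                g.add_node(node, bipartite=part, **(attrs or {}))
        weight = min(-np.log10(max(r.p, 10.0**-EDGE_WEIGHT_CAP)), EDGE_WEIGHT_CAP)
        g.add_edge(
            r.mirna_id,
            r.gene_id,
            weight=float(weight),
            p=float(r.p),
            q=float(r.q),
            pattern=r.pattern,
        )
    return g


def degree_summary(g: nx.Graph) -> dict:
    """Per-node degrees plus per-partition maxima and node counts."""
    mirnas = [n for n, d in g.nodes(data=True) if d.get("bipartite") == "mirna"]
    genes = [n for n, d in g.nodes(data=True) if d.get("bipartite") == "gene"]
    deg = dict(g.degree())
    return {
        "degree": deg,
        "n_mirna": len(mirnas),
        "n_gene": len(genes),
        "n_edges": g.number_of_edges(),
        "max_mirna_degree": max((deg[n] for n in mirnas), default=0),
        "max_gene_degree": max((deg[n] for n in genes), default=0),
    }


def find_hubs(g: nx.Graph, min_degree: int = 5) -> list[str]:
    """miRNA nodes with degree >= min_degree, sorted by degree descending."""
    mirnas = [n for n, d in g.nodes(data=True) if d.get("bipartite") == "mirna"]
    hubs = [n for n in mirnas if g.degree(n) >= min_degree]
    hubs.sort(key=lambda n: (-g.degree(n), n))
    return hubs


def edge_list_frame(g: nx.Graph) -> pd.DataFrame:
    rows = []
    for u, v, d in g.edges(data=True):
        if g.nodes[u].get("bipartite") == "mirna":
            mirna, gene = u, v
        else:
            mirna, gene = v, u
        rows.append(
            {"mirna_id": mirna, "gene_id": gene, "weight": d["weight"],
             "p": d["p"], "q": d["q"], "pattern": d["pattern"]}
        )
    return pd.DataFrame(rows)


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)
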