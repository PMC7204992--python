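"""Network topology, the RNs prioritization score, and consensus targets.

The composite score for a gene with SVM-RFE relevance Rs, degree K and
average shortest-path length L is

    RNs = L · Rs / K,

which rewards genes the classifier finds informative while down-weighting
hubs (large K) and favouring peripheral genes (large L) — the opposite of
hub-centric target selection. Topology is computed on the unweighted
interaction graph: edge confidences act only as a construction threshold,
never as path lengths. L, closeness and betweenness are restricted to a
node's connected component so unreachable pairs never enter the averages.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParameterError, PipelineError
from .io import PPINetwork

logger = logging.getLogger(__name__)


def topology(net: PPINetwork) -> pd.DataFrame:
    """Per-node degree K, average path length L, betweenness BC, closeness CC.

    * K — number of incident edges.
    * L — mean unweighted shortest-path distance to the other nodes of the
      node's connected component.
    * BC — sum over unordered pairs (i, j) within the component, both
      distinct from v, of the fraction of i–j shortest paths through v
      (unnormalized).
    * CC — (reachable − 1) / Σ distances, i.e. the reciprocal of L.
    """
    G = net.graph
    if G.number_of_nodes() == 0:
        raise PipelineError("cannot compute topology of an empty network")
    rows = {}
    bc = nx.betweenness_centrality(G, normalized=False)
    for v in G.nodes:
        dist = nx.single_source_shortest_path_length(G, v)
        del dist[v]
        total = sum(dist.values())
        reachable = len(dist)
        L = total / reachable  # reachable >= 1: isolates are excluded upstream
        rows[v] = {"K": G.degree[v], "L": L, "BC": bc[v], "CC": reachable / total}
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "gene_id"
    table["K"] = table["K"].astype(int)
    return table


def rns(topology_table: pd.DataFrame, rs: dict[str, float]) -> pd.Series:
    """RNs = L·Rs/K over genes present in both the network and the ranking.

    Genes on only one side are omitted (count logged); an empty
    intersection aborts the pipeline.
    """
    common = sorted(set(topology_table.index) & set(rs))
    if not common:
        raise PipelineError("no genes shared between topology table and Rs scores")
    dropped = (len(topology_table) - len(common)) + (len(rs) - len(common))
    if dropped:
        logger.info("%d gene(s) outside the topology∩Rs intersection omitted", dropped)
    sub = topology_table.loc[common]
    rs_vec = np.array([rs[g] for g in common])
    values = sub["L"].to_numpy() * rs_vec / sub["K"].to_numpy()
    out = pd.Series(values, index=pd.Index(common, name="gene_id"), name="RNs")
    return out


def top_k_genes(table: pd.Series, k: int) -> list[str]:
    """Top-k genes by RNs descending, ties broken by gene id."""
    if k > len(table):
        logger.warning("top_k=%d exceeds table size %d; using all genes", k, len(table))
        k = len(table)
    order = sorted(table.items(), key=lambda kv: (-kv[1], kv[0]))
    return [g for g, _ in order[:k]]


def consensus(
    tables: list[pd.Series],
    top_k: int = 20,
    min_datasets: int = 2,
    dataset_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Cross-dataset consensus of per-dataset top-k RNs lists.

    A gene's support is the number of datasets whose top-k list contains
    it; genes with support ≥ min_datasets are flagged ``selected``. Rows
    are sorted by (support desc, mean RNs over supporting datasets desc,
    gene id).
    """
    if min_datasets > len(tables):
        raise ParameterError(
            f"min_datasets={min_datasets} exceeds number of tables ({len(tables)})"
        )
    if min_datasets < 1:
        raise ParameterError("min_datasets must be >= 1")
    tops = [top_k_genes(t, top_k) for t in tables]
    support: dict[str, int] = {}
    sums: dict[str, float] = {}
    for table, top in zip(tables, tops):
        for g in top:
            support[g] = support.get(g, 0) + 1
            sums[g] = sums.get(g, 0.0) + float(table[g])
    rows = pd.DataFrame(
        {
            "support": pd.Series(support),
            "mean_rns": pd.Series({g: sums[g] / support[g] for g in support}),
        }
    )
    rows.index.name = "gene_id"
    rows["selected"] = rows["support"] >= min_datasets
    rows = rows.reset_index()
    rows = rows.sort_values(
        by=["support", "mean_rns", "gene_id"], ascending=[False, False, True],
        kind="stable",
    ).set_index("gene_id")
    return rows
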