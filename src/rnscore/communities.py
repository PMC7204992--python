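"""Functional module detection: edge-betweenness communities + semantic filter.

Communities are found with the Girvan–Newman procedure: repeatedly remove
the edge of highest edge-betweenness, tracking the modularity Q of the
resulting component partition, and keep the partition of maximal Q. The
retained modules are then refined functionally: edges whose two endpoint
genes have ontology-based semantic similarity below a threshold are
dropped, components are re-extracted and small fragments discarded — so a
surviving module is both topologically and functionally coherent.

Semantic similarity follows the Wang graph-based method: each annotated
term contributes S-values that decay up the term DAG by a per-relation
weight (is_a 0.8, part_of 0.6); two terms are compared by their shared
ancestors' S-values, and two genes by the best-match average over their
annotation sets. A plain Jaccard overlap of annotation sets is available
as a fallback method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx

from .errors import ParameterError, PipelineError, ValidationError
from .io import PPINetwork

RELATION_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


# ---------------------------------------------------------------------------
# Term DAG and Wang similarity
# ---------------------------------------------------------------------------


@dataclass
class TermDAG:
    """Ontology fragment: child→parent edges plus gene→term annotations."""

    parents: dict[str, list[tuple[str, str]]]  # term → [(parent, relation)]
    annotations: dict[str, frozenset[str]]  # gene → annotated terms

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for child, plist in self.parents.items():
            for parent, relation in plist:
                if relation not in RELATION_WEIGHTS:
                    raise ValidationError(f"unknown relation {relation!r}")
                g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            raise ValidationError("term graph contains a cycle")
        known = set(g.nodes)
        for gene, terms in self.annotations.items():
            unknown = terms - known
            if unknown:
                raise ValidationError(
                    f"gene {gene!r} annotated with unknown terms {sorted(unknown)}"
                )

    def s_values(self, term: str) -> dict[str, float]:
        """Wang S-values of ``term``'s ancestors: S(term)=1, decaying upward."""
        return dict(self._s_values_cached(term))

    @lru_cache(maxsize=None)  # noqa: B019 - DAG instances are effectively frozen
    def _s_values_cached(self, term: str) -> tuple[tuple[str, float], ...]:
        s = {term: 1.0}
        frontier = [term]
        while frontier:
            nxt = []
            for t in frontier:
                for parent, relation in self.parents.get(t, ()):
                    cand = RELATION_WEIGHTS[relation] * s[t]
                    if cand > s.get(parent, 0.0):
                        s[parent] = cand
                        nxt.append(parent)
            frontier = nxt
        return tuple(sorted(s.items()))

    def __hash__(self) -> int:  # identity hash: one DAG object, many queries
        return id(self)

    def __eq__(self, other: object) -> bool:
        return self is other


def term_similarity(term_a: str, term_b: str, dag: TermDAG) -> float:
    """Wang similarity of two terms via their shared ancestors' S-values."""
    sa, sb = dag.s_values(term_a), dag.s_values(term_b)
    common = set(sa) & set(sb)
    if not common:
        return 0.0
    num = sum(sa[t] + sb[t] for t in common)
    return num / (sum(sa.values()) + sum(sb.values()))


def semantic_similarity(
    gene_a: str, gene_b: str, dag: TermDAG, method: str = "wang"
) -> float | None:
    """Functional similarity of two genes' annotation sets in [0, 1].

    ``method="wang"`` aggregates Wang term similarities by best-match
    average; ``method="jaccard"`` is |A∩B| / |A∪B| on the raw sets.
    Returns ``None`` when either gene is unannotated — no evidence rather
    than zero similarity.
    """
    ta = dag.annotations.get(gene_a)
    tb = dag.annotations.get(gene_b)
    if not ta or not tb:
        return None
    if method == "jaccard":
        return len(ta & tb) / len(ta | tb)
    if method != "wang":
        raise ParameterError(f"unknown similarity method {method!r}")
    ta_l, tb_l = sorted(ta), sorted(tb)
    sims = [[term_similarity(x, y, dag) for y in tb_l] for x in ta_l]
    best_a = [max(row) for row in sims]
    best_b = [max(sims[i][j] for i in range(len(ta_l))) for j in range(len(tb_l))]
    return (sum(best_a) + sum(best_b)) / (len(ta_l) + len(tb_l))


# ---------------------------------------------------------------------------
# Girvan–Newman communities
# ---------------------------------------------------------------------------


@dataclass
class ModulePartition:
    """Disjoint gene modules with the modularity of the retained partition."""

    modules: list[frozenset[str]]
    modularity: float
    edge_similarity: dict[tuple[str, str], float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.modules:
            if m & seen:
                raise ValidationError("modules must be disjoint")
            seen |= m


def _best_edge(G: nx.Graph) -> tuple[str, str]:
    """Edge of maximal betweenness; ties by lexicographic endpoint pair."""
    eb = nx.edge_betweenness_centrality(G, normalized=False)
    best = None
    best_key = None
    for (u, v), val in eb.items():
        pair = (u, v) if u <= v else (v, u)
        key = (-val, pair)
        if best_key is None or key < best_key:
            best_key = key
            best = pair
    return best


def girvan_newman(net: PPINetwork) -> ModulePartition:
    """Edge-betweenness divisive clustering, keeping the max-modularity level.

    The dendrogram level reached after each edge removal (including the
    initial partition into connected components) is scored by Newman–Girvan
    modularity on the original graph; the first partition attaining the
    maximum Q is returned.
    """
    G0 = net.graph
    if G0.number_of_nodes() == 0:
        raise PipelineError("cannot detect communities in an empty network")
    work = G0.copy()
    best_partition = [frozenset(c) for c in nx.connected_components(work)]
    best_q = nx.community.modularity(G0, best_partition)
    while work.number_of_edges() > 0:
        u, v = _best_edge(work)
        work.remove_edge(u, v)
        partition = [frozenset(c) for c in nx.connected_components(work)]
        q = nx.community.modularity(G0, partition)
        if q > best_q + 1e-12:
            best_q = q
            best_partition = partition
    best_partition = sorted(best_partition, key=lambda m: sorted(m))
    return ModulePartition(modules=best_partition, modularity=best_q)


def detect_modules(
    net: PPINetwork,
    dag: TermDAG | None,
    sim_threshold: float = 0.5,
    min_size: int = 3,
    method: str = "wang",
) -> ModulePartition:
    """Topological modules refined by functional similarity.

    Girvan–Newman communities are computed first; inside each community,
    edges whose endpoint similarity is below ``sim_threshold`` are removed
    (edges without annotation evidence are kept), connected components are
    re-extracted, and components smaller than ``min_size`` are discarded.
    ``dag=None`` skips the functional filter entirely.
    """
    partition = girvan_newman(net)
    edge_sim: dict[tuple[str, str], float | None] = {}
    modules: list[frozenset[str]] = []
    for module in partition.modules:
        sub = net.graph.subgraph(module).copy()
        if dag is not None:
            for u, v in list(sub.edges):
                pair = (u, v) if u <= v else (v, u)
                sim = semantic_similarity(u, v, dag, method=method)
                edge_sim[pair] = sim
                if sim is not None and sim < sim_threshold:
                    sub.remove_edge(u, v)
        for comp in nx.connected_components(sub):
            if len(comp) >= min_size:
                modules.append(frozenset(comp))
    modules = sorted(modules, key=lambda m: sorted(m))
    return ModulePartition(
        modules=modules, modularity=partition.modularity, edge_similarity=edge_sim
    )


# ---------------------------------------------------------------------------
# DAG / annotation readers (two-TSV convention)
# ---------------------------------------------------------------------------


def read_term_dag(terms_path, annotations_path) -> TermDAG:
    """Read (child, parent, relation) and (gene, term) TSVs into a TermDAG."""
    import csv

    parents: dict[str, list[tuple[str, str]]] = {}
    with open(terms_path, encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "child":
                continue
            child, parent, relation = row[0], row[1], row[2] if len(row) > 2 else "is_a"
            parents.setdefault(child, []).append((parent, relation))
            parents.setdefault(parent, [])
    annotations: dict[str, set[str]] = {}
    with open(annotations_path, encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "gene":
                continue
            annotations.setdefault(row[0], set()).add(row[1])
    return TermDAG(
        parents=parents,
        annotations={g: frozenset(t) for g, t in annotations.items()},
    )
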