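"""Seeded generators for every input the pipeline consumes.

The generators emulate the study design the pipeline is built for: several
independent case/control microarray datasets sharing a planted set of
differentially expressed genes, of which a small subset are "disease
genes" distinguished by their network topology; a scale-free background
interactome in which the DEGs form a denser perturbed-pathway core and
the disease genes attach to that core with moderate degree (2–5,
peripheral but connected — the regime the RNs score rewards); clinical
follow-up with expression-linked exponential hazards and right
censoring; a toy ontology annotating the planted genes coherently; and
idealized Cα polymer chains for elastic-network analysis.

Every generator is a pure function of its parameters and seed:
regenerating with the same arguments is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParameterError
from .communities import TermDAG
from .io import ExpressionDataset, PPINetwork, StructureModel, SurvivalTable

#: tumor/normal sample sizes of the three emulated microarray datasets
DEFAULT_DATASET_SIZES = ((36, 36), (45, 45), (14, 8))


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def synth_expression(
    n_genes: int = 1000,
    n_tumor: int = 40,
    n_normal: int = 40,
    n_deg: int = 40,
    effect_sd: float = 3.0,
    seed: int = 0,
    dataset_id: str = "synth",
    deg_genes: Sequence[str] | None = None,
    effects: dict[str, float] | None = None,
) -> tuple[ExpressionDataset, frozenset[str]]:
    """One log2-scale case/control dataset with a planted DEG subset.

    Baseline per-gene means are Normal(7, 1.5) with residual SD 1 on the
    log2 scale; planted DEGs get a tumor-mean shift of ±effect_sd residual
    SDs, half up and half down. ``deg_genes`` pins the planted subset
    (so several datasets can share it); otherwise it is drawn at random.
    ``effects`` overrides the shift magnitude for individual planted genes
    (e.g. to give a disease-gene subset a stronger signal than the rest
    of the DEGs).
    """
    if min(n_genes, n_tumor, n_normal) <= 0 or n_deg < 0:
        raise ParameterError("sizes must be positive (n_deg may be zero)")
    if n_deg > n_genes:
        raise ParameterError("n_deg cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    if deg_genes is None:
        planted = sorted(map(str, rng.choice(genes, size=n_deg, replace=False)))
    else:
        planted = sorted(deg_genes)
        if not set(planted) <= set(genes):
            raise ParameterError("deg_genes must be a subset of the gene universe")
    base_mean = rng.normal(7.0, 1.5, size=n_genes)
    n_samples = n_tumor + n_normal
    values = base_mean[:, None] + rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    gene_pos = {g: i for i, g in enumerate(genes)}
    effects = effects or {}
    for j, g in enumerate(planted):
        sign = 1.0 if j < (len(planted) + 1) // 2 else -1.0
        values[gene_pos[g], :n_tumor] += sign * effects.get(g, effect_sd)
    samples = [f"T{i:03d}" for i in range(n_tumor)] + [
        f"N{i:03d}" for i in range(n_normal)
    ]
    groups = pd.Series(
        ["tumor"] * n_tumor + ["normal"] * n_normal, index=samples, name="group"
    )
    dataset = ExpressionDataset(
        dataset_id=dataset_id,
        values=pd.DataFrame(values, index=genes, columns=samples),
        groups=groups,
    )
    return dataset, frozenset(planted)


def synth_network(
    genes: Sequence[str],
    planted_targets: Sequence[str] = (),
    m_attach: int = 3,
    seed: int = 0,
    core_genes: Sequence[str] | None = None,
    core_m: int = 3,
) -> pd.DataFrame:
    """Scale-free interactome over ``genes`` with low-degree planted targets.

    A preferential-attachment (Barabási–Albert, ``m_attach`` edges per
    node) background graph is built over all non-target genes, so hubs
    exist. ``core_genes`` (minus the targets) additionally get a denser
    preferential-attachment subnetwork among themselves, emulating a
    perturbed pathway whose members interact; each planted target then
    attaches to 2–5 uniformly chosen core genes and to nothing else, so
    its total degree is moderate and its neighborhood peripheral.
    Edge confidences are Uniform(0.9, 1.0).

    Returns an edge list DataFrame (proteinA, proteinB, combined_score).
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    targets = sorted(set(planted_targets))
    if not set(targets) <= set(genes):
        raise ParameterError("planted_targets must be a subset of genes")
    background = sorted(set(genes) - set(targets))
    if len(background) <= m_attach:
        raise ParameterError("too few non-target genes for preferential attachment")
    ba_seed = int(rng.integers(0, 2**31 - 1))
    ba = nx.barabasi_albert_graph(len(background), m_attach, seed=ba_seed)
    order = rng.permutation(len(background))
    label = {i: background[order[i]] for i in range(len(background))}
    G = nx.relabel_nodes(ba, label)

    core = sorted(set(core_genes or ()) - set(targets))
    if len(core) > core_m + 1:
        core_seed = int(rng.integers(0, 2**31 - 1))
        sub = nx.barabasi_albert_graph(len(core), core_m, seed=core_seed)
        core_order = rng.permutation(len(core))
        core_label = {i: core[core_order[i]] for i in range(len(core))}
        G.add_edges_from(nx.relabel_nodes(sub, core_label).edges)

    attach_pool = core if core else background
    for t in targets:
        k = int(rng.integers(2, 6))
        k = min(k, len(attach_pool))
        partners = rng.choice(attach_pool, size=k, replace=False)
        G.add_edges_from((t, str(p)) for p in partners)

    rows = sorted((min(u, v), max(u, v)) for u, v in G.edges)
    conf = rng.uniform(0.9, 1.0, size=len(rows))
    return pd.DataFrame(
        {
            "proteinA": [r[0] for r in rows],
            "proteinB": [r[1] for r in rows],
            "combined_score": np.round(conf, 6),
        }
    )


def network_from_frame(edges: pd.DataFrame, min_confidence: float = 0.0) -> PPINetwork:
    """Build the in-memory PPINetwork for a generated edge list."""
    g = nx.Graph()
    for a, b, c in edges.itertuples(index=False):
        if a != b and c > min_confidence:
            g.add_edge(a, b, confidence=float(c))
    g.remove_nodes_from([n for n, d in g.degree if d == 0])
    return PPINetwork(g, min_confidence)


def synth_survival(
    n_patients: int = 176,
    prognostic_genes: Sequence[str] = (),
    hazard_ratio: float = 3.0,
    censor_frac: float = 0.3,
    seed: int = 0,
    null_genes: Sequence[str] = (),
) -> SurvivalTable:
    """Exponential survival with expression-linked hazards and censoring.

    Expression is standard normal per gene and patient. Each prognostic
    gene multiplies a patient's hazard by ``hazard_ratio`` when that
    patient's expression is above the gene's median (log-hazard linear in
    the high/low indicator). The baseline hazard gives the low group a
    500-day median survival. A fraction ``censor_frac`` of patients,
    chosen independently, is censored uniformly before its event time.
    """
    if not 0.0 <= censor_frac < 1.0:
        raise ParameterError("censor_frac must be in [0,1)")
    if hazard_ratio <= 0:
        raise ParameterError("hazard_ratio must be positive")
    rng = np.random.default_rng(seed)
    patients = [f"P{i:04d}" for i in range(n_patients)]
    genes = sorted(set(prognostic_genes) | set(null_genes))
    expr = {g: rng.normal(0.0, 1.0, size=n_patients) for g in genes}
    log_hazard = np.full(n_patients, np.log(np.log(2.0) / 500.0))
    for g in sorted(set(prognostic_genes)):
        high = expr[g] > np.median(expr[g])
        log_hazard = log_hazard + np.log(hazard_ratio) * high
    times = rng.exponential(1.0 / np.exp(log_hazard))
    events = np.ones(n_patients, dtype=int)
    censored = rng.random(n_patients) < censor_frac
    u = rng.random(n_patients)
    times = np.where(censored, np.maximum(times * u, 1e-6), times)
    events[censored] = 0
    data = pd.concat(
        [pd.DataFrame({"time": times, "event": events}, index=patients),
         pd.DataFrame(expr, index=patients)],
        axis=1,
    )
    data.index.name = "patient_id"
    return SurvivalTable(data)


def synth_structure(
    n_residues: int,
    topology: str = "helix",
    seed: int = 0,
    chain: str = "A",
) -> StructureModel:
    """Idealized Cα chain: α-helix, two-lobed dumbbell, or random coil.

    * ``helix`` — ideal geometry: 1.5 Å rise, 2.3 Å radius, 100°/residue.
    * ``dumbbell`` — two helical lobes bridged by a single linker residue
      placed on the helix axis, 5 Å from each lobe end; the lobes are far
      enough apart that the linker is the only inter-lobe contact region
      at the standard 7.3 Å cutoff.
    * ``coil`` — seeded random walk with 3.8 Å virtual bonds.
    """
    if n_residues < 2:
        raise ParameterError("need at least two residues")

    def helix_coords(n: int, x0: float = 0.0) -> np.ndarray:
        i = np.arange(n)
        theta = np.deg2rad(100.0) * i
        return np.column_stack(
            [x0 + 1.5 * i, 2.3 * np.cos(theta), 2.3 * np.sin(theta)]
        )

    if topology == "helix":
        coords = helix_coords(n_residues)
    elif topology == "dumbbell":
        m = (n_residues - 1) // 2
        m2 = n_residues - 1 - m
        lobe1 = helix_coords(m)
        linker_x = lobe1[-1, 0] + 5.0
        lobe2 = helix_coords(m2, x0=linker_x + 5.0)
        coords = np.vstack([lobe1, [[linker_x, 0.0, 0.0]], lobe2])
    elif topology == "coil":
        rng = np.random.default_rng(seed)
        steps = rng.normal(size=(n_residues - 1, 3))
        steps = 3.8 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
        coords = np.vstack([[0.0, 0.0, 0.0], np.cumsum(steps, axis=0)])
    else:
        raise ParameterError(f"unknown topology {topology!r}")
    return StructureModel(
        residue_ids=[(chain, i + 1) for i in range(n_residues)],
        coords=coords,
        residue_names=["ALA"] * n_residues,
    )


def dumbbell_linker_index(n_residues: int) -> int:
    """Residue index (0-based) of the dumbbell's linker residue."""
    return (n_residues - 1) // 2


def synth_term_dag(
    planted_groups: Sequence[Sequence[str]],
    other_genes: Sequence[str] = (),
    terms_per_gene: int = 2,
    seed: int = 0,
) -> TermDAG:
    """Toy ontology annotating each planted group coherently.

    One branch of leaf terms per group hangs under a shared root; genes of
    a group are annotated with leaves of their branch (high intra-group
    Wang similarity), while ``other_genes`` draw leaves uniformly from all
    branches (low, incoherent similarity).
    """
    rng = np.random.default_rng(seed)
    parents: dict[str, list[tuple[str, str]]] = {"ROOT": []}
    branch_leaves: list[list[str]] = []
    for b, group in enumerate(planted_groups):
        mid = f"B{b:02d}"
        parents[mid] = [("ROOT", "is_a")]
        leaves = []
        for l in range(max(3, terms_per_gene + 1)):
            leaf = f"B{b:02d}L{l:02d}"
            parents[leaf] = [(mid, "is_a")]
            leaves.append(leaf)
        branch_leaves.append(leaves)
    annotations: dict[str, frozenset[str]] = {}
    for b, group in enumerate(planted_groups):
        for g in group:
            terms = rng.choice(branch_leaves[b], size=terms_per_gene, replace=False)
            annotations[g] = frozenset(terms.tolist())
    all_leaves = [l for leaves in branch_leaves for l in leaves]
    for g in other_genes:
        if all_leaves:
            terms = rng.choice(all_leaves, size=min(terms_per_gene, len(all_leaves)),
                               replace=False)
            annotations[g] = frozenset(terms.tolist())
    return TermDAG(parents=parents, annotations=annotations)


@dataclass
class SyntheticStudy:
    """A full multi-dataset study with planted ground truth."""

    datasets: list[ExpressionDataset]
    edges: pd.DataFrame
    network: PPINetwork
    planted_degs: frozenset[str]
    planted_targets: frozenset[str]
    survival: SurvivalTable
    dag: TermDAG
    structures: dict[str, StructureModel]
    seed: int
    params: dict = field(default_factory=dict)


def synth_study(
    n_genes: int = 1000,
    n_deg: int = 40,
    n_targets: int = 8,
    effect_sd: float = 3.0,
    background_effect_sd: float = 2.0,
    dataset_sizes: Sequence[tuple[int, int]] = DEFAULT_DATASET_SIZES,
    m_attach: int = 3,
    n_patients: int = 176,
    hazard_ratio: float = 3.0,
    censor_frac: float = 0.3,
    structure_residues: int = 35,
    seed: int = 0,
) -> SyntheticStudy:
    """Generate every pipeline input with shared planted ground truth.

    The planted DEG set is common to all datasets; the planted disease
    genes are a subset of it, wired into the interactome with degree 2–5
    against the denser DEG core. Disease genes carry the full
    ``effect_sd`` expression shift while the remaining DEGs carry the
    weaker ``background_effect_sd`` (both comfortably past the DEG
    filter), so the classifier ranks disease genes highest — the signal
    regime the RNs score is designed for. Disease genes drive survival
    (``hazard_ratio`` high vs low) and receive a dumbbell test structure.
    """
    if n_targets > n_deg:
        raise ParameterError("n_targets cannot exceed n_deg")
    root = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    planted = sorted(map(str, root.choice(genes, size=n_deg, replace=False)))
    targets = sorted(map(str, root.choice(planted, size=n_targets, replace=False)))
    effects = {g: effect_sd if g in set(targets) else background_effect_sd
               for g in planted}

    datasets = []
    for d, (n_tumor, n_normal) in enumerate(dataset_sizes):
        ds, _ = synth_expression(
            n_genes=n_genes,
            n_tumor=n_tumor,
            n_normal=n_normal,
            n_deg=n_deg,
            effect_sd=effect_sd,
            seed=int(root.integers(0, 2**31 - 1)),
            dataset_id=f"SYN{d + 1:02d}",
            deg_genes=planted,
            effects=effects,
        )
        datasets.append(ds)

    edges = synth_network(
        genes,
        planted_targets=targets,
        m_attach=m_attach,
        seed=int(root.integers(0, 2**31 - 1)),
        core_genes=planted,
    )
    network = network_from_frame(edges, min_confidence=0.9)

    surv = synth_survival(
        n_patients=n_patients,
        prognostic_genes=targets,
        hazard_ratio=hazard_ratio,
        censor_frac=censor_frac,
        seed=int(root.integers(0, 2**31 - 1)),
        null_genes=sorted(set(planted) - set(targets)),
    )

    non_target_degs = sorted(set(planted) - set(targets))
    dag = synth_term_dag(
        planted_groups=[targets, non_target_degs],
        seed=int(root.integers(0, 2**31 - 1)),
    )

    structures = {
        t: synth_structure(structure_residues, "dumbbell",
                           seed=int(root.integers(0, 2**31 - 1)))
        for t in targets
    }
    return SyntheticStudy(
        datasets=datasets,
        edges=edges,
        network=network,
        planted_degs=frozenset(planted),
        planted_targets=frozenset(targets),
        survival=surv,
        dag=dag,
        structures=structures,
        seed=seed,
        params={
            "n_genes": n_genes,
            "n_deg": n_deg,
            "n_targets": n_targets,
            "effect_sd": effect_sd,
            "dataset_sizes": tuple(dataset_sizes),
            "m_attach": m_attach,
            "n_patients": n_patients,
            "hazard_ratio": hazard_ratio,
            "censor_frac": censor_frac,
        },
    )
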