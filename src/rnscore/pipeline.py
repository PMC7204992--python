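"""Stage orchestration: DEG → SVM-RFE → network/RNs → consensus → validation.

The pipeline mirrors the prioritization workflow: per-dataset
differential expression, SVM-RFE ranking of each dataset's DEGs, a shared
interaction network induced on the union of DEG sets, per-dataset RNs
scoring on that network, and a cross-dataset top-k consensus. Downstream
validation stages (modules, survival screen, enrichment, GNM) run on the
consensus targets when their inputs are configured. All hand-offs are
flat TSV files so every stage is inspectable and re-runnable standalone.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import communities, deg, enrichment, gnm, io, netscore, survival, svmrfe
from .errors import ParameterError, PipelineError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds and seeds of the pipeline, with their standard defaults."""

    p_thresh: float = 0.01  # DEG adjusted-p cutoff
    fc_thresh: float = 1.5  # DEG linear fold-change cutoff (symmetric)
    min_confidence: float = 0.9  # interaction confidence threshold
    top_k: int = 20  # per-dataset RNs short-list length
    min_datasets: int = 2  # consensus support requirement
    sim_threshold: float = 0.5  # semantic-similarity edge filter
    min_module_size: int = 3
    split_quantile: float = 0.5  # survival high/low split
    survival_p: float = 0.01  # prognostic-call threshold
    alpha: float = 0.05  # enrichment significance (BH-adjusted)
    gnm_cutoff: float = 7.3  # Å, GNM contact distance
    gnm_modes: int = 2
    shared_network: bool = True  # one network on the union of DEG sets
    seed: int = 0


def prioritize(
    datasets: list[io.ExpressionDataset],
    network: io.PPINetwork,
    config: PipelineConfig | None = None,
) -> dict:
    """Run the in-memory prioritization core and return all intermediates.

    Returns a dict with per-dataset DEG records and sets, rankings, the
    DEG-induced network, the topology table, per-dataset RNs tables and
    the consensus DataFrame.
    """
    config = config or PipelineConfig()
    if config.min_datasets > len(datasets):
        raise ParameterError(
            f"min_datasets={config.min_datasets} exceeds {len(datasets)} dataset(s)"
        )
    deg_records = {}
    deg_sets = {}
    for ds in datasets:
        records = deg.test_all_genes(ds)
        deg_records[ds.dataset_id] = records
        deg_sets[ds.dataset_id] = deg.filter_degs(
            records, p_thresh=config.p_thresh, fc_thresh=config.fc_thresh
        )

    union_degs = set().union(*deg_sets.values())
    if not union_degs:
        raise PipelineError("no DEGs passed the filter in any dataset")
    deg_net = network.subgraph(union_degs)
    if deg_net.graph.number_of_nodes() == 0:
        raise PipelineError("no DEG maps to the interaction network")
    topo = netscore.topology(deg_net)

    rankings = {}
    rns_tables = {}
    for ds in datasets:
        genes = deg_sets[ds.dataset_id] & set(ds.gene_ids)
        if config.shared_network:
            scorable = genes & set(topo.index)
        else:
            per_net = network.subgraph(genes)
            if per_net.graph.number_of_nodes() == 0:
                logger.warning("dataset %s: no DEG maps to the network", ds.dataset_id)
                continue
            topo = netscore.topology(per_net)
            scorable = genes & set(topo.index)
        if len(genes) < 2:
            logger.warning("dataset %s: fewer than 2 DEGs; skipped", ds.dataset_id)
            continue
        ranking = svmrfe.svm_rfe_rank(
            ds, genes, svmrfe.RFEConfig(seed=config.seed)
        )
        rankings[ds.dataset_id] = ranking
        rns_tables[ds.dataset_id] = netscore.rns(topo, ranking.rs)

    if len(rns_tables) < config.min_datasets:
        raise PipelineError(
            f"only {len(rns_tables)} dataset(s) produced RNs tables; "
            f"min_datasets={config.min_datasets}"
        )
    ids = sorted(rns_tables)
    cons = netscore.consensus(
        [rns_tables[i] for i in ids],
        top_k=config.top_k,
        min_datasets=config.min_datasets,
        dataset_ids=ids,
    )
    return {
        "deg_records": deg_records,
        "deg_sets": deg_sets,
        "network": deg_net,
        "topology": topo,
        "rankings": rankings,
        "rns_tables": rns_tables,
        "consensus": cons,
    }


def run_pipeline(
    matrices: list[tuple[str, str]],
    edges_path: str,
    out_dir: str,
    config: PipelineConfig | None = None,
    gmt_path: str | None = None,
    survival_path: str | None = None,
    dag_paths: tuple[str, str] | None = None,
    pdb_paths: list[str] | None = None,
) -> Path:
    """File-to-file pipeline: read inputs, run every configured stage.

    ``matrices`` is a list of (expression TSV, phenotype TSV) pairs. All
    stage outputs plus the resolved configuration are written under
    ``out_dir``; reruns with identical inputs and config are
    byte-identical.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    paths = [p for pair in matrices for p in pair] + [edges_path]
    paths += [p for p in (gmt_path, survival_path) if p]
    paths += list(dag_paths or ())
    paths += list(pdb_paths or ())
    missing = [p for p in paths if not Path(p).exists()]
    if missing:
        raise PipelineError(f"missing input file(s): {missing}")
    out.mkdir(parents=True, exist_ok=True)

    datasets = [
        io.read_expression(m, p, dataset_id=Path(m).stem) for m, p in matrices
    ]
    network = io.read_edge_list(edges_path, min_confidence=config.min_confidence)
    result = prioritize(datasets, network, config)

    for ds_id, records in result["deg_records"].items():
        io.write_table(deg.records_frame(records), out / f"deg_{ds_id}.tsv")
    for ds_id, ranking in result["rankings"].items():
        frame = pd.DataFrame(
            {"rank": pd.Series(ranking.ranks), "Rs": pd.Series(ranking.rs)}
        )
        frame.index.name = "gene_id"
        io.write_table(frame, out / f"ranks_{ds_id}.tsv")
    io.write_table(result["topology"], out / "topology.tsv")
    for ds_id, table in result["rns_tables"].items():
        io.write_table(table.to_frame(), out / f"rns_{ds_id}.tsv")
    # consensus rows keep their (support desc, mean RNs desc) ranking
    result["consensus"].to_csv(out / "targets.tsv", sep="\t")
    selected = sorted(result["consensus"].index[result["consensus"]["selected"]])

    if dag_paths:
        dag = communities.read_term_dag(*dag_paths)
        partition = communities.detect_modules(
            result["network"], dag,
            sim_threshold=config.sim_threshold, min_size=config.min_module_size,
        )
        rows = pd.DataFrame(
            [
                {"module": i + 1, "gene_id": g}
                for i, module in enumerate(partition.modules)
                for g in sorted(module)
            ]
        )
        if rows.empty:
            rows = pd.DataFrame(columns=["module", "gene_id"])
        rows.to_csv(out / "modules.tsv", sep="\t", index=False)
        (out / "modularity.txt").write_text(f"{partition.modularity:.6f}\n")

    if survival_path and selected:
        surv = io.read_survival(survival_path)
        present = [g for g in selected if g in surv.gene_ids]
        if present:
            screen = survival.survival_screen(
                present, surv,
                split_quantile=config.split_quantile, p_thresh=config.survival_p,
            )
            io.write_table(screen, out / "survival.tsv")

    if gmt_path and selected:
        sets = io.read_gmt(gmt_path)
        universe = result["network"].nodes
        in_universe = set(selected) & set(universe)
        if in_universe:
            table = enrichment.ora(in_universe, sets, universe, alpha=config.alpha)
            io.write_table(table, out / "enrichment.tsv", sort_by=None)

    for pdb_path in pdb_paths or ():
        structure = io.read_pdb_ca(pdb_path)
        res = gnm.gnm_analyze(structure, cutoff=config.gnm_cutoff)
        rows = []
        for mode in range(1, min(config.gnm_modes, res.n_nonzero) + 1):
            shape = res.squared_shape(mode)
            hinges = set(gnm.find_hinges(res, mode).hinges)
            for i, (chain, resnum) in enumerate(structure.residue_ids):
                rows.append(
                    {
                        "chain": chain,
                        "residue": resnum,
                        "mode": mode,
                        "shape": shape[i],
                        "hinge": int(i in hinges),
                    }
                )
        pd.DataFrame(rows).to_csv(
            out / f"gnm_{Path(pdb_path).stem}.tsv", sep="\t", index=False,
            float_format="%.8g",
        )

    (out / "config.yaml").write_text(yaml.safe_dump(asdict(config), sort_keys=True))
    return out
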