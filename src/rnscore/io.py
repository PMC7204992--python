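"""Readers and writers for the external formats the pipeline touches.

All downstream stages consume only the domain containers defined here:
:class:`ExpressionDataset` (log2 intensities with two-group labels),
:class:`PPINetwork` (confidence-thresholded undirected interactions),
:class:`SurvivalTable` (right-censored follow-up plus per-gene expression),
:class:`StructureModel` (Cα coordinates of one chain) and
:class:`GeneSetCollection` (GMT-style gene sets).

Everything is plain tab-delimited UTF-8 text; expression values are assumed
to be already normalized on the log2 scale, as typically distributed for
microarray series, and no normalization is applied here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

GROUP_LABELS = ("tumor", "normal")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """A single case/control expression study: genes × samples, log2 scale.

    Parameters
    ----------
    dataset_id
        Free-text identifier (e.g. a GEO-style accession).
    values
        DataFrame of finite log2 intensities, index = gene ids,
        columns = sample ids, both unique.
    groups
        Series mapping each sample id to ``"tumor"`` or ``"normal"``;
        each label must occur at least twice (the t-test needs two
        observations per group).
    """

    dataset_id: str
    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        if not list(self.groups.index) == list(self.values.columns):
            raise ValidationError("groups index must match sample columns")
        bad = set(self.groups) - set(GROUP_LABELS)
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            g, s = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                "non-finite expression value at "
                f"(gene={self.values.index[g]!r}, sample={self.values.columns[s]!r})"
            )
        counts = self.groups.value_counts()
        for label in GROUP_LABELS:
            if counts.get(label, 0) < 2:
                raise ValidationError(
                    f"group {label!r} has {counts.get(label, 0)} samples; need >= 2"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def group_matrix(self, label: str) -> np.ndarray:
        """Genes × samples sub-matrix for one group label."""
        cols = self.groups.index[self.groups == label]
        return self.values[cols].to_numpy(dtype=float)


@dataclass
class PPINetwork:
    """Simple undirected interaction graph with per-edge confidence in [0, 1].

    Invariants: no self-loops, no parallel edges, every confidence at or
    above the construction threshold, and no isolated nodes (genes without
    any retained interaction are excluded before scoring).
    """

    graph: nx.Graph
    min_confidence: float = 0.0

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValidationError("self-loops are not allowed")
        if any(d == 0 for _, d in self.graph.degree):
            raise ValidationError("isolated nodes are not allowed")
        for u, v, conf in self.graph.edges(data="confidence"):
            if conf is None or not 0.0 <= conf <= 1.0:
                raise ValidationError(f"edge ({u},{v}) confidence {conf} outside [0,1]")

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def subgraph(self, genes: Iterable[str]) -> "PPINetwork":
        """Induced subgraph on ``genes``, dropping nodes left isolated."""
        sub = self.graph.subgraph(set(genes)).copy()
        sub.remove_nodes_from([n for n, d in sub.degree if d == 0])
        return PPINetwork(sub, self.min_confidence)


@dataclass
class SurvivalTable:
    """Right-censored overall-survival records with per-gene expression.

    ``data`` is indexed by patient id with columns ``time`` (days, > 0),
    ``event`` (1 = death observed, 0 = censored) and one column per gene.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if "time" not in self.data.columns or "event" not in self.data.columns:
            raise FormatError("survival table needs 'time' and 'event' columns")
        if (self.data["time"] <= 0).any():
            raise ValidationError("survival times must be strictly positive")
        if not self.data["event"].isin((0, 1)).all():
            raise ValidationError("event flags must be 0 or 1")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("time", "event")]

    @property
    def times(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)


@dataclass
class StructureModel:
    """Cα trace of one (or more) chains: one coordinate triple per residue."""

    residue_ids: list[tuple[str, int]]
    coords: np.ndarray
    residue_names: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.residue_ids)
        if self.coords.shape != (n, 3):
            raise ValidationError(
                f"coords shape {self.coords.shape} does not match {n} residues"
            )
        if len(self.residue_names) != n:
            raise ValidationError("residue_names length mismatch")

    def __len__(self) -> int:
        return len(self.residue_ids)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): set id → (description, members)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_id, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {set_id!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def members(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_expression(
    matrix_path: str | Path,
    phenotype_path: str | Path,
    dataset_id: str | None = None,
) -> ExpressionDataset:
    """Read an expression matrix TSV plus a sample→group phenotype TSV.

    The matrix has a header row of sample ids and gene ids in the first
    column. The phenotype file has columns ``sample_id`` and ``group``.
    Samples present in the matrix but missing from the phenotype file are
    dropped with a warning; samples in the phenotype file but not in the
    matrix raise a format error.
    """
    matrix_path = Path(matrix_path)
    try:
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse expression matrix {matrix_path}: {exc}")
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()][0]
        raise FormatError(f"duplicate gene id in {matrix_path}: {dup!r}")
    # locate non-numeric cells before coercion so the error can name them
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & values.notna() | values.isna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric expression value at (gene={values.index[g]!r}, "
            f"sample={values.columns[s]!r}) in {matrix_path}"
        )
    values = numeric.astype(float)

    pheno = pd.read_csv(phenotype_path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(pheno.columns):
        raise FormatError(
            f"phenotype file {phenotype_path} needs columns sample_id, group"
        )
    groups = pd.Series(
        pheno["group"].to_numpy(), index=pheno["sample_id"].to_numpy(), name="group"
    )
    missing = [s for s in groups.index if s not in values.columns]
    if missing:
        raise FormatError(f"phenotype samples absent from matrix: {missing}")
    unlabelled = [s for s in values.columns if s not in groups.index]
    if unlabelled:
        logger.warning(
            "dropping %d sample(s) with no phenotype entry: %s",
            len(unlabelled),
            unlabelled,
        )
        values = values.drop(columns=unlabelled)
    groups = groups.reindex(values.columns)
    return ExpressionDataset(
        dataset_id=dataset_id or matrix_path.stem, values=values, groups=groups
    )


def read_edge_list(path: str | Path, min_confidence: float = 0.9) -> PPINetwork:
    """Read a STRING-style edge list and threshold on confidence.

    Columns ``proteinA, proteinB, combined_score``; scores may be in the
    STRING integer dialect (0–1000, divided by 1000) or already in [0, 1] —
    detected by whether any score exceeds 1. Edges with normalized
    confidence strictly greater than ``min_confidence`` are kept;
    self-loops are dropped, duplicate pairs collapsed keeping the maximum
    confidence, and nodes with no surviving edge are omitted.
    """
    if not 0.0 <= min_confidence < 1.0:
        raise ParameterError(f"min_confidence must be in [0,1), got {min_confidence}")
    rows: list[tuple[str, str, float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[:2] == ["proteinA", "proteinB"]:
                continue  # optional header
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                score = float(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed score {parts[2]!r}")
            rows.append((parts[0], parts[1], score))
    scores = np.array([r[2] for r in rows]) if rows else np.array([])
    milli = bool(scores.size) and float(scores.max()) > 1.0
    graph = nx.Graph()
    for a, b, score in rows:
        conf = score / 1000.0 if milli else score
        if not 0.0 <= conf <= 1.0:
            raise FormatError(f"confidence {conf} outside [0,1] for edge ({a},{b})")
        if a == b or conf <= min_confidence:
            continue
        if graph.has_edge(a, b):
            graph[a][b]["confidence"] = max(graph[a][b]["confidence"], conf)
        else:
            graph.add_edge(a, b, confidence=conf)
    return PPINetwork(graph, min_confidence)


def read_survival(path: str | Path) -> SurvivalTable:
    """Read a clinical TSV: patient_id, time, event, then one column per gene."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SurvivalTable(df)


def read_pdb_ca(path: str | Path, chain: str | None = None) -> StructureModel:
    """Extract the Cα trace of one chain from standard PDB ATOM records.

    ``chain=None`` selects the first chain encountered. Alternate locations
    are resolved by keeping, per residue, the CA with the highest occupancy
    (first wins on ties). Waters/hetero records are ignored.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("model", str(path))
    model = next(structure.get_models())
    chains = {c.id: c for c in model}
    if chain is None:
        chain = next(iter(chains))
    if chain not in chains:
        raise FormatError(f"chain {chain!r} not found in {path}")
    residue_ids, names, coords = [], [], []
    for residue in chains[chain]:
        hetflag, resseq, _ = residue.id
        if hetflag != " " or "CA" not in residue:
            continue
        ca = residue["CA"]
        if ca.is_disordered():
            alts = sorted(
                ca.disordered_get_list(),
                key=lambda a: (-a.get_occupancy(), a.get_altloc()),
            )
            ca = alts[0]
        residue_ids.append((chain, int(resseq)))
        names.append(residue.get_resname())
        coords.append(ca.get_coord())
    if not residue_ids:
        raise FormatError(f"no CA atoms on chain {chain!r} in {path}")
    order = np.argsort([r[1] for r in residue_ids], kind="stable")
    return StructureModel(
        residue_ids=[residue_ids[i] for i in order],
        coords=np.asarray(coords, dtype=float)[order],
        residue_names=[names[i] for i in order],
    )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read GMT gene sets: one set per line, ``id<TAB>description<TAB>members…``.

    Lines without any member genes are skipped with a warning.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            members = frozenset(p for p in parts[2:] if p)
            if not members:
                logger.warning("%s:%d: gene set %r has no members; skipped",
                               path, lineno, parts[0])
                continue
            if parts[0] in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set id {parts[0]!r}")
            sets[parts[0]] = (parts[1] if len(parts) > 1 else "", members)
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_table(records: pd.DataFrame, path: str | Path, sort_by: str | None = None) -> None:
    """Write a DataFrame as TSV with header, rows sorted by the primary key.

    ``sort_by=None`` sorts by the index so repeated runs emit byte-identical
    files regardless of in-memory row order.
    """
    df = records.sort_values(sort_by, kind="stable") if sort_by else records.sort_index()
    df.to_csv(path, sep="\t")


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id in sorted(collection.sets):
            desc, members = collection.sets[set_id]
            fh.write("\t".join([set_id, desc, *sorted(members)]) + "\n")


def write_expression(dataset: ExpressionDataset, matrix_path: str | Path,
                     phenotype_path: str | Path) -> None:
    dataset.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
    pd.DataFrame(
        {"sample_id": dataset.sample_ids, "group": dataset.groups.to_numpy()}
    ).to_csv(phenotype_path, sep="\t", index=False)


def write_edge_list(net: PPINetwork, path: str | Path) -> None:
    rows = sorted(
        (min(u, v), max(u, v), conf) for u, v, conf in net.graph.edges(data="confidence")
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("proteinA\tproteinB\tcombined_score\n")
        for a, b, conf in rows:
            fh.write(f"{a}\t{b}\t{conf:.6f}\n")


def write_survival(table: SurvivalTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="patient_id")


def write_pdb(structure: StructureModel, path: str | Path) -> None:
    """Emit minimal ATOM records (CA only) for a structure model."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, ((chain, resseq), name, xyz) in enumerate(
            zip(structure.residue_ids, structure.residue_names, structure.coords),
            start=1,
        ):
            fh.write(
                f"ATOM  {i:5d}  CA  {name:<3s} {chain}{resseq:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")
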