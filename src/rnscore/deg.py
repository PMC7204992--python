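"""Differential expression: per-gene Welch t-tests, BH adjustment, filtering.

Tumor and normal groups are compared gene-by-gene with a two-sided
unequal-variance (Welch) t-test on the log2 intensities; p-values are
adjusted with Benjamini–Hochberg over all tested genes of the dataset.
Genes pass the DEG filter when the adjusted p-value falls below the
significance threshold and the linear fold change 2^(Δlog2) lies outside
the symmetric band [1/fc_thresh, fc_thresh].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError
from .io import ExpressionDataset

logger = logging.getLogger(__name__)


@dataclass
class DEGRecord:
    """Per-gene differential-expression summary between tumor and normal."""

    gene_id: str
    log2_fc: float  # mean(log2 tumor) − mean(log2 normal)
    fold_change: float  # 2 ** log2_fc, linear ratio
    t_stat: float
    p_value: float
    adj_p: float

    @property
    def direction(self) -> str:
        return "up" if self.fold_change > 1 else "down"


def test_all_genes(dataset: ExpressionDataset) -> list[DEGRecord]:
    """Welch t-test tumor vs normal for every gene, BH-adjusted.

    Degenerate genes are handled without error: zero variance in both
    groups with equal means gives t = 0, p = 1; zero variance with unequal
    means gives p = 0 (logged, the difference is then unambiguous).
    """
    tumor = dataset.group_matrix("tumor")
    normal = dataset.group_matrix("normal")
    log2_fc = tumor.mean(axis=1) - normal.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p_value = stats.ttest_ind(tumor, normal, axis=1, equal_var=False)
    t_stat = np.asarray(t_stat, dtype=float)
    p_value = np.asarray(p_value, dtype=float)

    zero_var = (tumor.var(axis=1) == 0) & (normal.var(axis=1) == 0)
    equal_means = np.isclose(log2_fc, 0.0)
    degenerate_flat = zero_var & equal_means
    degenerate_sep = zero_var & ~equal_means
    t_stat[degenerate_flat] = 0.0
    p_value[degenerate_flat] = 1.0
    if degenerate_sep.any():
        logger.info(
            "%d gene(s) with zero variance but unequal means: p set to 0",
            int(degenerate_sep.sum()),
        )
        t_stat[degenerate_sep] = np.sign(log2_fc[degenerate_sep]) * np.inf
        p_value[degenerate_sep] = 0.0

    _, adj_p, _, _ = multipletests(p_value, method="fdr_bh")
    return [
        DEGRecord(
            gene_id=g,
            log2_fc=float(log2_fc[i]),
            fold_change=float(2.0 ** log2_fc[i]),
            t_stat=float(t_stat[i]),
            p_value=float(p_value[i]),
            adj_p=float(adj_p[i]),
        )
        for i, g in enumerate(dataset.gene_ids)
    ]


def filter_degs(
    records: list[DEGRecord], p_thresh: float = 0.01, fc_thresh: float = 1.5
) -> set[str]:
    """Genes with adj_p < p_thresh and linear |FC| beyond fc_thresh.

    The fold-change criterion is symmetric on the ratio scale: a gene is
    kept when fold_change > fc_thresh (up) or fold_change < 1/fc_thresh
    (down).
    """
    if fc_thresh <= 0:
        raise ParameterError("fc_thresh must be positive")
    return {
        r.gene_id
        for r in records
        if r.adj_p < p_thresh
        and (r.fold_change > fc_thresh or r.fold_change < 1.0 / fc_thresh)
    }


def common_degs(deg_sets: list[set[str]], min_datasets: int) -> dict[str, int]:
    """Genes found in at least ``min_datasets`` of the input DEG sets.

    Returns gene → support count (number of sets containing the gene).
    """
    if not deg_sets:
        raise ParameterError("need at least one DEG set")
    if min_datasets > len(deg_sets):
        raise ParameterError(
            f"min_datasets={min_datasets} exceeds number of sets ({len(deg_sets)})"
        )
    support: dict[str, int] = {}
    for s in deg_sets:
        for g in s:
            support[g] = support.get(g, 0) + 1
    return {g: c for g, c in support.items() if c >= min_datasets}


def records_frame(records: list[DEGRecord]) -> pd.DataFrame:
    """Tabular view of DEG records, indexed by gene id."""
    return pd.DataFrame(
        {
            "log2_fc": [r.log2_fc for r in records],
            "fold_change": [r.fold_change for r in records],
            "t_stat": [r.t_stat for r in records],
            "p_value": [r.p_value for r in records],
            "adj_p": [r.adj_p for r in records],
            "direction": [r.direction for r in records],
        },
        index=pd.Index([r.gene_id for r in records], name="gene_id"),
    )
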