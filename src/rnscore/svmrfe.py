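"""SVM recursive feature elimination and the rank-derived Rs score.

A soft-margin linear SVM is fit on the candidate genes; the features with
the smallest squared weights are removed and the model refit, until one
gene remains. The elimination order (last survivor first) is the gene
ranking r_i ∈ {1..n}, converted to the relevance score

    Rs_i = (1 + n − r_i) / n  ∈ (0, 1],

so the top-ranked gene scores 1 and the last 1/n. To stay tractable on
thousands of genes, a fraction of the remaining features is dropped per
round, switching to one-by-one elimination for the endgame where rank
resolution matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .errors import ParameterError, ValidationError
from .io import ExpressionDataset


@dataclass
class RFEConfig:
    """Hyperparameters of the elimination schedule and the SVM fit."""

    C: float = 1.0  # soft-margin penalty of the linear SVM
    step_fraction: float = 0.10  # fraction of remaining features dropped per round
    fine_cutoff: int = 50  # switch to one-by-one when this many remain
    seed: int = 0  # reserved for solver randomness; libsvm is deterministic


@dataclass
class RankedGenes:
    """SVM-RFE ranking of one dataset's genes and the derived Rs scores."""

    dataset_id: str
    ranks: dict[str, int]  # gene → r_i, 1 = most relevant
    rs: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.ranks)
        if sorted(self.ranks.values()) != list(range(1, n + 1)):
            raise ValidationError("ranks must be a permutation of 1..n")
        self.rs = rs_scores(self.ranks)

    @property
    def n(self) -> int:
        return len(self.ranks)


def rs_scores(ranks: dict[str, int]) -> dict[str, float]:
    """Rs = (1 + n − r_i)/n for a permutation ranking."""
    n = len(ranks)
    return {g: (1 + n - r) / n for g, r in ranks.items()}


def _standardize(X: np.ndarray) -> np.ndarray:
    """Zero-mean unit-variance columns; constant columns become all-zero."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe


def svm_rfe_rank(
    dataset: ExpressionDataset,
    genes: set[str] | list[str],
    config: RFEConfig | None = None,
) -> RankedGenes:
    """Rank candidate genes by recursive elimination under a linear SVM.

    Features are standardized before every fit so weight magnitudes are
    comparable across genes. Within a round, the features with the
    smallest squared weight are eliminated, ties broken by lexicographic
    gene id, and receive the worst still
    unassigned ranks. The ranking is a pure function of (data, genes,
    config): gene input order does not matter.
    """
    config = config or RFEConfig()
    genes = sorted(genes)
    missing = [g for g in genes if g not in dataset.values.index]
    if missing:
        raise ValidationError(f"genes absent from dataset: {missing[:5]}")
    if len(genes) < 1:
        raise ParameterError("need at least one gene to rank")
    labels = np.where(dataset.groups.to_numpy() == "tumor", 1, -1)
    if len(np.unique(labels)) < 2:
        raise ValidationError("both classes must be present")

    remaining = list(genes)
    ranks: dict[str, int] = {}
    next_worst = len(genes)
    X_full = dataset.values.loc[genes].to_numpy(dtype=float).T  # samples × genes
    col = {g: i for i, g in enumerate(genes)}

    while len(remaining) > 1:
        X = _standardize(X_full[:, [col[g] for g in remaining]])
        clf = SVC(kernel="linear", C=config.C)
        clf.fit(X, labels)
        w2 = np.square(np.asarray(clf.coef_).ravel())
        if len(remaining) > config.fine_cutoff:
            n_elim = max(1, int(round(config.step_fraction * len(remaining))))
            n_elim = min(n_elim, len(remaining) - config.fine_cutoff, len(remaining) - 1)
            n_elim = max(n_elim, 1)
        else:
            n_elim = 1
        # smallest squared weight goes out first; ties broken by gene id
        order = sorted(range(len(remaining)), key=lambda i: (w2[i], remaining[i]))
        victims = [remaining[i] for i in order[:n_elim]]
        # the weakest of this round's victims receives the worst open rank
        for g in victims:
            ranks[g] = next_worst
            next_worst -= 1
        remaining = [g for g in remaining if g not in set(victims)]
    ranks[remaining[0]] = 1
    return RankedGenes(dataset_id=dataset.dataset_id, ranks=ranks)
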