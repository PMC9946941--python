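"""Evaluation metrics for clonal-tree reconstruction.

Clustering of SNVs into clones is scored with V-measure, adjusted Rand index
and adjusted mutual information (scikit-learn implementations).  Tree
topology is scored by the ancestral reconstruction error: the mean absolute
difference between true and predicted SNV-pair ancestry matrices.  Cell
genotyping is scored by the (expected) number of per-cell mutation-status
errors, the expectation taken over the posterior cell-to-clone assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from sklearn.metrics import (
    adjusted_mutual_info_score,
    adjusted_rand_score,
    v_measure_score,
)

from .tree import ClonalTree, NodePath, mutation_status


@dataclass
class EvaluationReport:
    v_measure: float
    adjusted_rand_index: float
    adjusted_mutual_information: float
    ancestral_error: float | None = None
    mean_expected_genotype_loss: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def clustering_scores(labels_true: Sequence, labels_pred: Sequence) -> tuple[float, float, float]:
    """(V-measure, adjusted Rand index, adjusted mutual information)."""
    if len(labels_true) != len(labels_pred):
        raise ValueError("label vectors must have equal length")
    return (
        float(v_measure_score(labels_true, labels_pred)),
        float(adjusted_rand_score(labels_true, labels_pred)),
        float(adjusted_mutual_info_score(labels_true, labels_pred)),
    )


def ancestral_error(a_true: np.ndarray, a_pred: np.ndarray, ordered: bool = True) -> float:
    """Mean absolute error between ancestry matrices.

    By default sums |A*_{ij} - A_{ij}| over ordered pairs i != j and divides
    by N(N-1) (ancestry is asymmetric).  ``ordered=False`` instead scores
    unordered pairs: |(A*_{ij} + A*_{ji}) - (A_{ij} + A_{ji})| summed over
    i < j, divided by N(N-1)/2.
    """
    a_true = np.asarray(a_true)
    a_pred = np.asarray(a_pred)
    if a_true.shape != a_pred.shape or a_true.ndim != 2 or a_true.shape[0] != a_true.shape[1]:
        raise ValueError("ancestry matrices must be square and of equal shape")
    n = a_true.shape[0]
    if n < 2:
        raise ValueError("need at least two SNVs")
    diff = np.abs(a_true.astype(int) - a_pred.astype(int))
    np.fill_diagonal(diff, 0)
    if ordered:
        return float(diff.sum() / (n * (n - 1)))
    iu = np.triu_indices(n, k=1)
    both_true = a_true.astype(int) + a_true.T.astype(int)
    both_pred = a_pred.astype(int) + a_pred.T.astype(int)
    return float(np.abs(both_true - both_pred)[iu].sum() / (n * (n - 1) / 2))


def genotype_loss(mu_true_row: np.ndarray, mu_pred_row: np.ndarray) -> int:
    """Number of loci where predicted and true mutation status disagree."""
    return int(np.sum(np.asarray(mu_true_row) != np.asarray(mu_pred_row)))


def expected_genotype_loss(
    mu_true_row: np.ndarray,
    posterior_row: np.ndarray,
    tree: ClonalTree,
    z: Sequence[NodePath],
    nodes: Sequence[NodePath],
) -> float:
    """Posterior-expected per-cell genotype loss.

    Sum over nodes v of P(zeta_c = v) times the number of loci where the
    mutation status induced by v disagrees with the cell's true status.
    """
    posterior_row = np.asarray(posterior_row, dtype=float)
    if len(posterior_row) != len(nodes):
        raise ValueError("posterior row and node list length mismatch")
    if not np.isclose(posterior_row.sum(), 1.0, atol=1e-6):
        raise ValueError("posterior row must sum to 1")
    total = 0.0
    for p, v in zip(posterior_row, nodes):
        if p == 0.0:
            continue
        total += p * genotype_loss(mu_true_row, mutation_status(tree, z, v))
    return float(total)


def evaluate_clustering(
    labels_true: Sequence,
    labels_pred: Sequence,
    a_true: np.ndarray | None = None,
    a_pred: np.ndarray | None = None,
) -> EvaluationReport:
    v, ari, ami = clustering_scores(labels_true, labels_pred)
    ae = None
    if a_true is not None and a_pred is not None:
        ae = ancestral_error(a_true, a_pred)
    return EvaluationReport(
        v_measure=v,
        adjusted_rand_index=ari,
        adjusted_mutual_information=ami,
        ancestral_error=ae,
    )
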