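"""Agreement between cluster solutions: Cohen's kappa, weighted kappa.

Given the reference design's clusters and a reduced design's clusters
over the same subjects, a k x k contingency table is formed, its rows
matched to the reference clusters by optimal assignment (the diagonal
sum is maximised), and chance-corrected agreement computed: the raw
Cohen's kappa and, because the clusters are ordinal (fast improvement
to indifference), the quadratic-weighted kappa, which credits
near-misses with weights w_ij = 1 - (i-j)^2 / (k-1)^2.

Interpretation follows the Landis-Koch convention: above 0.75
excellent, 0.40-0.75 fair to good, below 0.40 poor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment


@dataclass(frozen=True)
class AgreementResult:
    kappa: float
    weighted_kappa: float
    observed_agreement: float
    expected_agreement: float
    interpretation: str


def crosstab(labels_ref, labels_alt, k: int | None = None) -> np.ndarray:
    """Contingency table: rows = alt labels, columns = ref labels.

    Labels are 1-based; subjects must be in the same order in both
    vectors.
    """
    ref = np.asarray(labels_ref, dtype=int)
    alt = np.asarray(labels_alt, dtype=int)
    if ref.shape != alt.shape:
        raise ValueError("label vectors must have equal length")
    if k is None:
        k = int(max(ref.max(), alt.max()))
    table = np.zeros((k, k), dtype=int)
    np.add.at(table, (alt - 1, ref - 1), 1)
    return table


def align_labels(table: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Permute rows to maximise the diagonal (optimal assignment).

    Returns the permuted table and the permutation ``perm`` such that
    row ``perm[i]`` of the input becomes row ``i`` — i.e. input cluster
    ``perm[i] + 1`` is matched to reference cluster ``i + 1``.
    """
    table = np.asarray(table)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise ValueError("table must be square")
    row_ind, col_ind = linear_sum_assignment(table, maximize=True)
    perm = np.empty(table.shape[0], dtype=int)
    perm[col_ind] = row_ind
    return table[perm], perm


def cohen_kappa(table: np.ndarray) -> float:
    """Raw chance-corrected agreement from a square contingency table."""
    p_o, p_e = _agreements(table, _identity_weights(len(table)))
    if p_e >= 1.0 - 1e-12:
        raise ValueError("expected agreement is 1: kappa undefined")
    return (p_o - p_e) / (1.0 - p_e)


def weighted_kappa(table: np.ndarray) -> float:
    """Quadratic-weighted kappa for ordinal cluster labels."""
    k = len(np.asarray(table))
    if k < 2:
        raise ValueError("need at least a 2x2 table")
    i, j = np.indices((k, k))
    w = 1.0 - (i - j) ** 2 / (k - 1) ** 2
    p_o, p_e = _agreements(table, w)
    if p_e >= 1.0 - 1e-12:
        raise ValueError("weighted expected agreement is 1: kappa undefined")
    return (p_o - p_e) / (1.0 - p_e)


def interpret_kappa(kappa: float) -> str:
    """Landis-Koch band: excellent / fair-to-good / poor."""
    if kappa > 1.0 + 1e-12:
        raise ValueError("kappa cannot exceed 1")
    if kappa > 0.75:
        return "excellent"
    if kappa >= 0.40:
        return "fair-to-good"
    return "poor"


def agreement(labels_ref, labels_alt) -> AgreementResult:
    """Full pipeline: crosstab -> align -> kappa + weighted kappa."""
    table, _ = align_labels(crosstab(labels_ref, labels_alt))
    return agreement_from_table(table)


def agreement_from_table(table: np.ndarray) -> AgreementResult:
    """Agreement statistics for an already-matched table (e.g. printed)."""
    p_o, p_e = _agreements(table, _identity_weights(len(np.asarray(table))))
    wk = weighted_kappa(table)
    return AgreementResult(
        kappa=cohen_kappa(table),
        weighted_kappa=wk,
        observed_agreement=p_o,
        expected_agreement=p_e,
        interpretation=interpret_kappa(wk),
    )


def _identity_weights(k: int) -> np.ndarray:
    return np.eye(k)


def _agreements(table: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("table must be square")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    n = t.sum()
    if n <= 0:
        raise ValueError("table total must be positive")
    p = t / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = float((weights * p).sum())
    p_e = float((weights * np.outer(row, col)).sum())
    return p_o, p_e
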