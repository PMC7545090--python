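"""Random walk with restart, pair scoring and adaptive-threshold network assembly."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "RWRScores",
    "InferredNetwork",
    "run_rwr",
    "score_pairs",
    "adaptive_threshold",
    "assemble_network",
]


@dataclass
class RWRScores:
    """Per-seed stationary distributions, pair scores and per-gene thresholds.

    Row i of ``stationary`` is the fixed point of the walk restarted at gene
    i's seed vector; ``mip[i, j]`` is the score of the candidate relation
    i -> j (stationary mass at j times the transition weight), with a zero
    diagonal; ``thresholds[i]`` is gene i's adaptive acceptance level.
    """

    stationary: np.ndarray
    mip: np.ndarray
    thresholds: np.ndarray
    iterations: np.ndarray


@dataclass
class InferredNetwork:
    """Undirected network over the gene panel, plus the pre-symmetrisation votes."""

    gene_ids: list[str]
    edges: frozenset = field(default_factory=frozenset)
    directed_votes: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        edges = set()
        n = len(self.gene_ids)
        for a, b in self.edges:
            if a == b:
                raise ValueError("self-edges are not allowed")
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"edge index out of range: ({a},{b})")
            edges.add((min(a, b), max(a, b)))
        self.edges = frozenset(edges)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def degree(self, g: int) -> int:
        return sum(1 for a, b in self.edges if g in (a, b))


def run_rwr(
    transition: np.ndarray,
    p0: np.ndarray,
    alpha: float,
    tol: float = 1e-6,
    max_iter: int = 10000,
) -> tuple[np.ndarray, int]:
    """Iterate ``p <- (1-alpha) * T @ p + alpha * p0`` to its fixed point.

    Starts at ``p0`` and stops when the L1 change drops below ``tol``.  The
    update is a contraction with factor ``1 - alpha``, so convergence is
    guaranteed; hitting ``max_iter`` raises a warning and returns the last
    iterate.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly in (0,1)")
    colsums = transition.sum(axis=0)
    if not np.allclose(colsums, 1.0, atol=1e-8):
        raise ValueError("transition matrix must be column-stochastic")
    if not np.isclose(p0.sum(), 1.0, atol=1e-9):
        raise ValueError("p0 must sum to 1")
    p = p0.astype(float).copy()
    for it in range(1, max_iter + 1):
        p_next = (1.0 - alpha) * (transition @ p) + alpha * p0
        if np.abs(p_next - p).sum() < tol:
            return p_next, it
        p = p_next
    warnings.warn(f"RWR did not converge within {max_iter} iterations")
    return p, max_iter


def score_pairs(stationary: np.ndarray, transition: np.ndarray, i: int) -> np.ndarray:
    """Score row for seed gene i: stationary mass times transition weight.

    ``row[j] = stationary[j] * transition[i, j]``; the self-score is zeroed so
    restart mass parked on the seed never enters thresholds.
    """
    row = stationary * transition[i, :]
    row[i] = 0.0
    return row


def adaptive_threshold(mip_row: np.ndarray, alpha: float, coef: float = 0.75) -> float:
    """Per-gene acceptance level: ``coef * alpha`` times the off-diagonal row sum."""
    return float(coef * alpha * mip_row.sum())


def assemble_network(
    mip: np.ndarray,
    thresholds: np.ndarray,
    gene_ids: list[str],
    symmetrize: str = "or",
) -> InferredNetwork:
    """Threshold the score matrix per gene and symmetrise the votes.

    ``votes[i, j]`` is true when ``mip[i, j]`` strictly exceeds gene i's
    threshold; an undirected edge survives under OR (default) when either
    direction votes, under AND only when both do.  Self-pairs never become
    edges.
    """
    if symmetrize not in ("or", "and"):
        raise ValueError(f"unknown symmetrisation mode {symmetrize!r}")
    votes = mip > thresholds[:, None]
    np.fill_diagonal(votes, False)
    combined = (votes | votes.T) if symmetrize == "or" else (votes & votes.T)
    ii, jj = np.nonzero(np.triu(combined, 1))
    return InferredNetwork(
        gene_ids=list(gene_ids),
        edges=frozenset(zip(ii.tolist(), jj.tolist())),
        directed_votes=votes,
    )
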