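"""Reconnect isolated genes via parent-child (PC) set discovery.

A gene left with degree 0 by thresholding is linked to the genes that remain
conditionally dependent on it after a staged conditional-independence search:
candidates are pruned whenever some conditioning subset (up to ``max_cond``
variables) pushes the conditional mutual information below ``ci_eps``.  Only
the parent-child set is used; spouse discovery is deliberately omitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np

from .io_formats import ExpressionMatrix
from .mi_estimation import EstimatorOptions, estimate_cmi, estimate_mi_matrix
from .rwr_inference import InferredNetwork

__all__ = ["PCResult", "find_isolated", "recognize_pc", "repair_network"]

logger = logging.getLogger(__name__)


@dataclass
class PCResult:
    """Parent-child set of a target gene plus the separating sets found."""

    target: int
    pc: list[int]
    sepsets: dict[int, tuple[int, ...]] = field(default_factory=dict)


def find_isolated(net: InferredNetwork) -> list[int]:
    """Genes with degree 0 in the undirected edge set, ascending index order."""
    touched = {g for edge in net.edges for g in edge}
    return [g for g in range(net.n_genes) if g not in touched]


def recognize_pc(
    expr: ExpressionMatrix,
    target: int,
    ci_eps: float = 0.03,
    max_cond: int = 3,
    opts: Optional[EstimatorOptions] = None,
) -> PCResult:
    """Staged conditional-independence pruning of the target's neighbourhood.

    Starting from all other genes, conditioning-set sizes s = 0..max_cond are
    tried in order; at each size the candidate list is rescanned (ascending
    index, subsets in lexicographic order over the surviving candidates) until
    no candidate can be removed.  Removal records the separating set.
    """
    opts = opts or EstimatorOptions()
    candidates = [g for g in range(expr.n_genes) if g != target]
    sepsets: dict[int, tuple[int, ...]] = {}
    for s in range(max_cond + 1):
        changed = True
        while changed:
            changed = False
            for x in list(candidates):
                others = [c for c in candidates if c != x]
                if len(others) < s:
                    continue
                for subset in combinations(others, s):
                    if estimate_cmi(expr, target, x, subset, opts) < ci_eps:
                        candidates.remove(x)
                        sepsets[x] = subset
                        changed = True
                        break
    return PCResult(target=target, pc=candidates, sepsets=sepsets)


def repair_network(
    net: InferredNetwork,
    expr: ExpressionMatrix,
    ci_eps: float = 0.03,
    max_cond: int = 3,
    opts: Optional[EstimatorOptions] = None,
    pc_symmetric: bool = False,
) -> InferredNetwork:
    """Connect every isolated gene to its PC set (top-MI fallback when empty).

    Existing edges are untouched; the result has minimum degree >= 1.  With
    ``pc_symmetric`` an edge is added only when membership holds both ways
    (the fallback edge still guarantees connectivity).
    """
    isolated = find_isolated(net)
    if not isolated:
        return net
    opts = opts or EstimatorOptions()
    edges = set(net.edges)
    mi = estimate_mi_matrix(expr, opts)
    pc_cache: dict[int, list[int]] = {}

    def pc_of(g: int) -> list[int]:
        if g not in pc_cache:
            pc_cache[g] = recognize_pc(expr, g, ci_eps, max_cond, opts).pc
        return pc_cache[g]

    for g in isolated:
        partners = pc_of(g)
        if pc_symmetric:
            partners = [p for p in partners if g in pc_of(p)]
        if not partners:
            row = mi.values[g].copy()
            row[g] = -np.inf
            partners = [int(row.argmax())]
            logger.info(
                "gene %s has an empty PC set; falling back to top-MI partner %s",
                net.gene_ids[g],
                net.gene_ids[partners[0]],
            )
        for p in partners:
            edges.add((min(g, p), max(g, p)))
    return InferredNetwork(
        gene_ids=list(net.gene_ids),
        edges=frozenset(edges),
        directed_votes=net.directed_votes,
    )
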