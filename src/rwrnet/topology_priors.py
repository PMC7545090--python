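"""Topology-derived ingredients of the improved random walk with restart.

Three pieces are computed from the pairwise MI matrix:

* a restart probability derived from average commute times on the MI graph
  (normalised Laplacian pseudo-inverse kernel),
* per-gene seed vectors that spread restart mass over a functional module
  (a centre gene plus its top-``ceil(log N)`` MI neighbours),
* a "roaming network": the MI matrix attenuated by an asymmetric ranking
  rule, column-normalised into the walk's transition matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .mi_estimation import MIMatrix

__all__ = [
    "CommuteKernel",
    "ModuleSeeding",
    "RoamingNetwork",
    "commute_kernel",
    "expression_levels",
    "select_centres",
    "build_modules",
    "initial_vector",
    "build_seeding",
    "build_roaming",
]

_EIG_NULL = 1e-10
_DEGREE_EPS = 1e-12
_ACT_EPS = 1e-12


@dataclass
class CommuteKernel:
    """Normalised Laplacian, its pseudo-inverse and the commute-time statistics.

    ``act[i,j]`` is the average commute time between genes i and j computed
    from the kernel; ``acf`` is its reciprocal (1 on the diagonal and wherever
    ACT underflows); ``alpha_raw`` is the mean of all N^2 ACF entries and
    ``alpha`` the value clamped into the admissible restart range.
    """

    laplacian: np.ndarray
    pinv: np.ndarray
    act: np.ndarray
    acf: np.ndarray
    alpha_raw: float
    alpha: float


@dataclass
class ModuleSeeding:
    """Functional-module centres and the per-gene initial probability vectors."""

    expression_level: np.ndarray
    centres: set[int]
    modules: dict[int, list[int]]
    p0: np.ndarray  # row g = seed vector for gene g

    @property
    def module_size(self) -> int:
        return max((len(m) for m in self.modules.values() if m), default=0)


@dataclass
class RoamingNetwork:
    """Rank-attenuated weight matrix and its column-stochastic transition form."""

    rank_factor: np.ndarray
    weights: np.ndarray
    transition: np.ndarray


def commute_kernel(
    mi: MIMatrix, alpha_min: float = 0.01, alpha_max: float = 0.99
) -> CommuteKernel:
    """Derive the restart probability from average commute times on the MI graph.

    The MI matrix acts as the weighted adjacency; degrees below ``1e-12`` are
    floored so the degree matrix stays invertible.  The Laplacian is the
    symmetrically normalised form, its pseudo-inverse comes from an
    eigendecomposition with eigenvalues below ``1e-10`` treated as null.
    """
    w = mi.values
    if not np.allclose(w, w.T):
        raise ValueError("commute_kernel requires a symmetric MI matrix")
    n = w.shape[0]
    deg = w.sum(axis=1)
    deg = np.maximum(deg, _DEGREE_EPS)
    d_isqrt = 1.0 / np.sqrt(deg)
    lap = d_isqrt[:, None] * (np.diag(deg) - w) * d_isqrt[None, :]
    lap = (lap + lap.T) / 2.0
    evals, evecs = np.linalg.eigh(lap)
    inv = np.where(evals > _EIG_NULL, 1.0 / np.where(evals > _EIG_NULL, evals, 1.0), 0.0)
    pinv = (evecs * inv) @ evecs.T
    pinv = (pinv + pinv.T) / 2.0

    diag = np.diag(pinv)
    act = diag[:, None] + diag[None, :] - 2.0 * pinv
    act = np.maximum(act, 0.0)
    np.fill_diagonal(act, 0.0)

    acf = np.ones_like(act)
    off = act >= _ACT_EPS
    acf[off] = 1.0 / act[off]
    np.fill_diagonal(acf, 1.0)

    alpha_raw = float(acf.sum() / (n * n))
    alpha = min(max(alpha_raw, alpha_min), alpha_max)
    if alpha != alpha_raw:
        warnings.warn(
            f"restart probability {alpha_raw:.6g} clamped into "
            f"[{alpha_min}, {alpha_max}] -> {alpha:.6g}"
        )
    return CommuteKernel(
        laplacian=lap, pinv=pinv, act=act, acf=acf, alpha_raw=alpha_raw, alpha=alpha
    )


def expression_levels(mi: MIMatrix) -> np.ndarray:
    """Per-gene total MI against all partners (row sums; zero diagonal)."""
    return mi.values.sum(axis=1)


def select_centres(el: np.ndarray) -> set[int]:
    """Centres: genes above the mean level, plus genes below mean - sample std.

    Both inequalities are strict; the set may be empty when all levels tie.
    """
    el = np.asarray(el, dtype=float)
    if el.size < 2:
        raise ValueError("need at least 2 genes to select centres")
    mean = el.mean()
    std = el.std(ddof=1)
    high = el > mean
    low = el < mean - std
    return set(np.nonzero(high | low)[0].tolist())


def _module_size(n: int, log_base: float) -> int:
    return min(math.ceil(math.log(n) / math.log(log_base)), n - 1)


def _top_partners(mi_row: np.ndarray, g: int, k: int) -> list[int]:
    n = mi_row.shape[0]
    # descending MI, ties broken by ascending index
    order = np.lexsort((np.arange(n), -mi_row))
    return [int(j) for j in order if j != g][:k]


def build_modules(
    mi: MIMatrix,
    centres: set[int],
    size: Optional[int] = None,
    log_base: float = math.e,
) -> dict[int, list[int]]:
    """Top-MI neighbourhoods of the centre genes.

    Each centre maps to its ``min(ceil(log N), N-1)`` strongest MI partners
    (descending, ties by ascending index, the centre itself excluded);
    non-centres map to empty lists.
    """
    n = mi.n_genes
    k = size if size is not None else _module_size(n, log_base)
    if k < 1:
        raise ValueError("module size must be >= 1")
    k = min(k, n - 1)
    modules: dict[int, list[int]] = {}
    for g in range(n):
        modules[g] = _top_partners(mi.values[g], g, k) if g in centres else []
    return modules


def initial_vector(
    g: int, centres: set[int], modules: dict[int, list[int]], n: int
) -> np.ndarray:
    """Seed vector for gene g: one-hot off-centre, uniform over centre+module."""
    p0 = np.zeros(n)
    if g in centres:
        members = [g] + list(modules[g])
        p0[members] = 1.0 / len(members)
    else:
        p0[g] = 1.0
    return p0


def build_seeding(
    mi: MIMatrix, size: Optional[int] = None, log_base: float = math.e
) -> ModuleSeeding:
    """Convenience wrapper: levels -> centres -> modules -> stacked seed matrix."""
    el = expression_levels(mi)
    centres = select_centres(el)
    modules = build_modules(mi, centres, size=size, log_base=log_base)
    n = mi.n_genes
    p0 = np.vstack([initial_vector(g, centres, modules, n) for g in range(n)])
    return ModuleSeeding(expression_level=el, centres=centres, modules=modules, p0=p0)


def build_roaming(mi: MIMatrix) -> RoamingNetwork:
    """Attenuate the MI matrix by the asymmetric ranking rule and normalise.

    With ``mbar_i`` the mean off-diagonal MI of row i and ``R[i,j]`` the
    descending-MI rank of j within row i (1 = strongest, ties by ascending
    index), the attenuation factor is::

        1             if MI[i,j] >= mbar_i
        1 - R[i,j]/N  if MI[i,j] <  mbar_i and MI[j,i] >= mbar_j
        0.1           otherwise

    Weights are ``factor * MI`` with a zero diagonal; the transition matrix
    divides each column by its sum (all-zero columns become uniform 1/N).
    """
    w_mi = mi.values
    n = mi.n_genes
    mbar = w_mi.sum(axis=1) / (n - 1)

    ranks = np.zeros((n, n), dtype=float)
    for i in range(n):
        order = np.lexsort((np.arange(n), -w_mi[i]))
        r = 1
        for j in order:
            if j == i:
                continue
            ranks[i, j] = r
            r += 1

    above_own = w_mi >= mbar[:, None]
    above_partner = w_mi >= mbar[None, :]  # MI symmetric: MI[j,i] vs mbar_j
    rank_factor = np.where(
        above_own, 1.0, np.where(above_partner, 1.0 - ranks / n, 0.1)
    )

    weights = rank_factor * w_mi
    np.fill_diagonal(weights, 0.0)

    colsum = weights.sum(axis=0)
    transition = np.empty_like(weights)
    zero = colsum <= 0
    nz = ~zero
    transition[:, nz] = weights[:, nz] / colsum[nz]
    transition[:, zero] = 1.0 / n
    return RoamingNetwork(
        rank_factor=rank_factor, weights=weights, transition=transition
    )
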