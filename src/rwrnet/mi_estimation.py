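"""Pairwise mutual information and conditional mutual information estimators.

The default estimator assumes joint Gaussianity, under which
``MI(X,Y) = -1/2 * ln(1 - r^2)`` with ``r`` the Pearson correlation, and
``CMI(X,Y|Z) = -1/2 * ln(1 - rho^2)`` with ``rho`` the partial correlation of
X and Y given Z.  A plug-in histogram estimator on equal-width bins is
available for non-Gaussian data.  Values are in nats unless a different log
base is configured.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .io_formats import ExpressionMatrix

__all__ = ["MIMatrix", "EstimatorOptions", "estimate_mi_matrix", "estimate_cmi"]

_RIDGE = 1e-6


@dataclass
class MIMatrix:
    """Symmetric non-negative N x N mutual-information matrix, zero diagonal."""

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or n != len(self.gene_ids):
            raise ValueError("MI matrix shape does not match gene ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("MI matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("MI matrix diagonal must be exactly 0")
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise ValueError("MI entries must be finite and >= 0")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class EstimatorOptions:
    method: str = "gaussian"
    bins: int = 10
    correlation_clamp: float = 0.99999
    log_base: float = math.e

    def __post_init__(self) -> None:
        if self.method not in ("gaussian", "histogram"):
            raise ValueError(f"unknown MI method {self.method!r}")
        if self.method == "histogram" and self.bins < 2:
            raise ValueError("histogram estimator needs bins >= 2")
        if not 0 < self.correlation_clamp < 1:
            raise ValueError("correlation_clamp must lie in (0,1)")

    @property
    def _log_scale(self) -> float:
        return math.log(self.log_base)


def _gaussian_mi_from_r(r: np.ndarray, opts: EstimatorOptions) -> np.ndarray:
    r = np.clip(r, -opts.correlation_clamp, opts.correlation_clamp)
    return -0.5 * np.log1p(-(r * r)) / opts._log_scale


def _discretize(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-width binning over the sample range; constant vectors map to bin 0."""
    lo, hi = x.min(), x.max()
    if hi <= lo:
        return np.zeros(x.shape, dtype=np.intp)
    edges = np.linspace(lo, hi, bins + 1)
    return np.clip(np.searchsorted(edges, x, side="right") - 1, 0, bins - 1)


def _entropy_from_codes(codes: np.ndarray) -> float:
    """Plug-in entropy (nats) of the empirical distribution of integer rows."""
    if codes.ndim == 1:
        codes = codes[:, None]
    _, counts = np.unique(codes, axis=0, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def _histogram_mi(x: np.ndarray, y: np.ndarray, opts: EstimatorOptions) -> float:
    cx = _discretize(x, opts.bins)
    cy = _discretize(y, opts.bins)
    mi = (
        _entropy_from_codes(cx)
        + _entropy_from_codes(cy)
        - _entropy_from_codes(np.column_stack([cx, cy]))
    )
    return max(mi, 0.0) / opts._log_scale


def estimate_mi_matrix(
    expr: ExpressionMatrix, opts: Optional[EstimatorOptions] = None
) -> MIMatrix:
    """Estimate the N x N pairwise MI matrix of an expression matrix.

    Constant (zero-variance) genes get MI 0 against every partner, with a
    warning rather than an error.  The diagonal is forced to 0.
    """
    opts = opts or EstimatorOptions()
    x = expr.values
    n = expr.n_genes
    if opts.method == "gaussian":
        if expr.n_samples < 3:
            raise ValueError("gaussian MI estimator needs at least 3 samples")
        sd = x.std(axis=1, ddof=1)
        constant = sd <= 0
        if constant.any():
            names = [expr.gene_ids[i] for i in np.nonzero(constant)[0]]
            warnings.warn(f"constant genes set to MI 0: {names}")
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(x)
        r[~np.isfinite(r)] = 0.0
        mi = _gaussian_mi_from_r(r, opts)
        mi[constant, :] = 0.0
        mi[:, constant] = 0.0
    else:
        mi = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                mi[i, j] = mi[j, i] = _histogram_mi(x[i], x[j], opts)
    np.fill_diagonal(mi, 0.0)
    mi = np.maximum(mi, 0.0)
    mi = (mi + mi.T) / 2.0
    return MIMatrix(gene_ids=list(expr.gene_ids), values=mi)


def _partial_correlation(x: np.ndarray, i: int, j: int, cond: list[int]) -> float:
    """Partial correlation of rows i and j of x given the rows in cond."""
    idx = [i, j] + cond
    sub = np.corrcoef(x[idx])
    sub = np.nan_to_num(sub, nan=0.0)
    np.fill_diagonal(sub, 1.0)
    try:
        prec = np.linalg.inv(sub)
    except np.linalg.LinAlgError:
        warnings.warn("singular conditioning correlation matrix; ridge applied")
        prec = np.linalg.inv(sub + _RIDGE * np.eye(sub.shape[0]))
    denom = math.sqrt(abs(prec[0, 0] * prec[1, 1]))
    if denom == 0:
        return 0.0
    return float(-prec[0, 1] / denom)


def estimate_cmi(
    expr: ExpressionMatrix,
    i: int,
    j: int,
    cond: Iterable[int] = (),
    opts: Optional[EstimatorOptions] = None,
) -> float:
    """Conditional mutual information CMI(g_i, g_j | cond), in nats by default.

    Empty ``cond`` reduces exactly to the pairwise MI; a conditioning set
    containing i or j yields 0 (degenerate conditioning).
    """
    opts = opts or EstimatorOptions()
    if i == j:
        raise ValueError("estimate_cmi requires i != j")
    cond = sorted(set(cond))
    if i in cond or j in cond:
        return 0.0
    x = expr.values
    if opts.method == "gaussian":
        sd = x.std(axis=1, ddof=1)
        if sd[i] <= 0 or sd[j] <= 0:
            return 0.0
        if not cond:
            r = float(np.corrcoef(x[i], x[j])[0, 1])
            if not math.isfinite(r):
                r = 0.0
            return float(_gaussian_mi_from_r(np.array(r), opts))
        rho = _partial_correlation(x, i, j, cond)
        return float(_gaussian_mi_from_r(np.array(rho), opts))

    # Histogram plug-in: CMI = H(X,Z) + H(Y,Z) - H(Z) - H(X,Y,Z).
    cx = _discretize(x[i], opts.bins)
    cy = _discretize(x[j], opts.bins)
    if not cond:
        return _histogram_mi(x[i], x[j], opts)
    cz = np.column_stack([_discretize(x[k], opts.bins) for k in cond])
    cmi = (
        _entropy_from_codes(np.column_stack([cx, cz]))
        + _entropy_from_codes(np.column_stack([cy, cz]))
        - _entropy_from_codes(cz)
        - _entropy_from_codes(np.column_stack([cx, cy, cz]))
    )
    return max(cmi, 0.0) / opts._log_scale
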