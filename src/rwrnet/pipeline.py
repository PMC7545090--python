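"""End-to-end inference pipeline and its configuration.

Stage order: MI matrix -> restart probability -> roaming network ->
expression levels / centres / modules -> per-gene seed + walk -> pair scores
-> adaptive-threshold network -> isolated-gene repair.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import yaml

from . import mb_repair, rwr_inference, topology_priors
from .io_formats import ExpressionMatrix
from .mi_estimation import EstimatorOptions, MIMatrix, estimate_mi_matrix
from .rwr_inference import InferredNetwork, RWRScores
from .topology_priors import CommuteKernel, ModuleSeeding, RoamingNetwork

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

_LOG_BASES = {"e": math.e, "2": 2.0, "10": 10.0}


@dataclass
class PipelineConfig:
    """Every knob of the pipeline; serialisable to/from YAML (unknown keys rejected)."""

    mi_method: str = "gaussian"
    bins: int = 10
    correlation_clamp: float = 0.99999
    log_base: str = "e"
    alpha_min: float = 0.01
    alpha_max: float = 0.99
    alpha_override: Optional[float] = None
    module_size: Optional[int] = None
    tol: float = 1e-6
    max_iter: int = 10000
    threshold_coef: float = 0.75
    symmetrize: str = "or"
    ci_eps: float = 0.03
    max_cond: int = 3
    repair: bool = True
    pc_symmetric: bool = False
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.log_base not in _LOG_BASES:
            raise ValueError(f"log_base must be one of {sorted(_LOG_BASES)}")
        if self.symmetrize not in ("or", "and"):
            raise ValueError("symmetrize must be 'or' or 'and'")

    def estimator_options(self) -> EstimatorOptions:
        return EstimatorOptions(
            method=self.mi_method,
            bins=self.bins,
            correlation_clamp=self.correlation_clamp,
        )

    @property
    def log_base_value(self) -> float:
        return _LOG_BASES[self.log_base]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    network: InferredNetwork
    raw_network: InferredNetwork
    scores: RWRScores
    kernel: CommuteKernel
    seeding: ModuleSeeding
    roaming: RoamingNetwork
    mi: MIMatrix
    alpha: float
    log: list[str] = field(default_factory=list)


def run_pipeline(
    expr: ExpressionMatrix, cfg: Optional[PipelineConfig] = None
) -> PipelineResult:
    """Run the full inference pipeline on an expression matrix."""
    cfg = cfg or PipelineConfig()
    log: list[str] = []
    n = expr.n_genes

    opts = cfg.estimator_options()
    mi = estimate_mi_matrix(expr, opts)
    log.append(f"MI matrix: {n} genes, method={cfg.mi_method}")

    kernel = topology_priors.commute_kernel(
        mi, alpha_min=cfg.alpha_min, alpha_max=cfg.alpha_max
    )
    alpha = cfg.alpha_override if cfg.alpha_override is not None else kernel.alpha
    log.append(
        f"restart probability: alpha_raw={kernel.alpha_raw:.6g} "
        f"alpha={alpha:.6g}"
        + (" (override)" if cfg.alpha_override is not None else "")
    )

    roaming = topology_priors.build_roaming(mi)
    log.append("roaming network built (column-stochastic transition)")

    seeding = topology_priors.build_seeding(
        mi, size=cfg.module_size, log_base=cfg.log_base_value
    )
    log.append(
        f"centres: |C|={len(seeding.centres)}, module size={seeding.module_size}"
    )

    stationary = np.zeros((n, n))
    mip = np.zeros((n, n))
    iterations = np.zeros(n, dtype=int)
    for g in range(n):
        p, its = rwr_inference.run_rwr(
            roaming.transition, seeding.p0[g], alpha, tol=cfg.tol, max_iter=cfg.max_iter
        )
        stationary[g] = p
        iterations[g] = its
        mip[g] = rwr_inference.score_pairs(p, roaming.transition, g)
    thresholds = np.array(
        [
            rwr_inference.adaptive_threshold(mip[g], alpha, coef=cfg.threshold_coef)
            for g in range(n)
        ]
    )
    scores = RWRScores(
        stationary=stationary, mip=mip, thresholds=thresholds, iterations=iterations
    )
    log.append(
        f"RWR: iterations min={iterations.min()} max={iterations.max()}"
    )

    raw_net = rwr_inference.assemble_network(
        mip, thresholds, expr.gene_ids, symmetrize=cfg.symmetrize
    )
    log.append(f"thresholded network: {len(raw_net.edges)} edges")

    if cfg.repair:
        net = mb_repair.repair_network(
            raw_net,
            expr,
            ci_eps=cfg.ci_eps,
            max_cond=cfg.max_cond,
            opts=opts,
            pc_symmetric=cfg.pc_symmetric,
        )
        n_isolated = len(mb_repair.find_isolated(raw_net))
        log.append(
            f"repair: {n_isolated} isolated genes reconnected; "
            f"{len(net.edges)} edges after repair"
        )
    else:
        net = raw_net
        log.append("repair skipped (--no-repair)")

    return PipelineResult(
        network=net,
        raw_network=raw_net,
        scores=scores,
        kernel=kernel,
        seeding=seeding,
        roaming=roaming,
        mi=mi,
        alpha=alpha,
        log=log,
    )
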