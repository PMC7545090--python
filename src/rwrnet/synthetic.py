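"""Synthetic benchmarks: chain / scale-free gold networks with linear-Gaussian data.

Undirected gold edges are oriented by ascending gene index (acyclic by
construction); each root gene is standard normal and each child is a weighted
sum of its parents plus Gaussian noise, so the conditional-independence
structure is known analytically.  Everything is bit-reproducible under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np

from .io_formats import ExpressionMatrix, GoldStandard

__all__ = ["SyntheticDataset", "generate_network", "simulate_expression", "make_fixture"]

FIXTURES = {
    # name: (topology, n_genes, n_samples, seed)
    "chain4": ("chain", 4, 100, 40),
    "chain8": ("chain", 8, 250, 80),
    "sf10": ("scale_free", 10, 10, 100),
    "sf50": ("scale_free", 50, 50, 500),
}


@dataclass
class SyntheticDataset:
    gold: GoldStandard
    expr: ExpressionMatrix
    params: dict


def _gene_ids(n: int) -> list[str]:
    return [f"G{i + 1}" for i in range(n)]


def generate_network(
    topology: str, n_genes: int, seed: int = 0, attach_m: int = 1
) -> GoldStandard:
    """Chain ({(i, i+1)}) or preferential-attachment gold network."""
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    if topology == "chain":
        edges = {(i, i + 1) for i in range(n_genes - 1)}
    elif topology == "scale_free":
        g = nx.barabasi_albert_graph(n_genes, attach_m, seed=seed)
        edges = {(min(a, b), max(a, b)) for a, b in g.edges()}
    else:
        raise ValueError(f"unknown topology {topology!r}")
    return GoldStandard(gene_ids=_gene_ids(n_genes), edges=frozenset(edges))


def simulate_expression(
    gold: GoldStandard,
    n_samples: int,
    noise_sd: float = 0.1,
    seed: int = 0,
    edge_weight_range: tuple[float, float] = (0.5, 1.5),
) -> ExpressionMatrix:
    """Linear-Gaussian structural model over the ascending-index orientation.

    Roots draw from N(0,1); a child is the weighted sum of its parents (weights
    uniform in ``edge_weight_range``) plus N(0, noise_sd^2) noise.  Columns are
    i.i.d. samples.
    """
    rng = np.random.default_rng(seed)
    n = gold.n_genes
    parents: dict[int, list[int]] = {j: [] for j in range(n)}
    for i, j in sorted(gold.edges):
        parents[j].append(i)
    weights = {
        (i, j): rng.uniform(*edge_weight_range)
        for j in range(n)
        for i in parents[j]
    }
    x = np.zeros((n, n_samples))
    for j in range(n):
        noise = rng.normal(size=n_samples)
        if parents[j]:
            x[j] = sum(weights[(i, j)] * x[i] for i in parents[j]) + noise_sd * noise
        else:
            x[j] = noise
    return ExpressionMatrix(gene_ids=list(gold.gene_ids), values=x)


def make_fixture(
    name: str, noise_sd: float = 0.1, seed: Optional[int] = None
) -> SyntheticDataset:
    """Canned datasets mirroring the benchmark sizes (chain4, chain8, sf10, sf50)."""
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    topology, n_genes, n_samples, default_seed = FIXTURES[name]
    seed = default_seed if seed is None else seed
    gold = generate_network(topology, n_genes, seed=seed)
    expr = simulate_expression(gold, n_samples, noise_sd=noise_sd, seed=seed)
    params = {
        "topology": topology,
        "n_genes": n_genes,
        "n_samples": n_samples,
        "noise_sd": noise_sd,
        "edge_weight_range": (0.5, 1.5),
        "seed": seed,
    }
    return SyntheticDataset(gold=gold, expr=expr, params=params)
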