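"""Text I/O: expression matrices, gold-standard networks, inferred networks, metric reports.

All formats are plain TSV/JSON.  Expression files carry gene identifiers in the
first column (``genes_rows``, the default) or in the header row (``genes_cols``).
Networks are exchanged as 3-column edge lists (``geneA<TAB>geneB<TAB>weight``)
or as raw square numeric adjacency matrices.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GoldStandard",
    "read_expression",
    "read_gold_standard",
    "write_network",
    "write_metrics",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with gene identifiers.

    Row order defines the gene index used by every downstream matrix.
    """

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, m = self.values.shape
        if len(self.gene_ids) != n:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n} rows of expression"
            )
        dupes = _duplicates(self.gene_ids)
        if dupes:
            raise ValueError(f"duplicate gene ids: {sorted(dupes)}")
        if n < 2 or m < 2:
            raise ValueError(f"need at least 2 genes and 2 samples, got {n}x{m}")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def index_of(self, gene: str) -> int:
        return self.gene_ids.index(gene)


@dataclass
class GoldStandard:
    """Undirected reference network as a set of unordered index pairs (i < j)."""

    gene_ids: list[str]
    edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        edges = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-pair ({a},{b}) in gold standard")
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"edge index out of range: ({a},{b}) for N={n}")
            edges.add((min(a, b), max(a, b)))
        self.edges = frozenset(edges)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def __len__(self) -> int:
        return len(self.edges)


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for x in items:
        if x in seen:
            dupes.add(x)
        seen.add(x)
    return dupes


def read_expression(path, orientation: str = "genes_rows") -> ExpressionMatrix:
    """Read a TSV expression matrix into genes x samples orientation.

    ``genes_rows``: first column holds gene ids, header row holds sample ids.
    ``genes_cols``: header row holds gene ids, first column holds sample ids;
    the matrix is transposed on load.
    """
    if orientation not in ("genes_rows", "genes_cols"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if orientation == "genes_cols":
        df = df.T
    gene_ids = [str(g) for g in df.index]
    dupes = _duplicates(gene_ids)
    if dupes:
        raise ValueError(f"duplicate gene ids in {path}: {sorted(dupes)}")
    values = np.empty(df.shape, dtype=float)
    for jc, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            gene = df.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"non-numeric cell in {path} at gene {gene!r}, column {col!r}"
            )
        values[:, jc] = converted.to_numpy()
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError(
            f"{path}: need at least 2 genes and 2 samples, "
            f"got {values.shape[0]}x{values.shape[1]}"
        )
    return ExpressionMatrix(gene_ids=gene_ids, values=values)


def _parse_rows(path) -> list[list[str]]:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t") if "\t" in line else line.split())
    return rows


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_gold_standard(path, gene_ids: Sequence[str]) -> GoldStandard:
    """Read a reference network: 2/3-column edge list or square adjacency.

    Edge-list direction is collapsed; rows labelled 0 are ignored.  Adjacency
    matrices are binarised at > 0 and symmetrised by logical OR (with a
    warning) when asymmetric.  Lines starting with '#' are comments.
    """
    gene_ids = [str(g) for g in gene_ids]
    n = len(gene_ids)
    rows = _parse_rows(path)
    if not rows:
        return GoldStandard(gene_ids=list(gene_ids), edges=frozenset())

    looks_adjacency = all(
        len(r) == n and all(_is_number(tok) for tok in r) for r in rows
    )
    if looks_adjacency:
        if len(rows) != n:
            raise ValueError(
                f"{path}: adjacency matrix is {len(rows)}x{n}, expected {n}x{n}"
            )
        mat = np.array([[float(tok) for tok in r] for r in rows])
        adj = mat > 0
        np.fill_diagonal(adj, False)
        if not np.array_equal(adj, adj.T):
            warnings.warn(
                f"{path}: adjacency not symmetric after binarisation; "
                "symmetrising by logical OR"
            )
            adj |= adj.T
        ii, jj = np.nonzero(np.triu(adj, 1))
        return GoldStandard(
            gene_ids=list(gene_ids),
            edges=frozenset(zip(ii.tolist(), jj.tolist())),
        )

    index = {g: i for i, g in enumerate(gene_ids)}
    edges = set()
    for r in rows:
        if len(r) not in (2, 3):
            raise ValueError(f"{path}: expected 2 or 3 columns, got {r!r}")
        a, b = r[0], r[1]
        for name in (a, b):
            if name not in index:
                raise ValueError(f"{path}: unknown gene name {name!r}")
        if len(r) == 3:
            if not _is_number(r[2]):
                raise ValueError(f"{path}: non-numeric edge label {r[2]!r}")
            if float(r[2]) <= 0:
                continue
        i, j = index[a], index[b]
        if i == j:
            warnings.warn(f"{path}: ignoring self-pair {a!r}")
            continue
        edges.add((min(i, j), max(i, j)))
    return GoldStandard(gene_ids=list(gene_ids), edges=frozenset(edges))


def write_network(net, path, scores=None) -> None:
    """Write an inferred network as a deterministic 3-column edge list.

    When ``scores`` (an :class:`rwrnet.rwr_inference.RWRScores`) is given the
    weight column holds the symmetrised score ``max(MIP[i,j], MIP[j,i])``;
    otherwise every edge gets weight 1.  Rows are sorted by descending weight
    then lexicographically, floats printed with 6 significant digits.
    """
    gene_ids = net.gene_ids
    records = []
    for i, j in net.edges:
        if scores is not None:
            w = max(scores.mip[i, j], scores.mip[j, i])
        else:
            w = 1.0
        records.append((gene_ids[i], gene_ids[j], float(w)))
    records.sort(key=lambda r: (-r[2], r[0], r[1]))
    lines = ["# gene_a\tgene_b\tweight"]
    for a, b, w in records:
        lines.append(f"{a}\t{b}\t{w:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_metrics(report, path) -> None:
    """Write a metrics report as JSON {TP, FP, TN, FN, TPR, FPR, PPV, ACC}."""
    c = report.counts
    payload = {
        "TP": c.tp,
        "FP": c.fp,
        "TN": c.tn,
        "FN": c.fn,
        "TPR": report.tpr,
        "FPR": report.fpr,
        "PPV": report.ppv,
        "ACC": report.acc,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
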