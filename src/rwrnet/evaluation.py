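"""Confusion counts and TPR/FPR/PPV/ACC over unordered gene pairs.

Direction is ignored: the universe is the N(N-1)/2 unordered pairs of the
gene panel.  Ratios with a zero denominator are reported as 0 and flagged
instead of producing NaN.  Display values use half-up rounding to 3 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

__all__ = ["ConfusionCounts", "MetricsReport", "confusion", "confusion_from_counts", "metrics"]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    n_genes: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        total = self.n_genes * (self.n_genes - 1) // 2
        if self.tp + self.fp + self.tn + self.fn != total:
            raise ValueError(
                f"counts sum to {self.tp + self.fp + self.tn + self.fn}, "
                f"expected C({self.n_genes},2) = {total}"
            )

    @property
    def total_pairs(self) -> int:
        return self.n_genes * (self.n_genes - 1) // 2


@dataclass
class MetricsReport:
    tpr: float
    fpr: float
    ppv: float
    acc: float
    counts: ConfusionCounts
    undefined: list[str] = field(default_factory=list)

    def rounded(self, decimals: int = 3) -> dict[str, float]:
        """Half-up rounding, matching the precision of printed benchmark tables."""
        q = Decimal(1).scaleb(-decimals)
        return {
            name: float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
            for name, value in (
                ("TPR", self.tpr),
                ("FPR", self.fpr),
                ("PPV", self.ppv),
                ("ACC", self.acc),
            )
        }


def confusion(pred, gold) -> ConfusionCounts:
    """Count TP/FP/TN/FN between a predicted network and a gold standard.

    Both must be defined over the same ordered gene panel.
    """
    if list(pred.gene_ids) != list(gold.gene_ids):
        diff = set(pred.gene_ids) ^ set(gold.gene_ids)
        raise ValueError(f"gene panels differ; symmetric difference: {sorted(diff)}")
    n = len(pred.gene_ids)
    p, g = set(pred.edges), set(gold.edges)
    tp = len(p & g)
    fp = len(p - g)
    fn = len(g - p)
    tn = n * (n - 1) // 2 - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, n_genes=n)


def confusion_from_counts(tp: int, fp: int, n_genes: int, n_gold_edges: int) -> ConfusionCounts:
    """Complete a confusion table from TP/FP, the panel size and the gold size.

    FN = gold edges - TP; TN = C(N,2) - gold edges - FP.
    """
    fn = n_gold_edges - tp
    tn = n_genes * (n_genes - 1) // 2 - n_gold_edges - fp
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, n_genes=n_genes)


def _ratio(num: int, den: int, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts) -> MetricsReport:
    """TPR = TP/(TP+FN), FPR = FP/(FP+TN), PPV = TP/(TP+FP), ACC = (TP+TN)/all."""
    undefined: list[str] = []
    tpr = _ratio(c.tp, c.tp + c.fn, "TPR", undefined)
    fpr = _ratio(c.fp, c.fp + c.tn, "FPR", undefined)
    ppv = _ratio(c.tp, c.tp + c.fp, "PPV", undefined)
    acc = _ratio(c.tp + c.tn, c.total_pairs, "ACC", undefined)
    return MetricsReport(tpr=tpr, fpr=fpr, ppv=ppv, acc=acc, counts=c, undefined=undefined)
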