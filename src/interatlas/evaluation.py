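"""Scoring a reconstructed atlas against the ground truth.

With ~10^4 true edges among ~10^7 candidate pairs the positive class is
vanishingly rare, so the headline metric is the area under the
precision-recall curve (average precision); a random classifier's AUC of
PRC equals the positive-class prevalence, which anchors fold-improvement
claims.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

from .pathway_atlas import Atlas

__all__ = [
    "PRResult",
    "candidate_pair_count",
    "baseline_prevalence",
    "auc_prc",
    "confusion_counts",
    "write_report",
]


def candidate_pair_count(n_nodes: int) -> int:
    """Number of unordered candidate pairs among ``n_nodes`` genes."""
    if n_nodes < 2:
        raise ValueError("need at least two nodes")
    return n_nodes * (n_nodes - 1) // 2


@dataclass
class PRResult:
    points: list[tuple[float, float]]  # (recall, precision) per threshold group
    auc: float
    baseline: float
    n_pairs: int
    n_true: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC outside [0, 1]")
        for i in range(1, len(self.points)):
            if self.points[i][0] < self.points[i - 1][0] - 1e-12:
                raise ValueError("recall must be nondecreasing")

    @property
    def fold_over_baseline(self) -> float:
        return self.auc / self.baseline


def baseline_prevalence(n_nodes: int, n_true_edges: int) -> float:
    """Positive-class prevalence: true edges over all candidate pairs."""
    n_pairs = candidate_pair_count(n_nodes)
    if not (0 < n_true_edges <= n_pairs):
        raise ValueError(
            f"n_true_edges must be in 1..{n_pairs}, got {n_true_edges}"
        )
    return n_true_edges / n_pairs


def auc_prc(
    scores: Mapping[tuple[str, str], float], truth: Atlas
) -> PRResult:
    """Average precision of the score ranking over all candidate pairs.

    Every unordered pair of truth nodes is a candidate; pairs absent from
    ``scores`` score 0. Pairs sharing a score enter as one threshold group
    and contribute the group's cumulative precision — the convention under
    which a constant scorer recovers the class prevalence exactly, so the
    dominant all-zero group is never ordered arbitrarily.
    """
    if not truth.edges:
        raise ValueError("truth atlas has no edges")
    nodes = truth.nodes
    n = len(nodes)
    n_pairs = n * (n - 1) // 2
    n_true = len(truth.edges)

    grouped: dict[float, list[int]] = {}  # score -> [count, true count]
    n_scored_nonzero = 0
    tp_nonzero = 0
    for pair, s in scores.items():
        a, b = pair
        if a not in nodes or b not in nodes:
            raise KeyError(f"scored pair {pair} references unknown node")
        key = (a, b) if a < b else (b, a)
        s = float(s)
        if s == 0.0:
            continue  # folds into the implicit zero group
        rec = grouped.setdefault(s, [0, 0])
        rec[0] += 1
        is_true = key in truth.edges
        rec[1] += int(is_true)
        n_scored_nonzero += 1
        tp_nonzero += int(is_true)

    points: list[tuple[float, float]] = []
    ap = 0.0
    cum_n = 0
    cum_tp = 0
    for s in sorted(grouped, reverse=True):
        cnt, tp = grouped[s]
        cum_n += cnt
        cum_tp += tp
        prec = cum_tp / cum_n
        ap += tp * prec
        points.append((cum_tp / n_true, prec))
    # implicit zero-score group: everything not scored above
    zero_n = n_pairs - cum_n
    zero_tp = n_true - cum_tp
    if zero_n > 0:
        cum_n += zero_n
        cum_tp += zero_tp
        prec = cum_tp / cum_n
        ap += zero_tp * prec
        points.append((1.0, prec))
    ap /= n_true
    return PRResult(
        points=points,
        auc=ap,
        baseline=n_true / n_pairs,
        n_pairs=n_pairs,
        n_true=n_true,
    )


def confusion_counts(
    predicted: Atlas, truth: Atlas
) -> tuple[int, int, int]:
    """(TP, FP, FN) of the predicted edge set against the truth."""
    if predicted.nodes != truth.nodes:
        raise ValueError("predicted and truth atlases must share one node set")
    tp = len(predicted.edges & truth.edges)
    fp = len(predicted.edges - truth.edges)
    fn = len(truth.edges - predicted.edges)
    return tp, fp, fn


def write_report(
    result: PRResult,
    confusion: tuple[int, int, int] | None,
    path: str | Path,
) -> None:
    report = {
        "auc_prc": float(result.auc),
        "baseline": float(result.baseline),
        "fold_over_baseline": float(result.fold_over_baseline),
        "n_pairs": int(result.n_pairs),
        "n_true": int(result.n_true),
    }
    if confusion is not None:
        report["TP"], report["FP"], report["FN"] = (
            int(x) for x in confusion
        )
    with open(path, "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=False)
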