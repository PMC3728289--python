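"""Scoring inferred networks against a reference.

Confusion metrics over ordered (or unordered) node pairs, ROC / PR AUC of
ranked edge scores, a three-class (activation / none / inhibition) AUC,
permutation null models with empirical p-values, and transitive-closure
utilities.  Reported specificity/sensitivity/precision/accuracy are
rounded to two decimals (half away from zero), matching the convention of
published evaluation tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable

import networkx as nx
import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .network import SignalingNetwork

__all__ = [
    "EvaluationReport",
    "confusion_metrics",
    "roc_pr_auc",
    "roc_pr_curve_points",
    "three_class_auc",
    "permutation_baseline",
    "PermutationResult",
    "transitive_closure",
]


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class EvaluationReport:
    """Confusion counts and derived metrics for one comparison."""

    tp: int
    tn: int
    fp: int
    fn: int
    sp: float
    sn: float
    pr: float
    ac: float
    mode: str = "directed"
    auc_roc: float | None = None
    auc_pr: float | None = None
    p_values: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_counts(cls, tp: int, tn: int, fp: int, fn: int, mode: str = "directed") -> "EvaluationReport":
        """Derive SP/SN/PR/AC (two decimals) from confusion counts."""
        sp = tn / (tn + fp) if tn + fp else float("nan")
        sn = tp / (tp + fn) if tp + fn else float("nan")
        pr = tp / (tp + fp) if tp + fp else float("nan")
        total = tp + tn + fp + fn
        ac = (tp + tn) / total if total else float("nan")
        return cls(tp=tp, tn=tn, fp=fp, fn=fn,
                   sp=_round2(sp), sn=_round2(sn), pr=_round2(pr), ac=_round2(ac),
                   mode=mode)

    def check_identities(self) -> None:
        ref = EvaluationReport.from_counts(self.tp, self.tn, self.fp, self.fn, self.mode)
        for name in ("sp", "sn", "pr", "ac"):
            got, want = getattr(self, name), getattr(ref, name)
            if not (np.isnan(got) and np.isnan(want)) and got != want:
                raise AssertionError(f"{name} = {got} inconsistent with counts ({want})")

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in ("mode", "tp", "tn", "fp", "fn", "sp", "sn", "pr", "ac")}
        if self.auc_roc is not None:
            d["auc_roc"] = self.auc_roc
        if self.auc_pr is not None:
            d["auc_pr"] = self.auc_pr
        if self.p_values:
            d["p_values"] = self.p_values
        return json.dumps(d, indent=2)

    def to_text(self) -> str:
        lines = [
            f"mode: {self.mode}",
            f"  TP {self.tp:5d}   FP {self.fp:5d}",
            f"  FN {self.fn:5d}   TN {self.tn:5d}",
            f"  SP {self.sp:.2f}  SN {self.sn:.2f}  PR {self.pr:.2f}  AC {self.ac:.2f}",
        ]
        if self.auc_roc is not None:
            lines.append(f"  AUC-ROC {self.auc_roc:.3f}" +
                         (f"  AUC-PR {self.auc_pr:.3f}" if self.auc_pr is not None else ""))
        return "\n".join(lines)


def _check_nodes(pred: SignalingNetwork, ref: SignalingNetwork) -> None:
    if set(pred.nodes) != set(ref.nodes):
        diff = sorted(set(pred.nodes) ^ set(ref.nodes))
        raise ValueError(f"node sets differ; symmetric difference: {diff}")


def _aligned_ref_weights(pred: SignalingNetwork, ref: SignalingNetwork) -> np.ndarray:
    """Reference weights reindexed to the prediction's node order."""
    perm = [ref.index(lab) for lab in pred.nodes]
    return ref.weights[np.ix_(perm, perm)]


def confusion_metrics(
    pred: SignalingNetwork, ref: SignalingNetwork, mode: str = "directed"
) -> EvaluationReport:
    """Edge-level confusion metrics.

    ``directed`` scores every ordered off-diagonal pair.  ``unsigned``
    (undirected) scores unordered pairs, an edge being present when either
    direction is.  ``rep`` relaxes the truth for a predicted edge (a, b):
    it counts as TP when the reference contains (a, b), (b, a), or a
    directed path a ~> b; symmetrically, a reference edge only counts as
    missed (FN) when no predicted edge explains it under the same relaxed
    rule (direct, reversed, or a predicted path).
    """
    _check_nodes(pred, ref)
    rw = _aligned_ref_weights(pred, ref)
    pw = pred.weights
    n = pred.n
    off = ~np.eye(n, dtype=bool)

    if mode == "directed":
        p = pw != 0
        t = rw != 0
        tp = int(np.sum(p & t & off))
        fp = int(np.sum(p & ~t & off))
        fn = int(np.sum(~p & t & off))
        tn = int(np.sum(~p & ~t & off))
    elif mode == "unsigned":
        p = (pw != 0) | (pw.T != 0)
        t = (rw != 0) | (rw.T != 0)
        iu = np.triu_indices(n, k=1)
        tp = int(np.sum(p[iu] & t[iu]))
        fp = int(np.sum(p[iu] & ~t[iu]))
        fn = int(np.sum(~p[iu] & t[iu]))
        tn = int(np.sum(~p[iu] & ~t[iu]))
    elif mode == "rep":
        reach_ref = _reachability(rw != 0)
        relaxed_truth = (rw != 0) | (rw.T != 0) | reach_ref
        p = pw != 0
        tp = int(np.sum(p & relaxed_truth & off))
        fp = int(np.sum(p & ~relaxed_truth & off))
        # A reference edge is found if any predicted edge explains it.
        reach_pred = _reachability(pw != 0)
        relaxed_pred = p | p.T | reach_pred
        ref_edges = (rw != 0) & off
        found = relaxed_pred & ref_edges
        fn = int(np.sum(ref_edges & ~found))
        tn = int(off.sum()) - tp - fp - fn
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    return EvaluationReport.from_counts(tp, tn, fp, fn, mode=mode)


def _reachability(adj: np.ndarray) -> np.ndarray:
    """Boolean reachability (path of length >= 1) matrix."""
    g = nx.from_numpy_array(adj.astype(int), create_using=nx.DiGraph)
    closure = nx.transitive_closure(g, reflexive=False)
    n = adj.shape[0]
    out = np.zeros((n, n), dtype=bool)
    for a, b in closure.edges:
        out[a, b] = True
    return out


def _off_diagonal(values: np.ndarray) -> np.ndarray:
    n = values.shape[0]
    return values[~np.eye(n, dtype=bool)]


def roc_pr_auc(
    weights: np.ndarray | SignalingNetwork,
    ref: SignalingNetwork | np.ndarray,
) -> tuple[float, float]:
    """ROC AUC and average-precision of |weight| as an edge score.

    One score per ordered off-diagonal pair; ties enter thresholds
    simultaneously (the standard rank-based treatment).  PR AUC is
    step-wise average precision, not trapezoidal interpolation.
    """
    w = weights.weights if isinstance(weights, SignalingNetwork) else np.asarray(weights, float)
    r = ref.weights if isinstance(ref, SignalingNetwork) else np.asarray(ref, float)
    if w.shape != r.shape:
        raise ValueError("prediction and reference shapes differ")
    scores = np.abs(_off_diagonal(w))
    truth = (_off_diagonal(r) != 0).astype(int)
    if truth.min() == truth.max():
        raise ValueError("reference has a single class; AUC undefined")
    return float(roc_auc_score(truth, scores)), float(average_precision_score(truth, scores))


def three_class_auc(
    weights: np.ndarray | SignalingNetwork,
    ref: SignalingNetwork | np.ndarray,
) -> float:
    """Macro-averaged one-vs-rest AUC over {activation, none, inhibition}.

    Signed weights serve as class scores: ``w`` for activation, ``-w`` for
    inhibition and ``-|w|`` for absence.  Classes absent from the
    reference are skipped.
    """
    w = weights.weights if isinstance(weights, SignalingNetwork) else np.asarray(weights, float)
    r = ref.weights if isinstance(ref, SignalingNetwork) else np.asarray(ref, float)
    s = _off_diagonal(w)
    labels = np.sign(_off_diagonal(r)).astype(int)
    aucs = []
    for cls, score in ((1, s), (0, -np.abs(s)), (-1, -s)):
        mask = (labels == cls).astype(int)
        if mask.min() == mask.max():
            continue  # class absent (or universal); skip
        aucs.append(roc_auc_score(mask, score))
    if not aucs:
        raise ValueError("no scorable class in the reference")
    return float(np.mean(aucs))


def roc_pr_curve_points(
    weights: np.ndarray | SignalingNetwork,
    ref: SignalingNetwork | np.ndarray,
):
    """ROC and PR curve coordinates for plotting, as two DataFrames
    (fpr/tpr/threshold and recall/precision)."""
    import pandas as pd
    from sklearn.metrics import precision_recall_curve, roc_curve

    w = weights.weights if isinstance(weights, SignalingNetwork) else np.asarray(weights, float)
    r = ref.weights if isinstance(ref, SignalingNetwork) else np.asarray(ref, float)
    scores = np.abs(_off_diagonal(w))
    truth = (_off_diagonal(r) != 0).astype(int)
    fpr, tpr, thr = roc_curve(truth, scores)
    prec, rec, _ = precision_recall_curve(truth, scores)
    roc_df = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    pr_df = pd.DataFrame({"recall": rec, "precision": prec})
    return roc_df, pr_df


@dataclass
class PermutationResult:
    null: np.ndarray
    observed: float | None
    p_value: float | None


def permutation_baseline(
    ref: SignalingNetwork,
    metric: Callable[[SignalingNetwork, SignalingNetwork], float],
    observed: float | None = None,
    n_perm: int = 100,
    seed: int = 0,
) -> PermutationResult:
    """Random-guessing null: relocate the reference's edges uniformly.

    Each permutation places the reference's edge weights on an
    edge-count-preserving uniform draw of off-diagonal slots and scores it
    with ``metric`` against the (unpermuted) reference.  The empirical
    p-value is ``(1 + #{null >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n = ref.n
    slots = [(j, i) for j in range(n) for i in range(n) if j != i]
    edge_weights = [w for (_, _, w) in ref.edges()]
    null = np.empty(n_perm)
    for t in range(n_perm):
        chosen = rng.choice(len(slots), size=len(edge_weights), replace=False)
        wmat = np.zeros((n, n))
        order = rng.permutation(len(edge_weights))
        for c, o in zip(chosen, order):
            j, i = slots[int(c)]
            wmat[j, i] = edge_weights[int(o)]
        perm_net = SignalingNetwork(list(ref.nodes), wmat, np.zeros(n))
        null[t] = metric(perm_net, ref)
    p = None
    if observed is not None:
        p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    return PermutationResult(null=null, observed=observed, p_value=p)


def transitive_closure(net: SignalingNetwork) -> SignalingNetwork:
    """Unsigned reachability closure: edge a -> b iff a directed path a ~> b."""
    reach = _reachability(net.weights != 0)
    np.fill_diagonal(reach, False)  # self-reachability on cycles is not an edge
    return SignalingNetwork(
        list(net.nodes), reach.astype(float), np.zeros(net.n),
        net.sources, net.sinks,
    )
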