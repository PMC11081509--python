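"""Scoring reconstructions against ground truth; thresholds and consensus.

Edge-level evaluation treats the reconstruction task as ranking all ordered
off-diagonal pairs by score. Because true connectivity is sparse the task is
heavily imbalanced, so the headline metric is the average precision score
(APS, the step-wise integral of the precision-recall curve); the Matthews
correlation coefficient (MCC) is used for thresholded graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spike_trains import SpikeTrainSet, jitter_surrogate

__all__ = [
    "PrCurve", "EvaluationReport", "ThresholdSpec",
    "precision_recall_curve", "average_precision", "matthews_cc",
    "best_mcc_threshold", "surrogate_alpha_threshold", "consensus_overlap",
    "evaluate_scores",
]


@dataclass
class PrCurve:
    thresholds: np.ndarray  # descending score thresholds
    precision: np.ndarray
    recall: np.ndarray
    prevalence: float


@dataclass
class EvaluationReport:
    aps: float
    mcc_best: float
    threshold_best: float
    confusion: dict
    per_class: dict = field(default_factory=dict)


@dataclass
class ThresholdSpec:
    alpha: float
    threshold: float
    n_surrogates: int
    jitter_ms: float

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _flatten(S, gt, mask):
    S = np.asarray(S, dtype=float)
    gt = np.asarray(gt)
    if mask is None:
        mask = ~np.eye(S.shape[0], dtype=bool)
    y_true = (gt[mask] != 0).astype(int)
    y_score = S[mask]
    return y_score, y_true


def precision_recall_curve(S, gt, mask=None) -> PrCurve:
    """PR curve over all distinct score values, descending.

    ``gt`` is binarized (any nonzero entry = connection); the diagonal (or a
    caller-supplied mask complement) is excluded.
    """
    y_score, y_true = _flatten(S, gt, mask)
    if y_true.sum() == 0:
        raise ValueError("no positives in ground truth; PR curve undefined")
    order = np.argsort(-y_score, kind="stable")
    ys, yt = y_score[order], y_true[order]
    tp_cum = np.cumsum(yt)
    # one point per distinct score value: predict s >= value
    run_end = np.concatenate([np.flatnonzero(np.diff(ys) != 0),
                              [ys.size - 1]])
    tp = tp_cum[run_end].astype(float)
    npred = run_end + 1.0
    prec = tp / npred
    rec = tp / yt.sum()
    return PrCurve(thresholds=ys[run_end], precision=prec, recall=rec,
                   prevalence=float(y_true.mean()))


def average_precision(curve: PrCurve) -> float:
    """Step-wise integral sum_k (R_k - R_{k-1}) * P_k, no interpolation."""
    r = np.concatenate([[0.0], curve.recall])
    return float(np.sum(np.diff(r) * curve.precision))


def _confusion(pred, gt, mask):
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt) != 0
    if mask is None:
        mask = ~np.eye(pred.shape[0], dtype=bool)
    p, g = pred[mask], gt[mask]
    tp = int(np.sum(p & g))
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    tn = int(np.sum(~p & ~g))
    return tp, fp, fn, tn


def mcc_from_confusion(tp: int, fp: int, fn: int, tn: int) -> float:
    """MCC from confusion counts; any zero marginal gives 0 by convention."""
    denom = ((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def matthews_cc(pred, gt, mask=None) -> float:
    """Matthews correlation coefficient between binary directed graphs."""
    return mcc_from_confusion(*_confusion(pred, gt, mask))


def best_mcc_threshold(S, gt, mask=None):
    """Scan all distinct score values; return (threshold, best MCC).

    An edge is predicted when ``s > threshold``. Ties in MCC are broken
    toward the smallest threshold (the densest graph).
    """
    y_score, y_true = _flatten(S, gt, mask)
    order = np.argsort(-y_score, kind="stable")
    ys, yt = y_score[order], y_true[order]
    n_pos = int(yt.sum())
    n = yt.size
    tp_cum = np.cumsum(yt)
    # candidate thresholds: each distinct value v, predicting s > v
    distinct_last = np.flatnonzero(np.diff(ys) != 0)  # last index of a run
    cand = np.concatenate([distinct_last, [n - 1]])
    best = (-2.0, None)
    for k in cand:
        thr = ys[k]
        # predictions: strictly greater than thr -> all indices before the
        # run containing k
        m = int(np.searchsorted(-ys, -thr, side="left"))
        tp = int(tp_cum[m - 1]) if m > 0 else 0
        fp = m - tp
        fn = n_pos - tp
        tn = n - m - fn
        v = mcc_from_confusion(tp, fp, fn, tn)
        if v > best[0] or (v == best[0] and best[1] is not None
                           and thr < best[1]):
            best = (v, float(thr))
    return best[1], best[0]


def evaluate_scores(S, gt, mask=None, ei_labels=None) -> EvaluationReport:
    """Full report: APS, best-MCC threshold and per-class (E/I) variants.

    Per-class metrics restrict the positives to one connection class while
    keeping all negatives.
    """
    curve = precision_recall_curve(S, gt, mask)
    aps = average_precision(curve)
    thr, mcc = best_mcc_threshold(S, gt, mask)
    pred = np.asarray(S) > thr
    tp, fp, fn, tn = _confusion(pred, gt, mask)
    per_class = {}
    gt_arr = np.asarray(gt, dtype=float)
    for cls, sel in (("E", gt_arr > 0), ("I", gt_arr < 0)):
        sub = np.where(sel | (gt_arr == 0), gt_arr, 0.0)
        if np.any(sub[mask if mask is not None else
                      ~np.eye(sub.shape[0], dtype=bool)] != 0):
            c = precision_recall_curve(S, sub, mask)
            t_c, m_c = best_mcc_threshold(S, sub, mask)
            per_class[cls] = dict(aps=average_precision(c), mcc=m_c)
    return EvaluationReport(aps=aps, mcc_best=mcc, threshold_best=thr,
                            confusion=dict(tp=tp, fp=fp, fn=fn, tn=tn),
                            per_class=per_class)


def surrogate_alpha_threshold(method_runner, sts: SpikeTrainSet,
                              alpha: float = 0.01, n_surrogates: int = 20,
                              jitter_ms: float = 10.0,
                              seed: int = 0) -> ThresholdSpec:
    """Score threshold at significance alpha from jittered surrogates.

    The method is re-run on ``n_surrogates`` jittered copies of the
    recording; all off-diagonal surrogate scores are pooled and the
    threshold is their empirical (1 - alpha) quantile.
    """
    if n_surrogates < 2:
        raise ValueError("n_surrogates must be >= 2")
    pooled = []
    for k in range(n_surrogates):
        surr = jitter_surrogate(sts, jitter_ms, seed=seed * 99991 + k)
        res = method_runner(surr)
        pooled.append(res.S[res.offdiag_mask()])
    pooled = np.concatenate(pooled)
    pooled = pooled[np.isfinite(pooled)]
    thr = float(np.quantile(pooled, 1.0 - alpha))
    return ThresholdSpec(alpha=alpha, threshold=thr,
                         n_surrogates=n_surrogates, jitter_ms=jitter_ms)


def consensus_overlap(reference_edges, method_graphs) -> np.ndarray:
    """Histogram over 0..k of how many method graphs contain each reference
    edge."""
    ref = np.asarray(reference_edges).astype(bool)
    k = len(method_graphs)
    count = np.zeros_like(ref, dtype=int)
    for g in method_graphs:
        g = np.asarray(g).astype(bool)
        if g.shape != ref.shape:
            raise ValueError("graph shape mismatch")
        count += g
    hist = np.bincount(count[ref], minlength=k + 1)
    return hist
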