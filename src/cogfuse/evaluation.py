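"""Metrics and statistical comparison against the text baseline.

Macro-averaged precision, recall and F1 from per-class confusion counts
(0/0 conventions resolve to 0, penalizing never-predicted classes under
label imbalance). Model comparisons use a paired bootstrap over test
sentences: sentences are resampled with replacement, the run-averaged
macro-F1 difference is recomputed per resample, and the one-sided p-value is
the fraction of resamples in which the advantage disappears. Family-wise
error is controlled with a Bonferroni correction: reject only when
p < alpha / N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

Label = object  # int for single-label, frozenset[int] for multi-label


@dataclass
class ConfusionCounts:
    """Per-class TP/FP/FN/TN over a prediction set."""

    classes: list
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray


@dataclass
class SignificanceConfig:
    alpha: float = 0.05
    n_hypotheses: int = 18
    n_boot: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_hypotheses < 1:
            raise ValueError("n_hypotheses must be >= 1")


def _as_sets(seq: list, multilabel: bool) -> list:
    if multilabel:
        return [frozenset(x) for x in seq]
    return list(seq)


def confusion_counts(predictions: list, truths: list, classes: list) -> ConfusionCounts:
    if len(predictions) != len(truths):
        raise ValueError("prediction/truth length mismatch")
    multilabel = any(isinstance(t, (set, frozenset)) for t in truths) or any(
        isinstance(p, (set, frozenset)) for p in predictions
    )
    preds = _as_sets(predictions, multilabel)
    trues = _as_sets(truths, multilabel)
    if not multilabel:
        known = set(classes)
        for p in preds:
            if p not in known:
                raise ValueError(f"prediction {p!r} outside class set")
    k = len(classes)
    tp = np.zeros(k)
    fp = np.zeros(k)
    fn = np.zeros(k)
    tn = np.zeros(k)
    for i, c in enumerate(classes):
        for p, t in zip(preds, trues):
            hit_p = (c in p) if multilabel else (p == c)
            hit_t = (c in t) if multilabel else (t == c)
            tp[i] += hit_p and hit_t
            fp[i] += hit_p and not hit_t
            fn[i] += hit_t and not hit_p
            tn[i] += not hit_p and not hit_t
    return ConfusionCounts(list(classes), tp, fp, fn, tn)


def macro_prf(predictions: list, truths: list, classes: list) -> tuple[float, float, float]:
    """Macro-averaged (precision, recall, F1); 0/0 ratios are defined as 0."""
    cc = confusion_counts(predictions, truths, classes)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(cc.tp + cc.fp > 0, cc.tp / (cc.tp + cc.fp), 0.0)
        r = np.where(cc.tp + cc.fn > 0, cc.tp / (cc.tp + cc.fn), 0.0)
        f1 = np.where(p + r > 0, 2 * p * r / (p + r), 0.0)
    return float(p.mean()), float(r.mean()), float(f1.mean())


def _normalize_runs(preds) -> list[list]:
    """Accept a flat prediction list (one run) or a list of per-run lists."""
    if preds and isinstance(preds[0], list):
        return preds
    return [list(preds)]


def bootstrap_pvalue(
    system_predictions,
    baseline_predictions,
    truths,
    config: SignificanceConfig,
    classes: list,
) -> float:
    """Paired sentence-level bootstrap p-value for system > baseline macro-F1.

    Arguments are aligned per run: for each run the two systems predicted the
    same test sentences. Each resample redraws sentences with replacement
    (per run), recomputes the run-averaged macro-F1 difference, and the
    p-value is the add-one-smoothed fraction of resamples with difference
    <= 0. Deterministic given `config.seed`.
    """
    sys_runs = _normalize_runs(system_predictions)
    base_runs = _normalize_runs(baseline_predictions)
    true_runs = _normalize_runs(truths)
    if not (len(sys_runs) == len(base_runs) == len(true_runs)):
        raise ValueError("run counts differ between systems")
    for s, b, t in zip(sys_runs, base_runs, true_runs):
        if not (len(s) == len(b) == len(t)):
            raise ValueError("misaligned prediction sets within a run")
    rng = np.random.default_rng(config.seed)
    runs = [
        (_indicators(s, classes), _indicators(b, classes), _indicators(t, classes))
        for s, b, t in zip(sys_runs, base_runs, true_runs)
    ]
    worse = 0
    for _ in range(config.n_boot):
        deltas = []
        for s_ind, b_ind, t_ind in runs:
            idx = rng.integers(t_ind.shape[0], size=t_ind.shape[0])
            t_star = t_ind[idx]
            deltas.append(_macro_f1_ind(s_ind[idx], t_star) - _macro_f1_ind(b_ind[idx], t_star))
        if np.mean(deltas) <= 0:
            worse += 1
    return (worse + 1) / (config.n_boot + 1)


def _indicators(labels: list, classes: list) -> np.ndarray:
    """n x k binary indicator matrix (works for class ids and label sets)."""
    pos = {c: j for j, c in enumerate(classes)}
    out = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        if isinstance(lab, (set, frozenset)):
            for c in lab:
                out[i, pos[c]] = 1.0
        else:
            out[i, pos[lab]] = 1.0
    return out


def _macro_f1_ind(pred: np.ndarray, true: np.ndarray) -> float:
    tp = (pred * true).sum(axis=0)
    fp = (pred * (1 - true)).sum(axis=0)
    fn = ((1 - pred) * true).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        r = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(p + r > 0, 2 * p * r / (p + r), 0.0)
    return float(f1.mean())


def bonferroni_reject(p: float, config: SignificanceConfig) -> tuple[bool, float]:
    """(reject, threshold) with threshold = alpha / N."""
    threshold = config.alpha / config.n_hypotheses
    return p < threshold, threshold
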