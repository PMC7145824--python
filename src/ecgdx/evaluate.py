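"""Multi-label evaluation statistics.

Conventions (documented once, used everywhere): a record is predicted
positive when its score is **at or above** the operating threshold; the
precision-recall curve has one point per distinct score value; average
precision uses the step-wise (rectangle) convention, identical to
summing precision at each positive's rank; undefined ratios (zero
denominators) are reported as NaN, never as zero; the F1-maximizing
threshold breaks ties toward the highest threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as spstats

from ecgdx.records import CLASSES

METRICS = ("precision", "recall", "specificity", "f1")


def _as_1d(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).astype(bool).ravel()
    if s.shape != y.shape:
        raise ValueError(f"scores {s.shape} and labels {y.shape} differ in length")
    return s, y


def pr_curve(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precision-recall points for one class.

    Returns ``(recall, precision, thresholds)`` with one entry per
    distinct score, ordered by rising threshold (recall non-increasing).
    Raises when the class has no positive labels (curve undefined).
    """
    s, y = _as_1d(scores, labels)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("precision-recall curve undefined without positive labels")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    # Last index of each run of equal scores = counts at threshold "score >= s".
    distinct = np.flatnonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])
    precision = tp[distinct] / (tp[distinct] + fp[distinct])
    recall = tp[distinct] / n_pos
    thresholds = s_sorted[distinct]
    # Ascending threshold order.
    return recall[::-1], precision[::-1], thresholds[::-1]


def select_threshold_max_f1(scores, labels) -> float:
    """Threshold (one of the observed scores) maximizing F1; ties break
    toward the highest threshold.

    F1 is computed directly from confusion counts (2TP / (2TP+FP+FN)) so
    exact ties are detected exactly.
    """
    s, y = _as_1d(scores, labels)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("F1 threshold selection undefined without positive labels")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    distinct = np.flatnonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])
    tp, fp = tp[distinct], fp[distinct]
    fn = n_pos - tp
    f1 = 2 * tp / (2 * tp + fp + fn)
    best = np.flatnonzero(f1 == f1.max())
    # distinct indices are in descending-threshold order: first hit wins.
    return float(s_sorted[distinct[best[0]]])


def _confusion(scores, labels, threshold: float) -> tuple[int, int, int, int]:
    s, y = _as_1d(scores, labels)
    pred = s >= threshold
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    return tp, fp, fn, tn


def _metrics_from_counts(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    def ratio(num, den):
        return num / den if den > 0 else np.nan

    precision = ratio(tp, tp + fp)
    recall = ratio(tp, tp + fn)
    specificity = ratio(tn, tn + fp)
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = np.nan if (np.isnan(precision) or np.isnan(recall)) else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "f1": f1,
    }


def class_scores(
    scores: np.ndarray, labels: np.ndarray, thresholds: Sequence[float]
) -> dict[str, dict]:
    """Per-class confusion counts and operating-point metrics.

    ``scores``/``labels`` are n x k matrices, ``thresholds`` one value
    per class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    k = scores.shape[1]
    if len(thresholds) != k:
        raise ValueError(f"need {k} thresholds, got {len(thresholds)}")
    names = CLASSES if k == len(CLASSES) else tuple(f"class{i}" for i in range(k))
    out: dict[str, dict] = {}
    for j, name in enumerate(names):
        tp, fp, fn, tn = _confusion(scores[:, j], labels[:, j], thresholds[j])
        entry = {"tp": tp, "fp": fp, "fn": fn, "tn": tn, "threshold": float(thresholds[j])}
        entry.update(_metrics_from_counts(tp, fp, fn, tn))
        out[name] = entry
    return out


def micro_average_precision(scores: np.ndarray, labels: np.ndarray) -> float:
    """Average precision on the flattened record x class pairs.

    Step-wise convention: AP = sum over ranked positives of precision at
    that rank, divided by the number of positives (ties in score share
    the precision of the full tied block).
    """
    s, y = _as_1d(scores, labels)
    if not y.any():
        raise ValueError("average precision undefined without positive labels")
    recall, precision, _ = pr_curve(s, y)
    # Descending-threshold order for the step sum.
    r = recall[::-1]
    p = precision[::-1]
    dr = np.diff(np.r_[0.0, r])
    return float(np.sum(p * dr))


def macro_average_precision(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean of per-class average precisions (the alternative reading)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    return float(
        np.mean([micro_average_precision(scores[:, j], labels[:, j]) for j in range(scores.shape[1])])
    )


def macro_f1(scores: np.ndarray, labels: np.ndarray, thresholds: Sequence[float]) -> float:
    """Unweighted mean of per-class F1 at the given thresholds (NaN-skipping)."""
    cs = class_scores(scores, labels, thresholds)
    return float(np.nanmean([v["f1"] for v in cs.values()]))


def bootstrap_scores(
    scores: np.ndarray,
    labels: np.ndarray,
    thresholds: Sequence[float],
    n_resamples: int = 1000,
    seed: int = 0,
    ci: float = 95.0,
) -> dict[str, dict[str, dict]]:
    """Bootstrap distributions of the per-class operating-point metrics.

    Each of the ``n_resamples`` resamples draws records with replacement
    at full size.  Resamples in which a metric is undefined (e.g. no
    positives drawn for a class) are recorded as NaN and excluded from
    the percentile interval — the documented convention.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    n, k = scores.shape
    rng = np.random.default_rng(seed)
    names = CLASSES if k == len(CLASSES) else tuple(f"class{i}" for i in range(k))
    dists = {name: {metric: np.empty(n_resamples) for metric in METRICS} for name in names}
    for b in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        cs = class_scores(scores[idx], labels[idx], thresholds)
        for name in names:
            for metric in METRICS:
                dists[name][metric][b] = cs[name][metric]
    point = class_scores(scores, labels, thresholds)
    alpha = (100.0 - ci) / 2.0
    out: dict[str, dict[str, dict]] = {}
    for name in names:
        out[name] = {}
        for metric in METRICS:
            d = dists[name][metric]
            finite = d[np.isfinite(d)]
            lo, hi = (
                (float(np.percentile(finite, alpha)), float(np.percentile(finite, 100 - alpha)))
                if finite.size
                else (np.nan, np.nan)
            )
            out[name][metric] = {
                "point": point[name][metric],
                "lo": lo,
                "hi": hi,
                "n_defined": int(finite.size),
                "distribution": d,
            }
    return out


def mcnemar_test(
    errors_a, errors_b, correction: bool = False, exact: str = "auto"
) -> tuple[float, float]:
    """McNemar test on paired misclassification indicators.

    ``b`` counts records A got wrong and B right, ``c`` the reverse.
    The statistic is ``(b-c)^2/(b+c)`` (continuity-corrected variant via
    ``correction=True``); with ``exact="auto"`` (default) an exact
    two-sided binomial test replaces the chi-square p-value when
    ``b + c < 25``.  No discordance returns (0.0, 1.0).
    """
    ea = np.asarray(errors_a).astype(bool)
    eb = np.asarray(errors_b).astype(bool)
    if ea.shape != eb.shape:
        raise ValueError("paired error indicators must have equal length")
    b = int(np.sum(ea & ~eb))
    c = int(np.sum(~ea & eb))
    if b + c == 0:
        return 0.0, 1.0
    if correction:
        statistic = (abs(b - c) - 1) ** 2 / (b + c)
    else:
        statistic = (b - c) ** 2 / (b + c)
    use_exact = exact == "always" or (exact == "auto" and b + c < 25)
    if use_exact:
        p = float(spstats.binomtest(min(b, c), b + c, 0.5, alternative="two-sided").pvalue)
    else:
        p = float(spstats.chi2.sf(statistic, df=1))
    return float(statistic), p


def cohen_kappa(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two binary raters.

    kappa = (p_o - p_e) / (1 - p_e).  Degenerate convention: when both
    raters are constant, kappa is 1.0 if they agree everywhere and 0.0
    otherwise.
    """
    a = np.asarray(labels_a).astype(bool)
    b = np.asarray(labels_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("ratings must have equal length")
    n = a.size
    if n == 0:
        raise ValueError("empty ratings")
    po = float(np.mean(a == b))
    pa1, pb1 = float(np.mean(a)), float(np.mean(b))
    pe = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1 - pe)


def select_run_above_median(maps: Sequence[float]) -> int:
    """Index of the run whose micro average precision is immediately
    above the median of all runs (the stated model-selection rule for an
    even number of runs)."""
    arr = np.asarray(maps, dtype=float)
    med = float(np.median(arr))
    above = np.flatnonzero(arr > med)
    if above.size == 0:
        raise ValueError("no run lies above the median")
    return int(above[np.argmin(arr[above])])


# ---------------------------------------------------------------------------
# Report assembly

def evaluate(
    scores: np.ndarray,
    labels: np.ndarray,
    thresholds: Optional[Sequence[float]] = None,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> dict:
    """Full evaluation report for an n x 6 score/label pair.

    Thresholds default to the per-class F1 maximizers.  Returns a
    JSON-serializable dict (bootstrap distributions summarized as
    percentile intervals).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    k = scores.shape[1]
    names = CLASSES if k == len(CLASSES) else tuple(f"class{i}" for i in range(k))
    if thresholds is None:
        thresholds = [
            select_threshold_max_f1(scores[:, j], labels[:, j]) for j in range(k)
        ]
    per_class = class_scores(scores, labels, thresholds)
    boot = bootstrap_scores(scores, labels, thresholds, n_resamples=n_bootstrap, seed=seed)
    report: dict = {"classes": {}, "micro_average_precision": micro_average_precision(scores, labels)}
    for j, name in enumerate(names):
        recall, precision, thr = pr_curve(scores[:, j], labels[:, j])
        entry = dict(per_class[name])
        entry["pr_curve"] = {
            "recall": recall.tolist(),
            "precision": precision.tolist(),
            "thresholds": thr.tolist(),
        }
        entry["bootstrap"] = {
            metric: {kk: vv for kk, vv in boot[name][metric].items() if kk != "distribution"}
            for metric in METRICS
        }
        report["classes"][name] = entry
    return report


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not serializable: {type(o)}")


def write_report(report: dict, path: str) -> None:
    with open(path, "w") as f:
        json.dump(report, f, indent=2, default=_json_default, allow_nan=True)
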