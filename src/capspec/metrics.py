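"""Confusion-matrix evaluation of binary predictors against K-locus labels.

A predictor here is a binary presence vector of one protein cluster; it is
scored against the indicator vector of its associated K-locus.  A true
positive is a carrier isolate with the K-locus, a false positive a carrier
without it, a false negative a non-carrier with it and a true negative a
non-carrier without it.  From these counts:

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)
    MCC       = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Degenerate denominators follow the usual conventions: a zero denominator
yields 0 for precision/recall/F1 and 0 for MCC, with flags recording which
metric was degenerate.

Evaluation can be collapsed to the sequence-cluster (SC) level, where an
SC counts as predictor-positive (or K-positive) if any member isolate is —
prophage acquisition is sporadic within lineages, so a single gain is
evidence.  Uncertainty comes from percentile bootstrap over isolates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from ._rng import child_rng

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "BootstrapCI",
    "PearsonResult",
    "confusion",
    "sc_confusion",
    "metric_set",
    "bootstrap_cis",
    "precision_recall_corr",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int
    level: str = "isolate"  # isolate | SC

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    precision: float
    recall: float
    f1: float
    mcc: float
    degenerate: tuple[str, ...] = ()


@dataclass
class BootstrapCI:
    """Percentile bootstrap CIs per metric.

    ``intervals`` maps metric name -> (point, lower, upper); metrics whose
    replicates were all undefined are absent and listed in
    ``unavailable``.  ``defined_replicates`` counts, per metric, the
    replicates where the metric had a non-degenerate denominator.
    """

    intervals: dict[str, tuple[float, float, float]]
    n_replicates: int
    level: float
    defined_replicates: dict[str, int] = field(default_factory=dict)
    unavailable: tuple[str, ...] = ()


@dataclass(frozen=True)
class PearsonResult:
    r: float
    ci_lower: float
    ci_upper: float
    n: int
    undefined: bool = False


def _as_binary(v: Sequence[int] | np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(v)
    if a.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if a.size and not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must be binary")
    return a.astype(bool)


def confusion(predictor: Sequence[int], klocus: Sequence[int]) -> ConfusionCounts:
    """Isolate-level confusion counts of a predictor against a K-locus vector."""
    p = _as_binary(predictor, "predictor")
    k = _as_binary(klocus, "klocus")
    if len(p) != len(k):
        raise ValueError(f"length mismatch: predictor {len(p)} vs klocus {len(k)}")
    return ConfusionCounts(
        tp=int(np.sum(p & k)),
        fp=int(np.sum(p & ~k)),
        fn=int(np.sum(~p & k)),
        tn=int(np.sum(~p & ~k)),
        level="isolate",
    )


def sc_confusion(
    predictor: Sequence[int],
    klocus: Sequence[int],
    sc_labels: Sequence[str],
    rule: str = "any",
) -> ConfusionCounts:
    """Confusion counts collapsed to one unit per sequence cluster.

    ``rule`` is ``"any"`` (an SC is positive if any member is; default) or
    ``"majority"`` (more than half the members).
    """
    p = _as_binary(predictor, "predictor")
    k = _as_binary(klocus, "klocus")
    if not (len(p) == len(k) == len(sc_labels)):
        raise ValueError("predictor, klocus and sc_labels must be equal length")
    if any(s is None or s == "" for s in sc_labels):
        raise ValueError("every isolate must be mapped to an SC")
    scs = np.asarray(sc_labels)
    p_pos, k_pos = [], []
    for sc in np.unique(scs):
        mask = scs == sc
        if rule == "any":
            p_pos.append(p[mask].any())
            k_pos.append(k[mask].any())
        elif rule == "majority":
            p_pos.append(p[mask].sum() * 2 > mask.sum())
            k_pos.append(k[mask].sum() * 2 > mask.sum())
        else:
            raise ValueError(f"unknown SC positivity rule {rule!r}")
    pa, ka = np.asarray(p_pos), np.asarray(k_pos)
    return ConfusionCounts(
        tp=int(np.sum(pa & ka)),
        fp=int(np.sum(pa & ~ka)),
        fn=int(np.sum(~pa & ka)),
        tn=int(np.sum(~pa & ~ka)),
        level="SC",
    )


def metric_set(counts: ConfusionCounts) -> MetricSet:
    """Precision/recall/F1/MCC with explicit degenerate-denominator conventions."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    degenerate: list[str] = []
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision = 0.0
        degenerate.append("precision")
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall = 0.0
        degenerate.append("recall")
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = 0.0
        degenerate.append("f1")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom > 0:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    else:
        mcc = 0.0
        degenerate.append("mcc")
    return MetricSet(precision=precision, recall=recall, f1=f1, mcc=mcc,
                     degenerate=tuple(degenerate))


_METRICS = ("precision", "recall", "f1", "mcc")


def bootstrap_cis(
    predictor: Sequence[int],
    klocus: Sequence[int],
    n_reps: int = 100,
    seed: int = 0,
    level: float = 0.95,
    sc_labels: Sequence[str] | None = None,
) -> BootstrapCI:
    """Percentile bootstrap CIs for the four metrics, resampling isolates.

    Full rows (predictor, K-locus and, if given, SC label) are resampled
    with replacement so TN-dependent metrics are valid too.  Replicates in
    which a metric's denominator is degenerate are excluded from that
    metric's quantiles; their number is reported.
    """
    p = _as_binary(predictor, "predictor")
    k = _as_binary(klocus, "klocus")
    if len(p) != len(k):
        raise ValueError("length mismatch")
    n = len(p)
    rng = child_rng(seed, "bootstrap_cis")
    point_counts = (
        sc_confusion(p, k, sc_labels) if sc_labels is not None else confusion(p, k)
    )
    point = metric_set(point_counts)
    samples: dict[str, list[float]] = {m: [] for m in _METRICS}
    for _ in range(n_reps):
        idx = rng.integers(n, size=n)
        if sc_labels is not None:
            cc = sc_confusion(p[idx], k[idx], np.asarray(sc_labels)[idx])
        else:
            cc = confusion(p[idx], k[idx])
        ms = metric_set(cc)
        for m in _METRICS:
            if m not in ms.degenerate:
                samples[m].append(getattr(ms, m))
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    intervals: dict[str, tuple[float, float, float]] = {}
    defined: dict[str, int] = {}
    unavailable: list[str] = []
    for m in _METRICS:
        vals = samples[m]
        defined[m] = len(vals)
        if not vals:
            unavailable.append(m)
            continue
        arr = np.asarray(vals)
        intervals[m] = (
            float(getattr(point, m)),
            float(np.quantile(arr, lo_q)),
            float(np.quantile(arr, hi_q)),
        )
    return BootstrapCI(
        intervals=intervals,
        n_replicates=n_reps,
        level=level,
        defined_replicates=defined,
        unavailable=tuple(unavailable),
    )


def precision_recall_corr(metric_sets: Sequence[MetricSet],
                          level: float = 0.95) -> PearsonResult:
    """Pearson correlation between precision and recall across predictors.

    The CI uses the Fisher z-transform.  Zero variance in either
    coordinate makes r undefined (flagged).
    """
    if len(metric_sets) < 3:
        raise ValueError("need at least 3 predictors for a correlation")
    x = np.asarray([m.precision for m in metric_sets])
    y = np.asarray([m.recall for m in metric_sets])
    n = len(x)
    if x.std() == 0 or y.std() == 0:
        return PearsonResult(r=float("nan"), ci_lower=float("nan"),
                             ci_upper=float("nan"), n=n, undefined=True)
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0 or n < 4:
        return PearsonResult(r=r, ci_lower=r, ci_upper=r, n=n)
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    crit = stats.norm.ppf(1 - (1 - level) / 2)
    return PearsonResult(
        r=r,
        ci_lower=math.tanh(z - crit * se),
        ci_upper=math.tanh(z + crit * se),
        n=n,
    )
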