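"""Classification metrics, multi-split evaluation, Wilcoxon signed-rank test.

Metrics follow the binary positive-class convention (positive = label 1,
the death event): accuracy = (TP+TN)/n, precision = TP/(TP+FP),
recall = TP/(TP+FN), F1 = harmonic mean, AUC = trapezoidal area under the
ROC. The signed-rank test reports TS = min(W+, W-) with an exact null
distribution (shift-convolution over midranks) for small samples and a
continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

import io
import itertools
import logging
import pickle
import time
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_auc_score

from hfens.core_data import ClinicalTable, SplitPlan, make_splits

logger = logging.getLogger(__name__)

EXACT_WSRT_LIMIT = 25


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Confusion counts with positive class = 1 (death)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("labels must be binary 0/1")
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


@dataclass
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "auc": self.auc,
        }


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); returning 0", name)
        return 0.0
    return num / den


def metrics(
    counts: ConfusionCounts,
    scores=None,
    y_true=None,
) -> MetricSet:
    """Accuracy/precision/recall/F1 from counts; AUC from ranked scores.

    ``scores`` are positive-class probabilities in [0, 1]; when omitted
    (or when y_true is single-class) AUC is reported as 0.5 for an
    uninformative scorer and 0 respectively, with a logged warning.
    """
    accuracy = _safe_ratio(counts.TP + counts.TN, counts.total, "accuracy")
    precision = _safe_ratio(counts.TP, counts.TP + counts.FP, "precision")
    recall = _safe_ratio(counts.TP, counts.TP + counts.FN, "recall")
    f1 = _safe_ratio(2 * precision * recall, precision + recall, "f1")
    auc = 0.5
    if scores is not None and y_true is not None:
        scores = np.asarray(scores, dtype=float)
        y_true = np.asarray(y_true, dtype=int)
        if len(y_true) != counts.total:
            raise ValueError("y_true length inconsistent with counts")
        if ((scores < 0) | (scores > 1)).any():
            raise ValueError("scores must lie in [0, 1]")
        if len(np.unique(y_true)) < 2:
            logger.warning("AUC undefined for single-class y_true; returning 0")
            auc = 0.0
        else:
            auc = float(roc_auc_score(y_true, scores))
    return MetricSet(accuracy=accuracy, precision=precision, recall=recall,
                     f1=f1, auc=auc)


def evaluate_model(model, test: ClinicalTable) -> MetricSet:
    """Convenience: confusion + metrics of a fitted model on a test table."""
    pred = model.predict_label(test.X)
    scores = model.predict_probability(test.X)[:, 1]
    return metrics(confusion(test.y, pred), scores, test.y)


@dataclass
class EvalSummary:
    per_split: list[MetricSet]
    mean: MetricSet
    fit_seconds: list[float] = field(default_factory=list)
    model_bytes: list[int] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "per_split": [m.as_dict() for m in self.per_split],
            "mean": self.mean.as_dict(),
        }


def evaluate_over_splits(
    model_factory, table: ClinicalTable, plan: SplitPlan
) -> EvalSummary:
    """Train a fresh model per split, average the per-split metric sets.

    ``model_factory(train_table)`` must return an object with
    ``predict_label`` / ``predict_probability``. Wall time per fit and a
    pickled-size estimate of each model are captured for informational
    profiling; they never enter the metric averages.
    """
    splits = make_splits(table, plan)
    per_split, fit_seconds, model_bytes = [], [], []
    for train, test in splits:
        assert not set(train.sample_ids) & set(test.sample_ids)
        t0 = time.perf_counter()
        model = model_factory(train)
        fit_seconds.append(time.perf_counter() - t0)
        try:
            buf = io.BytesIO()
            pickle.dump(model, buf)
            model_bytes.append(buf.getbuffer().nbytes)
        except Exception:  # unpicklable models still evaluate fine
            model_bytes.append(-1)
        per_split.append(evaluate_model(model, test))
    arr = np.array([[m.accuracy, m.precision, m.recall, m.f1, m.auc]
                    for m in per_split])
    mean = MetricSet(*(float(v) for v in arr.mean(axis=0)))
    return EvalSummary(per_split=per_split, mean=mean,
                       fit_seconds=fit_seconds, model_bytes=model_bytes)


@dataclass
class WsrtResult:
    TS: float
    p_value: float
    n_effective: int
    significant: bool
    degenerate: bool = False


@lru_cache(maxsize=512)
def _exact_cdf(doubled_ranks: tuple[int, ...]):
    """Null distribution of 2*W+ by shift-convolution over doubled midranks.

    Doubling turns midranks (multiples of 0.5) into integers, so the
    distribution is exact even with rank ties. Returns the probability
    vector over 2*W+ = 0 .. 2*sum(ranks).
    """
    total = sum(doubled_ranks)
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:len(dist) - r]
        dist = 0.5 * (dist + shifted)
    return dist


def wsrt(paired_a, paired_b, SL: float = 0.05) -> WsrtResult:
    """Two-sided Wilcoxon signed-rank test on paired measurements.

    Differences of exactly zero are dropped; |d| are ranked with midrank
    ties; TS = min(W+, W-). The p-value is exact (full null distribution)
    for n_effective <= 25 and a continuity-corrected normal approximation
    with tie correction beyond that. All-zero differences yield the
    degenerate result TS = 0, p = 1.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("paired vectors must be nonempty and equal length")
    d = a - b
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        logger.warning("all paired differences are zero; degenerate WSRT")
        return WsrtResult(TS=0.0, p_value=1.0, n_effective=0,
                          significant=False, degenerate=True)
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    ts = min(w_plus, w_minus)

    if n <= EXACT_WSRT_LIMIT:
        doubled = tuple(sorted(int(round(2 * r)) for r in ranks))
        dist = _exact_cdf(doubled)
        # two-sided: by symmetry of the null, P(min(W+, W-) <= ts)
        #            = min(1, 2 * P(W+ <= ts))
        p = min(1.0, 2.0 * float(dist[: int(round(2 * ts)) + 1].sum()))
    else:
        mean = n * (n + 1) / 4.0
        # midrank tie correction to the null variance
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (ts - mean + 0.5) / np.sqrt(var)
        p = float(min(1.0, 2.0 * norm.cdf(z)))
    return WsrtResult(TS=ts, p_value=p, n_effective=n,
                      significant=p < SL)


def compare_all_pairs(
    accuracies: dict[str, np.ndarray] | pd.DataFrame, SL: float = 0.05
) -> pd.DataFrame:
    """Signed-rank comparison of every unordered classifier pair.

    ``accuracies`` maps classifier name -> per-split metric vector (or a
    DataFrame with classifiers as columns). Returns one row per pair with
    TS, p-value and the significance flag at SL.
    """
    if isinstance(accuracies, pd.DataFrame):
        accuracies = {c: accuracies[c].to_numpy() for c in accuracies.columns}
    names = list(accuracies)
    if len(names) < 2:
        raise ValueError("need at least 2 classifiers")
    rows = []
    for a, b in itertools.combinations(names, 2):
        res = wsrt(accuracies[a], accuracies[b], SL=SL)
        rows.append({
            "classifier_a": a, "classifier_b": b, "TS": res.TS,
            "p_value": res.p_value, "n_effective": res.n_effective,
            "significant": res.significant,
        })
    return pd.DataFrame(rows)
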