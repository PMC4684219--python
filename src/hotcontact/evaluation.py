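"""Hot-spot classification metrics and correlation.

An observed mutation is a binding hot spot when its experimental ddG is
at least 2 kcal/mol, or (for categorically annotated datasets) when its
label is 'Strong'. Predicted hot spots are called by thresholding the
predicted ddG, conventionally at 1.5 kcal/mol to compensate for the
regressor's systematic underestimation; both comparisons are inclusive
(>=).

Counting hot spots as the positive class, the report carries precision,
recall, F1, accuracy, specificity, negative precision (TN / (TN + FN)),
and the Pearson correlation between numeric predictions and
observations. A ratio whose denominator is empty is reported as None
(undefined), never silently as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats

__all__ = [
    "LabeledPrediction",
    "MetricsReport",
    "classify",
    "true_label",
    "metrics",
    "pcc",
    "load_benchmark",
    "benchmark_metrics",
    "DEFAULT_LABEL_THRESHOLD",
    "DEFAULT_PREDICTION_THRESHOLD",
]

DEFAULT_LABEL_THRESHOLD = 2.0  # kcal/mol, observed hot-spot definition
DEFAULT_PREDICTION_THRESHOLD = 1.5  # kcal/mol, predicted hot-spot call

_CATEGORIES = {"STRONG", "INTERMEDIATE", "WEAK", "INSIGNIFICANT"}


@dataclass
class LabeledPrediction:
    """One mutation's prediction paired with its observation."""

    mutation_id: str
    predicted_ddg: Optional[float] = None  # kcal/mol
    predicted_call: Optional[bool] = None
    observed: Union[float, str, None] = None

    def __post_init__(self) -> None:
        if self.predicted_ddg is None and self.predicted_call is None:
            raise ValueError(f"{self.mutation_id}: no prediction at all")


@dataclass
class MetricsReport:
    """Confusion counts and the derived classification metrics."""

    tp: int
    fp: int
    tn: int
    fn: int
    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]
    accuracy: Optional[float]
    specificity: Optional[float]
    negative_precision: Optional[float]
    pcc: Optional[float] = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {
            "TP": self.tp,
            "FP": self.fp,
            "TN": self.tn,
            "FN": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "F1": self.f1,
            "accuracy": self.accuracy,
            "specificity": self.specificity,
            "negative_precision": self.negative_precision,
            "PCC": self.pcc,
        }


def classify(value: float, threshold: float = DEFAULT_PREDICTION_THRESHOLD) -> bool:
    """Hot spot iff ddG >= threshold (inclusive boundary)."""
    return value >= threshold


def true_label(
    observed: Union[float, str], threshold: float = DEFAULT_LABEL_THRESHOLD
) -> bool:
    """Observed hot-spot status from a numeric ddG or a categorical label.

    Numeric: hot iff ddG >= threshold. Categorical: hot iff 'Strong';
    Intermediate, Weak and Insignificant are non-hot.
    """
    if isinstance(observed, str):
        label = observed.strip().upper()
        if label not in _CATEGORIES:
            raise ValueError(f"unknown hot-spot category {observed!r}")
        return label == "STRONG"
    return float(observed) >= threshold


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def metrics(
    predictions: Sequence[LabeledPrediction],
    threshold: float = DEFAULT_PREDICTION_THRESHOLD,
    label_threshold: float = DEFAULT_LABEL_THRESHOLD,
) -> MetricsReport:
    """Confusion counts and all derived metrics over a prediction set."""
    if not predictions:
        raise ValueError("no predictions to score")
    tp = fp = tn = fn = 0
    pred_numeric: List[float] = []
    obs_numeric: List[float] = []
    for p in predictions:
        truth = true_label(p.observed, label_threshold)
        call = (
            p.predicted_call
            if p.predicted_call is not None
            else classify(p.predicted_ddg, threshold)
        )
        if call and truth:
            tp += 1
        elif call and not truth:
            fp += 1
        elif not call and not truth:
            tn += 1
        else:
            fn += 1
        if p.predicted_ddg is not None and not isinstance(p.observed, str):
            pred_numeric.append(p.predicted_ddg)
            obs_numeric.append(float(p.observed))

    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision is not None and recall is not None and (precision + recall) > 0
        else None
    )
    correlation = None
    if len(pred_numeric) >= 3:
        try:
            correlation = pcc(pred_numeric, obs_numeric)
        except ValueError:
            correlation = None
    return MetricsReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=_ratio(tp + tn, tp + fp + tn + fn),
        specificity=_ratio(tn, tn + fp),
        negative_precision=_ratio(tn, tn + fn),
        pcc=correlation,
    )


def pcc(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Pearson product-moment correlation; fatal on constant input."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size < 3:
        raise ValueError("need two equal-length series of at least 3 values")
    if np.all(pred == pred[0]) or np.all(obs == obs[0]):
        raise ValueError("Pearson correlation undefined for a constant series")
    return float(scipy_stats.pearsonr(pred, obs).statistic)


# ---------------------------------------------------------------------------
# Bundled three-complex benchmark
#
# Literature-reported predictions of five hot-spot prediction methods
# (this method's reference run `contact_rf`, Robetta, Hotpoint, KFC2a,
# KFC2b) for four shared residues of the 1TH1 / 1JPP / 3OUX complexes,
# with their experimentally derived categorical labels. Used to validate
# the metric computations against published numbers.


def load_benchmark(path: Optional[str] = None) -> pd.DataFrame:
    if path is None:
        source = resources.files("hotcontact.data").joinpath(
            "three_complex_benchmark.tsv"
        )
        with source.open() as fh:
            return pd.read_csv(fh, sep="\t", comment="#")
    return pd.read_csv(path, sep="\t", comment="#")


def benchmark_metrics(
    method: str,
    threshold: float = DEFAULT_PREDICTION_THRESHOLD,
    table: Optional[pd.DataFrame] = None,
) -> MetricsReport:
    """Score one method of the bundled benchmark, pooled over the 3 complexes."""
    table = table if table is not None else load_benchmark()
    rows = table[table["method"] == method]
    if rows.empty:
        raise ValueError(f"method {method!r} not in benchmark table")
    predictions = []
    for _, row in rows.iterrows():
        value = row["prediction"]
        call = None
        ddg = None
        if str(value).replace(".", "", 1).replace("-", "", 1).isdigit():
            ddg = float(value)
        else:
            call = str(value).strip().upper() == "HOT"
        predictions.append(
            LabeledPrediction(
                mutation_id=f"{row['complex_id']}:{row['residue']}",
                predicted_ddg=ddg,
                predicted_call=call,
                observed=row["observed"],
            )
        )
    return metrics(predictions, threshold=threshold)
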