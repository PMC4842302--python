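"""Confusion-matrix evaluation and F-beta metrics for labelled test pairs.

The multi-label target-prediction problem is evaluated as binary
classification over labelled (molecule, target) pairs. Metrics are always
computed from integer counts, never from pre-rounded rates; an undefined
denominator yields None ("undefined"), not 0.

F_beta = (1 + beta^2) * P * S / (beta^2 * P + S) weights precision over
sensitivity for beta < 1 (beta = 0.5 doubles, beta = 0.25 quadruples the
weight on precision).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import pandas as pd

#: column order of the standard report table
METRIC_COLUMNS = ("accuracy", "precision", "sensitivity", "specificity", "f_0.5", "f_0.25")
DEFAULT_BETAS = (0.5, 0.25)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float | None
    precision: float | None
    sensitivity: float | None
    specificity: float | None
    f_beta: dict = field(default_factory=dict)  # beta -> value or None

    def as_row(self) -> dict:
        row = {"accuracy": self.accuracy, "precision": self.precision,
               "sensitivity": self.sensitivity, "specificity": self.specificity}
        for beta, val in self.f_beta.items():
            row[f"f_{beta:g}"] = val
        return row


def confusion(predicted: Iterable, labels: Mapping) -> ConfusionCounts:
    """Counts from a predicted-positive pair set and a pair -> label mapping.

    Labels are truthy for active, falsy for inactive (the strings
    "active"/"inactive" are also understood). Every predicted pair must be
    labelled; labelled pairs never predicted land in TN/FN.
    """
    predicted = set(predicted)
    unlabelled = predicted - set(labels)
    if unlabelled:
        raise ValueError(f"{len(unlabelled)} predicted pair(s) missing from the label set, "
                         f"e.g. {sorted(unlabelled)[:3]}")
    tp = fp = tn = fn = 0
    for pair, label in labels.items():
        active = label not in (0, False, "inactive", "0")
        if pair in predicted:
            tp += active
            fp += not active
        else:
            fn += active
            tn += not active
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def f_beta(precision: float, sensitivity: float, beta: float) -> float | None:
    """Weighted harmonic mean of precision and sensitivity; None when undefined."""
    denom = beta * beta * precision + sensitivity
    if denom == 0:
        return None
    return (1.0 + beta * beta) * precision * sensitivity / denom


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(c: ConfusionCounts, betas: Sequence[float] = DEFAULT_BETAS) -> MetricSet:
    """Accuracy, precision, sensitivity, specificity and F_beta from counts."""
    precision = _ratio(c.tp, c.tp + c.fp)
    sensitivity = _ratio(c.tp, c.tp + c.fn)
    fb = {}
    for beta in betas:
        if precision is None or sensitivity is None:
            fb[beta] = None
        else:
            fb[beta] = f_beta(precision, sensitivity, beta)
    return MetricSet(
        accuracy=_ratio(c.tp + c.tn, c.total),
        precision=precision,
        sensitivity=sensitivity,
        specificity=_ratio(c.tn, c.fp + c.tn),
        f_beta=fb,
    )


def metrics_table(rows: Mapping[str, ConfusionCounts],
                  betas: Sequence[float] = DEFAULT_BETAS,
                  decimals: int = 3) -> pd.DataFrame:
    """One metrics row per model/scheme, in the standard column order."""
    records = {}
    for name, counts in rows.items():
        row = metrics(counts, betas).as_row()
        records[name] = {k: (round(v, decimals) if v is not None else None)
                         for k, v in row.items()}
    cols = [c for c in METRIC_COLUMNS if any(c in r for r in records.values())]
    return pd.DataFrame.from_dict(records, orient="index")[cols]
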