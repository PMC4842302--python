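"""Multi-voting election over per-fingerprint SEA models.

Each fitted model casts a vote for a (molecule, target) pair when its
P-value is at or below the cutoff; a k-vote scheme calls the pair
significant when at least k of the models vote. Pairs missing a model's
P-value simply receive no vote from it. Prediction sets are nested in k:
the 1-vote scheme is the union of single-model positives, the all-vote
scheme their intersection.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class VoteScheme:
    k: int
    alpha: float
    models: tuple

    def __post_init__(self):
        object.__setattr__(self, "models", tuple(self.models))
        if not self.models:
            raise ValueError("a vote scheme needs at least one model")
        if not 1 <= self.k <= len(self.models):
            raise ValueError(f"k={self.k} outside 1..{len(self.models)}")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")


def vote(p_values: Mapping[str, float], scheme: VoteScheme) -> tuple:
    """(significant, votes) for one pair's per-model P-values.

    A model votes when its p <= alpha (ties at alpha count, matching the
    "P value <= cutoff" convention); a missing or NaN p-value is a
    non-vote. Invariant to model ordering.
    """
    votes = 0
    for model_id in scheme.models:
        p = p_values.get(model_id)
        if p is not None and not (isinstance(p, float) and math.isnan(p)) and p <= scheme.alpha:
            votes += 1
    return votes >= scheme.k, votes


def ensemble_predict(p_table: pd.DataFrame, alpha: float,
                     models: Sequence[str] | None = None,
                     ks: Sequence[int] | None = None) -> dict:
    """Per-scheme significant-pair sets from a merged per-model P-value table.

    ``p_table`` is indexed by pair (e.g. a (molecule_id, target_id)
    MultiIndex) with one column per model. Returns {k: set of pairs};
    the sets are nested decreasingly in k.
    """
    models = list(models) if models is not None else list(p_table.columns)
    ks = list(ks) if ks is not None else list(range(1, len(models) + 1))
    votes = (p_table[models] <= alpha).sum(axis=1)  # NaN <= alpha is False
    return {k: set(p_table.index[votes >= k]) for k in ks}


def vote_table(p_table: pd.DataFrame, alpha: float,
               models: Sequence[str] | None = None) -> pd.DataFrame:
    """P-value table augmented with the vote count and per-k significance flags."""
    models = list(models) if models is not None else list(p_table.columns)
    out = p_table[models].copy()
    out["votes"] = (p_table[models] <= alpha).sum(axis=1)
    for k in range(1, len(models) + 1):
        out[f"significant_k{k}"] = out["votes"] >= k
    return out
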