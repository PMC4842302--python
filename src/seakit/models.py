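"""Estimator surface: SEA background model, target predictor, voting ensemble.

These follow scikit-learn conventions (``get_params``/``set_params``,
``fit`` returning self, fitted attributes with a trailing underscore) so
they compose with sklearn tooling; the per-module functions in
:mod:`seakit.background`, :mod:`seakit.scoring` and :mod:`seakit.ensemble`
hold or wrap the same computations.
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import background as bg
from . import scoring
from .ensemble import ensemble_predict, vote_table
from .similarity import tanimoto_matrix


class SeaModel(BaseEstimator):
    """SEA background statistics fitted on a universe of fingerprints.

    ``fit(X)`` draws random disjoint set pairs from the fingerprint list
    ``X`` over the configured size grid, scores them at every candidate
    Tanimoto threshold, fits the mean/sd laws F_mean(s) = mu*s and
    F_sd(s) = phi*s**eta per threshold, and keeps the threshold whose
    standardised scores best fit the standard Gumbel EVD (chi-square).

    Parameters
    ----------
    size_min, size_max, size_step : background set-size grid (reference
        protocol: 10..1000 step 10, giving 4950 distinct-size pairs).
    repetitions : draws of the full pair grid to pool (reference: 100).
    ts_grid : candidate Tanimoto thresholds (default 0.00..0.99 step 0.01).
    n_bins : equal-probability bins for the Gumbel chi-square.
    random_state : seed for the background draws.

    Attributes
    ----------
    ts_, mu_, phi_, eta_ : selected threshold and fitted law parameters.
    chi2_by_ts_ : per-threshold goodness-of-fit diagnostics.
    min_fitted_s_ : smallest set-size product seen by the fit (queries
        below it extrapolate the laws).
    """

    def __init__(self, size_min: int = 10, size_max: int = 1000, size_step: int = 10,
                 repetitions: int = 100, ts_grid: tuple | None = None,
                 n_bins: int = 20, random_state: int | None = None):
        self.size_min = size_min
        self.size_max = size_max
        self.size_step = size_step
        self.repetitions = repetitions
        self.ts_grid = ts_grid
        self.n_bins = n_bins
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def _config(self) -> bg.BackgroundConfig:
        grid = tuple(self.ts_grid) if self.ts_grid is not None else bg.default_ts_grid()
        return bg.BackgroundConfig(
            size_min=self.size_min, size_max=self.size_max, size_step=self.size_step,
            repetitions=self.repetitions, ts_grid=grid,
            seed=self.random_state if self.random_state is not None else 0)

    def fit(self, X: Sequence, y=None, tc_matrix: np.ndarray | None = None) -> "SeaModel":
        """Fit the background model on a fingerprint universe ``X``."""
        config = self._config()
        samples = list(bg.generate_background_pairs(X, config, tc_matrix=tc_matrix))
        fit = bg.select_ts(samples, config.ts_grid, n_bins=self.n_bins)
        self._adopt(fit)
        self.min_fitted_s_ = int(min(smp.s for smp in samples))
        self.n_background_samples_ = len(samples)
        return self

    def _adopt(self, fit: bg.BackgroundFit) -> None:
        self.background_fit_ = fit
        self.ts_ = fit.ts
        self.mu_ = fit.mu
        self.phi_ = fit.phi
        self.eta_ = fit.eta
        self.chi2_by_ts_ = fit.chi2_by_ts

    # -- scoring -----------------------------------------------------------

    def score_sets(self, fps_a: Sequence, fps_b: Sequence) -> scoring.SeaScore:
        """Full SEA comparison of two fingerprinted ligand sets."""
        check_is_fitted(self, "ts_")
        return scoring.compare_sets(fps_a, fps_b, self)

    # -- persistence (structured text) --------------------------------------

    def to_json(self, path, provider_key: str | None = None) -> None:
        check_is_fitted(self, "ts_")
        doc = {
            "provider": provider_key,
            "grid": {"size_min": self.size_min, "size_max": self.size_max,
                     "size_step": self.size_step, "repetitions": self.repetitions,
                     "seed": self.random_state},
            "fit": self.background_fit_.to_dict(),
            "min_fitted_s": getattr(self, "min_fitted_s_", None),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SeaModel":
        with open(path) as fh:
            doc = json.load(fh)
        grid = doc.get("grid", {})
        model = cls(size_min=grid.get("size_min", 10), size_max=grid.get("size_max", 1000),
                    size_step=grid.get("size_step", 10),
                    repetitions=grid.get("repetitions", 100),
                    random_state=grid.get("seed"))
        model._adopt(bg.BackgroundFit.from_dict(doc["fit"]))
        if doc.get("min_fitted_s") is not None:
            model.min_fitted_s_ = doc["min_fitted_s"]
        model.provider_key_ = doc.get("provider")
        return model


class SeaTargetPredictor(BaseEstimator):
    """Per-molecule target prediction against a library of ligand sets.

    ``fit`` stores the fingerprinted reference ligand sets; ``predict``
    scores each query molecule as a singleton set against every target
    under the attached background model and returns the significant calls.

    Parameters
    ----------
    model : fitted :class:`SeaModel`.
    alpha : significance cutoff on the P-value (default 0.05).
    """

    def __init__(self, model: SeaModel | None = None, alpha: float = 0.05):
        self.model = model
        self.alpha = alpha

    def fit(self, X: Mapping[str, Sequence], y=None) -> "SeaTargetPredictor":
        """``X``: mapping target_id -> sequence of member fingerprints."""
        if self.model is None:
            raise ValueError("SeaTargetPredictor requires a fitted SeaModel")
        check_is_fitted(self.model, "ts_")
        if not X:
            raise ValueError("no target ligand sets supplied")
        self.targets_ = {t: list(fps) for t, fps in X.items()}
        return self

    def score_table(self, X: Sequence, ids: Sequence[str] | None = None) -> pd.DataFrame:
        """All (molecule, target) SEA scores as a long-format DataFrame."""
        check_is_fitted(self, "targets_")
        ids = list(ids) if ids is not None else [f"q{i}" for i in range(len(X))]
        m = self.model
        rows = []
        for mol_id, fp in zip(ids, X):
            for target_id, fps in self.targets_.items():
                tc = tanimoto_matrix([fp], fps)
                rs = scoring.raw_score_from_matrix(tc, m.ts_)
                z = scoring.z_score(rs, 1, len(fps), m.mu_, m.phi_, m.eta_)
                rows.append((mol_id, target_id, rs, z,
                             scoring.p_value(z), scoring.log10_p_value(z)))
        return pd.DataFrame(rows, columns=["molecule_id", "target_id",
                                           "raw_score", "z_score", "p_value", "log10_p"])

    def predict(self, X: Sequence, ids: Sequence[str] | None = None) -> list:
        """Significant targets per query molecule, ascending P-value."""
        table = self.score_table(X, ids)
        out = []
        for mol_id in table["molecule_id"].unique():
            sub = table[(table["molecule_id"] == mol_id)
                        & (table["p_value"] <= self.alpha)]
            sub = sub.sort_values(["p_value", "target_id"])
            out.append(list(sub["target_id"]))
        return out

    def target_network(self, p_cutoff: float) -> pd.DataFrame:
        """Significance-thresholded target-vs-target edge list."""
        check_is_fitted(self, "targets_")
        edges = scoring.target_network(self.targets_, self.model, p_cutoff)
        return pd.DataFrame(edges, columns=["target_a", "target_b", "raw_score",
                                            "z_score", "p_value", "log10_p"])


class MultiVotingSea(BaseEstimator):
    """k-of-n election over per-fingerprint SEA predictors.

    Parameters
    ----------
    predictors : mapping model_id -> fitted :class:`SeaTargetPredictor`.
    k : votes required for a significant call.
    alpha : per-model P-value cutoff used as the vote criterion.
    """

    def __init__(self, predictors: Mapping[str, SeaTargetPredictor] | None = None,
                 k: int = 3, alpha: float = 0.05):
        self.predictors = predictors
        self.k = k
        self.alpha = alpha

    def fit(self, X=None, y=None) -> "MultiVotingSea":
        if not self.predictors:
            raise ValueError("MultiVotingSea requires at least one predictor")
        for name, pred in self.predictors.items():
            check_is_fitted(pred, "targets_")
        if not 1 <= self.k <= len(self.predictors):
            raise ValueError(f"k={self.k} outside 1..{len(self.predictors)}")
        self.model_ids_ = list(self.predictors)
        return self

    def p_value_table(self, X_by_model: Mapping[str, Sequence],
                      ids: Sequence[str] | None = None) -> pd.DataFrame:
        """Merged per-model P-values, indexed by (molecule_id, target_id).

        ``X_by_model`` maps model_id -> query fingerprints under that
        model's provider (same molecules, same order, across models).
        """
        check_is_fitted(self, "model_ids_")
        frames = []
        for name in self.model_ids_:
            t = self.predictors[name].score_table(X_by_model[name], ids)
            frames.append(t.set_index(["molecule_id", "target_id"])["p_value"].rename(name))
        return pd.concat(frames, axis=1)

    def predict_pairs(self, X_by_model: Mapping[str, Sequence],
                      ids: Sequence[str] | None = None) -> set:
        """Pairs called significant by at least k of the models."""
        table = self.p_value_table(X_by_model, ids)
        return ensemble_predict(table, self.alpha, models=self.model_ids_,
                                ks=[self.k])[self.k]

    def vote_table(self, X_by_model, ids=None) -> pd.DataFrame:
        return vote_table(self.p_value_table(X_by_model, ids), self.alpha,
                          models=self.model_ids_)
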