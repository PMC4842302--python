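"""Core SEA comparison statistics.

A comparison of two ligand sets A, B proceeds:

* raw score  RS(A, B) = sum of cross-pair Tanimoto coefficients TC >= TS,
  where TS is the model's fitted similarity cutoff;
* Z-score    z = (RS - mu*s) / (phi * s**eta)  with s = |A|*|B|, using the
  background mean/sd laws F_mean(s) = mu*s and F_sd(s) = phi*s**eta;
* P-value    the upper tail of the standard (zero-mean, unit-variance)
  Gumbel extreme-value distribution at z.

The Gumbel tail uses x(z) = -exp(-(z*pi/sqrt(6) + gamma)) with gamma the
Euler-Mascheroni constant. For z > 28, 1 - e^x loses all precision (x
underflows against 1), so the three-term Taylor expansion
-x - x^2/2 - x^3/6 is used instead; the two branches agree to better than
1e-6 relative at the switch point.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .similarity import tanimoto_matrix

logger = logging.getLogger(__name__)

EULER_GAMMA = 0.577215665
Z_TAYLOR_BRANCH = 28.0
_PI_OVER_SQRT6 = math.pi / math.sqrt(6.0)
_LN10 = math.log(10.0)


@dataclass(frozen=True)
class SeaScore:
    """Result of one set-vs-set SEA comparison."""

    raw_score: float
    z_score: float
    p_value: float
    log10_p: float
    n_a: int
    n_b: int
    ts_used: float


def raw_score(fps_a: Sequence, fps_b: Sequence, ts: float) -> float:
    """Sum of cross-pair similarities at or above the cutoff ``ts``.

    Semantics are the full O(|A|*|B|) double sum; the implementation is a
    masked matrix reduction.
    """
    if len(fps_a) == 0 or len(fps_b) == 0:
        raise ValueError("raw_score requires two non-empty sets")
    tc = tanimoto_matrix(fps_a, fps_b)
    return raw_score_from_matrix(tc, ts)


def raw_score_from_matrix(tc: np.ndarray, ts: float) -> float:
    """Raw score from a precomputed similarity matrix."""
    return float(tc[tc >= ts].sum())


def z_score(rs: float, n_a: int, n_b: int, mu: float, phi: float, eta: float) -> float:
    """Standardise a raw score against the background laws mu*s and phi*s^eta."""
    if phi <= 0:
        raise ValueError(f"invalid background model: phi={phi} must be > 0")
    s = n_a * n_b
    if s <= 0:
        raise ValueError("set sizes must be positive")
    return (rs - mu * s) / (phi * s ** eta)


def _x_of_z(z: float) -> float:
    return -math.exp(-(z * _PI_OVER_SQRT6 + EULER_GAMMA))


def p_value(z: float) -> float:
    """Upper-tail Gumbel probability of a Z-score; total on finite reals."""
    if not math.isfinite(z):
        raise ValueError(f"z must be finite, got {z}")
    x = _x_of_z(z)
    if z <= Z_TAYLOR_BRANCH:
        p = -math.expm1(x)  # 1 - e^x, accurately for small |x|
    else:
        p = -x - x * x / 2.0 - x ** 3 / 6.0
    return min(max(p, 0.0), 1.0)


def log10_p_value(z: float) -> float:
    """log10 of the P-value, stable far into the tail where p underflows.

    For large z, p ~ -x = exp(-(z*pi/sqrt(6) + gamma)), so the log tail is
    linear in z even when p itself is below the smallest double.
    """
    if z <= Z_TAYLOR_BRANCH:
        p = p_value(z)
        return math.log10(p) if p > 0.0 else -math.inf
    t = z * _PI_OVER_SQRT6 + EULER_GAMMA
    x = -math.exp(-t)  # may underflow to -0.0; the correction term then vanishes
    return -t / _LN10 + math.log1p(-x / 2.0 - x * x / 6.0) / _LN10


def compare_sets(fps_a: Sequence, fps_b: Sequence, model) -> SeaScore:
    """Full SEA comparison of two fingerprinted ligand sets under a fitted model.

    Symmetric in its set arguments. ``model`` is anything exposing fitted
    ``ts_``, ``mu_``, ``phi_``, ``eta_`` (a :class:`seakit.models.SeaModel`)
    or a :class:`seakit.background.BackgroundFit`.
    """
    ts, mu, phi, eta = _model_params(model)
    rs = raw_score(fps_a, fps_b, ts)
    z = z_score(rs, len(fps_a), len(fps_b), mu, phi, eta)
    return SeaScore(
        raw_score=rs, z_score=z, p_value=p_value(z), log10_p=log10_p_value(z),
        n_a=len(fps_a), n_b=len(fps_b), ts_used=ts,
    )


def _model_params(model):
    if hasattr(model, "ts_"):
        return model.ts_, model.mu_, model.phi_, model.eta_
    return model.ts, model.mu, model.phi, model.eta


def predict_targets(query_fp, model, targets, alpha: float = 0.05):
    """Score a single molecule (as a singleton set) against every target set.

    Parameters
    ----------
    query_fp : Fingerprint
    model : fitted background model
    targets : mapping target_id -> sequence of Fingerprint
    alpha : significance cutoff on the P-value, in (0, 1].

    Returns list of (target_id, SeaScore) with p <= alpha, ascending p.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    if not targets:
        logger.warning("predict_targets called with an empty target list")
        return []
    ts, mu, phi, eta = _model_params(model)
    min_fitted_s = getattr(model, "min_fitted_s_", None)
    hits = []
    for target_id, fps in targets.items():
        score = compare_sets([query_fp], fps, model)
        if min_fitted_s is not None and score.n_a * score.n_b < min_fitted_s:
            logger.debug(
                "s=%d below fitted background grid minimum %d for target %s; "
                "mean/sd laws extrapolated", score.n_a * score.n_b, min_fitted_s, target_id)
        if score.p_value <= alpha:
            hits.append((target_id, score))
    hits.sort(key=lambda pair: (pair[1].p_value, -pair[1].z_score, pair[0]))
    return hits


def target_network(targets, model, p_cutoff: float):
    """All unordered target pairs whose set-set comparison has p <= p_cutoff.

    Returns a list of (target_a, target_b, raw_score, z, p, log10_p). The
    cutoff is applied on log10 scale so edges far below double-precision
    p (e.g. the 1e-80 regime) are still thresholded exactly.
    """
    ids = sorted(targets)
    if p_cutoff <= 0:
        return []
    log_cut = math.log10(p_cutoff)
    edges = []
    for i, ta in enumerate(ids):
        for tb in ids[i + 1:]:
            sc = compare_sets(targets[ta], targets[tb], model)
            if sc.log10_p <= log_cut:
                edges.append((ta, tb, sc.raw_score, sc.z_score, sc.p_value, sc.log10_p))
    return edges
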