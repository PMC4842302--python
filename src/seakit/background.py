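"""Random-background statistical model for SEA.

Random ligand-set pairs are drawn over a grid of set sizes; their raw
scores, computed at every candidate Tanimoto threshold (TS) in one pass,
calibrate two laws of the set-size product s = |A|*|B|:

    F_mean(s) = mu * s          (expected raw score)
    F_sd(s)   = phi * s**eta    (its standard deviation)

The TS finally adopted is the one whose standardised scores
z = (RS - F_mean) / F_sd best fit the standard Gumbel extreme-value
distribution, judged by a chi-square statistic over equal-probability
bins.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Iterator, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

# zero-mean unit-variance Gumbel: scale sqrt(6)/pi, mode at -gamma*sqrt(6)/pi
_GUMBEL_SCALE = math.sqrt(6.0) / math.pi
_GUMBEL_LOC = -0.577215665 * _GUMBEL_SCALE
STANDARD_GUMBEL = stats.gumbel_r(loc=_GUMBEL_LOC, scale=_GUMBEL_SCALE)


class DegenerateFitError(ValueError):
    """A TS at which the mean/sd laws cannot be fitted (e.g. all-zero spread)."""


class ModelBuildError(RuntimeError):
    """No usable TS; the background model cannot be built."""


def default_ts_grid() -> tuple:
    """TC thresholds 0.00 to 0.99, step 0.01."""
    return tuple(np.round(np.arange(0, 100) * 0.01, 2))


@dataclass(frozen=True)
class BackgroundConfig:
    """Grid and sampling plan for the random background.

    Defaults follow the reference protocol: set sizes 10..1000 step 10
    (4950 unordered distinct-size pairs per repetition), 100 repetitions,
    TS grid 0.00..0.99 step 0.01.
    """

    size_min: int = 10
    size_max: int = 1000
    size_step: int = 10
    repetitions: int = 100
    ts_grid: tuple = field(default_factory=default_ts_grid)
    seed: int = 0

    def __post_init__(self):
        if self.size_min < 1 or self.size_max < self.size_min or self.size_step < 1:
            raise ValueError("invalid size grid")
        grid = tuple(float(t) for t in self.ts_grid)
        if not grid or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("ts_grid must be non-empty and strictly increasing")
        if grid[0] < 0 or grid[-1] >= 1:
            raise ValueError("ts_grid must lie within [0, 1)")
        object.__setattr__(self, "ts_grid", grid)

    @property
    def sizes(self) -> tuple:
        return tuple(range(self.size_min, self.size_max + 1, self.size_step))


def size_pairs(config: BackgroundConfig) -> list:
    """Unordered pairs of *distinct* grid sizes: C(len(sizes), 2) pairs."""
    sizes = config.sizes
    return [(a, b) for i, a in enumerate(sizes) for b in sizes[i + 1:]]


@dataclass
class BackgroundSample:
    """Raw scores of one random set pair, at every TS of the grid."""

    n_a: int
    n_b: int
    ts_grid: tuple
    raw_scores: np.ndarray  # aligned with ts_grid

    @property
    def s(self) -> int:
        return self.n_a * self.n_b

    def raw_score_at(self, ts: float) -> float:
        try:
            idx = self.ts_grid.index(float(ts))
        except ValueError:
            raise KeyError(f"TS {ts} not on this sample's grid") from None
        return float(self.raw_scores[idx])


def raw_scores_over_grid(tc: np.ndarray, ts_grid: Sequence[float]) -> np.ndarray:
    """Raw score at every TS threshold, from one similarity matrix, in one pass.

    Each TC is assigned to the highest grid threshold not exceeding it; a
    reversed cumulative sum then yields sum(TC >= ts) for every ts.
    """
    grid = np.asarray(ts_grid, dtype=float)
    flat = np.ravel(tc)
    pos = np.searchsorted(grid, flat, side="right") - 1
    keep = pos >= 0  # TCs below the lowest threshold never contribute
    w = np.bincount(pos[keep], weights=flat[keep], minlength=len(grid))
    return np.cumsum(w[::-1])[::-1]


def generate_background_pairs(universe: Sequence, config: BackgroundConfig,
                              tc_matrix: np.ndarray | None = None) -> Iterator[BackgroundSample]:
    """Stream random disjoint set pairs over the size grid, scored at all TS.

    For each repetition and each unordered pair of distinct grid sizes,
    two disjoint subsets of the universe are drawn (seeded) and their
    cross-similarity raw scores recorded over the whole TS grid.

    ``tc_matrix`` may supply the precomputed all-pairs similarity of the
    universe; otherwise it is computed once here.
    """
    from .similarity import tanimoto_matrix

    pairs = size_pairs(config)
    need = max((a + b for a, b in pairs), default=0)
    if len(universe) < max(need, config.size_max):
        raise ValueError(
            f"universe of {len(universe)} molecules cannot supply disjoint "
            f"set pairs up to total size {need}")
    if tc_matrix is None:
        tc_matrix = tanimoto_matrix(universe, universe)
    rng = np.random.default_rng(config.seed)
    grid = config.ts_grid
    for _rep in range(config.repetitions):
        for n_a, n_b in pairs:
            chosen = rng.choice(len(universe), size=n_a + n_b, replace=False)
            ia, ib = chosen[:n_a], chosen[n_a:]
            sub = tc_matrix[np.ix_(ia, ib)]
            yield BackgroundSample(n_a=n_a, n_b=n_b, ts_grid=grid,
                                   raw_scores=raw_scores_over_grid(sub, grid))


def fit_mean_sd(samples: Sequence[BackgroundSample], ts: float) -> tuple:
    """Fit (mu, phi, eta) at one TS.

    Raw scores are grouped by s; mu is the least-squares slope through the
    origin of group means against s; (phi, eta) come from ordinary least
    squares of log(group sd) on log(s), zero-sd groups excluded.
    """
    groups: dict = {}
    for sample in samples:
        groups.setdefault(sample.s, []).append(sample.raw_score_at(ts))
    usable = {s: np.asarray(v) for s, v in groups.items() if len(v) >= 2}
    if len(usable) < 2:
        raise DegenerateFitError(f"need >= 2 s-groups with >= 2 samples at TS {ts}")
    s_vals = np.array(sorted(usable))
    means = np.array([usable[s].mean() for s in s_vals])
    sds = np.array([usable[s].std(ddof=1) for s in s_vals])
    mu = float((s_vals * means).sum() / (s_vals ** 2).sum())
    nz = sds > 0
    if nz.sum() < 2:
        raise DegenerateFitError(f"fewer than 2 s-groups with nonzero spread at TS {ts}")
    eta, log_phi = np.polyfit(np.log(s_vals[nz]), np.log(sds[nz]), 1)
    return mu, float(np.exp(log_phi)), float(eta)


@dataclass
class BackgroundFit:
    """Selected TS with its fitted background laws and goodness diagnostics."""

    ts: float
    mu: float
    phi: float
    eta: float
    chi2_by_ts: dict          # ts -> chi-square statistic (NaN where unusable)
    params_by_ts: dict = field(default_factory=dict)  # ts -> (mu, phi, eta)
    n_samples: int = 0

    def __post_init__(self):
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")

    def to_dict(self) -> dict:
        return {
            "ts": self.ts, "mu": self.mu, "phi": self.phi, "eta": self.eta,
            "n_samples": self.n_samples,
            "chi2_by_ts": {f"{t:.2f}": (None if np.isnan(v) else float(v))
                           for t, v in self.chi2_by_ts.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BackgroundFit":
        chi2 = {float(t): (np.nan if v is None else float(v))
                for t, v in d.get("chi2_by_ts", {}).items()}
        return cls(ts=d["ts"], mu=d["mu"], phi=d["phi"], eta=d["eta"],
                   chi2_by_ts=chi2, n_samples=d.get("n_samples", 0))


def gumbel_chi_square(z: np.ndarray, n_bins: int = 20) -> float:
    """Chi-square of a z sample against the standard (unit-variance) Gumbel.

    Equal-probability bins under the Gumbel, capped so every bin expects
    at least 5 observations.
    """
    z = np.asarray(z, dtype=float)
    n = len(z)
    n_bins = max(2, min(n_bins, n // 5))
    edges = STANDARD_GUMBEL.ppf(np.linspace(0.0, 1.0, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    obs, _ = np.histogram(z, bins=edges)
    expected = n / n_bins
    return float(((obs - expected) ** 2 / expected).sum())


def select_ts(samples: Sequence[BackgroundSample], ts_grid: Sequence[float] | None = None,
              n_bins: int = 20) -> BackgroundFit:
    """Pick the TS whose standardised background scores best fit the Gumbel.

    Every usable TS is fitted with :func:`fit_mean_sd`; its samples are
    z-scored and scored by :func:`gumbel_chi_square`; the minimal statistic
    wins (ties break to the lowest TS). Raises :class:`ModelBuildError`
    when no TS is usable.
    """
    samples = list(samples)
    if not samples:
        raise ModelBuildError("no background samples")
    grid = tuple(ts_grid) if ts_grid is not None else samples[0].ts_grid
    s_arr = np.array([smp.s for smp in samples], dtype=float)
    rs_mat = np.stack([smp.raw_scores for smp in samples])  # (n_samples, n_ts)

    # group samples by s once; per-TS statistics then vectorise over the grid
    s_unique, inverse, counts = np.unique(s_arr, return_inverse=True, return_counts=True)
    ok = counts >= 2
    group_mean = np.zeros((len(s_unique), len(grid)))
    group_m2 = np.zeros_like(group_mean)
    np.add.at(group_mean, inverse, rs_mat)
    group_mean /= counts[:, None]
    np.add.at(group_m2, inverse, (rs_mat - group_mean[inverse]) ** 2)
    with np.errstate(invalid="ignore"):
        group_sd = np.sqrt(group_m2 / np.maximum(counts - 1, 1)[:, None])

    if ok.sum() < 2:
        raise ModelBuildError("need >= 2 set-size groups with >= 2 samples each")
    s_g = s_unique[ok]
    log_s = np.log(s_g)
    mu_by_ts = (s_g[:, None] * group_mean[ok]).sum(axis=0) / (s_g ** 2).sum()

    chi2_by_ts: dict = {}
    params_by_ts: dict = {}
    best = None
    for idx, ts in enumerate(grid):
        sds = group_sd[ok, idx]
        nz = sds > 0
        if nz.sum() < 2:
            chi2_by_ts[ts] = np.nan
            continue
        eta, log_phi = np.polyfit(log_s[nz], np.log(sds[nz]), 1)
        mu, phi = float(mu_by_ts[idx]), float(np.exp(log_phi))
        z = (rs_mat[:, idx] - mu * s_arr) / (phi * s_arr ** eta)
        chi2 = gumbel_chi_square(z, n_bins=n_bins)
        chi2_by_ts[ts] = chi2
        params_by_ts[ts] = (mu, phi, float(eta))
        if best is None or chi2 < best[0]:
            best = (chi2, ts, mu, phi, float(eta))
    if best is None:
        raise ModelBuildError("no TS produced a usable mean/sd fit")
    _, ts, mu, phi, eta = best
    return BackgroundFit(ts=ts, mu=mu, phi=phi, eta=eta,
                         chi2_by_ts=chi2_by_ts, params_by_ts=params_by_ts,
                         n_samples=len(samples))
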