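"""Score-based parameter-instability tests for node growth-curve models.

For a least-squares fit of the (offset-adjusted) response on (1, time)
within a node, the per-observation score contributions are the
residual-weighted regressors.  Ordering the scores by a candidate
partitioning covariate and cumulating them yields a process that, under
parameter stability, behaves like a Brownian bridge; systematic drifts
indicate a parameter change along that covariate.  Two covariance
estimators for the decorrelation matrix are supported:

* ``observation`` — outer product of per-observation scores (the classic
  estimator, which ignores within-subject dependence), and
* ``clustered`` — scores summed within subject before the outer product,
  a meat-only (OPG) clustered covariance that accounts for the repeated
  measures.

Continuous covariates use the supLM (maximally selected Lagrange
multiplier) statistic; unordered factors use a chi-square statistic on
level-wise score sums that is invariant to level order.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreMatrix",
    "InstabilityResult",
    "gaussian_scores",
    "covariance_estimate",
    "inverse_sqrt",
    "cumulative_score_process",
    "sup_lm",
    "sup_lm_pvalue",
    "categorical_test",
]

#: eigenvalue floor for the symmetric inverse square root
EIG_FLOOR = 1e-10

#: Monte-Carlo null distribution of the supLM statistic: replicates and
#: time-grid resolution of the simulated Brownian bridges
MC_REPLICATES = 50_000
MC_GRID = 1_000
_MC_SEED = 987654321  # internal, fixed: p-values must not depend on user seeds


@dataclass
class ScoreMatrix:
    """Per-observation score contributions with their subject mapping."""

    scores: np.ndarray  # (n, k)
    cluster: np.ndarray  # (n,) integer subject codes

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.cluster = np.asarray(self.cluster, dtype=np.int64)
        if self.scores.ndim != 2 or self.scores.shape[0] != self.cluster.shape[0]:
            raise ValueError("scores and cluster ids have mismatched lengths")

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def cluster_sums(self) -> tuple[np.ndarray, np.ndarray]:
        """(unique cluster codes, scores summed within cluster)."""
        uniq, inv = np.unique(self.cluster, return_inverse=True)
        sums = np.zeros((uniq.shape[0], self.k))
        np.add.at(sums, inv, self.scores)
        return uniq, sums


@dataclass
class InstabilityResult:
    variable: str
    statistic: float
    p_value: float
    p_adjusted: float
    test_type: str  # "supLM" | "categorical"
    df: float | None = None

    def as_record(self) -> dict:
        return {
            "variable": self.variable,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "p_adjusted": float(self.p_adjusted),
            "test_type": self.test_type,
        }


def gaussian_scores(
    X: np.ndarray, y: np.ndarray, offset: np.ndarray, beta: np.ndarray, cluster: np.ndarray
) -> ScoreMatrix:
    """Scores of the Gaussian node model at the fitted coefficients.

    Row i is ``x_i * (y_i - offset_i - x_i' beta)``.  The 1/sigma^2 factor
    of the Gaussian log-density gradient is omitted; the decorrelation by
    the covariance estimate built from the same scores makes every test
    statistic invariant to that scaling.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    offset = np.zeros_like(y) if offset is None else np.asarray(offset, dtype=float)
    if not (X.shape[0] == y.shape[0] == offset.shape[0]):
        raise ValueError("X, y and offset have mismatched lengths")
    resid = y - offset - X @ np.asarray(beta, dtype=float)
    return ScoreMatrix(scores=X * resid[:, None], cluster=cluster)


def covariance_estimate(scores: ScoreMatrix, mode: str = "observation") -> np.ndarray:
    """Outer-product-of-gradients covariance (the "meat" only).

    ``observation``: J = (1/n) sum_i psi_i psi_i'.  ``clustered``: scores
    are summed within subject first, and n counts subjects.  With all
    clusters singletons the two coincide exactly.
    """
    if mode == "observation":
        S = scores.scores
    elif mode == "clustered":
        _, S = scores.cluster_sums()
    else:
        raise ValueError(f"unknown covariance mode {mode!r}")
    return (S.T @ S) / S.shape[0]


def inverse_sqrt(J: np.ndarray) -> tuple[np.ndarray, bool]:
    """Symmetric inverse square root with an eigenvalue floor.

    Returns (J^{-1/2}, degenerate) where ``degenerate`` flags a
    rank-deficient input handled through the pseudo-inverse path.
    """
    J = (J + J.T) / 2.0
    w, V = np.linalg.eigh(J)
    degenerate = bool(np.any(w < EIG_FLOOR))
    if degenerate:
        logger.debug("rank-deficient score covariance; eigenvalues floored")
    w = np.maximum(w, EIG_FLOOR)
    return (V / np.sqrt(w)) @ V.T, degenerate


def cumulative_score_process(scores: np.ndarray, J: np.ndarray) -> np.ndarray:
    """Decorrelated cumulative score process W at t = 1/n, ..., 1.

    ``scores`` must already be ordered by the candidate covariate.  Row m of
    the result is ``J^{-1/2} n^{-1/2} sum_{i<=m} psi_(i)``; the last row is
    the zero vector because the scores sum to zero at the optimum.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    Ji, _ = inverse_sqrt(J)
    return np.cumsum(scores, axis=0) @ Ji.T / np.sqrt(n)


def sup_lm(
    W: np.ndarray,
    trim: tuple[float, float] = (0.1, 0.9),
    eval_mask: np.ndarray | None = None,
) -> float:
    """supLM statistic: max over admissible t of ||W(t)||^2 / (t(1-t)).

    ``eval_mask`` restricts the evaluation grid (e.g. to boundaries between
    distinct covariate values, so ties never host a maximum).  Raises if
    trimming leaves no admissible grid point.
    """
    lo, hi = trim
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("trim must satisfy 0 < lo < hi < 1")
    n = W.shape[0]
    t = np.arange(1, n + 1) / n
    admissible = (t >= lo) & (t <= hi)
    if eval_mask is not None:
        admissible &= np.asarray(eval_mask, dtype=bool)
    if not admissible.any():
        raise ValueError("trimming leaves no admissible split point")
    ss = np.einsum("ij,ij->i", W, W)
    crit = ss[admissible] / (t[admissible] * (1.0 - t[admissible]))
    return float(crit.max())


@functools.lru_cache(maxsize=8)
def _suplm_null(k: int, lo: float, hi: float) -> np.ndarray:
    """Sorted Monte-Carlo null distribution of the supLM functional.

    Simulates k independent Brownian bridges on a grid of MC_GRID steps and
    records sup over t in [lo, hi] of ||B(t)||^2 / (t(1-t)).  Cached per
    (k, trim); the internal seed is fixed so p-values are reproducible.
    """
    rng = np.random.default_rng(_MC_SEED)
    m = MC_GRID
    t = np.arange(1, m + 1) / m
    sel = (t >= lo) & (t <= hi)
    weight = 1.0 / (t[sel] * (1.0 - t[sel]))
    out = np.empty(MC_REPLICATES)
    chunk = 2_000
    pos = 0
    while pos < MC_REPLICATES:
        b = min(chunk, MC_REPLICATES - pos)
        incr = rng.standard_normal((b, m, k)) / np.sqrt(m)
        wpath = np.cumsum(incr, axis=1)
        bridge = wpath - t[None, :, None] * wpath[:, -1:, :]
        ss = np.einsum("rtk,rtk->rt", bridge[:, sel, :], bridge[:, sel, :])
        out[pos : pos + b] = (ss * weight[None, :]).max(axis=1)
        pos += b
    out.sort()
    return out


def sup_lm_pvalue(statistic: float, k: int, trim: tuple[float, float] = (0.1, 0.9)) -> float:
    """Asymptotic p-value of the supLM statistic.

    Computed from a cached Monte-Carlo sample of the limiting Brownian-bridge
    functional; p = (1 + #{null >= stat}) / (R + 1), hence p in (0, 1] and
    monotone non-increasing in the statistic.
    """
    if statistic < 0:
        raise ValueError("supLM statistic must be nonnegative")
    if k < 1:
        raise ValueError("k must be >= 1")
    null = _suplm_null(int(k), round(float(trim[0]), 6), round(float(trim[1]), 6))
    n_ge = null.shape[0] - np.searchsorted(null, statistic, side="left")
    return float((1 + n_ge) / (null.shape[0] + 1))


def categorical_test(
    scores: ScoreMatrix,
    levels: np.ndarray,
    J: np.ndarray,
    mode: str = "observation",
    variable: str = "",
) -> InstabilityResult | None:
    """Chi-square instability test for an unordered factor covariate.

    Scores are binned (summed) per observed factor level; with decorrelated
    level sums S_l and level shares t_l the statistic is
    ``sum_l ||J^{-1/2} n^{-1/2} S_l||^2 / t_l`` with reference distribution
    chi-square on k(L-1) degrees of freedom.  Invariant to level order.
    Returns None when fewer than two levels are observed (untestable).

    ``mode="clustered"`` bins subject-summed scores and counts subjects
    (valid because the factor is constant within subject).
    """
    if mode == "clustered":
        codes, S = scores.cluster_sums()
        lv = np.asarray(levels)
    else:
        S = scores.scores
        lv = np.asarray(levels)
    if lv.shape[0] != S.shape[0]:
        raise ValueError("levels do not match score rows for this mode")

    uniq, inv, counts = np.unique(lv, return_inverse=True, return_counts=True)
    L = uniq.shape[0]
    if L < 2:
        return None
    n = S.shape[0]
    sums = np.zeros((L, S.shape[1]))
    np.add.at(sums, inv, S)
    Ji, _ = inverse_sqrt(J)
    dec = sums @ Ji.T / np.sqrt(n)
    t_l = counts / n
    stat = float((np.einsum("ij,ij->i", dec, dec) / t_l).sum())
    k = S.shape[1]
    df = k * (L - 1)
    p = float(stats.chi2.sf(stat, df))
    return InstabilityResult(
        variable=variable,
        statistic=stat,
        p_value=p,
        p_adjusted=p,
        test_type="categorical",
        df=df,
    )
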