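"""Linear mixed-model engine for node-specific growth curves.

Fits the model ``y_i = X_i beta_j + Z_i b_i + eps_i`` in which the fixed
intercept and time slope are *local* to the terminal node j of a partition
while the random-effect (co)variances are *global*, shared by all subjects.
``Z_i`` is a subset of the (1, time) growth design: nothing, a random
intercept, or a random intercept and slope.

Estimation profiles the fixed effects and the residual variance out of the
(restricted) Gaussian likelihood and optimizes only the 1-3 free elements
of the relative Cholesky factor of the random-effect covariance
(``Psi = sigma_eps^2 L L'``).  Because every subject contributes through a
handful of 2x2 sufficient statistics, one likelihood evaluation is a few
vectorized einsums over subjects, which keeps the alternating tree
algorithm and the simulation harness fast.  Variance ratios are bounded at
zero, so boundary estimates (a variance estimated as exactly 0) are
admissible and simply flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .data_model import LongitudinalDataset

logger = logging.getLogger(__name__)

__all__ = ["RandomEffectsSpec", "LmmFit", "fit_lmm", "extract_offset"]

_LOG2PI = np.log(2.0 * np.pi)
_THETA_BOUND = 50.0


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Which growth-curve terms get random effects, and their covariance.

    kind: "none" | "intercept" | "intercept_slope"
    covariance: "diagonal" | "unstructured" (only meaningful for
        intercept_slope; the correlation is fixed at 0 under "diagonal").
    """

    kind: str = "intercept"
    covariance: str = "diagonal"

    def __post_init__(self) -> None:
        if self.kind not in ("none", "intercept", "intercept_slope"):
            raise ValueError(f"unknown random-effects kind {self.kind!r}")
        if self.covariance not in ("diagonal", "unstructured"):
            raise ValueError(f"unknown covariance structure {self.covariance!r}")

    @property
    def q(self) -> int:
        return {"none": 0, "intercept": 1, "intercept_slope": 2}[self.kind]

    @property
    def n_theta(self) -> int:
        if self.q <= 1:
            return self.q
        return 3 if self.covariance == "unstructured" else 2


@dataclass
class LmmFit:
    """A fitted linear mixed model with node-specific fixed effects."""

    beta: dict  # node label -> (intercept, slope)
    sigma_b: np.ndarray  # (q,) random-effect standard deviations
    re_corr: float | None  # intercept-slope correlation (q=2), else None
    sigma_eps: float
    b_hat: np.ndarray  # (N, q) per-subject random-effect estimates
    loglik: float
    converged: bool
    method: str  # "ML" | "REML"
    re_spec: RandomEffectsSpec
    theta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    node_labels: list = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"Linear mixed model ({self.method}), random effects: {self.re_spec.kind}",
            f"  log-likelihood: {self.loglik:.4f}   converged: {self.converged}",
            f"  sigma_eps: {self.sigma_eps:.4f}",
        ]
        names = ["intercept", "slope"]
        for j, s in enumerate(self.sigma_b):
            lines.append(f"  sigma_b ({names[j]}): {s:.4f}")
        if self.re_corr is not None:
            lines.append(f"  corr(b0, b1): {self.re_corr:.4f}")
        lines.append("  fixed effects per node:")
        for lab in self.node_labels:
            b0, b1 = self.beta[lab]
            lines.append(f"    node {lab}: intercept {b0:.4f}  slope {b1:.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# sufficient statistics
# ---------------------------------------------------------------------------


def _subject_stats(data: LongitudinalDataset):
    """Per-subject cross-products of the (1, time) design with the response."""
    subj, t, y = data.subject, data.time, data.y
    N = data.n_subjects
    S1 = np.bincount(subj, minlength=N).astype(float)
    St = np.bincount(subj, weights=t, minlength=N)
    Stt = np.bincount(subj, weights=t * t, minlength=N)
    Sy = np.bincount(subj, weights=y, minlength=N)
    Sty = np.bincount(subj, weights=t * y, minlength=N)
    Syy = np.bincount(subj, weights=y * y, minlength=N)
    A = np.empty((N, 2, 2))
    A[:, 0, 0] = S1
    A[:, 0, 1] = A[:, 1, 0] = St
    A[:, 1, 1] = Stt
    a = np.stack([Sy, Sty], axis=1)
    return A, a, Syy


def _theta_to_L(theta: np.ndarray, spec: RandomEffectsSpec) -> np.ndarray:
    q = spec.q
    L = np.zeros((q, q))
    if q == 0:
        return L
    if q == 1:
        L[0, 0] = theta[0]
    elif spec.covariance == "diagonal":
        L[0, 0], L[1, 1] = theta[0], theta[1]
    else:
        L[0, 0], L[1, 0], L[1, 1] = theta[0], theta[1], theta[2]
    return L


class _Profile:
    """Profiled (restricted) likelihood machinery for a fixed partition."""

    def __init__(
        self,
        data: LongitudinalDataset,
        node_codes: np.ndarray,
        spec: RandomEffectsSpec,
        method: str,
    ):
        self.spec = spec
        self.method = method
        self.n = data.n_obs
        self.J = int(node_codes.max()) + 1 if node_codes.size else 1
        self.node_codes = node_codes
        self.A, self.a, self.Syy = _subject_stats(data)
        q = spec.q
        zc = list(range(q))
        self.M = self.A[np.ix_(range(self.A.shape[0]), zc, zc)]  # (N,q,q)
        self.ZW = self.A[:, zc, :]  # (N,q,2)
        self.Zy = self.a[:, zc]  # (N,q)
        self.Iq = np.eye(q)

    def _components(self, L: np.ndarray):
        """Node-wise GLS blocks and per-subject quantities for factor L."""
        N = self.A.shape[0]
        q = self.spec.q
        if q == 0:
            K = np.zeros((N, 0, 0))
            H = np.zeros((N, 2, 2))
            h = np.zeros((N, 2))
            u = np.zeros(N)
            logdet = 0.0
        else:
            C = self.Iq[None] + np.einsum("ab,nbc,cd->nad", L.T, self.M, L)
            if q == 1:
                det = C[:, 0, 0]
                Cinv = (1.0 / det)[:, None, None]
            else:
                det = C[:, 0, 0] * C[:, 1, 1] - C[:, 0, 1] * C[:, 1, 0]
                Cinv = np.empty_like(C)
                Cinv[:, 0, 0] = C[:, 1, 1]
                Cinv[:, 1, 1] = C[:, 0, 0]
                Cinv[:, 0, 1] = -C[:, 0, 1]
                Cinv[:, 1, 0] = -C[:, 1, 0]
                Cinv /= det[:, None, None]
            logdet = float(np.log(det).sum())
            K = np.einsum("ab,nbc,dc->nad", L, Cinv, L)  # L C^-1 L'
            H = np.einsum("nqa,nqr,nrb->nab", self.ZW, K, self.ZW)
            h = np.einsum("nqa,nqr,nr->na", self.ZW, K, self.Zy)
            u = np.einsum("nq,nqr,nr->n", self.Zy, K, self.Zy)

        G = np.zeros((self.J, 2, 2))
        g = np.zeros((self.J, 2))
        np.add.at(G, self.node_codes, self.A - H)
        np.add.at(g, self.node_codes, self.a - h)
        qq = float((self.Syy - u).sum())
        return G, g, qq, logdet, K

    def solve_beta(self, G: np.ndarray, g: np.ndarray) -> np.ndarray:
        beta = np.empty((self.J, 2))
        for j in range(self.J):
            try:
                beta[j] = np.linalg.solve(G[j], g[j])
            except np.linalg.LinAlgError:
                beta[j] = np.linalg.pinv(G[j]) @ g[j]
        return beta

    def neg2ll(self, theta: np.ndarray) -> float:
        L = _theta_to_L(np.asarray(theta, dtype=float), self.spec)
        G, g, qq, logdet, _ = self._components(L)
        beta = self.solve_beta(G, g)
        rss = qq - float(np.einsum("ja,ja->", g, beta))
        rss = max(rss, 1e-12)
        n, p = self.n, 2 * self.J
        if self.method == "REML":
            dof = n - p
            sig2 = rss / dof
            sld = 0.0
            for j in range(self.J):
                sign, ld = np.linalg.slogdet(G[j])
                sld += ld
            return dof * (np.log(sig2) + _LOG2PI) + logdet + sld + dof
        sig2 = rss / n
        return n * (np.log(sig2) + _LOG2PI) + logdet + n

    def finalize(self, theta: np.ndarray):
        L = _theta_to_L(np.asarray(theta, dtype=float), self.spec)
        G, g, qq, logdet, K = self._components(L)
        beta = self.solve_beta(G, g)
        rss = max(qq - float(np.einsum("ja,ja->", g, beta)), 1e-12)
        n, p = self.n, 2 * self.J
        dof = n - p if self.method == "REML" else n
        sig2 = rss / dof
        loglik = -0.5 * self.neg2ll(theta)
        # BLUPs: b_i = L C_i^{-1} L' Z_i'(y_i - X_i beta_{j(i)})
        if self.spec.q:
            resid_z = self.Zy - np.einsum("nqa,na->nq", self.ZW, beta[self.node_codes])
            b_hat = np.einsum("nqr,nr->nq", K, resid_z)
        else:
            b_hat = np.zeros((self.A.shape[0], 0))
        Psi = sig2 * (L @ L.T)
        return beta, sig2, Psi, b_hat, loglik


def _node_codes(data: LongitudinalDataset, partition) -> tuple[np.ndarray, list]:
    """Normalize a subject->node mapping to contiguous codes + label list."""
    N = data.n_subjects
    if isinstance(partition, dict):
        labels_per_subject = np.asarray([partition[i] for i in range(N)])
    else:
        labels_per_subject = np.asarray(partition)
        if labels_per_subject.shape[0] != N:
            raise ValueError("partition must assign a node to every subject")
    uniq, codes = np.unique(labels_per_subject, return_inverse=True)
    return codes.astype(np.int64), list(uniq)


def fit_lmm(
    data: LongitudinalDataset,
    partition,
    re_spec: RandomEffectsSpec = RandomEffectsSpec(),
    method: str = "ML",
    start: np.ndarray | None = None,
) -> LmmFit:
    """Fit the mixed model for a given partition of subjects into nodes.

    Fixed effects (intercept, slope) are estimated per node; random-effect
    (co)variances globally.  ``partition`` maps subject code -> node label
    (array of length N or dict).  ``start`` optionally warm-starts the
    relative-Cholesky parameters from a previous iteration.
    """
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    codes, labels = _node_codes(data, partition)
    prof = _Profile(data, codes, re_spec, method)

    converged = True
    if re_spec.n_theta == 0:
        theta = np.zeros(0)
    elif re_spec.n_theta == 1:
        res = optimize.minimize_scalar(
            lambda s: prof.neg2ll([s]), bounds=(0.0, _THETA_BOUND), method="bounded",
            options={"xatol": 1e-8},
        )
        theta = np.array([res.x])
        converged = bool(res.success)
    else:
        bounds = [(0.0, _THETA_BOUND)] * 2
        starts = [np.array([0.5, 0.15]), np.array([2.0, 0.6])]
        if re_spec.n_theta == 3:
            bounds = [(0.0, _THETA_BOUND), (-_THETA_BOUND, _THETA_BOUND), (0.0, _THETA_BOUND)]
            starts = [np.array([0.5, 0.0, 0.15]), np.array([2.0, 0.0, 0.6])]
        if start is not None and len(start) == re_spec.n_theta:
            starts = [np.asarray(start, dtype=float)] + starts[:1]
        best = None
        for s0 in starts:
            res = optimize.minimize(
                prof.neg2ll, s0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 200, "ftol": 1e-10},
            )
            if best is None or res.fun < best.fun - 1e-9:
                best = res
        theta = np.asarray(best.x)
        converged = bool(best.success)
    if not converged:
        logger.warning("LMM optimizer did not report convergence (flagged, not fatal)")

    beta, sig2, Psi, b_hat, loglik = prof.finalize(theta)
    q = re_spec.q
    sigma_b = np.sqrt(np.diag(Psi)) if q else np.zeros(0)
    re_corr = None
    if q == 2:
        denom = sigma_b[0] * sigma_b[1]
        re_corr = float(Psi[0, 1] / denom) if denom > 0 else 0.0
        if re_spec.covariance == "diagonal":
            re_corr = 0.0
    beta_map = {lab: (float(beta[j, 0]), float(beta[j, 1])) for j, lab in enumerate(labels)}
    return LmmFit(
        beta=beta_map,
        sigma_b=sigma_b,
        re_corr=re_corr,
        sigma_eps=float(np.sqrt(sig2)),
        b_hat=b_hat,
        loglik=float(loglik),
        converged=converged,
        method=method,
        re_spec=re_spec,
        theta=theta,
        node_labels=labels,
    )


def extract_offset(fit: LmmFit, data: LongitudinalDataset) -> np.ndarray:
    """Per-observation random-effect offset ``Z_i b_hat_i``.

    Zero when no random effects are present.  Raises if the fit does not
    cover every subject in ``data``.
    """
    q = fit.re_spec.q
    if q == 0:
        return np.zeros(data.n_obs)
    if fit.b_hat.shape[0] != data.n_subjects:
        raise ValueError("fit does not cover all subjects in the data")
    off = fit.b_hat[data.subject, 0].copy()
    if q == 2:
        off += fit.b_hat[data.subject, 1] * data.time
    return off
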