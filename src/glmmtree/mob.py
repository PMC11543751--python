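"""Model-based recursive partitioning of growth curves (the tree grower).

Grows a binary tree over subject-level covariates for the linear model
``y - offset ~ intercept + slope * time``.  In every node the algorithm
(a) fits the node model by least squares, (b) tests parameter stability
against each candidate covariate via score-based tests, (c) splits on the
covariate with the smallest (Bonferroni-adjusted) p-value if it is below
alpha, choosing the cutpoint that minimizes the summed residual sum of
squares of the two child fits, and (d) recurses into the children.

Candidate covariates are time-constant, so split rules act on subjects:
cutpoints are searched over subject-level values and node sizes are
counted in subjects.  The random-effect structure enters only through the
per-observation ``offset``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import LongitudinalDataset, PartitionTree, Split, TreeNode
from .stability import (
    InstabilityResult,
    ScoreMatrix,
    categorical_test,
    covariance_estimate,
    cumulative_score_process,
    sup_lm,
    sup_lm_pvalue,
)

logger = logging.getLogger(__name__)

__all__ = ["MobOptions", "grow_lm_tree", "test_node", "select_split_variable", "select_cutpoint"]


@dataclass(frozen=True)
class MobOptions:
    """Stopping and testing options for the tree grower.

    alpha: significance level for the pre-split instability tests.
    bonferroni: adjust p-values for the number of testable candidates.
    covariance_mode: "observation" (classic) or "clustered" (subject-summed
        scores) covariances in the stability tests.
    min_subjects_per_node: smallest admissible terminal node, in subjects.
    max_depth: depth limit (root has depth 0); None = unlimited.
    trim: supLM trimming interval as fractions of the ordered sample.
    max_exhaustive_levels: categorical cutpoint search is exhaustive up to
        this many levels, greedy (ordered by node-mean response) beyond.
    """

    alpha: float = 0.05
    bonferroni: bool = True
    covariance_mode: str = "observation"
    min_subjects_per_node: int = 10
    max_depth: int | None = None
    trim: tuple[float, float] = (0.1, 0.9)
    max_exhaustive_levels: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_subjects_per_node < 2:
            raise ValueError("min_subjects_per_node must be >= 2")
        if self.covariance_mode not in ("observation", "clustered"):
            raise ValueError(f"unknown covariance mode {self.covariance_mode!r}")


class _NodeData:
    """Observation- and subject-level views of one tree node."""

    def __init__(self, grower: "_Grower", subjects: np.ndarray):
        self.g = grower
        self.subjects = subjects  # global subject codes, ascending
        self.n_subjects = subjects.shape[0]
        mask = grower.data.subset_subjects(subjects)
        self.obs_idx = np.flatnonzero(mask)
        self.n_obs = self.obs_idx.shape[0]
        # node sufficient statistics on the offset-adjusted response
        self.G = grower.A[subjects].sum(axis=0)
        self.gvec = grower.a[subjects].sum(axis=0)
        self.sq = grower.s[subjects].sum()

    def fit(self) -> tuple[np.ndarray, float]:
        """OLS coefficients of r ~ (1, time) in the node, and the RSS."""
        try:
            beta = np.linalg.solve(self.G, self.gvec)
        except np.linalg.LinAlgError:
            beta = np.linalg.pinv(self.G) @ self.gvec
        rss = self.sq - float(self.gvec @ beta)
        return beta, max(rss, 0.0)

    def obs_scores(self, beta: np.ndarray) -> ScoreMatrix:
        g = self.g
        t = g.data.time[self.obs_idx]
        r = g.r[self.obs_idx]
        subj = g.data.subject[self.obs_idx]
        resid = r - beta[0] - beta[1] * t
        X = np.column_stack([np.ones_like(t), t])
        return ScoreMatrix(scores=X * resid[:, None], cluster=subj)

    def subject_scores(self, beta: np.ndarray) -> np.ndarray:
        """Within-subject score sums, computable from sufficient statistics."""
        g = self.g
        return g.a[self.subjects] - g.A[self.subjects] @ beta


def test_node(
    node: _NodeData,
    beta: np.ndarray,
    candidates: list[str],
    options: MobOptions,
) -> list[InstabilityResult]:
    """Instability tests of the node model against each candidate covariate.

    Numeric candidates take the supLM path, factors the level-binned
    chi-square path; constant-in-node candidates are untestable and are
    skipped (logged).  Bonferroni adjustment uses the number of *testable*
    candidates.
    """
    data = node.g.data
    clustered = options.covariance_mode == "clustered"
    sub_scores = node.subject_scores(beta)
    obs_sm = node.obs_scores(beta)
    if clustered:
        J = covariance_estimate(obs_sm, "clustered")
    else:
        J = covariance_estimate(obs_sm, "observation")

    results: list[InstabilityResult] = []
    for name in candidates:
        u_subj = data.covariates[name].to_numpy()[node.subjects]
        if data.is_categorical(name):
            if len(pd.unique(u_subj)) < 2:
                logger.debug("candidate %s constant in node; untestable", name)
                continue
            if clustered:
                # node.subjects is ascending, matching cluster_sums order
                res = categorical_test(obs_sm, u_subj, J, mode="clustered", variable=name)
            else:
                u_obs = data.covariates[name].to_numpy()[data.subject[node.obs_idx]]
                res = categorical_test(obs_sm, u_obs, J, mode="observation", variable=name)
            if res is None:
                continue
            results.append(res)
        else:
            u = u_subj.astype(float)
            if np.unique(u).shape[0] < 2:
                logger.debug("candidate %s constant in node; untestable", name)
                continue
            if clustered:
                order = np.argsort(u, kind="stable")
                S = sub_scores[order]
                u_sorted = u[order]
            else:
                u_obs = data.covariates[name].to_numpy()[data.subject[node.obs_idx]].astype(float)
                order = np.lexsort((data.subject[node.obs_idx], u_obs))
                S = obs_sm.scores[order]
                u_sorted = u_obs[order]
            boundary = np.empty(u_sorted.shape[0], dtype=bool)
            boundary[:-1] = u_sorted[:-1] != u_sorted[1:]
            boundary[-1] = False
            W = cumulative_score_process(S, J)
            try:
                stat = sup_lm(W, trim=options.trim, eval_mask=boundary)
            except ValueError:
                logger.debug("candidate %s: no admissible split point", name)
                continue
            p = sup_lm_pvalue(stat, k=S.shape[1], trim=options.trim)
            results.append(
                InstabilityResult(
                    variable=name, statistic=stat, p_value=p, p_adjusted=p,
                    test_type="supLM",
                )
            )

    m = len(results)
    if options.bonferroni and m > 1:
        for r in results:
            r.p_adjusted = min(1.0, m * r.p_value)
    return results


def select_split_variable(
    results: list[InstabilityResult], alpha: float
) -> InstabilityResult | None:
    """Candidate with smallest adjusted p-value if significant, else None.

    Ties on the p-value are broken by the larger statistic, then by
    candidate order, so selection is deterministic.
    """
    best = None
    for r in results:
        if r.p_adjusted > alpha:
            continue
        if best is None or (r.p_adjusted, -r.statistic) < (best.p_adjusted, -best.statistic):
            best = r
    return best


def _child_rss(cumG, cumg, cums, totG, totg, tots):
    """Vectorized left+right RSS at every prefix boundary (2x2 closed form)."""

    def rss(G, g, s):
        det = G[..., 0, 0] * G[..., 1, 1] - G[..., 0, 1] * G[..., 1, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            b0 = (G[..., 1, 1] * g[..., 0] - G[..., 0, 1] * g[..., 1]) / det
            b1 = (G[..., 0, 0] * g[..., 1] - G[..., 0, 1] * g[..., 0]) / det
            out = s - (g[..., 0] * b0 + g[..., 1] * b1)
        out = np.where(np.abs(det) < 1e-12, np.inf, out)
        return out

    left = rss(cumG, cumg, cums)
    right = rss(totG - cumG, totg - cumg, tots - cums)
    return left + right


def select_cutpoint(
    node: _NodeData, variable: str, options: MobOptions
) -> Split | None:
    """Cutpoint minimizing the summed child RSS of the offset-adjusted fits.

    Numeric: thresholds at midpoints between adjacent distinct subject-level
    values; categorical: best binary level partition (exhaustive up to
    ``max_exhaustive_levels``, greedy by level-mean response beyond).  Only
    cutpoints whose children hold at least ``min_subjects_per_node``
    subjects are admissible; returns None when no cutpoint is admissible.
    """
    g = node.g
    data = g.data
    u = data.covariates[variable].to_numpy()[node.subjects]
    msize = options.min_subjects_per_node
    totG, totg, tots = node.G, node.gvec, node.sq

    if not data.is_categorical(variable):
        u = u.astype(float)
        order = np.argsort(u, kind="stable")
        us = u[order]
        subj = node.subjects[order]
        cumG = np.cumsum(g.A[subj], axis=0)
        cumg = np.cumsum(g.a[subj], axis=0)
        cums = np.cumsum(g.s[subj])
        n = us.shape[0]
        idx = np.arange(n - 1)
        admissible = (us[:-1] != us[1:]) & (idx + 1 >= msize) & (n - idx - 1 >= msize)
        if not admissible.any():
            logger.debug("no admissible cutpoint for %s", variable)
            return None
        obj = _child_rss(cumG[:-1], cumg[:-1], cums[:-1], totG, totg, tots)
        obj = np.where(admissible, obj, np.inf)
        best = int(np.argmin(obj))
        if not np.isfinite(obj[best]):
            return None
        thr = 0.5 * (us[best] + us[best + 1])
        return Split(variable=variable, kind="numeric", threshold=float(thr))

    # categorical
    levels, inv, counts = np.unique(u, return_inverse=True, return_counts=True)
    L = levels.shape[0]
    if L < 2:
        return None
    aggG = np.zeros((L, 2, 2))
    agga = np.zeros((L, 2))
    aggs = np.zeros(L)
    np.add.at(aggG, inv, g.A[node.subjects])
    np.add.at(agga, inv, g.a[node.subjects])
    np.add.at(aggs, inv, g.s[node.subjects])

    def part_rss(mask: np.ndarray) -> float:
        nl = counts[mask].sum()
        if nl < msize or counts[~mask].sum() < msize:
            return np.inf
        GL = aggG[mask].sum(axis=0)
        gL = agga[mask].sum(axis=0)
        sL = aggs[mask].sum()
        val = _child_rss(GL[None], gL[None], np.array([sL]), totG, totg, tots)[0]
        return float(val)

    best_mask, best_obj = None, np.inf
    if L <= options.max_exhaustive_levels:
        # level 0 fixed to the left side: enumerates each bipartition once
        for code in range(2 ** (L - 1)):
            mask = np.zeros(L, dtype=bool)
            mask[0] = True
            for b in range(L - 1):
                if code >> b & 1:
                    mask[b + 1] = True
            if mask.all():
                continue
            val = part_rss(mask)
            if val < best_obj - 1e-12:
                best_obj, best_mask = val, mask.copy()
    else:
        mean_lvl = agga[:, 0] / np.maximum(aggG[:, 0, 0], 1.0)
        lorder = np.argsort(mean_lvl, kind="stable")
        for cut in range(1, L):
            mask = np.zeros(L, dtype=bool)
            mask[lorder[:cut]] = True
            val = part_rss(mask)
            if val < best_obj - 1e-12:
                best_obj, best_mask = val, mask.copy()

    if best_mask is None or not np.isfinite(best_obj):
        logger.debug("no admissible level partition for %s", variable)
        return None
    return Split(
        variable=variable,
        kind="categorical",
        left_levels=tuple(np.asarray(levels[best_mask]).tolist()),
        right_levels=tuple(np.asarray(levels[~best_mask]).tolist()),
    )


class _Grower:
    def __init__(self, data, offset, candidates, options):
        self.data = data
        self.options = options
        self.candidates = list(candidates)
        self.r = data.y - (np.zeros(data.n_obs) if offset is None else np.asarray(offset, float))
        subj, t = data.subject, data.time
        N = data.n_subjects
        S1 = np.bincount(subj, minlength=N).astype(float)
        St = np.bincount(subj, weights=t, minlength=N)
        Stt = np.bincount(subj, weights=t * t, minlength=N)
        Sr = np.bincount(subj, weights=self.r, minlength=N)
        Str = np.bincount(subj, weights=t * self.r, minlength=N)
        Srr = np.bincount(subj, weights=self.r * self.r, minlength=N)
        self.A = np.empty((N, 2, 2))
        self.A[:, 0, 0] = S1
        self.A[:, 0, 1] = self.A[:, 1, 0] = St
        self.A[:, 1, 1] = Stt
        self.a = np.stack([Sr, Str], axis=1)
        self.s = Srr
        self.nodes: dict[int, TreeNode] = {}
        self._next_id = 1

    def grow(self) -> PartitionTree:
        all_subjects = np.arange(self.data.n_subjects)
        self._build(all_subjects, depth=0)
        return PartitionTree(nodes=self.nodes, root_id=1)

    def _build(self, subjects: np.ndarray, depth: int) -> int:
        node_id = self._next_id
        self._next_id += 1
        nd = _NodeData(self, subjects)
        beta, rss = nd.fit()
        tn = TreeNode(
            node_id=node_id, depth=depth, n_subjects=nd.n_subjects, n_obs=nd.n_obs,
            beta=(float(beta[0]), float(beta[1])),
        )
        self.nodes[node_id] = tn

        opt = self.options
        can_split = (
            (opt.max_depth is None or depth < opt.max_depth)
            and nd.n_subjects >= 2 * opt.min_subjects_per_node
            and rss / max(nd.n_obs, 1) > 1e-12  # degenerate (constant) response
        )
        if not can_split:
            return node_id

        results = test_node(nd, beta, self.candidates, opt)
        tn.test_record = [r.as_record() for r in results]
        chosen = select_split_variable(results, opt.alpha)
        if chosen is None:
            return node_id
        split = select_cutpoint(nd, chosen.variable, opt)
        if split is None:
            logger.debug("node %d: %s selected but no admissible cutpoint", node_id, chosen.variable)
            return node_id

        u = self.data.covariates[split.variable].to_numpy()[subjects]
        left = split.goes_left(u)
        tn.split = split
        tn.beta = None
        left_id = self._build(subjects[left], depth + 1)
        right_id = self._build(subjects[~left], depth + 1)
        tn.children = (left_id, right_id)
        return node_id


def grow_lm_tree(
    data: LongitudinalDataset,
    offset: np.ndarray | None,
    candidates: list[str] | None = None,
    options: MobOptions = MobOptions(),
) -> PartitionTree:
    """Grow an LM tree on the offset-adjusted response.

    Terminal-node coefficients are the node-wise least-squares estimates of
    ``y - offset ~ (1, time)``; every internal node stores the instability
    test table that produced its split.
    """
    if candidates is None:
        candidates = data.covariate_names
    grower = _Grower(data, offset, candidates, options)
    return grower.grow()
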