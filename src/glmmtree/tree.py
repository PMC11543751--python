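"""Alternating estimation of GLMM trees: tree step <-> mixed-model step.

The fitted model combines a binary partition of subjects (over
time-constant covariates) with node-specific fixed growth curves and
globally estimated random effects.  Estimation alternates between

1. growing an LM tree on the response minus the current random-effect
   predictions (used as an offset), and
2. refitting the mixed model with node-specific fixed effects for the
   partition just found, extracting updated per-subject random effects,

until the partition repeats, the mixed-model log-likelihood stabilizes, or
an iteration cap is reached.  Two initializations are supported: ``zero``
starts from all random effects at zero (so iteration 1 is an LM tree on the
raw data), while ``random_effects`` first fits the one-group mixed model to
the full sample and starts from its predicted random effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_model import LongitudinalDataset, PartitionTree, route_subjects
from .lmm import LmmFit, RandomEffectsSpec, extract_offset, fit_lmm
from .mob import MobOptions, grow_lm_tree

logger = logging.getLogger(__name__)

__all__ = ["GlmmTreeSpec", "GlmmTreeModel", "fit_glmm_tree", "predict_fixed"]


@dataclass(frozen=True)
class GlmmTreeSpec:
    """Full specification of one GLMM-tree fit."""

    re_spec: RandomEffectsSpec = RandomEffectsSpec()
    init_mode: str = "zero"  # "zero" | "random_effects"
    mob: MobOptions = MobOptions()
    max_iterations: int = 25
    loglik_tol: float = 1e-4
    method: str = "ML"

    def __post_init__(self) -> None:
        if self.init_mode not in ("zero", "random_effects"):
            raise ValueError(f"unknown init mode {self.init_mode!r}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.loglik_tol <= 0:
            raise ValueError("loglik_tol must be > 0")


@dataclass
class GlmmTreeModel:
    tree: PartitionTree
    lmm: LmmFit
    iterations: int
    loglik_trace: list[float] = field(default_factory=list)
    converged_by: str = "partition_repeat"

    @property
    def n_splits(self) -> int:
        return self.tree.n_splits

    def summary(self) -> str:
        head = (
            f"GLMM tree: {self.tree.n_splits} split(s), "
            f"{len(self.tree.terminal_ids)} terminal node(s); "
            f"{self.iterations} iteration(s), converged by {self.converged_by}"
        )
        return head + "\n" + self.tree.render() + "\n" + self.lmm.summary()


def _canonical(partition: np.ndarray) -> tuple:
    """Label-free key for a partition (first-occurrence relabeling)."""
    seen: dict = {}
    out = []
    for v in partition:
        if v not in seen:
            seen[v] = len(seen)
        out.append(seen[v])
    return tuple(out)


def _leaf_betas_into_tree(tree: PartitionTree, lmm: LmmFit) -> None:
    for lab in lmm.node_labels:
        tree.nodes[int(lab)].beta = lmm.beta[lab]


def fit_glmm_tree(
    data: LongitudinalDataset,
    candidates: list[str] | None = None,
    spec: GlmmTreeSpec = GlmmTreeSpec(),
) -> GlmmTreeModel:
    """Fit a GLMM tree by alternating tree and mixed-model estimation.

    With ``re_spec.kind == "none"`` this reduces to a single LM-tree pass.
    Terminal-node coefficients of the returned tree are the mixed-model
    fixed effects for the final partition.
    """
    if candidates is None:
        candidates = data.covariate_names
    re_spec = spec.re_spec

    if re_spec.kind == "none":
        tree = grow_lm_tree(data, None, candidates, spec.mob)
        part = route_subjects(tree, data)
        lmm = fit_lmm(data, part, re_spec, spec.method)
        _leaf_betas_into_tree(tree, lmm)
        return GlmmTreeModel(
            tree=tree, lmm=lmm, iterations=1, loglik_trace=[lmm.loglik],
            converged_by="partition_repeat",
        )

    if spec.init_mode == "random_effects":
        try:
            init_fit = fit_lmm(data, np.zeros(data.n_subjects, dtype=int), re_spec, spec.method)
        except Exception as exc:  # pragma: no cover - fatal by contract
            raise RuntimeError("full-sample mixed-model initialization failed") from exc
        offset = extract_offset(init_fit, data)
        theta = init_fit.theta
    else:
        offset = np.zeros(data.n_obs)
        theta = None

    prev_key = None
    prev_ll = None
    trace: list[float] = []
    seen: dict[tuple, tuple[PartitionTree, LmmFit]] = {}
    tree = None
    lmm = None
    converged_by = "max_iter"

    for _ in range(spec.max_iterations):
        new_tree = grow_lm_tree(data, offset, candidates, spec.mob)
        part = route_subjects(new_tree, data)
        key = _canonical(part)
        if key == prev_key:
            converged_by = "partition_repeat"
            tree = new_tree
            break
        tree = new_tree

        try:
            new_lmm = fit_lmm(data, part, re_spec, spec.method, start=theta)
        except Exception:
            logger.warning("mixed-model fit failed mid-alternation; keeping previous estimates")
            if lmm is None:
                raise
            converged_by = "lmm_failure"
            break
        if key in seen:
            # partition seen before but not in the previous iteration: cycle
            old_tree, old_lmm = seen[key]
            if old_lmm.loglik >= new_lmm.loglik:
                tree, lmm = old_tree, old_lmm
            else:
                lmm = new_lmm
            trace.append(new_lmm.loglik)
            converged_by = "cycle"
            logger.warning("alternation cycled between partitions; keeping higher-loglik model")
            break
        seen[key] = (tree, new_lmm)
        lmm = new_lmm
        trace.append(lmm.loglik)
        theta = lmm.theta

        if prev_ll is not None and abs(lmm.loglik - prev_ll) < spec.loglik_tol:
            converged_by = "loglik"
            break
        prev_ll = lmm.loglik
        prev_key = key
        offset = extract_offset(lmm, data)

    if lmm is None:  # max_iterations == 1 edge: fit the model for the tree we grew
        part = route_subjects(tree, data)
        lmm = fit_lmm(data, part, re_spec, spec.method, start=theta)
        trace.append(lmm.loglik)

    # make terminal coefficients those of the mixed model for the final
    # partition; refit (warm-started, instant) if the final tree's leaf ids
    # differ from the ones the last mixed model was fitted under
    part = route_subjects(tree, data)
    if sorted(map(int, lmm.node_labels)) != sorted(np.unique(part).tolist()):
        lmm = fit_lmm(data, part, re_spec, spec.method, start=lmm.theta)
    _leaf_betas_into_tree(tree, lmm)

    return GlmmTreeModel(
        tree=tree, lmm=lmm, iterations=len(trace), loglik_trace=trace,
        converged_by=converged_by,
    )


def predict_fixed(model: GlmmTreeModel, newdata: LongitudinalDataset, unseen: str = "error") -> np.ndarray:
    """Fixed-effects predictions for new data (no random effects used).

    Each subject is routed through the tree; the prediction is the terminal
    node's intercept plus slope times the observation time.
    """
    leaf = model.tree.route(newdata.covariates, unseen=unseen)
    b = np.asarray([model.tree.nodes[int(l)].beta for l in leaf])
    return b[newdata.subject, 0] + b[newdata.subject, 1] * newdata.time
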