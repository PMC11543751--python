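"""Synthetic-data generator and evaluation harness for subgroup recovery.

The generator emulates a four-subgroup linear growth curve design: one
binary covariate ``u1`` splits the population first, a continuous ``u2``
splits the ``u1 = 0`` branch and a continuous ``u3`` the ``u1 = 1``
branch, giving four terminal subgroups with their own fixed intercept and
slope (three true splits).  All candidate covariates are drawn with
variance 25; ``u1`` is a standard normal draw binarized at its population
mean; an optional intercorrelation ``rho`` couples the three true
partitioning variables (Gaussian copula applied before binarizing).  Noise
covariates are independent.  Every subject is observed at timepoints
0..4; random intercepts/slopes have a diagonal covariance and the residual
variance is 5.

The factorial study grid varies sample size (100/250), random-intercept
variance (1/4), random-slope variance (0.1/0.4), number of noise
covariates (5/25) and rho (0/0.3) - 32 cells.  Evaluation counts tree
splits (true size 3; more = type I, fewer = type II) and the covariate
chosen for the first split.
"""

from __future__ import annotations

import itertools
import logging
import time as _time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import LongitudinalDataset
from .lmm import RandomEffectsSpec
from .mob import MobOptions
from .tree import GlmmTreeModel, GlmmTreeSpec, fit_glmm_tree

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_BETA_BY_NODE",
    "APPROACHES",
    "SimulationDesign",
    "StudyResult",
    "simulate_dataset",
    "implied_icc",
    "full_grid",
    "evaluate_tree",
    "run_study",
]

#: Node-specific (intercept, slope) for the four terminal subgroups, in the
#: order (u1=0 & u2<=thr), (u1=0 & u2>thr), (u1=1 & u3<=thr), (u1=1 & u3>thr).
#: Configuration values of the built-in design; see docs/methods.md for how
#: they were chosen.
DEFAULT_BETA_BY_NODE: tuple[tuple[float, float], ...] = (
    (0.0, 0.75),
    (1.5, 1.5),
    (3.0, 2.25),
    (4.5, 3.0),
)


@dataclass(frozen=True)
class SimulationDesign:
    """One cell of the data-generating design."""

    N: int = 100
    sigma_b0_sq: float = 1.0
    sigma_b1_sq: float = 0.1
    n_noise: int = 5
    rho: float = 0.0
    sigma_eps_sq: float = 5.0
    timepoints: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0)
    beta_by_node: tuple[tuple[float, float], ...] = DEFAULT_BETA_BY_NODE
    u2_threshold: float = 0.0
    u3_threshold: float = 0.0
    covariate_var: float = 25.0

    def label(self) -> str:
        return (
            f"N{self.N}_sb0{self.sigma_b0_sq:g}_sb1{self.sigma_b1_sq:g}"
            f"_p{self.n_noise}_rho{self.rho:g}"
        )


def full_grid() -> list[SimulationDesign]:
    """The 2^5 factorial grid (32 cells) in fixed factor order."""
    grid = []
    for N, sb0, sb1, p, rho in itertools.product(
        (100, 250), (1.0, 4.0), (0.1, 0.4), (5, 25), (0.0, 0.3)
    ):
        grid.append(SimulationDesign(N=N, sigma_b0_sq=sb0, sigma_b1_sq=sb1, n_noise=p, rho=rho))
    return grid


def implied_icc(sigma_b0_sq: float, sigma_eps_sq: float) -> float:
    """Intra-class correlation implied by the variance components.

    ``sigma_b0_sq / (sigma_b0_sq + sigma_eps_sq)``, rounded to 3 decimals
    for reporting.
    """
    if sigma_b0_sq < 0 or sigma_eps_sq < 0:
        raise ValueError("variances must be nonnegative")
    if sigma_b0_sq == 0 and sigma_eps_sq == 0:
        raise ValueError("at least one variance must be positive")
    return round(sigma_b0_sq / (sigma_b0_sq + sigma_eps_sq), 3)


def simulate_dataset(
    design: SimulationDesign, seed
) -> tuple[LongitudinalDataset, dict]:
    """Draw one dataset from the design; returns (dataset, truth).

    ``truth`` holds the per-subject subgroup index (0-3, in the node order
    of ``beta_by_node``), the true first-split variable ("u1") and the true
    number of splits (3).  ``seed`` may be an int or a seed sequence.
    """
    rng = np.random.default_rng(seed)
    N = design.N
    sd_u = np.sqrt(design.covariate_var)

    # true partitioning variables: correlated trivariate normal, u1 binarized
    C = np.full((3, 3), design.rho)
    np.fill_diagonal(C, 1.0)
    z = rng.multivariate_normal(np.zeros(3), C, size=N, method="cholesky") * sd_u
    u1 = (z[:, 0] > 0.0).astype(int)  # binarize at the population mean
    u2, u3 = z[:, 1], z[:, 2]
    noise = rng.normal(0.0, sd_u, size=(N, design.n_noise))

    node = np.where(
        u1 == 0,
        np.where(u2 <= design.u2_threshold, 0, 1),
        np.where(u3 <= design.u3_threshold, 2, 3),
    )
    beta = np.asarray(design.beta_by_node, dtype=float)

    T = len(design.timepoints)
    t = np.tile(np.asarray(design.timepoints, dtype=float), N)
    subj = np.repeat(np.arange(N), T)
    b0 = rng.normal(0.0, np.sqrt(design.sigma_b0_sq), N)
    b1 = rng.normal(0.0, np.sqrt(design.sigma_b1_sq), N)
    eps = rng.normal(0.0, np.sqrt(design.sigma_eps_sq), N * T)
    y = beta[node][subj, 0] + beta[node][subj, 1] * t + b0[subj] + b1[subj] * t + eps

    cov = pd.DataFrame({"u1": pd.Categorical(u1, categories=[0, 1]), "u2": u2, "u3": u3})
    for j in range(design.n_noise):
        cov[f"u{4 + j}"] = noise[:, j]

    data = LongitudinalDataset(
        subject=subj, subject_ids=np.arange(N), time=t, y=y, covariates=cov
    )
    truth = {
        "subgroup": node,
        "first_split_variable": "u1",
        "n_splits": 3,
        "b0": b0,
        "b1": b1,
        "design": design,
    }
    return data, truth


# ---------------------------------------------------------------------------
# fitting approaches
# ---------------------------------------------------------------------------


def _approach(re_kind: str, covariance: str, init: str) -> GlmmTreeSpec:
    return GlmmTreeSpec(
        re_spec=RandomEffectsSpec(kind=re_kind, covariance="diagonal"),
        init_mode=init,
        mob=MobOptions(covariance_mode=covariance),
    )


#: The ten fitting approaches of the subgroup-recovery study: LM trees
#: (no random effects) x {observation, clustered} covariances, and LMM
#: trees (random intercepts, or intercepts+slopes) x {default, clustered
#: covariances, random-effects initialization, both}.
APPROACHES: dict[str, GlmmTreeSpec] = {
    "lm_default": _approach("none", "observation", "zero"),
    "lm_clcov": _approach("none", "clustered", "zero"),
    "lmm_int_default": _approach("intercept", "observation", "zero"),
    "lmm_int_clcov": _approach("intercept", "clustered", "zero"),
    "lmm_int_ranef": _approach("intercept", "observation", "random_effects"),
    "lmm_int_clcov_ranef": _approach("intercept", "clustered", "random_effects"),
    "lmm_slope_default": _approach("intercept_slope", "observation", "zero"),
    "lmm_slope_clcov": _approach("intercept_slope", "clustered", "zero"),
    "lmm_slope_ranef": _approach("intercept_slope", "observation", "random_effects"),
    "lmm_slope_clcov_ranef": _approach("intercept_slope", "clustered", "random_effects"),
}

#: The three default-covariance, zero-initialization approaches.
DEFAULT_APPROACHES = ("lm_default", "lmm_int_default", "lmm_slope_default")


def evaluate_tree(model_or_tree, truth: dict) -> dict:
    """Per-dataset recovery metrics against the generating truth.

    n_splits deviation from the true 3 classifies the tree: more = "type_I",
    fewer = "type_II", equal = "correct".  The first-split variable is one
    of u1/u2/u3, a noise covariate name, or "none" for a rootless tree.
    """
    tree = model_or_tree.tree if isinstance(model_or_tree, GlmmTreeModel) else model_or_tree
    n_splits = tree.n_splits
    true_n = truth["n_splits"]
    if n_splits > true_n:
        err = "type_I"
    elif n_splits < true_n:
        err = "type_II"
    else:
        err = "correct"
    first = tree.first_split_variable() or "none"
    return {
        "n_splits": n_splits,
        "deviation": n_splits - true_n,
        "error_class": err,
        "first_split_variable": first,
        "first_split_correct": first == truth["first_split_variable"],
    }


def _first_split_group(var: str) -> str:
    if var in ("u1", "u2", "u3", "none"):
        return "no split" if var == "none" else var
    return "noise"


@dataclass
class StudyResult:
    """Row-per-fit study results with the aggregate views of the harness."""

    rows: pd.DataFrame

    def tree_size_summary(self) -> pd.DataFrame:
        """Per approach: mean splits M, SD, MAD from the true 3 splits, and
        the share of trees with more than 3 splits (type I)."""

        def agg(g: pd.DataFrame) -> pd.Series:
            ns = g["n_splits"].to_numpy(dtype=float)
            return pd.Series(
                {
                    "M": ns.mean(),
                    "SD": ns.std(ddof=1) if ns.size > 1 else 0.0,
                    "MAD": np.abs(ns - 3).mean(),
                    "share_gt3": float((ns > 3).mean()),
                    "n": ns.size,
                }
            )

        out = self.rows.groupby("approach", sort=False).apply(agg, include_groups=False)
        return out

    def first_split_table(self) -> pd.DataFrame:
        """Relative frequency of the first-split variable per approach,
        over the columns u1, u2, u3, noise, no split (rows sum to 1)."""
        cols = ["u1", "u2", "u3", "noise", "no split"]
        grp = self.rows.assign(
            group=self.rows["first_split_variable"].map(_first_split_group)
        )
        tab = pd.crosstab(grp["approach"], grp["group"], normalize="index")
        for c in cols:
            if c not in tab.columns:
                tab[c] = 0.0
        return tab[cols]


def run_study(
    designs: list[SimulationDesign],
    approaches: list[str],
    reps: int,
    seed: int,
    out_path: str | Path | None = None,
    progress: bool = False,
) -> StudyResult:
    """Fit every approach to every generated dataset of the grid.

    Per-dataset random streams derive reproducibly from ``(seed, cell,
    rep)``.  With ``out_path``, rows stream to a CSV as they complete and a
    rerun resumes, skipping (cell, rep, approach) rows already on disk.
    Individual fit failures are recorded as failed rows; the study goes on.
    """
    unknown = [a for a in approaches if a not in APPROACHES]
    if unknown:
        raise ValueError(f"unknown approach name(s): {unknown}")
    if reps < 1:
        raise ValueError("reps must be >= 1")

    done: set[tuple] = set()
    rows: list[dict] = []
    out_file = None
    columns = [
        "cell", "cell_label", "rep", "approach", "n_splits", "deviation",
        "error_class", "first_split_variable", "first_split_correct",
        "iterations", "converged_by", "runtime", "status",
    ]
    if out_path is not None:
        out_path = Path(out_path)
        if out_path.exists():
            prev = pd.read_csv(out_path)
            rows = prev.to_dict("records")
            done = {(r["cell"], r["rep"], r["approach"]) for r in rows}
            logger.info("resuming study: %d rows already complete", len(done))
        out_file = out_path.open("a")
        if not done:
            out_file.write(",".join(columns) + "\n")
            out_file.flush()

    for cell, design in enumerate(designs):
        for rep in range(reps):
            todo = [a for a in approaches if (cell, rep, a) not in done]
            if not todo:
                continue
            data, truth = simulate_dataset(design, seed=[seed, cell, rep])
            for name in todo:
                spec = APPROACHES[name]
                t0 = _time.perf_counter()
                row = {
                    "cell": cell, "cell_label": design.label(), "rep": rep,
                    "approach": name,
                }
                try:
                    model = fit_glmm_tree(data, ["u1", "u2", "u3"] + [
                        f"u{4 + j}" for j in range(design.n_noise)
                    ], spec)
                    row.update(evaluate_tree(model, truth))
                    row["iterations"] = model.iterations
                    row["converged_by"] = model.converged_by
                    row["status"] = "ok"
                except Exception as exc:
                    logger.warning("fit failed (cell %d rep %d %s): %s", cell, rep, name, exc)
                    row.update(
                        n_splits=np.nan, deviation=np.nan, error_class="failed",
                        first_split_variable="failed", first_split_correct=False,
                        iterations=0, converged_by="failed",
                    )
                    row["status"] = "failed"
                row["runtime"] = _time.perf_counter() - t0
                rows.append(row)
                if out_file is not None:
                    out_file.write(",".join(str(row[c]) for c in columns) + "\n")
                    out_file.flush()
            if progress:
                logger.info("cell %d rep %d done", cell, rep)
    if out_file is not None:
        out_file.close()

    df = pd.DataFrame(rows)
    ok = df[df["status"] == "ok"] if "status" in df else df
    return StudyResult(rows=ok.reset_index(drop=True))
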