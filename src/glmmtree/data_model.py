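"""Containers for long-format longitudinal data and fitted partition trees.

A :class:`LongitudinalDataset` holds repeated measures in long format (one
row per subject x timepoint) together with *subject-level* candidate
partitioning covariates, which must be constant within subject.  A
:class:`PartitionTree` is a binary tree over those covariates whose terminal
nodes carry node-specific fixed effects (intercept and time slope) of a
linear growth curve model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LongitudinalDataset",
    "Split",
    "TreeNode",
    "PartitionTree",
    "load_long_csv",
    "write_long_csv",
    "route_subjects",
]


class ValidationError(ValueError):
    """Raised when input data violate the longitudinal-data contract."""


class SchemaError(KeyError):
    """Raised when a required column is missing from an input table."""


def _is_categorical(s: pd.Series) -> bool:
    return isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object or s.dtype == bool


@dataclass
class LongitudinalDataset:
    """Long-format repeated measures with subject-level covariates.

    Parameters
    ----------
    subject : (n_obs,) integer codes 0..N-1, one per row.
    subject_ids : (N,) original subject labels, indexed by code.
    time : (n_obs,) observation times (the single time-varying covariate).
    y : (n_obs,) continuous response.
    covariates : subject-level candidate partitioning covariates, one row
        per subject (index = subject code).  Numeric columns are treated as
        continuous, categorical/object/bool columns as unordered factors.
    """

    subject: np.ndarray
    subject_ids: np.ndarray
    time: np.ndarray
    y: np.ndarray
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        self.subject = np.asarray(self.subject, dtype=np.int64)
        self.time = np.asarray(self.time, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.subject.shape[0]
        if not (self.time.shape[0] == n == self.y.shape[0]):
            raise ValidationError("subject, time and y must have equal length")
        if np.isnan(self.time).any() or np.isnan(self.y).any():
            raise ValidationError("missing time or response values after validation")
        if len(self.covariates) != self.n_subjects:
            raise ValidationError(
                f"covariate table has {len(self.covariates)} rows, expected "
                f"{self.n_subjects} (one per subject)"
            )

    # -- basic geometry ------------------------------------------------
    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def n_subjects(self) -> int:
        return int(self.subject_ids.shape[0])

    @property
    def n_obs_per_subject(self) -> np.ndarray:
        return np.bincount(self.subject, minlength=self.n_subjects)

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariates.columns)

    def is_categorical(self, name: str) -> bool:
        return _is_categorical(self.covariates[name])

    # -- construction --------------------------------------------------
    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        subject: str,
        time: str,
        response: str,
        covariates: Sequence[str] | None = None,
    ) -> "LongitudinalDataset":
        """Build and validate a dataset from a long-format table.

        Rows with missing time or response are dropped (logged); a covariate
        that varies within any subject raises :class:`ValidationError`.
        """
        for col in (subject, time, response):
            if col not in df.columns:
                raise SchemaError(f"required column {col!r} not found")
        if covariates is None:
            covariates = [c for c in df.columns if c not in (subject, time, response)]
        missing = [c for c in covariates if c not in df.columns]
        if missing:
            raise SchemaError(f"covariate column(s) {missing} not found")

        keep = df[time].notna() & df[response].notna() & df[subject].notna()
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("dropped %d rows with missing subject/time/response", n_drop)
        df = df.loc[keep]
        if len(df) == 0:
            raise ValidationError("no valid rows remain after dropping missing values")

        codes, uniques = pd.factorize(df[subject], use_na_sentinel=False)
        cov_rows = []
        for name in covariates:
            col = df[name]
            first = col.groupby(codes).transform("first")
            varies = ~((col == first) | (col.isna() & first.isna()))
            if varies.any():
                bad_code = codes[np.asarray(varies)][0]
                raise ValidationError(
                    f"covariate {name!r} is not constant within subject "
                    f"{uniques[bad_code]!r}"
                )
        # one covariate row per subject, in code order
        first_idx = np.zeros(len(uniques), dtype=np.int64)
        seen = np.zeros(len(uniques), dtype=bool)
        for pos, c in enumerate(codes):
            if not seen[c]:
                seen[c] = True
                first_idx[c] = pos
        cov = df.iloc[first_idx][list(covariates)].reset_index(drop=True)
        for name in covariates:
            if _is_categorical(cov[name]) and not isinstance(cov[name].dtype, pd.CategoricalDtype):
                cov[name] = cov[name].astype("category")
            elif not _is_categorical(cov[name]):
                cov[name] = cov[name].astype(float)
        cov_rows = cov

        return cls(
            subject=codes,
            subject_ids=np.asarray(uniques),
            time=df[time].to_numpy(dtype=float),
            y=df[response].to_numpy(dtype=float),
            covariates=cov_rows,
        )

    def to_frame(
        self,
        subject: str = "subject",
        time: str = "time",
        response: str = "y",
    ) -> pd.DataFrame:
        """Long-format table with subject-level covariates broadcast to rows."""
        out = pd.DataFrame(
            {
                subject: self.subject_ids[self.subject],
                time: self.time,
                response: self.y,
            }
        )
        for name in self.covariate_names:
            out[name] = self.covariates[name].to_numpy()[self.subject]
        return out

    def subset_subjects(self, subject_codes: np.ndarray) -> np.ndarray:
        """Boolean observation mask selecting the given subject codes."""
        keep = np.zeros(self.n_subjects, dtype=bool)
        keep[subject_codes] = True
        return keep[self.subject]


def load_long_csv(
    path,
    subject: str = "subject",
    time: str = "time",
    response: str = "y",
    covariates: Sequence[str] | None = None,
) -> LongitudinalDataset:
    """Read a long-format CSV and validate it into a :class:`LongitudinalDataset`."""
    df = pd.read_csv(path)
    return LongitudinalDataset.from_frame(
        df, subject=subject, time=time, response=response, covariates=covariates
    )


def write_long_csv(
    data: LongitudinalDataset,
    path,
    subject: str = "subject",
    time: str = "time",
    response: str = "y",
) -> None:
    data.to_frame(subject=subject, time=time, response=response).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Split:
    """A binary split rule on one subject-level covariate.

    Numeric rule: ``value <= threshold`` goes left.  Categorical rule:
    ``value in left_levels`` goes left.
    """

    variable: str
    kind: str  # "numeric" | "categorical"
    threshold: float | None = None
    left_levels: tuple | None = None
    right_levels: tuple | None = None

    def goes_left(self, values) -> np.ndarray:
        if self.kind == "numeric":
            return np.asarray(values, dtype=float) <= self.threshold
        left = set(self.left_levels)
        return np.asarray([v in left for v in np.asarray(values, dtype=object)])

    def describe(self) -> tuple[str, str]:
        if self.kind == "numeric":
            return (f"{self.variable} <= {self.threshold:g}", f"{self.variable} > {self.threshold:g}")
        left = ", ".join(map(str, self.left_levels))
        return (f"{self.variable} in {{{left}}}", f"{self.variable} not in {{{left}}}")


@dataclass
class TreeNode:
    node_id: int
    depth: int = 0
    split: Split | None = None
    children: tuple[int, int] | None = None
    beta: tuple[float, float] | None = None  # terminal: (intercept, slope)
    n_subjects: int = 0
    n_obs: int = 0
    test_record: list[dict] = field(default_factory=list)

    @property
    def is_terminal(self) -> bool:
        return self.children is None


@dataclass
class PartitionTree:
    """Binary partition of subjects over time-constant covariates.

    Node ids are assigned in depth-first preorder starting at 1.  A tree
    with ``n_splits == 0`` is the single-group (root-only) model.
    """

    nodes: dict[int, TreeNode]
    root_id: int = 1

    @property
    def n_splits(self) -> int:
        return sum(1 for n in self.nodes.values() if not n.is_terminal)

    @property
    def depth(self) -> int:
        return max(n.depth for n in self.nodes.values())

    @property
    def terminal_ids(self) -> list[int]:
        return [i for i, n in sorted(self.nodes.items()) if n.is_terminal]

    def first_split_variable(self) -> str | None:
        root = self.nodes[self.root_id]
        return None if root.is_terminal else root.split.variable

    # -- routing -------------------------------------------------------
    def route(self, covariates: pd.DataFrame, unseen: str = "error") -> np.ndarray:
        """Terminal node id per row of the subject-level covariate table.

        ``unseen`` controls categorical levels not in a split's stored level
        universe: ``"error"`` (default) raises, ``"left"`` routes left.
        """
        n = len(covariates)
        out = np.empty(n, dtype=np.int64)
        idx = np.arange(n)

        def descend(node_id: int, rows: np.ndarray) -> None:
            node = self.nodes[node_id]
            if node.is_terminal:
                out[rows] = node_id
                return
            vals = covariates[node.split.variable].to_numpy()[rows]
            left = node.split.goes_left(vals)
            if node.split.kind == "categorical":
                universe = set(node.split.left_levels) | set(node.split.right_levels or ())
                unknown = np.asarray([v not in universe for v in vals])
                if unknown.any():
                    if unseen == "error":
                        bad = vals[unknown][0]
                        raise ValidationError(
                            f"unseen level {bad!r} for split variable "
                            f"{node.split.variable!r}"
                        )
                    left = left | unknown  # route-to-left policy
            descend(node.children[0], rows[left])
            descend(node.children[1], rows[~left])

        descend(self.root_id, idx)
        return out

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        def node_dict(n: TreeNode) -> dict:
            d = {
                "node_id": n.node_id,
                "depth": n.depth,
                "n_subjects": n.n_subjects,
                "n_obs": n.n_obs,
                "test_record": n.test_record,
            }
            if n.split is not None:
                d["split"] = {
                    "variable": n.split.variable,
                    "kind": n.split.kind,
                    "threshold": n.split.threshold,
                    "left_levels": list(n.split.left_levels)
                    if n.split.left_levels is not None
                    else None,
                    "right_levels": list(n.split.right_levels)
                    if n.split.right_levels is not None
                    else None,
                }
                d["children"] = list(n.children)
            if n.beta is not None:
                d["beta"] = list(n.beta)
            return d

        return {
            "root_id": self.root_id,
            "nodes": [node_dict(self.nodes[i]) for i in sorted(self.nodes)],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PartitionTree":
        nodes = {}
        for nd in d["nodes"]:
            split = None
            children = None
            if "split" in nd:
                s = nd["split"]
                split = Split(
                    variable=s["variable"],
                    kind=s["kind"],
                    threshold=s["threshold"],
                    left_levels=tuple(s["left_levels"]) if s["left_levels"] is not None else None,
                    right_levels=tuple(s["right_levels"])
                    if s.get("right_levels") is not None
                    else None,
                )
                children = tuple(nd["children"])
            nodes[nd["node_id"]] = TreeNode(
                node_id=nd["node_id"],
                depth=nd["depth"],
                split=split,
                children=children,
                beta=tuple(nd["beta"]) if nd.get("beta") is not None else None,
                n_subjects=nd["n_subjects"],
                n_obs=nd["n_obs"],
                test_record=nd.get("test_record", []),
            )
        return cls(nodes=nodes, root_id=d["root_id"])

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, s: str) -> "PartitionTree":
        return cls.from_dict(json.loads(s))

    def render(self) -> str:
        """Indented text rendering with per-node n, coefficients, split p-value."""
        lines: list[str] = []

        def walk(node_id: int, label: str, indent: int) -> None:
            n = self.nodes[node_id]
            pad = "  " * indent
            if n.is_terminal:
                b = (
                    f" beta=({n.beta[0]:.3f}, {n.beta[1]:.3f})"
                    if n.beta is not None
                    else ""
                )
                lines.append(f"{pad}[{node_id}] {label}* n={n.n_subjects}{b}")
            else:
                pv = ""
                if n.test_record:
                    best = min(n.test_record, key=lambda r: r.get("p_adjusted", 1.0))
                    pv = f" (p={best['p_adjusted']:.4g})"
                lines.append(f"{pad}[{node_id}] {label}n={n.n_subjects}{pv}")
                ldesc, rdesc = n.split.describe()
                walk(n.children[0], f"{ldesc}: ", indent + 1)
                walk(n.children[1], f"{rdesc}: ", indent + 1)

        walk(self.root_id, "", 0)
        return "\n".join(lines)


def route_subjects(
    tree: PartitionTree, data: LongitudinalDataset, unseen: str = "error"
) -> np.ndarray:
    """Terminal node id per subject (code order); a total, deterministic map."""
    return tree.route(data.covariates, unseen=unseen)
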