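"""Survival trees split by the CGE permutation test.

The tree recursively partitions the covariate space with binary single-
covariate splits ``{z_j <= q}`` vs ``{z_j > q}``.  At each node a grid
search over all covariates and feasible cutoffs runs the two-sample L1
permutation test on the induced groups and keeps the split with the
smallest p-value; the node is split only if that p-value is at or below
the threshold ``p_threshold`` (default 0.01), which is the tree's only
stopping rule besides a minimum child size.  The child with the larger
integrated survival (positive signed statistic) is placed on the right, so
terminal nodes - numbered right to left starting at 1 - are ordered from
best to worst prognosis: node 1 has the highest survival, high numbers
short survival.

Each terminal node carries the copula-graphic estimator fitted on its
training subjects; predictions for new subjects are the curve of the node
they are routed to, extrapolated as constant beyond the node's last
observed time.

A logrank-based comparator tree (``split_test="logrank"``) is produced by
the same engine with the split criterion swapped, mirroring classical
logrank trees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold

from .copulas import archimedean_copula
from .estimators import SurvivalSample, copula_graphic
from .stepcurve import StepCurve
from .twosample import (
    TwoSampleData,
    l1_statistic,
    permutation_test,
    weighted_logrank,
)

__all__ = ["SplitCandidate", "CGESurvivalTree", "cv_select_tau"]


@dataclass(frozen=True)
class SplitCandidate:
    """A candidate binary split: left = {z_j <= cutoff}, right = {z_j > cutoff}."""

    covariate_index: int
    cutoff: float
    p_value: float
    l1: float
    l1_signed: float
    left_size: int
    right_size: int


class _Node:
    """Tree node; terminal iff ``left is None``."""

    __slots__ = (
        "feature",
        "cutoff",
        "p_value",
        "le_side",
        "left",
        "right",
        "node_number",
        "member_idx",
        "curve",
        "median_survival",
        "n_members",
    )

    def __init__(self):
        self.feature = None
        self.cutoff = None
        self.p_value = None
        self.le_side = None  # 'left' or 'right': where the <= group went
        self.left = None
        self.right = None
        self.node_number = None
        self.member_idx = None
        self.curve = None
        self.median_survival = None
        self.n_members = None

    @property
    def is_terminal(self) -> bool:
        return self.left is None


def _median_survival_time(curve: StepCurve) -> float:
    below = curve.values <= 0.5
    if not np.any(below):
        return float("inf")
    return float(curve.breakpoints[np.argmax(below)])


def _extract_survival(y):
    """Accept (time, event) tuples, 2-col arrays, DataFrames or structured
    arrays (scikit-survival convention with event first)."""
    if isinstance(y, pd.DataFrame):
        return y["time"].to_numpy(float), y["event"].to_numpy(int)
    if isinstance(y, tuple) and len(y) == 2:
        return np.asarray(y[0], float), np.asarray(y[1], int)
    arr = np.asarray(y)
    if arr.dtype.names:
        names = arr.dtype.names
        # structured: (event, time) if first field is boolean
        if arr.dtype[names[0]].kind == "b":
            return arr[names[1]].astype(float), arr[names[0]].astype(int)
        return arr[names[0]].astype(float), arr[names[1]].astype(int)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return arr[:, 0].astype(float), arr[:, 1].astype(int)
    raise ValueError("y must provide observed times and 0/1 event indicators")


class CGESurvivalTree(BaseEstimator):
    """Survival tree with a CGE permutation-test splitting criterion.

    Parameters
    ----------
    family : copula family assumed between event and censoring times.
    tau : assumed Kendall's tau; 0 reduces the node curves to Kaplan-Meier
        and the split test to a permutation test on KM distance.
    p_threshold : split acceptance threshold on the split test's p-value.
    nperm : permutations per split test.
    min_child : minimum subjects per child node (1 allows singleton leaves).
    split_test : "cge_l1" (the permutation test) or "logrank" (comparator
        tree driven by the logrank chi-square p-value).
    random_state : root seed; per-node seeds are derived from the node's
        path in the tree so growth is reproducible and order-independent.

    Attributes
    ----------
    tree_ : root node.
    n_terminal_nodes_, n_internal_nodes_ : tree size.
    split_features_ : covariate indices used by internal nodes.
    """

    def __init__(
        self,
        family: str = "clayton",
        tau: float = 0.0,
        p_threshold: float = 0.01,
        nperm: int = 1000,
        min_child: int = 2,
        split_test: str = "cge_l1",
        random_state: Optional[int] = None,
    ):
        self.family = family
        self.tau = tau
        self.p_threshold = p_threshold
        self.nperm = nperm
        self.min_child = min_child
        self.split_test = split_test
        self.random_state = random_state

    # -- growth ------------------------------------------------------------

    def _node_seed(self, path):
        root = self.random_state if self.random_state is not None else 0
        ss = np.random.SeedSequence(entropy=root, spawn_key=tuple(path))
        return ss

    def _best_split(self, X, times, events, rng) -> Optional[SplitCandidate]:
        n = X.shape[0]
        if n < 2 * self.min_child:
            return None
        best = None
        for j in range(X.shape[1]):
            col = X[:, j]
            if np.any(np.isnan(col)):
                raise ValueError("missing covariate values are not supported")
            cutoffs = np.unique(col)[:-1]  # exclude max so '>' side nonempty
            for q in cutoffs:
                left = col <= q
                n_left = int(left.sum())
                if n_left < self.min_child or n - n_left < self.min_child:
                    continue
                data = TwoSampleData(
                    SurvivalSample(times[left], events[left]),
                    SurvivalSample(times[~left], events[~left]),
                )
                if self.split_test == "logrank":
                    try:
                        _, p = weighted_logrank(data, "logrank")
                    except ValueError:
                        continue
                    l1, l1s = l1_statistic(data, self._copula)
                else:
                    res = permutation_test(
                        data, self._copula, self.nperm, rng
                    )
                    p, l1, l1s = res.p_value, res.l1, res.l1_signed
                cand = SplitCandidate(
                    covariate_index=j,
                    cutoff=float(q),
                    p_value=p,
                    l1=l1,
                    l1_signed=l1s,
                    left_size=n_left,
                    right_size=n - n_left,
                )
                if (
                    best is None
                    or cand.p_value < best.p_value
                    or (cand.p_value == best.p_value and cand.l1 > best.l1)
                ):
                    best = cand
        return best

    def _grow(self, X, times, events, idx, path) -> _Node:
        node = _Node()
        node.member_idx = idx
        node.n_members = idx.size
        rng = np.random.default_rng(self._node_seed(path))
        cand = self._best_split(X[idx], times[idx], events[idx], rng)
        if cand is None or cand.p_value > self.p_threshold:
            sample = SurvivalSample(times[idx], events[idx])
            node.curve = copula_graphic(sample, self._copula)
            node.median_survival = _median_survival_time(node.curve)
            return node
        node.feature = cand.covariate_index
        node.cutoff = cand.cutoff
        node.p_value = cand.p_value
        le_mask = X[idx, cand.covariate_index] <= cand.cutoff
        le_idx, gt_idx = idx[le_mask], idx[~le_mask]
        # better prognosis goes right; l1_signed > 0 means the <= group
        # (group 1 of the split) has the larger integrated survival
        if cand.l1_signed > 0:
            node.le_side = "right"
            right_idx, left_idx = le_idx, gt_idx
        else:
            node.le_side = "left"
            left_idx, right_idx = le_idx, gt_idx
        node.left = self._grow(X, times, events, left_idx, path + (0,))
        node.right = self._grow(X, times, events, right_idx, path + (1,))
        return node

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-d (subjects x covariates)")
        times, events = _extract_survival(y)
        if X.shape[0] != times.size or X.shape[0] == 0:
            raise ValueError("X and y must agree on a positive sample size")
        if self.split_test not in ("cge_l1", "logrank"):
            raise ValueError("split_test must be 'cge_l1' or 'logrank'")
        self._copula = archimedean_copula(self.family, self.tau)
        self.n_features_in_ = X.shape[1]
        self.tree_ = self._grow(
            X, times, events, np.arange(X.shape[0]), ()
        )
        self._number_terminals()
        return self

    def _number_terminals(self):
        counter = [0]
        internal = [0]
        features = []

        def visit(node):
            if node.is_terminal:
                counter[0] += 1
                node.node_number = counter[0]
            else:
                internal[0] += 1
                features.append(node.feature)
                visit(node.right)  # right first: node 1 = best prognosis
                visit(node.left)

        visit(self.tree_)
        self.n_terminal_nodes_ = counter[0]
        self.n_internal_nodes_ = internal[0]
        self.split_features_ = features

    # -- prediction --------------------------------------------------------

    def _route(self, z) -> _Node:
        node = self.tree_
        while not node.is_terminal:
            val = z[node.feature]
            if np.isnan(val):
                raise ValueError("missing covariate values are not supported")
            goes_le = val <= node.cutoff
            if (node.le_side == "left") == goes_le:
                node = node.left
            else:
                node = node.right
        return node

    def _check_X(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        return X

    def predict(self, X):
        """Terminal node numbers (1 = best prognosis, high = short survival)."""
        X = self._check_X(X)
        return np.array([self._route(row).node_number for row in X])

    def predict_survival_function(self, X) -> list[StepCurve]:
        X = self._check_X(X)
        return [self._route(row).curve for row in X]

    def predict_survival(self, X, t):
        """Survival probabilities S(t | z) as an (n_subjects, n_times) array."""
        X = self._check_X(X)
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty((X.shape[0], t.size))
        for i, row in enumerate(X):
            out[i] = self._route(row).curve(t, clip=True)
        return out

    # -- introspection / serialization --------------------------------------

    def terminal_nodes(self) -> list[_Node]:
        nodes = []

        def visit(node):
            if node.is_terminal:
                nodes.append(node)
            else:
                visit(node.right)
                visit(node.left)

        visit(self.tree_)
        return nodes

    def to_dict(self, feature_names: Optional[Sequence[str]] = None) -> dict:
        def name(j):
            return feature_names[j] if feature_names is not None else f"z{j + 1}"

        def encode(node):
            if node.is_terminal:
                return {
                    "type": "terminal",
                    "node_number": node.node_number,
                    "n": int(node.n_members),
                    "median_survival": (
                        None
                        if np.isinf(node.median_survival)
                        else node.median_survival
                    ),
                    "curve": {
                        "breakpoints": node.curve.breakpoints.tolist(),
                        "values": node.curve.values.tolist(),
                        "domain_max": node.curve.domain_max,
                    },
                }
            return {
                "type": "internal",
                "covariate": name(node.feature),
                "covariate_index": node.feature,
                "cutoff": node.cutoff,
                "p_value": node.p_value,
                "le_side": node.le_side,
                "n": int(node.n_members),
                "left": encode(node.left),
                "right": encode(node.right),
            }

        return {
            "params": self.get_params(),
            "n_terminal_nodes": self.n_terminal_nodes_,
            "root": encode(self.tree_),
        }

    def to_json(self, feature_names=None, **kwargs) -> str:
        return json.dumps(self.to_dict(feature_names), **kwargs)

    def to_dot(self, feature_names: Optional[Sequence[str]] = None) -> str:
        """Graphviz DOT export of the tree structure."""

        def name(j):
            return feature_names[j] if feature_names is not None else f"z{j + 1}"

        lines = ["digraph survival_tree {", "  node [shape=box];"]
        counter = [0]

        def visit(node):
            my_id = counter[0]
            counter[0] += 1
            if node.is_terminal:
                med = (
                    "inf"
                    if np.isinf(node.median_survival)
                    else f"{node.median_survival:.3g}"
                )
                lines.append(
                    f'  n{my_id} [label="node {node.node_number}\\n'
                    f'n={node.n_members}\\nmedian={med}"];'
                )
                return my_id
            le_label, gt_label = "<=", ">"
            if node.le_side == "right":
                left_edge, right_edge = gt_label, le_label
            else:
                left_edge, right_edge = le_label, gt_label
            lines.append(
                f'  n{my_id} [label="{name(node.feature)}\\n'
                f'cut={node.cutoff:.4g}\\np={node.p_value:.3g}"];'
            )
            left_id = visit(node.left)
            lines.append(
                f'  n{my_id} -> n{left_id} [label="{left_edge} {node.cutoff:.4g}"];'
            )
            right_id = visit(node.right)
            lines.append(
                f'  n{my_id} -> n{right_id} [label="{right_edge} {node.cutoff:.4g}"];'
            )
            return my_id

        visit(self.tree_)
        lines.append("}")
        return "\n".join(lines)


def cv_select_tau(
    X,
    y,
    tau_grid: Sequence[float],
    folds: int = 10,
    family: str = "clayton",
    p_threshold: float = 0.01,
    nperm: int = 1000,
    min_child: int = 2,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Cross-validated sensitivity analysis over the assumed Kendall's tau.

    For each tau, trees are grown on the training folds and evaluated on
    the held-out fold (event-stratified K-fold).  Returns the per-tau means
    of the number of terminal nodes, Harrell's C on terminal-node ranks and
    the integrated Brier score with Kaplan-Meier censoring weights.  The
    tau with the best cross-validated C-index (with the IBS as a secondary
    check) is the recommended assumed dependence.
    """
    from .metrics import harrells_c, integrated_brier, km_censoring_curve

    X = np.asarray(X, dtype=float)
    times, events = _extract_survival(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if events.sum() < folds:
        raise ValueError("need at least one event per fold")
    for attempt in range(10):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=(seed or 0) + attempt
        )
        splits = list(skf.split(X, events))
        if all(
            events[tr].sum() > 0 and events[te].sum() > 0 for tr, te in splits
        ):
            break
    else:  # pragma: no cover
        raise RuntimeError("could not form folds with events on both sides")

    rows = []
    for tau in tau_grid:
        sizes, cs, ibss = [], [], []
        for k, (tr, te) in enumerate(splits):
            tree = CGESurvivalTree(
                family=family,
                tau=tau,
                p_threshold=p_threshold,
                nperm=nperm,
                min_child=min_child,
                random_state=(seed or 0) + 1000 * k,
            ).fit(X[tr], (times[tr], events[tr]))
            sizes.append(tree.n_terminal_nodes_)
            test_sample = SurvivalSample(times[te], events[te])
            node_numbers = tree.predict(X[te])
            c = harrells_c(node_numbers, test_sample)
            if c is not None:
                cs.append(c)
            curves = tree.predict_survival_function(X[te])
            grid = np.unique(np.concatenate([times[tr], times[te]]))
            ibss.append(
                integrated_brier(
                    curves,
                    test_sample,
                    km_censoring_curve(test_sample),
                    grid,
                )
            )
        rows.append(
            {
                "tau": tau,
                "mean_terminal_nodes": float(np.mean(sizes)),
                "mean_harrells_c": float(np.mean(cs)) if cs else np.nan,
                "mean_ibs": float(np.mean(ibss)),
            }
        )
    return pd.DataFrame(rows)
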