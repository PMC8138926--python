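"""Recursive-partitioning classifier over binary immunostain predictors.

A greedy binary decision tree in the CART family, specialized to categorical
binary predictors (H3K27me3 NR/NL, ATRX retained/lost, IDH1-R132H pos/neg)
and a binary response (IDH-mutant 1p/19q-codeleted oligodendroglioma vs the
rest). Splits are scored by the likelihood-ratio statistic

    G2 = 2 * sum_children sum_classes O * ln(O / E),

with expected counts E taken from the parent node's class proportions; each
predictor is used at most once per path; recursion stops when no candidate
split leaves both children with at least ``min_leaf`` cases or improves G2.
Leaf class probabilities are smoothed toward the root prior,
(n_c + prior_c) / (N + 1), so a pure leaf reports a probability below 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

#: fixed predictor order for tie-breaks, and canonical child order per variable
PREDICTOR_ORDER = ("h3k27me3", "atrx", "idh1_r132h")
VALUE_ORDER = {
    "h3k27me3": ("NL", "NR"),
    "atrx": ("RETAINED", "LOST"),
    "idh1_r132h": ("POS", "NEG"),
}


def split_score(parent_counts, left_counts, right_counts) -> float:
    """Likelihood-ratio statistic G2 of a binary split (larger is better).

    ``parent_counts`` etc. are per-class count vectors; left + right must
    equal parent and both children must be nonempty.
    """
    parent = np.asarray(parent_counts, dtype=np.float64)
    left = np.asarray(left_counts, dtype=np.float64)
    right = np.asarray(right_counts, dtype=np.float64)
    if not np.array_equal(left + right, parent):
        raise ValueError("child counts must sum to the parent counts")
    if left.sum() == 0 or right.sum() == 0:
        raise ValueError("both children must be nonempty")
    p_parent = parent / parent.sum()
    g2 = 0.0
    for child in (left, right):
        expected = child.sum() * p_parent
        observed = child
        nz = observed > 0
        g2 += 2.0 * float(np.sum(observed[nz] * np.log(observed[nz] / expected[nz])))
    return g2


@dataclass
class TreeNode:
    """One node of a fitted partition tree."""

    counts: dict  # class -> count
    depth: int
    split_variable: str | None = None
    children: dict = dataclass_field(default_factory=dict)  # value -> TreeNode

    @property
    def is_leaf(self) -> bool:
        return self.split_variable is None

    @property
    def n(self) -> int:
        return int(sum(self.counts.values()))

    def to_dict(self) -> dict:
        d = {"counts": dict(self.counts), "depth": self.depth,
             "split_variable": self.split_variable}
        if not self.is_leaf:
            d["children"] = {v: c.to_dict() for v, c in self.children.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(counts=dict(d["counts"]), depth=d["depth"],
                   split_variable=d.get("split_variable"))
        for v, child in d.get("children", {}).items():
            node.children[v] = cls.from_dict(child)
        return node


def leaf_probability(leaf_counts, prior, smoothing: str = "laplace_prior"):
    """Per-class probabilities at a leaf.

    ``raw`` is the maximum-likelihood estimate n_c / N; ``laplace_prior``
    (default) shrinks one pseudo-case of the root prior into the leaf,
    (n_c + prior_c) / (N + 1).
    """
    counts = np.asarray(leaf_counts, dtype=np.float64)
    prior = np.asarray(prior, dtype=np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty leaf")
    if smoothing == "raw":
        return counts / total
    if smoothing == "laplace_prior":
        return (counts + prior) / (total + 1.0)
    raise ValueError(f"unknown smoothing {smoothing!r}")


class PartitionTreeClassifier(ClassifierMixin, BaseEstimator):
    """Greedy G2 recursive-partitioning classifier for binary markers.

    Parameters
    ----------
    min_leaf : int
        Minimum cases in each child of an admissible split (default 5).
    forced_root : str or None
        Overrides the root's split variable only; deeper splits stay greedy.
    forced_order : sequence of str or None
        Forces the split variable by depth (element d for all nodes at depth
        d), reproducing a published tree layout; beyond the sequence the
        choice is greedy. Takes precedence over ``forced_root`` at depth 0.
    smoothing : "laplace_prior" or "raw"
        Leaf probability estimate (see :func:`leaf_probability`).

    Attributes
    ----------
    tree_ : TreeNode            root of the fitted tree
    classes_ : ndarray          class labels (sorted)
    prior_ : ndarray            root class proportions
    feature_names_in_ : ndarray predictor names seen in fit
    """

    def __init__(self, min_leaf: int = 5, forced_root: str | None = None,
                 forced_order=None, smoothing: str = "laplace_prior"):
        self.min_leaf = min_leaf
        self.forced_root = forced_root
        self.forced_order = forced_order
        self.smoothing = smoothing

    # -- fitting ------------------------------------------------------------
    def fit(self, X: pd.DataFrame, y):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame of categorical binary predictors")
        if len(X) == 0:
            raise ValueError("empty cohort")
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        for col in X.columns:
            n_levels = X[col].nunique()
            if n_levels > 2:
                raise ValueError(f"predictor {col!r} is not binary ({n_levels} levels)")
        if np.unique(y).size > 2:
            raise ValueError("response must be binary")
        self.classes_ = np.unique(y)
        self.feature_names_in_ = np.asarray(list(X.columns), dtype=object)
        counts = {str(c): int((y == c).sum()) for c in self.classes_}
        self.prior_ = np.array([counts[str(c)] / len(y) for c in self.classes_])
        self.tree_ = self._grow(X, y, depth=0, used=frozenset(), counts=counts)
        return self

    def _class_counts(self, y) -> dict:
        return {str(c): int((np.asarray(y) == c).sum()) for c in self.classes_}

    def _candidate_order(self, columns):
        ordered = [c for c in PREDICTOR_ORDER if c in columns]
        return ordered + [c for c in columns if c not in ordered]

    def _value_order(self, var: str, observed):
        canonical = [v for v in VALUE_ORDER.get(var, ()) if v in observed]
        return canonical + sorted(v for v in observed if v not in canonical)

    def _grow(self, X, y, depth, used, counts) -> TreeNode:
        node = TreeNode(counts=counts, depth=depth)
        if len(np.unique(y)) < 2:
            return node
        forced_var = None
        if self.forced_order is not None and depth < len(self.forced_order):
            forced_var = self.forced_order[depth]
        elif depth == 0 and self.forced_root is not None:
            forced_var = self.forced_root
        candidates = (
            [forced_var]
            if forced_var is not None
            else self._candidate_order([c for c in X.columns if c not in used])
        )
        best = None
        for var in candidates:
            if var in used or var not in X.columns:
                continue
            values = self._value_order(var, set(X[var].unique()))
            if len(values) != 2:
                continue
            left_mask = (X[var] == values[0]).to_numpy()
            n_left, n_right = int(left_mask.sum()), int((~left_mask).sum())
            if n_left < self.min_leaf or n_right < self.min_leaf:
                continue
            parent_vec = [counts[str(c)] for c in self.classes_]
            left_vec = [int((y[left_mask] == c).sum()) for c in self.classes_]
            right_vec = [p - l for p, l in zip(parent_vec, left_vec)]
            g2 = split_score(parent_vec, left_vec, right_vec)
            if g2 <= 0.0:
                continue
            if best is None or g2 > best[0]:  # ties keep the earlier candidate
                best = (g2, var, values, left_mask)
        if best is None:
            return node
        _, var, values, left_mask = best
        node.split_variable = var
        for value, mask in ((values[0], left_mask), (values[1], ~left_mask)):
            sub_X, sub_y = X.loc[mask], y[mask]
            node.children[value] = self._grow(
                sub_X, sub_y, depth + 1, used | {var}, self._class_counts(sub_y)
            )
        return node

    # -- prediction ---------------------------------------------------------
    def _route(self, profile: dict) -> TreeNode:
        node = self.tree_
        while not node.is_leaf:
            var = node.split_variable
            if var not in profile:
                raise KeyError(f"profile is missing tested variable {var!r}")
            value = profile[var]
            if value not in node.children:
                raise KeyError(f"unknown value {value!r} for variable {var!r}")
            node = node.children[value]
        return node

    def predict_profile(self, profile: dict):
        """Route one marker profile; return (class, probability of that class)."""
        check_is_fitted(self, "tree_")
        leaf = self._route(profile)
        counts = [leaf.counts[str(c)] for c in self.classes_]
        probs = leaf_probability(counts, self.prior_, smoothing=self.smoothing)
        idx = int(np.argmax(probs))
        return self.classes_[idx], float(probs[idx])

    def predict(self, X: pd.DataFrame):
        check_is_fitted(self, "tree_")
        return np.asarray(
            [self.predict_profile(row._asdict() if hasattr(row, "_asdict") else dict(row))[0]
             for _, row in pd.DataFrame(X).iterrows()]
        )

    def predict_proba(self, X: pd.DataFrame):
        check_is_fitted(self, "tree_")
        out = np.empty((len(X), len(self.classes_)))
        for i, (_, row) in enumerate(pd.DataFrame(X).iterrows()):
            leaf = self._route(dict(row))
            counts = [leaf.counts[str(c)] for c in self.classes_]
            out[i] = leaf_probability(counts, self.prior_, smoothing=self.smoothing)
        return out

    # -- introspection / serialization --------------------------------------
    def split_variable_sequence(self) -> list[str]:
        """Distinct split variables in preorder (left child first)."""
        check_is_fitted(self, "tree_")
        seen: list[str] = []

        def walk(node: TreeNode):
            if node.is_leaf:
                return
            if node.split_variable not in seen:
                seen.append(node.split_variable)
            for value in self._value_order(node.split_variable, node.children.keys()):
                walk(node.children[value])

        walk(self.tree_)
        return seen

    def node_at_path(self, path: dict) -> TreeNode:
        """Follow split values from the root; e.g. {'idh1_r132h': 'POS', 'atrx': 'RETAINED'}."""
        check_is_fitted(self, "tree_")
        node = self.tree_
        while not node.is_leaf and node.split_variable in path:
            node = node.children[path[node.split_variable]]
        return node

    def to_json(self) -> str:
        check_is_fitted(self, "tree_")
        return json.dumps(
            {
                "classes": [str(c) for c in self.classes_],
                "prior": list(map(float, self.prior_)),
                "smoothing": self.smoothing,
                "min_leaf": self.min_leaf,
                "tree": self.tree_.to_dict(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PartitionTreeClassifier":
        d = json.loads(text)
        est = cls(min_leaf=d["min_leaf"], smoothing=d["smoothing"])
        est.classes_ = np.asarray(d["classes"], dtype=object)
        est.prior_ = np.asarray(d["prior"], dtype=np.float64)
        est.tree_ = TreeNode.from_dict(d["tree"])
        est.feature_names_in_ = np.asarray([], dtype=object)
        return est


def fit_tree(cohort: pd.DataFrame, predictors=PREDICTOR_ORDER,
             response: str = "codeleted", min_leaf: int = 5,
             forced_root: str | None = None,
             forced_order=None) -> PartitionTreeClassifier:
    """Fit a partition tree on a cohort table (thin wrapper).

    ``response`` names a cohort column; the fitted classes are that column's
    values (for ``codeleted``: False/True, True being the oligodendroglioma
    class).
    """
    X = cohort[list(predictors)]
    y = cohort[response].to_numpy()
    return PartitionTreeClassifier(
        min_leaf=min_leaf, forced_root=forced_root, forced_order=forced_order
    ).fit(X, y)


def predict(tree: PartitionTreeClassifier, profile: dict):
    """Route a marker profile through a fitted tree (thin wrapper)."""
    return tree.predict_profile(profile)
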