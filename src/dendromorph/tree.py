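"""Binary decision-tree induction with the chi-square split criterion.

Candidate splits are midpoints between adjacent distinct values of a
continuous predictor; each candidate is scored by the Pearson chi-square of
the 2 x k side-by-class contingency table (k = classes present at the node).
A node is split only when the best candidate's p-value, Bonferroni-adjusted
for the number of candidate predictors, falls below ``alpha_split`` — a
CHAID-style stopping rule that lets a four-specimen hybrid class form its
own leaf without growing spurious structure on noise.

Convention: observations with value <= threshold go left.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import ValidationError

__all__ = [
    "SplitCandidate",
    "TreeNode",
    "TreeModel",
    "best_split",
    "fit_tree",
    "predict_tree",
    "tree_to_text",
    "tree_from_text",
]


@dataclass(frozen=True)
class SplitCandidate:
    """A scored binary split of one continuous predictor."""

    variable: str
    threshold: float
    chi_square: float
    p_value: float
    left_counts: dict[str, int]
    right_counts: dict[str, int]


@dataclass
class TreeNode:
    depth: int
    counts: dict[str, int]
    split: SplitCandidate | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def majority_label(self, class_order: Sequence[str]) -> str:
        # ties broken by the configured class order for determinism
        return max(
            self.counts,
            key=lambda c: (self.counts[c], -list(class_order).index(c)),
        )

    def proportions(self) -> dict[str, float]:
        n = self.n
        return {c: k / n for c, k in self.counts.items()}


@dataclass
class TreeModel:
    """A fitted binary classification tree over continuous index predictors."""

    root: TreeNode
    variables: tuple[str, ...]
    class_order: tuple[str, ...]
    min_leaf: int
    alpha_split: float
    max_depth: int

    def used_variables(self) -> list[str]:
        used: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.split is not None:
                if node.split.variable not in used:
                    used.append(node.split.variable)
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return used


def _chi_square_2xk(left: np.ndarray, right: np.ndarray) -> tuple[float, float, int]:
    """Pearson chi-square (no continuity correction) of a 2 x k table."""
    table = np.vstack([left, right]).astype(float)
    col = table.sum(axis=0)
    keep = col > 0
    table = table[:, keep]
    col = col[keep]
    row = table.sum(axis=1)
    n = table.sum()
    k = table.shape[1]
    if k < 2 or (row <= 0).any():
        return 0.0, 1.0, max(k - 1, 1)
    expected = np.outer(row, col) / n
    chi2 = float(((table - expected) ** 2 / expected).sum())
    df = k - 1
    return chi2, float(sps.chi2.sf(chi2, df)), df


def best_split(
    values: Sequence[float],
    labels: Sequence[str],
    variable: str = "x",
    min_each: int = 1,
) -> SplitCandidate | None:
    """Best chi-square midpoint split of one predictor, or ``None``.

    Evaluates every midpoint between adjacent distinct sorted values whose
    two sides each contain at least ``min_each`` observations; returns the
    candidate maximizing the chi-square statistic, with ties resolved in
    favour of the smallest threshold.  ``None`` when no admissible split
    exists (single class, constant values, or size constraints).
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray([str(l) for l in labels])
    if v.size != y.size:
        raise ValidationError("values and labels must have equal length")
    if np.isnan(v).any():
        return None
    classes = list(pd.unique(y))
    if len(classes) < 2:
        return None
    distinct = np.unique(v)
    if distinct.size < 2:
        return None

    class_idx = {c: i for i, c in enumerate(classes)}
    order = np.argsort(v, kind="stable")
    v_sorted = v[order]
    y_sorted = y[order]
    total = np.zeros(len(classes), dtype=int)
    for label in y_sorted:
        total[class_idx[label]] += 1

    best: SplitCandidate | None = None
    cum = np.zeros(len(classes), dtype=int)
    n = v.size
    for i in range(n - 1):
        cum[class_idx[y_sorted[i]]] += 1
        if v_sorted[i] == v_sorted[i + 1]:
            continue
        n_left = i + 1
        n_right = n - n_left
        if n_left < min_each or n_right < min_each:
            continue
        threshold = (v_sorted[i] + v_sorted[i + 1]) / 2.0
        chi2, p, _ = _chi_square_2xk(cum, total - cum)
        if best is None or chi2 > best.chi_square + 1e-12:
            best = SplitCandidate(
                variable=variable,
                threshold=float(threshold),
                chi_square=chi2,
                p_value=p,
                left_counts={c: int(cum[class_idx[c]]) for c in classes},
                right_counts={
                    c: int(total[class_idx[c]] - cum[class_idx[c]]) for c in classes
                },
            )
    return best


def fit_tree(
    data: pd.DataFrame,
    labels: Sequence[str],
    variables: Sequence[str] | None = None,
    min_leaf: int = 2,
    alpha_split: float = 0.05,
    max_depth: int = 5,
) -> TreeModel:
    """Grow a binary chi-square tree on the given predictor columns.

    At each node the best split of every candidate variable (taken in column
    order; ties across variables favour the earlier column) competes on the
    chi-square statistic; the winner is applied only if its
    Bonferroni-adjusted p-value (times the number of candidate variables)
    is <= ``alpha_split``, both children have >= ``min_leaf`` observations
    and the depth budget allows.
    """
    if variables is None:
        variables = list(data.columns)
    variables = list(variables)
    y = np.asarray([str(l) for l in labels])
    if len(y) != len(data):
        raise ValidationError("labels must match the data length")
    class_order = tuple(dict.fromkeys(y))

    def counts_of(idx: np.ndarray) -> dict[str, int]:
        sub = y[idx]
        return {c: int((sub == c).sum()) for c in class_order if (sub == c).any()}

    def grow(idx: np.ndarray, depth: int, used: frozenset[str]) -> TreeNode:
        node = TreeNode(depth=depth, counts=counts_of(idx))
        if (
            depth >= max_depth
            or len(node.counts) < 2
            or idx.size < 2 * min_leaf
        ):
            return node
        candidates: list[SplitCandidate] = []
        n_tested = 0
        # each predictor is used at most once per root-to-leaf path: the
        # deliverable is a shallow chain of single-index thresholds
        for var in variables:
            if var in used:
                continue
            col = data[var].to_numpy(dtype=float)[idx]
            if np.isnan(col).any():
                continue
            n_tested += 1
            cand = best_split(col, y[idx], variable=var, min_each=min_leaf)
            if cand is not None:
                candidates.append(cand)
        if not candidates:
            return node

        def margin(cand: SplitCandidate) -> float:
            # relative separation gap at the threshold: the proportional
            # measurement error the cut-point can absorb; among chi-square
            # ties the most error-tolerant threshold wins (indices are
            # strictly positive ratios, so the gap/threshold scale is
            # well defined)
            col = data[cand.variable].to_numpy(dtype=float)[idx]
            left_max = col[col <= cand.threshold].max()
            right_min = col[col > cand.threshold].min()
            if cand.threshold <= 0:
                return 0.0
            return float(right_min - left_max) / float(cand.threshold)

        best_chi2 = max(c.chi_square for c in candidates)
        tied = [
            (i, c) for i, c in enumerate(candidates)
            if c.chi_square >= best_chi2 - 1e-9
        ]
        winner = max(tied, key=lambda ic: (margin(ic[1]), -ic[0]))[1]
        if min(1.0, winner.p_value * max(n_tested, 1)) > alpha_split:
            return node
        col = data[winner.variable].to_numpy(dtype=float)[idx]
        left_mask = col <= winner.threshold
        node.split = winner
        child_used = used | {winner.variable}
        node.left = grow(idx[left_mask], depth + 1, child_used)
        node.right = grow(idx[~left_mask], depth + 1, child_used)
        return node

    root = grow(np.arange(len(y)), 0, frozenset())
    return TreeModel(
        root=root,
        variables=tuple(variables),
        class_order=class_order,
        min_leaf=min_leaf,
        alpha_split=alpha_split,
        max_depth=max_depth,
    )


def predict_tree(
    model: TreeModel, profile: Mapping[str, float] | object
) -> tuple[str, dict[str, float]]:
    """Route one specimen's index profile through the tree.

    ``profile`` is a mapping of variable name to value, or any object with
    matching attributes (an ``IndexProfile`` works directly).  Returns the
    leaf's majority label and its class proportions.  Values equal to a
    threshold go left ("<= threshold").
    """

    def lookup(var: str) -> float:
        if isinstance(profile, Mapping):
            if var not in profile or profile[var] is None:
                raise ValidationError(f"required index {var!r} absent from profile")
            return float(profile[var])
        value = getattr(profile, var, None)
        if value is None:
            raise ValidationError(f"required index {var!r} absent from profile")
        return float(value)

    node = model.root
    while not node.is_leaf:
        value = lookup(node.split.variable)
        node = node.left if value <= node.split.threshold else node.right
    return node.majority_label(model.class_order), node.proportions()


# --- plain-text serialization -------------------------------------------


def _counts_to_text(counts: dict[str, int]) -> str:
    return ";".join(f"{c}:{k}" for c, k in counts.items())


def _counts_from_text(text: str) -> dict[str, int]:
    if not text:
        return {}
    out: dict[str, int] = {}
    for part in text.split(";"):
        c, k = part.rsplit(":", 1)
        out[c] = int(k)
    return out


def tree_to_text(model: TreeModel) -> str:
    """Serialize a tree to a line-oriented plain-text form (round-trippable)."""
    lines = [
        "dendromorph-tree v1",
        f"variables\t{','.join(model.variables)}",
        f"classes\t{','.join(model.class_order)}",
        f"params\tmin_leaf={model.min_leaf};alpha_split={model.alpha_split!r};"
        f"max_depth={model.max_depth}",
    ]

    def walk(node: TreeNode) -> None:
        if node.is_leaf:
            lines.append(f"{node.depth}\tleaf\t\t\t{_counts_to_text(node.counts)}")
        else:
            s = node.split
            lines.append(
                f"{node.depth}\tnode\t{s.variable}\t{s.threshold!r}\t"
                f"{_counts_to_text(node.counts)}\t{s.chi_square!r}\t{s.p_value!r}"
            )
            walk(node.left)
            walk(node.right)

    walk(model.root)
    return "\n".join(lines) + "\n"


def tree_from_text(text: str) -> TreeModel:
    """Inverse of :func:`tree_to_text`."""
    lines = [l for l in text.splitlines() if l.strip()]
    if not lines or not lines[0].startswith("dendromorph-tree"):
        raise ValidationError("not a serialized tree")
    variables = tuple(x for x in lines[1].split("\t", 1)[1].split(",") if x)
    classes = tuple(x for x in lines[2].split("\t", 1)[1].split(",") if x)
    params = dict(
        kv.split("=", 1) for kv in lines[3].split("\t", 1)[1].split(";")
    )
    body = lines[4:]
    pos = 0

    def parse() -> TreeNode:
        nonlocal pos
        parts = body[pos].split("\t")
        pos += 1
        depth, kind = int(parts[0]), parts[1]
        if kind == "leaf":
            return TreeNode(depth=depth, counts=_counts_from_text(parts[4]))
        counts = _counts_from_text(parts[4])
        left = parse()
        right = parse()
        split = SplitCandidate(
            variable=parts[2],
            threshold=float(parts[3]),
            chi_square=float(parts[5]),
            p_value=float(parts[6]),
            left_counts=left.counts,
            right_counts=right.counts,
        )
        return TreeNode(depth=depth, counts=counts, split=split, left=left, right=right)

    root = parse()
    return TreeModel(
        root=root,
        variables=variables,
        class_order=classes,
        min_leaf=int(params["min_leaf"]),
        alpha_split=float(params["alpha_split"]),
        max_depth=int(params["max_depth"]),
    )
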