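"""Nonparametric two-sample tests, compact letter displays, and OLS fits.

The Mann-Whitney U test here uses midranks for ties, the tie-corrected
normal approximation for large samples, and full enumeration of all
C(n1+n2, n1) group labelings for small ones — appropriate for comparing two
balanced series of 33 specimens as well as a 4-specimen hybrid group against
either parent.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import ValidationError

__all__ = [
    "RankTestMethod",
    "RankTestResult",
    "mann_whitney",
    "LetterDisplay",
    "pairwise_letter_display",
    "RegressionFit",
    "fit_linear_regression",
]

DEFAULT_EXACT_THRESHOLD = 12


class RankTestMethod(str, Enum):
    NORMAL_APPROX = "normal_approx"
    EXACT_ENUMERATION = "exact_enumeration"


@dataclass(frozen=True)
class RankTestResult:
    """Mann-Whitney U test outcome for samples of sizes ``n1`` and ``n2``.

    ``u_statistic`` is the U of the first sample; ``z_statistic`` is positive
    when the first sample has the larger mean rank.
    """

    n1: int
    n2: int
    u_statistic: float
    z_statistic: float
    p_two_sided: float
    method: RankTestMethod

    @property
    def u_other(self) -> float:
        return self.n1 * self.n2 - self.u_statistic


def _u_first(ranks: np.ndarray, n1: int) -> float:
    """U of the first sample from pooled midranks (first n1 entries)."""
    r1 = float(ranks[:n1].sum())
    return r1 - n1 * (n1 + 1) / 2.0


def mann_whitney(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
) -> RankTestResult:
    """Two-sided Mann-Whitney U test.

    When ``n1 + n2 <= exact_threshold`` the p-value comes from full
    enumeration of every assignment of the pooled observations into groups of
    the given sizes (exact even with ties, since midranks are enumerated);
    otherwise from the tie-corrected normal approximation without continuity
    correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    n1, n2 = int(a.size), int(b.size)
    n = n1 + n2
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u1 = _u_first(ranks, n1)
    mu = n1 * n2 / 2.0

    # tie-corrected variance of U
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:  # every pooled value identical
        return RankTestResult(n1, n2, u1, 0.0, 1.0, RankTestMethod.NORMAL_APPROX)
    z = (u1 - mu) / math.sqrt(sigma2)

    if n <= exact_threshold:
        observed = abs(u1 - mu)
        hits = 0
        total = 0
        idx = range(n)
        for combo in itertools.combinations(idx, n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            u = float(ranks[mask].sum()) - n1 * (n1 + 1) / 2.0
            if abs(u - mu) >= observed - 1e-9:
                hits += 1
            total += 1
        return RankTestResult(
            n1, n2, u1, z, hits / total, RankTestMethod.EXACT_ENUMERATION
        )

    p = 2.0 * float(sps.norm.sf(abs(z)))
    return RankTestResult(n1, n2, u1, z, min(1.0, p), RankTestMethod.NORMAL_APPROX)


# --- compact letter display ---------------------------------------------


@dataclass(frozen=True)
class LetterDisplay:
    """Compact letter display: groups sharing a letter are indistinguishable
    at the chosen alpha under the pairwise Mann-Whitney test."""

    letters: Mapping[str, str]
    alpha: float
    p_values: Mapping[tuple[str, str], float]


def pairwise_letter_display(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.01,
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
) -> LetterDisplay:
    """Insert-and-absorb compact letter display over pairwise rank tests.

    ``groups`` maps group labels to their raw samples; order of insertion
    fixes the letter assignment, making the display deterministic.
    """
    names = list(groups.keys())
    if len(names) < 2:
        raise ValidationError("at least two groups are required")
    for name in names:
        if len(groups[name]) == 0:
            raise ValidationError(f"group {name!r} is empty")

    p_values: dict[tuple[str, str], float] = {}
    for g1, g2 in itertools.combinations(names, 2):
        res = mann_whitney(groups[g1], groups[g2], exact_threshold=exact_threshold)
        p_values[(g1, g2)] = res.p_two_sided

    # insert-and-absorb: letter classes start as one class holding everyone
    classes: list[set[str]] = [set(names)]
    for (g1, g2), p in p_values.items():
        if p > alpha:
            continue
        for cls in list(classes):
            if g1 in cls and g2 in cls:
                classes.remove(cls)
                classes.append(cls - {g1})
                classes.append(cls - {g2})
        # absorb duplicates/subsets
        kept: list[set[str]] = []
        for cls in classes:
            if not cls:
                continue
            if any(cls < other or cls == other for other in kept):
                continue
            kept = [k for k in kept if not (k < cls)]
            kept.append(cls)
        classes = kept

    # deterministic letter order: sort classes by first member's input position
    order = {name: i for i, name in enumerate(names)}
    classes.sort(key=lambda cls: min(order[m] for m in cls))
    letters = {name: "" for name in names}
    for i, cls in enumerate(classes):
        letter = chr(ord("a") + i)
        for name in names:
            if name in cls:
                letters[name] += letter
    return LetterDisplay(letters=letters, alpha=alpha, p_values=p_values)


# --- ordinary least squares ---------------------------------------------


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of y on x with slope p-value from the t distribution (n-2 df)."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    p_slope: float

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept


def fit_linear_regression(
    x: Sequence[float], y: Sequence[float]
) -> RegressionFit:
    """Ordinary least squares of ``y`` on ``x``."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValidationError("x and y must have equal length")
    if xa.size < 3:
        raise ValidationError("at least three points are required")
    if np.allclose(xa, xa[0]):
        raise ValidationError("degenerate predictor: x is constant")
    fit = sps.linregress(xa, ya)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n=int(xa.size),
        p_slope=float(fit.pvalue),
    )
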