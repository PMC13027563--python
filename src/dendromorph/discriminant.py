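"""Two-group linear discriminant analysis with backward stepwise selection.

Wilks' lambda for two groups is the ratio of within-group to total
generalized variance, det(W)/det(T).  For g = 2 groups and p predictors it
admits an exact F transform, F = ((n-p-1)/p) * (1-L)/L on (p, n-p-1) df.
The F-to-remove of a predictor is the F for the change in lambda when that
predictor is deleted from the current model,

    F_remove = (n - p - 1) * (L_without / L_with - 1),

on (1, n-p-1) df.  Backward stepwise selection repeatedly deletes the
predictor with the smallest F-to-remove while its p-value exceeds the
removal threshold.

Hybrids are excluded from discriminant fitting by the callers: with four
specimens the within-group covariance prerequisites are not met, so the
analysis is restricted to the two parental species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import ValidationError

__all__ = [
    "DiscriminantModel",
    "FRemoveEntry",
    "fit_two_group_lda",
    "f_remove_table",
    "backward_stepwise_select",
]

_COND_LIMIT = 1e12


class SingularMatrixError(ValidationError):
    """Pooled within-group covariance is singular; remove collinear predictors."""


@dataclass(frozen=True)
class DiscriminantModel:
    """A fitted two-group Fisher discriminant."""

    variables: tuple[str, ...]
    coefficients: tuple[float, ...]
    wilks_lambda: float
    overall_f: float
    df1: int
    df2: int
    p_value: float
    group_means: dict[str, dict[str, float]]
    n_per_group: dict[str, int]

    @property
    def n_total(self) -> int:
        return sum(self.n_per_group.values())


@dataclass(frozen=True)
class FRemoveEntry:
    variable: str
    f_remove: float
    p_value: float


def _split_matrices(
    data: pd.DataFrame, group: Sequence, variables: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, list, np.ndarray]:
    g = np.asarray(group)
    levels = list(pd.unique(g))
    if len(levels) != 2:
        raise ValidationError(f"exactly two groups required, got {len(levels)}")
    X = data.loc[:, list(variables)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValidationError("predictors contain missing values")
    return X, g, levels, np.asarray([g == lv for lv in levels])


def _wilks_lambda(X: np.ndarray, masks: np.ndarray) -> float:
    """det(W)/det(T) for the predictor block X under the two group masks."""
    if X.shape[1] == 0:
        return 1.0
    grand = X.mean(axis=0)
    T = (X - grand).T @ (X - grand)
    W = np.zeros_like(T)
    for mask in masks:
        Xi = X[mask]
        ci = Xi - Xi.mean(axis=0)
        W += ci.T @ ci
    sign_t, logdet_t = np.linalg.slogdet(T)
    sign_w, logdet_w = np.linalg.slogdet(W)
    if sign_w <= 0 or not np.isfinite(logdet_w) or np.linalg.cond(W) > _COND_LIMIT:
        raise SingularMatrixError(
            "singular pooled within-group covariance; remove a collinear or "
            "constant predictor"
        )
    if sign_t <= 0 or not np.isfinite(logdet_t):
        raise SingularMatrixError("singular total covariance matrix")
    return float(math.exp(logdet_w - logdet_t))


def fit_two_group_lda(
    data: pd.DataFrame,
    group: Sequence,
    variables: Sequence[str] | None = None,
) -> DiscriminantModel:
    """Fit a two-group linear discriminant on the given predictor columns.

    ``group`` is a length-matching sequence with exactly two distinct labels.
    """
    if variables is None:
        variables = list(data.columns)
    variables = list(variables)
    if not variables:
        raise ValidationError("at least one predictor is required")
    X, g, levels, masks = _split_matrices(data, group, variables)
    n, p = X.shape
    for lv, mask in zip(levels, masks):
        if mask.sum() < 2:
            raise ValidationError(f"group {lv!r} needs at least 2 specimens")
    if n <= p + 2:
        raise ValidationError(
            f"{n} specimens cannot support {p} predictors (need n > p + 2)"
        )

    lam = _wilks_lambda(X, masks)
    df1, df2 = p, n - p - 1
    overall_f = (df2 / df1) * (1.0 - lam) / lam if lam > 0 else math.inf
    p_value = float(sps.f.sf(overall_f, df1, df2))

    # Fisher direction: pooled within-covariance inverse times mean difference
    mean_by = [X[mask].mean(axis=0) for mask in masks]
    W = np.zeros((p, p))
    for mask in masks:
        Xi = X[mask]
        ci = Xi - Xi.mean(axis=0)
        W += ci.T @ ci
    Sp = W / (n - 2)
    coef = np.linalg.solve(Sp, mean_by[0] - mean_by[1])

    return DiscriminantModel(
        variables=tuple(variables),
        coefficients=tuple(float(c) for c in coef),
        wilks_lambda=lam,
        overall_f=float(overall_f),
        df1=df1,
        df2=df2,
        p_value=p_value,
        group_means={
            str(lv): dict(zip(variables, map(float, m)))
            for lv, m in zip(levels, mean_by)
        },
        n_per_group={str(lv): int(mask.sum()) for lv, mask in zip(levels, masks)},
    )


def f_remove_table(
    model: DiscriminantModel, data: pd.DataFrame, group: Sequence
) -> list[FRemoveEntry]:
    """F-to-remove and its p-value for each predictor of a fitted model.

    Deleting the only predictor is assessed against the null model
    (lambda = 1), making the single-predictor F-to-remove equal the model's
    overall F.
    """
    variables = list(model.variables)
    X, g, levels, masks = _split_matrices(data, group, variables)
    n, p = X.shape
    lam_with = model.wilks_lambda
    df2 = n - p - 1
    entries = []
    for i, var in enumerate(variables):
        rest = [v for v in variables if v != var]
        if rest:
            Xr = data.loc[:, rest].to_numpy(dtype=float)
            lam_without = _wilks_lambda(Xr, masks)
        else:
            lam_without = 1.0
        f_rm = df2 * (lam_without / lam_with - 1.0)
        f_rm = max(0.0, float(f_rm))
        entries.append(
            FRemoveEntry(
                variable=var,
                f_remove=f_rm,
                p_value=float(sps.f.sf(f_rm, 1, df2)),
            )
        )
    return entries


def backward_stepwise_select(
    data: pd.DataFrame,
    group: Sequence,
    variables: Sequence[str] | None = None,
    p_remove: float = 0.10,
) -> tuple[DiscriminantModel | None, pd.DataFrame]:
    """Backward stepwise predictor selection for the two-group discriminant.

    Starting from the full model, the predictor with the smallest F-to-remove
    is deleted while its p-value exceeds ``p_remove``; ties in F-to-remove
    are broken by removing the later variable in input order.  Returns the
    final model (``None`` if every predictor was removed) and the removal
    trace with columns
    ``step, action, variable, f_remove, p_value, wilks_lambda_after``.
    """
    if variables is None:
        variables = list(data.columns)
    current = list(variables)
    if len(current) < 2:
        raise ValidationError("backward selection needs at least two predictors")
    trace_rows = []
    step = 0
    model = fit_two_group_lda(data, group, current)
    while current:
        entries = f_remove_table(model, data, group)
        # smallest F-to-remove; ties -> later variable in input order
        worst = min(
            enumerate(entries),
            key=lambda ie: (ie[1].f_remove, -ie[0]),
        )[1]
        if worst.p_value <= p_remove:
            break
        current.remove(worst.variable)
        step += 1
        if current:
            model = fit_two_group_lda(data, group, current)
            lam_after = model.wilks_lambda
        else:
            model = None
            lam_after = 1.0
        trace_rows.append(
            {
                "step": step,
                "action": "remove",
                "variable": worst.variable,
                "f_remove": worst.f_remove,
                "p_value": worst.p_value,
                "wilks_lambda_after": lam_after,
            }
        )
        if model is None:
            break
    trace = pd.DataFrame(
        trace_rows,
        columns=["step", "action", "variable", "f_remove", "p_value", "wilks_lambda_after"],
    )
    return model, trace
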