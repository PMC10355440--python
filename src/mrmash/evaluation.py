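"""Prediction-accuracy metrics and prior-sharing reports.

The headline metric is the standardized root mean squared error: RMSE divided
by the standard deviation of the true values in the test set, so that a value
of 1 corresponds to the naive predictor that ignores the predictors entirely.
Relative RMSE compares a method against a named reference method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mrmash.inference import ModelFit


def standardized_rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """RMSE divided by the sample (n-1 denominator) SD of the true values.

    Entries where either input is NaN are excluded pairwise. With the sample
    SD convention the constant mean predictor scores exactly 1.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    keep = ~(np.isnan(y_true) | np.isnan(y_pred))
    y_true, y_pred = y_true[keep], y_pred[keep]
    m = y_true.size
    if m < 2:
        raise ValueError("need at least two paired observations")
    sd = y_true.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation of true values: RMSE standardization undefined")
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    return rmse / float(sd)


def relative_rmse(rmse_method: float, rmse_ref: float) -> float:
    """Relative difference in RMSE versus a reference; negative = better than it."""
    if rmse_ref <= 0:
        raise ValueError("reference RMSE must be positive")
    return (rmse_method - rmse_ref) / rmse_ref


@dataclass
class SharingPattern:
    """The dominant effect-sharing pattern in an estimated prior.

    ``correlation`` is the winning prior covariance scaled to a correlation
    matrix; conditions with zero prior variance are undefined (False in
    ``defined``; NaN rows/columns in ``correlation``).
    """

    correlation: np.ndarray
    label: str
    weight: float
    defined: np.ndarray


def report_top_pattern(fits: ModelFit | list[ModelFit]) -> SharingPattern:
    """Correlation matrix of the non-null prior component with the largest weight.

    For a list of fits sharing the same prior template, weights are summed
    across fits before taking the argmax.
    """
    if isinstance(fits, ModelFit):
        fits = [fits]
    if not fits:
        raise ValueError("need at least one fit")
    prior = fits[0].prior
    K = prior.K
    total_w = np.zeros(K)
    for fit in fits:
        if fit.prior.K != K:
            raise ValueError("all fits must share the same prior template")
        total_w += fit.prior.w0
    nonnull = np.array([prior.S0[k].any() for k in range(K)])
    if not nonnull.any() or total_w[nonnull].max() <= 0:
        raise ValueError("no non-null component carries positive weight")
    masked = np.where(nonnull, total_w, -np.inf)
    k = int(np.argmax(masked))
    S = prior.S0[k]
    d = np.diag(S).copy()
    defined = d > 0
    corr = np.full_like(S, np.nan)
    if defined.any():
        sub = np.ix_(defined, defined)
        scale = 1.0 / np.sqrt(d[defined])
        corr[sub] = S[sub] * np.outer(scale, scale)
    return SharingPattern(
        correlation=corr,
        label=prior.component_labels[k],
        weight=float(total_w[k] / len(fits)),
        defined=defined,
    )


def accuracy_table(
    Y_true: np.ndarray,
    predictions: dict[str, np.ndarray],
    reference: str | None = None,
    condition_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-condition standardized RMSE for each method, with optional relative columns.

    ``Y_true`` may contain NaN for unobserved test entries; those entries are
    excluded pairwise per condition.
    """
    Y_true = np.asarray(Y_true, dtype=float)
    r = Y_true.shape[1]
    if condition_ids is None:
        condition_ids = [f"cond{s + 1:02d}" for s in range(r)]
    if reference is not None and reference not in predictions:
        raise ValueError(f"reference method {reference!r} not among predictions")
    rows = {}
    rows["n_test"] = [int((~np.isnan(Y_true[:, s])).sum()) for s in range(r)]
    for name, pred in predictions.items():
        pred = np.asarray(pred, dtype=float)
        if pred.shape != Y_true.shape:
            raise ValueError(f"prediction {name!r} shape mismatch")
        rows[name] = [
            standardized_rmse(Y_true[:, s], pred[:, s]) for s in range(r)
        ]
    table = pd.DataFrame(rows, index=condition_ids)
    if reference is not None:
        for name in predictions:
            if name == reference:
                continue
            table[f"rel_{name}_vs_{reference}"] = [
                relative_rmse(table.loc[c, name], table.loc[c, reference])
                for c in condition_ids
            ]
    table.index.name = "condition"
    return table
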