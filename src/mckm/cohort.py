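"""Campaign-level aggregation of per-run parameter estimates.

Fitted parameter vectors from many runs are collected into a cohort table,
summarised per campaign/passage (mean and clone-to-clone standard
deviation, the layout used to compare screening campaigns), and fed into a
Fisher linear discriminant analysis that asks which kinetic parameters
separate well- from poorly performing, or stable from unstable, clones.

Because the 13 parameters span about six orders of magnitude, LDA operates
on standardised parameters (zero mean, unit variance); the discriminant
direction is w ~ Sigma_pooled^-1 (mu_1 - mu_0), defined up to sign and
scale, and classification accuracy is reported leave-one-out with the
midpoint threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import PARAM_NAMES
from .regression import RegressionResult
from .simulate import FeedSchedule

__all__ = [
    "LdaResult",
    "cohort_table",
    "summarize_parameters",
    "label_performance",
    "fisher_lda",
]

logger = logging.getLogger(__name__)


def cohort_table(
    results: Sequence[RegressionResult],
    metadata: Sequence[dict] | pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per run: metadata, mode, fitted parameters, fit metrics."""
    rows = []
    meta_frame = (
        metadata
        if isinstance(metadata, pd.DataFrame)
        else pd.DataFrame(list(metadata))
        if metadata is not None
        else None
    )
    for k, result in enumerate(results):
        row: dict = {}
        if meta_frame is not None:
            row.update(meta_frame.iloc[k].to_dict())
        row["mode"] = result.mode
        row.update(result.theta_hat.to_dict())
        row.update({f"r2_{name}": value for name, value in result.r2.items()})
        row.update({f"nrmse_{name}": value for name, value in result.nrmse.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_parameters(
    cohort: pd.DataFrame, by: str | Sequence[str] = "campaign"
) -> pd.DataFrame:
    """Per-group mean and sample standard deviation of the 13 parameters."""
    by = [by] if isinstance(by, str) else list(by)
    for column in by:
        if column not in cohort.columns:
            raise KeyError(f"grouping column {column!r} not in cohort table")
    present = [n for n in PARAM_NAMES if n in cohort.columns]
    groups = cohort.groupby(by, dropna=False)
    summary = groups[present].agg(["mean", "std"])
    empty = [key for key, frame in groups if len(frame) == 0]
    if empty:  # pragma: no cover - pandas drops empty groups already
        warnings.warn(f"empty groups omitted from summary: {empty}")
    return summary


def label_performance(
    cohort: pd.DataFrame,
    titre_column: str = "final_titre",
    by: str | None = "campaign",
) -> pd.Series:
    """Top-50% final-titre indicator per campaign (ties land in the top).

    The split is on the within-group median, so the labels are invariant
    to any monotone rescaling of the titre.
    """
    if titre_column not in cohort.columns:
        raise KeyError(f"titre column {titre_column!r} not in cohort table")

    def split(values: pd.Series) -> pd.Series:
        return values >= values.median()

    if by is not None and by in cohort.columns:
        return cohort.groupby(by, group_keys=False)[titre_column].apply(split)
    return split(cohort[titre_column])


@dataclass
class LdaResult:
    """Fisher discriminant over kinetic parameters (binary classes)."""

    coefficients: np.ndarray  # discriminant direction, one entry per feature
    feature_names: tuple[str, ...]
    class_means: dict[int, np.ndarray]  # standardized-space means per class
    loo_accuracy: float
    standardized: bool

    def top_feature(self) -> str:
        return self.feature_names[int(np.argmax(np.abs(self.coefficients)))]


def _lda_direction(
    X: np.ndarray, y: np.ndarray, ridge: float | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X0, X1 = X[y == 0], X[y == 1]
    m0, m1 = X0.mean(axis=0), X1.mean(axis=0)
    n0, n1 = len(X0), len(X1)
    p = X.shape[1]
    cov0 = np.cov(X0, rowvar=False) if n0 > 1 else np.zeros((p, p))
    cov1 = np.cov(X1, rowvar=False) if n1 > 1 else np.zeros((p, p))
    pooled = ((n0 - 1) * cov0 + (n1 - 1) * cov1) / max(n0 + n1 - 2, 1)
    if ridge is not None:
        pooled = pooled + np.eye(p) * ridge * np.trace(pooled) / p
    try:
        w = np.linalg.solve(pooled, m1 - m0)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular; pass ridge=1e-6 (or larger) to "
            "regularise, or reduce the feature set"
        ) from exc
    return w, m0, m1


def _classify(X: np.ndarray, w: np.ndarray, m0: np.ndarray, m1: np.ndarray) -> np.ndarray:
    z = X @ w
    threshold = (m0 @ w + m1 @ w) / 2.0
    orientation = np.sign(m1 @ w - threshold) or 1.0
    return (orientation * (z - threshold) > 0).astype(int)


def fisher_lda(
    X: np.ndarray,
    y: Sequence[int],
    feature_names: Sequence[str] | None = None,
    standardize: bool = True,
    ridge: float | None = None,
) -> LdaResult:
    """Fisher LDA with leave-one-out accuracy.

    ``X`` is runs x features (typically the 13 fitted parameters), ``y`` a
    binary label per run. Features are standardised by default; the
    returned coefficient vector lives in that standardised space, so its
    magnitudes are comparable across parameters and indicate each
    parameter's discriminatory power.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one label per row")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    y = (y == classes[1]).astype(int)
    names = tuple(feature_names) if feature_names is not None else tuple(
        PARAM_NAMES[: X.shape[1]]
    )

    if standardize:
        loc = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        scale = np.where(scale > 0, scale, 1.0)
        Xs = (X - loc) / scale
    else:
        Xs = X

    w, m0, m1 = _lda_direction(Xs, y, ridge)

    correct = 0
    for k in range(len(y)):
        keep = np.ones(len(y), dtype=bool)
        keep[k] = False
        y_train = y[keep]
        if len(np.unique(y_train)) < 2:
            continue
        try:
            w_k, m0_k, m1_k = _lda_direction(Xs[keep], y_train, ridge)
        except np.linalg.LinAlgError:
            continue
        pred = _classify(Xs[k : k + 1], w_k, m0_k, m1_k)[0]
        correct += int(pred == y[k])
    loo = correct / len(y)

    return LdaResult(
        coefficients=w,
        feature_names=names,
        class_means={0: m0, 1: m1},
        loo_accuracy=float(loo),
        standardized=standardize,
    )


def final_titre(run_observations: np.ndarray) -> float:
    """Last observed titre of a run's observation matrix."""
    from .model import VARIABLE_NAMES

    column = run_observations[:, VARIABLE_NAMES.index("P")]
    present = np.flatnonzero(np.isfinite(column))
    return float(column[present[-1]]) if len(present) else float("nan")
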