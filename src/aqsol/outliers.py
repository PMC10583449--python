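"""Local Outlier Factor diagnostics and with/without-outlier refits.

Outliers are sought in the *training* partition only: the question is whether
locally isolated training molecules distort the fitted models, so the test
partition is never touched. Group differences between flagged and unflagged
rows are summarized per descriptor with Welch t-tests (raw p-values, no
multiplicity correction — the table is a screening report, not an inference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import LocalOutlierFactor

from .models import ModelMetrics, evaluate

__all__ = ["OutlierReport", "lof_flags", "group_ttests", "refit_without_outliers"]


@dataclass
class OutlierReport:
    """Row-level LOF diagnostics: scores, flags, and optional extras."""

    scores: np.ndarray  # LOF score per row (~1 = inlier density)
    flags: np.ndarray  # True = outlier
    n_neighbors: int
    score_threshold: float

    @property
    def n_outliers(self) -> int:
        return int(self.flags.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"row": np.arange(len(self.scores)), "lof_score": self.scores, "outlier": self.flags}
        )


def lof_flags(
    X, n_neighbors: int = 20, score_threshold: float = 1.5
) -> OutlierReport:
    """Score each row with Local Outlier Factor and flag high scores.

    The LOF score is the ratio of a point's neighbors' local density to its
    own; ~1 means the point sits in density comparable to its neighborhood,
    and rows with score > *score_threshold* are flagged. Duplicated rows
    (zero pairwise distance) are handled by the library's definition and
    come out as inliers.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n_neighbors >= n:
        raise ValueError(f"n_neighbors={n_neighbors} must be < n rows ({n})")
    lof = LocalOutlierFactor(n_neighbors=n_neighbors)
    lof.fit(X)
    scores = -lof.negative_outlier_factor_
    return OutlierReport(
        scores=scores,
        flags=scores > score_threshold,
        n_neighbors=n_neighbors,
        score_threshold=score_threshold,
    )


def group_ttests(X, flags, feature_names=None) -> pd.DataFrame:
    """Welch two-sided t-test per feature: outlier group vs inlier group."""
    X = np.asarray(X, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    if flags.shape[0] != X.shape[0]:
        raise ValueError("flags must align with rows")
    n_out, n_in = int(flags.sum()), int((~flags).sum())
    if n_out < 2 or n_in < 2:
        raise ValueError(f"each group needs >= 2 rows (got {n_out} outliers, {n_in} inliers)")
    t, p = stats.ttest_ind(X[flags], X[~flags], equal_var=False, axis=0)
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(X.shape[1])]
    return pd.DataFrame({"feature": feature_names, "t": t, "p": p})


def refit_without_outliers(
    X_train,
    y_train,
    X_test,
    y_test,
    flags,
    model_factory,
) -> dict[str, ModelMetrics]:
    """Compare test metrics with and without flagged training rows.

    *model_factory* is a zero-argument callable returning an unfitted model
    with a ``fit`` method (keeps RF seeds/hyperparameters identical across
    the two fits). The test partition is evaluated untouched in both arms.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    flags = np.asarray(flags, dtype=bool)

    m_with = model_factory().fit(X_train, y_train)
    m_without = model_factory().fit(X_train[~flags], y_train[~flags])
    with_metrics = evaluate(m_with, X_test, y_test, partition="test")
    without_metrics = evaluate(m_without, X_test, y_test, partition="test")
    return {
        "with_outliers": with_metrics,
        "without_outliers": without_metrics,
        "delta_rmse": without_metrics.rmse - with_metrics.rmse,
        "delta_mae": without_metrics.mae - with_metrics.mae,
    }
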