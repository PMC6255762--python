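"""Holdout validation of the fitted treatment-seeking model.

A 10% random subset of children with observed responses is excluded from
fitting; the fitted model's posterior-median predicted probabilities on this
subset are binarised and scored by misclassification error and the receiver
operating characteristic (sensitivity/specificity sweep with trapezoidal
AUC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ValidationReport",
    "holdout_split",
    "predict_holdout",
    "misclassification",
    "roc_curve",
    "validate",
]


@dataclass
class ValidationReport:
    n_train: int
    n_test: int
    misclassification_error: float
    cutoff: float
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_dict(self) -> dict:
        return {
            "n_train": self.n_train,
            "n_test": self.n_test,
            "misclassification_error": self.misclassification_error,
            "cutoff": self.cutoff,
            "auc": self.auc,
        }

    def roc_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


def holdout_split(children: pd.DataFrame, fraction: float = 0.10,
                  seed: int = 0, survey_col: str | None = None):
    """Random train/test partition of children with observed responses.

    The test set has ``round(fraction * n)`` children drawn uniformly without
    replacement among those with a non-missing response (stratified per
    survey when ``survey_col`` is given and present); everything else —
    including children without responses — stays in the training set.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"holdout fraction must be in (0, 1), got {fraction}")
    y = children["y"].to_numpy(dtype=float)
    observed = np.nonzero(~np.isnan(y))[0]
    if observed.size < 10:
        raise ValueError("need at least 10 non-missing responses to split")
    rng = np.random.default_rng(seed)
    if survey_col and survey_col in children.columns:
        surveys = children[survey_col].to_numpy()
        test_idx = []
        for sv in pd.unique(surveys[observed]):
            pool = observed[surveys[observed] == sv]
            k = int(round(fraction * pool.size))
            test_idx.append(rng.choice(pool, size=k, replace=False))
        test_idx = np.sort(np.concatenate(test_idx))
    else:
        k = int(round(fraction * observed.size))
        test_idx = np.sort(rng.choice(observed, size=k, replace=False))
    mask = np.zeros(len(children), dtype=bool)
    mask[test_idx] = True
    return children.loc[~mask].copy(), children.loc[mask].copy()


def predict_holdout(results, test: pd.DataFrame, mode: str = "median") -> np.ndarray:
    """Posterior predicted probabilities for the holdout children."""
    return results.predict(
        test["travel_time_min"].to_numpy(dtype=float),
        test["urban"].to_numpy(dtype=float),
        mode=mode,
    )


def misclassification(predictions, observed, cutoff: float = 0.5) -> float:
    """Mean of 1[(prediction >= cutoff) != observed]."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(observed, dtype=float)
    if p.size == 0:
        raise ValueError("empty predictions")
    if p.shape != y.shape:
        raise ValueError("predictions and observed must have equal length")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("observed outcomes must be 0/1")
    return float(np.mean((p >= cutoff).astype(float) != y))


def roc_curve(predictions, observed):
    """ROC sweep over unique score thresholds plus trapezoidal AUC.

    Returns (fpr, tpr, auc). Thresholds descend through the unique scores so
    the curve runs from (0, 0) to (1, 1); ties share a threshold, making the
    trapezoid AUC equal to the Mann-Whitney statistic
    P(score1 > score0) + 0.5 * P(tie).
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(observed, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-p, kind="stable")
    p_sorted, y_sorted = p[order], y[order]
    # cumulative counts at each distinct-threshold boundary
    distinct = np.nonzero(np.diff(p_sorted))[0]
    bounds = np.concatenate([distinct, [p.size - 1]])
    tp = np.cumsum(y_sorted)[bounds]
    fp = np.cumsum(1.0 - y_sorted)[bounds]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def validate(results, train: pd.DataFrame, test: pd.DataFrame,
             cutoff: float = 0.5, mode: str = "median") -> ValidationReport:
    """Score the fitted model on the holdout set."""
    y = test["y"].to_numpy(dtype=float)
    keep = ~np.isnan(y)
    preds = predict_holdout(results, test.loc[keep], mode=mode)
    fpr, tpr, auc = roc_curve(preds, y[keep])
    err = misclassification(preds, y[keep], cutoff=cutoff)
    return ValidationReport(
        n_train=int(train["y"].notna().sum()),
        n_test=int(keep.sum()),
        misclassification_error=err,
        cutoff=cutoff,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
    )
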