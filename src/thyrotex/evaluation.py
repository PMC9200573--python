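"""Diagnostic-performance metrics, ROC/AUC, and logistic regression.

Positive class is malignant (label 1), so

    accuracy    = (tp + tn) / (tp + tn + fp + fn)
    sensitivity = tp / (tp + fn)   — probability the test is positive in the ill
    specificity = tn / (tn + fp)   — probability the test is negative in the well

A metric whose denominator is zero is reported as NaN and recorded in the
``undefined`` set rather than raising.

The ROC curve sweeps a decision threshold over the unique score values; AUC
is the trapezoidal area, which (with ties grouped at a single threshold)
equals the Mann-Whitney probability that a random positive case scores above
a random negative one, counting ties as one half.

Logistic regression is fit in-repo by iteratively reweighted least squares
(Newton's method on the log-likelihood) with Wald standard errors from the
observed information matrix, so the risk-factor analysis is a tested part of
the package rather than a delegated call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "RocCurve",
    "LogisticFit",
    "confusion",
    "metrics",
    "roc_auc",
    "logistic_fit",
    "evaluate_pipeline",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total < 1:
            raise ValueError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricReport:
    """Accuracy/sensitivity/specificity as proportions, plus optional AUC.

    Undefined metrics (zero denominator) are NaN and listed in
    ``undefined``.  ``as_percent`` renders the report in percent to one
    decimal place.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    auc: float | None = None
    undefined: frozenset[str] = frozenset()

    def as_percent(self) -> dict[str, str]:
        out = {}
        for name in ("accuracy", "sensitivity", "specificity"):
            value = getattr(self, name)
            out[name] = "undefined" if name in self.undefined else f"{100 * value:.1f}%"
        if self.auc is not None:
            out["auc"] = f"{self.auc:.3f}"
        return out


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit (intercept first) with Wald inference."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    z_values: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    iterations: int
    converged: bool
    separation_flag: bool = False


def confusion(predictions: np.ndarray, labels: np.ndarray) -> ConfusionCounts:
    """Exact cross-tabulation of binary predictions against binary labels."""
    p = np.asarray(predictions)
    y = np.asarray(labels)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {y.shape}")
    if not (set(np.unique(p)) <= {0, 1} and set(np.unique(y)) <= {0, 1}):
        raise ValueError("predictions and labels must be 0/1")
    return ConfusionCounts(
        tp=int(np.sum((p == 1) & (y == 1))),
        tn=int(np.sum((p == 0) & (y == 0))),
        fp=int(np.sum((p == 1) & (y == 0))),
        fn=int(np.sum((p == 0) & (y == 1))),
    )


def metrics(counts: ConfusionCounts) -> MetricReport:
    """Accuracy, sensitivity and specificity from confusion counts."""
    undefined = set()

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.add(name)
            return float("nan")
        return num / den

    report = MetricReport(
        accuracy=ratio(counts.tp + counts.tn, counts.total, "accuracy"),
        sensitivity=ratio(counts.tp, counts.tp + counts.fn, "sensitivity"),
        specificity=ratio(counts.tn, counts.tn + counts.fp, "specificity"),
    )
    report.undefined = frozenset(undefined)
    return report


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[RocCurve, float]:
    """ROC curve over unique score thresholds and its trapezoidal area.

    The sweep classifies score >= threshold as positive; tied scores move
    together, so the trapezoidal area equals the tie-corrected pairwise
    (Mann-Whitney) probability exactly.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # group ties: cumulative counts at the last index of each tied block
    distinct = np.flatnonzero(np.diff(s_sorted)) if s.size > 1 else np.empty(0, int)
    block_ends = np.concatenate((distinct, [s.size - 1]))
    cum_tp = np.cumsum(y_sorted == 1)[block_ends]
    cum_fp = np.cumsum(y_sorted == 0)[block_ends]
    tpr = np.concatenate(([0.0], cum_tp / n_pos))
    fpr = np.concatenate(([0.0], cum_fp / n_neg))
    thresholds = np.concatenate(([np.inf], s_sorted[block_ends]))
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr), auc


def logistic_fit(
    design: np.ndarray,
    labels: np.ndarray,
    add_intercept: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Logistic regression by iteratively reweighted least squares.

    ``design`` is the n x d covariate matrix; an intercept column is
    prepended unless ``add_intercept=False``.  Convergence is declared when
    the largest absolute score (gradient) component drops below ``tol``.
    Diverging coefficients (complete or quasi-complete separation) set
    ``separation_flag`` instead of raising.
    """
    from scipy import stats

    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("design matrix contains non-finite values")
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
    n, d = X.shape
    if n <= d:
        raise ValueError(f"need n > number of parameters ({d}), got n={n}")

    beta = np.zeros(d)
    separation = False
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        W = mu * (1.0 - mu)
        info = X.T @ (X * W[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            separation = True
            break
        # step-halving keeps the likelihood non-decreasing
        ll_old = _bernoulli_ll(y, eta)
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            if _bernoulli_ll(y, X @ cand) >= ll_old:
                break
            factor /= 2.0
        beta = beta + factor * step
        if np.linalg.norm(beta) > 1e4:
            separation = True
            break

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    # fitted probabilities indistinguishable from the labels: the MLE is at
    # infinity (complete separation) even though the score already vanished
    if np.max(np.abs(y - mu)) < 1e-6:
        separation = True
    W = mu * (1.0 - mu)
    info = X.T @ (X * W[:, None])
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(d, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return LogisticFit(
        coefficients=beta,
        standard_errors=se,
        z_values=z,
        p_values=p,
        log_likelihood=_bernoulli_ll(y, eta),
        iterations=iteration,
        converged=converged,
        separation_flag=separation,
    )


def _bernoulli_ll(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + e^eta), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def evaluate_pipeline(model, features: np.ndarray, labels: np.ndarray):
    """Predict with an ensemble and summarize: metrics plus ROC from margins.

    Returns (MetricReport, RocCurve).
    """
    from .classifier import predict

    pred_labels, margins = predict(model, features)
    counts = confusion(pred_labels, np.asarray(labels))
    report = metrics(counts)
    curve, auc = roc_auc(margins, np.asarray(labels))
    report.auc = auc
    return report, curve
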