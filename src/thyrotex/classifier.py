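"""AdaBoost ensemble of decision stumps, written from scratch.

The boosting loop is the classical discrete AdaBoost of Freund and Schapire.
Round t fits the decision stump minimizing weighted 0/1 error eps_t over all
(feature, threshold, polarity) candidates, then multiplies the weights of
correctly classified examples by beta_t = eps_t / (1 - eps_t) and
renormalizes, so mistakes gain relative weight.  The strong classifier is
the weighted-majority vote

    H(x) = 1   iff   sum_t log(1/beta_t) h_t(x) >= 1/2 sum_t log(1/beta_t),

with h_t in {0, 1}; the signed distance of the vote from the 1/2 quorum is
exposed as a margin score for ROC analysis.  Every retained round has
eps_t < 1/2, hence beta_t in (0, 1) and a strictly positive vote weight.
A perfect round (eps_t = 0) would make beta_t = 0; it is assigned
beta_t = BETA_FLOOR and boosting stops, since the remaining rounds could
only refit the same stump.

Labels are {0, 1} with 1 = malignant = positive class throughout the
package.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TrainingSet",
    "Stump",
    "ExampleWeights",
    "EnsembleModel",
    "fit_stump",
    "update_weights",
    "train_adaboost",
    "predict",
    "stratified_split",
    "save_model",
    "load_model",
]

BETA_FLOOR = 1e-10


@dataclass(frozen=True)
class TrainingSet:
    """Feature matrix (n x d), binary labels, and feature names."""

    features: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=float)
        y = np.asarray(self.labels)
        if X.ndim != 2:
            raise ValueError(f"features must be 2-D, got shape {X.shape}")
        if X.shape[0] != y.shape[0]:
            raise ValueError(
                f"{X.shape[0]} feature rows but {y.shape[0]} labels"
            )
        if X.shape[0] < 2:
            raise ValueError("need at least 2 examples")
        if not np.isfinite(X).all():
            raise ValueError("features contain non-finite values")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be 0 or 1")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y.astype(int))
        if not self.feature_names:
            object.__setattr__(
                self,
                "feature_names",
                tuple(f"f{j}" for j in range(X.shape[1])),
            )
        elif len(self.feature_names) != X.shape[1]:
            raise ValueError("feature_names length must match feature count")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]


@dataclass(frozen=True)
class Stump:
    """One-split threshold classifier on a single feature.

    ``polarity`` "le" predicts 1 where feature <= threshold; "gt" predicts 1
    where feature > threshold.  ``error`` is the weighted 0/1 error at fit
    time; ``degenerate`` marks a fit on single-class effective weights.
    """

    feature_index: int
    threshold: float
    polarity: str  # "le" | "gt"
    error: float
    degenerate: bool = False

    def predict(self, X: np.ndarray) -> np.ndarray:
        col = np.asarray(X, dtype=float)[:, self.feature_index]
        if self.polarity == "le":
            return (col <= self.threshold).astype(int)
        return (col > self.threshold).astype(int)


@dataclass
class ExampleWeights:
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {w.sum()}")
        self.weights = w

    @classmethod
    def uniform(cls, n: int) -> "ExampleWeights":
        return cls(np.full(n, 1.0 / n))


@dataclass
class EnsembleModel:
    """Trained stump list with multiplicative round weights beta_t.

    The vote weight of round t is log(1/beta_t) > 0.  ``history`` records
    (eps_t, weighted accuracy) per retained round.
    """

    stumps: list[Stump]
    betas: list[float]
    feature_names: tuple[str, ...] = ()
    history: list[tuple[float, float]] = field(default_factory=list)

    @property
    def rounds(self) -> int:
        return len(self.stumps)

    def vote_weights(self) -> np.ndarray:
        return np.log(1.0 / np.asarray(self.betas))


def fit_stump(data: TrainingSet, weights: ExampleWeights) -> Stump:
    """Exhaustive weighted-error minimization over all stump candidates.

    Candidate thresholds are the midpoints between consecutive sorted unique
    values of each feature, plus sentinels below the minimum and above the
    maximum (constant-prediction stumps).  Ties are broken toward the lowest
    feature index, then the lowest threshold, with "le" polarity preferred.
    """
    X, y, w = data.features, data.labels, weights.weights
    pos_mass = float(w[y == 1].sum())
    degenerate = pos_mass < 1e-12 or pos_mass > 1 - 1e-12

    best: tuple[float, int, float, str] | None = None  # (error, j, thr, pol)
    for j in range(data.d):
        col = X[:, j]
        uniq = np.unique(col)
        mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.empty(0)
        thresholds = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
        # weighted error of "le" stumps for all thresholds at once:
        # err_le(thr) = sum_{col<=thr} w*[y==0] + sum_{col>thr} w*[y==1]
        order = np.argsort(col, kind="stable")
        w_pos_sorted = np.where(y[order] == 1, w[order], 0.0)
        w_neg_sorted = np.where(y[order] == 0, w[order], 0.0)
        cum_pos = np.concatenate(([0.0], np.cumsum(w_pos_sorted)))
        cum_neg = np.concatenate(([0.0], np.cumsum(w_neg_sorted)))
        # number of examples with col <= thr, per threshold
        k = np.searchsorted(col[order], thresholds, side="right")
        err_le = cum_neg[k] + (pos_mass - cum_pos[k])
        for thr, e_le in zip(thresholds, err_le):
            for pol, err in (("le", float(e_le)), ("gt", float(1.0 - e_le))):
                # cumsum rounding can leave a tiny negative residue
                cand = (min(max(err, 0.0), 1.0), j, float(thr), pol)
                if best is None or _stump_better(cand, best):
                    best = cand
    assert best is not None
    err, j, thr, pol = best
    return Stump(
        feature_index=j, threshold=thr, polarity=pol, error=err, degenerate=degenerate
    )


def _stump_better(cand: tuple, best: tuple) -> bool:
    """Strictly better error, else tie-break (feature, threshold, 'le' first)."""
    c_err, c_j, c_thr, c_pol = cand
    b_err, b_j, b_thr, b_pol = best
    if c_err != b_err:
        return c_err < b_err
    if c_j != b_j:
        return c_j < b_j
    if c_thr != b_thr:
        return c_thr < b_thr
    return c_pol == "le" and b_pol == "gt"


def update_weights(
    weights: ExampleWeights,
    stump: Stump,
    predictions: np.ndarray,
    labels: np.ndarray,
) -> tuple[ExampleWeights, float]:
    """One AdaBoost reweighting step; returns (new weights, beta_t).

    Correct examples are multiplied by beta_t = eps_t/(1-eps_t) and the
    vector is renormalized, which leaves exactly half the total weight on
    the examples the stump misclassified.
    """
    eps = stump.error
    if not 0.0 < eps < 0.5:
        raise ValueError(f"weight update requires 0 < error < 0.5, got {eps}")
    beta = eps / (1.0 - eps)
    correct = np.asarray(predictions) == np.asarray(labels)
    w = weights.weights * np.where(correct, beta, 1.0)
    w = w / w.sum()
    return ExampleWeights(w), beta


def train_adaboost(data: TrainingSet, rounds: int = 50, seed: int = 0) -> EnsembleModel:
    """Boost decision stumps for up to ``rounds`` rounds.

    Early stop on a perfect stump (eps_t = 0: round kept with
    beta_t = BETA_FLOOR) or a useless one (eps_t >= 0.5: round dropped).
    Training is deterministic given the data ordering; ``seed`` is accepted
    for interface uniformity and currently unused (no randomized step).
    """
    if rounds < 1:
        raise ValueError(f"rounds must be >= 1, got {rounds}")
    y = data.labels
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    weights = ExampleWeights.uniform(data.n)
    stumps: list[Stump] = []
    betas: list[float] = []
    history: list[tuple[float, float]] = []
    for _ in range(rounds):
        stump = fit_stump(data, weights)
        preds = stump.predict(data.features)
        weighted_acc = float(weights.weights[preds == y].sum())
        if stump.error >= 0.5:
            break
        if stump.error <= 0.0:
            stumps.append(stump)
            betas.append(BETA_FLOOR)
            history.append((stump.error, weighted_acc))
            break
        stumps.append(stump)
        history.append((stump.error, weighted_acc))
        weights, beta = update_weights(weights, stump, preds, y)
        betas.append(beta)
    return EnsembleModel(
        stumps=stumps, betas=betas, feature_names=data.feature_names, history=history
    )


def predict(
    model: EnsembleModel, features: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Strong-classifier labels and margins for a feature matrix or vector.

    The margin is  sum_t log(1/beta_t) h_t(x) - 1/2 sum_t log(1/beta_t);
    the label is 1 where the margin is >= 0.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    d = len(model.feature_names) if model.feature_names else X.shape[1]
    if X.shape[1] != d:
        raise ValueError(f"expected {d} features, got {X.shape[1]}")
    alpha = model.vote_weights()
    votes = np.zeros(X.shape[0])
    for a, stump in zip(alpha, model.stumps):
        votes += a * stump.predict(X)
    margin = votes - 0.5 * alpha.sum()
    labels = (margin >= 0).astype(int)
    if np.asarray(features).ndim == 1:
        return labels[0], margin[0]
    return labels, margin


def stratified_split(
    features: np.ndarray,
    labels: np.ndarray,
    test_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded per-class shuffle; returns (train_indices, test_indices).

    Each class contributes round(test_fraction * class size) test examples,
    so the split preserves class balance as closely as integer counts allow.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_test = int(round(test_fraction * idx.size))
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


# ---------------------------------------------------------------------------
# JSON serialization


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]


def save_model(model: EnsembleModel, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "feature_names": list(model.feature_names),
        "stumps": [
            {
                "feature_index": s.feature_index,
                "threshold": s.threshold,
                "polarity": s.polarity,
                "error": s.error,
                "degenerate": s.degenerate,
            }
            for s in model.stumps
        ],
        "betas": model.betas,
        "history": model.history,
    }
    payload["config_hash"] = _config_hash(payload)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return path


def load_model(path: str | Path) -> EnsembleModel:
    with open(path) as fh:
        payload = json.load(fh)
    return EnsembleModel(
        stumps=[Stump(**s) for s in payload["stumps"]],
        betas=list(payload["betas"]),
        feature_names=tuple(payload["feature_names"]),
        history=[tuple(h) for h in payload.get("history", [])],
    )
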