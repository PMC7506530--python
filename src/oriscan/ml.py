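"""Machine-learning refinement of genome-scan candidates.

A hierarchical classifier on top of the hyper-motif scan: candidates
(retained window pairs) are scored by sequence features and filtered by
either greedy incremental logistic regression or an L1-regularised linear
SVM, selected under 10-fold cross-validation. The selection criterion is
the length-weighted balanced accuracy — positive candidates are merged
into non-overlapping regions and TP/TN/FP/FN are measured in base pairs of
region set algebra, so a model is rewarded for covering origin bases, not
for counting windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from .core import (
    GenomicInterval,
    intersect_intervals,
    merge_intervals,
    overlap_flags,
    total_covered,
)


def balanced_accuracy(
    pred: Sequence[GenomicInterval],
    truth: Sequence[GenomicInterval],
    genome_span: Mapping[str, int] | Sequence[GenomicInterval],
) -> float:
    """Length-weighted balanced accuracy 0.5*(TP/(TP+FN) + TN/(TN+FP)).

    The four categories are base-pair lengths of prediction/truth set
    algebra inside ``genome_span`` (chromosome sizes or explicit evaluated
    intervals). A class of zero length contributes 0 to its term.
    """
    if isinstance(genome_span, Mapping):
        span = [GenomicInterval(c, 0, l) for c, l in genome_span.items() if l > 0]
    else:
        span = merge_intervals(genome_span)
    total = total_covered(span)
    pred_c = intersect_intervals(pred, span) if pred else []
    truth_c = intersect_intervals(truth, span) if truth else []
    tp = total_covered(intersect_intervals(pred_c, truth_c)) if pred_c and truth_c else 0
    fp = total_covered(pred_c) - tp
    fn = total_covered(truth_c) - tp
    tn = total - tp - fp - fn
    tpr = tp / (tp + fn) if tp + fn > 0 else 0.0
    tnr = tn / (tn + fp) if tn + fp > 0 else 0.0
    return 0.5 * (tpr + tnr)


def kfold_split(n_items: int, k: int = 10, seed: int = 0) -> np.ndarray:
    """Seeded fold labels 0..k-1; fold sizes differ by at most one."""
    if n_items < k:
        raise ValueError("need at least k items")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_items)
    folds = np.empty(n_items, dtype=int)
    for f, idx in enumerate(np.array_split(perm, k)):
        folds[idx] = f
    return folds


@dataclass
class TrainedModel:
    """A fitted candidate filter with its cross-validation record."""

    method: str                     # "greedy_lr" or "sparse_svm"
    selected_features: list[str]
    coefficients: np.ndarray        # aligned with selected_features
    intercept: float
    cv_balanced_accuracy: float
    seed: int
    cv_trajectory: list[float] = field(default_factory=list)
    scaler_mean: np.ndarray | None = None
    scaler_scale: np.ndarray | None = None
    penalty: float | None = None    # chosen C for the SVM

    def decision_values(self, features: pd.DataFrame) -> np.ndarray:
        if not self.selected_features:
            return np.full(len(features), -np.inf)
        x = features[self.selected_features].to_numpy(dtype=float)
        if self.scaler_mean is not None:
            x = (x - self.scaler_mean) / self.scaler_scale
        return x @ self.coefficients + self.intercept

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Positive-candidate flags at the 0.5-probability (0 margin) threshold."""
        return self.decision_values(features) > 0.0

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "selected_features": self.selected_features,
            "coefficients": list(map(float, self.coefficients)),
            "intercept": float(self.intercept),
            "cv_balanced_accuracy": float(self.cv_balanced_accuracy),
            "seed": int(self.seed),
            "cv_trajectory": list(map(float, self.cv_trajectory)),
            "scaler_mean": None
            if self.scaler_mean is None
            else list(map(float, self.scaler_mean)),
            "scaler_scale": None
            if self.scaler_scale is None
            else list(map(float, self.scaler_scale)),
            "penalty": self.penalty,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedModel":
        return cls(
            method=d["method"],
            selected_features=list(d["selected_features"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            cv_balanced_accuracy=float(d["cv_balanced_accuracy"]),
            seed=int(d["seed"]),
            cv_trajectory=list(d.get("cv_trajectory", [])),
            scaler_mean=None
            if d.get("scaler_mean") is None
            else np.asarray(d["scaler_mean"], dtype=float),
            scaler_scale=None
            if d.get("scaler_scale") is None
            else np.asarray(d["scaler_scale"], dtype=float),
            penalty=d.get("penalty"),
        )


def _fold_spans(
    candidates: Sequence[GenomicInterval], idx: np.ndarray
) -> list[GenomicInterval]:
    return merge_intervals([candidates[i] for i in idx])


def _cv_balanced_accuracy(
    fit_predict,
    x: np.ndarray,
    y: np.ndarray,
    candidates: Sequence[GenomicInterval],
    truth: Sequence[GenomicInterval],
    folds: np.ndarray,
) -> float:
    """Mean length-weighted BA over folds.

    Each fold is scored over the merged extent of its own candidate pair
    intervals: predicted-positive candidates are merged into regions and
    compared with the truth clipped to that extent.
    """
    bas = []
    for f in np.unique(folds):
        tr, va = folds != f, folds == f
        if len(np.unique(y[tr])) < 2:
            raise ValueError("training fold with a single class")
        flags = fit_predict(x[tr], y[tr], x[va])
        va_idx = np.flatnonzero(va)
        span = _fold_spans(candidates, va_idx)
        pred = merge_intervals([candidates[i] for i, p in zip(va_idx, flags) if p])
        bas.append(balanced_accuracy(pred, truth, span))
    return float(np.mean(bas))


def _lr_fit_predict(x_tr, y_tr, x_va) -> np.ndarray:
    model = LogisticRegression(C=np.inf, max_iter=2000, tol=1e-8)
    model.fit(x_tr, y_tr)
    return model.predict_proba(x_va)[:, 1] >= 0.5


def greedy_lr_select(
    features: pd.DataFrame,
    labels: np.ndarray,
    candidates: Sequence[GenomicInterval],
    truth: Sequence[GenomicInterval],
    k: int = 10,
    seed: int = 0,
    tol: float = 1e-3,
    folds: np.ndarray | None = None,
) -> TrainedModel:
    """Greedy incremental feature selection for logistic regression.

    Starting from the empty model (balanced accuracy 0.5), each round adds
    the feature that maximises the mean cross-validated length-weighted
    balanced accuracy; selection stops when the best improvement falls
    below ``tol``. The accepted-feature BA trajectory is non-decreasing by
    construction. The final model is refit on all data.
    """
    y = np.asarray(labels, dtype=int)
    feature_names = [c for c in features.columns if c != "label"]
    if folds is None:
        folds = kfold_split(len(y), k, seed)
    selected: list[str] = []
    trajectory: list[float] = []
    current_ba = 0.5
    remaining = list(feature_names)
    while remaining:
        scores = {}
        for f in remaining:
            cols = selected + [f]
            x = features[cols].to_numpy(dtype=float)
            scores[f] = _cv_balanced_accuracy(
                _lr_fit_predict, x, y, candidates, truth, folds
            )
        best = max(scores, key=lambda f: (scores[f], -remaining.index(f)))
        if scores[best] - current_ba < tol:
            break
        selected.append(best)
        remaining.remove(best)
        current_ba = scores[best]
        trajectory.append(current_ba)

    if selected:
        final = LogisticRegression(C=np.inf, max_iter=2000, tol=1e-8)
        final.fit(features[selected].to_numpy(dtype=float), y)
        coef, intercept = final.coef_[0], float(final.intercept_[0])
    else:
        coef, intercept = np.array([]), -np.inf
    return TrainedModel(
        method="greedy_lr",
        selected_features=selected,
        coefficients=np.asarray(coef, dtype=float),
        intercept=intercept,
        cv_balanced_accuracy=current_ba,
        seed=seed,
        cv_trajectory=trajectory,
    )


DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0)


def sparse_svm_train(
    features: pd.DataFrame,
    labels: np.ndarray,
    candidates: Sequence[GenomicInterval],
    truth: Sequence[GenomicInterval],
    k: int = 10,
    seed: int = 0,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    folds: np.ndarray | None = None,
) -> TrainedModel:
    """L1-regularised linear SVM over a penalty grid.

    Features are standardised (train-fold statistics) before fitting; the
    penalty maximising mean cross-validated length-weighted balanced
    accuracy wins (smaller C on ties). Zero-weight features of the final
    refit are reported as unselected.
    """
    y = np.asarray(labels, dtype=int)
    feature_names = [c for c in features.columns if c != "label"]
    x_all = features[feature_names].to_numpy(dtype=float)
    if folds is None:
        folds = kfold_split(len(y), k, seed)

    def make_fit_predict(c):
        def fit_predict(x_tr, y_tr, x_va):
            mu, sd = x_tr.mean(axis=0), x_tr.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            model = LinearSVC(penalty="l1", dual=False, C=c, max_iter=20_000)
            model.fit((x_tr - mu) / sd, y_tr)
            return model.decision_function((x_va - mu) / sd) > 0.0

        return fit_predict

    cv_scores = [
        _cv_balanced_accuracy(make_fit_predict(c), x_all, y, candidates, truth, folds)
        for c in c_grid
    ]
    best_i = int(np.argmax(cv_scores))  # argmax takes the first (smallest C) on ties
    best_c = float(c_grid[best_i])

    mu, sd = x_all.mean(axis=0), x_all.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    final = LinearSVC(penalty="l1", dual=False, C=best_c, max_iter=50_000)
    final.fit((x_all - mu) / sd, y)
    coef = final.coef_[0]
    nonzero = np.abs(coef) > 1e-12
    selected = [f for f, nz in zip(feature_names, nonzero) if nz]
    return TrainedModel(
        method="sparse_svm",
        selected_features=selected,
        coefficients=coef[nonzero],
        intercept=float(final.intercept_[0]),
        cv_balanced_accuracy=float(cv_scores[best_i]),
        seed=seed,
        cv_trajectory=[float(s) for s in cv_scores],
        scaler_mean=mu[nonzero],
        scaler_scale=sd[nonzero],
        penalty=best_c,
    )


def predict_genome(
    model: TrainedModel,
    features: pd.DataFrame,
    candidates: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    """Merged (book-ended) non-overlapping regions from positive candidates."""
    flags = model.predict(features)
    positives = [c for c, p in zip(candidates, flags) if p]
    return merge_intervals(positives)


@dataclass
class PredictionEvaluation:
    sensitivity_by_quantile: dict[int, float]
    sensitivity_core: float
    sensitivity_stochastic: float
    fpr_regions: float        # fraction of predicted regions hitting no origin
    fpr_bp: float             # fraction of predicted bases outside origins
    n_predictions: int


def evaluate_predictions(
    pred: Sequence[GenomicInterval],
    origins: Sequence[GenomicInterval],
    quantiles: np.ndarray | None = None,
) -> PredictionEvaluation:
    """Per-quantile origin sensitivity plus the false-positive rate.

    Sensitivity(Qk) is the fraction of Qk origins overlapping at least one
    predicted region; FPR is reported both on region counts (fraction of
    predictions hitting no origin) and base-pair weighted.
    """
    origins = list(origins)
    pred = list(pred)
    hit = overlap_flags(origins, pred) if pred else np.zeros(len(origins), bool)
    by_q: dict[int, float] = {}
    core = stoch = float("nan")
    if quantiles is not None:
        quantiles = np.asarray(quantiles)
        for q in sorted(set(quantiles.tolist())):
            by_q[int(q)] = float(hit[quantiles == q].mean())
        if (quantiles <= 2).any():
            core = float(hit[quantiles <= 2].mean())
        if (quantiles > 2).any():
            stoch = float(hit[quantiles > 2].mean())
    if pred:
        pred_hit = overlap_flags(pred, origins)
        fpr_regions = float(1.0 - pred_hit.mean())
        pred_len = sum(p.length for p in pred)
        tp_len = total_covered(intersect_intervals(pred, origins)) if origins else 0
        fpr_bp = float((pred_len - tp_len) / pred_len)
    else:
        fpr_regions = fpr_bp = float("nan")
    return PredictionEvaluation(by_q, core, stoch, fpr_regions, fpr_bp, len(pred))
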