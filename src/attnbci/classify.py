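"""Linear discriminant analysis and leave-one-subject-out evaluation.

LDA with a shared (pooled within-class) covariance and equal priors: the
Gaussian model whose decision surfaces are hyperplanes.  A small ridge
(epsilon * trace / dim on the diagonal) keeps the pooled covariance
positive definite when features are collinear or folds are small.

Evaluation is leave-one-subject-out (LOSO): feature standardization and
probe-guarded OFR selection are fit on the training subjects only, the
held-out subject is scored on the selected top-k features for every k in a
grid, and accuracies are averaged over folds.  LOSO therefore estimates
cross-subject transfer, not within-subject fit.  Because the class design
is balanced, chance level is 50% for pairwise discriminations and 33.3%
for the three-class one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .selection import SelectionConfig, encode_target, probe_select
from .synth import CONDITIONS

DISCRIMINATIONS: tuple[str, ...] = ("3class", "easy-medium", "easy-hard", "medium-hard")


def classes_of(discrimination: str) -> list[str]:
    if discrimination == "3class":
        return list(CONDITIONS)
    parts = discrimination.split("-")
    if len(parts) == 2 and all(p in CONDITIONS for p in parts):
        return parts
    raise ValueError(f"unknown discrimination {discrimination!r}")


@dataclass
class LdaModel:
    classes: list[str]
    class_means: np.ndarray      # (n_classes, n_features)
    pooled_cov: np.ndarray       # (n_features, n_features), ridge included
    priors: np.ndarray
    ridge: float
    _cov_inv: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self._cov_inv is None:
            self._cov_inv = np.linalg.inv(self.pooled_cov)


def fit_lda(X: np.ndarray, labels: np.ndarray, ridge: float = 1e-6) -> LdaModel:
    """Fit shared-covariance LDA with equal priors.

    ``ridge`` scales the diagonal load: ridge * trace(S)/dim is added to
    the pooled covariance diagonal.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] == len(np.ravel(labels)) and X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    present = [c for c in CONDITIONS if c in set(labels.tolist())]
    if not present:
        present = sorted(set(labels.tolist()))
    if len(present) < 2:
        raise ValueError("need at least 2 classes")
    n, d = X.shape
    means = np.empty((len(present), d))
    S = np.zeros((d, d))
    for k, c in enumerate(present):
        Xc = X[labels == c]
        if len(Xc) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        means[k] = Xc.mean(axis=0)
        dev = Xc - means[k]
        S += dev.T @ dev
    S /= n - len(present)
    load = ridge * np.trace(S) / d if np.trace(S) > 0 else ridge
    S = S + load * np.eye(d)
    priors = np.full(len(present), 1.0 / len(present))
    return LdaModel(present, means, S, priors, ridge)


def predict(model: LdaModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class labels and per-class discriminant scores for new observations.

    Scores are the Gaussian log-discriminants
    ``x' S^-1 mu_c - mu_c' S^-1 mu_c / 2 + log prior``; the argmax wins.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    d = model.class_means.shape[1]
    if X.shape[1] != d:
        raise ValueError(f"feature dimension {X.shape[1]} != model dimension {d}")
    W = model._cov_inv @ model.class_means.T           # (d, C)
    scores = X @ W - 0.5 * np.einsum("kd,dk->k", model.class_means, W) + np.log(model.priors)
    labels = np.asarray(model.classes, dtype=object)[np.argmax(scores, axis=1)]
    return labels.astype(str), scores


def decision_scores(model: LdaModel, X: np.ndarray) -> np.ndarray:
    """Binary decision axis: score of the second class minus the first."""
    if len(model.classes) != 2:
        raise ValueError("decision scores are defined for binary models")
    _, s = predict(model, X)
    return s[:, 1] - s[:, 0]


def best_threshold_sens_spec(
    scores: np.ndarray, labels: np.ndarray, positive: str
) -> tuple[float, float]:
    """Sensitivity/specificity at the threshold maximizing balanced accuracy.

    Sweeps all midpoints between consecutive distinct scores (plus the two
    outer extremes); observations with score >= threshold are called
    positive.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    if pos.sum() == 0 or pos.sum() == len(labels):
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    cuts = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]])
    best = (-1.0, 0.0, 0.0)
    for t in cuts:
        called = scores >= t
        sens = (called & pos).sum() / pos.sum()
        spec = (~called & ~pos).sum() / (~pos).sum()
        bal = (sens + spec) / 2.0
        if bal > best[0]:
            best = (bal, sens, spec)
    return float(best[1]), float(best[2])


@dataclass
class LosoReport:
    discrimination: str
    epoch_length_s: float
    subjects: list[str]
    k_grid: list[int]
    fold_accuracy: np.ndarray        # (n_folds, len(k_grid))
    kept_per_fold: list[list[int]]   # selected feature indices per fold (kept prefix)
    mean_accuracy_vs_k: np.ndarray
    best_k: int
    mean_accuracy: float
    sensitivity: float | None = None   # binary only, pooled held-out scores, best threshold
    specificity: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fi, subj in enumerate(self.subjects):
            for ki, k in enumerate(self.k_grid):
                rows.append(
                    {
                        "discrimination": self.discrimination,
                        "epoch_length_s": self.epoch_length_s,
                        "held_out_subject": subj,
                        "n_features": k,
                        "accuracy": self.fold_accuracy[fi, ki],
                    }
                )
        return pd.DataFrame(rows)


def loso_evaluate(
    fm: FeatureMatrix,
    discrimination: str,
    selection_cfg: SelectionConfig | None = None,
    k_grid: list[int] | None = None,
    ridge: float = 1e-6,
) -> LosoReport:
    """Leave-one-subject-out evaluation with per-fold selection.

    For each held-out subject: standardize on the training subjects, run
    probe-guarded OFR on the training subjects only, fit LDA on the top-k
    kept features for each k, and score the held-out epochs.  If a fold
    keeps no feature, the top-ranked feature is used so the classifier is
    always defined.  Every epoch is tested exactly once per k.
    """
    cls = classes_of(discrimination)
    mask = np.isin(fm.labels, cls)
    X_all = fm.values[mask]
    y_all = fm.labels[mask]
    subj_all = fm.subject_ids[mask]
    subjects = sorted(set(subj_all.tolist()))
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    _, counts = np.unique(y_all, return_counts=True)
    if counts.max() - counts.min() > 0.1 * counts.mean():
        warnings.warn("class design is unbalanced; chance level shifts", RuntimeWarning,
                      stacklevel=2)
    cfg = selection_cfg or SelectionConfig()
    k_grid = list(k_grid) if k_grid is not None else list(range(1, min(cfg.max_features, 30) + 1))

    fold_acc = np.zeros((len(subjects), len(k_grid)))
    kept_per_fold: list[list[int]] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []

    for fi, subj in enumerate(subjects):
        test = subj_all == subj
        Xtr, ytr = X_all[~test], y_all[~test]
        Xte, yte = X_all[test], y_all[test]
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (Xtr - mu) / sd
        Xte = (Xte - mu) / sd

        Y = encode_target(ytr, cls)
        ranking = probe_select(Xtr, Y, cfg)
        chosen = ranking.kept_order if ranking.n_kept > 0 else ranking.order[:1]
        if not chosen:  # pathological: nothing selected at all
            chosen = [0]
        kept_per_fold.append(list(chosen))

        best_binary_scores = None
        for ki, k in enumerate(k_grid):
            idx = chosen[: max(1, min(k, len(chosen)))]
            model = fit_lda(Xtr[:, idx], ytr, ridge=ridge)
            pred, _ = predict(model, Xte[:, idx])
            fold_acc[fi, ki] = float((pred == yte).mean())
        if len(cls) == 2:
            model = fit_lda(Xtr[:, chosen], ytr, ridge=ridge)
            pooled_scores.append(decision_scores(model, Xte[:, chosen]))
            pooled_labels.append(yte)

    mean_vs_k = fold_acc.mean(axis=0)
    best_ki = int(np.argmax(mean_vs_k))
    sens = spec = None
    if len(cls) == 2 and pooled_scores:
        s = np.concatenate(pooled_scores)
        l = np.concatenate(pooled_labels)
        sens, spec = best_threshold_sens_spec(s, l, positive=cls[1])

    return LosoReport(
        discrimination=discrimination,
        epoch_length_s=fm.epoch_length_s,
        subjects=subjects,
        k_grid=k_grid,
        fold_accuracy=fold_acc,
        kept_per_fold=kept_per_fold,
        mean_accuracy_vs_k=mean_vs_k,
        best_k=k_grid[best_ki],
        mean_accuracy=float(mean_vs_k[best_ki]),
        sensitivity=sens,
        specificity=spec,
    )


def single_feature_loso(
    fm: FeatureMatrix, discrimination: str, ridge: float = 1e-6
) -> pd.Series:
    """Mean LOSO accuracy of every single feature on its own.

    Exhaustive per-feature evaluation producing the per-channel/band
    accuracy map; returns a Series indexed by feature name.
    """
    cls = classes_of(discrimination)
    mask = np.isin(fm.labels, cls)
    X_all = fm.values[mask]
    y_all = fm.labels[mask]
    subj_all = fm.subject_ids[mask]
    subjects = sorted(set(subj_all.tolist()))
    acc = np.zeros(X_all.shape[1])
    for subj in subjects:
        test = subj_all == subj
        Xtr, ytr = X_all[~test], y_all[~test]
        Xte, yte = X_all[test], y_all[test]
        for j in range(X_all.shape[1]):
            model = fit_lda(Xtr[:, [j]], ytr, ridge=ridge)
            pred, _ = predict(model, Xte[:, [j]])
            acc[j] += (pred == yte).mean()
    acc /= len(subjects)
    return pd.Series(acc, index=fm.feature_names, name=f"loso_accuracy_{discrimination}")
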