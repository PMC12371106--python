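"""Cancer detection from the neomer density matrix.

Two detectors are provided:

* a feature-hashed regularized linear model: the sparse neomer columns
  are hashed into ``m`` buckets (default 8192) and a
  classifier — logistic regression with L2 penalty by default — is
  evaluated with nested cross-validation (10-fold inner grid search
  maximizing balanced accuracy inside a 10-fold outer loop);
* a simple neomer-count threshold: t = max(training control counts) - 1,
  with a validation sample called cancer when its count is >= t.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    balanced_accuracy_score,
    confusion_matrix,
    f1_score,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .scanner import NeomerDensityMatrix

DEFAULT_HASH_DIM = 8192
_C_GRID = np.logspace(-3, 3, 7)


# ---------------------------------------------------------------------------
# feature hashing


def _hash64(text: str, seed: int) -> int:
    key = int(seed).to_bytes(8, "little", signed=False)
    digest = hashlib.blake2b(text.encode("ascii"), digest_size=8, key=key).digest()
    return int.from_bytes(digest, "little")


@dataclass
class HashedFeatureMatrix:
    """Samples x m bucket matrix from feature hashing."""

    X: np.ndarray
    m: int
    seed: int
    signed: bool
    sample_ids: List[str] = field(default_factory=list)


def hash_features(
    ndm: NeomerDensityMatrix,
    m: int = DEFAULT_HASH_DIM,
    seed: int = 0,
    signed: bool = False,
) -> HashedFeatureMatrix:
    """Hash neomer density columns into ``m`` buckets.

    bucket(neomer) = h(sequence) mod m with a keyed 64-bit hash.
    Unsigned hashing (the default) sums densities per bucket, preserving
    the aggregate neomer-abundance signal that dominates sparse cfDNA
    profiles; ``signed`` adds a +/-1 hash-bit sign, the classic
    collision-bias correction, at the cost of cancelling that aggregate
    signal.  The mapping
    depends only on the neomer sequence and the seed, never on the
    sample, so it is identical across samples and runs.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    dens = ndm.densities
    X = np.zeros((len(dens), m))
    for col in dens.columns:
        h = _hash64(col, seed)
        bucket = h % m
        sign = (1.0 if (h >> 40) & 1 else -1.0) if signed else 1.0
        X[:, bucket] += sign * dens[col].to_numpy()
    return HashedFeatureMatrix(
        X=X, m=m, seed=seed, signed=signed, sample_ids=list(dens.index)
    )


# ---------------------------------------------------------------------------
# nested cross-validation

MODEL_GRIDS: Dict[str, Tuple[object, Dict[str, list]]] = {}


def _build_model(name: str, seed: int):
    if name == "lr_l2":
        return (
            LogisticRegression(  # default penalty is the L2 ridge
                max_iter=5000, class_weight="balanced", random_state=seed,
            ),
            {"C": list(_C_GRID)},
        )
    if name == "lr_l1":
        return (
            LogisticRegression(
                solver="liblinear", l1_ratio=1, max_iter=5000,
                class_weight="balanced", random_state=seed,
            ),
            {"C": list(_C_GRID)},
        )
    if name == "linear_svm":
        return (
            SVC(kernel="linear", class_weight="balanced", random_state=seed),
            {"C": list(_C_GRID)},
        )
    if name == "rbf_svm":
        return (
            SVC(kernel="rbf", class_weight="balanced", random_state=seed),
            {"C": list(_C_GRID), "gamma": ["scale", 0.01, 0.1]},
        )
    if name == "random_forest":
        return (
            RandomForestClassifier(class_weight="balanced", random_state=seed),
            {"n_estimators": [100, 300], "max_depth": [None, 5]},
        )
    raise ValueError(f"unknown model {name!r}")


def _scores(clf, X: np.ndarray) -> np.ndarray:
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(X)[:, 1]
    return clf.decision_function(X)


@dataclass
class DetectionReport:
    """Outer-CV detection metrics, pooled and per fold."""

    auc: float
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    confusion: np.ndarray
    fold_auc: List[float]
    fold_balanced_accuracy: List[float]
    y_true: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    y_score: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    y_pred: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    stage_metrics: Dict[str, dict] = field(default_factory=dict)
    sensitivity_at_specificity: Dict[str, float] = field(default_factory=dict)

    def roc_points(self) -> pd.DataFrame:
        fpr, tpr, thr = roc_curve(self.y_true, self.y_score)
        return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def _sens_at_spec(y_true: np.ndarray, y_score: np.ndarray, spec: float) -> float:
    fpr, tpr, _ = roc_curve(y_true, y_score)
    ok = fpr <= 1 - spec
    return float(tpr[ok].max()) if ok.any() else 0.0


def nested_cv_detect(
    X: HashedFeatureMatrix | np.ndarray,
    labels: Sequence[int],
    model: str = "lr_l2",
    outer: int = 10,
    inner: int = 10,
    seed: int = 0,
    stages: Optional[Sequence[str]] = None,
) -> DetectionReport:
    """Nested CV evaluation of a case/control classifier.

    Hyperparameters are grid-searched per outer fold on the inner folds,
    maximizing balanced accuracy; the outer folds pool held-out decision
    scores into a single ROC/AUC.  ``stages`` (per-sample labels, e.g.
    tumor stage, empty for controls) adds stage-stratified metrics over
    the pooled validation predictions.
    """
    Xm = X.X if isinstance(X, HashedFeatureMatrix) else np.asarray(X)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if outer < 2 or inner < 2:
        raise ValueError("outer and inner fold counts must be >= 2")
    est, grid = _build_model(model, seed)
    outer_cv = StratifiedKFold(n_splits=outer, shuffle=True, random_state=seed)
    inner_cv = StratifiedKFold(n_splits=inner, shuffle=True, random_state=seed + 1)

    y_score = np.zeros(len(y))
    y_pred = np.zeros(len(y), dtype=int)
    fold_auc, fold_bacc = [], []
    for train_idx, test_idx in outer_cv.split(Xm, y):
        search = GridSearchCV(
            est, grid, scoring="balanced_accuracy", cv=inner_cv, n_jobs=1
        )
        search.fit(Xm[train_idx], y[train_idx])
        best = search.best_estimator_
        scores = _scores(best, Xm[test_idx])
        preds = best.predict(Xm[test_idx])
        y_score[test_idx] = scores
        y_pred[test_idx] = preds
        if len(np.unique(y[test_idx])) == 2:
            fold_auc.append(float(roc_auc_score(y[test_idx], scores)))
        fold_bacc.append(float(balanced_accuracy_score(y[test_idx], preds)))

    conf = confusion_matrix(y, y_pred, labels=[0, 1])
    tn, fp, fn, tp = conf.ravel()
    report = DetectionReport(
        auc=float(roc_auc_score(y, y_score)),
        balanced_accuracy=float(balanced_accuracy_score(y, y_pred)),
        sensitivity=tp / max(tp + fn, 1),
        specificity=tn / max(tn + fp, 1),
        confusion=conf,
        fold_auc=fold_auc,
        fold_balanced_accuracy=fold_bacc,
        y_true=y,
        y_score=y_score,
        y_pred=y_pred,
        sensitivity_at_specificity={
            "0.85": _sens_at_spec(y, y_score, 0.85),
            "0.95": _sens_at_spec(y, y_score, 0.95),
        },
    )
    if stages is not None:
        stages = np.asarray(
            [
                "" if s is None or (isinstance(s, float) and np.isnan(s))
                else str(s)
                for s in stages
            ],
            dtype=object,
        )
        for stage in sorted({s for s in stages if s}):
            mask = (stages == stage) | (y == 0)
            if len(np.unique(y[mask])) < 2:
                continue
            report.stage_metrics[str(stage)] = {
                "auc": float(roc_auc_score(y[mask], y_score[mask])),
                "balanced_accuracy": float(
                    balanced_accuracy_score(y[mask], y_pred[mask])
                ),
                "n_cases": int((y[mask] == 1).sum()),
            }
    return report


# ---------------------------------------------------------------------------
# threshold detector


def threshold_detect(
    train_controls: Sequence[float],
    train_cases: Sequence[float],
    validation: Sequence[float],
    strict: bool = False,
) -> Tuple[float, np.ndarray]:
    """Count-threshold cancer calls.

    t = max(training control neomer counts) - 1; a validation sample is
    designated cancer when its count is >= t (or > t with ``strict`` —
    the printed rule admits the maximal training control, which is kept
    verbatim by default).  ``train_cases`` is accepted for interface
    symmetry; the rule uses controls only.
    """
    if not len(train_controls):
        raise ValueError("training controls must be nonempty")
    t = float(max(train_controls)) - 1.0
    if t < 0:
        warnings.warn("all training controls are zero; every sample flags cancer")
    v = np.asarray(validation, dtype=float)
    calls = (v > t) if strict else (v >= t)
    return t, calls.astype(int)


def repeated_threshold_f1(
    control_counts: Sequence[float],
    case_counts: Sequence[float],
    n_splits: int = 100,
    train_fraction: float = 0.5,
    seed: int = 0,
) -> dict:
    """Repeated random-split evaluation of the threshold detector.

    Before each split the larger class is randomly downsampled so the two
    groups are of equal size; half of each (by default) trains the
    threshold and the rest is validation.  Returns mean and SD of the F1
    score over ``n_splits`` repeats.
    """
    controls = np.asarray(control_counts, dtype=float)
    cases = np.asarray(case_counts, dtype=float)
    if not len(controls) or not len(cases):
        raise ValueError("both groups must be nonempty")
    rng = np.random.default_rng(seed)
    f1s = []
    for _ in range(n_splits):
        n = min(len(controls), len(cases))
        ctl = rng.permutation(controls)[:n]
        cas = rng.permutation(cases)[:n]
        n_train = max(1, int(round(train_fraction * n)))
        if n_train >= n:
            n_train = n - 1
        t, _calls = threshold_detect(ctl[:n_train], cas[:n_train], [])
        val_counts = np.concatenate([ctl[n_train:], cas[n_train:]])
        val_truth = np.concatenate(
            [np.zeros(n - n_train, dtype=int), np.ones(n - n_train, dtype=int)]
        )
        calls = (val_counts >= t).astype(int)
        f1s.append(f1_score(val_truth, calls, zero_division=0))
    return {
        "f1_mean": float(np.mean(f1s)),
        "f1_sd": float(np.std(f1s)),
        "n_splits": n_splits,
    }


def cross_cancer_specificity(
    counts_matched: Sequence[float],
    counts_mismatched: Sequence[float],
    labels: Sequence[int],
) -> dict:
    """Compare detection with the matched vs a mismatched neomer list.

    ``counts_matched``/``counts_mismatched`` are per-sample neomer counts
    of the same samples scanned against the cancer-type-matched list and
    against another type's list; AUC of counts against case/control
    labels quantifies each list's detection power.
    """
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    a = np.asarray(counts_matched, dtype=float)
    b = np.asarray(counts_mismatched, dtype=float)
    if not len(a) or not len(b):
        raise ValueError("empty count vector")
    return {
        "auc_matched": float(roc_auc_score(y, a)),
        "auc_mismatched": float(roc_auc_score(y, b)),
    }
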