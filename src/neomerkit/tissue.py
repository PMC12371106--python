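"""Tumor tissue-of-origin classification from neomer profile vectors.

Each patient is summarized as a vector of per-cancer-type neomer
intersection counts (dimension = number of cancer types).  A linear-kernel
SVM is trained on these profiles.  Cross-validation recomputes the neomer
catalog inside every fold from the training patients only, so a neomer
that is recurrent only because of a held-out patient can never enter that
fold's catalog.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Set

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

from .catalog import DEFAULT_TARGET, NeomerCatalog, build_catalog, patient_profile


def train_svm(X: np.ndarray, y: np.ndarray, seed: int = 0) -> SVC:
    """Fit a linear-kernel SVM with default regularization on profiles."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes to train")
    clf = SVC(kernel="linear", random_state=seed)
    clf.fit(np.asarray(X, dtype=float), y)
    return clf


@dataclass
class TissueReport:
    """Cross-validated tissue-of-origin metrics."""

    accuracy: float
    per_class_accuracy: float
    macro_f1: float
    per_class_f1: Dict[str, float]
    confusion: pd.DataFrame
    y_true: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    y_pred: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    # populated when keep_fold_details is requested: per fold, the
    # training patients and the catalog derived from them alone
    fold_details: list = field(default_factory=list, repr=False)


def _profiles(
    patient_sets: Mapping[str, Set[str]],
    patients: Iterable[str],
    catalog: NeomerCatalog,
) -> np.ndarray:
    return np.vstack(
        [patient_profile(patient_sets[p], catalog) for p in patients]
    )


def cross_validate_tissue(
    patient_sets: Mapping[str, Set[str]],
    labels: Mapping[str, str],
    folds: int = 10,
    seed: int = 0,
    target: int = DEFAULT_TARGET,
    fixed_r: Optional[int] = None,
    keep_fold_details: bool = False,
) -> TissueReport:
    """Stratified k-fold CV of the tissue-of-origin SVM.

    ``patient_sets`` maps patient -> set of (canonical) resurfaced
    nullomers; ``labels`` maps patient -> cancer type.  In every fold the
    per-type catalogs (recurrence filter and threshold choice) are rebuilt
    from the training patients only, and held-out profiles are computed
    against those training-derived catalogs.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    patients = np.array(sorted(patient_sets))
    y = np.array([labels[p] for p in patients])
    class_counts = pd.Series(y).value_counts()
    if folds > class_counts.min():
        # leave-one-out and tiny classes cannot be stratified exactly
        warnings.warn(
            "some classes have fewer members than folds; "
            "falling back to unstratified folds"
        )
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    else:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    details = []
    for train_idx, test_idx in splitter.split(patients, y):
        train_patients = patients[train_idx]
        by_type: Dict[str, Dict[str, Set[str]]] = {}
        for p in train_patients:
            by_type.setdefault(labels[p], {})[p] = patient_sets[p]
        catalog = build_catalog(by_type, target=target, fixed_r=fixed_r)
        X_train = _profiles(patient_sets, train_patients, catalog)
        X_test = _profiles(patient_sets, patients[test_idx], catalog)
        clf = train_svm(X_train, y[train_idx], seed=seed)
        y_pred[test_idx] = clf.predict(X_test)
        if keep_fold_details:
            details.append(
                {
                    "train_patients": list(train_patients),
                    "held_out_patients": list(patients[test_idx]),
                    "catalog": catalog,
                }
            )

    types = sorted(set(y))
    conf = pd.DataFrame(
        confusion_matrix(y, y_pred, labels=types), index=types, columns=types
    )
    f1s = f1_score(y, y_pred, labels=types, average=None, zero_division=0)
    recalls = np.diag(conf.values) / np.maximum(conf.values.sum(axis=1), 1)
    return TissueReport(
        accuracy=float(accuracy_score(y, y_pred)),
        per_class_accuracy=float(np.mean(recalls)),
        macro_f1=float(f1_score(y, y_pred, average="macro", zero_division=0)),
        per_class_f1=dict(zip(types, map(float, f1s))),
        confusion=conf,
        y_true=y,
        y_pred=y_pred,
        fold_details=details,
    )
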