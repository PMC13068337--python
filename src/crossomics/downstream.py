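"""Binary IBD-vs-healthy classification on input, predicted and
ground-truth feature tables.

UC and CD collapse to a single IBD label.  Fairness protocol: for one
input→output combination, every data source is restricted to the same
sample set (the smallest across sources), and each training set is
further subsampled to exactly equal IBD/HC counts; subsampling is
deterministic under the split seed.  Classifiers are random forests
tuned by randomized search over patient-level stratified inner folds,
scored by balanced accuracy; a stratified-sampling dummy classifier
provides the chance baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    balanced_accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import RandomizedSearchCV

from . import evaluation, partition
from .containers import SampleMetadata, ValidationError

IBD_LABEL = "IBD"
HC_LABEL = "HC"

#: declared default randomized-search grid (artifact defaults)
DEFAULT_SEARCH_GRID = {
    "n_estimators": [100, 200, 300, 400, 500, 600, 700, 800, 900, 1000],
    "max_depth": [None, 4, 8, 16, 32],
    "min_samples_leaf": [1, 2, 4, 8],
    "max_features": ["sqrt", "log2", 0.3],
}


def binary_labels(metadata: SampleMetadata) -> pd.Series:
    """Collapse UC/CD to IBD, keep HC; indexed by sample id."""
    diag = metadata.table["diagnosis"]
    return diag.map(lambda d: HC_LABEL if d == HC_LABEL else IBD_LABEL)


@dataclass
class ClassificationRun:
    """One classifier evaluation on one split for one data source."""

    source: str  # input | predicted | ground_truth | dummy
    split_seed: int
    n_train: dict[str, int]
    n_test: dict[str, int]
    metrics: dict[str, float]

    def __post_init__(self) -> None:
        for name, v in self.metrics.items():
            if v is not None and not np.isnan(v) and not (0.0 <= v <= 1.0):
                raise ValidationError(f"metric {name}={v} outside [0, 1]")


def downsample_for_fairness(
    sources: dict[str, pd.DataFrame],
    metadata: SampleMetadata,
    train_samples: list[str],
    test_samples: list[str],
    seed: int,
) -> dict:
    """Size- and class-match the training sets across data sources.

    All sources are restricted to their common samples within the split
    (train and test), then the training set is subsampled so IBD and HC
    counts are exactly equal.  The same sample ids are used for every
    source, so training sets are identical in size and composition
    across sources.  Deterministic under ``seed``.
    """
    common = None
    for df in sources.values():
        ids = set(df.index)
        common = ids if common is None else (common & ids)
    train = [s for s in train_samples if s in common]
    test = [s for s in test_samples if s in common]
    labels = binary_labels(metadata)
    by_class = {
        IBD_LABEL: [s for s in train if labels[s] == IBD_LABEL],
        HC_LABEL: [s for s in train if labels[s] == HC_LABEL],
    }
    n_min = min(len(v) for v in by_class.values())
    if n_min == 0:
        raise ValidationError(
            "a class was emptied by downsampling: "
            + str({k: len(v) for k, v in by_class.items()})
        )
    rng = np.random.default_rng(seed)
    balanced = []
    for label in (IBD_LABEL, HC_LABEL):
        pool = by_class[label]
        chosen = rng.choice(len(pool), size=n_min, replace=False)
        balanced.extend(pool[i] for i in sorted(chosen))
    return {
        "train_samples": balanced,
        "test_samples": test,
        "train_labels": labels[balanced],
        "test_labels": labels[test],
    }


def train_classifier(
    x: pd.DataFrame,
    y: pd.Series,
    metadata: SampleMetadata,
    seed: int,
    n_iter: int = 50,
    k_folds: int = 5,
    search_grid: dict | None = None,
) -> RandomizedSearchCV:
    """Random forest tuned by randomized search on balanced accuracy.

    Inner folds are patient-level and class-stratified; the search is
    refit on the full (balanced) training set.  Deterministic given
    ``seed``.
    """
    if y.nunique() < 2:
        raise ValidationError("single-class training data")
    sub_meta = metadata.select_samples(list(x.index))
    patient_labels = {
        p: (HC_LABEL if d == HC_LABEL else IBD_LABEL)
        for p, d in sub_meta.patient_diagnosis().items()
    }
    folds = partition.inner_cv_folds(
        sub_meta, sub_meta.patient_ids, k=k_folds, seed=seed,
        labels=patient_labels,
    )
    cv = partition.fold_sample_indices(sub_meta, list(x.index), folds)
    search = RandomizedSearchCV(
        RandomForestClassifier(random_state=seed, n_jobs=1),
        param_distributions=search_grid or DEFAULT_SEARCH_GRID,
        n_iter=n_iter,
        scoring="balanced_accuracy",
        cv=cv,
        random_state=seed,
        refit=True,
        n_jobs=1,
    )
    search.fit(x.to_numpy(), y.to_numpy())
    return search


def evaluate_classifier(model, x_test: pd.DataFrame, y_test: pd.Series,
                        source: str = "", split_seed: int = 0,
                        n_train: dict | None = None) -> ClassificationRun:
    """Balanced accuracy, ROC-AUC and IBD-class precision/recall/F1."""
    y_true = y_test.to_numpy()
    y_pred = model.predict(x_test.to_numpy())
    metrics = {
        "balanced_accuracy": float(balanced_accuracy_score(y_true, y_pred)),
        "precision": float(precision_score(
            y_true, y_pred, pos_label=IBD_LABEL, zero_division=0)),
        "recall": float(recall_score(
            y_true, y_pred, pos_label=IBD_LABEL, zero_division=0)),
        "f1": float(f1_score(
            y_true, y_pred, pos_label=IBD_LABEL, zero_division=0)),
    }
    if len(np.unique(y_true)) < 2:
        metrics["roc_auc"] = float("nan")  # undefined on single-class test
    else:
        proba = model.predict_proba(x_test.to_numpy())
        classes = list(model.classes_)
        metrics["roc_auc"] = float(
            roc_auc_score(y_true == IBD_LABEL,
                          proba[:, classes.index(IBD_LABEL)])
        )
    counts = y_test.value_counts().to_dict()
    return ClassificationRun(
        source=source, split_seed=split_seed,
        n_train=n_train or {}, n_test={str(k): int(v) for k, v in counts.items()},
        metrics=metrics,
    )


def dummy_baseline(y_train: pd.Series, x_test: pd.DataFrame,
                   y_test: pd.Series, seed: int,
                   split_seed: int = 0) -> ClassificationRun:
    """Stratified-sampling dummy classifier (chance baseline)."""
    dummy = DummyClassifier(strategy="stratified", random_state=seed)
    dummy.fit(np.zeros((len(y_train), 1)), y_train.to_numpy())

    class _Wrapped:
        classes_ = dummy.classes_

        def predict(self, x):
            return dummy.predict(np.zeros((len(x), 1)))

        def predict_proba(self, x):
            return dummy.predict_proba(np.zeros((len(x), 1)))

    return evaluate_classifier(
        _Wrapped(), x_test, y_test, source="dummy", split_seed=split_seed,
        n_train=y_train.value_counts().to_dict(),
    )


def compare_classifiers(runs: dict[str, list[ClassificationRun]]) -> pd.DataFrame:
    """Pairwise two-sided Mann–Whitney U on balanced accuracies.

    ``runs`` maps each data source to its per-split runs; all sources
    must cover the same split seeds.
    """
    seeds = None
    accs = {}
    for source, source_runs in runs.items():
        s = sorted(r.split_seed for r in source_runs)
        if seeds is None:
            seeds = s
        elif s != seeds:
            raise ValidationError(
                f"source {source!r} covers splits {s}, expected {seeds}"
            )
        accs[source] = [r.metrics["balanced_accuracy"]
                        for r in sorted(source_runs,
                                        key=lambda r: r.split_seed)]
    rows = []
    names = list(accs)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            test = evaluation.mann_whitney(accs[a], accs[b])
            rows.append({"source_a": a, "source_b": b,
                         "U": test["U"], "p_value": test["p_value"],
                         "method": test["method"]})
    return pd.DataFrame(rows)
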