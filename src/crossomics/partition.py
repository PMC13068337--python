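"""Patient-level, diagnosis-stratified train/test splitting.

Longitudinal cohorts contain several samples per patient; splitting at
the sample level would place a patient's samples on both sides of a
split and inflate held-out performance.  Splits here operate on
patients: within each diagnosis class, patients are shuffled by a fixed
seed and divided 80/20 (test-side count rounded up so no class has an
empty test set).  Sample lists are derived from patient membership.
Ten seeded splits are the default evaluation protocol.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import SampleMetadata, ValidationError


@dataclass
class SplitPlan:
    """One patient-level train/test split with its derived sample lists."""

    seed: int
    train_patients: list[str]
    test_patients: list[str]
    train_samples: list[str]
    test_samples: list[str]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "train_patients": self.train_patients,
            "test_patients": self.test_patients,
            "train_samples": self.train_samples,
            "test_samples": self.test_samples,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "SplitPlan":
        return cls(**json.loads(Path(path).read_text()))


def _patients_by_class(metadata: SampleMetadata) -> dict[str, list[str]]:
    diag = metadata.patient_diagnosis()
    by_class: dict[str, list[str]] = {}
    for patient in metadata.patient_ids:  # stable first-appearance order
        by_class.setdefault(diag[patient], []).append(patient)
    return by_class


def make_splits(
    metadata: SampleMetadata,
    n_splits: int = 10,
    test_fraction: float = 0.2,
    seeds: list[int] | None = None,
) -> list[SplitPlan]:
    """Generate seeded, class-stratified, patient-level 80/20 splits."""
    if seeds is None:
        seeds = list(range(n_splits))
    if len(seeds) != n_splits:
        raise ValidationError(f"{len(seeds)} seeds for {n_splits} splits")
    by_class = _patients_by_class(metadata)
    for label, patients in by_class.items():
        if len(patients) < 2:
            raise ValidationError(
                f"class {label!r} has {len(patients)} patient(s); "
                "cannot stratify"
            )
    plans = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        train, test = [], []
        for label in sorted(by_class):
            patients = list(by_class[label])
            rng.shuffle(patients)
            n_test = math.ceil(test_fraction * len(patients))
            test.extend(patients[:n_test])
            train.extend(patients[n_test:])
        plans.append(
            SplitPlan(
                seed=seed,
                train_patients=sorted(train),
                test_patients=sorted(test),
                train_samples=metadata.samples_of(train),
                test_samples=metadata.samples_of(test),
            )
        )
    return plans


def inner_cv_folds(
    metadata: SampleMetadata,
    train_patients: list[str],
    k: int = 5,
    seed: int = 0,
    labels: dict[str, str] | None = None,
) -> list[list[str]]:
    """Partition training patients into k class-stratified folds.

    ``labels`` optionally overrides the metadata diagnosis (e.g. the
    binary IBD/HC collapse used by the downstream classifiers).  Folds
    are dealt round-robin within each class after a seeded shuffle, so
    per-fold class proportions are within one patient of the target.
    """
    diag = labels or metadata.patient_diagnosis()
    by_class: dict[str, list[str]] = {}
    for p in train_patients:
        by_class.setdefault(diag[p], []).append(p)
    for label, patients in by_class.items():
        if len(patients) < k:
            raise ValidationError(
                f"class {label!r} has {len(patients)} training patients "
                f"(< {k} folds)"
            )
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    for label in sorted(by_class):
        patients = list(by_class[label])
        rng.shuffle(patients)
        for i, p in enumerate(patients):
            folds[i % k].append(p)
    return [sorted(f) for f in folds]


def fold_sample_indices(
    metadata: SampleMetadata,
    sample_ids: list[str],
    folds: list[list[str]],
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Translate patient folds into (train_idx, val_idx) pairs over
    ``sample_ids`` for use as a scikit-learn ``cv`` iterable."""
    patient_of = metadata.table["patient_id"].to_dict()
    out = []
    for fold in folds:
        fold_set = set(fold)
        val = np.array(
            [i for i, s in enumerate(sample_ids) if patient_of[s] in fold_set],
            dtype=int,
        )
        train = np.array(
            [i for i in range(len(sample_ids)) if i not in set(val.tolist())],
            dtype=int,
        )
        out.append((train, val))
    return out
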