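"""Core in-memory containers for paired microbiome multi-omics data.

An :class:`AbundanceTable` is a samples × features matrix of nonnegative
abundances (relative or count scale) tagged with its omics modality
(mGx = metagenomics, mTx = metatranscriptomics, mPx = metaproteomics,
mBx = metabolomics).  :class:`SampleMetadata` carries the patient id,
diagnosis (UC / CD / HC) and visit index of each sample; diagnosis is a
patient-level attribute, so conflicting per-sample diagnoses are rejected
at construction.  :class:`PairedDataset` aligns one input table (possibly
a multi-omics concatenation) with one output table over a common sample
set for a single input→output prediction task.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MODALITIES = ("mGx", "mTx", "mPx", "mBx", "concat")
DIAGNOSES = ("UC", "CD", "HC")
SCALES = ("relative", "count")

#: closure tolerance for normalized relative-abundance rows
CLOSURE_ATOL = 1e-9


class ValidationError(ValueError):
    """Raised when a container or table violates its invariants."""


@dataclass
class AbundanceTable:
    """Samples × features abundance matrix with modality and scale tags.

    Parameters
    ----------
    data:
        DataFrame with sample ids as index and feature ids as columns.
        All values must be finite and nonnegative.
    modality:
        One of ``mGx, mTx, mPx, mBx, concat``.
    scale:
        ``"relative"`` (fractions) or ``"count"`` (raw counts).
    normalized:
        If True (only meaningful for relative scale) every row must sum
        to 1 within ``CLOSURE_ATOL``.
    """

    data: pd.DataFrame
    modality: str
    scale: str = "relative"
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise ValidationError("non-finite abundance values")
        if values.size and (values < 0).any():
            rows, cols_ = np.nonzero(values < 0)
            raise ValidationError(
                f"negative abundance at sample {idx[rows[0]]!r}, "
                f"feature {self.data.columns[cols_[0]]!r}"
            )
        if self.normalized:
            if self.scale != "relative":
                raise ValidationError("only relative tables can be normalized")
            sums = values.sum(axis=1)
            bad = np.abs(sums - 1.0) > CLOSURE_ATOL
            if bad.any():
                raise ValidationError(
                    f"rows not summing to 1: {idx[bad].tolist()[:5]}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        # fixed memory layout so reductions are bit-reproducible
        # regardless of the frame's internal block history
        return np.ascontiguousarray(self.data.to_numpy(dtype=float))

    def select_samples(self, sample_ids) -> "AbundanceTable":
        """Row-subset (and reorder) by sample id, preserving feature order."""
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing[:5]}")
        return AbundanceTable(
            self.data.loc[list(sample_ids)],
            modality=self.modality,
            scale=self.scale,
            normalized=self.normalized,
        )

    def with_data(self, data: pd.DataFrame, **overrides) -> "AbundanceTable":
        kwargs = dict(modality=self.modality, scale=self.scale,
                      normalized=self.normalized)
        kwargs.update(overrides)
        return AbundanceTable(data, **kwargs)


@dataclass
class SampleMetadata:
    """Per-sample patient id, diagnosis and visit index.

    Diagnosis is treated as a patient-level label: if two samples of the
    same patient disagree the table is rejected.
    """

    table: pd.DataFrame  # index: sample_id; columns: patient_id, diagnosis, visit

    REQUIRED = ("patient_id", "diagnosis", "visit")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique()
            raise ValidationError(f"duplicate sample ids: {list(dups)}")
        bad = set(self.table["diagnosis"]) - set(DIAGNOSES)
        if bad:
            raise ValidationError(f"unknown diagnosis labels: {sorted(bad)}")
        per_patient = self.table.groupby("patient_id")["diagnosis"].nunique()
        conflicted = per_patient[per_patient > 1]
        if len(conflicted):
            raise ValidationError(
                f"patients with conflicting diagnoses: {list(conflicted.index)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def patient_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["patient_id"]))

    def patient_diagnosis(self) -> dict[str, str]:
        """Mapping patient id → diagnosis."""
        return dict(
            self.table.groupby("patient_id", sort=False)["diagnosis"].first()
        )

    def samples_of(self, patients) -> list[str]:
        patients = set(patients)
        mask = self.table["patient_id"].isin(patients)
        return list(self.table.index[mask])

    def select_samples(self, sample_ids) -> "SampleMetadata":
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing[:5]}")
        return SampleMetadata(self.table.loc[list(sample_ids)])


@dataclass
class PairedDataset:
    """Sample-aligned (input, output) table pair for one prediction task."""

    input: AbundanceTable
    output: AbundanceTable
    metadata: SampleMetadata
    combo_label: str = ""

    def __post_init__(self) -> None:
        if self.input.sample_ids != self.output.sample_ids:
            raise ValidationError(
                "input and output sample ids differ or are misordered"
            )
        if self.metadata.sample_ids != self.input.sample_ids:
            raise ValidationError("metadata sample ids differ from tables")

    @property
    def sample_ids(self) -> list[str]:
        return self.input.sample_ids

    def select_samples(self, sample_ids) -> "PairedDataset":
        return PairedDataset(
            self.input.select_samples(sample_ids),
            self.output.select_samples(sample_ids),
            self.metadata.select_samples(sample_ids),
            combo_label=self.combo_label,
        )
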