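"""Reading, writing and preprocessing of abundance tables.

Covers total-sum scaling, zero imputation (additive epsilon for relative
tables, pseudocount for count tables), prevalence/abundance feature
filtering in a strict and a lenient variant, de-stratification of
taxon-stratified EC features, and assembly of paired input→output
datasets (with multi-omics concatenation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    AbundanceTable,
    PairedDataset,
    SampleMetadata,
    ValidationError,
)

#: additive imputation constant for relative-abundance tables
RELATIVE_EPSILON = 1e-7
#: additive pseudocount for count tables
COUNT_PSEUDOCOUNT = 1.0


@dataclass
class FilterSpec:
    """Feature-filtering thresholds.

    ``lenient`` keeps a feature iff it reaches ``min_abundance`` (0.005%)
    in strictly more than ``prevalence`` (10%) of samples and has at most
    ``max_zero_fraction`` (95%) zeros.  ``strict`` raises the abundance
    threshold to 0.01% and additionally drops features that fall below
    ``strict_low_abundance_cut`` (0.0001%) in strictly more than 10% of
    samples (exact zeros count as below the cut).
    """

    mode: str = "lenient"  # "strict" | "lenient"
    min_abundance: float | None = None
    prevalence: float = 0.10
    max_zero_fraction: float = 0.95
    strict_low_abundance_cut: float = 1e-6

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "lenient"):
            raise ValidationError(f"unknown filter mode {self.mode!r}")
        if self.min_abundance is None:
            self.min_abundance = 1e-4 if self.mode == "strict" else 5e-5
        for name in ("min_abundance", "prevalence", "max_zero_fraction",
                     "strict_low_abundance_cut"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name}={v} outside (0, 1)")


def read_table(path, modality: str, scale: str = "relative",
               transposed: bool = False) -> AbundanceTable:
    """Read a TSV abundance table (rows = samples, columns = features).

    ``transposed=True`` declares that the file stores features as rows;
    orientation is never guessed.
    """
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    if transposed:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    non_numeric = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]
    ]
    if len(non_numeric):
        raise ValidationError(
            f"non-numeric values in columns: {list(non_numeric)[:5]}"
        )
    return AbundanceTable(df.astype(float), modality=modality, scale=scale)


def write_table(table: AbundanceTable, path) -> None:
    """Write a TSV abundance table; numeric content round-trips exactly
    at float 17-significant-digit precision."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.data.to_csv(path, sep="\t", float_format="%.17g")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    metadata.table.to_csv(path, sep="\t")


def tss_normalize(table: AbundanceTable) -> AbundanceTable:
    """Total-sum scaling: divide each sample row by its sum (closure)."""
    values = table.values()
    sums = values.sum(axis=1)
    zero_rows = np.nonzero(sums == 0)[0]
    if len(zero_rows):
        raise ValidationError(
            f"all-zero sample rows: {[table.sample_ids[i] for i in zero_rows[:5]]}"
        )
    out = pd.DataFrame(values / sums[:, None], index=table.data.index,
                       columns=table.data.columns)
    return table.with_data(out, scale="relative", normalized=True)


def impute_zeros(table: AbundanceTable, renormalize: bool = True) -> AbundanceTable:
    """Make every entry strictly positive.

    Relative tables get ``RELATIVE_EPSILON`` added to every entry; count
    tables get ``COUNT_PSEUDOCOUNT``.  Relative tables are re-closed to
    sum 1 afterwards when ``renormalize`` (the default), so the CLR
    transform downstream operates on a composition.
    """
    shift = RELATIVE_EPSILON if table.scale == "relative" else COUNT_PSEUDOCOUNT
    values = table.values() + shift
    out = pd.DataFrame(values, index=table.data.index, columns=table.data.columns)
    result = table.with_data(out, normalized=False)
    if table.scale == "relative" and renormalize:
        result = tss_normalize(result)
    return result


def filter_features(
    table: AbundanceTable, spec: FilterSpec
) -> tuple[AbundanceTable, dict[str, str]]:
    """Drop low-abundance / low-prevalence / over-sparse features.

    Returns the filtered table and a report mapping each dropped feature
    id to the reason it failed.  All "more than 10%" comparisons are
    strict inequalities; ties at exactly the prevalence threshold fail.
    """
    if table.scale != "relative":
        raise ValidationError("filtering requires a normalized relative table")
    values = table.values()
    n = values.shape[0]
    frac_abundant = (values >= spec.min_abundance).sum(axis=0) / n
    frac_zero = (values == 0).sum(axis=0) / n
    keep = frac_abundant > spec.prevalence
    reasons: dict[str, str] = {}
    for j, fid in enumerate(table.feature_ids):
        if not frac_abundant[j] > spec.prevalence:
            reasons[fid] = (
                f"abundance >= {spec.min_abundance:g} in only "
                f"{frac_abundant[j]:.1%} of samples"
            )
    if spec.mode == "strict":
        frac_low = (values < spec.strict_low_abundance_cut).sum(axis=0) / n
        low_fail = frac_low > spec.prevalence
        for j, fid in enumerate(table.feature_ids):
            if keep[j] and low_fail[j]:
                reasons[fid] = (
                    f"abundance < {spec.strict_low_abundance_cut:g} in "
                    f"{frac_low[j]:.1%} of samples"
                )
        keep &= ~low_fail
    zero_fail = frac_zero > spec.max_zero_fraction
    for j, fid in enumerate(table.feature_ids):
        if keep[j] and zero_fail[j]:
            reasons[fid] = f"{frac_zero[j]:.1%} zeros"
    keep &= ~zero_fail
    if not keep.any():
        raise ValidationError(
            f"all {len(keep)} features dropped by {spec.mode} filtering"
        )
    kept_ids = [f for f, k in zip(table.feature_ids, keep) if k]
    out = table.with_data(table.data[kept_ids], normalized=False)
    return out, reasons


def write_filter_report(reasons: dict[str, str], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(reasons, fh, indent=2, sort_keys=True)


def destratify_ec(table: AbundanceTable, delimiter: str = "|") -> AbundanceTable:
    """Sum taxon-stratified EC features into one column per EC id.

    Feature ids of the form ``"<EC>|<taxon>"`` are pooled over taxa;
    ids without the delimiter pass through unchanged.  Output feature
    order follows first appearance of each EC id.
    """
    groups: dict[str, list[str]] = {}
    for fid in table.feature_ids:
        if delimiter in fid:
            ec, _, taxon = fid.partition(delimiter)
            if not ec or not taxon:
                raise ValidationError(f"unparseable stratified feature id {fid!r}")
        else:
            ec = fid
        groups.setdefault(ec, []).append(fid)
    if all(len(v) == 1 and k == v[0] for k, v in groups.items()):
        return table  # nothing stratified
    data = {ec: table.data[cols].sum(axis=1) for ec, cols in groups.items()}
    out = pd.DataFrame(data, index=table.data.index)[list(groups)]
    return table.with_data(out, normalized=table.normalized)


def make_paired(
    input_tables: AbundanceTable | list[AbundanceTable],
    output_table: AbundanceTable,
    metadata: SampleMetadata,
    combo_label: str | None = None,
) -> PairedDataset:
    """Align tables on their common samples and concatenate multi-omics input.

    Multiple input tables are column-concatenated with modality-prefixed
    feature ids (``"mGx:featureX"``) to guarantee uniqueness.  Sample
    order follows the first input table restricted to the intersection.
    """
    if isinstance(input_tables, AbundanceTable):
        input_tables = [input_tables]
    if not input_tables:
        raise ValidationError("at least one input table required")
    all_tables = list(input_tables) + [output_table]
    common = set(all_tables[0].sample_ids)
    for t in all_tables[1:]:
        common &= set(t.sample_ids)
    common &= set(metadata.sample_ids)
    if not common:
        counts = {t.modality: t.n_samples for t in all_tables}
        raise ValidationError(f"empty sample intersection; per-table counts: {counts}")
    order = [s for s in input_tables[0].sample_ids if s in common]

    if len(input_tables) == 1:
        inp = input_tables[0].select_samples(order)
        label_in = inp.modality
    else:
        frames = []
        for t in input_tables:
            sub = t.select_samples(order).data
            sub.columns = [f"{t.modality}:{c}" for c in sub.columns]
            frames.append(sub)
        inp = AbundanceTable(pd.concat(frames, axis=1), modality="concat",
                             scale=input_tables[0].scale)
        label_in = "+".join(t.modality for t in input_tables)
    out = output_table.select_samples(order)
    label = combo_label or f"{label_in}→{out.modality}"
    return PairedDataset(inp, out, metadata.select_samples(order), combo_label=label)
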