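"""Per-feature prediction scoring and robustness analyses.

The central statistic is Spearman's rank correlation between a
predicted and a ground-truth feature vector, computed per output
feature on each held-out test set.  Scores are aggregated across the
repeated train/test splits as a per-feature mean and SD; the reported
summary is the mean over the top-k features (k = 50 by default) by
per-feature mean, with the error defined as the mean per-feature SD
over those features.  Constant vectors have undefined rank correlation
and are recorded as 0 with a flag (common for very sparse modalities).

Robustness analyses: pairwise Jaccard similarity of top-quartile
("core") feature sets across splits or input types, feature-variance
versus prediction-quality association, Fisher-exact enrichment of EC
classes among well-predicted features, and Mann–Whitney U comparisons
between models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ValidationError


# ---------------------------------------------------------------------------
# rank correlation
# ---------------------------------------------------------------------------

def spearman(pred, truth) -> float:
    """Spearman rank correlation; NaN if either vector is constant."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValidationError(
            f"length mismatch: {pred.shape} vs {truth.shape}"
        )
    if pred.size < 2:
        raise ValidationError("need at least 2 observations")
    if np.ptp(pred) == 0 or np.ptp(truth) == 0:
        return float("nan")
    rho, _ = stats.spearmanr(pred, truth)
    return float(rho)


def per_feature_spearman(pred: pd.DataFrame, truth: pd.DataFrame,
                         fill_constant: float = 0.0) -> pd.Series:
    """Columnwise Spearman between aligned prediction/truth frames.

    Constant columns (undefined correlation) receive ``fill_constant``;
    the returned Series carries the affected ids in ``.attrs["constant"]``.
    """
    if list(pred.columns) != list(truth.columns):
        raise ValidationError("prediction/truth feature ids differ")
    if list(pred.index) != list(truth.index):
        raise ValidationError("prediction/truth samples differ")
    out = {}
    constant = []
    for col in pred.columns:
        rho = spearman(pred[col].to_numpy(), truth[col].to_numpy())
        if np.isnan(rho):
            constant.append(col)
            rho = fill_constant
        out[col] = rho
    series = pd.Series(out)
    series.attrs["constant"] = constant
    return series


# ---------------------------------------------------------------------------
# aggregation across splits
# ---------------------------------------------------------------------------

@dataclass
class FeatureScores:
    """Per-feature prediction quality across splits, with top-k summary."""

    per_split: pd.DataFrame  # features × splits

    @property
    def mean(self) -> pd.Series:
        return self.per_split.mean(axis=1)

    @property
    def sd(self) -> pd.Series:
        return self.per_split.std(axis=1, ddof=1)

    def top_k(self, k: int) -> list[str]:
        """Top-k feature ids by descending mean; ties by feature id."""
        if k > len(self.per_split):
            raise ValidationError(
                f"k={k} exceeds {len(self.per_split)} features"
            )
        mean = self.mean
        return sorted(self.per_split.index, key=lambda f: (-mean[f], f))[:k]

    def top_fraction(self, fraction: float) -> set[str]:
        n = int(np.ceil(fraction * len(self.per_split)))
        if n < 1:
            raise ValidationError(f"fraction {fraction} yields an empty set")
        return set(self.top_k(n))

    def summary(self, k: int = 50) -> dict[str, float]:
        """Reported score (mean of top-k means) and its error (mean of
        the same features' across-split SDs)."""
        top = self.top_k(k)
        return {
            "score": float(self.mean[top].mean()),
            "error": float(self.sd[top].mean()),
            "k": k,
        }


def score_features(per_split_pairs: list[tuple[pd.DataFrame, pd.DataFrame]]
                   ) -> FeatureScores:
    """Build :class:`FeatureScores` from per-split (pred, truth) frames."""
    columns = {}
    feature_set = None
    for i, (pred, truth) in enumerate(per_split_pairs):
        if feature_set is None:
            feature_set = list(pred.columns)
        elif list(pred.columns) != feature_set:
            raise ValidationError(f"split {i} has a different feature set")
        columns[i] = per_feature_spearman(pred, truth)
    return FeatureScores(pd.DataFrame(columns))


def scores_from_correlations(corr: pd.DataFrame) -> FeatureScores:
    """Wrap an existing features × splits correlation frame."""
    return FeatureScores(corr)


# ---------------------------------------------------------------------------
# density comparison: input-vs-truth against predicted-vs-truth
# ---------------------------------------------------------------------------

def correlation_shift_densities(
    input_df: pd.DataFrame,
    pred_df: pd.DataFrame,
    truth_df: pd.DataFrame,
    feature_subset: list[str] | None = None,
) -> dict:
    """Correlation samples behind the "does prediction beat the central
    dogma shortcut" comparison.

    For every feature id shared between the input and output tables
    (matched by id, e.g. the same EC number measured in two omics
    layers), computes Spearman(input, truth) and
    Spearman(predicted, truth), optionally restricted to
    ``feature_subset``, plus a one-sided Mann–Whitney test that the
    predicted-vs-truth correlations are larger.
    """
    shared = [f for f in truth_df.columns if f in set(input_df.columns)]
    if feature_subset is not None:
        keep = set(feature_subset)
        shared = [f for f in shared if f in keep]
    if not shared:
        raise ValidationError("no shared feature ids between input and output")
    input_corr, pred_corr = [], []
    for f in shared:
        r_in = spearman(input_df[f].to_numpy(), truth_df[f].to_numpy())
        r_pr = spearman(pred_df[f].to_numpy(), truth_df[f].to_numpy())
        if not np.isnan(r_in):
            input_corr.append(r_in)
        if not np.isnan(r_pr):
            pred_corr.append(r_pr)
    test = mann_whitney(pred_corr, input_corr, alternative="greater")
    return {
        "features": shared,
        "input_vs_truth": np.asarray(input_corr),
        "predicted_vs_truth": np.asarray(pred_corr),
        "mann_whitney": test,
    }


# ---------------------------------------------------------------------------
# core-set robustness
# ---------------------------------------------------------------------------

def jaccard(a: set, b: set) -> float:
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


@dataclass
class CoreSetReport:
    """Top-fraction feature sets with pairwise Jaccard similarities."""

    sets: dict[str, set[str]]
    jaccard_matrix: pd.DataFrame
    core: set[str]  # intersection across all sets
    union: set[str]

    @property
    def core_fraction_of_union(self) -> float:
        return len(self.core) / len(self.union) if self.union else 0.0


def core_feature_analysis(score_sets: dict[str, FeatureScores],
                          top_fraction: float = 0.25) -> CoreSetReport:
    """Pairwise overlap of top-fraction well-predicted feature sets.

    ``score_sets`` maps a label (a split id, or an input type) to its
    :class:`FeatureScores`; for per-split analyses pass one single-column
    FeatureScores per split.
    """
    if len(score_sets) < 2:
        raise ValidationError("need at least 2 score sets to compare")
    tops = {name: fs.top_fraction(top_fraction)
            for name, fs in score_sets.items()}
    names = list(tops)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for a, b in combinations(names, 2):
        mat.loc[a, b] = mat.loc[b, a] = jaccard(tops[a], tops[b])
    core = set.intersection(*tops.values())
    union = set.union(*tops.values())
    return CoreSetReport(sets=tops, jaccard_matrix=mat, core=core, union=union)


# ---------------------------------------------------------------------------
# variance vs prediction quality
# ---------------------------------------------------------------------------

def variance_vs_quality(truth_frames: list[pd.DataFrame],
                        scores: FeatureScores) -> dict:
    """Association between test-set feature variance and mean prediction
    quality (two-sided Spearman)."""
    features = list(scores.per_split.index)
    variances = pd.DataFrame(
        {i: df[features].var(axis=0, ddof=1) for i, df in enumerate(truth_frames)}
    ).mean(axis=1)
    rho, p = stats.spearmanr(variances.to_numpy(),
                             scores.mean[features].to_numpy())
    return {
        "variance": variances,
        "mean_correlation": scores.mean[features],
        "spearman": float(rho),
        "p_value": float(p),
    }


# ---------------------------------------------------------------------------
# EC-class enrichment
# ---------------------------------------------------------------------------

def ec_class_of(feature_id: str) -> str | None:
    """First EC digit of an ``"d.x.x.x"``-style id, else None."""
    head = feature_id.split(".", 1)[0]
    return head if head.isdigit() else None


def ec_class_enrichment(
    scores: FeatureScores,
    fractions: tuple[float, ...] = (0.10, 0.25, 0.50),
    class_labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Fisher's exact test of EC-class over-representation among the
    top-fraction well-predicted features.

    The background is the full scored feature set.  ``class_labels``
    overrides the default first-EC-digit parsing.  Classes absent from
    the background are skipped.  Degenerate tables (top set equal to
    the background) report odds ratio 1 and p = 1 by convention.
    """
    features = list(scores.per_split.index)
    if class_labels is None:
        class_labels = {f: ec_class_of(f) for f in features}
    background_classes = sorted(
        {c for c in class_labels.values() if c is not None}
    )
    rows = []
    for fraction in fractions:
        top = scores.top_fraction(fraction)
        for cls in background_classes:
            in_cls = {f for f in features if class_labels.get(f) == cls}
            a = len(top & in_cls)
            b = len(top - in_cls)
            c = len(in_cls - top)
            d = len(set(features) - top - in_cls)
            if (c + d) == 0:  # top set == background
                odds, p = 1.0, 1.0
            else:
                odds, p = stats.fisher_exact([[a, b], [c, d]],
                                             alternative="two-sided")
            rows.append({"fraction": fraction, "ec_class": cls,
                         "top_in_class": a, "top_out_class": b,
                         "rest_in_class": c, "rest_out_class": d,
                         "odds_ratio": float(odds), "p_value": float(p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def mann_whitney(sample_a, sample_b, alternative: str = "two-sided",
                 exact_threshold: int = 50) -> dict:
    """Mann–Whitney U rank-sum test between two correlation samples.

    Exact null distribution below ``exact_threshold`` observations per
    sample when there are no ties; normal approximation with tie
    correction otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need at least 2 observations per sample")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = ("exact"
              if max(len(a), len(b)) <= exact_threshold and not has_ties
              else "asymptotic")
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return {"U": float(res.statistic), "p_value": float(res.pvalue),
            "method": method, "alternative": alternative}


def compare_models(scores_a: pd.Series, scores_b: pd.Series) -> dict:
    """Two-sided Mann–Whitney U between two models' per-feature mean
    correlations over the same feature universe."""
    if set(scores_a.index) != set(scores_b.index):
        raise ValidationError("models scored on different feature universes")
    return mann_whitney(scores_a.to_numpy(), scores_b.to_numpy())
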