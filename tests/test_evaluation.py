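"""Rank statistics against independent brute-force oracles, score
aggregation, core sets, enrichment and model comparison."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from crossomics import evaluation
from crossomics.containers import ValidationError
from crossomics.evaluation import FeatureScores


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def rank_with_ties(v):
    """Average ranks, brute force."""
    v = np.asarray(v, dtype=float)
    ranks = np.empty(len(v))
    for i, x in enumerate(v):
        less = (v < x).sum()
        equal = (v == x).sum()
        ranks[i] = less + (equal + 1) / 2
    return ranks


def spearman_oracle(a, b):
    """Rank both vectors, then plain Pearson."""
    ra, rb = rank_with_ties(a), rank_with_ties(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    return float((ra * rb).sum() / np.sqrt((ra ** 2).sum() * (rb ** 2).sum()))


def mann_whitney_exact_oracle(a, b):
    """Two-sided p by enumeration over all C(n+m, n) group assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    n = len(a)

    def u_stat(first_idx):
        first = [pooled[i] for i in first_idx]
        second = [pooled[i] for i in range(len(pooled)) if i not in set(first_idx)]
        return sum(x > y for x in first for y in second)

    observed = sum(x > y for x in a for y in b)
    m = len(b)
    mean_u = n * m / 2
    count = total = 0
    for idx in combinations(range(len(pooled)), n):
        u = u_stat(idx)
        if abs(u - mean_u) >= abs(observed - mean_u) - 1e-12:
            count += 1
        total += 1
    return count / total


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by hypergeometric enumeration."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (math.comb(col1, x) * math.comb(n - col1, row1 - x)
                / math.comb(n, row1))

    p_obs = prob(a)
    lo, hi = max(0, row1 - (n - col1)), min(row1, col1)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


# ---------------------------------------------------------------------------
# spearman
# ---------------------------------------------------------------------------

def test_spearman_perfect_concordance_and_discordance():
    v = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
    assert evaluation.spearman(v, v) == pytest.approx(1.0)
    assert evaluation.spearman(v, -v) == pytest.approx(-1.0)


def test_spearman_matches_brute_force_oracle():
    rng = np.random.default_rng(10)
    for _ in range(20):
        a = rng.integers(0, 8, size=20).astype(float)  # ties likely
        b = rng.normal(size=20)
        assert evaluation.spearman(a, b) == pytest.approx(
            spearman_oracle(a, b), abs=1e-12)


def test_spearman_constant_vector_is_undefined_marker():
    assert np.isnan(evaluation.spearman(np.ones(5), np.arange(5.0)))


def test_spearman_length_mismatch_rejected():
    with pytest.raises(ValidationError, match="mismatch"):
        evaluation.spearman(np.ones(3), np.ones(4))


def test_per_feature_spearman_flags_constants():
    pred = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5]})
    truth = pd.DataFrame({"a": [1.0, 3, 2], "b": [1.0, 2, 3]})
    s = evaluation.per_feature_spearman(pred, truth)
    assert s["b"] == 0.0
    assert s.attrs["constant"] == ["b"]


# ---------------------------------------------------------------------------
# score aggregation
# ---------------------------------------------------------------------------

def test_score_features_toy_summary_matches_hand_computation():
    corr = pd.DataFrame(
        {"s0": [0.9, 0.2, 0.5], "s1": [0.7, 0.4, 0.5]},
        index=["f1", "f2", "f3"])
    fs = FeatureScores(corr)
    # means: f1 0.8, f2 0.3, f3 0.5 → top-2 = f1, f3
    assert fs.top_k(2) == ["f1", "f3"]
    summary = fs.summary(k=2)
    assert summary["score"] == pytest.approx((0.8 + 0.5) / 2)
    sd_f1 = np.std([0.9, 0.7], ddof=1)
    assert summary["error"] == pytest.approx((sd_f1 + 0.0) / 2)


def test_identical_splits_give_zero_error():
    corr = pd.DataFrame({"s0": [0.5, 0.1], "s1": [0.5, 0.1]},
                        index=["f1", "f2"])
    assert FeatureScores(corr).summary(k=2)["error"] == 0.0


def test_top_k_exceeding_feature_count_rejected():
    corr = pd.DataFrame({"s0": [0.5]}, index=["f1"])
    with pytest.raises(ValidationError, match="exceeds"):
        FeatureScores(corr).top_k(5)


def test_top_k_tie_break_is_feature_id_order():
    corr = pd.DataFrame({"s0": [0.5, 0.5, 0.5]}, index=["z", "a", "m"])
    assert FeatureScores(corr).top_k(2) == ["a", "m"]


def test_score_features_permutation_equivariance():
    rng = np.random.default_rng(11)
    pred = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
    truth = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
    fs = evaluation.score_features([(pred, truth)])
    perm = ["c", "a", "d", "b"]
    fs_perm = evaluation.score_features([(pred[perm], truth[perm])])
    for f in "abcd":
        assert fs.mean[f] == fs_perm.mean[f]


def test_summary_monotone_in_single_feature_scores():
    corr = pd.DataFrame({"s0": [0.6, 0.3], "s1": [0.6, 0.3]},
                        index=["f1", "f2"])
    low = FeatureScores(corr).summary(k=2)["score"]
    bumped = corr.copy()
    bumped.loc["f2"] += 0.2
    assert FeatureScores(bumped).summary(k=2)["score"] >= low


def test_score_features_rejects_mismatched_feature_sets():
    pred = pd.DataFrame({"a": [1.0, 2]}, index=[0, 1])
    with pytest.raises(ValidationError, match="different feature set"):
        evaluation.score_features([
            (pred, pred), (pred.rename(columns={"a": "b"}),
                           pred.rename(columns={"a": "b"}))])


# ---------------------------------------------------------------------------
# core sets
# ---------------------------------------------------------------------------

def _scores(values: dict):
    return FeatureScores(pd.DataFrame({"s0": pd.Series(values)}))


def test_identical_score_sets_full_overlap():
    s = _scores({"a": 0.9, "b": 0.8, "c": 0.1, "d": 0.05})
    report = evaluation.core_feature_analysis({"x": s, "y": s},
                                              top_fraction=0.25)
    assert (report.jaccard_matrix.to_numpy() == 1.0).all()
    assert report.core == {"a"}
    assert report.core_fraction_of_union == 1.0


def test_disjoint_top_sets_zero_jaccard_empty_core():
    s1 = _scores({"a": 0.9, "b": 0.1, "c": 0.0, "d": 0.0})
    s2 = _scores({"a": 0.0, "b": 0.9, "c": 0.0, "d": 0.0})
    report = evaluation.core_feature_analysis({"x": s1, "y": s2},
                                              top_fraction=0.25)
    assert report.jaccard_matrix.loc["x", "y"] == 0.0
    assert report.core == set()


def test_jaccard_matrix_matches_hand_computation():
    s1 = _scores({"a": 0.9, "b": 0.8, "c": 0.1, "d": 0.0})
    s2 = _scores({"a": 0.9, "b": 0.1, "c": 0.8, "d": 0.0})
    s3 = _scores({"a": 0.1, "b": 0.9, "c": 0.8, "d": 0.0})
    report = evaluation.core_feature_analysis(
        {"x": s1, "y": s2, "z": s3}, top_fraction=0.5)
    # tops: x={a,b}, y={a,c}, z={b,c}; all pairwise |∩|=1, |∪|=3
    for pair in (("x", "y"), ("x", "z"), ("y", "z")):
        assert report.jaccard_matrix.loc[pair] == pytest.approx(1 / 3)
    assert np.diag(report.jaccard_matrix) == pytest.approx(1.0)
    assert report.core == set() and report.union == {"a", "b", "c"}


# ---------------------------------------------------------------------------
# variance vs quality
# ---------------------------------------------------------------------------

def test_variance_scaling_leaves_association_unchanged():
    rng = np.random.default_rng(12)
    truth = pd.DataFrame(rng.normal(size=(30, 6)),
                         columns=[f"f{j}" for j in range(6)])
    scores = FeatureScores(pd.DataFrame(
        {"s0": rng.random(6)}, index=truth.columns))
    base = evaluation.variance_vs_quality([truth], scores)
    scaled = evaluation.variance_vs_quality([truth * 2], scores)
    np.testing.assert_allclose(scaled["variance"], base["variance"] * 4)
    assert scaled["spearman"] == pytest.approx(base["spearman"])


def test_variance_null_pvalues_roughly_uniform():
    """With planted quality independent of variance, the association
    test should reject at ~nominal rate."""
    rng = np.random.default_rng(13)
    rejections = 0
    reps = 100
    for _ in range(reps):
        truth = pd.DataFrame(
            rng.normal(scale=rng.uniform(0.5, 2.0, size=8), size=(25, 8)),
            columns=[f"f{j}" for j in range(8)])
        scores = FeatureScores(pd.DataFrame({"s0": rng.random(8)},
                                            index=truth.columns))
        out = evaluation.variance_vs_quality([truth], scores)
        rejections += out["p_value"] < 0.05
    assert rejections / reps <= 0.10  # nominal 5% ± 5 points


# ---------------------------------------------------------------------------
# EC-class enrichment
# ---------------------------------------------------------------------------

def test_fisher_hand_table_odds_ratio_and_oracle():
    from scipy.stats import fisher_exact

    odds, p = fisher_exact([[8, 2], [10, 80]], alternative="two-sided")
    assert odds == pytest.approx(32.0)
    assert p == pytest.approx(fisher_oracle(8, 2, 10, 80), abs=1e-10)


def test_enrichment_detects_planted_class_excess():
    # 12 of 16 class-1 features in the top quartile of 64 features
    ids = [f"{1 + (j % 4)}.{j}.1.1" for j in range(64)]
    values = {fid: 0.0 for fid in ids}
    class1 = [fid for fid in ids if fid.startswith("1.")]
    for fid in class1[:12]:
        values[fid] = 1.0
    for fid in [f for f in ids if not f.startswith("1.")][:4]:
        values[fid] = 1.0
    fs = _scores(values)
    table = evaluation.ec_class_enrichment(fs, fractions=(0.25,))
    row = table[(table.ec_class == "1")].iloc[0]
    assert row.p_value < 0.05 and row.odds_ratio > 1


def test_enrichment_null_pvalues_not_inflated():
    rng = np.random.default_rng(14)
    small_ps = 0
    reps = 60
    for _ in range(reps):
        ids = [f"{1 + (j % 5)}.{j}.1.1" for j in range(40)]
        fs = _scores(dict(zip(ids, rng.random(40))))
        table = evaluation.ec_class_enrichment(fs, fractions=(0.25,))
        small_ps += (table.p_value < 0.05).any()
    # 5 classes tested per rep; Fisher is conservative on small tables
    assert small_ps / reps <= 0.25


def test_enrichment_degenerate_top_equals_background():
    ids = ["1.1.1.1", "2.1.1.1"]
    fs = _scores(dict(zip(ids, [0.5, 0.4])))
    table = evaluation.ec_class_enrichment(fs, fractions=(1.0,))
    assert (table.p_value == 1.0).all()
    assert (table.odds_ratio == 1.0).all()


def test_enrichment_skips_unlabeled_features():
    fs = _scores({"1.1.1.1": 0.9, "unknown_feature": 0.1, "2.2.2.2": 0.5})
    table = evaluation.ec_class_enrichment(fs, fractions=(0.5,))
    assert set(table.ec_class) == {"1", "2"}


# ---------------------------------------------------------------------------
# Mann–Whitney
# ---------------------------------------------------------------------------

def test_mann_whitney_identical_samples_p_one():
    out = evaluation.compare_models(
        pd.Series([0.1, 0.2, 0.3], index=list("abc")),
        pd.Series([0.1, 0.2, 0.3], index=list("abc")))
    assert out["p_value"] == pytest.approx(1.0)


def test_mann_whitney_fully_separated_exact_p():
    out = evaluation.mann_whitney([1, 2, 3], [4, 5, 6])
    assert out["U"] == 0.0
    assert out["method"] == "exact"
    assert out["p_value"] == pytest.approx(0.1)
    assert out["p_value"] == pytest.approx(
        mann_whitney_exact_oracle([1, 2, 3], [4, 5, 6]), abs=1e-10)


def test_mann_whitney_matches_enumeration_oracle_on_random_samples():
    rng = np.random.default_rng(15)
    for _ in range(5):
        a = rng.normal(size=5)
        b = rng.normal(size=4)
        out = evaluation.mann_whitney(a, b)
        assert out["p_value"] == pytest.approx(
            mann_whitney_exact_oracle(a, b), abs=1e-10)


def test_mann_whitney_invariant_to_joint_monotone_transform():
    rng = np.random.default_rng(16)
    a, b = rng.normal(size=8), rng.normal(size=8) + 0.5
    base = evaluation.mann_whitney(a, b)
    warped = evaluation.mann_whitney(np.exp(a), np.exp(b))
    assert warped["U"] == base["U"]
    assert warped["p_value"] == pytest.approx(base["p_value"])


def test_compare_models_requires_common_universe():
    with pytest.raises(ValidationError, match="universe"):
        evaluation.compare_models(
            pd.Series([0.1, 0.2], index=["a", "b"]),
            pd.Series([0.1, 0.2], index=["a", "c"]))


# ---------------------------------------------------------------------------
# correlation shift densities
# ---------------------------------------------------------------------------

def test_density_comparison_perfect_predictions():
    rng = np.random.default_rng(17)
    truth = pd.DataFrame(rng.normal(size=(20, 5)),
                         columns=[f"1.1.1.{j}" for j in range(5)])
    noisy_input = truth + rng.normal(scale=2.0, size=truth.shape)
    out = evaluation.correlation_shift_densities(noisy_input, truth, truth)
    np.testing.assert_allclose(out["predicted_vs_truth"], 1.0)
    assert len(out["features"]) == 5


def test_density_comparison_null_input_centered_at_zero():
    rng = np.random.default_rng(18)
    truth = pd.DataFrame(rng.normal(size=(40, 30)),
                         columns=[f"f{j}" for j in range(30)])
    unrelated_input = pd.DataFrame(rng.normal(size=(40, 30)),
                                   columns=truth.columns)
    pred = truth + rng.normal(scale=0.5, size=truth.shape)
    out = evaluation.correlation_shift_densities(unrelated_input, pred, truth)
    assert abs(np.mean(out["input_vs_truth"])) < 0.15
    assert out["mann_whitney"]["p_value"] < 0.01  # predictions clearly better


def test_density_comparison_subset_containment():
    rng = np.random.default_rng(19)
    truth = pd.DataFrame(rng.normal(size=(15, 6)),
                         columns=[f"f{j}" for j in range(6)])
    out_all = evaluation.correlation_shift_densities(truth, truth, truth)
    out_top = evaluation.correlation_shift_densities(
        truth, truth, truth, feature_subset=["f0", "f1"])
    assert set(out_top["features"]) <= set(out_all["features"])


def test_density_comparison_requires_shared_ids():
    a = pd.DataFrame({"x": [1.0, 2]}, index=[0, 1])
    b = pd.DataFrame({"y": [1.0, 2]}, index=[0, 1])
    with pytest.raises(ValidationError, match="shared"):
        evaluation.correlation_shift_densities(a, b, b)
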