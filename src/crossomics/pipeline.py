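"""End-to-end benchmark orchestration.

Wires the stages together: preprocess (normalize → filter → pair),
split (patient-level, stratified, seeded), fit each requested model on
every training slice, predict and score held-out samples per feature,
aggregate across splits, and optionally run the downstream IBD
classification under the fairness protocol.  Fit stages only ever
receive training slices, so no fitting step can read test-sample
values; an audit test poisons test rows and asserts unchanged models.

Feature filtering supports two scopes: ``global`` (the whole table is
filtered before splitting — faithful to a fixed published preprocessing
of one cohort) and ``train_only`` (thresholds computed on the training
slice of each split — the leakage-free variant).  ``global`` is the
default.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import downstream as ds
from . import evaluation, io_prep, partition, regressors
from .containers import (
    AbundanceTable,
    PairedDataset,
    SampleMetadata,
    ValidationError,
)

logger = logging.getLogger("crossomics")

#: upstream→downstream ordering of the omics layers (central dogma order)
MODALITY_ORDER = {"mGx": 0, "mTx": 1, "mPx": 2, "mBx": 3}


@dataclass
class RunConfig:
    """Configuration of one benchmark run."""

    combos: list[tuple[list[str], str]] = field(
        default_factory=lambda: [(["mGx"], "mBx")]
    )
    models: list[str] = field(default_factory=lambda: ["elastic_net"])
    filter_mode: str | None = "lenient"  # None disables filtering
    filter_scope: str = "global"  # "global" | "train_only"
    n_splits: int = 10
    split_seeds: list[int] | None = None
    top_k: int = 50
    top_fraction: float = 0.25
    run_downstream: bool = False
    classifier_search_iters: int = 50
    out_dir: str | None = None

    def validate(self, available_modalities) -> None:
        avail = set(available_modalities)
        for inputs, output in self.combos:
            for m in list(inputs) + [output]:
                if m not in avail:
                    raise ValidationError(
                        f"combo references modality {m!r} not in the "
                        f"input manifest {sorted(avail)}"
                    )
                if m not in MODALITY_ORDER:
                    raise ValidationError(f"unknown modality {m!r}")
            for m in inputs:
                if MODALITY_ORDER[m] >= MODALITY_ORDER[output]:
                    raise ValidationError(
                        f"combo {inputs}→{output} violates the "
                        "upstream→downstream directionality"
                    )
        for m in self.models:
            if m not in regressors.FITTERS:
                raise ValidationError(f"unknown model {m!r}")
        if self.filter_scope not in ("global", "train_only"):
            raise ValidationError(f"unknown filter scope {self.filter_scope!r}")

    def to_dict(self) -> dict:
        return {
            "combos": [[list(i), o] for i, o in self.combos],
            "models": list(self.models),
            "filter_mode": self.filter_mode,
            "filter_scope": self.filter_scope,
            "n_splits": self.n_splits,
            "split_seeds": self.split_seeds,
            "top_k": self.top_k,
            "top_fraction": self.top_fraction,
            "run_downstream": self.run_downstream,
            "classifier_search_iters": self.classifier_search_iters,
        }


def preprocess_table(table: AbundanceTable,
                     filter_spec: io_prep.FilterSpec | None) -> AbundanceTable:
    """Normalize (TSS) and, if requested, filter one abundance table."""
    if table.scale == "count":
        table = io_prep.impute_zeros(table, renormalize=False)
    table = io_prep.tss_normalize(table)
    if filter_spec is not None:
        table, _ = io_prep.filter_features(table, filter_spec)
        table = io_prep.tss_normalize(table)
    return table


def _train_only_filter(paired: PairedDataset, plan: partition.SplitPlan,
                       filter_spec: io_prep.FilterSpec) -> PairedDataset:
    """Restrict features to those passing the filter on the training slice."""
    train = paired.select_samples(
        [s for s in paired.sample_ids if s in set(plan.train_samples)]
    )
    kept = {}
    for side in ("input", "output"):
        table = getattr(train, side)
        normalized = io_prep.tss_normalize(table)
        filtered, _ = io_prep.filter_features(normalized, filter_spec)
        kept[side] = filtered.feature_ids
    new_in = paired.input.with_data(paired.input.data[kept["input"]],
                                    normalized=False)
    new_out = paired.output.with_data(paired.output.data[kept["output"]],
                                      normalized=False)
    new_in = io_prep.tss_normalize(new_in)
    new_out = io_prep.tss_normalize(new_out)
    return PairedDataset(new_in, new_out, paired.metadata,
                         combo_label=paired.combo_label)


@dataclass
class SplitResult:
    """One model fitted and scored on one split."""

    plan: partition.SplitPlan
    model: regressors.FittedCrossOmicsModel
    predictions: pd.DataFrame  # test samples × output features (transformed)
    truth: pd.DataFrame  # test truth in the same transformed space
    scores: pd.Series  # per-feature Spearman


def fit_and_score_split(
    paired: PairedDataset,
    plan: partition.SplitPlan,
    spec: regressors.RegressorSpec,
    filter_spec: io_prep.FilterSpec | None = None,
) -> SplitResult:
    """Fit on the plan's training samples, score on its test samples.

    ``filter_spec`` enables train-only feature filtering for this split.
    """
    if filter_spec is not None:
        paired = _train_only_filter(paired, plan, filter_spec)
    train_ids = [s for s in paired.sample_ids if s in set(plan.train_samples)]
    test_ids = [s for s in paired.sample_ids if s in set(plan.test_samples)]
    train = paired.select_samples(train_ids)
    t0 = time.perf_counter()
    model = regressors.fit(train, spec)
    test_input = paired.input.select_samples(test_ids)
    test_output = paired.output.select_samples(test_ids)
    pred = model.predict(test_input)
    truth = model.transform_output(test_output)
    scores = evaluation.per_feature_spearman(pred, truth)
    logger.info(
        "split seed=%d model=%s combo=%s n_train=%d n_test=%d "
        "features=%dx%d wall=%.1fs",
        plan.seed, spec.kind, paired.combo_label, len(train_ids),
        len(test_ids), paired.input.n_features, paired.output.n_features,
        time.perf_counter() - t0,
    )
    return SplitResult(plan=plan, model=model, predictions=pred,
                       truth=truth, scores=scores)


def run_model_over_splits(
    paired: PairedDataset,
    plans: list[partition.SplitPlan],
    spec: regressors.RegressorSpec,
    filter_spec: io_prep.FilterSpec | None = None,
) -> list[SplitResult]:
    return [fit_and_score_split(paired, p, spec, filter_spec) for p in plans]


def feature_scores(results: list[SplitResult]) -> evaluation.FeatureScores:
    corr = pd.DataFrame({r.plan.seed: r.scores for r in results})
    return evaluation.scores_from_correlations(corr)


# ---------------------------------------------------------------------------
# full benchmark with on-disk artifacts
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_benchmark(config: RunConfig, tables: dict[str, AbundanceTable],
                  metadata: SampleMetadata) -> dict:
    """Run every (combo, model, split); write artifacts and a manifest.

    Layout: ``<out>/<combo>/<model>/<seed>/{predictions,scores}.tsv`` and
    ``model.json`` where serializable, aggregates under
    ``<out>/<combo>/summary/``, and ``manifest.json`` at the root tying
    each file to its producing step, config hash and seeds.
    """
    config.validate(tables.keys())
    out_dir = Path(config.out_dir) if config.out_dir else None
    config_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]
    filter_spec = (io_prep.FilterSpec(mode=config.filter_mode)
                   if config.filter_mode else None)
    manifest = {"config": config.to_dict(), "config_hash": config_hash,
                "files": {}}
    results: dict = {}

    for inputs, output in config.combos:
        global_spec = filter_spec if config.filter_scope == "global" else None
        prepped_inputs = [preprocess_table(tables[m], global_spec)
                          for m in inputs]
        prepped_output = preprocess_table(tables[output], global_spec)
        paired = io_prep.make_paired(prepped_inputs, prepped_output, metadata)
        combo_key = paired.combo_label
        plans = partition.make_splits(
            paired.metadata, n_splits=config.n_splits,
            seeds=config.split_seeds,
        )
        per_split_filter = (filter_spec if config.filter_scope == "train_only"
                            else None)
        combo_results: dict = {"plans": plans, "models": {}}
        for model_name in config.models:
            spec = regressors.RegressorSpec(kind=model_name)
            split_results = run_model_over_splits(
                paired, plans, spec, per_split_filter
            )
            fs = feature_scores(split_results)
            combo_results["models"][model_name] = {
                "splits": split_results,
                "feature_scores": fs,
                "summary": fs.summary(min(config.top_k, fs.per_split.shape[0])),
            }
            if out_dir is not None:
                for r in split_results:
                    d = out_dir / combo_key / model_name / str(r.plan.seed)
                    d.mkdir(parents=True, exist_ok=True)
                    r.predictions.to_csv(d / "predictions.tsv", sep="\t",
                                         float_format="%.17g")
                    r.scores.to_frame("spearman").to_csv(
                        d / "scores.tsv", sep="\t", float_format="%.17g")
                    (d / "model.json").write_text(r.model.to_json()
                                                  if r.model.coefficients
                                                  is not None
                                                  else json.dumps(
                                                      {"kind": r.model.kind,
                                                       "seed": r.model.seed}))
                    for f in ("predictions.tsv", "scores.tsv", "model.json"):
                        rel = str((d / f).relative_to(out_dir))
                        manifest["files"][rel] = {
                            "sha256": _sha256(d / f),
                            "step": f"train:{combo_key}:{model_name}:"
                                    f"seed{r.plan.seed}",
                        }
        # cross-split core-set analysis on the first model
        first = config.models[0]
        fs = combo_results["models"][first]["feature_scores"]
        per_split_scores = {
            str(seed): evaluation.scores_from_correlations(
                fs.per_split[[seed]])
            for seed in fs.per_split.columns
        }
        combo_results["core_sets"] = evaluation.core_feature_analysis(
            per_split_scores, top_fraction=config.top_fraction
        )
        if config.run_downstream:
            combo_results["downstream"] = run_downstream(
                paired, plans,
                combo_results["models"][first]["splits"],
                n_iter=config.classifier_search_iters,
            )
        if out_dir is not None:
            sd = out_dir / combo_key / "summary"
            sd.mkdir(parents=True, exist_ok=True)
            agg = pd.DataFrame({"mean": fs.mean, "sd": fs.sd})
            agg.to_csv(sd / "feature_scores.tsv", sep="\t",
                       float_format="%.17g")
            summary = {m: combo_results["models"][m]["summary"]
                       for m in config.models}
            (sd / "summary.json").write_text(
                json.dumps(summary, indent=2, sort_keys=True))
            for f in ("feature_scores.tsv", "summary.json"):
                rel = str((sd / f).relative_to(out_dir))
                manifest["files"][rel] = {"sha256": _sha256(sd / f),
                                          "step": f"aggregate:{combo_key}"}
        results[combo_key] = combo_results

    if out_dir is not None:
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results


def run_downstream(
    paired: PairedDataset,
    plans: list[partition.SplitPlan],
    split_results: list[SplitResult],
    n_iter: int = 50,
    sources: tuple[str, ...] = ("input", "predicted", "ground_truth", "dummy"),
) -> dict:
    """IBD classification per split on input / predicted / truth / dummy.

    Classifier features live in each model's transformed space; the
    predicted source uses the regression model's held-out predictions,
    so its test rows are genuinely model-generated.  Training-side
    predicted features are produced by the same fitted model applied to
    the (seen) training samples.
    """
    by_seed = {r.plan.seed: r for r in split_results}
    runs: dict[str, list[ds.ClassificationRun]] = {s: [] for s in sources}
    fairness = []
    for plan in plans:
        r = by_seed[plan.seed]
        model = r.model
        input_t = model.input_transform.apply(
            regressors._positive_matrix(paired.input,
                                        model.input_transform.kind))
        input_df = pd.DataFrame(input_t, index=paired.sample_ids,
                                columns=paired.input.feature_ids)
        truth_df = model.transform_output(paired.output)
        pred_train = model.predict(
            paired.input.select_samples(
                [s for s in paired.sample_ids
                 if s in set(plan.train_samples)]))
        pred_df = pd.concat([pred_train, r.predictions]).loc[paired.sample_ids]
        frames = {"input": input_df, "predicted": pred_df,
                  "ground_truth": truth_df}
        sel = ds.downsample_for_fairness(
            frames, paired.metadata, plan.train_samples, plan.test_samples,
            seed=plan.seed,
        )
        fairness.append({
            "seed": plan.seed,
            "n_train": len(sel["train_samples"]),
            "class_counts": sel["train_labels"].value_counts().to_dict(),
        })
        for source in sources:
            if source == "dummy":
                runs["dummy"].append(
                    ds.dummy_baseline(sel["train_labels"],
                                      truth_df.loc[sel["test_samples"]],
                                      sel["test_labels"], seed=plan.seed,
                                      split_seed=plan.seed))
                continue
            frame = frames[source]
            clf = ds.train_classifier(
                frame.loc[sel["train_samples"]], sel["train_labels"],
                paired.metadata, seed=plan.seed, n_iter=n_iter,
            )
            runs[source].append(
                ds.evaluate_classifier(
                    clf, frame.loc[sel["test_samples"]], sel["test_labels"],
                    source=source, split_seed=plan.seed,
                    n_train=sel["train_labels"].value_counts().to_dict(),
                ))
    comparison = ds.compare_classifiers(runs) if len(plans) >= 2 else None
    return {"runs": runs, "fairness": fairness, "comparison": comparison,
            "mean_balanced_accuracy": {
                s: float(np.mean([r.metrics["balanced_accuracy"]
                                  for r in runs[s]]))
                for s in sources
            }}
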