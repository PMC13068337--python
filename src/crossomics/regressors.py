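"""Cross-omics multi-output regression models.

Four model families over a common fit/predict surface:

* ``elastic_net`` — one elastic-net linear model per output feature
  (the MelonnPan-style scheme), penalty strength chosen by internal
  patient-grouped cross-validation over a log-spaced grid with a fixed
  L1/L2 mixing parameter.
* ``random_forest`` — a single multi-output RandomForestRegressor
  baseline (default parameters, seed 42).
* ``mlp`` — a feed-forward multi-output network with optional
  Gaussian-jitter training-set augmentation; an empty hidden-layer
  configuration degrades to an exactly linear model.
* ``autoencoder_then_elastic_net`` — a linear autoencoder over
  concatenated multi-omics input trained with a joint
  reconstruction + regression loss by exact alternating least squares
  (each block update is a closed-form minimiser, so the joint loss is
  non-increasing), followed by an elastic net on the frozen latent
  features.

Models receive a :class:`~crossomics.containers.PairedDataset` already
restricted to training samples; transforms are fitted on those samples
only and frozen into the model, so prediction on unseen samples reuses
training-time state.  Transforms requiring strict positivity (CLR)
trigger epsilon-imputation of the raw table first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNetCV, LinearRegression
from sklearn.neural_network import MLPRegressor

from . import evaluation, io_prep
from .containers import AbundanceTable, PairedDataset, ValidationError
from .transforms import FittedTransform

#: default input/output transform pairing per model kind
DEFAULT_TRANSFORMS = {
    "elastic_net": ("quantile", "quantile"),
    "random_forest": ("arcsin", "arcsin"),
    "mlp": ("quantile", "quantile"),
    "autoencoder_then_elastic_net": ("quantile", "quantile"),
}

DEFAULT_ALPHA_GRID = np.logspace(-4, 1, 13)


@dataclass
class RegressorSpec:
    """Model kind, transform pairing, hyperparameters and seed."""

    kind: str = "elastic_net"
    input_transform: str | None = None
    output_transform: str | None = None
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 42

    def __post_init__(self) -> None:
        if self.kind not in DEFAULT_TRANSFORMS:
            raise ValidationError(f"unknown regressor kind {self.kind!r}")
        din, dout = DEFAULT_TRANSFORMS[self.kind]
        if self.input_transform is None:
            self.input_transform = din
        if self.output_transform is None:
            self.output_transform = dout
        mixing = self.hyperparameters.get("l1_ratio", 0.5)
        if not (0.0 <= mixing <= 1.0):
            raise ValidationError(f"mixing parameter {mixing} outside [0, 1]")
        if self.hyperparameters.get("augmentation_factor", 1) < 1:
            raise ValidationError("augmentation_factor must be >= 1")

    def hp(self, name, default):
        return self.hyperparameters.get(name, default)


@dataclass
class FittedCrossOmicsModel:
    """A fitted cross-omics predictor with its frozen transforms."""

    kind: str
    input_transform: FittedTransform
    output_transform: FittedTransform
    input_feature_ids: list[str]
    output_feature_ids: list[str]
    seed: int
    # elastic net: (n_out × n_in) coefficients + intercepts (+ chosen alphas)
    coefficients: np.ndarray | None = None
    intercepts: np.ndarray | None = None
    alphas: np.ndarray | None = None
    constant_outputs: list[str] = field(default_factory=list)
    estimator: object = None  # forest / MLP / linear fallback
    encoder: np.ndarray | None = None  # autoencoder projection (p × k)
    training_loss: list[float] = field(default_factory=list)

    # -- input/output preparation ---------------------------------------
    def _prepare_input(self, table: AbundanceTable) -> np.ndarray:
        if table.feature_ids != self.input_feature_ids:
            missing = set(self.input_feature_ids) - set(table.feature_ids)
            extra = set(table.feature_ids) - set(self.input_feature_ids)
            if missing or extra:
                raise ValidationError(
                    f"input features mismatch; missing={sorted(missing)[:5]} "
                    f"extra={sorted(extra)[:5]}"
                )
            table = table.with_data(table.data[self.input_feature_ids])
        return self.input_transform.apply(
            _positive_matrix(table, self.input_transform.kind)
        )

    def transform_output(self, table: AbundanceTable) -> pd.DataFrame:
        """Map a ground-truth output table into the model's output space."""
        if table.feature_ids != self.output_feature_ids:
            table = table.with_data(table.data[self.output_feature_ids])
        values = self.output_transform.apply(
            _positive_matrix(table, self.output_transform.kind)
        )
        return pd.DataFrame(values, index=table.data.index,
                            columns=self.output_feature_ids)

    def predict(self, table: AbundanceTable) -> pd.DataFrame:
        """Predict output features (in transformed space) for new samples."""
        x = self._prepare_input(table)
        if self.encoder is not None:
            x = x @ self.encoder
        if self.coefficients is not None:
            pred = x @ self.coefficients.T + self.intercepts
        else:
            pred = np.asarray(self.estimator.predict(x))
            if pred.ndim == 1:
                pred = pred[:, None]
        return pd.DataFrame(pred, index=table.data.index,
                            columns=self.output_feature_ids)

    def to_json(self) -> str:
        payload = {
            "kind": self.kind,
            "seed": self.seed,
            "input_feature_ids": self.input_feature_ids,
            "output_feature_ids": self.output_feature_ids,
            "input_transform": json.loads(self.input_transform.to_json()),
            "output_transform": json.loads(self.output_transform.to_json()),
            "constant_outputs": self.constant_outputs,
        }
        if self.coefficients is not None:
            payload["coefficients"] = self.coefficients.tolist()
            payload["intercepts"] = self.intercepts.tolist()
            if self.alphas is not None:
                payload["alphas"] = np.asarray(self.alphas).tolist()
        if self.encoder is not None:
            payload["encoder"] = self.encoder.tolist()
        return json.dumps(payload)


def _positive_matrix(table: AbundanceTable, kind: str) -> np.ndarray:
    """Table values, epsilon-imputed and re-closed when the transform
    requires strict positivity."""
    if kind == "clr" and (table.values() == 0).any():
        table = io_prep.impute_zeros(table)
    return table.values()


def _group_kfold(paired: PairedDataset, k: int, seed: int):
    """Patient-grouped k-fold (train_idx, val_idx) pairs over the
    paired dataset's samples."""
    patients = list(dict.fromkeys(paired.metadata.table["patient_id"]))
    k = min(k, len(patients))
    rng = np.random.default_rng(seed)
    patients = list(patients)
    rng.shuffle(patients)
    folds = [patients[i::k] for i in range(k)]
    patient_of = paired.metadata.table["patient_id"].to_dict()
    samples = paired.sample_ids
    out = []
    for fold in folds:
        fold_set = set(fold)
        val = np.array([i for i, s in enumerate(samples)
                        if patient_of[s] in fold_set], dtype=int)
        train = np.array([i for i, s in enumerate(samples)
                          if patient_of[s] not in fold_set], dtype=int)
        if len(val) and len(train):
            out.append((train, val))
    return out


def _fit_transforms(paired: PairedDataset, spec: RegressorSpec):
    tin = FittedTransform(spec.input_transform)
    tout = FittedTransform(spec.output_transform)
    x = tin.fit_apply(_positive_matrix(paired.input, spec.input_transform))
    y = tout.fit_apply(_positive_matrix(paired.output, spec.output_transform))
    return tin, tout, x, y


def _elastic_net_per_output(x, y, output_ids, paired, spec):
    """Per-output-feature elastic net with patient-grouped internal CV."""
    alphas = np.asarray(spec.hp("alphas", DEFAULT_ALPHA_GRID), dtype=float)
    l1_ratio = spec.hp("l1_ratio", 0.5)
    cv = _group_kfold(paired, spec.hp("cv_folds", 10), spec.seed)
    n_out = y.shape[1]
    coefs = np.zeros((n_out, x.shape[1]))
    intercepts = np.zeros(n_out)
    chosen = np.full(n_out, np.nan)
    constant = []
    for j in range(n_out):
        col = y[:, j]
        if np.ptp(col) == 0:
            intercepts[j] = col[0]
            constant.append(output_ids[j])
            continue
        model = ElasticNetCV(
            l1_ratio=l1_ratio, alphas=alphas, cv=cv,
            max_iter=spec.hp("max_iter", 5000), tol=spec.hp("tol", 1e-4),
        )
        model.fit(x, col)
        coefs[j] = model.coef_
        intercepts[j] = model.intercept_
        chosen[j] = model.alpha_
    return coefs, intercepts, chosen, constant


def fit_elastic_net(paired: PairedDataset, spec: RegressorSpec | None = None
                    ) -> FittedCrossOmicsModel:
    """Fit one elastic-net model per output feature (MelonnPan scheme)."""
    spec = spec or RegressorSpec(kind="elastic_net")
    tin, tout, x, y = _fit_transforms(paired, spec)
    coefs, intercepts, chosen, constant = _elastic_net_per_output(
        x, y, paired.output.feature_ids, paired, spec
    )
    return FittedCrossOmicsModel(
        kind="elastic_net", input_transform=tin, output_transform=tout,
        input_feature_ids=paired.input.feature_ids,
        output_feature_ids=paired.output.feature_ids, seed=spec.seed,
        coefficients=coefs, intercepts=intercepts, alphas=chosen,
        constant_outputs=constant,
    )


def fit_random_forest(paired: PairedDataset, spec: RegressorSpec | None = None
                      ) -> FittedCrossOmicsModel:
    """Multi-output random-forest regression baseline (seed 42 default)."""
    spec = spec or RegressorSpec(kind="random_forest")
    tin, tout, x, y = _fit_transforms(paired, spec)
    forest = RandomForestRegressor(
        n_estimators=spec.hp("n_estimators", 100),
        random_state=spec.seed,
        n_jobs=1,
    )
    forest.fit(x, y)
    return FittedCrossOmicsModel(
        kind="random_forest", input_transform=tin, output_transform=tout,
        input_feature_ids=paired.input.feature_ids,
        output_feature_ids=paired.output.feature_ids, seed=spec.seed,
        estimator=forest,
    )


def augment_training_set(x: np.ndarray, y: np.ndarray, factor: int,
                         seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Expand (x, y) to ``factor`` × its size with Gaussian jitter.

    Jitter SD is 0.1 × the per-feature training SD, applied in
    transformed space to the inputs of the appended copies; outputs are
    repeated unchanged.  ``factor`` = 1 returns the data untouched.
    """
    if factor == 1:
        return x, y
    rng = np.random.default_rng(seed)
    sd = 0.1 * x.std(axis=0, ddof=0)
    xs, ys = [x], [y]
    for _ in range(factor - 1):
        xs.append(x + rng.normal(0.0, 1.0, size=x.shape) * sd)
        ys.append(y)
    return np.vstack(xs), np.vstack(ys)


def fit_mlp(paired: PairedDataset, spec: RegressorSpec | None = None
            ) -> FittedCrossOmicsModel:
    """Feed-forward multi-output regressor with optional augmentation."""
    spec = spec or RegressorSpec(kind="mlp")
    tin, tout, x, y = _fit_transforms(paired, spec)
    factor = int(spec.hp("augmentation_factor", 1))
    x_tr, y_tr = augment_training_set(x, y, factor, spec.seed)
    hidden = tuple(spec.hp("hidden_layer_sizes", (256, 128)))
    if hidden:
        net = MLPRegressor(
            hidden_layer_sizes=hidden, activation="relu", solver="adam",
            alpha=spec.hp("alpha", 1e-3),
            learning_rate_init=spec.hp("learning_rate", 1e-3),
            max_iter=spec.hp("max_iter", 400), random_state=spec.seed,
        )
    else:
        # no hidden layers: the network is exactly linear
        net = LinearRegression()
    import warnings

    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(x_tr, y_tr)
    if hidden and not np.isfinite(net.loss_):
        raise ValidationError(
            f"non-finite MLP loss after {net.n_iter_} epochs"
        )
    return FittedCrossOmicsModel(
        kind="mlp", input_transform=tin, output_transform=tout,
        input_feature_ids=paired.input.feature_ids,
        output_feature_ids=paired.output.feature_ids, seed=spec.seed,
        estimator=net,
    )


def _pca_init(x: np.ndarray, k: int) -> np.ndarray:
    _, _, vt = np.linalg.svd(x - x.mean(axis=0), full_matrices=False)
    w = vt[:k].T
    # deterministic sign: largest-magnitude loading positive per component
    signs = np.sign(w[np.abs(w).argmax(axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    return w * signs


def fit_autoencoder_then_regress(
    paired: PairedDataset, spec: RegressorSpec | None = None
) -> FittedCrossOmicsModel:
    """Joint-loss linear autoencoder, then elastic net on the latents.

    Minimises ``||X − XWV||² + λ·||Y − XWU||²`` by alternating exact
    least-squares updates of the decoder/regression head (V, U) and the
    encoder (W); the loss recorded after each cycle is non-increasing.
    The elastic net is then fitted on the frozen latent features XW.
    """
    spec = spec or RegressorSpec(kind="autoencoder_then_elastic_net")
    if paired.input.modality != "concat":
        raise ValidationError(
            "autoencoder model requires multi-omics (concatenated) input"
        )
    tin, tout, x, y = _fit_transforms(paired, spec)
    k = int(spec.hp("latent_dim", 16))
    if k >= x.shape[1]:
        raise ValidationError(
            f"latent dimension {k} >= input dimension {x.shape[1]}"
        )
    lam = float(spec.hp("loss_weight", 1.0))
    epochs = int(spec.hp("epochs", 30))

    w = _pca_init(x, k)
    gram = x.T @ x
    losses = []
    for _ in range(epochs):
        latent = x @ w
        v, *_ = np.linalg.lstsq(latent, x, rcond=None)
        u, *_ = np.linalg.lstsq(latent, y, rcond=None)
        m = v @ v.T + lam * (u @ u.T)
        c = gram @ v.T + lam * (x.T @ y @ u.T)
        w = np.linalg.pinv(gram) @ c @ np.linalg.pinv(m)
        latent = x @ w
        recon = latent @ v
        loss = float(((x - recon) ** 2).sum()
                     + lam * ((y - latent @ u) ** 2).sum())
        losses.append(loss)

    latent = x @ w
    en_spec = RegressorSpec(kind="elastic_net", seed=spec.seed,
                            hyperparameters=spec.hyperparameters)
    coefs, intercepts, chosen, constant = _elastic_net_per_output(
        latent, y, paired.output.feature_ids, paired, en_spec
    )
    return FittedCrossOmicsModel(
        kind="autoencoder_then_elastic_net", input_transform=tin,
        output_transform=tout,
        input_feature_ids=paired.input.feature_ids,
        output_feature_ids=paired.output.feature_ids, seed=spec.seed,
        coefficients=coefs, intercepts=intercepts, alphas=chosen,
        constant_outputs=constant, encoder=w, training_loss=losses,
    )


FITTERS = {
    "elastic_net": fit_elastic_net,
    "random_forest": fit_random_forest,
    "mlp": fit_mlp,
    "autoencoder_then_elastic_net": fit_autoencoder_then_regress,
}


def fit(paired: PairedDataset, spec: RegressorSpec) -> FittedCrossOmicsModel:
    return FITTERS[spec.kind](paired, spec)


def predict(model: FittedCrossOmicsModel, table: AbundanceTable) -> pd.DataFrame:
    """Module-level alias for :meth:`FittedCrossOmicsModel.predict`."""
    return model.predict(table)


@dataclass
class FeatureSelection:
    """Result of the random-forest pre-training feature-selection step."""

    ranked_ids: list[str]
    fold_scores: pd.DataFrame  # features × folds
    mean_scores: pd.Series
    selected_ids: list[str]


def pretrain_feature_selection(
    paired: PairedDataset,
    keep_fraction: float,
    k_folds: int = 10,
    spec: RegressorSpec | None = None,
) -> FeatureSelection:
    """Rank output features by cross-validated random-forest predictability.

    Fits one forest per fold on the fold's training part, scores
    per-feature Spearman on the fold's validation part, averages scores
    across folds, and returns the top ``keep_fraction`` of features
    (descending mean score, ties broken by feature id order).  Applies
    to the training partition only.
    """
    spec = spec or RegressorSpec(kind="random_forest")
    output_ids = paired.output.feature_ids
    n_keep = int(np.floor(keep_fraction * len(output_ids)))
    if n_keep < 1:
        raise ValidationError(
            f"keep_fraction {keep_fraction} retains no feature "
            f"out of {len(output_ids)}"
        )
    folds = _group_kfold(paired, k_folds, spec.seed)
    samples = paired.sample_ids
    scores = {}
    for f, (tr, va) in enumerate(folds):
        sub_train = paired.select_samples([samples[i] for i in tr])
        sub_val_in = paired.input.select_samples([samples[i] for i in va])
        sub_val_out = paired.output.select_samples([samples[i] for i in va])
        model = fit_random_forest(sub_train, spec)
        pred = model.predict(sub_val_in)
        truth = model.transform_output(sub_val_out)
        scores[f] = evaluation.per_feature_spearman(pred, truth)
    fold_scores = pd.DataFrame(scores)
    mean_scores = fold_scores.mean(axis=1)
    order = sorted(output_ids, key=lambda f: (-mean_scores[f], f))
    return FeatureSelection(
        ranked_ids=order,
        fold_scores=fold_scores,
        mean_scores=mean_scores,
        selected_ids=order[:n_keep],
    )
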