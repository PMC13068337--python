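"""Synthetic paired multi-omics cohorts with planted ground truth.

The generator emulates the statistical regime of paired gut-microbiome
meta-omics tables: compositional rows summing to 1, zero inflation,
many more features than samples, longitudinal samples nested within
patients, a sparse planted dependency of a subset of output features on
the input modality, and a diagnosis-linked shift on a subset of
features.  It is a stand-in: no generative description of real cohorts
is available, so all distributional choices are declared and documented
rather than estimated.

Generative model
----------------
Input features carry log-normal latent intensities

    z_si = mu_i + a_{patient(s)} + class_shift_i(s) + e_si,

with feature baselines ``mu_i ~ N(0, 1)``, a patient-level intercept
``a_p ~ N(0, patient_sd^2)`` shared by all of a patient's samples, and
``e_si ~ N(0, 1)``.  Each planted signal output is a sparse linear
combination of input latents plus Gaussian noise whose variance is set
so that var(signal) / var(noise) equals ``signal_strength``; remaining
outputs are independent noise.  Class-affected features receive an
additive log-scale shift of ``class_effect_size`` for IBD (UC/CD)
samples, applied in both the input and the output modality (output
class features are drawn from the signal outputs first, so the class
signal is predictable from the inputs).  Latents are exponentiated,
zeroed to the target per-feature sparsity, and closed to sum 1.

Zeros default to detection-limit censoring (the lowest-intensity
entries of each feature fall below the detection limit), which mirrors
how zeros arise in sequencing and MS data and preserves the monotone
planted map; independent Bernoulli presence masks are available via
``zero_mechanism="bernoulli"``.

All randomness flows from a single seed split into named substreams
(intensity, presence, noise, labels), so one component's draw count
changing does not perturb the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AbundanceTable, SampleMetadata, ValidationError
from . import io_prep

_SUBSTREAMS = ("labels", "intensity", "presence", "noise")


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic paired cohort.

    Defaults produce the package's reference recovery fixture: 40
    patients × 5 visits = 200 samples, 100 input (mGx) and 50 output
    (mBx) features, 10 signal outputs at signal-to-noise ratio 5, and a
    log-scale class shift of 1.0 on 10 features per modality.
    """

    n_patients: int = 40
    samples_per_patient: int | tuple[int, int] = 5
    n_features: dict[str, int] = field(
        default_factory=lambda: {"mGx": 100, "mBx": 50}
    )
    sparsity: dict[str, float] = field(
        default_factory=lambda: {"mGx": 0.0, "mBx": 0.0}
    )
    n_signal_outputs: int = 10
    signal_strength: float = 5.0
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {"UC": 0.3, "CD": 0.3, "HC": 0.4}
    )
    n_class_features: int = 10
    class_effect_size: float = 1.0
    n_parents: int = 5  # nonzero inputs per signal output
    patient_sd: float = 0.5
    zero_mechanism: str = "censor"  # "censor" | "bernoulli"
    seed: int = 0

    @property
    def input_modality(self) -> str:
        return list(self.n_features)[0]

    @property
    def output_modality(self) -> str:
        return list(self.n_features)[1]

    def validate(self) -> None:
        if len(self.n_features) != 2:
            raise ValidationError("exactly one input and one output modality")
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValidationError("class_proportions must sum to 1")
        if set(self.class_proportions) != {"UC", "CD", "HC"}:
            raise ValidationError("class_proportions must cover UC, CD, HC")
        for m, s in self.sparsity.items():
            if not (0.0 <= s < 1.0):
                raise ValidationError(f"sparsity[{m}]={s} outside [0, 1)")
        n_out = self.n_features[self.output_modality]
        if self.n_signal_outputs > n_out:
            raise ValidationError(
                f"n_signal_outputs={self.n_signal_outputs} > {n_out} outputs"
            )
        for m, p in self.n_features.items():
            if self.n_class_features > p:
                raise ValidationError(
                    f"n_class_features={self.n_class_features} > {p} "
                    f"features of {m}"
                )
        if self.n_parents > self.n_features[self.input_modality]:
            raise ValidationError("n_parents exceeds input feature count")
        n_samples = self._n_samples_upper()
        for m, s in self.sparsity.items():
            if s > 0 and round(s * n_samples) >= n_samples:
                raise ValidationError(
                    f"sparsity[{m}]={s} would zero a feature in every sample"
                )
        if self.zero_mechanism not in ("censor", "bernoulli"):
            raise ValidationError(
                f"unknown zero_mechanism {self.zero_mechanism!r}"
            )
        if self.signal_strength <= 0:
            raise ValidationError("signal_strength must be positive")

    def _n_samples_upper(self) -> int:
        if isinstance(self.samples_per_patient, int):
            return self.n_patients * self.samples_per_patient
        return self.n_patients * self.samples_per_patient[0]


@dataclass
class SyntheticTruth:
    """Planted generative parameters for parameter-recovery tests."""

    coefficients: pd.DataFrame  # output features × input features, sparse
    signal_output_ids: list[str]
    class_feature_ids: dict[str, list[str]]  # modality → feature ids
    patient_assignments: dict[str, str]  # patient → diagnosis

    def __post_init__(self) -> None:
        signal = set(self.signal_output_ids)
        rows = self.coefficients.abs().sum(axis=1)
        nonzero = set(rows.index[rows > 0])
        if nonzero != signal:
            raise ValidationError(
                "nonzero coefficient rows must be exactly the signal outputs"
            )

    def save(self, path) -> None:
        payload = {
            "coefficients": {
                "index": list(self.coefficients.index),
                "columns": list(self.coefficients.columns),
                "values": self.coefficients.to_numpy().tolist(),
            },
            "signal_output_ids": self.signal_output_ids,
            "class_feature_ids": self.class_feature_ids,
            "patient_assignments": self.patient_assignments,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        coef = pd.DataFrame(
            payload["coefficients"]["values"],
            index=payload["coefficients"]["index"],
            columns=payload["coefficients"]["columns"],
        )
        return cls(coef, payload["signal_output_ids"],
                   payload["class_feature_ids"], payload["patient_assignments"])


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    seqs = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(s) for name, s in zip(_SUBSTREAMS, seqs)}


def _apply_zeros(abund: np.ndarray, sparsity: float, mechanism: str,
                 rng: np.random.Generator) -> np.ndarray:
    """Zero entries per feature to hit the target sparsity."""
    if sparsity <= 0:
        return abund
    n = abund.shape[0]
    out = abund.copy()
    if mechanism == "censor":
        k = int(round(sparsity * n))
        if k:
            order = np.argsort(abund, axis=0, kind="stable")
            rows = order[:k, :]
            cols = np.broadcast_to(np.arange(abund.shape[1]), rows.shape)
            out[rows, cols] = 0.0
    else:
        mask = rng.random(abund.shape) < sparsity
        out[mask] = 0.0
    return out


def generate_paired(
    config: SyntheticConfig,
) -> tuple[dict[str, AbundanceTable], SampleMetadata, SyntheticTruth]:
    """Generate one paired synthetic cohort; deterministic given the seed."""
    config.validate()
    rngs = _substreams(config.seed)
    in_mod, out_mod = config.input_modality, config.output_modality
    p_in = config.n_features[in_mod]
    p_out = config.n_features[out_mod]

    # --- patients, visits, labels --------------------------------------
    rng_lab = rngs["labels"]
    patients = [f"P{i:03d}" for i in range(config.n_patients)]
    classes = sorted(config.class_proportions)  # CD, HC, UC
    counts = {c: int(np.floor(config.class_proportions[c] * config.n_patients))
              for c in classes}
    remainder = config.n_patients - sum(counts.values())
    frac = {c: config.class_proportions[c] * config.n_patients - counts[c]
            for c in classes}
    for c in sorted(classes, key=lambda c: -frac[c])[:remainder]:
        counts[c] += 1
    label_pool = [c for c in classes for _ in range(counts[c])]
    rng_lab.shuffle(label_pool)
    assignments = dict(zip(patients, label_pool))

    if isinstance(config.samples_per_patient, int):
        visits = {p: config.samples_per_patient for p in patients}
    else:
        lo, hi = config.samples_per_patient
        visits = {p: int(rng_lab.integers(lo, hi + 1)) for p in patients}
    sample_rows = []
    for p in patients:
        for v in range(visits[p]):
            sample_rows.append((f"{p}_V{v}", p, assignments[p], v))
    meta = pd.DataFrame(
        sample_rows, columns=["sample_id", "patient_id", "diagnosis", "visit"]
    ).set_index("sample_id")
    metadata = SampleMetadata(meta)
    n_samples = len(meta)
    ibd = meta["diagnosis"].isin(["UC", "CD"]).to_numpy().astype(float)

    in_ids = [f"{in_mod}_f{i:03d}" for i in range(p_in)]
    out_ids = [f"{out_mod}_f{j:03d}" for j in range(p_out)]

    # --- planted structure ---------------------------------------------
    rng_int = rngs["intensity"]
    signal_idx = rng_int.choice(p_out, size=config.n_signal_outputs,
                                replace=False)
    signal_idx = np.sort(signal_idx)
    coef = np.zeros((p_out, p_in))
    for j in signal_idx:
        parents = rng_int.choice(p_in, size=config.n_parents, replace=False)
        weights = rng_int.uniform(0.5, 1.5, size=config.n_parents)
        weights *= rng_int.choice([-1.0, 1.0], size=config.n_parents)
        coef[j, parents] = weights / np.sqrt(config.n_parents)

    # class-affected features: output side drawn from signal outputs first
    n_cls = config.n_class_features
    out_signal = list(signal_idx)
    out_rest = [j for j in range(p_out) if j not in set(out_signal)]
    cls_out = (out_signal + out_rest)[:n_cls]
    cls_in = list(rng_int.choice(p_in, size=n_cls, replace=False))

    # --- input latents --------------------------------------------------
    mu_in = rng_int.normal(0.0, 1.0, size=p_in)
    intercepts = {p: rng_int.normal(0.0, config.patient_sd) for p in patients}
    a = np.array([intercepts[pid] for pid in meta["patient_id"]])
    z = (mu_in[None, :] + a[:, None]
         + rngs["noise"].normal(0.0, 1.0, size=(n_samples, p_in)))
    z[:, cls_in] += config.class_effect_size * ibd[:, None]

    # --- output latents -------------------------------------------------
    rng_noise = rngs["noise"]
    mu_out = rng_int.normal(0.0, 1.0, size=p_out)
    t = np.empty((n_samples, p_out))
    # planted map acts on row-centered latents: centering is what survives
    # closure + CLR, so the dependency is exactly linear in CLR space
    z_centered = z - z.mean(axis=1, keepdims=True)
    lin = z_centered @ coef.T
    for j in range(p_out):
        if j in set(signal_idx):
            sd = lin[:, j].std(ddof=0) / np.sqrt(config.signal_strength)
            t[:, j] = lin[:, j] + rng_noise.normal(0.0, sd, size=n_samples)
        else:
            t[:, j] = mu_out[j] + rng_noise.normal(0.0, 1.0, size=n_samples)
    t[:, cls_out] += config.class_effect_size * ibd[:, None]

    # --- observation: exponentiate, zero, close -------------------------
    tables = {}
    for mod, latent, ids in ((in_mod, z, in_ids), (out_mod, t, out_ids)):
        abund = np.exp(latent)
        # censor on the composition: detection depends on relative
        # abundance, and closure cancels sample-level (depth/intercept)
        # effects that would otherwise zero out whole samples
        abund = abund / abund.sum(axis=1, keepdims=True)
        abund = _apply_zeros(abund, config.sparsity.get(mod, 0.0),
                             config.zero_mechanism, rngs["presence"])
        if (abund.sum(axis=1) == 0).any():
            raise ValidationError(
                f"sparsity configuration left an all-zero sample in {mod}"
            )
        closed = abund / abund.sum(axis=1, keepdims=True)
        tables[mod] = AbundanceTable(
            pd.DataFrame(closed, index=meta.index, columns=ids),
            modality=mod, scale="relative", normalized=True,
        )

    truth = SyntheticTruth(
        coefficients=pd.DataFrame(coef, index=out_ids, columns=in_ids),
        signal_output_ids=[out_ids[j] for j in signal_idx],
        class_feature_ids={
            in_mod: sorted(in_ids[i] for i in cls_in),
            out_mod: sorted(out_ids[j] for j in cls_out),
        },
        patient_assignments=assignments,
    )
    return tables, metadata, truth


def write_dataset(tables, metadata, truth, out_dir) -> None:
    """Write tables (TSV), metadata (TSV) and truth (JSON) to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for mod, table in tables.items():
        io_prep.write_table(table, out_dir / f"{mod}.tsv")
    io_prep.write_metadata(metadata, out_dir / "metadata.tsv")
    truth.save(out_dir / "truth.json")
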