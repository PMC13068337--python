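"""Compositional and distributional feature transforms.

Three transforms used before model fitting:

* ``clr`` — centered log-ratio, ``clr(x)_i = log(x_i / g(x))`` with
  ``g`` the row geometric mean.  Requires strictly positive closed rows
  (impute zeros first); every output row sums to 0.
* ``arcsin_sqrt`` — ``arcsin(sqrt(x_i))`` on relative abundances in
  [0, 1]; handles zeros without imputation.
* ``quantile_to_normal`` — per-feature empirical quantile map to the
  standard normal, fitted on training samples only.  The convention is
  pinned for bit-stability: training values receive plotting positions
  ``(rank − 0.5) / n`` (average positions for ties), unseen values are
  clamped to the training range and mapped by linear interpolation
  between training quantiles before applying the normal quantile
  function.

All transforms are exposed through a common fit/apply object so the
pipeline can freeze training-time state and re-apply it to unseen
samples; fitted state serializes to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy import stats

from .containers import ValidationError

TRANSFORM_KINDS = ("clr", "arcsin", "quantile", "identity")


def clr(matrix: np.ndarray, atol: float = 1e-6) -> np.ndarray:
    """Centered log-ratio of strictly positive composition rows."""
    x = np.asarray(matrix, dtype=float)
    if (x <= 0).any():
        raise ValidationError(
            "CLR requires strictly positive entries; impute zeros first"
        )
    sums = x.sum(axis=1)
    if np.abs(sums - 1.0).max() > atol:
        raise ValidationError("CLR input rows must sum to 1 (normalize first)")
    logx = np.log(x)
    return logx - logx.mean(axis=1, keepdims=True)


def arcsin_sqrt(matrix: np.ndarray) -> np.ndarray:
    """arcsin(sqrt(x)) elementwise; requires entries in [0, 1]."""
    x = np.asarray(matrix, dtype=float)
    if (x < 0).any() or (x > 1).any():
        raise ValidationError("arcsin-sqrt requires entries in [0, 1]")
    return np.arcsin(np.sqrt(x))


class FittedTransform:
    """Common fit/apply interface over the four transform kinds."""

    def __init__(self, kind: str):
        if kind not in TRANSFORM_KINDS:
            raise ValidationError(f"unknown transform kind {kind!r}")
        self.kind = kind
        self._state: dict | None = None
        self.constant_features: list[int] = []

    # -- fitting ---------------------------------------------------------
    def fit(self, train_matrix: np.ndarray) -> "FittedTransform":
        x = np.asarray(train_matrix, dtype=float)
        if self.kind == "quantile":
            self._fit_quantile(x)
        else:
            self._state = {"n_features": x.shape[1]}
        return self

    def _fit_quantile(self, x: np.ndarray) -> None:
        n, p = x.shape
        sorted_vals, scores = [], []
        self.constant_features = []
        for j in range(p):
            col = x[:, j]
            order = np.sort(col)
            if order[0] == order[-1]:
                self.constant_features.append(j)
                sorted_vals.append(np.array([order[0]]))
                scores.append(np.array([0.0]))
                continue
            # plotting positions with average positions for tied values
            pp = (np.arange(1, n + 1) - 0.5) / n
            uniq, inverse = np.unique(order, return_inverse=True)
            pos = np.bincount(inverse, weights=pp) / np.bincount(inverse)
            sorted_vals.append(uniq)
            scores.append(stats.norm.ppf(pos))
        self._state = {
            "n_features": p,
            "values": sorted_vals,
            "scores": scores,
        }
        if self.constant_features:
            import warnings

            warnings.warn(
                f"{len(self.constant_features)} constant training feature(s) "
                "mapped to all-zeros by the quantile transform"
            )

    # -- application -----------------------------------------------------
    def apply(self, matrix: np.ndarray) -> np.ndarray:
        if self._state is None:
            raise ValidationError("transform not fitted")
        x = np.asarray(matrix, dtype=float)
        if x.shape[1] != self._state["n_features"]:
            raise ValidationError(
                f"feature count {x.shape[1]} != fitted "
                f"{self._state['n_features']}"
            )
        if self.kind == "identity":
            return x.copy()
        if self.kind == "clr":
            return clr(x)
        if self.kind == "arcsin":
            return arcsin_sqrt(x)
        out = np.empty_like(x)
        for j in range(x.shape[1]):
            vals = np.asarray(self._state["values"][j])
            scr = np.asarray(self._state["scores"][j])
            if len(vals) == 1:  # constant training feature
                out[:, j] = 0.0
                continue
            clamped = np.clip(x[:, j], vals[0], vals[-1])
            out[:, j] = np.interp(clamped, vals, scr)
        return out

    def fit_apply(self, train_matrix: np.ndarray) -> np.ndarray:
        return self.fit(train_matrix).apply(train_matrix)

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        state = None
        if self._state is not None:
            state = {"n_features": self._state["n_features"]}
            if self.kind == "quantile":
                state["values"] = [v.tolist() for v in self._state["values"]]
                state["scores"] = [s.tolist() for s in self._state["scores"]]
        return json.dumps(
            {"kind": self.kind, "state": state,
             "constant_features": self.constant_features}
        )

    @classmethod
    def from_json(cls, text: str) -> "FittedTransform":
        payload = json.loads(text)
        t = cls(payload["kind"])
        t.constant_features = payload.get("constant_features", [])
        state = payload["state"]
        if state is not None:
            t._state = {"n_features": state["n_features"]}
            if t.kind == "quantile":
                t._state["values"] = [np.asarray(v) for v in state["values"]]
                t._state["scores"] = [np.asarray(s) for s in state["scores"]]
        return t

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "FittedTransform":
        return cls.from_json(Path(path).read_text())
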