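"""One-against-all multiclass SVM with a Gaussian RBF kernel.

One soft-margin binary SVM per class (class vs rest) on standardized
features; prediction takes the class whose decision function is largest,
ties broken by the lowest class id. The kernel is

    k(xa, xb) = exp(-||xa - xb||^2 / (2 gamma^2)),

so gamma is a length scale in standardized feature units. The binary
subproblems are solved by scikit-learn's SVC (libsvm); decision values
are then evaluated from the extracted support vectors, dual coefficients
and intercept, so a model serialized to JSON and reloaded reproduces the
in-memory decision values exactly.

Gamma selection modes:

* ``fixed`` — use ``SvmConfig.gamma`` as given;
* ``median-heuristic`` (default) — median pairwise Euclidean distance of
  a seeded subsample of <= 500 standardized training rows;
* ``inverse-dim-variance`` — gamma = sqrt(d * mean feature variance / 2),
  equivalent to scikit-learn's ``gamma='scale'`` in this parameterization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

GAMMA_MODES = ("fixed", "median-heuristic", "inverse-dim-variance")
_MEDIAN_SUBSAMPLE = 500


@dataclass
class SvmConfig:
    gamma_mode: str = "median-heuristic"
    gamma: float | None = None
    c_penalty: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma_mode not in GAMMA_MODES:
            raise ValueError(f"gamma_mode must be one of {GAMMA_MODES}, got {self.gamma_mode!r}")
        if self.gamma_mode == "fixed" and (self.gamma is None or self.gamma <= 0):
            raise ValueError("fixed gamma_mode requires gamma > 0")
        if not (self.c_penalty > 0):
            raise ValueError(f"c_penalty must be > 0, got {self.c_penalty}")


def rbf_kernel(xa: np.ndarray, xb: np.ndarray, gamma: float) -> float:
    """Gaussian RBF similarity exp(-||xa - xb||^2 / (2 gamma^2))."""
    a = np.asarray(xa, dtype=float)
    b = np.asarray(xb, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if not (gamma > 0):
        raise ValueError(f"gamma must be > 0, got {gamma}")
    return float(np.exp(-np.sum((a - b) ** 2) / (2.0 * gamma**2)))


def _rbf_gram(xa: np.ndarray, xb: np.ndarray, gamma: float) -> np.ndarray:
    """Pairwise kernel matrix between row sets (vectorized)."""
    sq = (
        np.sum(xa**2, axis=1)[:, None]
        + np.sum(xb**2, axis=1)[None, :]
        - 2.0 * xa @ xb.T
    )
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-sq / (2.0 * gamma**2))


@dataclass
class _BinarySvm:
    """One class-vs-rest decision function in support-vector form."""

    support_vectors: np.ndarray  # (n_sv, d), standardized space
    dual_coef: np.ndarray  # (n_sv,)
    intercept: float

    def decision_values(self, x_std: np.ndarray, gamma: float) -> np.ndarray:
        k = _rbf_gram(x_std, self.support_vectors, gamma)
        return k @ self.dual_coef + self.intercept


@dataclass
class OaaModel:
    binary_models: list[_BinarySvm]
    class_ids: np.ndarray
    config: SvmConfig  # gamma resolved to the value actually used
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    input_dim: int = field(init=False)

    def __post_init__(self) -> None:
        self.input_dim = int(self.scaler_mean.shape[0])

    def _standardize(self, features: np.ndarray) -> np.ndarray:
        X = np.asarray(features, dtype=float)
        if X.ndim != 2:
            raise ValueError(f"features must be 2-D, got shape {X.shape}")
        if X.shape[1] != self.input_dim:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match training dimension {self.input_dim}"
            )
        return (X - self.scaler_mean) / self.scaler_scale

    def decision_matrix(self, features: np.ndarray) -> np.ndarray:
        """Per-class decision values, one column per class id."""
        x_std = self._standardize(features)
        if x_std.shape[0] == 0:
            return np.empty((0, len(self.binary_models)))
        return np.column_stack(
            [m.decision_values(x_std, self.config.gamma) for m in self.binary_models]
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "class_ids": self.class_ids.tolist(),
            "gamma": self.config.gamma,
            "gamma_mode": self.config.gamma_mode,
            "c_penalty": self.config.c_penalty,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "binary_models": [
                {
                    "support_vectors": m.support_vectors.tolist(),
                    "dual_coef": m.dual_coef.tolist(),
                    "intercept": m.intercept,
                }
                for m in self.binary_models
            ],
        }
        text = json.dumps(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "OaaModel":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text()
        else:
            text = str(source)
        d = json.loads(text)
        return cls(
            binary_models=[
                _BinarySvm(
                    support_vectors=np.array(m["support_vectors"], dtype=float),
                    dual_coef=np.array(m["dual_coef"], dtype=float),
                    intercept=float(m["intercept"]),
                )
                for m in d["binary_models"]
            ],
            class_ids=np.array(d["class_ids"], dtype=int),
            config=SvmConfig(
                gamma_mode="fixed", gamma=float(d["gamma"]), c_penalty=float(d["c_penalty"])
            ),
            scaler_mean=np.array(d["scaler_mean"], dtype=float),
            scaler_scale=np.array(d["scaler_scale"], dtype=float),
        )


def resolve_gamma(x_std: np.ndarray, config: SvmConfig, seed: int) -> float:
    """Concrete kernel width for standardized training features."""
    if config.gamma_mode == "fixed":
        return float(config.gamma)
    if config.gamma_mode == "inverse-dim-variance":
        var = float(x_std.var(axis=0).mean())
        g = np.sqrt(x_std.shape[1] * var / 2.0)
        return float(g) if g > 0 else 1.0
    rng = np.random.default_rng(seed)
    n = x_std.shape[0]
    if n > _MEDIAN_SUBSAMPLE:
        idx = rng.choice(n, _MEDIAN_SUBSAMPLE, replace=False)
        sub = x_std[idx]
    else:
        sub = x_std
    iu = np.triu_indices(sub.shape[0], k=1)
    dists = np.sqrt(
        np.maximum(
            np.sum(sub**2, axis=1)[:, None]
            + np.sum(sub**2, axis=1)[None, :]
            - 2.0 * sub @ sub.T,
            0.0,
        )
    )[iu]
    dists = dists[dists > 0]
    return float(np.median(dists)) if dists.size else 1.0


def train_oaa(
    features: np.ndarray,
    labels: np.ndarray,
    config: SvmConfig | None = None,
    seed: int = 0,
) -> OaaModel:
    """Train one class-vs-rest RBF SVM per class on standardized features."""
    if config is None:
        config = SvmConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("features must be 2-D with one label per row")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError(f"need >= 2 classes, got {classes.size}")
    small = classes[counts < 2]
    if small.size:
        raise ValueError(f"class {small[0]} has fewer than 2 samples")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0  # zero-variance features pass through unscaled
    x_std = (X - mean) / scale
    gamma = resolve_gamma(x_std, config, seed)
    resolved = replace(config, gamma_mode="fixed", gamma=gamma)
    sk_gamma = 1.0 / (2.0 * gamma**2)  # sklearn parameterization
    binaries = []
    for c in classes:
        svc = SVC(
            kernel="rbf", gamma=sk_gamma, C=config.c_penalty, random_state=seed
        )
        svc.fit(x_std, (y == c).astype(int))
        binaries.append(
            _BinarySvm(
                support_vectors=svc.support_vectors_.copy(),
                dual_coef=svc.dual_coef_[0].copy(),
                intercept=float(svc.intercept_[0]),
            )
        )
    return OaaModel(
        binary_models=binaries,
        class_ids=classes,
        config=resolved,
        scaler_mean=mean,
        scaler_scale=scale,
    )


def predict(model: OaaModel, features: np.ndarray) -> np.ndarray:
    """Argmax over per-class decision values; ties -> lowest class id."""
    decisions = model.decision_matrix(features)
    if decisions.shape[0] == 0:
        return np.empty(0, dtype=int)
    return model.class_ids[np.argmax(decisions, axis=1)]
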