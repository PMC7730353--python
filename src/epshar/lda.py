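"""Fisher linear discriminant analysis with scatter matrices.

Given feature vectors x_n with class labels, the within-class scatter is
S_w = sum_k S_k with S_k = sum_{n in C_k} (x_n - m_k)(x_n - m_k)^T, the
between-class scatter S_B = sum_k N_k (m_k - m)(m_k - m)^T, and the total
scatter obeys S_T = S_B + S_w. The projection W maximizes the Rayleigh
quotient tr[(W S_w W^T)^{-1} (W S_B W^T)]; its rows are the eigenvectors
of the symmetric-definite generalized problem S_B w = lambda (S_w + eI) w,
sorted by eigenvalue. Coefficients are y = W x.

All input_dim directions are returned, not only the K-1 with nonzero
between-class rank: the trailing directions carry near-zero eigenvalues
and serve the "how many features" sweep, where performance degrades as
noise directions are added. A scaled ridge e = 1e-6 tr(S_w)/d regularizes
S_w, which is always singular when dimensionality exceeds N - K (the
usual case for spectrum features).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import linalg

DEFAULT_REG_SCALE = 1e-6


@dataclass
class ScatterSet:
    """Class means and within/between/total scatter matrices."""

    class_means: np.ndarray  # (K, d)
    global_mean: np.ndarray  # (d,)
    within: np.ndarray  # S_w, (d, d)
    between: np.ndarray  # S_B, (d, d)
    total: np.ndarray  # S_T, (d, d)
    counts: np.ndarray  # N_k, (K,)
    n_total: int
    n_classes: int


@dataclass
class LdaModel:
    """Fitted discriminant projection.

    ``projection`` has one unit-norm row per direction (directions x
    input_dim), rows ordered by descending eigenvalue, sign fixed so the
    first non-negligible component of each row is positive.
    ``raw_projection`` keeps the solver's (S_w + eI)-orthonormal rows
    before sign fixing and normalization.
    """

    projection: np.ndarray
    eigenvalues: np.ndarray
    regularization: float
    input_dim: int
    n_classes: int
    raw_projection: np.ndarray | None = None

    def transform(self, features: np.ndarray, n_features: int) -> np.ndarray:
        return transform(self, features, n_features)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "projection": self.projection.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "regularization": self.regularization,
            "input_dim": self.input_dim,
            "n_classes": self.n_classes,
        }
        text = json.dumps(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LdaModel":
        text = Path(source).read_text() if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ) else source
        d = json.loads(text)
        return cls(
            projection=np.array(d["projection"], dtype=float),
            eigenvalues=np.array(d["eigenvalues"], dtype=float),
            regularization=float(d["regularization"]),
            input_dim=int(d["input_dim"]),
            n_classes=int(d["n_classes"]),
        )


def _check_features(features: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2:
        raise ValueError(f"features must be 2-D, got shape {X.shape}")
    if y.shape != (X.shape[0],):
        raise ValueError(f"labels shape {y.shape} does not match {X.shape[0]} rows")
    if not np.isfinite(X).all():
        raise ValueError("features contain non-finite values")
    return X, y


def compute_scatter(features: np.ndarray, labels: np.ndarray) -> ScatterSet:
    """Within/between/total scatter matrices and class means."""
    X, y = _check_features(features, labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError(f"need >= 2 classes, got {classes.size}")
    if (counts < 1).any():
        raise ValueError("every class needs >= 1 sample")
    d = X.shape[1]
    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    m = (counts[:, None] * means).sum(axis=0) / counts.sum()
    s_w = np.zeros((d, d))
    for c, mk in zip(classes, means):
        dev = X[y == c] - mk
        s_w += dev.T @ dev
    dev_b = means - m
    s_b = (counts[:, None] * dev_b).T @ dev_b
    # symmetrize: accumulation order can leave ~eps asymmetry
    s_w = (s_w + s_w.T) / 2
    s_b = (s_b + s_b.T) / 2
    return ScatterSet(
        class_means=means,
        global_mean=m,
        within=s_w,
        between=s_b,
        total=s_b + s_w,
        counts=counts,
        n_total=int(counts.sum()),
        n_classes=int(classes.size),
    )


def default_regularization(scatter: ScatterSet) -> float:
    """Scaled ridge e = 1e-6 tr(S_w)/d (0 only if S_w is identically 0)."""
    d = scatter.within.shape[0]
    return DEFAULT_REG_SCALE * float(np.trace(scatter.within)) / d


def fit_lda(
    features: np.ndarray,
    labels: np.ndarray,
    regularization: float | None = None,
) -> LdaModel:
    """Fit the Fisher discriminant projection.

    Solves S_B w = lambda (S_w + eI) w for all input_dim directions. With
    ``regularization=None`` the scaled-ridge default is used; an explicit
    0 is honoured only when S_w is nonsingular.
    """
    X, y = _check_features(features, labels)
    scatter = compute_scatter(X, y)
    eps = default_regularization(scatter) if regularization is None else float(regularization)
    if eps < 0:
        raise ValueError(f"regularization must be >= 0, got {eps}")
    d = scatter.within.shape[0]
    s_w_reg = scatter.within + eps * np.eye(d)
    try:
        linalg.cholesky(s_w_reg, lower=True)
    except linalg.LinAlgError:
        raise ValueError(
            "within-class scatter is singular; set regularization > 0 "
            "(default is 1e-6 * trace(S_w)/d)"
        ) from None
    eigvals, eigvecs = linalg.eigh(scatter.between, s_w_reg)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    raw = eigvecs[:, order].T  # rows are directions, (S_w + eI)-orthonormal
    signed = raw.copy()
    for i, row in enumerate(signed):
        nz = np.flatnonzero(np.abs(row) > 1e-12 * max(np.abs(row).max(), 1e-300))
        if nz.size and row[nz[0]] < 0:
            signed[i] = -row
    norms = np.linalg.norm(signed, axis=1)
    norms[norms == 0] = 1.0
    projection = signed / norms[:, None]
    return LdaModel(
        projection=projection,
        eigenvalues=eigvals,
        regularization=eps,
        input_dim=d,
        n_classes=scatter.n_classes,
        raw_projection=raw,
    )


def transform(model: LdaModel, features: np.ndarray, n_features: int) -> np.ndarray:
    """Project rows onto the top ``n_features`` discriminant directions."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"features must be 2-D, got shape {X.shape}")
    if X.shape[1] != model.input_dim:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model input_dim {model.input_dim}"
        )
    n_dirs = model.projection.shape[0]
    if not (1 <= n_features <= n_dirs):
        raise ValueError(f"n_features must be in [1, {n_dirs}], got {n_features}")
    return X @ model.projection[:n_features].T
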