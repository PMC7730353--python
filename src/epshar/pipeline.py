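"""EPS -> LDA -> OAA-SVM pipeline glue.

A :class:`PipelineConfig` collects the knobs of every stage; ``fit`` runs
feature extraction on the training windows, fits the discriminant
projection and the multiclass SVM, and the resulting
:class:`TrainedPipeline` maps raw windows to predicted class ids. All
data-dependent state (LDA projection, feature scaler, kernel width,
support vectors) is estimated from the training set only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import lda as lda_mod
from . import mcsvm
from .eps import eps_feature_matrix
from .io_signals import LabeledDataset


@dataclass
class PipelineConfig:
    """Configuration of the full classification pipeline.

    ``n_features`` is the discriminant coefficient count kept after LDA
    ("all" keeps every direction). ``lda_regularization=None`` selects the
    scaled-ridge default.
    """

    channel_order: Sequence[int] | None = None
    envelope_enabled: bool = True
    lda_regularization: float | None = None
    n_features: int | str = 5
    svm: mcsvm.SvmConfig = field(default_factory=mcsvm.SvmConfig)
    averaging: str = "macro"

    def __post_init__(self) -> None:
        if isinstance(self.n_features, str) and self.n_features != "all":
            raise ValueError(f"n_features must be an integer or 'all', got {self.n_features!r}")
        if self.averaging not in ("macro", "micro"):
            raise ValueError(f"averaging must be 'macro' or 'micro', got {self.averaging!r}")


@dataclass
class TrainedPipeline:
    config: PipelineConfig
    lda_model: lda_mod.LdaModel
    svm_model: mcsvm.OaaModel
    n_features: int  # resolved ("all" -> direction count)

    def reduce(self, dataset: LabeledDataset) -> tuple[np.ndarray, np.ndarray]:
        """EPS features projected onto the top discriminant directions."""
        X, y = eps_feature_matrix(
            dataset, self.config.channel_order, self.config.envelope_enabled
        )
        return self.lda_model.transform(X, self.n_features), y

    def predict(self, dataset: LabeledDataset) -> np.ndarray:
        reduced, _ = self.reduce(dataset)
        return mcsvm.predict(self.svm_model, reduced)


def resolve_n_features(n_features: int | str, n_directions: int) -> int:
    if n_features == "all":
        return n_directions
    n = int(n_features)
    if not (1 <= n <= n_directions):
        raise ValueError(f"n_features must be in [1, {n_directions}], got {n}")
    return n


def fit_pipeline(
    train: LabeledDataset, config: PipelineConfig | None = None, seed: int = 0
) -> TrainedPipeline:
    """Fit EPS + LDA + OAA-SVM on a training dataset."""
    if config is None:
        config = PipelineConfig()
    X, y = eps_feature_matrix(train, config.channel_order, config.envelope_enabled)
    model = lda_mod.fit_lda(X, y, config.lda_regularization)
    k = resolve_n_features(config.n_features, model.projection.shape[0])
    reduced = model.transform(X, k)
    svm = mcsvm.train_oaa(reduced, y, config.svm, seed)
    return TrainedPipeline(config=config, lda_model=model, svm_model=svm, n_features=k)
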