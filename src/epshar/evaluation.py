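"""Confusion matrices, classification metrics, splits, cross-validation
and the feature-count sweep experiment.

Per class, with Tp the diagonal count, Fp the rest of its predicted
column, Fn the rest of its true row and Tn the remainder:

    accuracy  = trace / total
    precision = Tp / (Tp + Fp)
    recall    = Tp / (Tp + Fn)
    F1        = 2 P R / (P + R)

with 0/0 conventions mapped to 0. Macro averaging takes the unweighted
class mean; micro pools Tp/Fp/Fn over classes, under which precision =
recall = accuracy for single-label classification (an identity the tests
assert). Both averages are always computed; reports carry the configured
one in their headline fields.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_signals import LabeledDataset
from .pipeline import PipelineConfig, TrainedPipeline, fit_pipeline, resolve_n_features
from . import lda as lda_mod
from . import mcsvm
from .eps import eps_feature_matrix


@dataclass
class ConfusionMatrix:
    """K x K count matrix; rows = true class, columns = predicted."""

    counts: np.ndarray
    class_names: list[str]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def per_class_counts(self) -> dict[str, np.ndarray]:
        """Tp/Fp/Fn/Tn per class; each quadruple sums to the total."""
        tp = np.diag(self.counts).astype(int)
        fp = self.counts.sum(axis=0) - tp
        fn = self.counts.sum(axis=1) - tp
        tn = self.total - tp - fp - fn
        return {"tp": tp, "fp": fp, "fn": fn, "tn": tn}

    def to_csv(self, path: str | Path, comment: str | None = None) -> None:
        lines = []
        if comment:
            lines.append(f"# {comment}")
        lines.append("true\\pred," + ",".join(self.class_names))
        for name, row in zip(self.class_names, self.counts):
            lines.append(name + "," + ",".join(str(int(v)) for v in row))
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class EvalReport:
    """Metrics for one train/test experiment (fractions in [0, 1])."""

    confusion: ConfusionMatrix
    accuracy: float
    precision: float
    recall: float
    f1: float
    averaging: str
    per_class: list[dict]
    macro: dict = field(default_factory=dict)
    micro: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "averaging": self.averaging,
            "macro": self.macro,
            "micro": self.micro,
            "per_class": self.per_class,
            "confusion": self.confusion.counts.tolist(),
            "class_names": self.confusion.class_names,
        }

    def to_json(self, path: str | Path | None = None, extra: dict | None = None) -> str:
        payload = self.to_dict()
        if extra:
            payload.update(extra)
        text = json.dumps(payload, sort_keys=True, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def confusion(
    true_labels: Sequence[int],
    predicted_labels: Sequence[int],
    n_classes: int,
    class_names: Sequence[str] | None = None,
) -> ConfusionMatrix:
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape[0]} true vs {p.shape[0]} predicted")
    for name, arr in (("true", t), ("predicted", p)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} labels outside [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (t, p), 1)
    names = list(class_names) if class_names else [str(i) for i in range(n_classes)]
    if len(names) != n_classes:
        raise ValueError(f"{len(names)} class names for {n_classes} classes")
    return ConfusionMatrix(counts=counts, class_names=names)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def metrics(conf: ConfusionMatrix, averaging: str = "macro") -> EvalReport:
    """Accuracy, precision, recall and F1 from a confusion matrix."""
    if averaging not in ("macro", "micro"):
        raise ValueError(f"averaging must be 'macro' or 'micro', got {averaging!r}")
    if conf.total == 0:
        raise ValueError("empty confusion matrix")
    pc = conf.per_class_counts()
    tp, fp, fn = pc["tp"], pc["fp"], pc["fn"]
    prec = np.array([_safe_div(a, a + b) for a, b in zip(tp, fp)])
    rec = np.array([_safe_div(a, a + b) for a, b in zip(tp, fn)])
    f1 = np.array([_safe_div(2 * p * r, p + r) for p, r in zip(prec, rec)])
    accuracy = float(np.trace(conf.counts) / conf.total)
    macro_p, macro_r = float(prec.mean()), float(rec.mean())
    micro_p = _safe_div(tp.sum(), tp.sum() + fp.sum())
    micro_r = _safe_div(tp.sum(), tp.sum() + fn.sum())
    macro = {
        "precision": macro_p,
        "recall": macro_r,
        "f1": _safe_div(2 * macro_p * macro_r, macro_p + macro_r),
    }
    micro = {
        "precision": float(micro_p),
        "recall": float(micro_r),
        "f1": float(_safe_div(2 * micro_p * micro_r, micro_p + micro_r)),
    }
    chosen = macro if averaging == "macro" else micro
    per_class = [
        {
            "class": conf.class_names[i],
            "tp": int(tp[i]), "fp": int(fp[i]), "fn": int(fn[i]), "tn": int(pc["tn"][i]),
            "precision": float(prec[i]), "recall": float(rec[i]), "f1": float(f1[i]),
        }
        for i in range(len(conf.class_names))
    ]
    return EvalReport(
        confusion=conf,
        accuracy=accuracy,
        precision=chosen["precision"],
        recall=chosen["recall"],
        f1=chosen["f1"],
        averaging=averaging,
        per_class=per_class,
        macro=macro,
        micro=micro,
    )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_train_test(
    dataset: LabeledDataset,
    train_fraction: float,
    stratified: bool = True,
    seed: int = 0,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Seeded disjoint-exhaustive split; stratified keeps per-class counts
    at round(fraction * N_k)."""
    if not (0 < train_fraction < 1):
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    labels = dataset.labels
    train_idx: list[int] = []
    test_idx: list[int] = []
    if stratified:
        for c in range(dataset.n_classes):
            idx = np.flatnonzero(labels == c)
            if idx.size < 2:
                raise ValueError(
                    f"class {dataset.class_names[c]} has {idx.size} samples; "
                    "stratified split needs >= 2"
                )
            perm = rng.permutation(idx)
            n_train = _round_half_up(train_fraction * idx.size)
            train_idx.extend(perm[:n_train].tolist())
            test_idx.extend(perm[n_train:].tolist())
    else:
        perm = rng.permutation(len(dataset))
        n_train = _round_half_up(train_fraction * len(dataset))
        train_idx = perm[:n_train].tolist()
        test_idx = perm[n_train:].tolist()
    return dataset.subset(sorted(train_idx)), dataset.subset(sorted(test_idx))


def evaluate_pipeline(
    fitted: TrainedPipeline, test: LabeledDataset, averaging: str | None = None
) -> EvalReport:
    """Predict a held-out dataset and compute its metrics."""
    pred = fitted.predict(test)
    conf = confusion(test.labels, pred, test.n_classes, test.class_names)
    return metrics(conf, averaging or fitted.config.averaging)


def _stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Deal each class's shuffled indices round-robin into k folds."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for c in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == c))
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.array(sorted(f), dtype=int) for f in folds]


@dataclass
class CvResult:
    """Mean report plus per-fold reports from cross-validation."""

    mean_report: EvalReport  # pooled confusion, metrics averaged over folds
    fold_reports: list[EvalReport]
    mode: str
    k: int


def kfold_cv(
    dataset: LabeledDataset,
    k: int,
    pipeline_config: PipelineConfig | None = None,
    seed: int = 0,
    mode: str = "rotating",
) -> CvResult:
    """Stratified k-fold cross-validation of the full pipeline.

    ``rotating`` tests each fold once and averages the metrics;
    ``single-split`` trains on folds 1..k-1 and tests only fold k. All
    stages (LDA, scaler, kernel width, SVMs) are fitted inside each
    training fold, never on test windows.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if mode not in ("rotating", "single-split"):
        raise ValueError(f"mode must be 'rotating' or 'single-split', got {mode!r}")
    labels = dataset.labels
    _, counts = np.unique(labels, return_counts=True)
    if (counts < k).any() or len(counts) < dataset.n_classes:
        raise ValueError(f"every class needs >= k={k} samples for stratified folds")
    config = pipeline_config or PipelineConfig()
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(labels, k, rng)
    test_folds = range(k) if mode == "rotating" else [k - 1]
    reports = []
    for j in test_folds:
        train_idx = np.concatenate([folds[i] for i in range(k) if i != j])
        fitted = fit_pipeline(dataset.subset(sorted(train_idx.tolist())), config, seed)
        reports.append(evaluate_pipeline(fitted, dataset.subset(folds[j].tolist())))
    pooled = ConfusionMatrix(
        counts=np.sum([r.confusion.counts for r in reports], axis=0),
        class_names=list(dataset.class_names),
    )
    mean_report = EvalReport(
        confusion=pooled,
        accuracy=float(np.mean([r.accuracy for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
        averaging=config.averaging,
        per_class=[],
        macro={
            key: float(np.mean([r.macro[key] for r in reports]))
            for key in ("precision", "recall", "f1")
        },
        micro={
            key: float(np.mean([r.micro[key] for r in reports]))
            for key in ("precision", "recall", "f1")
        },
    )
    return CvResult(mean_report=mean_report, fold_reports=reports, mode=mode, k=k)


@dataclass
class SweepResult:
    """Rows of the feature-count sweep; metrics as percentages."""

    rows: list[dict]

    def to_csv(self, path: str | Path, comment: str | None = None) -> None:
        lines = []
        if comment:
            lines.append(f"# {comment}")
        lines.append("n_features,accuracy,precision,recall,f1")
        for r in self.rows:
            lines.append(
                f"{r['n_features']},"
                + ",".join(f"{r[m]:.2f}" for m in ("accuracy", "precision", "recall", "f1"))
            )
        Path(path).write_text("\n".join(lines) + "\n")


DEFAULT_SWEEP_COUNTS: tuple = (5, 10, 15, 20, 25, 30, 35, 40, "all")


def feature_sweep(
    train: LabeledDataset,
    test: LabeledDataset,
    counts: Sequence[int | str] = DEFAULT_SWEEP_COUNTS,
    pipeline_config: PipelineConfig | None = None,
    seed: int = 0,
) -> SweepResult:
    """Retrain and evaluate the classifier at each feature count.

    EPS extraction and the LDA fit happen once on the training set; only
    the projection width and the SVM vary across rows.
    """
    counts = list(counts)
    if not counts:
        raise ValueError("counts must be non-empty")
    ints = [c for c in counts if c != "all"]
    if any(not isinstance(c, (int, np.integer)) for c in ints):
        raise ValueError(f"counts must be integers with optional trailing 'all', got {counts}")
    if ints != sorted(set(ints)):
        raise ValueError(f"integer counts must be strictly increasing, got {ints}")
    if "all" in counts and counts[-1] != "all":
        raise ValueError("'all' must be the last entry")
    config = pipeline_config or PipelineConfig()
    x_train, y_train = eps_feature_matrix(train, config.channel_order, config.envelope_enabled)
    x_test, y_test = eps_feature_matrix(test, config.channel_order, config.envelope_enabled)
    model = lda_mod.fit_lda(x_train, y_train, config.lda_regularization)
    n_dirs = model.projection.shape[0]
    rows = []
    for c in counts:
        n_feat = resolve_n_features(c, n_dirs)
        svm = mcsvm.train_oaa(model.transform(x_train, n_feat), y_train, config.svm, seed)
        pred = mcsvm.predict(svm, model.transform(x_test, n_feat))
        rep = metrics(
            confusion(y_test, pred, test.n_classes, test.class_names), config.averaging
        )
        rows.append(
            {
                "n_features": c if c == "all" else int(c),
                "accuracy": 100.0 * rep.accuracy,
                "precision": 100.0 * rep.precision,
                "recall": 100.0 * rep.recall,
                "f1": 100.0 * rep.f1,
            }
        )
    return SweepResult(rows=rows)
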