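"""Dataset containers and text-format I/O for windowed inertial signals.

The package consumes fixed-length, multi-channel windows of accelerometer
(g) and gyroscope (rad/s) samples. Two on-disk layouts are supported:

* the UCI-HAR "Inertial Signals" layout — one whitespace-delimited text
  file per channel, one window of samples per row, plus a label file with
  one integer activity code per row;
* a portable CSV container (``window_id,label,channel,s0..s{n-1}``) used
  for all intermediate artifacts so that fixtures stay diffable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class DatasetFormatError(ValueError):
    """Raised when an on-disk dataset violates its layout contract."""


@dataclass
class SignalWindow:
    """One fixed-length multi-channel sample block.

    Parameters
    ----------
    values : ndarray, shape (channels, samples)
        Sensor samples; g for accelerometer channels, rad/s for gyroscope.
    sample_rate : float
        Sampling rate in Hz; must be positive.
    label : int, optional
        0-based class id.
    subject : int, optional
        Subject identifier, when the source provides one.
    """

    values: np.ndarray
    sample_rate: float
    label: int | None = None
    subject: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"window values must be 2-D (channels x samples), got ndim={self.values.ndim}")
        if self.values.shape[1] < 2:
            raise ValueError(f"windows need >= 2 samples per channel, got {self.values.shape[1]}")
        if not np.isfinite(self.values).all():
            raise ValueError("window contains non-finite sample values")
        if not (self.sample_rate > 0):
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class LabeledDataset:
    """Ordered collection of equally-shaped labeled windows."""

    windows: list[SignalWindow]
    class_names: list[str]
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.windows:
            shape = self.windows[0].values.shape
            for i, w in enumerate(self.windows):
                if w.values.shape != shape:
                    raise ValueError(
                        f"window {i} has shape {w.values.shape}, expected {shape}"
                    )
                if w.label is None:
                    raise ValueError(f"window {i} has no label")
                if not (0 <= w.label < len(self.class_names)):
                    raise ValueError(
                        f"window {i} label {w.label} outside [0, {len(self.class_names)})"
                    )
            if not self.channel_names:
                self.channel_names = [f"ch{i}" for i in range(shape[0])]
            elif len(self.channel_names) != shape[0]:
                raise ValueError(
                    f"{len(self.channel_names)} channel names for {shape[0]} channels"
                )

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def labels(self) -> np.ndarray:
        return np.array([w.label for w in self.windows], dtype=int)

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(
            windows=[self.windows[i] for i in indices],
            class_names=list(self.class_names),
            channel_names=list(self.channel_names),
        )


def _load_numeric_table(path: Path) -> np.ndarray:
    """Parse a whitespace-delimited numeric file, locating bad tokens."""
    rows: list[list[float]] = []
    with open(path) as fh:
        for r, line in enumerate(fh):
            tokens = line.split()
            if not tokens:
                continue
            row = []
            for c, tok in enumerate(tokens):
                try:
                    v = float(tok)
                except ValueError:
                    raise DatasetFormatError(
                        f"{path}: non-numeric token {tok!r} at row {r}, column {c}"
                    ) from None
                if not np.isfinite(v):
                    raise DatasetFormatError(
                        f"{path}: non-finite value {tok!r} at row {r}, column {c}"
                    )
                row.append(v)
            rows.append(row)
    if not rows:
        raise DatasetFormatError(f"{path}: file is empty")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise DatasetFormatError(f"{path}: ragged rows, widths {sorted(widths)}")
    return np.array(rows, dtype=float)


def read_ucihar_inertial(
    directory: str | Path,
    channel_files: Sequence[str],
    label_file: str,
    sample_rate: float = 50.0,
) -> LabeledDataset:
    """Read a UCI-HAR-style inertial-signal directory.

    Each channel file holds one window per row; the label file one integer
    per row. Labels are remapped to a contiguous 0-based range preserving
    sorted original order; the original codes become ``class_names``.
    """
    directory = Path(directory)
    if not channel_files:
        raise DatasetFormatError("no channel files given")
    tables = []
    for name in channel_files:
        tables.append((name, _load_numeric_table(directory / name)))
    n_rows = tables[0][1].shape[0]
    for name, tab in tables[1:]:
        if tab.shape[0] != n_rows:
            raise DatasetFormatError(
                f"row-count mismatch: {tables[0][0]} has {n_rows} rows, "
                f"{name} has {tab.shape[0]}"
            )
        if tab.shape[1] != tables[0][1].shape[1]:
            raise DatasetFormatError(
                f"width mismatch: {tables[0][0]} is {tables[0][1].shape[1]} wide, "
                f"{name} is {tab.shape[1]}"
            )
    raw_labels = _load_numeric_table(directory / label_file)
    if raw_labels.shape[1] != 1:
        raise DatasetFormatError(f"{label_file}: expected one integer per row")
    raw_labels = raw_labels[:, 0]
    if raw_labels.shape[0] != n_rows:
        raise DatasetFormatError(
            f"row-count mismatch: {tables[0][0]} has {n_rows} rows, "
            f"{label_file} has {raw_labels.shape[0]}"
        )
    if not np.all(raw_labels == raw_labels.astype(int)):
        raise DatasetFormatError(f"{label_file}: labels must be integers")
    originals = np.unique(raw_labels.astype(int))
    remap = {orig: i for i, orig in enumerate(originals)}
    windows = [
        SignalWindow(
            values=np.stack([tab[i] for _, tab in tables]),
            sample_rate=sample_rate,
            label=remap[int(raw_labels[i])],
        )
        for i in range(n_rows)
    ]
    return LabeledDataset(
        windows=windows,
        class_names=[str(int(o)) for o in originals],
        channel_names=[Path(n).stem for n, _ in tables],
    )


#: Default UCI-HAR channel order: total acceleration x,y,z then gyroscope
#: x,y,z (6 x 128 = 768 flattened, matching the dataset's signal dimension).
UCIHAR_DEFAULT_CHANNELS = (
    "total_acc_x_train.txt",
    "total_acc_y_train.txt",
    "total_acc_z_train.txt",
    "body_gyro_x_train.txt",
    "body_gyro_y_train.txt",
    "body_gyro_z_train.txt",
)


def write_csv_dataset(dataset: LabeledDataset, path: str | Path) -> None:
    """Write the portable CSV container (deterministic row order)."""
    path = Path(path)
    n_samples = dataset.windows[0].n_samples if dataset.windows else 0
    header = ["window_id", "label", "channel"] + [f"s{i}" for i in range(n_samples)]
    lines = [",".join(header)]
    for wid, w in enumerate(dataset.windows):
        for ch in range(w.n_channels):
            vals = ",".join(repr(float(v)) for v in w.values[ch])
            lines.append(f"{wid},{w.label},{ch},{vals}")
    path.write_text("\n".join(lines) + "\n")


def read_csv_dataset(path: str | Path, sample_rate: float = 50.0) -> LabeledDataset:
    """Read the portable CSV container written by :func:`write_csv_dataset`."""
    path = Path(path)
    df = pd.read_csv(path)
    required = ["window_id", "label", "channel"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"{path}: missing required columns {missing}")
    sample_cols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
    sample_cols.sort(key=lambda c: int(c[1:]))
    if len(df) == 0:
        return LabeledDataset(windows=[], class_names=[], channel_names=[])
    if not sample_cols:
        raise DatasetFormatError(f"{path}: no sample columns (s0, s1, ...)")
    if df.duplicated(subset=["window_id", "channel"]).any():
        dup = df[df.duplicated(subset=["window_id", "channel"])].iloc[0]
        raise DatasetFormatError(
            f"{path}: duplicate (window_id={dup['window_id']}, channel={dup['channel']}) row"
        )
    samples = df[sample_cols].to_numpy(dtype=float)
    if not np.isfinite(samples).all():
        raise DatasetFormatError(f"{path}: ragged or non-finite sample columns")
    windows = []
    for wid, grp in df.groupby("window_id", sort=True):
        grp = grp.sort_values("channel")
        labels = grp["label"].unique()
        if len(labels) != 1:
            raise DatasetFormatError(f"{path}: window {wid} has conflicting labels {labels}")
        windows.append(
            SignalWindow(
                values=grp[sample_cols].to_numpy(dtype=float),
                sample_rate=sample_rate,
                label=int(labels[0]),
            )
        )
    n_classes = max(w.label for w in windows) + 1
    return LabeledDataset(
        windows=windows,
        class_names=[str(i) for i in range(n_classes)],
    )


def flatten_window(
    window: SignalWindow, channel_order: Sequence[int] | None = None
) -> np.ndarray:
    """Concatenate channels into the single sequence fed to EPS.

    ``channel_order`` selects and orders channels; default is all channels
    in stored order (accelerometer x,y,z then gyroscope x,y,z for the
    standard 6-channel layout, giving 6 x 128 = 768).
    """
    if channel_order is None:
        channel_order = range(window.n_channels)
    order = list(channel_order)
    for idx in order:
        if not (0 <= idx < window.n_channels):
            raise IndexError(
                f"channel index {idx} out of range [0, {window.n_channels})"
            )
    return np.concatenate([window.values[i] for i in order])
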