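"""Seeded generator of labeled synthetic IMU activity windows.

Emulates the structure of waist-mounted smartphone recordings: 6 channels
(3-axis accelerometer in g, 3-axis gyroscope in rad/s) sampled at 50 Hz
in fixed-length windows. Two class archetypes:

* static postures — a constant 1 g gravity vector along a class-specific
  orientation plus Gaussian sensor noise (sitting/standing/laying
  analogues, distinguishable through the DC region of the spectrum);
* dynamic activities — gravity plus a quasi-periodic, amplitude-modulated
  oscillation at a class-specific fundamental in the human-gait band
  (0.5-4 Hz), projected on a per-window random movement axis with a
  per-window random phase, plus noise (walking/stairs analogues,
  distinguishable through the envelope spectrum's low-frequency peaks).

One shared random stream per dataset, consumed class-major then
window-major, with a fixed per-window draw order (phase, axis, channel
noise), so an identical spec reproduces a bit-identical dataset.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .io_signals import LabeledDataset, SignalWindow

GYRO_NOISE_SD = 0.05  # rad/s, baseline gyroscope noise

# distinct tilt patterns: the per-channel gravity magnitudes must differ
# between postures (axis-permuted orientations would leave near-identical
# envelope spectra after channel concatenation)
_STATIC_ARCHETYPES = [
    ("laying", (0.0, 0.0, 1.0)),
    ("sitting", (0.8, 0.0, 0.6)),
    ("standing", (0.36, 0.8, 0.48)),
]
# fundamentals pairwise separated by >= 0.5 Hz for any prefix
_DYNAMIC_ARCHETYPES = [
    ("walking", 1.0),
    ("climbing_stairs", 2.0),
    ("jogging", 3.0),
    ("descending_stairs", 0.5),
    ("shuffling", 1.5),
    ("dancing", 2.5),
    ("jumping", 3.5),
]


@dataclass
class ClassArchetype:
    """Parameters of one synthetic activity class."""

    name: str
    kind: str  # "dynamic" or "static"
    orientation: tuple[float, float, float]  # unit gravity direction
    fundamental_hz: float = 0.0  # dynamic only
    amplitude: float = 0.4  # g
    modulation_depth: float = 0.3
    noise_sd: float = 0.05  # g

    def validate(self, sample_rate: float) -> None:
        if self.kind not in ("dynamic", "static"):
            raise ValueError(f"kind must be 'dynamic' or 'static', got {self.kind!r}")
        if self.kind == "dynamic" and not (0 < self.fundamental_hz < sample_rate / 2):
            raise ValueError(
                f"{self.name}: fundamental {self.fundamental_hz} Hz outside "
                f"(0, {sample_rate / 2})"
            )
        if self.noise_sd < 0:
            raise ValueError(f"{self.name}: noise_sd must be >= 0")
        if not (0 <= self.modulation_depth < 1):
            raise ValueError(f"{self.name}: modulation_depth must be in [0, 1)")
        if abs(np.linalg.norm(self.orientation) - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: orientation must be a unit vector")


@dataclass
class SyntheticSpec:
    """Full description of a synthetic dataset (including its seed)."""

    archetypes: list[ClassArchetype]
    n_per_class: int
    samples: int
    sample_rate: float = 50.0
    channels: int = 6
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.samples < 16:
            raise ValueError("samples must be >= 16")
        if self.channels != 6:
            raise ValueError("generator emits 6 channels (3 acc + 3 gyro)")
        for a in self.archetypes:
            a.validate(self.sample_rate)

    def to_json(self, path: str | Path | None = None, extra: dict | None = None) -> str:
        payload = asdict(self)
        if extra:
            payload.update(extra)
        text = json.dumps(payload, sort_keys=True, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def default_spec(
    n_classes: int = 5,
    n_per_class: int = 200,
    samples: int = 128,
    seed: int = 0,
    sample_rate: float = 50.0,
) -> SyntheticSpec:
    """Archetype mix mimicking daily-activity datasets.

    Up to three static postures with orthogonal orientations, the rest
    dynamic with distinct gait-band fundamentals; the 5-class default is
    three postures (laying/sitting/standing) plus walking and stair
    climbing, matching the common smartphone-HAR class list. Five classes
    of 128-sample 6-channel windows flatten to 768 values.
    """
    if not (2 <= n_classes <= 10):
        raise ValueError(f"n_classes must be in [2, 10], got {n_classes}")
    n_static = min(3, n_classes - 1)
    n_dynamic = n_classes - n_static
    archetypes = [
        ClassArchetype(name=name, kind="static", orientation=ori)
        for name, ori in _STATIC_ARCHETYPES[:n_static]
    ]
    for name, f0 in _DYNAMIC_ARCHETYPES[:n_dynamic]:
        archetypes.append(
            ClassArchetype(
                name=name, kind="dynamic", orientation=(0.0, 0.0, 1.0), fundamental_hz=f0
            )
        )
    spec = SyntheticSpec(
        archetypes=archetypes,
        n_per_class=n_per_class,
        samples=samples,
        sample_rate=sample_rate,
        seed=seed,
    )
    spec.validate()
    return spec


def _oscillation(a: ClassArchetype, t: np.ndarray, phase: float) -> tuple[np.ndarray, np.ndarray]:
    """AM oscillation and its time derivative scaled to O(amplitude)."""
    w = 2 * np.pi * a.fundamental_hz
    wm = w / 4.0  # modulator at a quarter of the fundamental
    mod = 1.0 + a.modulation_depth * np.sin(wm * t)
    osc = a.amplitude * mod * np.sin(w * t + phase)
    dosc = a.amplitude * (
        a.modulation_depth * wm * np.cos(wm * t) * np.sin(w * t + phase)
        + mod * w * np.cos(w * t + phase)
    )
    return osc, dosc / w  # derivative scaled by 1/w -> rad/s-scale values


def generate(spec: SyntheticSpec) -> LabeledDataset:
    """Draw the dataset described by ``spec`` (deterministic in its seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.samples) / spec.sample_rate
    windows = []
    for label, arch in enumerate(spec.archetypes):
        gravity = np.asarray(arch.orientation, dtype=float)
        for _ in range(spec.n_per_class):
            # fixed draw order: phase, movement axis, acc noise, gyro noise
            phase = rng.uniform(0, 2 * np.pi)
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            acc_noise = rng.normal(0.0, arch.noise_sd, size=(3, spec.samples))
            gyro_white = rng.normal(0.0, GYRO_NOISE_SD, size=(3, spec.samples))
            acc = gravity[:, None] + acc_noise
            # 5-point smoothing band-limits the gyro noise floor
            kernel = np.ones(5) / 5.0
            gyro = np.stack([np.convolve(g, kernel, mode="same") for g in gyro_white])
            if arch.kind == "dynamic":
                osc, dosc = _oscillation(arch, t, phase)
                acc = acc + axis[:, None] * osc[None, :]
                gyro = gyro + axis[:, None] * dosc[None, :]
            windows.append(
                SignalWindow(
                    values=np.vstack([acc, gyro]),
                    sample_rate=spec.sample_rate,
                    label=label,
                )
            )
    return LabeledDataset(
        windows=windows,
        class_names=[a.name for a in spec.archetypes],
        channel_names=["acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z"],
    )
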