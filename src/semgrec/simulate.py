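"""Synthetic multi-channel surface-EMG generator for four lower-limb movements.

Real lower-limb sEMG of this kind (7 thigh/shank muscles, 1 kHz, cyclic gait
movements) is not publicly deposited, so the package ships a generative stand-in
with the statistical structure the downstream pipeline assumes:

* a zero-mean Gaussian carrier band-limited to the standard 20-450 Hz sEMG
  bandwidth, amplitude-modulated per channel by a class-specific raised-cosine
  activation envelope over each movement cycle (2 s cycles for walking and
  stair ascent/descent, 3 s for squatting);
* 50 Hz powerline interference with a random phase per channel;
* a common-mode ECG-like artifact: a periodic train of narrow Gaussian pulses;
* additive white measurement noise.

Everything is deterministic under the spec seed. The envelopes are a stated
world, not a physiological model: they give each movement a distinct activation
pattern across the seven muscles so that class information exists, without any
attempt at motor-unit realism.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

__all__ = [
    "CLASSES",
    "CHANNEL_NAMES",
    "GeneratorSpec",
    "RawRecording",
    "generate_recording",
    "generate_dataset",
    "save_recording",
    "load_recording",
]

#: Fixed class order; integer codes follow this order (0 walk ... 3 squat).
CLASSES = ("walk", "ascend", "descend", "squat")

#: The seven recorded muscles, channel 1..7.
CHANNEL_NAMES = (
    "rectus_femoris",
    "vastus_lateralis",
    "vastus_medialis",
    "semitendinosus",
    "tibialis_anterior",
    "gastrocnemius_lateralis",
    "gastrocnemius_medialis",
)

# Per-class, per-channel raised-cosine burst parameters:
# (onset as fraction of cycle, duration as fraction of cycle, amplitude scale).
# Patterns are loosely gait-like (quadriceps in stance/ascent, tibialis anterior
# in swing, gastrocnemii in push-off / descent) but chosen mainly to be
# pairwise distinct across classes on several channels.
_DEFAULT_ENVELOPES: dict[str, tuple[tuple[float, float, float], ...]] = {
    "walk": (
        (0.00, 0.35, 0.8),   # rectus femoris: early stance
        (0.00, 0.30, 0.6),   # vastus lateralis
        (0.00, 0.30, 0.6),   # vastus medialis
        (0.55, 0.30, 0.5),   # semitendinosus: swing
        (0.50, 0.40, 1.0),   # tibialis anterior: swing dorsiflexion
        (0.25, 0.30, 0.9),   # gastrocnemius lat.: push-off
        (0.25, 0.30, 0.8),   # gastrocnemius med.
    ),
    "ascend": (
        (0.05, 0.45, 1.2),
        (0.05, 0.45, 1.1),
        (0.05, 0.45, 1.0),
        (0.40, 0.30, 0.4),
        (0.55, 0.30, 0.6),
        (0.35, 0.35, 0.7),
        (0.35, 0.35, 0.6),
    ),
    "descend": (
        (0.30, 0.40, 0.7),
        (0.30, 0.40, 0.8),
        (0.30, 0.40, 0.7),
        (0.10, 0.25, 0.3),
        (0.05, 0.30, 0.5),
        (0.00, 0.45, 1.2),
        (0.00, 0.45, 1.1),
    ),
    "squat": (
        (0.10, 0.70, 1.3),
        (0.10, 0.70, 1.2),
        (0.10, 0.70, 1.2),
        (0.20, 0.55, 0.7),
        (0.15, 0.55, 0.4),
        (0.30, 0.40, 0.5),
        (0.30, 0.40, 0.5),
    ),
}

_DEFAULT_CYCLES = {"walk": 2.0, "ascend": 2.0, "descend": 2.0, "squat": 3.0}


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic sEMG world.

    ``envelope_contrast`` interpolates each class's envelope table between the
    cross-class mean pattern (0: classes indistinguishable in expectation) and
    the full class-specific pattern (1, default). Amplitudes are in arbitrary
    voltage-like units.
    """

    n_channels: int = 7
    fs: float = 1000.0
    classes: tuple[str, ...] = CLASSES
    cycle_duration_s: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_CYCLES))
    envelope_table: dict[str, tuple[tuple[float, float, float], ...]] = field(
        default_factory=lambda: dict(_DEFAULT_ENVELOPES)
    )
    envelope_contrast: float = 1.0
    envelope_baseline: float = 0.1    # resting tone, as a fraction of the burst scale
    carrier_band_hz: tuple[float, float] = (20.0, 450.0)
    powerline_amp: float = 0.10
    powerline_freq_hz: float = 50.0
    ecg_amp: float = 0.15
    ecg_rate_hz: float = 1.2
    ecg_width_s: float = 0.015
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for c in self.classes:
            n = self.cycle_duration_s[c] * self.fs
            if abs(n - round(n)) > 1e-9:
                raise ValueError(f"cycle_duration_s[{c!r}] x fs is not an integer sample count")
        for name, val in [
            ("powerline_amp", self.powerline_amp),
            ("ecg_amp", self.ecg_amp),
            ("noise_sd", self.noise_sd),
        ]:
            if val < 0:
                raise ValueError(f"{name} must be >= 0")

    def cycle_samples(self, label: str) -> int:
        return int(round(self.cycle_duration_s[label] * self.fs))

    def effective_envelopes(self, label: str) -> np.ndarray:
        """(n_channels, 3) array of (onset, duration, scale) after applying the
        contrast interpolation toward the cross-class mean pattern."""
        table = np.array([self.envelope_table[c] for c in self.classes])  # (K, C, 3)
        mean = table.mean(axis=0)
        own = np.array(self.envelope_table[label])
        return mean + self.envelope_contrast * (own - mean)


@dataclass
class RawRecording:
    """A labelled multi-channel sEMG record with cycle-onset annotations."""

    samples: np.ndarray          # (n_channels, n_samples)
    fs: float
    label: str
    cycle_onsets: list[int]
    channel_names: tuple[str, ...] = CHANNEL_NAMES
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if list(self.cycle_onsets) != sorted(set(self.cycle_onsets)):
            raise ValueError("cycle_onsets must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


def _raised_cosine_envelope(phase: np.ndarray, onset: float, dur: float, scale: float,
                            baseline: float) -> np.ndarray:
    """Raised-cosine burst on the cycle phase in [0, 1), plus a resting tone."""
    env = np.full_like(phase, baseline * scale)
    if dur > 0 and scale > 0:
        u = (phase - onset) / dur
        inside = (u >= 0) & (u <= 1)
        env[inside] += scale * 0.5 * (1.0 - np.cos(2.0 * np.pi * u[inside]))
    return env


def _bandlimited_carrier(n: int, fs: float, band: tuple[float, float],
                         rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    lo, hi = band
    hi = min(hi, 0.499 * fs)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    out = sps.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(out ** 2))
    return out / rms if rms > 0 else out


def _ecg_train(n: int, fs: float, amp: float, rate_hz: float, width_s: float,
               rng: np.random.Generator) -> np.ndarray:
    """Periodic train of narrow Gaussian pulses; a cartoon of ECG contamination."""
    t = np.arange(n) / fs
    out = np.zeros(n)
    if amp <= 0 or rate_hz <= 0:
        return out
    period = 1.0 / rate_hz
    start = rng.uniform(0, period)
    centers = np.arange(start, t[-1] + period, period)
    for c in centers:
        out += amp * np.exp(-0.5 * ((t - c) / width_s) ** 2)
    return out


def generate_recording(spec: GeneratorSpec, label: str, n_cycles: int,
                       seed: int | None = None) -> RawRecording:
    """Simulate one recording of ``n_cycles`` repetitions of ``label``.

    The per-channel signal is
    ``envelope * carrier + powerline + ecg_artifact + white_noise``; identical
    (spec, label, n_cycles, seed) inputs give bit-identical output.
    """
    if label not in spec.classes:
        raise ValueError(f"unknown movement label {label!r}; expected one of {spec.classes}")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    cyc = spec.cycle_samples(label)
    n = cyc * n_cycles
    t = np.arange(n) / spec.fs
    phase = (np.arange(n) % cyc) / cyc
    env_params = spec.effective_envelopes(label)

    ecg = _ecg_train(n, spec.fs, spec.ecg_amp, spec.ecg_rate_hz, spec.ecg_width_s, rng)
    samples = np.empty((spec.n_channels, n))
    for ch in range(spec.n_channels):
        onset, dur, scale = env_params[ch]
        env = _raised_cosine_envelope(phase, onset, dur, scale, spec.envelope_baseline)
        carrier = _bandlimited_carrier(n, spec.fs, spec.carrier_band_hz, rng)
        powerline = spec.powerline_amp * np.sin(
            2.0 * np.pi * spec.powerline_freq_hz * t + rng.uniform(0, 2 * np.pi)
        ) if spec.powerline_amp > 0 else 0.0
        noise = spec.noise_sd * rng.standard_normal(n) if spec.noise_sd > 0 else 0.0
        samples[ch] = env * carrier + powerline + ecg + noise

    onsets = [i * cyc for i in range(n_cycles)]
    return RawRecording(samples=samples, fs=spec.fs, label=label, cycle_onsets=onsets,
                        channel_names=CHANNEL_NAMES[: spec.n_channels],
                        source_id=f"sim-{label}-seed{spec.seed if seed is None else seed}")


def generate_dataset(spec: GeneratorSpec,
                     cycles_per_class: dict[str, int]) -> list[RawRecording]:
    """One recording per movement class, with per-class sub-seeds derived from
    ``spec.seed`` so that the dataset is reproducible as a whole."""
    missing = [c for c in spec.classes if c not in cycles_per_class]
    if missing:
        raise ValueError(f"cycles_per_class missing classes: {missing}")
    recs = []
    for i, label in enumerate(spec.classes):
        n_cycles = cycles_per_class[label]
        if n_cycles < 1:
            raise ValueError(f"cycles_per_class[{label!r}] must be >= 1")
        sub_seed = int(np.random.SeedSequence(spec.seed, spawn_key=(i,)).generate_state(1)[0])
        recs.append(generate_recording(spec, label, n_cycles, seed=sub_seed))
    return recs


def save_recording(rec: RawRecording, csv_path: str | Path,
                   json_path: str | Path | None = None) -> None:
    """Write samples as CSV (one row per sample, channel columns) plus a JSON
    sidecar holding sampling rate, label and cycle onsets."""
    csv_path = Path(csv_path)
    header = ",".join(rec.channel_names)
    np.savetxt(csv_path, rec.samples.T, delimiter=",", header=header, comments="")
    meta = {
        "fs": rec.fs,
        "label": rec.label,
        "cycle_onsets": [int(o) for o in rec.cycle_onsets],
        "source_id": rec.source_id,
    }
    json_path = Path(json_path) if json_path else csv_path.with_suffix(".json")
    json_path.write_text(json.dumps(meta, indent=2))


def load_recording(csv_path: str | Path,
                   json_path: str | Path | None = None) -> RawRecording:
    csv_path = Path(csv_path)
    json_path = Path(json_path) if json_path else csv_path.with_suffix(".json")
    meta = json.loads(json_path.read_text())
    with open(csv_path) as fh:
        names = tuple(fh.readline().strip().split(","))
    samples = np.loadtxt(csv_path, delimiter=",", skiprows=1).T
    if samples.ndim == 1:
        samples = samples[None, :]
    return RawRecording(samples=samples, fs=meta["fs"], label=meta["label"],
                        cycle_onsets=list(meta["cycle_onsets"]),
                        channel_names=names, source_id=meta.get("source_id", ""))
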