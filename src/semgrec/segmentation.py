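"""Cycle segmentation and overlapped sliding-window expansion.

Recordings are first cut at the annotated action-cycle onsets (2 s cycles for
walking and stair movements, 3 s for squats), then each cycle is expanded into
fixed 7 x 1024-sample windows with a 1024 ms window and 512 ms step. Windows
are the unit of classification throughout the package.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .simulate import CLASSES, RawRecording

__all__ = ["WindowSpec", "Window", "WindowDataset", "segment_cycles",
           "slide_windows", "build_dataset", "split_dataset"]

log = logging.getLogger(__name__)

#: Integer codes: 0 walking, 1 ascending stairs, 2 descending stairs, 3 squatting.
CLASS_CODES = {c: i for i, c in enumerate(CLASSES)}


@dataclass(frozen=True)
class WindowSpec:
    window_ms: int = 1024
    step_ms: int = 512
    fs: float = 1000.0
    min_rms: float = 0.0          # screening floor; 0 disables screening

    def __post_init__(self) -> None:
        if self.window_ms <= 0 or not (0 < self.step_ms <= self.window_ms):
            raise ValueError("require window_ms > 0 and 0 < step_ms <= window_ms")
        w = self.window_ms * self.fs / 1000.0
        if abs(w - round(w)) > 1e-9:
            raise ValueError("window_ms x fs must give an integer sample count")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_ms * self.fs / 1000.0))

    @property
    def step_samples(self) -> int:
        return int(round(self.step_ms * self.fs / 1000.0))


@dataclass
class Window:
    samples: np.ndarray           # (n_channels, window_samples)
    label: str
    source_id: str = ""
    cycle_index: int = 0
    offset: int = 0               # start sample within the cycle


@dataclass
class WindowDataset:
    """Ordered window collection with labels and an optional train/test split."""

    windows: list[Window]
    class_counts: dict[str, int] = field(default_factory=dict)
    split_assignment: np.ndarray | None = None   # array of "train"/"test" per window

    def __post_init__(self) -> None:
        if not self.class_counts:
            self.class_counts = {c: 0 for c in CLASSES}
            for w in self.windows:
                self.class_counts[w.label] = self.class_counts.get(w.label, 0) + 1

    def __len__(self) -> int:
        return len(self.windows)

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """(n, C, W) float array of samples and (n,) integer label codes."""
        X = np.stack([w.samples for w in self.windows]).astype(float)
        y = np.array([CLASS_CODES[w.label] for w in self.windows], dtype=int)
        return X, y

    def subset_indices(self, part: str) -> np.ndarray:
        if self.split_assignment is None:
            raise ValueError("dataset has no split; call split_dataset first")
        return np.nonzero(self.split_assignment == part)[0]

    def save(self, path: str | Path) -> None:
        X, y = self.stacked()
        with h5py.File(path, "w") as f:
            f.create_dataset("windows", data=X.astype(np.float32))
            f.create_dataset("labels", data=y)
            f.attrs["class_order"] = list(CLASSES)
            meta = f.create_group("meta")
            meta.create_dataset("cycle_index", data=[w.cycle_index for w in self.windows])
            meta.create_dataset("offset", data=[w.offset for w in self.windows])
            meta.create_dataset("source_id",
                                data=[w.source_id.encode() for w in self.windows])
            if self.split_assignment is not None:
                f.create_dataset("split",
                                 data=[s.encode() for s in self.split_assignment])

    @classmethod
    def load(cls, path: str | Path) -> "WindowDataset":
        with h5py.File(path, "r") as f:
            X = f["windows"][...].astype(float)
            y = f["labels"][...]
            cyc = f["meta/cycle_index"][...]
            off = f["meta/offset"][...]
            src = [s.decode() for s in f["meta/source_id"][...]]
            split = ([s.decode() for s in f["split"][...]] if "split" in f else None)
        windows = [Window(samples=X[i], label=CLASSES[y[i]], source_id=src[i],
                          cycle_index=int(cyc[i]), offset=int(off[i]))
                   for i in range(len(y))]
        ds = cls(windows=windows)
        if split is not None:
            ds.split_assignment = np.array(split)
        return ds


def segment_cycles(rec: RawRecording, cycle_len_samples: int) -> list[np.ndarray]:
    """One (n_channels, cycle_len_samples) slice per annotated onset."""
    cycles = []
    for onset in rec.cycle_onsets:
        end = onset + cycle_len_samples
        if end > rec.n_samples:
            raise ValueError(
                f"cycle starting at sample {onset} runs past the recording "
                f"({end} > {rec.n_samples})"
            )
        cycles.append(rec.samples[:, onset:end])
    return cycles


def slide_windows(cycle: np.ndarray, spec: WindowSpec) -> list[tuple[np.ndarray, int]]:
    """Overlapped sliding windows over one cycle.

    Returns (window_array, offset) pairs; window j covers samples
    [j*step, j*step + window). A cycle shorter than one window yields an empty
    list with a warning rather than an error, so screened-out short cycles do
    not abort a run.
    """
    W, S = spec.window_samples, spec.step_samples
    L = cycle.shape[1]
    if L < W:
        log.warning("cycle of length %d shorter than window %d; skipped", L, W)
        return []
    n_win = (L - W) // S + 1
    return [(cycle[:, j * S: j * S + W], j * S) for j in range(n_win)]


def build_dataset(recs: list[RawRecording], spec: WindowSpec,
                  cycle_samples: dict[str, int] | None = None) -> WindowDataset:
    """Expand recordings into a screened window dataset.

    A window is dropped iff its mean per-channel RMS falls below
    ``spec.min_rms`` or it contains non-finite values. ``cycle_samples`` maps
    label -> cycle length in samples; by default it is inferred from the
    spacing of each recording's onsets.
    """
    if not recs:
        raise ValueError("no recordings given")
    fss = {r.fs for r in recs}
    nchs = {r.n_channels for r in recs}
    if len(fss) > 1 or len(nchs) > 1:
        raise ValueError("recordings disagree in sampling rate or channel count")
    windows: list[Window] = []
    for rec in recs:
        if cycle_samples is not None:
            cyc_len = cycle_samples[rec.label]
        elif len(rec.cycle_onsets) >= 2:
            cyc_len = rec.cycle_onsets[1] - rec.cycle_onsets[0]
        else:
            cyc_len = rec.n_samples - rec.cycle_onsets[0]
        for ci, cycle in enumerate(segment_cycles(rec, cyc_len)):
            for arr, off in slide_windows(cycle, spec):
                if not np.all(np.isfinite(arr)):
                    log.warning("window with non-finite samples screened out "
                                "(%s cycle %d offset %d)", rec.source_id, ci, off)
                    continue
                mean_rms = float(np.mean(np.sqrt(np.mean(arr ** 2, axis=1))))
                if mean_rms < spec.min_rms:
                    continue
                windows.append(Window(samples=arr.copy(), label=rec.label,
                                      source_id=rec.source_id,
                                      cycle_index=ci, offset=off))
    return WindowDataset(windows=windows)


def split_dataset(ds: WindowDataset, test_fraction: float, seed: int) -> WindowDataset:
    """Stratified window-level train/test split, deterministic under seed.

    Per class, round(test_fraction x count) windows go to test. Overlapping
    windows from one cycle can land on both sides; this is the documented
    window-level convention (no subject structure exists in synthetic data).
    """
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    labels = np.array([w.label for w in ds.windows])
    assignment = np.array(["train"] * len(ds.windows), dtype=object)
    rng = np.random.default_rng(seed)
    for c in sorted(set(labels)):
        idx = np.nonzero(labels == c)[0]
        if idx.size < 2:
            raise ValueError(f"class {c!r} has fewer than 2 windows; cannot split")
        n_test = int(round(test_fraction * idx.size))
        chosen = rng.choice(idx, size=n_test, replace=False)
        assignment[chosen] = "test"
    ds.split_assignment = assignment.astype(str)
    return ds
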