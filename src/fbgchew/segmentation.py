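"""Chew-movement segmentation of wavelength traces.

The signal mean is evaluated over consecutive one-second blocks, subtracted,
and rising zero crossings of the detrended signal delimit individual jaw
movements.  Each movement keeps its original (mean-restored) samples together
with the block mean used for detrending; short instances are later padded with
that mean to a fixed length of 1000 samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import CLASSES, UNLABELED, WavelengthTrace

__all__ = [
    "SegmentationParams",
    "Movement",
    "blockwise_mean",
    "detect_rising_crossings",
    "segment_movements",
    "pad_to_length",
    "write_movements_csv",
    "read_movements_csv",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the segmentation stage.

    block_s: duration of the averaging block (s).
    min_movement_s: spans shorter than this are rejected as noise artifacts.
    target_length: fixed instance length in samples after padding.
    """

    block_s: float = 1.0
    min_movement_s: float = 0.05
    target_length: int = 1000

    def __post_init__(self) -> None:
        if self.block_s <= 0:
            raise ValueError("block_s must be positive")
        if self.min_movement_s <= 0:
            raise ValueError("min_movement_s must be positive")
        if self.target_length < 1:
            raise ValueError("target_length must be >= 1")


@dataclass
class Movement:
    """One segmented chew cycle: native samples plus provenance."""

    samples: np.ndarray
    start_index: int
    mean_nm: float
    label: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.size == 0:
            raise ValueError("movement must contain at least one sample")

    @property
    def native_length(self) -> int:
        return int(self.samples.size)


def blockwise_mean(
    samples: np.ndarray, sampling_rate_hz: float, block_s: float = 1.0
) -> np.ndarray:
    """Per-sample piecewise-constant baseline of non-overlapping block means.

    The final partial block is averaged over its own samples.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot compute blockwise mean of an empty trace")
    block_n = max(1, round(block_s * sampling_rate_hz))
    n_blocks = -(-x.size // block_n)
    baseline = np.empty_like(x)
    for b in range(n_blocks):
        lo, hi = b * block_n, min((b + 1) * block_n, x.size)
        baseline[lo:hi] = x[lo:hi].mean()
    return baseline


def detect_rising_crossings(detrended: np.ndarray) -> np.ndarray:
    """Indices i with detrended[i-1] < 0 and detrended[i] >= 0, ascending.

    Exact zeros count as non-negative; an all-positive (or all-negative)
    series yields an empty result.
    """
    x = np.asarray(detrended, dtype=np.float64)
    if x.size < 2:
        return np.empty(0, dtype=np.intp)
    return np.flatnonzero((x[:-1] < 0.0) & (x[1:] >= 0.0)) + 1


def _majority_label(labels: np.ndarray, class_order: Sequence[str]) -> str | None:
    """Modal label over labeled samples; ties break toward earliest class.

    Returns None when the span carries no labeled samples at all.
    """
    labeled = labels[labels != UNLABELED]
    if labeled.size == 0:
        return None
    values, counts = np.unique(labeled, return_counts=True)
    order = {c: i for i, c in enumerate(class_order)}

    def rank(item: tuple[str, int]) -> tuple[int, int, str]:
        value, count = item
        return (-count, order.get(value, len(order)), value)

    return sorted(zip(values.tolist(), counts.tolist()), key=rank)[0][0]


def segment_movements(
    trace: WavelengthTrace,
    params: SegmentationParams = SegmentationParams(),
    class_order: Sequence[str] = CLASSES,
) -> list[Movement]:
    """Split a trace into movements between consecutive rising crossings.

    The leading span before the first crossing and the trailing span after the
    last crossing are discarded; spans shorter than ``min_movement_s`` (or with
    no labeled samples) are dropped.  Each movement keeps the original sample
    values and the mean of the detrending baseline over its span.
    """
    if trace.sampling_rate_hz is None or trace.sampling_rate_hz <= 0:
        raise ValueError("trace sampling rate must be known and positive")
    baseline = blockwise_mean(trace.samples, trace.sampling_rate_hz, params.block_s)
    crossings = detect_rising_crossings(trace.samples - baseline)
    min_n = max(1, round(params.min_movement_s * trace.sampling_rate_hz))
    movements: list[Movement] = []
    for lo, hi in zip(crossings[:-1], crossings[1:]):
        if hi - lo < min_n:
            continue
        label = _majority_label(trace.labels[lo:hi], class_order)
        if label is None:
            continue
        movements.append(
            Movement(
                samples=trace.samples[lo:hi].copy(),
                start_index=int(lo),
                mean_nm=float(baseline[lo:hi].mean()),
                label=label,
            )
        )
    return movements


def pad_to_length(movement: Movement, target_length: int = 1000) -> np.ndarray:
    """Fixed-length sample vector: mean-padded at the tail, or tail-truncated.

    Padding an already-padded movement is the identity.
    """
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    x = movement.samples
    if x.size >= target_length:
        return x[:target_length].copy()
    out = np.full(target_length, movement.mean_nm, dtype=np.float64)
    out[: x.size] = x
    return out


def write_movements_csv(
    movements: Sequence[Movement], path, target_length: int = 1000
) -> None:
    """One row per movement: start_index, native_length, mean_nm, label, padded samples."""
    rows = []
    for m in movements:
        rows.append(
            [m.start_index, m.native_length, m.mean_nm, m.label]
            + pad_to_length(m, target_length).tolist()
        )
    columns = ["start_index", "native_length", "mean_nm", "label"] + [
        f"s{i}" for i in range(1, target_length + 1)
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False, float_format="%.12g")


def read_movements_csv(path) -> list[Movement]:
    """Read movements written by :func:`write_movements_csv`.

    Native (unpadded) sample vectors are restored using the stored
    native_length; movements stored truncated keep their padded length.
    """
    frame = pd.read_csv(path, keep_default_na=False, dtype={"label": str})
    sample_cols = [c for c in frame.columns if c.startswith("s") and c[1:].isdigit()]
    sample_cols.sort(key=lambda c: int(c[1:]))
    movements = []
    for _, row in frame.iterrows():
        native = min(int(row["native_length"]), len(sample_cols))
        samples = row[sample_cols].to_numpy(dtype=np.float64)[:native]
        movements.append(
            Movement(
                samples=samples,
                start_index=int(row["start_index"]),
                mean_nm=float(row["mean_nm"]),
                label=str(row["label"]),
            )
        )
    return movements
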