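"""Feature construction: fixed-length time samples plus DFT harmonics.

Each instance concatenates the mean-padded 1000-sample movement with the
magnitudes of the first 30 components of the discrete Fourier transform

    X(k) = (1/N) * sum_{n=0}^{N-1} x(n) exp(-j 2 pi k n / N),

computed over the UNPADDED native segment (N = native length).  Under the 1/N
normalization the k = 0 magnitude equals |segment mean|, and because a segment
spans one chew cycle the bin spacing fs/N sits at the movement's fundamental
frequency — which is what makes the harmonic magnitudes class-discriminative.
A config switch allows computing the spectrum on the padded vector instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .segmentation import Movement, pad_to_length
from .synthetic import CLASSES

__all__ = [
    "Spectrum",
    "FeatureParams",
    "Instance",
    "Dataset",
    "dft",
    "spectral_attributes",
    "build_instance",
    "build_dataset",
]


@dataclass
class Spectrum:
    """Magnitude spectrum of one segment under the 1/N normalization."""

    magnitudes: np.ndarray
    bin_spacing_hz: float
    native_length: int


@dataclass(frozen=True)
class FeatureParams:
    """Feature-stage configuration.

    time_attrs selects the number of time-domain attributes kept from the
    padded vector (uniform decimation); 1000 is the primary configuration,
    500 and 250 are the reduced variants.
    """

    n_spectral: int = 30
    fft_input: str = "native"
    time_attrs: int = 1000
    target_length: int = 1000

    def __post_init__(self) -> None:
        if self.fft_input not in ("native", "padded"):
            raise ValueError("fft_input must be 'native' or 'padded'")
        if self.n_spectral < 1:
            raise ValueError("n_spectral must be >= 1")
        if self.time_attrs < 1 or self.target_length % self.time_attrs:
            raise ValueError("time_attrs must divide target_length")


@dataclass
class Instance:
    """One feature vector (time attributes + spectral attributes) with label."""

    attributes: np.ndarray
    label: str


@dataclass
class Dataset:
    """Feature matrix with labels and a per-class census."""

    X: np.ndarray
    y: np.ndarray
    class_names: tuple[str, ...]
    attribute_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X and y are inconsistent")
        if self.X.shape[1] != len(self.attribute_names):
            raise ValueError("attribute_names must match the number of columns")

    @property
    def m(self) -> int:
        return int(self.X.shape[0])

    @property
    def n_attributes(self) -> int:
        return int(self.X.shape[1])

    @property
    def per_class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.y == c)) for c in self.class_names}

    def to_dataframe(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=list(self.attribute_names))
        frame["label"] = self.y
        return frame

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, class_order: Sequence[str] = CLASSES
    ) -> "Dataset":
        if "label" not in frame.columns:
            raise ValueError("dataset must have a 'label' column")
        attribute_names = tuple(c for c in frame.columns if c != "label")
        y = frame["label"].to_numpy(dtype=str)
        present = set(y.tolist())
        ordered = [c for c in class_order if c in present]
        ordered += sorted(present - set(ordered))
        return cls(
            X=frame[list(attribute_names)].to_numpy(dtype=np.float64),
            y=y,
            class_names=tuple(ordered),
            attribute_names=attribute_names,
        )

    @classmethod
    def from_csv(cls, path, class_order: Sequence[str] = CLASSES) -> "Dataset":
        return cls.from_dataframe(
            pd.read_csv(path, keep_default_na=False, dtype={"label": str}),
            class_order,
        )


def dft(segment: np.ndarray, sampling_rate_hz: float) -> Spectrum:
    """Magnitude spectrum of ``segment`` with 1/N normalization.

    N is the segment's own length, so bin_spacing = sampling_rate / N and the
    DC magnitude equals |mean(segment)|.
    """
    x = np.asarray(segment, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot transform an empty segment")
    n = x.size
    magnitudes = np.abs(np.fft.fft(x) / n)
    return Spectrum(magnitudes, sampling_rate_hz / n, n)


def spectral_attributes(spectrum: Spectrum, n_components: int = 30) -> np.ndarray:
    """Magnitudes of bins 0..n_components-1 (DC first)."""
    if spectrum.magnitudes.size < n_components:
        raise ValueError(
            f"segment has only {spectrum.magnitudes.size} bins, "
            f"need {n_components}"
        )
    return spectrum.magnitudes[:n_components].copy()


def build_instance(
    movement: Movement,
    sampling_rate_hz: float,
    params: FeatureParams = FeatureParams(),
) -> Instance:
    """Assemble one instance: decimated padded samples + spectral magnitudes."""
    padded = pad_to_length(movement, params.target_length)
    step = params.target_length // params.time_attrs
    time_part = padded[::step]
    source = movement.samples if params.fft_input == "native" else padded
    spec = spectral_attributes(dft(source, sampling_rate_hz), params.n_spectral)
    return Instance(np.concatenate([time_part, spec]), movement.label)


def build_dataset(
    movements: Sequence[Movement],
    sampling_rate_hz: float,
    params: FeatureParams = FeatureParams(),
    per_class_cap: int = 200,
    class_order: Sequence[str] = CLASSES,
) -> Dataset:
    """Featurize movements, keeping the first ``per_class_cap`` of each class.

    Movements are consumed in the given (temporal) order; classes with zero
    movements are omitted with a warning.
    """
    taken: dict[str, int] = {}
    instances: list[Instance] = []
    for movement in movements:
        if taken.get(movement.label, 0) >= per_class_cap:
            continue
        instances.append(build_instance(movement, sampling_rate_hz, params))
        taken[movement.label] = taken.get(movement.label, 0) + 1
    present = [c for c in class_order if taken.get(c)]
    present += sorted(set(taken) - set(present))
    for c in class_order:
        if c not in taken:
            warnings.warn(f"class {c!r} has no movements and is omitted", stacklevel=2)
    n_attrs = params.time_attrs + params.n_spectral
    names = tuple(f"a{i}" for i in range(1, n_attrs + 1))
    if not instances:
        return Dataset(np.empty((0, n_attrs)), np.empty(0, dtype="<U20"), (), names)
    X = np.vstack([inst.attributes for inst in instances])
    y = np.asarray([inst.label for inst in instances], dtype="<U20")
    return Dataset(X, y, tuple(present), names)
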