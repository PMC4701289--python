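"""Synthetic fiber-Bragg-grating (FBG) chewing sessions.

A strain sensor glued to the mandible sees one quasi-periodic strain cycle per
jaw movement: a positive pulse while the mouth opens, a shallower trough while
the jaw closes, riding on a food-dependent DC offset.  The optical interrogator
reports the Bragg wavelength, which shifts linearly with strain.  This module
generates labeled sessions with that structure: five behavioral classes
(dietary supplement, hay, ryegrass, rumination, idleness), class-specific peak
strains, chew rates and DC levels, multiplicative amplitude/period jitter and
additive noise.

All randomness flows through one :class:`numpy.random.Generator` per session;
identical :class:`SessionSpec` (including seed) gives bit-identical traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "CLASSES",
    "UNLABELED",
    "SensorModel",
    "ClassProfile",
    "SessionSpec",
    "StrainTrace",
    "WavelengthTrace",
    "default_profiles",
    "generate_movement",
    "generate_session",
    "encode_wavelength",
    "decode_strain",
    "write_trace_csv",
    "read_trace_csv",
]

#: Canonical class order; used for label tie-breaks everywhere downstream.
CLASSES = ("dietary_supplement", "hay", "ryegrass", "rumination", "idleness")

#: Marker for samples that carry no class label.
UNLABELED = ""

# Label dtype wide enough for every class name.
_LABEL_DTYPE = "<U20"


@dataclass(frozen=True)
class SensorModel:
    """Linear strain-to-wavelength transducer model.

    ``strain_sensitivity_pm_per_microstrain`` defaults to 1.2 pm per µm/m,
    a typical figure for a silica FBG near 1550 nm.
    """

    bragg_wavelength_nm: float = 1541.0
    strain_sensitivity_pm_per_microstrain: float = 1.2

    def __post_init__(self) -> None:
        if self.bragg_wavelength_nm <= 0:
            raise ValueError("bragg_wavelength_nm must be positive")
        if self.strain_sensitivity_pm_per_microstrain <= 0:
            raise ValueError("strain_sensitivity_pm_per_microstrain must be positive")

    @property
    def nm_per_microstrain(self) -> float:
        return self.strain_sensitivity_pm_per_microstrain / 1000.0


@dataclass(frozen=True)
class ClassProfile:
    """Class-conditional waveform parameters for one chewing pattern."""

    label: str
    peak_strain_microstrain: float
    dc_strain_microstrain: float
    fundamental_hz: float
    trough_fraction: float = 0.3
    amplitude_jitter_cv: float = 0.05
    period_jitter_cv: float = 0.05
    noise_sd_microstrain: float = 2.0

    def __post_init__(self) -> None:
        if self.peak_strain_microstrain < 0:
            raise ValueError("peak_strain_microstrain must be >= 0")
        if self.fundamental_hz <= 0:
            raise ValueError("fundamental_hz must be positive")
        for name in ("amplitude_jitter_cv", "period_jitter_cv"):
            cv = getattr(self, name)
            if not 0.0 <= cv <= 0.5:
                raise ValueError(f"{name} must be in [0, 0.5]")
        if self.noise_sd_microstrain < 0:
            raise ValueError("noise_sd_microstrain must be >= 0")
        if not 0.0 <= self.trough_fraction <= 1.0:
            raise ValueError("trough_fraction must be in [0, 1]")


def default_profiles() -> dict[str, ClassProfile]:
    """Default per-class profiles.

    Peak strains: supplement 50, hay 178, ryegrass 100, rumination 42,
    idleness 12 µm/m; chew-cycle fundamentals 2.49, 1.66, 2.0, 1.66, 1.54 Hz.
    DC offsets are strictly ordered idleness < rumination < every food class.
    Ryegrass carries a larger amplitude jitter so its peaks spread down toward
    ~60 µm/m; idleness/rumination carry smaller additive noise (quiet jaw).
    """
    return {
        "dietary_supplement": ClassProfile(
            "dietary_supplement", 50.0, 30.0, 2.49, noise_sd_microstrain=2.0
        ),
        "hay": ClassProfile("hay", 178.0, 40.0, 1.66, noise_sd_microstrain=2.0),
        "ryegrass": ClassProfile(
            "ryegrass", 100.0, 35.0, 2.0, amplitude_jitter_cv=0.2, noise_sd_microstrain=2.0
        ),
        "rumination": ClassProfile("rumination", 42.0, 15.0, 1.66, noise_sd_microstrain=1.5),
        "idleness": ClassProfile("idleness", 12.0, 5.0, 1.54, noise_sd_microstrain=0.5),
    }


@dataclass(frozen=True)
class SessionSpec:
    """Recipe for one labeled acquisition session.

    ``segments`` is an ordered list of (class name, movement count) pairs.
    When ``align_block_s`` is set, each class segment is padded (by widening
    its inter-movement gaps) to a whole number of averaging blocks so that
    downstream per-block means never mix classes, and the session ends with
    ``terminal_baseline_s`` of extra baseline that closes the final movement.
    """

    segments: tuple[tuple[str, int], ...]
    sampling_rate_hz: float = 1000.0
    inter_movement_gap_s: float = 0.1
    align_block_s: float | None = 1.0
    terminal_baseline_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.inter_movement_gap_s < 0:
            raise ValueError("inter_movement_gap_s must be >= 0")
        if self.align_block_s is not None and self.align_block_s <= 0:
            raise ValueError("align_block_s must be positive or None")
        for label, count in self.segments:
            if count < 1:
                raise ValueError(f"movement count for {label!r} must be >= 1")
        object.__setattr__(self, "segments", tuple((str(l), int(c)) for l, c in self.segments))


@dataclass
class StrainTrace:
    """Uniformly sampled strain series (µm/m) with per-sample labels."""

    samples: np.ndarray
    sampling_rate_hz: float
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=_LABEL_DTYPE)
        if self.samples.shape != self.labels.shape:
            raise ValueError("samples and labels must have equal length")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class WavelengthTrace:
    """Uniformly sampled Bragg-wavelength series (nm) with per-sample labels."""

    samples: np.ndarray
    sampling_rate_hz: float
    labels: np.ndarray

    __post_init__ = StrainTrace.__post_init__
    __len__ = StrainTrace.__len__


#: Correlation time of the additive noise (s).  Jaw-strain disturbances are
#: slow relative to a 1 kS/s sampling rate; band-limiting the noise keeps the
#: baseline crossings of the detrended signal clean, as in the recordings the
#: generator emulates.
NOISE_CORRELATION_S = 0.015


def _smooth_noise(n: int, sampling_rate_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise low-passed to NOISE_CORRELATION_S."""
    sigma = NOISE_CORRELATION_S * sampling_rate_hz
    white = rng.standard_normal(n)
    if sigma < 0.5 or n < 3:
        return white
    smooth = gaussian_filter1d(white, sigma, mode="reflect")
    # variance of Gaussian-filtered white noise is 1 / (2 sigma sqrt(pi))
    return smooth * math.sqrt(2.0 * sigma * math.sqrt(math.pi))


def _movement_waveform(n: int, peak: float, trough_fraction: float) -> np.ndarray:
    # Raised-cosine aperture pulse over the first ~60% of the cycle, then a
    # negative raised-cosine closure trough; starts and ends at the baseline.
    n_pulse = min(n - 1, max(2, round(0.6 * n)))
    n_trough = n - n_pulse
    t1 = np.arange(n_pulse) / n_pulse
    t2 = np.arange(n_trough) / n_trough
    pulse = peak * 0.5 * (1.0 - np.cos(2.0 * np.pi * t1))
    trough = -trough_fraction * peak * 0.5 * (1.0 - np.cos(2.0 * np.pi * t2))
    return np.concatenate([pulse, trough])


def generate_movement(
    profile: ClassProfile,
    sampling_rate_hz: float,
    rng: np.random.Generator,
) -> StrainTrace:
    """Generate one chew cycle for ``profile``.

    The cycle has nominal duration ``1/fundamental_hz`` (multiplicatively
    jittered), begins and ends at the DC baseline, and contains one aperture
    peak of height ~``peak_strain`` above DC followed by one closure trough of
    depth ``trough_fraction * peak`` below DC, plus additive Gaussian noise.

    Raises ``ValueError`` if the sampling rate does not resolve the cycle
    (``sampling_rate_hz <= 2 * fundamental_hz``).
    """
    if sampling_rate_hz <= 2.0 * profile.fundamental_hz:
        raise ValueError(
            f"sampling rate {sampling_rate_hz} Hz aliases a "
            f"{profile.fundamental_hz} Hz movement"
        )
    nominal = 1.0 / profile.fundamental_hz
    period = nominal * (1.0 + profile.period_jitter_cv * rng.standard_normal())
    period = float(np.clip(period, 0.5 * nominal, 2.0 * nominal))
    peak = profile.peak_strain_microstrain * (
        1.0 + profile.amplitude_jitter_cv * rng.standard_normal()
    )
    peak = max(peak, 0.05 * profile.peak_strain_microstrain)
    n = max(4, round(sampling_rate_hz * period))
    samples = profile.dc_strain_microstrain + _movement_waveform(
        n, peak, profile.trough_fraction
    )
    if profile.noise_sd_microstrain > 0:
        samples = samples + profile.noise_sd_microstrain * _smooth_noise(
            n, sampling_rate_hz, rng
        )
    labels = np.full(n, profile.label, dtype=_LABEL_DTYPE)
    return StrainTrace(samples, sampling_rate_hz, labels)


def _baseline_chunk(
    profile: ClassProfile, n: int, sampling_rate_hz: float, rng: np.random.Generator
) -> np.ndarray:
    chunk = np.full(n, profile.dc_strain_microstrain, dtype=np.float64)
    if profile.noise_sd_microstrain > 0 and n > 0:
        chunk += profile.noise_sd_microstrain * _smooth_noise(n, sampling_rate_hz, rng)
    return chunk


def generate_session(
    spec: SessionSpec,
    profiles: Mapping[str, ClassProfile] | None = None,
) -> StrainTrace:
    """Assemble a full labeled session from ``spec``.

    Movements of each segment are concatenated with baseline gaps; gap samples
    carry the segment's class label.  With block alignment on (the default),
    each segment occupies a whole number of averaging blocks and one extra
    baseline block ends the session, so blockwise detrending downstream sees
    class-pure blocks and a terminating zero crossing.
    """
    if profiles is None:
        profiles = default_profiles()
    for label, _ in spec.segments:
        if label not in profiles:
            raise ValueError(f"unknown class name {label!r}")
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate_hz
    gap_n = round(spec.inter_movement_gap_s * fs)
    block_n = None
    if spec.align_block_s is not None:
        block_n = max(1, round(spec.align_block_s * fs))

    chunks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for label, count in spec.segments:
        profile = profiles[label]
        movements = [generate_movement(profile, fs, rng) for _ in range(count)]
        content_n = sum(len(m) for m in movements) + count * gap_n
        # Widen this segment's gaps evenly so it ends on a block boundary.
        extra = 0
        if block_n is not None:
            extra = (-content_n) % block_n
        per_gap = extra // count
        remainder = extra - per_gap * count
        for i, movement in enumerate(movements):
            this_gap = gap_n + per_gap + (1 if i < remainder else 0)
            chunks.append(movement.samples)
            chunks.append(_baseline_chunk(profile, this_gap, fs, rng))
            labels.append(movement.labels)
            labels.append(np.full(this_gap, label, dtype=_LABEL_DTYPE))
    if spec.terminal_baseline_s > 0:
        last_label = spec.segments[-1][0]
        profile = profiles[last_label]
        n_term = round(spec.terminal_baseline_s * fs)
        # A 1 µm/m settling ramp guarantees the terminal baseline crosses its
        # own block mean, closing the final movement for the segmenter.
        chunk = _baseline_chunk(profile, n_term, fs, rng)
        chunk += np.linspace(0.0, 1.0, n_term)
        chunks.append(chunk)
        labels.append(np.full(n_term, last_label, dtype=_LABEL_DTYPE))
    return StrainTrace(np.concatenate(chunks), fs, np.concatenate(labels))


def encode_wavelength(trace: StrainTrace, sensor: SensorModel) -> WavelengthTrace:
    """Map strain to Bragg wavelength: λ(t) = λB + k·ε(t), k in nm per µm/m."""
    samples = sensor.bragg_wavelength_nm + sensor.nm_per_microstrain * trace.samples
    return WavelengthTrace(samples, trace.sampling_rate_hz, trace.labels.copy())


def decode_strain(trace: WavelengthTrace, sensor: SensorModel) -> StrainTrace:
    """Exact inverse of :func:`encode_wavelength`: ε(t) = (λ(t) − λB)/k."""
    samples = (trace.samples - sensor.bragg_wavelength_nm) / sensor.nm_per_microstrain
    return StrainTrace(samples, trace.sampling_rate_hz, trace.labels.copy())


def write_trace_csv(trace: WavelengthTrace, path) -> None:
    """Write a wavelength trace as CSV with columns time_s, wavelength_nm, label."""
    n = len(trace)
    frame = pd.DataFrame(
        {
            "time_s": np.arange(n) / trace.sampling_rate_hz,
            "wavelength_nm": trace.samples,
            "label": trace.labels,
        }
    )
    frame.to_csv(path, index=False, float_format="%.9f")


def read_trace_csv(path, sampling_rate_hz: float | None = None) -> WavelengthTrace:
    """Read a trace CSV written by :func:`write_trace_csv`.

    The sampling rate is inferred from the time column unless given.
    """
    frame = pd.read_csv(path, keep_default_na=False, dtype={"label": str})
    required = {"time_s", "wavelength_nm", "label"}
    if not required.issubset(frame.columns):
        raise ValueError(f"trace CSV must have columns {sorted(required)}")
    if len(frame) == 0:
        raise ValueError("trace CSV contains no samples")
    if sampling_rate_hz is None:
        if len(frame) < 2:
            raise ValueError("cannot infer sampling rate from a single sample")
        dt = np.diff(frame["time_s"].to_numpy())
        sampling_rate_hz = 1.0 / float(np.median(dt))
    return WavelengthTrace(
        frame["wavelength_nm"].to_numpy(dtype=np.float64),
        float(sampling_rate_hz),
        frame["label"].to_numpy(dtype=_LABEL_DTYPE),
    )
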