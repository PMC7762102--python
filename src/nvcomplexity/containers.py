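"""In-memory carriers for multimodal EEG-fNIRS data.

All signal containers are thin dataclasses around ``numpy`` arrays with a
uniform sampling rate.  EEG and derived envelope series live in
:class:`MultichannelSeries`; raw two-wavelength optical intensities in
:class:`OpticalRecording`; optical densities and hemoglobin concentration
changes in :class:`OpticalDensitySeries` / :class:`HbSeries`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

LONG = "long"
SHORT = "short"


def _as2d(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[np.newaxis, :]
    if a.ndim != 2:
        raise ValueError(f"expected (channels, samples) array, got shape {a.shape}")
    return a


@dataclass
class MultichannelSeries:
    """Uniformly sampled channels x samples array with rate and labels."""

    data: np.ndarray
    rate: float
    labels: Sequence[str] = field(default_factory=list)
    units: str = "a.u."

    def __post_init__(self):
        self.data = _as2d(self.data)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not self.labels:
            self.labels = [f"ch{i:02d}" for i in range(self.data.shape[0])]
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels do not match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate

    def with_data(self, data: np.ndarray) -> "MultichannelSeries":
        return replace(self, data=_as2d(data))


@dataclass
class GFPSeries:
    """Global field power: across-channel SD of an EEG-derived quantity."""

    values: np.ndarray
    rate: float
    band: str = ""
    phase: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("GFP is a single time course")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("GFP contains non-finite values")
        if np.any(self.values < -1e-12):
            raise ValueError("GFP must be non-negative")


@dataclass
class OpticalRecording:
    """Two-wavelength intensity time courses with channel geometry.

    ``intensities`` has shape (channels, wavelengths, samples) in detector
    counts; ``distances`` are geometric source-detector separations in mm and
    ``roles`` marks each channel ``"long"`` (cortical, 35 mm) or ``"short"``
    (scalp-only, 15 mm).
    """

    intensities: np.ndarray
    rate: float
    wavelengths: Sequence[float] = (690.0, 830.0)
    distances: np.ndarray | None = None
    roles: Sequence[str] | None = None
    labels: Sequence[str] = field(default_factory=list)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be (channels, wavelengths, samples)")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.intensities.shape[1] != len(self.wavelengths):
            raise ValueError("wavelength axis mismatch")
        n_ch = self.intensities.shape[0]
        if self.distances is None:
            self.distances = np.full(n_ch, 35.0)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.roles is None:
            self.roles = [LONG] * n_ch
        self.roles = list(self.roles)
        if len(self.roles) != n_ch or len(self.distances) != n_ch:
            raise ValueError("geometry does not match channel count")
        if not self.labels:
            self.labels = [f"S{i + 1}-D{i + 1}" for i in range(n_ch)]
        self.labels = list(self.labels)

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[2]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def channel_indices(self, role: str) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r == role], dtype=int)


@dataclass
class OpticalDensitySeries:
    """Optical densities -ln(I/I_avg), dimensionless, per channel/wavelength."""

    od: np.ndarray
    rate: float
    wavelengths: np.ndarray
    distances: np.ndarray
    roles: Sequence[str]

    def __post_init__(self):
        self.od = np.asarray(self.od, dtype=float)
        if self.od.ndim != 3:
            raise ValueError("od must be (channels, wavelengths, samples)")
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        self.roles = list(self.roles)

    @property
    def n_channels(self) -> int:
        return self.od.shape[0]

    @property
    def n_samples(self) -> int:
        return self.od.shape[2]

    def with_od(self, od: np.ndarray) -> "OpticalDensitySeries":
        return replace(self, od=np.asarray(od, dtype=float))

    def channel_indices(self, role: str) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r == role], dtype=int)


@dataclass
class HbSeries:
    """Hemoglobin concentration changes (uM) per channel over time."""

    o2hb: np.ndarray
    hhb: np.ndarray
    rate: float
    roles: Sequence[str] | None = None

    def __post_init__(self):
        self.o2hb = _as2d(self.o2hb)
        self.hhb = _as2d(self.hhb)
        if self.o2hb.shape != self.hhb.shape:
            raise ValueError("O2Hb/HHb shape mismatch")
        if self.roles is not None:
            self.roles = list(self.roles)
            if len(self.roles) != self.o2hb.shape[0]:
                raise ValueError("roles do not match channel count")

    @property
    def n_channels(self) -> int:
        return self.o2hb.shape[0]

    @property
    def n_samples(self) -> int:
        return self.o2hb.shape[1]

    def channel_indices(self, role: str) -> np.ndarray:
        if self.roles is None:
            raise ValueError("no channel roles attached")
        return np.array([i for i, r in enumerate(self.roles) if r == role], dtype=int)

    def select(self, idx: np.ndarray) -> "HbSeries":
        roles = [self.roles[i] for i in idx] if self.roles is not None else None
        return HbSeries(self.o2hb[idx], self.hhb[idx], self.rate, roles)


PhaseMarker = tuple[str, float, float]


@dataclass
class SubjectRecording:
    """One subject's concurrent EEG + optical recording with task phases.

    ``truth`` optionally carries the generating model's latent variables
    (injected hemoglobin, neural drive, scalp waveform) for validation of the
    processing chain; it is never used by the analysis itself.
    """

    subject_id: str
    group: int  # AD = 1, HC = 0
    age: float
    eeg: MultichannelSeries
    optical: OpticalRecording
    phase_markers: list[PhaseMarker]
    truth: dict | None = None

    def __post_init__(self):
        if self.group not in (0, 1):
            raise ValueError("group label must be 0 (HC) or 1 (AD)")
        last_end = 0.0
        for name, start, end in self.phase_markers:
            if start < last_end - 1e-9 or end <= start:
                raise ValueError(f"phase {name!r} interval invalid or overlapping")
            last_end = end
        span = min(self.eeg.duration, self.optical.duration)
        if last_end > span + 1e-6:
            raise ValueError("phase markers extend past the recording")

    @property
    def phases(self) -> list[str]:
        return [name for name, _, _ in self.phase_markers]
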