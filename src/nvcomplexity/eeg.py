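"""EEG preprocessing: broadband/notch filtering, five-band Hilbert power
envelopes, and global field power (GFP).

All filtering is zero-phase (forward-backward Butterworth).  The five
analysis bands are implemented exactly as printed in the protocol the
pipeline follows — note that the theta (3.5-8.2 Hz) and alpha (7.4-13 Hz)
bands deliberately overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .containers import GFPSeries, MultichannelSeries, PhaseMarker

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "BAND_ORDER",
    "broadband_filter",
    "band_envelope",
    "global_field_power",
    "slice_phase",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self):
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(f"invalid band edges for {self.name!r}")


BAND_ORDER = ("theta", "alpha", "beta", "delta", "gamma")

DEFAULT_BANDS: dict[str, BandDefinition] = {
    "theta": BandDefinition("theta", 3.5, 8.2),
    "alpha": BandDefinition("alpha", 7.4, 13.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "delta": BandDefinition("delta", 1.0, 4.0),
    "gamma": BandDefinition("gamma", 26.0, 40.0),
}


def _sos_filtfilt(data: np.ndarray, sos: np.ndarray) -> np.ndarray:
    return sps.sosfiltfilt(sos, data, axis=-1)


def broadband_filter(
    eeg: MultichannelSeries,
    low_hz: float = 1.0,
    high_hz: float = 80.0,
    notch_hz: float = 50.0,
    notch_width: float = 2.0,
    order: int = 2,
) -> MultichannelSeries:
    """Zero-lag 2nd-order Butterworth band-pass (1-80 Hz) plus 50 Hz notch."""
    if eeg.rate <= 2 * high_hz:
        raise ValueError(
            f"sampling rate {eeg.rate} Hz too low for a {high_hz} Hz cutoff"
        )
    sos_bp = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=eeg.rate, output="sos")
    sos_notch = sps.butter(
        order,
        [notch_hz - notch_width, notch_hz + notch_width],
        btype="bandstop",
        fs=eeg.rate,
        output="sos",
    )
    out = _sos_filtfilt(eeg.data, sos_bp)
    out = _sos_filtfilt(out, sos_notch)
    return eeg.with_data(out)


def band_envelope(
    eeg: MultichannelSeries, band: BandDefinition, order: int = 4
) -> MultichannelSeries:
    """Per-channel power temporal envelope of one frequency band.

    Zero-lag Butterworth band-pass to [low, high] followed by the modulus of
    the Hilbert analytic signal.
    """
    nyq = eeg.rate / 2.0
    if band.high_hz >= nyq:
        raise ValueError(f"band {band.name!r} exceeds Nyquist ({nyq} Hz)")
    sos = sps.butter(
        order, [band.low_hz, band.high_hz], btype="bandpass", fs=eeg.rate, output="sos"
    )
    narrow = _sos_filtfilt(eeg.data, sos)
    env = np.abs(sps.hilbert(narrow, axis=-1))
    return eeg.with_data(env)


def global_field_power(
    envelopes: MultichannelSeries, band: str = "", phase: str = ""
) -> GFPSeries:
    """Instantaneous across-channel population SD of the envelopes.

    GFP at each sample is the root-mean-square deviation of channel values
    from the instantaneous across-channel mean; it is invariant to a common
    offset on all channels and scales linearly with channel gain.
    """
    if envelopes.n_channels < 2:
        raise ValueError("GFP needs at least two channels")
    values = np.std(envelopes.data, axis=0, ddof=0)
    return GFPSeries(values=values, rate=envelopes.rate, band=band, phase=phase)


def _phase_bounds(markers: list[PhaseMarker], phase: str) -> tuple[float, float]:
    for name, start, end in markers:
        if name == phase:
            return start, end
    known = [name for name, _, _ in markers]
    raise KeyError(f"phase {phase!r} not found; available: {known}")


def slice_phase(
    series: MultichannelSeries, markers: list[PhaseMarker], phase: str
) -> MultichannelSeries:
    """Samples of the named phase, half-open in time: t in [start, end)."""
    start, end = _phase_bounds(markers, phase)
    i0 = int(np.ceil(start * series.rate - 1e-9))
    i1 = int(np.ceil(end * series.rate - 1e-9))
    i1 = min(i1, series.n_samples)
    if i1 <= i0:
        raise ValueError(f"phase {phase!r} spans no samples")
    return series.with_data(series.data[:, i0:i1])


def trim_edges(series: MultichannelSeries, seconds: float = 1.0) -> MultichannelSeries:
    """Drop transient-contaminated samples at both epoch edges."""
    n = int(round(seconds * series.rate))
    if series.n_samples <= 2 * n:
        raise ValueError("series too short to trim edges")
    return series.with_data(series.data[:, n : series.n_samples - n])
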