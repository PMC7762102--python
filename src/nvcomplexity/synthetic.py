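"""Synthetic multimodal EEG-fNIRS cohort generator.

Emulates the statistical structure the analysis pipeline assumes, for a
two-group (AD vs healthy-control) working-memory study:

* EEG: per channel, a sum over the five analysis bands of amplitude-
  modulated narrowband Gaussian noise (a band-shared "cortical source" mixed
  with channel-specific noise) plus broadband 1/f background, at 250 Hz.
* Neurovascular coupling: a latent neural drive — the low-passed Hilbert
  power envelope of the summed band sources — is convolved with the
  canonical HRF, scaled by a group-dependent coupling gain, and injected
  into the *long* optical channels as dO2Hb > 0 with dHHb = -0.3 * dO2Hb
  (functional-hyperemia polarity).
* Scalp physiology: Mayer-wave (~0.1 Hz), respiratory (~0.3 Hz) and cardiac
  (~1 Hz) oscillations form a single global scalp waveform injected, up to a
  per-channel gain, into both short and long channels.
* Optics: channel hemoglobin time courses are mapped to two-wavelength
  intensities by the exact inverse of the modified Beer-Lambert operation
  used in preprocessing (same extinction/DPF constants), with optional
  measurement noise and motion spikes added on the optical-density scale.

Identical configuration and seed give a bit-identical cohort.  Each
:class:`~nvcomplexity.containers.SubjectRecording` carries the latent
ground-truth signals in ``truth`` for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .containers import (
    LONG,
    SHORT,
    MultichannelSeries,
    OpticalRecording,
    SubjectRecording,
)
from .features import HRFParams, canonical_hrf
from .fnirs import ChromophoreConstants

__all__ = ["SyntheticConfig", "generate_subject", "generate_cohort", "PHASE_NAMES"]

PHASE_NAMES = ("ROCF_copying", "RPM", "ROCF_recall")

# Group age moments (years): AD mean 67.6 SD 9.3, HC mean 69.2 SD 9.1,
# truncated to [50, 90]; the DPF depends on age, so ages matter optically.
_AGE_MOMENTS = {1: (67.6, 9.3), 0: (69.2, 9.1)}
_AGE_RANGE = (50.0, 90.0)


@dataclass
class SyntheticConfig:
    """Cohort-level generating parameters (defaults = study conditions)."""

    n_ad: int = 17
    n_hc: int = 18
    eeg_rate: float = 250.0
    fnirs_rate: float = 10.42
    n_eeg_channels: int = 16
    n_long_channels: int = 16
    n_short_channels: int = 4
    phase_durations: tuple[float, ...] = (240.0, 240.0, 240.0)
    # per-band oscillation amplitudes, uV
    band_powers: dict[str, float] = field(
        default_factory=lambda: {
            "delta": 20.0, "theta": 10.0, "alpha": 15.0, "beta": 8.0, "gamma": 5.0,
        }
    )
    pink_amplitude: float = 10.0  # broadband 1/f background, uV
    coupling_gain_ad: float = 0.1
    coupling_gain_hc: float = 1.0
    nc_amplitude_um: float = 0.5  # dO2Hb SD at coupling gain 1, uM
    hhb_ratio: float = 0.3  # dHHb = -ratio * dO2Hb
    # Mayer (~0.1 Hz), respiratory (~0.3 Hz), cardiac (~1 Hz) amplitudes, uM
    scalp_amplitudes: tuple[float, float, float] = (0.4, 0.15, 0.3)
    noise_sd: float = 0.01  # measurement noise on the OD scale
    spike_rate: float = 1.0  # motion spikes per minute per trace
    seed: int = 0

    def __post_init__(self):
        if self.n_ad < 1 or self.n_hc < 1:
            raise ValueError("both groups need at least one subject")
        if self.eeg_rate <= 0 or self.fnirs_rate <= 0:
            raise ValueError("sampling rates must be positive")
        if any(d <= 0 for d in self.phase_durations):
            raise ValueError("phase durations must be positive")

    @property
    def phase_markers(self) -> list[tuple[str, float, float]]:
        markers, t = [], 0.0
        for name, dur in zip(PHASE_NAMES, self.phase_durations):
            markers.append((name, t, t + dur))
            t += dur
        return markers

    @property
    def total_duration(self) -> float:
        return float(sum(self.phase_durations))


_BAND_EDGES = {
    "delta": (1.0, 4.0), "theta": (3.5, 8.2), "alpha": (7.4, 13.0),
    "beta": (13.0, 30.0), "gamma": (26.0, 40.0),
}


def _lowpass(x: np.ndarray, cutoff: float, rate: float, order: int = 2) -> np.ndarray:
    sos = sps.butter(order, cutoff, btype="lowpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, x)


def _narrowband(rng, shape, band: tuple[float, float], rate: float) -> np.ndarray:
    """Unit-variance narrowband Gaussian noise; last axis is time."""
    sos = sps.butter(4, band, btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _pink(rng, n: int) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec *= f ** -0.5
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def _draw_age(rng, group: int) -> float:
    mean, sd = _AGE_MOMENTS[group]
    lo, hi = _AGE_RANGE
    for _ in range(1000):
        age = mean + sd * rng.standard_normal()
        if lo <= age <= hi:
            return float(age)
    return float(np.clip(mean, lo, hi))


def generate_subject(
    config: SyntheticConfig,
    group: int,
    subject_seed: int,
    subject_id: str | None = None,
) -> SubjectRecording:
    """Generate one subject's concurrent EEG + two-wavelength optical data."""
    if group not in (0, 1):
        raise ValueError("group must be 0 (HC) or 1 (AD)")
    rng = np.random.default_rng(subject_seed)
    age = _draw_age(rng, group)
    duration = config.total_duration
    n_eeg = int(round(duration * config.eeg_rate))
    n_f = int(round(duration * config.fnirs_rate))

    # ----- EEG: amplitude-modulated band oscillations + 1/f background ----
    # Each band has one shared cortical source projecting to the channels
    # with heterogeneous topographic gains (so the across-channel dispersion
    # of the envelopes — the GFP — scales with source activity), plus
    # channel-local narrowband noise.
    mix = 0.8  # relative weight of the shared source vs local noise
    eeg = np.zeros((config.n_eeg_channels, n_eeg))
    summed_sources = np.zeros(n_eeg)
    for name, amp in config.band_powers.items():
        band = _BAND_EDGES[name]
        modulator = 1.0 + 0.4 * _standardize(
            _lowpass(rng.standard_normal(n_eeg), 0.2, config.eeg_rate)
        )
        np.clip(modulator, 0.05, None, out=modulator)
        source = _narrowband(rng, n_eeg, band, config.eeg_rate)
        summed_sources += amp * modulator * source
        topography = rng.uniform(0.2, 1.4, size=config.n_eeg_channels)
        local = _narrowband(
            rng, (config.n_eeg_channels, n_eeg), band, config.eeg_rate
        )
        eeg += (amp * modulator) * (
            mix * topography[:, None] * source[None, :]
            + np.sqrt(1.0 - mix**2) * local
        )
    for ch in range(config.n_eeg_channels):
        eeg[ch] += config.pink_amplitude * _pink(rng, n_eeg)

    eeg_series = MultichannelSeries(
        data=eeg,
        rate=config.eeg_rate,
        labels=[f"EEG{c + 1:03d}" for c in range(config.n_eeg_channels)],
        units="uV",
    )

    # ----- latent neural drive -> HRF -> hemoglobin in long channels ------
    drive = np.abs(sps.hilbert(summed_sources))
    drive = _lowpass(drive, 0.5, config.eeg_rate, order=4)
    n_dec = max(int(round(n_eeg / config.eeg_rate * config.fnirs_rate)), 1)
    drive_f = sps.resample(drive, n_dec)[:n_f]
    if drive_f.size < n_f:
        drive_f = np.pad(drive_f, (0, n_f - drive_f.size), mode="edge")
    hrf = canonical_hrf(HRFParams(), config.fnirs_rate)
    neural = sps.fftconvolve(_standardize(drive_f), hrf, mode="full")[:n_f]
    neural = _standardize(neural)
    gain = config.coupling_gain_ad if group == 1 else config.coupling_gain_hc

    # ----- global scalp waveform ------------------------------------------
    t_f = np.arange(n_f) / config.fnirs_rate
    scalp = np.zeros(n_f)
    for amp, freq in zip(config.scalp_amplitudes, (0.1, 0.3, 1.0)):
        phase = rng.uniform(0, 2 * np.pi)
        slow = 1.0 + 0.3 * _standardize(
            _lowpass(rng.standard_normal(n_f), 0.05, config.fnirs_rate)
        )
        scalp += amp * np.sin(2 * np.pi * freq * t_f + phase) * slow

    # ----- per-channel hemoglobin and forward Beer-Lambert ----------------
    n_ch = config.n_long_channels + config.n_short_channels
    roles = [LONG] * config.n_long_channels + [SHORT] * config.n_short_channels
    distances = np.array(
        [35.0] * config.n_long_channels + [15.0] * config.n_short_channels
    )
    scalp_gain = rng.uniform(0.5, 1.5, size=n_ch)
    neural_gain = rng.uniform(0.8, 1.2, size=config.n_long_channels)

    o2hb = np.empty((n_ch, n_f))
    for c in range(n_ch):
        o2hb[c] = scalp_gain[c] * scalp
        if roles[c] == LONG:
            o2hb[c] += gain * config.nc_amplitude_um * neural_gain[c] * neural
    hhb = -config.hhb_ratio * o2hb

    constants = ChromophoreConstants()
    wavelengths = (690.0, 830.0)
    m = constants.mbll_matrix(wavelengths, age)
    conc = np.stack([o2hb, hhb], axis=1)  # (channels, chromophores, samples)
    od = np.einsum("ij,cjt->cit", m, conc) * distances[:, None, None]

    if config.noise_sd > 0:
        od += config.noise_sd * rng.standard_normal(od.shape)
    if config.spike_rate > 0:
        spike_kernel = np.exp(-np.arange(4) / 1.5)
        minutes = duration / 60.0
        base = max(config.noise_sd, 0.005)
        for c in range(n_ch):
            for w in range(2):
                for _ in range(rng.poisson(config.spike_rate * minutes)):
                    pos = rng.integers(0, n_f)
                    amp = rng.uniform(5, 15) * base * rng.choice((-1.0, 1.0))
                    seg = min(spike_kernel.size, n_f - pos)
                    od[c, w, pos : pos + seg] += amp * spike_kernel[:seg]

    if np.max(np.abs(od)) > 50:
        raise ValueError(
            "generated optical densities too large (amplitudes too large); "
            "intensities would vanish"
        )
    i0 = 1e6 * rng.uniform(0.5, 2.0, size=(n_ch, 2, 1))
    intensities = i0 * np.exp(-od)
    if np.any(intensities <= 0) or not np.all(np.isfinite(intensities)):
        raise ValueError("non-positive generated intensity (amplitudes too large)")

    optical = OpticalRecording(
        intensities=intensities,
        rate=config.fnirs_rate,
        wavelengths=wavelengths,
        distances=distances,
        roles=roles,
    )
    if subject_id is None:
        subject_id = f"{'AD' if group else 'HC'}{subject_seed % 1000:03d}"
    markers = [
        (name, s, min(e, min(eeg_series.duration, optical.duration)))
        for name, s, e in config.phase_markers
    ]
    truth = {
        "o2hb": o2hb, "hhb": hhb, "neural": neural, "scalp": scalp,
        "coupling_gain": gain, "age": age,
    }
    return SubjectRecording(
        subject_id=subject_id,
        group=group,
        age=age,
        eeg=eeg_series,
        optical=optical,
        phase_markers=markers,
        truth=truth,
    )


def generate_cohort(config: SyntheticConfig) -> list[SubjectRecording]:
    """Generate the full two-group cohort with per-subject seeds derived
    deterministically from ``config.seed``."""
    n_total = config.n_ad + config.n_hc
    seeds = np.random.SeedSequence(config.seed).generate_state(n_total)
    subjects = []
    for i in range(config.n_ad):
        subjects.append(
            generate_subject(config, 1, int(seeds[i]), subject_id=f"AD{i + 1:02d}")
        )
    for i in range(config.n_hc):
        subjects.append(
            generate_subject(
                config, 0, int(seeds[config.n_ad + i]), subject_id=f"HC{i + 1:02d}"
            )
        )
    return subjects
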