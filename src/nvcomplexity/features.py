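"""Per-subject, per-phase construction of the 17 complexity features.

The feature vector combines three families:

* 5 EEG SampEn values — sample entropy of the global-field-power (GFP) time
  course of the Hilbert power envelope in each frequency band;
* 2 fNIRS SampEn values — sample entropy of the channel-averaged O2Hb and
  HHb concentration changes;
* 10 neurovascular-coupling CondEn values — conditional entropy of each
  hemoglobin series given each band's GFP envelope after convolution with
  the canonical hemodynamic response function (HRF) and resampling to the
  fNIRS rate.

Every entropy input passes a Phillips-Perron stationarity gate (with one
linear-detrend retry); features whose inputs stay non-stationary are marked
invalid rather than silently zeroed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.stats import gamma as gamma_dist

from . import eeg as eegmod
from .containers import GFPSeries, MultichannelSeries, OpticalRecording, SubjectRecording
from .entropy import EntropyParams, check_stationarity, conditional_entropy, sample_entropy, truncate_common
from .fnirs import ChromophoreConstants, process_optical

__all__ = [
    "HRFParams",
    "AnalysisConfig",
    "FeatureVector",
    "FEATURE_NAMES",
    "FAMILIES",
    "canonical_hrf",
    "eeg_to_hemo_timescale",
    "compute_feature_vector",
    "features_to_frame",
]


EEG_FEATURES = tuple(f"sampen_eeg_{b}" for b in eegmod.BAND_ORDER)
FNIRS_FEATURES = ("sampen_o2hb", "sampen_hhb")
NC_FEATURES = tuple(
    f"conden_{hb}_{b}" for hb in ("o2hb", "hhb") for b in eegmod.BAND_ORDER
)
FEATURE_NAMES: tuple[str, ...] = EEG_FEATURES + FNIRS_FEATURES + NC_FEATURES

FAMILIES: dict[str, tuple[str, ...]] = {
    "EEG": EEG_FEATURES,
    "fNIRS": FNIRS_FEATURES,
    "NC": NC_FEATURES,
}


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF; the response peaks at ``peak_delay`` s
    (gamma mode parameterization) with an undershoot at ``undershoot_delay`` s
    scaled by 1/``peak_undershoot_ratio``."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    kernel_length: float = 32.0


def canonical_hrf(params: HRFParams, rate: float) -> np.ndarray:
    """Sampled double-gamma HRF kernel, peak-normalized to 1."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    n = int(round(params.kernel_length * rate))
    if n < 10:
        raise ValueError("kernel too short: kernel_length * rate < 10 samples")
    t = np.arange(n) / rate
    peak_shape = params.peak_delay / params.peak_dispersion + 1.0
    under_shape = params.undershoot_delay / params.undershoot_dispersion + 1.0
    kernel = gamma_dist.pdf(t, peak_shape, scale=params.peak_dispersion)
    kernel -= (
        gamma_dist.pdf(t, under_shape, scale=params.undershoot_dispersion)
        / params.peak_undershoot_ratio
    )
    peak = kernel.max()
    if peak <= 0 or kernel.sum() <= 0:
        raise ValueError("degenerate HRF parameters")
    return kernel / peak


def _resample(values: np.ndarray, rate: float, target_rate: float) -> np.ndarray:
    frac = Fraction(target_rate / rate).limit_denominator(100_000)
    return sps.resample_poly(values, frac.numerator, frac.denominator)


def eeg_to_hemo_timescale(
    gfp: GFPSeries,
    hrf_params: HRFParams,
    target_rate: float,
    trim_start: bool = True,
) -> np.ndarray:
    """Convolve a GFP envelope with the canonical HRF and move it to the
    hemodynamic timescale.

    Causal same-length convolution, anti-alias low-pass at ``0.4 *
    target_rate``, then evaluation on the target-rate time grid (the
    low-pass leaves no content near the new Nyquist, so grid interpolation
    is exact to numerical precision); by default the first ``kernel_length``
    seconds (convolution start-up transient) are discarded.
    """
    if target_rate > gfp.rate:
        raise ValueError("target rate must not exceed the envelope rate")
    kernel = canonical_hrf(hrf_params, gfp.rate)
    conv = sps.fftconvolve(gfp.values, kernel, mode="full")[: gfp.values.size]
    sos = sps.butter(4, 0.4 * target_rate, btype="lowpass", fs=gfp.rate, output="sos")
    conv = sps.sosfiltfilt(sos, conv)
    n_out = int(np.floor(conv.size / gfp.rate * target_rate))
    t_dst = np.arange(n_out) / target_rate
    out = np.interp(t_dst, np.arange(conv.size) / gfp.rate, conv)
    if trim_start:
        n_trim = int(math.ceil(hrf_params.kernel_length * target_rate))
        if n_trim >= out.size:
            raise ValueError("series shorter than the HRF start-up transient")
        out = out[n_trim:]
    return out


@dataclass
class AnalysisConfig:
    """All tunables of the feature pipeline, with study defaults."""

    bands: dict[str, eegmod.BandDefinition] = field(
        default_factory=lambda: dict(eegmod.DEFAULT_BANDS)
    )
    entropy: EntropyParams = field(default_factory=EntropyParams)
    hrf: HRFParams = field(default_factory=HRFParams)
    conden_bins: int = 8
    envelope_decimate_hz: float = 25.0  # SampEn cost control; 0 disables
    pp_alpha: float = 0.05
    edge_trim_s: float = 1.0
    despike: bool = True
    despike_alpha: float = 0.1
    constants: ChromophoreConstants = field(default_factory=ChromophoreConstants)


@dataclass
class FeatureVector:
    """The 17 named complexity features for one subject x phase.

    ``valid`` flags features excluded by the stationarity gate (and, later,
    by the bootstrap confidence-interval filter); invalid features hold NaN.
    """

    subject_id: str
    phase: str
    group: int
    values: dict[str, float]
    valid: dict[str, bool]

    def __post_init__(self):
        if tuple(self.values) != FEATURE_NAMES or tuple(self.valid) != FEATURE_NAMES:
            raise ValueError("feature vector must contain exactly the 17 named features")


def _slice_optical(optical: OpticalRecording, markers, phase: str) -> OpticalRecording:
    start, end = None, None
    for name, s, e in markers:
        if name == phase:
            start, end = s, e
    if start is None:
        raise KeyError(f"phase {phase!r} not found")
    i0 = int(np.ceil(start * optical.rate - 1e-9))
    i1 = min(int(np.ceil(end * optical.rate - 1e-9)), optical.n_samples)
    return OpticalRecording(
        intensities=optical.intensities[:, :, i0:i1],
        rate=optical.rate,
        wavelengths=optical.wavelengths,
        distances=optical.distances,
        roles=optical.roles,
        labels=optical.labels,
    )


def _gated(series: np.ndarray, alpha: float):
    """Apply the stationarity gate; returns (series-or-None, ok)."""
    verdict, out = check_stationarity(series, alpha=alpha)
    return (out, True) if verdict.stationary else (None, False)


def compute_feature_vector(
    subject: SubjectRecording,
    phase: str,
    config: AnalysisConfig | None = None,
) -> FeatureVector:
    """Run both preprocessing chains on one phase and assemble the features."""
    if config is None:
        config = AnalysisConfig()
    fnirs_rate = subject.optical.rate

    # --- EEG chain: broadband filter, per-band envelopes, GFP -------------
    eeg_filtered = eegmod.broadband_filter(subject.eeg)
    eeg_phase = eegmod.slice_phase(eeg_filtered, subject.phase_markers, phase)

    gfp_by_band: dict[str, GFPSeries] = {}
    for name in eegmod.BAND_ORDER:
        env = eegmod.band_envelope(eeg_phase, config.bands[name])
        env = eegmod.trim_edges(env, config.edge_trim_s)
        gfp_by_band[name] = eegmod.global_field_power(env, band=name, phase=phase)

    # --- fNIRS chain: OD -> despike -> band-pass -> MBLL -> scalp regression
    optical_phase = _slice_optical(subject.optical, subject.phase_markers, phase)
    _, hb_mean = process_optical(
        optical_phase,
        subject.age,
        constants=config.constants,
        despike=config.despike,
        despike_alpha=config.despike_alpha,
    )
    hb_traces = {"o2hb": hb_mean.o2hb[0], "hhb": hb_mean.hhb[0]}

    values: dict[str, float] = {name: float("nan") for name in FEATURE_NAMES}
    valid: dict[str, bool] = {name: False for name in FEATURE_NAMES}

    # EEG SampEn on (optionally decimated) band GFP envelopes.  The
    # stationarity gate runs on the measured envelope series; its verdict
    # also governs the NC features derived from the same band.
    band_ok: dict[str, bool] = {}
    for name in eegmod.BAND_ORDER:
        series = gfp_by_band[name].values
        rate = gfp_by_band[name].rate
        if config.envelope_decimate_hz and config.envelope_decimate_hz < rate:
            series = _resample(series, rate, config.envelope_decimate_hz)
        series, ok = _gated(series, config.pp_alpha)
        band_ok[name] = ok
        if ok:
            values[f"sampen_eeg_{name}"] = sample_entropy(series, config.entropy)
            valid[f"sampen_eeg_{name}"] = True

    # fNIRS SampEn on the averaged hemoglobin traces
    hb_gated: dict[str, np.ndarray | None] = {}
    for hb_name, trace in hb_traces.items():
        series, ok = _gated(trace, config.pp_alpha)
        hb_gated[hb_name] = series
        if ok:
            values[f"sampen_{hb_name}"] = sample_entropy(series, config.entropy)
            valid[f"sampen_{hb_name}"] = True

    # NC CondEn: H(hemoglobin | HRF-convolved band envelope).  The HRF
    # convolution is a deterministic linear transform of the gated envelope,
    # so validity follows the underlying measured series.
    conv_by_band: dict[str, np.ndarray] = {
        name: eeg_to_hemo_timescale(gfp_by_band[name], config.hrf, fnirs_rate)
        for name in eegmod.BAND_ORDER
    }
    # The regressor's first kernel_length seconds (start-up transient) were
    # discarded, so drop the same initial window from the hemoglobin traces
    # to keep the pair aligned in time.
    n_transient = int(math.ceil(config.hrf.kernel_length * fnirs_rate))
    for hb_name in ("o2hb", "hhb"):
        for name in eegmod.BAND_ORDER:
            feat = f"conden_{hb_name}_{name}"
            x, y = conv_by_band[name], hb_gated[hb_name]
            if not band_ok[name] or y is None:
                continue
            x_t, y_t = truncate_common([x, y[n_transient:]])
            values[feat] = conditional_entropy(x_t, y_t, bins=config.conden_bins)
            valid[feat] = True

    if not any(valid.values()):
        raise ValueError(f"subject-phase unusable: all features failed the gates "
                         f"({subject.subject_id}, {phase})")
    return FeatureVector(subject.subject_id, phase, subject.group, values, valid)


def features_to_frame(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into a cohort table (one row per subject x phase)."""
    rows = []
    for fv in vectors:
        row = {"subject_id": fv.subject_id, "phase": fv.phase, "group": fv.group}
        row.update(fv.values)
        row.update({f"valid_{k}": v for k, v in fv.valid.items()})
        rows.append(row)
    return pd.DataFrame(rows)
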