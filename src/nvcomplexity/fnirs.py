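"""fNIRS preprocessing: optical densities, wavelet despiking, band-pass
filtering, the modified Beer-Lambert law, short-channel scalp regression and
long-channel averaging.

The attenuation chain is: intensities -> optical densities
``OD(t) = -ln(I(t)/I_avg)`` -> (despike, 0.01-0.4 Hz band-pass) ->
hemoglobin concentration changes via the modified Beer-Lambert law with an
age/wavelength-dependent differential pathlength factor (DPF) -> removal of
the global scalp-hemodynamic component estimated from the 15 mm short
channels -> average of the 35 mm long channels into a single O2Hb and a
single HHb time course.

Extinction coefficients (mm^-1 uM^-1, Gratzer/Prahl compilation) and the
general age/wavelength DPF polynomial ship as a versioned JSON data file and
can be overridden through :class:`ChromophoreConstants`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pywt
from scipy import signal as sps
from scipy.stats import norm

from .containers import (
    LONG,
    SHORT,
    HbSeries,
    OpticalDensitySeries,
    OpticalRecording,
)

__all__ = [
    "ChromophoreConstants",
    "intensity_to_od",
    "wavelet_despike",
    "od_bandpass",
    "mbll",
    "short_channel_regress",
    "average_long_channels",
    "process_optical",
]


def _load_constants_table() -> dict:
    with resources.files("nvcomplexity.data").joinpath("chromophores.json").open() as fh:
        return json.load(fh)


@dataclass
class ChromophoreConstants:
    """Extinction coefficients epsilon(chromophore, lambda) and DPF(lambda, age).

    ``extinction`` maps wavelength (nm) -> {"o2hb": eps, "hhb": eps} in
    mm^-1 uM^-1.  The DPF follows the general age/wavelength polynomial
    ``a + b*age**c + d*lam**3 + e*lam**2 + f*lam``; alternative coefficient
    tables can be substituted at construction.
    """

    extinction: dict[float, dict[str, float]] = field(default_factory=dict)
    dpf_coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.extinction or not self.dpf_coefficients:
            table = _load_constants_table()
            if not self.extinction:
                self.extinction = {
                    float(lam): dict(eps) for lam, eps in table["extinction"].items()
                }
            if not self.dpf_coefficients:
                self.dpf_coefficients = dict(table["dpf_coefficients"])

    def epsilon(self, chromophore: str, wavelength: float) -> float:
        key = min(self.extinction, key=lambda lam: abs(lam - wavelength))
        if abs(key - wavelength) > 1.0:
            raise KeyError(f"no extinction coefficients near {wavelength} nm")
        return self.extinction[key][chromophore]

    def dpf(self, wavelength: float, age: float) -> float:
        c = self.dpf_coefficients
        value = (
            c["a"]
            + c["b"] * age ** c["c"]
            + c["d"] * wavelength**3
            + c["e"] * wavelength**2
            + c["f"] * wavelength
        )
        if value <= 0:
            raise ValueError("DPF model produced a non-positive pathlength factor")
        return value

    def mbll_matrix(self, wavelengths, age: float) -> np.ndarray:
        """M[i][j] = eps_j(lambda_i) * DPF(lambda_i, age), j in (o2hb, hhb)."""
        m = np.array(
            [
                [
                    self.epsilon("o2hb", lam) * self.dpf(lam, age),
                    self.epsilon("hhb", lam) * self.dpf(lam, age),
                ]
                for lam in wavelengths
            ]
        )
        return m


def intensity_to_od(optical: OpticalRecording) -> OpticalDensitySeries:
    """OD(t) = -ln(I(t) / I_avg) per channel and wavelength.

    Invariant to a global intensity gain; raises on non-positive intensities.
    """
    intensity = optical.intensities
    if np.any(intensity <= 0) or not np.all(np.isfinite(intensity)):
        raise ValueError("intensities must be strictly positive and finite")
    i_avg = intensity.mean(axis=-1, keepdims=True)
    od = -np.log(intensity / i_avg)
    return OpticalDensitySeries(
        od=od,
        rate=optical.rate,
        wavelengths=optical.wavelengths,
        distances=optical.distances,
        roles=optical.roles,
    )


def wavelet_despike(
    od: OpticalDensitySeries,
    alpha: float = 0.1,
    wavelet: str = "db5",
    level: int = 4,
) -> OpticalDensitySeries:
    """Remove motion spikes by zeroing outlying wavelet detail coefficients.

    Each trace is decomposed (Daubechies-5, 4 levels by default); detail
    coefficients whose magnitude falls outside the central ``1 - alpha``
    probability mass of a Gaussian fitted to that level are set to zero
    before reconstruction.  Sharp spikes concentrate energy in a few detail
    coefficients, while smooth hemodynamic content survives in the
    approximation coefficients.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if od.n_samples < 2**4:
        raise ValueError("series too short for wavelet decomposition")
    z = norm.ppf(1 - alpha / 2)
    # boundary coefficients reflect the signal extension, not motion; they
    # are exempt from outlier flagging to avoid edge distortion
    n_edge = pywt.Wavelet(wavelet).dec_len // 2 + 1
    out = np.empty_like(od.od)
    n = od.n_samples
    for ch in range(od.od.shape[0]):
        for wl in range(od.od.shape[1]):
            trace = od.od[ch, wl]
            coeffs = pywt.wavedec(trace, wavelet, level=level)
            cleaned = [coeffs[0]]
            for detail in coeffs[1:]:
                mu = detail.mean()
                sd = detail.std()
                if sd > 0:
                    keep = np.abs(detail - mu) <= z * sd
                    keep[:n_edge] = True
                    keep[-n_edge:] = True
                    detail = np.where(keep, detail, 0.0)
                cleaned.append(detail)
            out[ch, wl] = pywt.waverec(cleaned, wavelet)[:n]
    return od.with_od(out)


def od_bandpass(
    od: OpticalDensitySeries,
    low_hz: float = 0.01,
    high_hz: float = 0.4,
    order: int = 4,
) -> OpticalDensitySeries:
    """Zero-lag 4th-order Butterworth band-pass (0.01-0.4 Hz) of the ODs."""
    if od.rate <= 2 * high_hz:
        raise ValueError(f"rate {od.rate} Hz too low for a {high_hz} Hz cutoff")
    min_seconds = 3.0 / (2 * np.pi * low_hz)
    if od.n_samples / od.rate < min_seconds:
        raise ValueError(
            f"record shorter than 3 high-pass time constants ({min_seconds:.0f} s)"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=od.rate, output="sos")
    return od.with_od(sps.sosfiltfilt(sos, od.od, axis=-1))


def mbll(
    od: OpticalDensitySeries,
    constants: ChromophoreConstants,
    age: float,
) -> HbSeries:
    """Modified Beer-Lambert law: OD changes -> hemoglobin changes (uM).

    Per channel, ``(dO2Hb, dHHb)^T = (1/d) * M^{-1} (dOD(l1), dOD(l2))^T``
    with ``M[i][j] = eps_j(lambda_i) * DPF(lambda_i, age)`` and ``d`` the
    geometric source-detector distance in mm.
    """
    if od.od.shape[1] != 2:
        raise ValueError("MBLL inversion needs exactly two wavelengths")
    m = constants.mbll_matrix(od.wavelengths, age)
    if abs(np.linalg.det(m)) < 1e-18:
        raise np.linalg.LinAlgError("singular extinction/DPF matrix")
    m_inv = np.linalg.inv(m)
    conc = np.einsum("ij,cjt->cit", m_inv, od.od)
    conc /= od.distances[:, np.newaxis, np.newaxis]
    return HbSeries(o2hb=conc[:, 0], hhb=conc[:, 1], rate=od.rate, roles=od.roles)


def _first_pc(traces: np.ndarray) -> np.ndarray:
    """First principal-component time course of (channels, samples) traces."""
    centered = traces - traces.mean(axis=1, keepdims=True)
    if np.allclose(centered, 0.0):
        raise ValueError("short channels have zero variance")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    pc = vt[0] * s[0]
    if pc @ centered.mean(axis=0) < 0:  # orient along the mean scalp signal
        pc = -pc
    return pc


def short_channel_regress(hb_long: HbSeries, hb_short: HbSeries) -> HbSeries:
    """Remove the global scalp-hemodynamic component from long channels.

    The first principal component across short-channel traces defines a
    global scalp-hemodynamic model; each long channel's scalar coefficient on
    that regressor is estimated by least squares and the fitted contribution
    subtracted, chromophore by chromophore.
    """
    if hb_short.n_channels < 1:
        raise ValueError("at least one short channel required")
    if hb_long.n_samples != hb_short.n_samples:
        raise ValueError("long and short series must have equal length")
    out = {}
    for attr in ("o2hb", "hhb"):
        long_tr = getattr(hb_long, attr)
        pc = _first_pc(getattr(hb_short, attr))
        pc_centered = pc - pc.mean()
        denom = pc_centered @ pc_centered
        betas = (long_tr - long_tr.mean(axis=1, keepdims=True)) @ pc_centered / denom
        out[attr] = long_tr - betas[:, np.newaxis] * pc_centered[np.newaxis, :]
    return HbSeries(out["o2hb"], out["hhb"], hb_long.rate, hb_long.roles)


def average_long_channels(hb: HbSeries) -> HbSeries:
    """Unweighted mean across long channels per chromophore."""
    if hb.roles is not None:
        idx = hb.channel_indices(LONG)
        if idx.size == 0:
            raise ValueError("no long channels to average")
        hb = hb.select(idx)
    return HbSeries(
        o2hb=hb.o2hb.mean(axis=0, keepdims=True),
        hhb=hb.hhb.mean(axis=0, keepdims=True),
        rate=hb.rate,
        roles=[LONG],
    )


def process_optical(
    optical: OpticalRecording,
    age: float,
    constants: ChromophoreConstants | None = None,
    despike: bool = True,
    despike_alpha: float = 0.1,
    bandpass: bool = True,
) -> tuple[HbSeries, HbSeries]:
    """Full optical chain: intensities -> corrected long channels + average.

    Returns ``(hb_long_corrected, hb_mean)`` where the second item holds the
    single averaged O2Hb and HHb traces used by the complexity analysis.
    """
    if constants is None:
        constants = ChromophoreConstants()
    od = intensity_to_od(optical)
    if despike:
        od = wavelet_despike(od, alpha=despike_alpha)
    if bandpass:
        od = od_bandpass(od)
    hb = mbll(od, constants, age)
    long_idx = hb.channel_indices(LONG)
    short_idx = hb.channel_indices(SHORT)
    hb_long = hb.select(long_idx)
    if short_idx.size:
        hb_long = short_channel_regress(hb_long, hb.select(short_idx))
    return hb_long, average_long_channels(hb_long)
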