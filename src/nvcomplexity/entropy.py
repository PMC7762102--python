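"""Complexity metrics: sample entropy, conditional entropy, stationarity gate.

Sample entropy (SampEn) quantifies the irregularity of a single series as the
negative log conditional probability that subseries of length ``m`` matching
within tolerance ``r`` (Chebyshev distance) also match at the ``m+1``-th
point.  Conditional entropy H(Y|X) quantifies the residual uncertainty of one
series given another after discretization, and is used here as a
neurovascular-coupling index with Y = hemoglobin and X = HRF-convolved EEG
envelope.

Template counting follows the Richman-Moorman convention: ordered template
pairs (i != j), with both the length-``m`` and length-``m+1`` counts taken
over the same starting-index range, so SampEn is always >= 0.

Stationarity is checked with a Phillips-Perron Z_tau unit-root test
(Newey-West long-run variance, MacKinnon asymptotic p-values); non-stationary
series are linearly detrended and retested.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import signal as sps
from statsmodels.tsa.adfvalues import mackinnonp

__all__ = [
    "EntropyParams",
    "StationarityVerdict",
    "sample_entropy",
    "conditional_entropy",
    "conditional_entropy_from_joint",
    "quantile_bin",
    "phillips_perron",
    "check_stationarity",
    "truncate_common",
]


@dataclass(frozen=True)
class EntropyParams:
    """Sample-entropy parameters: embedding dimension m, tolerance factor
    r_factor (r = r_factor * SD), delay tau in samples."""

    m: int = 2
    r_factor: float = 0.2
    tau: int = 1

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_factor <= 0:
            raise ValueError("r_factor must be positive")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")


@njit(cache=True)
def _template_counts(x, m, tau, r):  # pragma: no cover - exercised via wrapper
    n = x.shape[0]
    n_templates = n - m * tau
    b = 0
    a = 0
    for i in range(n_templates):
        for j in range(i + 1, n_templates):
            d = 0.0
            for k in range(m):
                diff = abs(x[i + k * tau] - x[j + k * tau])
                if diff > d:
                    d = diff
            if d <= r:
                b += 1
                if abs(x[i + m * tau] - x[j + m * tau]) <= r:
                    a += 1
    return b, a


def sample_entropy(
    x,
    params: EntropyParams = EntropyParams(),
    r: float | None = None,
) -> float:
    """SampEn(m, r, N) of a 1-D series.

    Parameters
    ----------
    x : array-like
        The series.
    params : EntropyParams
        Embedding dimension, tolerance factor and delay.
    r : float, optional
        Absolute tolerance.  When omitted, ``r = r_factor * SD(x)``
        (population SD).

    Returns
    -------
    float
        ``-ln(A/B)`` with B the count of ordered length-m template pairs
        within Chebyshev distance r and A the same count at length m+1.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("sample_entropy expects a 1-D series")
    n = x.size
    m, tau = params.m, params.tau
    if n < m * tau + 2:
        raise ValueError(f"series too short: N={n} < m*tau + 2 = {m * tau + 2}")
    if r is None:
        sd = float(np.std(x))
        if sd == 0.0:
            raise ValueError("degenerate series: zero variance with relative tolerance")
        r = params.r_factor * sd
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    b, a = _template_counts(x, m, tau, float(r))
    if b == 0:
        raise ValueError("no template matches at length m")
    if a == 0:
        raise ValueError("no m+1 matches: SampEn undefined (log of zero)")
    return float(-math.log(a / b))


def quantile_bin(x, bins: int) -> np.ndarray:
    """Discretize a series into equal-mass bins by its own quantiles.

    Returns integer bin indices in [0, n_occupied_bins).  Classification is
    rank-based, so any strictly monotone transform of ``x`` yields the same
    labels (up to interpolation at exactly repeated values).
    """
    x = np.asarray(x, dtype=float)
    if bins < 2:
        raise ValueError("bins must be >= 2")
    edges = np.quantile(x, np.linspace(0.0, 1.0, bins + 1))
    inner = np.unique(edges[1:-1])
    return np.searchsorted(inner, x, side="right")


def _entropy_nats(counts: np.ndarray) -> float:
    c = counts[counts > 0].astype(float)
    p = c / c.sum()
    return float(-np.sum(p * np.log(p)))


def conditional_entropy_from_joint(joint) -> float:
    """H(Y|X) in nats from a joint count/probability table (rows = x)."""
    joint = np.asarray(joint, dtype=float)
    if joint.ndim != 2 or np.any(joint < 0) or joint.sum() <= 0:
        raise ValueError("joint table must be a non-negative 2-D array with mass")
    p = joint / joint.sum()
    h_xy = _entropy_nats(p)
    h_x = _entropy_nats(p.sum(axis=1))
    return max(h_xy - h_x, 0.0)


def conditional_entropy(x, y, bins: int = 8) -> float:
    """H(Y|X) in nats with per-variable quantile (equal-mass) discretization.

    ``x`` is the predictor (EEG-derived), ``y`` the target (hemoglobin).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if x.size < bins * bins / 5:
        warnings.warn(
            f"sparse joint histogram: N={x.size} < bins^2/5 = {bins * bins / 5:.0f}",
            stacklevel=2,
        )
    xi = quantile_bin(x, bins)
    yi = quantile_bin(y, bins)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny)
    return conditional_entropy_from_joint(joint)


@dataclass
class StationarityVerdict:
    """Outcome of the unit-root gate applied before entropy estimation."""

    statistic: float
    p_value: float
    stationary: bool
    detrended: bool


def phillips_perron(x, trend: str = "c", lshort: bool = True) -> tuple[float, float]:
    """Phillips-Perron Z_tau unit-root test.

    Fits ``y_t = c (+ b t) + rho * y_{t-1} + u_t`` by OLS and corrects the
    Dickey-Fuller t-statistic for serial correlation with a Bartlett-kernel
    (Newey-West) long-run variance estimate.  ``trend`` is ``"c"`` (constant)
    or ``"ct"`` (constant + linear trend); ``lshort`` selects the short
    truncation lag ``floor(4 (n/100)^{1/4})``.

    Returns ``(Z_tau, p_value)``; small p rejects the unit root
    (series treated as stationary).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if x.size < 20:
        raise ValueError("series too short for a unit-root test (N < 20)")
    if np.ptp(x) == 0:
        raise ValueError("constant series: stationarity test undefined")
    if trend not in ("c", "ct"):
        raise ValueError("trend must be 'c' or 'ct'")

    y = x[1:]
    ylag = x[:-1]
    n = y.size
    cols = [np.ones(n), ylag] if trend == "c" else [np.ones(n), np.arange(1, n + 1), ylag]
    design = np.column_stack(cols)
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    k = design.shape[1]
    s2 = resid @ resid / (n - k)
    xtx_inv = np.linalg.inv(design.T @ design)
    se_rho = math.sqrt(s2 * xtx_inv[-1, -1])
    tau = (beta[-1] - 1.0) / se_rho

    gamma0 = resid @ resid / n
    q = int(4 * (n / 100.0) ** 0.25) if lshort else int(12 * (n / 100.0) ** 0.25)
    lam2 = gamma0
    for j in range(1, q + 1):
        gamma_j = resid[j:] @ resid[:-j] / n
        lam2 += 2.0 * (1.0 - j / (q + 1.0)) * gamma_j
    lam2 = max(lam2, 1e-300)

    z_tau = math.sqrt(gamma0 / lam2) * tau - (lam2 - gamma0) * n * se_rho / (
        2.0 * math.sqrt(lam2) * math.sqrt(s2)
    )
    p = float(mackinnonp(z_tau, regression=trend, N=1))
    return float(z_tau), p


def check_stationarity(
    x, alpha: float = 0.05, lshort: bool = False
) -> tuple[StationarityVerdict, np.ndarray]:
    """Gate a series on stationarity; detrend once if the unit root survives.

    Runs the Phillips-Perron test at level ``alpha``.  If the unit-root null
    is not rejected, the series is linearly detrended and retested.  Series
    still non-stationary after detrending are flagged (``stationary=False``)
    for exclusion downstream; entropy metrics are only kept for stationary
    series.

    The long Newey-West truncation lag (``lshort=False``) is the default:
    band-limited physiological signals are heavily oversampled relative to
    their bandwidth, and the short lag leaves the serial-correlation
    correction badly undersized for them (stationary hemodynamics get
    flagged as unit roots).
    """
    x = np.asarray(x, dtype=float)
    stat, p = phillips_perron(x, lshort=lshort)
    if p < alpha:
        return StationarityVerdict(stat, p, True, False), x
    detrended = sps.detrend(x, type="linear")
    stat2, p2 = phillips_perron(detrended, lshort=lshort)
    return StationarityVerdict(stat2, p2, p2 < alpha, True), detrended


def truncate_common(epochs: list) -> list[np.ndarray]:
    """Cut all epochs to the duration of the shortest, keeping initial samples."""
    if not epochs:
        raise ValueError("no epochs to truncate")
    arrays = [np.asarray(e) for e in epochs]
    n_min = min(a.shape[-1] for a in arrays)
    return [a[..., :n_min] for a in arrays]
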