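"""Time- and frequency-domain estimators of intrinsic neural timescales.

The two quantities computed here are

* the autocorrelation window (ACW): the first lag at which the sample
  autocorrelation function of a signal reaches a threshold (0 for ACW-0,
  0.5 for ACW-50), converted to seconds.  Longer windows mean the signal
  retains memory of its past for longer.
* the median frequency (MF): the frequency that splits the in-band power
  spectral density into two halves of equal area.  Slower signals have a
  lower median frequency, so MF moves opposite to the ACW.

The sample autocorrelation uses the biased estimator: the lag-``m``
autocovariance ``(1/N) * sum_{t=1}^{N-m} (x_t - xbar)(x_{t+m} - xbar)``
divided by the biased variance ``(1/N) * sum (x_t - xbar)^2``.  Both sums
share the ``1/N`` factor, so ``r[0] == 1`` exactly and ``|r[m]| <= 1``.

Band limits default to the infra-slow BOLD band 0.01-0.23 Hz sampled at a
repetition time of 2.16 s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

#: Default analysis band in Hz (lower edge keeps >= 3 cycles in a
#: 145-sample series; upper edge sits just below the Nyquist frequency).
DEFAULT_BAND: tuple[float, float] = (0.01, 0.23)

#: Default sampling interval (fMRI repetition time) in seconds.
DEFAULT_TR: float = 2.16

#: Thresholds of the two autocorrelation windows.
ACW_THRESHOLDS = {"acw0": 0.0, "acw50": 0.5}


class ZeroVarianceError(ValueError):
    """Raised when an operation requires a non-constant series."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class TimeSeriesMatrix:
    """Sampled signals arranged time points x units.

    Units may be voxels, parcels, or model regions.  ``dt`` is the sampling
    interval in seconds; ``unit_ids`` label the columns; ``meta`` carries
    free-form provenance (subject, state, ...).
    """

    data: np.ndarray
    dt: float
    unit_ids: Sequence | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D time x units matrix")
        if self.data.shape[0] < 3:
            raise ValueError("need at least 3 time points")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.unit_ids is None:
            self.unit_ids = list(range(self.data.shape[1]))
        else:
            self.unit_ids = list(self.unit_ids)
        if len(self.unit_ids) != self.data.shape[1]:
            raise ValueError("unit_ids length does not match number of columns")
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise ValueError("unit_ids must be unique")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_units(self) -> int:
        return self.data.shape[1]


@dataclass
class AcfResult:
    """Sample autocorrelation curve plus the windows derived from it.

    ``acw0``/``acw50`` are in seconds and NaN when the corresponding
    crossing was not reached within the computed lags.
    """

    lags: np.ndarray
    r: np.ndarray
    dt: float
    acw0: float = np.nan
    acw50: float = np.nan


@dataclass
class SpectrumResult:
    """Periodogram restricted to the analysis band plus its median frequency."""

    freqs: np.ndarray
    psd: np.ndarray
    mf: float
    band: tuple[float, float]


# ---------------------------------------------------------------------------
# autocorrelation
# ---------------------------------------------------------------------------


def _acf_columns(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample ACF of every column of ``x`` for lags ``0..max_lag``.

    Uses an FFT-based linear correlation, which is algebraically identical
    to the direct sum; columns with zero variance come back as NaN.
    """

    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(xc, n=nfft, axis=0)
    acov = np.fft.irfft((fx * fx.conj()).real, n=nfft, axis=0)[: max_lag + 1]
    var = acov[0].copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = acov / var
    r[:, var <= 0] = np.nan
    return r


def sample_acf(x: np.ndarray, max_lag: int | None = None) -> AcfResult:
    """Sample autocorrelation of a single series (ACW fields left NaN).

    ``r[m]`` is the biased autocovariance at lag ``m`` divided by the biased
    variance; ``r[0] == 1``.  ``max_lag`` defaults to ``N - 2`` (all
    computable lags leaving at least two products in the shortest sum).

    Raises
    ------
    ZeroVarianceError
        if the series is constant.
    ValueError
        if ``max_lag`` is outside ``[1, N - 1]`` or the series is too short.
    """

    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 3:
        raise ValueError("series must have at least 3 points")
    if max_lag is None:
        max_lag = n - 2
    if not 1 <= max_lag <= n - 1:
        raise ValueError(f"max_lag must be in [1, {n - 1}], got {max_lag}")
    if np.ptp(x) == 0 or np.allclose(np.var(x), 0.0):
        raise ZeroVarianceError("zero variance: constant series has no autocorrelation")
    r = _acf_columns(x[:, None], max_lag)[:, 0]
    r[0] = 1.0  # exact by construction; guard against rounding
    return AcfResult(lags=np.arange(max_lag + 1), r=r, dt=np.nan)


def acw(acf: AcfResult | np.ndarray, threshold: float, dt: float) -> float:
    """First-crossing autocorrelation window, in seconds.

    Returns ``m* . dt`` where ``m*`` is the smallest lag ``m >= 1`` with
    ``r[m] <= threshold``.  No sub-lag interpolation is applied: the window
    is reported at lag resolution.  When no computed lag crosses the
    threshold, NaN is returned (the "not reached" sentinel) and a warning
    naming the largest computed lag is logged; the caller decides policy.
    """

    r = acf.r if isinstance(acf, AcfResult) else np.asarray(acf, dtype=float)
    if r.ndim != 1 or r.size < 2:
        raise ValueError("need an autocorrelation curve with at least lags 0 and 1")
    if not np.isclose(r[0], 1.0):
        raise ValueError("r[0] must equal 1")
    below = r[1:] <= threshold
    if not below.any():
        logger.warning(
            "ACW threshold %g not reached within %d computed lags", threshold, r.size - 1
        )
        return float("nan")
    return float((1 + np.argmax(below)) * dt)


def acf_with_acw(x: np.ndarray, dt: float, max_lag: int | None = None) -> AcfResult:
    """Sample ACF of one series with both windows filled in."""

    res = sample_acf(x, max_lag=max_lag)
    res.dt = dt
    res.acw0 = acw(res, ACW_THRESHOLDS["acw0"], dt)
    res.acw50 = acw(res, ACW_THRESHOLDS["acw50"], dt)
    return res


# ---------------------------------------------------------------------------
# spectrum
# ---------------------------------------------------------------------------


def _periodogram(x: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Raw (rectangular-window, mean-removed) periodogram along axis 0."""

    return signal.periodogram(
        x, fs=1.0 / dt, window="boxcar", detrend="constant", axis=0
    )


def median_frequency(
    x: np.ndarray, dt: float, band: tuple[float, float] = DEFAULT_BAND
) -> SpectrumResult:
    """Median frequency of a single series within ``band``.

    The raw periodogram is restricted to the bins inside ``[f_lo, f_hi]``
    (inclusive); the median frequency is the smallest bin frequency at which
    the cumulative in-band power reaches half the total in-band power, with
    ties resolved toward the lower frequency and no interpolation between
    bins.
    """

    x = np.asarray(x, dtype=float).ravel()
    if x.size < 8:
        raise ValueError("series must have at least 8 points")
    f_lo, f_hi = band
    nyq = 0.5 / dt
    if not 0 < f_lo < f_hi <= nyq + 1e-12:
        raise ValueError(f"band must satisfy 0 < f_lo < f_hi <= Nyquist ({nyq:g} Hz)")
    freqs, psd = _periodogram(x, dt)
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    if not mask.any():
        raise ValueError("band contains no frequency bins at this resolution")
    freqs, psd = freqs[mask], psd[mask]
    total = psd.sum()
    if total <= 0:
        raise ZeroVarianceError("no in-band power")
    idx = int(np.argmax(np.cumsum(psd) >= 0.5 * total))
    return SpectrumResult(freqs=freqs, psd=psd, mf=float(freqs[idx]), band=(f_lo, f_hi))


# ---------------------------------------------------------------------------
# band limiting
# ---------------------------------------------------------------------------


def _bandpass_sos(f_lo: float, f_hi: float, dt: float):
    nyq = 0.5 / dt
    if not 0 < f_lo < f_hi <= nyq + 1e-12:
        raise ValueError(f"band must satisfy 0 < f_lo < f_hi <= Nyquist ({nyq:g} Hz)")
    f_hi = min(f_hi, nyq * (1 - 1e-9))  # keep the design strictly below Nyquist
    return signal.butter(4, [f_lo, f_hi], btype="bandpass", fs=1.0 / dt, output="sos")


def bandpass(
    ts: TimeSeriesMatrix | np.ndarray,
    f_lo: float = DEFAULT_BAND[0],
    f_hi: float = DEFAULT_BAND[1],
    dt: float | None = None,
) -> TimeSeriesMatrix | np.ndarray:
    """Zero-phase band-pass filter (4th-order Butterworth, forward-backward).

    Accepts either a :class:`TimeSeriesMatrix` or a plain array plus ``dt``.
    The zero-phase pass preserves in-band sinusoid amplitude and removes any
    constant offset (DC sits outside the passband).  Series shorter than the
    filter warm-up (the forward-backward padding) raise an error.
    """

    if isinstance(ts, TimeSeriesMatrix):
        out = bandpass(ts.data, f_lo, f_hi, dt=ts.dt)
        return TimeSeriesMatrix(out, dt=ts.dt, unit_ids=ts.unit_ids, meta=dict(ts.meta))
    if dt is None:
        raise ValueError("dt is required when filtering a plain array")
    x = np.asarray(ts, dtype=float)
    sos = _bandpass_sos(f_lo, f_hi, dt)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.shape[0] <= padlen:
        raise ValueError(
            f"series of length {x.shape[0]} is shorter than the filter warm-up ({padlen + 1} samples)"
        )
    return signal.sosfiltfilt(sos, x, axis=0)


# ---------------------------------------------------------------------------
# per-unit sweeps
# ---------------------------------------------------------------------------


def metric_map(
    ts: TimeSeriesMatrix,
    metric: str,
    band: tuple[float, float] = DEFAULT_BAND,
    max_lag: int | None = None,
) -> np.ndarray:
    """One metric value per unit (column), in the order of ``unit_ids``.

    ``metric`` is one of ``"acw0"``, ``"acw50"`` (seconds) or ``"mf"`` (Hz).
    Degenerate units (constant series, window never reached) yield NaN
    sentinels and a logged warning; the sweep itself never aborts.
    """

    if metric not in ("acw0", "acw50", "mf"):
        raise ValueError(f"unknown metric {metric!r}")
    x = ts.data
    n = x.shape[0]
    if metric == "mf":
        freqs, psd = _periodogram(x, ts.dt)
        f_lo, f_hi = band
        mask = (freqs >= f_lo) & (freqs <= f_hi)
        if not mask.any():
            raise ValueError("band contains no frequency bins at this resolution")
        freqs, psd = freqs[mask], psd[mask]
        total = psd.sum(axis=0)
        good = total > 0
        out = np.full(ts.n_units, np.nan)
        if good.any():
            cum = np.cumsum(psd[:, good], axis=0)
            idx = (cum >= 0.5 * total[good]).argmax(axis=0)
            out[good] = freqs[idx]
        if (~good).any():
            logger.warning("metric_map: %d unit(s) with no in-band power", int((~good).sum()))
        return out

    if max_lag is None:
        max_lag = n - 2
    r = _acf_columns(x, max_lag)
    threshold = ACW_THRESHOLDS[metric]
    below = r[1:] <= threshold  # NaN columns compare False everywhere
    reached = below.any(axis=0)
    out = np.full(ts.n_units, np.nan)
    out[reached] = (1 + below.argmax(axis=0)[reached]) * ts.dt
    n_bad = int((~reached).sum())
    if n_bad:
        logger.warning(
            "metric_map: %d unit(s) degenerate or threshold not reached within %d lags",
            n_bad,
            max_lag,
        )
    return out
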