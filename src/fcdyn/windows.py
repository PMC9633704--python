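"""Time-resolved connectivity from parcellated BOLD timeseries.

Primary method: Pearson correlation inside a Gaussian-tapered sliding
window (default 24 timepoints moved by 1 timepoint, i.e. one TR).
Alternative: instantaneous phase synchrony of narrow band-passed signals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .complexity import UndefinedMeasureWarning

__all__ = [
    "RegionTimeSeries",
    "ConnectivitySeries",
    "gaussian_taper",
    "weighted_pearson",
    "sliding_window_connectivity",
    "phase_synchrony_series",
]


@dataclass(frozen=True)
class RegionTimeSeries:
    """Parcellated BOLD: T timepoints by R regions, with TR metadata."""

    values: np.ndarray  # (T, R)
    tr_seconds: float
    region_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a T x R matrix")
        if not np.isfinite(v).all():
            bad = np.argwhere(~np.isfinite(v))
            raise ValueError(f"non-finite values at (t, region) {bad[:5].tolist()}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        ids = tuple(self.region_ids) or tuple(f"r{i:03d}" for i in range(v.shape[1]))
        if len(ids) != v.shape[1]:
            raise ValueError("region_ids length must match number of regions")
        if len(set(ids)) != len(ids):
            raise ValueError("region_ids must be unique")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "region_ids", ids)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ConnectivitySeries:
    """Ordered sequence of symmetric R x R connectivity matrices.

    ``flagged`` lists window indices containing a degenerate
    (zero-variance) region; downstream operations reject them.
    """

    matrices: np.ndarray  # (N, R, R)
    window_length: int
    step: int
    taper_weights: np.ndarray | None
    method: str = "windowed"
    flagged: tuple[int, ...] = field(default_factory=tuple)

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_regions(self) -> int:
        return self.matrices.shape[1]

    def truncated(self, n: int) -> "ConnectivitySeries":
        """First ``n`` windows (cross-dataset harmonisation truncates every
        subject's series to the cohort-wide minimum, from the start)."""
        if not 1 <= n <= self.n_windows:
            raise ValueError("n out of range")
        return ConnectivitySeries(
            matrices=self.matrices[:n], window_length=self.window_length,
            step=self.step, taper_weights=self.taper_weights,
            method=self.method, flagged=tuple(i for i in self.flagged if i < n))


def gaussian_taper(window_length: int, sigma: float) -> np.ndarray:
    """Gaussian taper weights, symmetric about the window centre, peaked at
    the centre, normalised to sum 1. De-weights the window's extremities."""
    if window_length < 2:
        raise ValueError("window_length must be >= 2")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    centre = (window_length - 1) / 2.0
    idx = np.arange(window_length, dtype=float)
    w = np.exp(-0.5 * ((idx - centre) / sigma) ** 2)
    return w / w.sum()


def weighted_pearson(x, y, w) -> float:
    """Weighted Pearson correlation: weighted covariance over the product of
    weighted standard deviations. NaN (with a warning) if either input has
    zero weighted variance."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    w = np.asarray(w, dtype=float).ravel()
    if not (x.size == y.size == w.size):
        raise ValueError("x, y, w must have equal length")
    if (w < 0).any() or not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be nonnegative and sum to 1")
    mx, my = w @ x, w @ y
    cov = w @ ((x - mx) * (y - my))
    vx = w @ ((x - mx) ** 2)
    vy = w @ ((y - my) ** 2)
    # constant inputs can leave a tiny nonzero variance in floating point
    if vx == 0.0 or vy == 0.0 or np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        warnings.warn("zero weighted variance: correlation undefined",
                      UndefinedMeasureWarning, stacklevel=2)
        return float("nan")
    return float(cov / np.sqrt(vx * vy))


def n_windows(n_timepoints: int, window_length: int, step: int = 1) -> int:
    """Number of sliding windows: floor((T - W) / step) + 1."""
    if n_timepoints < window_length:
        raise ValueError("series shorter than window")
    return (n_timepoints - window_length) // step + 1


def sliding_window_connectivity(
    ts: RegionTimeSeries,
    window_length: int = 24,
    step: int = 1,
    taper_sigma: float | None = None,
    taper: np.ndarray | None = None,
) -> ConnectivitySeries:
    """Tapered sliding-window Pearson connectivity.

    Window n covers timepoints [n*step, n*step + W); N = floor((T-W)/step)+1
    matrices result. The default taper is Gaussian with sigma = W/6.

    A region with zero weighted variance inside a window makes that
    window's entries involving it NaN and flags the window.
    """
    T, R = ts.values.shape
    if T < window_length:
        raise ValueError(f"series length {T} shorter than window {window_length}")
    if taper is None:
        sigma = window_length / 6.0 if taper_sigma is None else taper_sigma
        taper = gaussian_taper(window_length, sigma)
    else:
        taper = np.asarray(taper, dtype=float)
        if taper.size != window_length or (taper <= 0).any():
            raise ValueError("taper must be strictly positive, length W")
        taper = taper / taper.sum()

    n = n_windows(T, window_length, step)
    out = np.empty((n, R, R))
    flagged: list[int] = []
    for i in range(n):
        seg = ts.values[i * step:i * step + window_length]
        mu = taper @ seg
        centred = seg - mu
        cov = (centred * taper[:, None]).T @ centred
        sd = np.sqrt(np.abs(np.diag(cov)))
        zero = (sd == 0.0) | (np.ptp(seg, axis=0) == 0.0)
        sd[zero] = 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = cov / np.outer(sd, sd)
        np.fill_diagonal(corr, 1.0)
        if zero.any():
            corr[zero, :] = np.nan
            corr[:, zero] = np.nan
            np.fill_diagonal(corr, 1.0)
            flagged.append(i)
        out[i] = np.clip(corr, -1.0, 1.0, out=corr)
    if flagged:
        warnings.warn(f"{len(flagged)} window(s) contain a zero-variance "
                      f"region and were flagged: {flagged[:10]}",
                      UndefinedMeasureWarning, stacklevel=2)
    return ConnectivitySeries(out, window_length, step, taper,
                              method="windowed", flagged=tuple(flagged))


def phase_synchrony_series(
    ts: RegionTimeSeries,
    band_low: float = 0.03,
    band_high: float = 0.07,
    edge_trim: int = 0,
) -> ConnectivitySeries:
    """Instantaneous phase synchrony 1 - |sin(dtheta / 2)| from analytic-signal
    phases of narrow band-passed series.

    One R x R matrix per timepoint (values in [0, 1], diagonal 1).
    ``edge_trim`` removes that many timepoints from each end to suppress
    filter transients.
    """
    fs = 1.0 / ts.tr_seconds
    nyq = fs / 2.0
    if not 0 < band_low < band_high < nyq:
        raise ValueError(f"band ({band_low}, {band_high}) outside (0, {nyq})")
    sos = butter(2, [band_low, band_high], btype="bandpass", fs=fs, output="sos")
    filtered = sosfiltfilt(sos, ts.values, axis=0)
    theta = np.angle(hilbert(filtered, axis=0))  # (T, R)
    dtheta = theta[:, :, None] - theta[:, None, :]
    sync = 1.0 - np.abs(np.sin(dtheta / 2.0))
    for t in range(sync.shape[0]):
        np.fill_diagonal(sync[t], 1.0)
    if edge_trim:
        if 2 * edge_trim >= sync.shape[0]:
            raise ValueError("edge_trim removes the whole series")
        sync = sync[edge_trim:-edge_trim]
    return ConnectivitySeries(sync, window_length=1, step=1,
                              taper_weights=None, method="phase")
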