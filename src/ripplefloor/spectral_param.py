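"""PSD estimation and aperiodic (1/f) parameterization, static and time-resolved.

Spectra are estimated on Hann-tapered segments, averaged, interpolated onto a
2-128 Hz grid in 1 Hz steps, and smoothed along log-frequency with a Gaussian
kernel of 1/4-octave FWHM.  The aperiodic component is an ordinary
least-squares line of log10(power) on log10(frequency) over 20-45 Hz — the
"fixed" aperiodic model with no oscillatory peaks, which is exact for the
peak-free surrogate signals this package works with.  The fitted slope is the
spectral exponent chi (negative by convention); R^2 of the line quantifies
goodness of fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_core import SignalTrace

FREQ_GRID = np.arange(2.0, 129.0, 1.0)
DEFAULT_FIT_RANGE = (20.0, 45.0)


@dataclass
class PowerSpectrum:
    """Averaged power spectral density on a fixed frequency grid."""

    freqs: np.ndarray
    power: np.ndarray
    segment_length: float
    overlap: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclass
class SpectralFit:
    """Aperiodic parameterization of a PSD: exponent (slope form), offset
    (log10-power intercept), the fitted frequency range, and R^2."""

    exponent: float
    offset: float
    fit_range: tuple[float, float]
    r_squared: float

    def __post_init__(self) -> None:
        if not self.fit_range[0] < self.fit_range[1]:
            raise ValueError("fit_range must be (lo, hi) with lo < hi")
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError("r_squared outside [0, 1]")


@dataclass
class ExponentSeries:
    """Time-resolved exponent estimates on a sliding-segment grid."""

    times: np.ndarray
    exponents: np.ndarray
    r_squared: np.ndarray
    window: float
    step: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.exponents = np.asarray(self.exponents, dtype=float)
        self.r_squared = np.asarray(self.r_squared, dtype=float)
        if len(self.times) != len(self.exponents):
            raise ValueError("times and exponents must have equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be increasing")

    @property
    def low_quality(self) -> np.ndarray:
        """Segments whose aperiodic fit had R^2 < 0.5 (flagged, never dropped)."""
        return self.r_squared < 0.5

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# window_s: {self.window}\n# step_s: {self.step}\n")
            fh.write("# time_s exponent r_squared\n")
            for t, e, r in zip(self.times, self.exponents, self.r_squared):
                fh.write(f"{t:.4f} {e:.6f} {r:.6f}\n")


def _smoothing_matrix(freqs: np.ndarray, fwhm_octaves: float = 0.25) -> np.ndarray:
    """Row-normalized Gaussian smoothing weights along log2-frequency."""
    log_f = np.log2(freqs)
    sigma = fwhm_octaves / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    d = log_f[:, None] - log_f[None, :]
    w = np.exp(-0.5 * (d / sigma) ** 2)
    return w / w.sum(axis=1, keepdims=True)


def _segment_matrix(x: np.ndarray, n_seg: int, step: int) -> np.ndarray:
    n_windows = (x.size - n_seg) // step + 1
    idx = np.arange(n_seg)[None, :] + step * np.arange(n_windows)[:, None]
    return x[idx]


def _psd_of_segments(segments: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Hann-tapered periodograms of each row, on the native rfft grid."""
    n = segments.shape[1]
    taper = np.hanning(n)
    norm = rate * (taper ** 2).sum()
    spec = np.fft.rfft(segments * taper, axis=1)
    psd = (np.abs(spec) ** 2) / norm
    if n % 2 == 0:
        psd[:, 1:-1] *= 2.0
    else:
        psd[:, 1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    return freqs, psd


def _to_grid(native_freqs: np.ndarray, psd: np.ndarray,
             grid: np.ndarray = FREQ_GRID) -> np.ndarray:
    """Interpolate (rows of) a PSD onto the 1 Hz analysis grid."""
    return np.vstack([np.interp(grid, native_freqs, row) for row in np.atleast_2d(psd)])


def compute_psd(trace: SignalTrace, segment_length: float = 30.0,
                overlap: float = 0.7, smooth_octaves: float = 0.25) -> PowerSpectrum:
    """Segment-averaged Hann PSD on a 2-128 Hz, 1 Hz grid.

    The trace is cut into ``segment_length`` windows with fractional
    ``overlap``, each Hann-tapered periodogram is averaged, the average is
    interpolated to integer frequencies, and log-power is smoothed with a
    1/4-octave Gaussian along log-frequency.
    """
    n_seg = int(round(segment_length * trace.rate))
    if trace.n_samples < n_seg:
        raise ValueError("trace shorter than one segment")
    step = max(int(round(n_seg * (1.0 - overlap))), 1)
    segments = _segment_matrix(trace.samples, n_seg, step)
    native_freqs, psd = _psd_of_segments(segments, trace.rate)
    mean_psd = psd.mean(axis=0)
    grid_psd = _to_grid(native_freqs, mean_psd)[0]
    if smooth_octaves:
        sm = _smoothing_matrix(FREQ_GRID, smooth_octaves)
        grid_psd = 10.0 ** (sm @ np.log10(np.maximum(grid_psd, 1e-300)))
    return PowerSpectrum(FREQ_GRID.copy(), grid_psd, segment_length, overlap)


def fit_aperiodic(spectrum: PowerSpectrum,
                  fit_range: tuple[float, float] = DEFAULT_FIT_RANGE) -> SpectralFit:
    """OLS fit of log10(power) on log10(f) over ``fit_range`` (default 20-45 Hz).

    Returns the slope as the spectral exponent, the intercept as the offset,
    and the R^2 of the line.  Raises on non-positive power inside the range
    (logarithm undefined) or fewer than 5 bins.
    """
    lo, hi = fit_range
    mask = (spectrum.freqs >= lo) & (spectrum.freqs <= hi)
    if mask.sum() < 5:
        raise ValueError("fewer than 5 frequency bins inside fit_range")
    p = spectrum.power[mask]
    if np.any(p <= 0):
        raise ValueError("non-positive power inside fit range (log undefined)")
    log_f = np.log10(spectrum.freqs[mask])
    log_p = np.log10(p)
    slope, intercept = np.polyfit(log_f, log_p, 1)
    resid = log_p - (slope * log_f + intercept)
    ss_tot = float(np.sum((log_p - log_p.mean()) ** 2))
    r2 = 1.0 if ss_tot < 1e-30 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return SpectralFit(float(slope), float(intercept), (lo, hi),
                       float(np.clip(r2, 0.0, 1.0)))


def time_resolved_exponent(trace: SignalTrace, window: float = 30.0,
                           step: float = 3.0,
                           fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
                           smooth_octaves: float = 0.25,
                           subsegment: float | None = None) -> ExponentSeries:
    """Sliding-window aperiodic exponent.

    Windows of ``window`` seconds advance by ``step`` seconds.  Within each
    window, Hann periodograms of ``subsegment``-second pieces (default: the
    window itself for windows <= 2 s, else 2 s, half-overlapping) are
    averaged before the log-log fit — a single long taper per window would
    leave the 20-45 Hz slope estimate with several-fold higher variance.
    Times are window centers relative to the trace start time.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    n_win = int(round(window * trace.rate))
    if trace.n_samples < n_win:
        raise ValueError("trace shorter than one window")
    if subsegment is None:
        subsegment = window if window <= 2.0 else 2.0
    step_n = max(int(round(step * trace.rate)), 1)
    sub_n = min(int(round(subsegment * trace.rate)), n_win)
    # hop aligned with the window step so every window contains at least one
    # fully interior sub-periodogram
    hop_n = max(min(sub_n // 2, step_n), 1)
    pieces = _segment_matrix(trace.samples, sub_n, hop_n)
    native_freqs, piece_psd = _psd_of_segments(pieces, trace.rate)
    cum = np.vstack([np.zeros(piece_psd.shape[1]), np.cumsum(piece_psd, axis=0)])

    n_windows = (trace.n_samples - n_win) // step_n + 1
    starts = step_n * np.arange(n_windows)
    # sub-periodogram k covers [k*hop_n, k*hop_n + sub_n)
    k_lo = np.ceil(starts / hop_n).astype(int)
    k_hi = np.floor((starts + n_win - sub_n) / hop_n).astype(int)
    k_hi = np.clip(k_hi, 0, piece_psd.shape[0] - 1)
    k_lo = np.clip(np.minimum(k_lo, k_hi), 0, None)
    psd = (cum[k_hi + 1] - cum[k_lo]) / (k_hi - k_lo + 1)[:, None]
    grid_psd = _to_grid(native_freqs, psd)
    if smooth_octaves:
        sm = _smoothing_matrix(FREQ_GRID, smooth_octaves)
        grid_psd = 10.0 ** (np.log10(np.maximum(grid_psd, 1e-300)) @ sm.T)

    lo, hi = fit_range
    mask = (FREQ_GRID >= lo) & (FREQ_GRID <= hi)
    log_f = np.log10(FREQ_GRID[mask])
    log_p = np.log10(np.maximum(grid_psd[:, mask], 1e-300))
    design = np.vstack([log_f, np.ones_like(log_f)]).T
    coef, *_ = np.linalg.lstsq(design, log_p.T, rcond=None)
    slopes, intercepts = coef
    fitted = design @ coef
    ss_res = np.sum((log_p.T - fitted) ** 2, axis=0)
    ss_tot = np.sum((log_p - log_p.mean(axis=1, keepdims=True)) ** 2, axis=1)
    r2 = np.where(ss_tot < 1e-30, 1.0, 1.0 - ss_res / np.maximum(ss_tot, 1e-300))
    times = trace.start_time + window / 2.0 + step_n / trace.rate * np.arange(n_windows)
    return ExponentSeries(times, slopes, np.clip(r2, 0.0, 1.0), window,
                          step_n / trace.rate)
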