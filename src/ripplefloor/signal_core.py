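"""Core signal containers, minimal preprocessing, file I/O, and synthetic fixtures.

The central object is :class:`SignalTrace`, a uniformly sampled continuous
recording (intracranial EEG or a synthetic stand-in) with its sampling rate
and channel label.  All event times throughout the package are expressed in
seconds from trace start; sample indices are 0-based; intervals are half-open
``[start, end)``.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps


class DegenerateSignalError(ValueError):
    """Raised when an operation is undefined on a (near-)constant signal."""


class FormatError(ValueError):
    """Raised for unreadable files or missing required metadata (e.g. rate)."""


@dataclass
class SignalTrace:
    """A uniformly sampled continuous signal.

    Parameters
    ----------
    samples : ndarray
        Signal values (arbitrary units, or z-units after preprocessing).
    rate : float
        Sampling rate in Hz.  Must be positive.
    start_time : float
        Time of the first sample in seconds.
    channel_id : str
        Channel label.
    """

    samples: np.ndarray
    rate: float
    start_time: float = 0.0
    channel_id: str = "ch0"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not (self.rate > 0):
            raise ValueError("rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds (n_samples / rate)."""
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.rate

    def index_of(self, t: float) -> int:
        """Sample index of time ``t`` (seconds), clipped to the trace."""
        i = int(round((t - self.start_time) * self.rate))
        return min(max(i, 0), self.n_samples - 1)


@dataclass
class StateSchedule:
    """Ordered, non-overlapping, contiguous epochs of behavioral/sleep state.

    ``epochs`` is a list of ``(start_s, end_s, label)`` with labels such as
    wake, N1, N2, SWS, REM, task, ITI.
    """

    epochs: list[tuple[float, float, str]]

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("schedule must contain at least one epoch")
        eps = [(float(a), float(b), str(lab)) for a, b, lab in self.epochs]
        for a, b, _ in eps:
            if not a < b:
                raise ValueError(f"epoch start {a} must precede end {b}")
        for (a0, b0, _), (a1, b1, _) in zip(eps, eps[1:]):
            if a1 < b0 - 1e-9:
                raise ValueError("epochs overlap")
            if a1 > b0 + 1e-9:
                raise ValueError("epochs must cover a contiguous span")
        self.epochs = eps

    @property
    def span(self) -> tuple[float, float]:
        return self.epochs[0][0], self.epochs[-1][1]

    @property
    def labels(self) -> list[str]:
        return [lab for _, _, lab in self.epochs]

    def label_at(self, t: float) -> str | None:
        for a, b, lab in self.epochs:
            if a <= t < b:
                return lab
        return None

    def intervals(self, label: str) -> list[tuple[float, float]]:
        return [(a, b) for a, b, lab in self.epochs if lab == label]


@dataclass
class FixtureSpec:
    """Recipe for a synthetic recording with state-dependent 1/f background.

    The background of each scheduled epoch is colored noise whose spectral
    exponent is looked up in ``exponent_by_state``.  Optional ripple bursts
    (band-limited, Hann-enveloped sinusoids) and IED-like sharp transients can
    be injected on top; amplitudes are expressed in units of the background
    standard deviation.  Injection exists to exercise detector plumbing — the
    surrogate analyses of this package never inject oscillations.
    """

    schedule: StateSchedule
    exponent_by_state: dict[str, float]
    injected_ripples: list[tuple[float, float, float, float]] = field(default_factory=list)
    injected_ieds: list[tuple[float, float]] = field(default_factory=list)
    seed: int = 0
    rate: float = 1000.0

    def __post_init__(self) -> None:
        missing = set(self.schedule.labels) - set(self.exponent_by_state)
        if missing:
            raise ValueError(f"no exponent given for states: {sorted(missing)}")
        for t, f, d, a in self.injected_ripples:
            if not 70.0 <= f <= 180.0:
                raise ValueError(f"ripple frequency {f} Hz outside 70-180 Hz")
            if not 0.02 <= d <= 0.2:
                raise ValueError(f"ripple duration {d} s outside 0.02-0.2 s")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess_minimal(trace: SignalTrace, band: tuple[float, float] = (0.5, 150.0),
                       order: int = 3) -> SignalTrace:
    """Demean, linearly detrend, band-pass filter and z-normalize a trace.

    The band-pass is a zero-phase (two-pass) Butterworth of the given order.
    z-normalization uses the mean and SD of the entire trace, matching the
    convention that detection thresholds are derived from whole-recording
    statistics.

    Raises
    ------
    DegenerateSignalError
        If the signal is constant (z-normalization undefined).
    """
    x = trace.samples
    if x.size < int(2 * trace.rate):
        raise ValueError("trace must be at least 2 s long")
    if np.ptp(x) == 0:
        raise DegenerateSignalError("constant signal: z-normalization undefined")
    x = sps.detrend(x, type="linear")
    nyq = trace.rate / 2.0
    lo, hi = band
    if hi >= nyq:
        sos = sps.butter(order, lo / nyq, btype="highpass", output="sos")
    else:
        sos = sps.butter(order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    x = sps.sosfiltfilt(sos, x)
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateSignalError("filtered signal has zero variance")
    x = (x - x.mean()) / sd
    return SignalTrace(x, trace.rate, trace.start_time, trace.channel_id)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix in {".f64", ".raw", ".bin"}:
        return "raw-float"
    if suffix in {".csv", ".tsv", ".txt", ".dat"}:
        return "delimited"
    raise FormatError(f"cannot infer format from suffix {suffix!r}")


def read_trace(path, format: str | None = None, rate: float | None = None) -> list[SignalTrace]:
    """Read one or more channels of continuous signal from ``path``.

    Supported formats: ``edf`` (via MNE), ``raw-float`` (little-endian float64
    with a JSON sidecar holding rate/label), and ``delimited`` (single column
    of samples; the rate must come from a ``# rate_hz:`` header line or the
    ``rate`` argument).

    Returns a list of :class:`SignalTrace`, one per channel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "edf":
        import mne

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        fs = float(raw.info["sfreq"])
        try:
            # undo MNE's Volt conversion: EDF amplitudes are stored in uV
            data = raw.get_data(units="uV")
        except (ValueError, TypeError):
            data = raw.get_data()
        return [SignalTrace(data[i], fs, 0.0, ch) for i, ch in enumerate(raw.ch_names)]
    if fmt == "raw-float":
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
        elif rate is not None:
            meta = {"rate": rate, "channel_id": path.stem}
        else:
            raise FormatError("raw-float file without sidecar metadata and no rate override")
        samples = np.fromfile(path, dtype="<f8")
        return [SignalTrace(samples, float(meta["rate"]), float(meta.get("start_time", 0.0)),
                            str(meta.get("channel_id", path.stem)))]
    if fmt == "delimited":
        header_rate = None
        with open(path) as fh:
            lines = fh.readlines()
        body = []
        for line in lines:
            if line.startswith("#"):
                if "rate_hz" in line:
                    header_rate = float(line.split(":", 1)[1])
                continue
            if line.strip():
                body.append(float(line.strip()))
        fs = rate if rate is not None else header_rate
        if fs is None:
            raise FormatError("delimited file without rate metadata and no rate override")
        return [SignalTrace(np.asarray(body), float(fs), 0.0, path.stem)]
    raise FormatError(f"unknown format {fmt!r}")


def write_trace(trace: SignalTrace, path, format: str | None = None) -> None:
    """Write a trace in ``raw-float``, ``delimited`` or ``edf`` format."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "raw-float":
        trace.samples.astype("<f8").tofile(path)
        meta = {"rate": trace.rate, "start_time": trace.start_time,
                "channel_id": trace.channel_id}
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))
    elif fmt == "delimited":
        with open(path, "w") as fh:
            fh.write(f"# rate_hz: {trace.rate}\n")
            for v in trace.samples:
                fh.write(f"{v:.10g}\n")
    elif fmt == "edf":
        write_edf([trace], path)
    else:
        raise FormatError(f"unknown format {fmt!r}")


def write_edf(traces: list[SignalTrace], path) -> None:
    """Write channels as a minimal EDF file (16-bit, one data record).

    All channels must share rate and length.  Samples are scaled to the full
    16-bit range per channel, so round-trips are exact only to ~1/65536 of the
    signal range — adequate for test fixtures and interchange.
    """
    path = Path(path)
    rates = {t.rate for t in traces}
    lengths = {t.n_samples for t in traces}
    if len(rates) != 1 or len(lengths) != 1:
        raise FormatError("EDF writer requires channels of equal rate and length")
    fs = traces[0].rate
    ns = traces[0].n_samples
    n_chan = len(traces)
    record_dur = ns / fs

    def pad(s: str, n: int) -> bytes:
        return s[:n].ljust(n).encode("ascii")

    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("X X X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 + 256 * n_chan), 8), pad("", 44),
        pad("1", 8), pad(f"{record_dur:.6g}", 8), pad(str(n_chan), 4),
    ])
    phys_min, phys_max, dig_min, dig_max, scaled = [], [], [], [], []
    for t in traces:
        lo, hi = float(t.samples.min()), float(t.samples.max())
        if hi == lo:
            hi = lo + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        dig_min.append(-32768)
        dig_max.append(32767)
        gain = (hi - lo) / 65535.0
        scaled.append(np.round((t.samples - lo) / gain - 32768).astype("<i2"))
    fields = [
        [pad(t.channel_id, 16) for t in traces],
        [pad("", 80)] * n_chan,
        [pad("uV", 8)] * n_chan,
        [pad(f"{v:.6g}", 8) for v in phys_min],
        [pad(f"{v:.6g}", 8) for v in phys_max],
        [pad(str(v), 8) for v in dig_min],
        [pad(str(v), 8) for v in dig_max],
        [pad("", 80)] * n_chan,
        [pad(str(ns), 8)] * n_chan,
        [pad("", 32)] * n_chan,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for f in fields:
            fh.write(b"".join(f))
        for s in scaled:
            fh.write(struct.pack(f"<{ns}h", *s.tolist()))


def read_schedule(path) -> StateSchedule:
    """Read a StateSchedule from 3-column delimited text (start_s, end_s, label)."""
    epochs = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            a, b, lab = line.split()[:3]
            epochs.append((float(a), float(b), lab))
    return StateSchedule(epochs)


def write_schedule(schedule: StateSchedule, path) -> None:
    with open(path, "w") as fh:
        fh.write("# start_s end_s label\n")
        for a, b, lab in schedule.epochs:
            fh.write(f"{a:.6f} {b:.6f} {lab}\n")


# ---------------------------------------------------------------------------
# fixture generation
# ---------------------------------------------------------------------------

def _ripple_burst(rate: float, freq: float, duration: float, amplitude: float) -> np.ndarray:
    """Band-limited sinusoid with a Hann amplitude envelope."""
    n = max(int(round(duration * rate)), 3)
    t = np.arange(n) / rate
    return amplitude * np.hanning(n) * np.sin(2 * np.pi * freq * t)


def _ied_transient(rate: float, amplitude: float, duration: float = 0.06,
                   freq: float = 50.0) -> np.ndarray:
    """Sharp interictal-discharge-like transient: a large Hann-windowed
    oscillatory spike whose energy lies in the 25-80 Hz band."""
    n = max(int(round(duration * rate)), 3)
    t = np.arange(n) / rate
    return amplitude * np.hanning(n) * np.sin(2 * np.pi * freq * t + np.pi / 2)


def generate_fixture(spec: FixtureSpec) -> tuple[SignalTrace, StateSchedule]:
    """Synthesize a recording following ``spec``.

    Each epoch's background is 1/f^chi colored noise at the exponent of its
    state, z-normalized per epoch, and concatenated; optional ripple bursts
    and IED transients are added at the stated times with amplitudes in units
    of the background SD (= 1 after per-epoch normalization).  Identical specs
    (including seed) yield bit-identical traces.
    """
    from .noise_sim import concat_with_taper, generate_colored_noise

    pieces = []
    for i, (a, b, lab) in enumerate(spec.schedule.epochs):
        chi = spec.exponent_by_state[lab]
        seg = generate_colored_noise(chi, b - a, spec.rate, seed=spec.seed + i)
        pieces.append(seg.samples)
    x = concat_with_taper(pieces, spec.rate)
    t0 = spec.schedule.span[0]
    for t, f, d, a in spec.injected_ripples:
        burst = _ripple_burst(spec.rate, f, d, a)
        i0 = int(round((t - t0 - d / 2) * spec.rate))
        if i0 < 0 or i0 + burst.size > x.size:
            raise ValueError(f"injected ripple at {t} s outside trace")
        x[i0:i0 + burst.size] += burst
    for t, a in spec.injected_ieds:
        tr = _ied_transient(spec.rate, a)
        i0 = int(round((t - t0) * spec.rate)) - tr.size // 2
        if i0 < 0 or i0 + tr.size > x.size:
            raise ValueError(f"injected IED at {t} s outside trace")
        x[i0:i0 + tr.size] += tr
    return SignalTrace(x, spec.rate, t0, "fixture"), spec.schedule
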