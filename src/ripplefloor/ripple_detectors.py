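"""Five published-style sharp-wave-ripple detectors plus an IED detector.

All five detectors share one engine: band-pass filter, amplitude envelope
(analytic-signal magnitude), optional smoothing and normalization, a
threshold rule whose statistics come from the ENTIRE recording, duration
criteria, event merging, secondary amplitude/frequency criteria, and
alignment of each event to the nearest broadband trough.  The presets encode
the published parameterizations; everything is configurable through
:class:`DetectorConfig`.

Because thresholds are global (mean/SD or percentile over the whole trace),
detection rates depend strongly on the spectral exponent of the background —
the property quantified in :mod:`ripplefloor.noise_floor`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signal_core import DegenerateSignalError, SignalTrace


@dataclass
class DetectorConfig:
    """Full parameterization of the shared detection engine.

    ``smoothing`` is ``("lowpass", hz)`` (Butterworth), ``("lowpass_kaiser",
    hz)`` (Kaiser FIR), ``("moving_average", seconds)``, or ``None``.
    ``threshold_rule`` is ``("sd_range", lo, hi)`` (detect at lo SD, require
    peak <= hi SD), ``("sd_min", x)``, ``("percentile", p)``, or
    ``("rms_fraction", f)``.  ``duration`` is (min_s, max_s) with ``inf``
    allowed.  FIR orders follow the cycles convention: the number of taps is
    ``order x rate / lowest-cutoff``.
    """

    detector_id: str
    band: tuple[float, float]
    filter_family: str = "butterworth"
    filter_order: int = 3
    envelope: str = "hilbert_abs"
    smoothing: tuple | None = None
    normalize: str = "zscore"
    threshold_rule: tuple = ("sd_min", 2.0)
    duration: tuple[float, float] = (0.025, 0.2)
    merge_gap: float | None = None
    merge_before_duration: bool = False
    amplitude_clip: float | None = None
    square_envelope: bool = False
    frequency_min: float | None = None
    max_peak_diff: float | None = None
    ied_exclusion: float | None = None
    fir_convention: str = "literal"

    def __post_init__(self) -> None:
        if not self.band[0] < self.band[1]:
            raise ValueError("band must be (lo, hi) with lo < hi")
        if not self.duration[0] < self.duration[1]:
            raise ValueError("duration must be (min, max) with min < max")


@dataclass
class DetectedEvent:
    """One candidate ripple (or IED): trough-aligned time, bounds, envelope
    peak in z-units, mean intra-event frequency, and provenance labels."""

    trough_time: float
    start: float
    end: float
    peak_amplitude: float
    mean_frequency: float
    detector_id: str
    channel_id: str = "ch0"

    @property
    def duration(self) -> float:
        return self.end - self.start


def preset(detector_id: int) -> DetectorConfig:
    """Published parameterization for detectors 1-5.

    1: 80-120 Hz Butterworth, Hilbert envelope, 10 Hz low-pass smoothing,
       z-normalized; detect at 2 SD with peak in 2-4 SD, 25-200 ms, mean
       frequency > 80 Hz, successive peak-to-peak differential < 2 z-units,
       merge within 500 ms, IED exclusion +/- 2.5 s.
    2: 80 Hz high-pass then 100 Hz low-pass FIR (order 3), Hilbert envelope
       with 20 ms moving-average smoothing, z-normalized; threshold at the
       99th envelope percentile, 38-100 ms, IED exclusion +/- 1.5 s.
    3: 80-120 Hz Butterworth order 2 two-pass, Hilbert envelope; > 2 SD for
       >= 25 ms, events within 15 ms merged (before the duration criterion).
    4: 70-180 Hz FIR order 5 two-pass, Hilbert envelope; extremes clipped to
       4 SD, squared, 40 Hz Kaiser low-pass smoothed; mean/SD of that
       transformed signal threshold the squared unclipped envelope at 4 SD,
       20-200 ms, merge within 30 ms, artifact exclusion +/- 50 ms.
    5: as 1 but 20-200 ms, merge within 100 ms, IED exclusion +/- 1 s.
    """
    presets = {
        1: DetectorConfig(
            detector_id="1", band=(80.0, 120.0), filter_family="butterworth",
            filter_order=3, smoothing=("lowpass", 10.0), normalize="zscore",
            threshold_rule=("sd_range", 2.0, 4.0), duration=(0.025, 0.2),
            merge_gap=0.5, merge_before_duration=False, frequency_min=80.0,
            max_peak_diff=2.0, ied_exclusion=2.5),
        2: DetectorConfig(
            detector_id="2", band=(80.0, 100.0), filter_family="fir",
            filter_order=3, smoothing=("moving_average", 0.02),
            normalize="zscore", threshold_rule=("percentile", 99.0),
            duration=(0.038, 0.1), ied_exclusion=1.5),
        3: DetectorConfig(
            detector_id="3", band=(80.0, 120.0), filter_family="butterworth",
            filter_order=2, smoothing=None, normalize="none",
            threshold_rule=("sd_min", 2.0), duration=(0.025, np.inf),
            merge_gap=0.015, merge_before_duration=True),
        4: DetectorConfig(
            detector_id="4", band=(70.0, 180.0), filter_family="fir",
            filter_order=5, smoothing=("lowpass_kaiser", 40.0),
            normalize="none", threshold_rule=("sd_min", 4.0),
            duration=(0.02, 0.2), merge_gap=0.03, merge_before_duration=True,
            amplitude_clip=4.0, square_envelope=True, ied_exclusion=0.05,
            fir_convention="cycles"),
        5: DetectorConfig(
            detector_id="5", band=(80.0, 120.0), filter_family="butterworth",
            filter_order=3, smoothing=("lowpass", 10.0), normalize="zscore",
            threshold_rule=("sd_range", 2.0, 4.0), duration=(0.02, 0.2),
            merge_gap=0.1, merge_before_duration=False, frequency_min=80.0,
            ied_exclusion=1.0),
    }
    if detector_id not in presets:
        raise ValueError(f"unknown detector id {detector_id!r} (expected 1-5)")
    return presets[detector_id]


# ---------------------------------------------------------------------------
# filtering / envelope helpers
# ---------------------------------------------------------------------------

def _fir_taps(rate: float, cutoff, order: int, btype: str,
              convention: str = "literal") -> np.ndarray:
    """Window-method FIR taps under one of two published order conventions.

    ``literal``: fir1-style, ``order`` + 1 taps (high-pass lengths bumped to
    the next odd value, as fir1 does).  Such short filters have very wide
    transition bands; the resulting out-of-band leakage into the
    "ripple-band" signal is what couples those detectors' statistics to the
    spectral exponent of the background.

    ``cycles``: fieldtrip-style, taps = order x rate / lowest cutoff — a
    proper band-limiting filter.
    """
    f_ref = cutoff[0] if np.iterable(cutoff) else cutoff
    if convention == "cycles":
        numtaps = max(int(order * rate / f_ref), 5)
        numtaps += 1 - numtaps % 2
    elif convention == "literal":
        numtaps = order + 1
        if btype == "highpass" and numtaps % 2 == 0:
            numtaps += 1
    else:
        raise ValueError(f"unknown FIR convention {convention!r}")
    return sps.firwin(numtaps, cutoff, fs=rate, pass_zero=(btype == "lowpass"))


def bandpass_filter(x: np.ndarray, rate: float, config: DetectorConfig) -> np.ndarray:
    """Zero-phase band-pass per the detector's filter family and order."""
    lo, hi = config.band
    if rate < 2.0 * hi:
        raise ValueError(f"rate {rate} Hz too low for band up to {hi} Hz")
    if config.filter_family == "butterworth":
        nyq = rate / 2.0
        sos = sps.butter(config.filter_order, [lo / nyq, hi / nyq],
                         btype="bandpass", output="sos")
        return sps.sosfiltfilt(sos, x)
    if config.filter_family == "fir":
        if config.detector_id == "2":
            # sequential high-pass then low-pass, as published
            hp = _fir_taps(rate, lo, config.filter_order, "highpass",
                           config.fir_convention)
            lp = _fir_taps(rate, hi, config.filter_order, "lowpass",
                           config.fir_convention)
            return sps.filtfilt(lp, 1.0, sps.filtfilt(hp, 1.0, x))
        taps = _fir_taps(rate, [lo, hi], config.filter_order, "bandpass",
                         config.fir_convention)
        return sps.filtfilt(taps, 1.0, x)
    raise ValueError(f"unknown filter family {config.filter_family!r}")


def _smooth(env: np.ndarray, rate: float, smoothing: tuple | None) -> np.ndarray:
    if smoothing is None:
        return env
    kind, value = smoothing
    if kind == "lowpass":
        sos = sps.butter(3, value / (rate / 2.0), btype="lowpass", output="sos")
        return sps.sosfiltfilt(sos, env)
    if kind == "lowpass_kaiser":
        taps = sps.firwin(max(int(3 * rate / value) | 1, 5), value,
                          fs=rate, window=("kaiser", 5.0))
        return sps.filtfilt(taps, 1.0, env)
    if kind == "moving_average":
        n = max(int(round(value * rate)), 1)
        kernel = np.ones(n) / n
        return np.convolve(env, kernel, mode="same")
    raise ValueError(f"unknown smoothing {kind!r}")


def _runs_above(x: np.ndarray, threshold: float) -> np.ndarray:
    """Half-open [start, stop) index pairs of runs where x > threshold."""
    above = x > threshold
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        stops = np.r_[stops, above.size]
    return np.column_stack([starts, stops]) if starts.size else np.empty((0, 2), int)


def _merge_runs(runs: np.ndarray, gap_samples: int) -> np.ndarray:
    if runs.shape[0] < 2:
        return runs
    merged = [runs[0].tolist()]
    for s, e in runs[1:]:
        if s - merged[-1][1] <= gap_samples:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return np.asarray(merged, int)


def _strict_local_minima(x: np.ndarray) -> np.ndarray:
    return np.flatnonzero((x[1:-1] < x[:-2]) & (x[1:-1] < x[2:])) + 1


def _mean_frequency(trough_idx_sorted: np.ndarray, start: int, stop: int,
                    rate: float) -> float:
    """(number of band-passed troughs inside the event - 1) / duration."""
    n = np.searchsorted(trough_idx_sorted, stop) - np.searchsorted(trough_idx_sorted, start)
    dur = (stop - start) / rate
    return max(n - 1, 0) / dur if dur > 0 else 0.0


def _max_peak_to_peak_diff(x_z: np.ndarray) -> float:
    """Max absolute difference between successive extremum-to-extremum swings
    of a (z-scaled) snippet; 0 when fewer than 2 swings.

    Applied to the broadband signal inside a candidate event, this rejects
    sharp transients (abrupt cycle-amplitude changes) while passing smoothly
    enveloped oscillatory bursts.
    """
    peaks = _strict_local_minima(-x_z)
    troughs = _strict_local_minima(x_z)
    ext = np.sort(np.concatenate([peaks, troughs]))
    if ext.size < 3:
        return 0.0
    swings = np.abs(np.diff(x_z[ext]))
    return float(np.max(np.abs(np.diff(swings))))


# ---------------------------------------------------------------------------
# main detection
# ---------------------------------------------------------------------------

def detect_ripples(trace: SignalTrace, config: DetectorConfig,
                   ieds: list[DetectedEvent] | None = None) -> list[DetectedEvent]:
    """Run the configured detector over a continuous trace.

    Threshold statistics are computed over the entire recording.  Events are
    returned sorted by trough time; every configured criterion (duration,
    amplitude window, mean frequency, peak-to-peak differential, merging,
    IED exclusion) has been applied.
    """
    if trace.duration < 10.0:
        raise ValueError("trace must be at least 10 s for stable threshold statistics")
    if np.ptp(trace.samples) == 0:
        raise DegenerateSignalError("constant trace")
    rate = trace.rate
    bp = bandpass_filter(trace.samples, rate, config)
    env = np.abs(sps.hilbert(bp))

    if config.square_envelope:
        # detector-4 style: stats from the clipped/squared/smoothed envelope,
        # detection on the unclipped squared (smoothed) envelope
        mu0, sd0 = env.mean(), env.std()
        clip_at = mu0 + (config.amplitude_clip or 4.0) * sd0
        transformed = _smooth(np.minimum(env, clip_at) ** 2, rate, config.smoothing)
        det_sig = _smooth(env ** 2, rate, config.smoothing)
        mu, sd = transformed.mean(), transformed.std()
        det_z = (det_sig - mu) / sd
    else:
        env_s = _smooth(env, rate, config.smoothing)
        mu, sd = env_s.mean(), env_s.std()
        if sd == 0:
            raise DegenerateSignalError("flat envelope")
        det_z = (env_s - mu) / sd

    rule = config.threshold_rule
    if rule[0] in ("sd_range", "sd_min"):
        threshold = float(rule[1])
        peak_max = float(rule[2]) if rule[0] == "sd_range" else np.inf
    elif rule[0] == "percentile":
        threshold = float(np.percentile(det_z, rule[1]))
        peak_max = np.inf
    elif rule[0] == "rms_fraction":
        threshold = float(rule[1]) * float(np.sqrt(np.mean(det_z ** 2)))
        peak_max = np.inf
    else:
        raise ValueError(f"unknown threshold rule {rule[0]!r}")

    runs = _runs_above(det_z, threshold)
    if config.merge_before_duration and config.merge_gap:
        runs = _merge_runs(runs, int(round(config.merge_gap * rate)))

    min_n = config.duration[0] * rate
    max_n = config.duration[1] * rate
    lengths = runs[:, 1] - runs[:, 0]
    runs = runs[(lengths >= min_n) & (lengths <= max_n)]

    bp_troughs = _strict_local_minima(bp)
    # broadband in z-units: the amp-diff criterion targets sharp transients
    # in the raw signal, whose scale varies strongly with the exponent
    x_z = trace.samples / trace.samples.std()
    events: list[DetectedEvent] = []
    for s, e in runs:
        seg = det_z[s:e]
        peak = float(seg.max())
        if peak > peak_max:
            continue
        freq = _mean_frequency(bp_troughs, s, e, rate)
        if config.frequency_min is not None and freq <= config.frequency_min:
            continue
        if config.max_peak_diff is not None:
            if _max_peak_to_peak_diff(x_z[s:e]) >= config.max_peak_diff:
                continue
        peak_time = trace.start_time + (s + int(np.argmax(seg))) / rate
        events.append(DetectedEvent(
            trough_time=peak_time, start=trace.start_time + s / rate,
            end=trace.start_time + e / rate, peak_amplitude=peak,
            mean_frequency=freq, detector_id=config.detector_id,
            channel_id=trace.channel_id))

    if not config.merge_before_duration and config.merge_gap:
        events = merge_events(events, config.merge_gap)
    events = [align_to_trough(ev, trace, strict=False) for ev in events]
    if ieds is not None and config.ied_exclusion:
        events = exclude_near_ieds(events, ieds, config.ied_exclusion)
    events.sort(key=lambda ev: ev.trough_time)
    return events


def merge_events(events: list[DetectedEvent], gap: float) -> list[DetectedEvent]:
    """Merge events whose gap (end to next start) is <= ``gap`` seconds.

    The merged event spans the union, keeps the maximum peak amplitude, and
    takes its trough from the constituent with that peak.  Idempotent.
    """
    if not events:
        return []
    events = sorted(events, key=lambda ev: ev.start)
    out = [events[0]]
    for ev in events[1:]:
        prev = out[-1]
        if ev.start - prev.end <= gap:
            best = prev if prev.peak_amplitude >= ev.peak_amplitude else ev
            out[-1] = replace(best, start=min(prev.start, ev.start),
                              end=max(prev.end, ev.end))
        else:
            out.append(ev)
    return out


def align_to_trough(event: DetectedEvent, trace: SignalTrace,
                    strict: bool = True) -> DetectedEvent:
    """Set the event's trough time to the broadband local minimum nearest the
    envelope peak.  Ties break toward the earlier time.  With ``strict=True``
    an event containing no interior strict minimum raises; otherwise the
    current trough time is kept."""
    i0 = trace.index_of(event.start)
    i1 = max(trace.index_of(event.end), i0 + 1)
    snippet = trace.samples[i0:i1 + 1]
    minima = _strict_local_minima(snippet)
    if minima.size == 0:
        if strict:
            raise ValueError("no interior local minimum inside event")
        return event
    ref = int(round((event.trough_time - trace.start_time) * trace.rate)) - i0
    dist = np.abs(minima - ref)
    best = minima[np.lexsort((minima, dist))[0]]  # nearest; earlier on ties
    return replace(event, trough_time=trace.start_time + (i0 + best) / trace.rate)


def detect_ieds(trace: SignalTrace) -> list[DetectedEvent]:
    """Detect interictal-epileptiform-discharge-like transients.

    The trace is band-passed 25-80 Hz, the analytic envelope z-normalized,
    and events taken where it exceeds 2 SD for 20-100 ms; candidates whose
    raw (broadband) envelope does not also exceed 2 SD are discarded; events
    within 1 s of one another are concatenated.
    """
    if trace.duration < 10.0:
        raise ValueError("trace must be at least 10 s")
    rate = trace.rate
    nyq = rate / 2.0
    sos = sps.butter(3, [25.0 / nyq, 80.0 / nyq], btype="bandpass", output="sos")
    bp = sps.sosfiltfilt(sos, trace.samples)
    env = np.abs(sps.hilbert(bp))
    env_z = (env - env.mean()) / env.std()
    raw_env = np.abs(sps.hilbert(trace.samples - trace.samples.mean()))
    raw_z = (raw_env - raw_env.mean()) / raw_env.std()

    runs = _runs_above(env_z, 2.0)
    lengths = runs[:, 1] - runs[:, 0]
    runs = runs[(lengths >= 0.02 * rate) & (lengths <= 0.1 * rate)]
    events = []
    for s, e in runs:
        if raw_z[s:e].max() <= 2.0:
            continue
        peak_i = s + int(np.argmax(env_z[s:e]))
        events.append(DetectedEvent(
            trough_time=trace.start_time + peak_i / rate,
            start=trace.start_time + s / rate, end=trace.start_time + e / rate,
            peak_amplitude=float(env_z[s:e].max()), mean_frequency=0.0,
            detector_id="IED", channel_id=trace.channel_id))
    return merge_events(events, 1.0)


def exclude_near_ieds(ripples: list[DetectedEvent], ieds: list[DetectedEvent],
                      window: float) -> list[DetectedEvent]:
    """Drop ripples whose trough lies within +/- ``window`` s of any IED."""
    if not ieds:
        return list(ripples)
    ied_times = np.sort([ev.trough_time for ev in ieds])
    out = []
    for ev in ripples:
        i = np.searchsorted(ied_times, ev.trough_time)
        near = []
        if i > 0:
            near.append(abs(ev.trough_time - ied_times[i - 1]))
        if i < ied_times.size:
            near.append(abs(ev.trough_time - ied_times[i]))
        if min(near) > window:
            out.append(ev)
    return out


def event_locked_average(events: list[DetectedEvent], trace: SignalTrace,
                         window: float = 2.5,
                         baseline: tuple[float, float] = (-2.5, -2.0),
                         ) -> tuple[np.ndarray, np.ndarray, int]:
    """Trough-locked broadband average, z-normalized to a pre-event baseline.

    Events whose +/- ``window`` snippet extends past the trace are skipped.
    Returns (lags_s, average, n_events_used).
    """
    n_half = int(round(window * trace.rate))
    b0 = int(round((baseline[0] + window) * trace.rate))
    b1 = int(round((baseline[1] + window) * trace.rate))
    snippets = []
    for ev in events:
        c = trace.index_of(ev.trough_time)
        if c - n_half < 0 or c + n_half + 1 > trace.n_samples:
            continue
        snip = trace.samples[c - n_half:c + n_half + 1].astype(float)
        base = snip[b0:max(b1, b0 + 2)]
        bsd = base.std()
        snippets.append((snip - base.mean()) / (bsd if bsd > 0 else 1.0))
    if not snippets:
        raise ValueError("no events fully inside the trace")
    lags = np.arange(-n_half, n_half + 1) / trace.rate
    return lags, np.mean(snippets, axis=0), len(snippets)


# ---------------------------------------------------------------------------
# event-table I/O
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ["channel", "detector", "trough_s", "start_s", "end_s",
                 "peak_z", "freq_hz"]


def events_to_frame(events: list[DetectedEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(ev.channel_id, ev.detector_id, ev.trough_time, ev.start, ev.end,
          ev.peak_amplitude, ev.mean_frequency) for ev in events],
        columns=EVENT_COLUMNS)


def frame_to_events(frame: pd.DataFrame) -> list[DetectedEvent]:
    return [DetectedEvent(r.trough_s, r.start_s, r.end_s, r.peak_z, r.freq_hz,
                          str(r.detector), str(r.channel))
            for r in frame.itertuples(index=False)]


def write_events(events: list[DetectedEvent], path) -> None:
    events_to_frame(events).to_csv(path, sep="\t", index=False)


def read_events(path) -> list[DetectedEvent]:
    return frame_to_events(pd.read_csv(path, sep="\t"))
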