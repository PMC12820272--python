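# Methods

This note records the models, estimators, and design decisions behind
`ripplefloor`, including choices the underlying methods literature leaves
open and the behaviour of the synthetic benchmarks.

## Signal model and preprocessing

All analyses operate on uniformly sampled continuous traces. The minimal
preprocessing chain mirrors standard practice for intracranial EEG: demean,
linear detrend, zero-phase (two-pass) Butterworth band-pass 0.5–150 Hz of
order 3, and z-normalization over the *entire* trace. Whole-trace
normalization is deliberate: every detector derives its threshold from
whole-recording statistics, and that coupling between global statistics and
local detection is the phenomenon under study.

Two consequences of the order-3 band-pass are worth knowing. First, an
out-of-band line at 200 Hz is attenuated by ≈ 19.5 dB (|H|⁴ of the two-pass
filter), not arbitrarily much. Second, preprocessing is only approximately
idempotent: reapplying it attenuates band-edge content again and the
z-normalization rescales globally (~16 % raw RMS change on white noise);
interior-band (2–80 Hz) shape is preserved to < 1 % after an optimal global
rescale.

## Colored-noise simulation

1/f^χ noise is generated by shaping the discrete Fourier amplitudes of white
Gaussian noise by f^(χ/2), zeroing DC, and inverse transforming; the raw
output's periodogram slope over 1–150 Hz matches χ essentially exactly, and
the preprocessed output is used everywhere else. Exponents are accepted in
[−8, 0] (slope form). The generator is fully seeded; identical seeds give
bit-identical traces.

Surrogate recordings reproduce a recording's exponent dynamics segment by
segment: one exponent per fixed-length segment, each segment generated from
an independent seed (`seed + segment_index`, so editing one segment's
exponent leaves all others' samples unchanged), preprocessed (hence
z-normalized per segment), and concatenated. Only the exponent is matched —
never the offset (z-normalization removes absolute scale) and never any
oscillation.

**Junction taper.** Segments are joined with a 10 ms half-cosine fade at
each junction rather than bluntly. Blunt concatenation leaves step
discontinuities whose broadband clicks carry ripple-band energy; on steep
backgrounds (χ ≈ −3), where the genuine ripple-band power is tiny, those
clicks inflate the global envelope SD enough to suppress detection counts
several-fold (measured: 42 vs 158 detector-3 events on a 600 s surrogate).
The taper touches < 1 % of samples and leaves per-segment spectra intact.

**Exponent-matching noise is not harmless.** When the per-segment exponents
are *estimated* (sampling SD ≈ 0.13 for 30 s segments, see below), the
segment-to-segment jitter modulates relative ripple-band power by a factor
of ~2 per ±0.13 of χ. Under a global threshold, detections concentrate in
the shallowest-fitted segments, so a fitted-plan surrogate of a
*stationary* steep recording can over-detect substantially relative to the
recording itself. Floor estimates at steep exponents are therefore biased
toward "within the floor"; synthetic tests that need an unbiased control use
the ground-truth plan instead.

## Aperiodic parameterization

PSDs are estimated on Hann-tapered segments (default 30 s, 70 % overlap),
averaged, interpolated onto a 2–128 Hz grid in 1 Hz steps, and smoothed
along log-frequency with a Gaussian kernel of 1/4-octave FWHM applied to
log-power (the smoothing named by the source toolchain is realized as this
kernel; the exact original kernel is implementation-defined there). The
aperiodic component is the ordinary least-squares line of log₁₀ power on
log₁₀ f over 20–45 Hz — the "fixed" aperiodic model with no oscillatory
peaks, exact for the peak-free signals simulated here — with the slope as
the exponent and R² as goodness of fit. Fits with R² < 0.5 are flagged, not
dropped.

**Sampling error.** With 600 s of data the fitted exponent has |bias|
< 0.01 and MAE ≈ 0.07. A single 30 s Hann periodogram, by contrast, leaves
the 20–45 Hz slope with SD ≈ 0.8; the per-segment and time-resolved
estimators therefore average half-overlapping 2 s sub-periodograms within
each window, which brings the per-30 s-segment SD to ≈ 0.13 — the practical
floor for this fit range and smoothing. For 1 s task windows the window
itself is the sub-segment (1 Hz native resolution).

`time_resolved_exponent` slides a window (30 s / 3 s step for sleep-style
analyses, 1 s / 0.1 s for task-style) and reports window-center times.

## Ripple detectors

Five detector presets share one engine: band-pass filter → analytic-signal
envelope → optional smoothing → normalization → threshold (statistics from
the entire recording) → duration criteria → merging → secondary criteria →
alignment to the nearest broadband trough (ties toward earlier time) →
optional IED exclusion. Published parameters are kept exactly (bands,
SD multipliers, duration bounds, merge windows, exclusion windows). Where
the sources are ambiguous, the choices are:

- **Butterworth orders** (detectors 1 and 5, unstated): order 3, zero-phase
  two-pass; detector 3 uses its stated order 2 two-pass.
- **FIR "order"**: detector 2 uses the literal fir1-style reading — order 3
  means 4–5 taps. Such near-transparent filters leak out-of-band power, and
  that leakage is what couples the envelope timescale (and hence the
  38–100 ms duration window) to the background exponent; with textbook-length
  FIRs detector 2's noise profile is flat in χ, which contradicts its
  published behaviour. Detector 4 instead uses the cycles convention
  (taps = order × rate / low cutoff): its published inverse
  density-vs-exponent relationship requires a genuinely band-limiting
  filter. The two detectors descend from different source methods with
  different conventions; both readings are exposed via
  ``DetectorConfig.fir_convention``.
- **Detector 2's "99 % of RMS"**: the 99th percentile of the smoothed
  envelope; ``("rms_fraction", 0.99)`` is available as an alternative rule.
- **Detector 1's "max amplitude difference < 2"**: the maximum absolute
  difference between successive extremum-to-extremum swings of the
  *broadband* z-scored signal inside the event. Any within-band reading is
  scale-free and therefore independent of χ; the broadband reading rejects
  sharp transients (its evident purpose), passes smoothly enveloped bursts,
  and produces the inverted-U noise profile. Detector 5 omits this
  criterion, which is why its noise profile rises monotonically toward
  white noise instead of turning over.
- **Event frequency** is (number of band-passed-signal troughs − 1) /
  duration; note this estimator is biased low by ≈ 1/duration, so the
  "> 80 Hz" criterion of detectors 1/5 implicitly disfavours short events.
- **Merge ordering**: detectors 3 and 4 merge threshold crossings before the
  duration filter (their merge windows are listed with detection); detectors
  1 and 5 merge after all amplitude/frequency criteria. Merged events span
  the union and keep the strongest constituent's peak and trough.
- **Detector 4** clips envelope extremes at 4 SD, squares, smooths (40 Hz
  Kaiser FIR); mean/SD of that transformed signal threshold the *unclipped*
  squared smoothed envelope at 4 SD.

The IED detector band-passes 25–80 Hz, thresholds the z-normalized envelope
at 2 SD for 20–100 ms, requires the raw broadband envelope to also exceed
2 SD, and concatenates events within 1 s. Ripples within a preset-specific
window of an IED are discarded; for pure-noise sweeps no IED exclusion is
applied (it belongs to the experimental-data pipeline).

## Noise-floor analytics

`run_sweep` simulates fresh colored noise per (exponent, iteration), runs
the detectors, and reports densities in Hz. Published scale is one-hour
traces with 100 iterations; this package's own tests and the acceptance
script use 600 s × 10 iterations, which resolves the curve shapes in about
two minutes of CPU. At that scale detector 1's density profile is an
inverted U peaking on a plateau around χ ≈ −1.4 ± 0.2 and detector 2's
peaks at −1.8; detectors 3/4 decline toward white noise; detector 5 rises
monotonically (ceiling). Effect sizes use a one-way repeated-measures ANOVA
with iterations as subjects; note that partial η² at desk scale reflects
the ratio of curve spread to per-trace Poisson noise and is *not*
comparable to values obtained at 100 × 3600 s.

`density_by_exponent` assigns each event (by trough time) to its containing
segment's exponent bin (−8 to 0 in 0.1 steps by default) and divides by the
time spent in each bin. `estimate_floor` reports
100 × min(1, n_surrogate / n_experimental) per group — the capped
orientation makes "77 % within the noise floor" representable; the raw
ratio and both counts are always carried alongside, since the literal
published wording (experimental / surrogate) exceeds 1. `floor_range`
returns the exponent span of nonzero surrogate density; on recordings whose
exponent spans [−4, −0.5], detector 1's detections concentrate around
[−1.2, −0.4] — the global threshold, dominated by the shallow segments,
silences the steep ones entirely.

Argmax ties on the exponent grid break toward the more negative exponent.

## Trial-locked statistics

Event-density timecourses use a 1 s moving window in 0.1 s steps, averaged
across trials; per-condition densities divide event counts by total
condition time. The pseudo-population statistics treat channels as the unit
of observation: one-way within-subject RM-ANOVA (partial η² =
SS_cond / (SS_cond + SS_error); Greenhouse–Geisser correction available but
off by default), tie-corrected Spearman correlation, first-order partial
correlation via residual regression (p on n − 3 df), and the Fisher-z test
for comparing two independent correlations (channel counts enter as n).

## Synthetic recordings (fixtures)

`generate_fixture` emulates the statistical skeleton of a state-scored
recording: per-epoch colored noise at state-specific exponents (wake ≈ −2,
SWS ≈ −3, task epochs with raised exponents), optional band-limited
Hann-enveloped ripple bursts and IED-like 60 ms sharp transients, amplitudes
in units of the (unit) background SD. It does **not** emulate oscillatory
peaks (spindles, theta), knees or multi-component aperiodic structure,
artifacts, or inter-channel correlation — so passing tests demonstrate
detector/analytics behaviour under exponent dynamics alone, not performance
on real recordings.

One consequence of steep backgrounds deserves emphasis: because the ripple
band carries a tiny fraction of total variance at χ ≈ −3, *any* burst that
is detectable in envelope z-units is enormous in band units, and a handful
of large injected bursts can inflate the global envelope SD enough to
silence background detections. Tests that inject "true ripples" therefore
calibrate amplitudes via the envelope oracle (e.g. 0.02 SD bursts at
χ = −3 land a few envelope-SDs above threshold).

## Problem sizes and tolerances

Test-suite simulations use 600 s traces (2400 s for detector 4's
event-locked average, whose low event rate otherwise leaves the
baseline-normalized average unstable), 10 sweep iterations, 50 simulated
channels for the task-bias analysis, and 20 replicates for exponent
recovery; the whole suite runs in ~3 minutes on one CPU. Statistical
kernels are checked to 1e-12 against brute-force oracles; exponent recovery
to |bias| < 0.05 and MAE < 0.1; fixture epoch exponents to ±0.15. All
stochastic tests are seeded.

## Known limitations

- The five detectors are faithful to their published parameters but the
  original implementations are not public; ambiguous criteria were resolved
  as documented above, and exact event-for-event agreement with the original
  code is not claimed. In particular the location of detector 1's density
  peak is sensitive to the amplitude-differential interpretation (a plateau
  over roughly [−1.7, −1.3] here versus a reported −1.6).
- Single-exponent and piecewise-constant-exponent noise only; no knees,
  no multiscale aperiodic mixtures.
- The floor estimate is a count ratio, blind to *which* events are false;
  at steep exponents fitted-plan surrogates overestimate the floor (see
  above).
- RM-ANOVA is the only pseudo-population model; mixed-effects confirmation
  is out of scope.
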