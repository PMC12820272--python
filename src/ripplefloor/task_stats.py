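"""Trial-locked event-density analysis and pseudo-population statistics.

Statistics operate at the channel level (channels are the unit of
observation): one-way repeated-measures ANOVA with partial eta-squared,
tie-corrected Spearman rank correlation, first-order partial correlation via
residual regression, and a Fisher-z test for comparing two correlation
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .ripple_detectors import DetectedEvent


@dataclass
class TrialTable:
    """Trials as (onset_s, offset_s, condition), e.g. ITI_1 / task / ITI_2."""

    trials: list[tuple[float, float, str]]

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValueError("trial table must contain at least one trial")
        tr = [(float(a), float(b), str(c)) for a, b, c in self.trials]
        for a, b, _ in tr:
            if not b > a:
                raise ValueError("trial offset must exceed onset")
        if any(a1 < a0 for (a0, _, _), (a1, _, _) in zip(tr, tr[1:])):
            raise ValueError("trial onsets must be increasing")
        self.trials = tr

    @property
    def conditions(self) -> list[str]:
        seen = []
        for _, _, c in self.trials:
            if c not in seen:
                seen.append(c)
        return seen

    def intervals(self, condition: str) -> list[tuple[float, float]]:
        return [(a, b) for a, b, c in self.trials if c == condition]

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# onset_s offset_s condition\n")
            for a, b, c in self.trials:
                fh.write(f"{a:.4f} {b:.4f} {c}\n")

    @classmethod
    def from_text(cls, path) -> "TrialTable":
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                a, b, c = line.split()[:3]
                rows.append((float(a), float(b), c))
        return cls(rows)


@dataclass
class DensityTimecourse:
    """Trial-averaged event density on a relative-time grid."""

    times: np.ndarray
    density: np.ndarray
    window: float
    step: float

    def __post_init__(self) -> None:
        if not (self.window > 0 and self.step > 0):
            raise ValueError("window and step must be positive")


def density_timecourse(events: list[DetectedEvent], trials: TrialTable,
                       window: float = 1.0, step: float = 0.1,
                       t_range: tuple[float, float] | None = None,
                       ) -> DensityTimecourse:
    """Sliding-window event density locked to trial onsets.

    At each relative time t, density is the number of event troughs inside
    [onset + t - window/2, onset + t + window/2), summed over trials and
    divided by n_trials * window — i.e. events per second averaged across
    trials.
    """
    if t_range is None:
        t_range = (0.0, max(b - a for a, b, _ in trials.trials))
    if window > t_range[1] - t_range[0] + window:
        raise ValueError("window longer than the analyzed span")
    times = np.arange(t_range[0], t_range[1] + step / 2, step)
    ev_times = np.sort([ev.trough_time for ev in events])
    n_trials = len(trials.trials)
    density = np.zeros_like(times)
    for onset, _, _ in trials.trials:
        lo = np.searchsorted(ev_times, onset + times - window / 2.0, side="left")
        hi = np.searchsorted(ev_times, onset + times + window / 2.0, side="left")
        density += hi - lo
    return DensityTimecourse(times, density / (n_trials * window), window, step)


def epoch_density(events: list[DetectedEvent], trials: TrialTable,
                  ) -> dict[str, float]:
    """Mean event density (Hz) per condition: events inside the condition's
    trials divided by the condition's total duration."""
    ev_times = np.sort([ev.trough_time for ev in events])
    out = {}
    for cond in trials.conditions:
        total = 0.0
        count = 0
        for a, b in trials.intervals(cond):
            total += b - a
            count += int(np.searchsorted(ev_times, b) - np.searchsorted(ev_times, a))
        if total <= 0:
            raise ValueError(f"zero total time for condition {cond!r}")
        out[cond] = count / total
    return out


def rm_anova(values: np.ndarray, correction: bool = False,
             ) -> tuple[float, float, float]:
    """One-way repeated-measures ANOVA on a (subjects x conditions) table.

    Returns (F, p, partial eta-squared) with
    partial eta^2 = SS_condition / (SS_condition + SS_error).
    With ``correction=True`` a Greenhouse-Geisser adjustment is applied to
    the degrees of freedom for the p-value (off by default).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be 2-D (subjects x conditions)")
    n_subj, n_cond = values.shape
    if n_cond < 2 or n_subj < 2:
        raise ValueError("need >= 2 conditions and >= 2 subjects")
    if not np.all(np.isfinite(values)):
        raise ValueError("missing cells are not supported")
    grand = values.mean()
    cond_means = values.mean(axis=0)
    subj_means = values.mean(axis=1)
    ss_cond = n_subj * float(np.sum((cond_means - grand) ** 2))
    ss_subj = n_cond * float(np.sum((subj_means - grand) ** 2))
    ss_total = float(np.sum((values - grand) ** 2))
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = n_cond - 1
    df_err = (n_cond - 1) * (n_subj - 1)
    tiny = 1e-12 * max(ss_total, 1.0)
    if ss_cond <= tiny:
        return 0.0, 1.0, 0.0
    if ss_err <= tiny:
        return np.inf, 0.0, 1.0
    f = (ss_cond / df_cond) / (ss_err / df_err)
    eps = 1.0
    if correction:
        eps = _greenhouse_geisser_epsilon(values)
    p = float(sstats.f.sf(f, df_cond * eps, df_err * eps))
    eta = ss_cond / (ss_cond + ss_err)
    return float(f), p, float(eta)


def _greenhouse_geisser_epsilon(values: np.ndarray) -> float:
    centered = values - values.mean(axis=1, keepdims=True)
    cov = np.cov(centered.T, ddof=1)
    k = cov.shape[0]
    mean_diag = np.trace(cov) / k
    num = (k * mean_diag - cov.mean()) ** 2
    den = (k - 1) * (np.sum(cov ** 2) - 2 * k * np.sum(cov.mean(axis=1) ** 2)
                     + k ** 2 * cov.mean() ** 2)
    return float(np.clip(num / den if den > 0 else 1.0, 1.0 / (k - 1), 1.0))


def spearman(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("x and y must have equal length >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    rho, p = sstats.spearmanr(x, y)
    return float(rho), float(p)


def partial_correlation(x, y, control) -> tuple[float, float]:
    """First-order partial correlation of x and y controlling for ``control``.

    Both variables are regressed on the control (with intercept); the Pearson
    correlation of the residuals is returned with a two-sided p-value on
    n - 3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(control, dtype=float)
    n = x.size
    if not (y.size == n and c.size == n) or n < 5:
        raise ValueError("x, y, control must have equal length >= 5")
    if np.ptp(c) == 0:
        raise ValueError("constant control variable")
    design = np.vstack([np.ones(n), c]).T
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    # a variable fully explained by the control has no residual variance
    if (np.sum(rx ** 2) <= 1e-20 * np.sum((x - x.mean()) ** 2)
            or np.sum(ry ** 2) <= 1e-20 * np.sum((y - y.mean()) ** 2)):
        return 0.0, 1.0
    denom = np.sqrt(np.sum(rx ** 2) * np.sum(ry ** 2))
    r = float(np.sum(rx * ry) / denom)
    df = n - 3
    r_clip = min(abs(r), 1.0 - 1e-15)
    t = r_clip * np.sqrt(df / (1.0 - r_clip ** 2))
    p = float(2.0 * sstats.t.sf(t, df))
    return r, p


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> float:
    """Two-sided p for the difference of two independent correlations
    (Fisher z-transform test)."""
    if not (abs(r1) < 1 and abs(r2) < 1):
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n1 < 4 or n2 < 4:
        raise ValueError("need n >= 4 in both samples")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(2.0 * sstats.norm.sf(abs(z)))


def stats_record(name: str, statistic: float, df, p: float,
                 effect_size: float | None = None) -> dict:
    """Uniform JSON-style record for an inferential result."""
    return {"test": name, "statistic": statistic, "df": df, "p": p,
            "effect_size": effect_size}
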