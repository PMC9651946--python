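"""Saccade detection, kinematics, post-saccade damping, and group statistics.

Saccades are rapid, ballistic head (or body) turns. Detection uses a
velocity threshold with hysteresis: an event starts when |velocity| crosses
the threshold and extends outward to where it falls below a fraction of the
threshold. The return toward the neutral position after a saccade is
summarized by the time constant tau of a decaying exponential fitted to the
trace immediately after the saccade ends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .signals import TimeSeries

DEFAULT_VEL_THRESHOLD = 100.0  # deg/s, head saccades
DEFAULT_HYSTERESIS_FRACTION = 0.25
DEFAULT_MIN_INTERVAL = 0.1     # s
DEFAULT_TAU_WINDOW = 1.0       # s of data after the saccade offset
MIN_FIT_R2 = 0.5

METRICS = ("amplitude", "peak_velocity", "duration", "tau")


@dataclass
class SaccadeEvent:
    """One detected rapid turn with its kinematics and damping fit."""

    onset: float
    offset: float
    amplitude: float
    peak_velocity: float
    direction: int
    tau: float | None = None
    fit_quality: float | None = None

    def __post_init__(self) -> None:
        if not (self.offset > self.onset):
            raise ValueError("duration must be positive")
        if self.tau is not None and not (self.tau > 0):
            raise ValueError("tau must be positive when present")

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def metric(self, name: str) -> float | None:
        if name == "amplitude":
            return abs(self.amplitude)
        if name == "peak_velocity":
            return self.peak_velocity
        if name == "duration":
            return self.duration
        if name == "tau":
            return self.tau
        raise ValueError(f"unknown metric {name!r}")


def detect_saccades(ts: TimeSeries, vel_threshold: float = DEFAULT_VEL_THRESHOLD,
                    min_interval: float = DEFAULT_MIN_INTERVAL,
                    hysteresis_fraction: float = DEFAULT_HYSTERESIS_FRACTION
                    ) -> list:
    """Detect saccades as hysteresis-bounded velocity-threshold crossings.

    Each supra-threshold run is extended outward while the speed stays above
    ``hysteresis_fraction * vel_threshold`` *and* the velocity keeps the
    saccade's sign; the sign condition stops the event at the movement
    turn-around so the post-saccade return is not absorbed into it. Events
    whose gaps are shorter than ``min_interval`` are merged. Amplitude is the
    displacement from onset to offset; peak velocity is the maximum
    |velocity| within the event. A warning is raised when the threshold sits
    below 3x the velocity-noise floor (median-based robust SD), where false
    positives are expected.
    """
    if not (vel_threshold > 0):
        raise ValueError("vel_threshold must be > 0")
    vel = ts.velocity()
    speed = np.abs(vel)
    noise_sd = 1.4826 * np.median(np.abs(vel - np.median(vel)))
    if vel_threshold < 3 * noise_sd:
        warnings.warn(
            f"vel_threshold {vel_threshold:.1f} deg/s is below 3x the velocity "
            f"noise SD ({noise_sd:.1f} deg/s); expect false positives",
            stacklevel=2)
    low = hysteresis_fraction * vel_threshold
    above = speed >= vel_threshold
    if not above.any():
        return []
    starts = list(np.flatnonzero(np.diff(above.astype(int)) == 1) + 1)
    stops = list(np.flatnonzero(np.diff(above.astype(int)) == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(speed.size)
    events_idx = []
    for i0, i1 in zip(starts, stops):
        peak = i0 + int(np.argmax(speed[i0:i1]))
        sign = np.sign(vel[peak]) or 1.0
        same_sign_fast = (speed >= low) & (np.sign(vel) == sign)
        while i0 > 0 and same_sign_fast[i0 - 1]:
            i0 -= 1
        while i1 < speed.size and same_sign_fast[i1]:
            i1 += 1
        events_idx.append([i0, i1])
    # merge events separated by less than min_interval
    merged = [events_idx[0]]
    gap = int(round(min_interval * ts.sample_rate))
    for i0, i1 in events_idx[1:]:
        if i0 - merged[-1][1] < gap:
            merged[-1][1] = i1
        else:
            merged.append([i0, i1])
    events = []
    dt = ts.dt
    for i0, i1 in merged:
        i1 = min(i1, len(ts) - 1)
        amp = float(ts.values[i1] - ts.values[i0])
        direction = int(np.sign(amp)) or 1
        events.append(SaccadeEvent(
            onset=ts.t0 + i0 * dt, offset=ts.t0 + i1 * dt, amplitude=amp,
            peak_velocity=float(speed[i0:i1 + 1].max()), direction=direction))
    return events


def fit_decay_tau(ts: TimeSeries, event: SaccadeEvent,
                  window: float = DEFAULT_TAU_WINDOW) -> tuple[float, float]:
    """Fit theta(t) = theta0*exp(-t/tau) + theta_inf after the saccade offset.

    Nonlinear least squares with a log-linear initialization; ``theta_inf``
    is a free offset. Returns (tau, R^2); fits with R^2 < 0.5 (including
    degenerate flat traces) should be treated as unreliable.
    """
    i0 = int(round((event.offset - ts.t0) * ts.sample_rate))
    i1 = i0 + int(round(window * ts.sample_rate))
    if i1 > len(ts):
        raise ValueError("tau-fit window truncated by the end of the trial")
    y = ts.values[i0:i1]
    t = np.arange(y.size) * ts.dt

    def model(t, theta0, tau, theta_inf):
        return theta0 * np.exp(-t / tau) + theta_inf

    theta_inf0 = y[-1]
    theta00 = y[0] - theta_inf0
    # log-linear initialization for tau on the offset-removed magnitude
    resid = np.abs(y - theta_inf0)
    pos = resid > 1e-9 * max(1.0, np.abs(theta00))
    if pos.sum() >= 2 and abs(theta00) > 0:
        slope = np.polyfit(t[pos], np.log(resid[pos]), 1)[0]
        tau0 = -1.0 / slope if slope < 0 else window
    else:
        tau0 = window / 3
    tau0 = float(np.clip(tau0, 1e-3, 100.0))
    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=(theta00, tau0, theta_inf0),
            bounds=([-np.inf, 1e-4, -np.inf], [np.inf, 1e3, np.inf]),
            maxfev=2000)
    except RuntimeError:
        return np.inf, 0.0
    fitted = model(t, *popt)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(popt[1]), r2


def attach_taus(ts: TimeSeries, events: list, window: float = DEFAULT_TAU_WINDOW
                ) -> list:
    """Fit tau after each event where the window is clean; annotate in place.

    Events whose post-offset window contains another event, or is truncated
    by the trial end, are left without a tau. Unreliable fits (R^2 < 0.5)
    are likewise not assigned a tau but keep their fit quality.
    """
    onsets = [e.onset for e in events]
    for k, ev in enumerate(events):
        next_onset = onsets[k + 1] if k + 1 < len(events) else np.inf
        if ev.offset + window > next_onset:
            continue
        try:
            tau, r2 = fit_decay_tau(ts, ev, window)
        except ValueError:
            continue
        ev.fit_quality = r2
        if np.isfinite(tau) and tau > 0 and r2 >= MIN_FIT_R2:
            ev.tau = tau
    return events


def saccade_population_stats(events: list, fly_ids=None) -> pd.DataFrame:
    """Per-metric count/mean/median/SD, pooled and (optionally) per fly.

    ``fly_ids`` aligns with ``events``; when given, per-fly means are
    computed first and summarized alongside the pooled statistics.
    """
    if not events:
        raise ValueError("no events to summarize")
    rows = []
    for metric in METRICS:
        vals = np.array([e.metric(metric) for e in events
                         if e.metric(metric) is not None], dtype=float)
        if vals.size == 0:
            continue
        rows.append({
            "metric": metric, "level": "pooled", "n": int(vals.size),
            "mean": float(vals.mean()), "median": float(np.median(vals)),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        })
        if fly_ids is not None:
            per_fly = pd.DataFrame({
                "fly": [f for f, e in zip(fly_ids, events)
                        if e.metric(metric) is not None],
                "value": vals,
            }).groupby("fly")["value"].mean()
            rows.append({
                "metric": metric, "level": "per_fly_means", "n": int(per_fly.size),
                "mean": float(per_fly.mean()), "median": float(per_fly.median()),
                "sd": float(per_fly.std(ddof=1)) if per_fly.size > 1 else 0.0,
            })
    return pd.DataFrame(rows)


def compare_groups(group_a: list, group_b: list, metric: str) -> dict:
    """Two-sided Wilcoxon rank-sum and t-test on a saccade metric.

    Also reports the ratio of group medians (b/a), the natural summary for
    between-condition contrasts such as damping time constants.
    """
    a = np.array([e.metric(metric) for e in group_a
                  if e.metric(metric) is not None], dtype=float)
    b = np.array([e.metric(metric) for e in group_b
                  if e.metric(metric) is not None], dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError(f"metric {metric!r} absent in one of the groups")
    w_stat, w_p = stats.ranksums(a, b)
    t_stat, t_p = stats.ttest_ind(a, b, equal_var=False)
    med_a, med_b = float(np.median(a)), float(np.median(b))
    return {
        "metric": metric, "n_a": int(a.size), "n_b": int(b.size),
        "ranksum_stat": float(w_stat), "ranksum_p": float(w_p),
        "t_stat": float(t_stat), "t_p": float(t_p),
        "median_a": med_a, "median_b": med_b,
        "median_ratio_b_over_a": med_b / med_a if med_a != 0 else np.inf,
    }


def compare_variances(displacements_a, displacements_b) -> tuple[float, float]:
    """Two-sided F-test on the variances of two displacement samples."""
    a = np.asarray(displacements_a, dtype=float)
    b = np.asarray(displacements_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two samples per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        raise ValueError("zero variance in one of the groups")
    f_stat = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    cdf = stats.f.cdf(f_stat, dfa, dfb)
    p = 2 * min(cdf, 1 - cdf)
    return float(f_stat), float(min(p, 1.0))
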