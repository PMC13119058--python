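"""Magnetic-tweezer trace analysis.

Pipeline for bead-extension time series at fixed force and magnet turns:
sliding-window smoothing, baseline statistics from a protein-free tether,
threshold event calling (3 SD above baseline, > 2.5 s dwell), per-event
extension rates and lifetimes, exponential lifetime fitting, and hat-curve
buckling-arm slopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

__all__ = [
    "Trace", "HatCurve", "EventDetectionConfig", "EventCall", "LifetimeFit",
    "HatSlopeFit", "smooth", "baseline_stats", "detect_events",
    "fit_lifetimes", "hat_slope", "screen_compaction",
]


@dataclass
class Trace:
    """A bead time series at constant force / turns.

    time is strictly increasing and (nearly) uniform; extension in µm.
    ``force`` may carry a per-sample force channel for clamp/pull records.
    """

    time: np.ndarray  # s
    extension: np.ndarray  # µm
    turns: float = 0.0
    force: float | np.ndarray = 0.0  # pN
    condition: str = ""
    bead_id: str = ""
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        if self.time.shape != self.extension.shape:
            raise ValueError("time and extension must have the same shape")
        if self.time.size >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if np.max(np.abs(dt - dt.mean())) > 0.01 * dt.mean() + 1e-12:
                raise ValueError("time grid must be uniform within 1% jitter")
        if not np.all(np.isfinite(self.extension)):
            raise ValueError("extension must be finite everywhere")

    @property
    def sample_rate(self) -> float:
        """Samples per second."""
        if self.time.size < 2:
            raise ValueError("need at least 2 samples")
        return 1.0 / float(np.mean(np.diff(self.time)))

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass
class HatCurve:
    """Rotation–extension data: extension (µm) versus magnet turns."""

    turns: np.ndarray
    extension: np.ndarray

    def __post_init__(self) -> None:
        self.turns = np.asarray(self.turns, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        if self.turns.shape != self.extension.shape:
            raise ValueError("turns and extension must have the same shape")


@dataclass(frozen=True)
class EventDetectionConfig:
    """Event-calling thresholds.

    window : smoothing window, s (default 5).
    sd_multiplier : event threshold in baseline SDs (default 3).
    min_duration : minimum dwell above threshold, s (default 2.5).
    """

    window: float = 5.0
    sd_multiplier: float = 3.0
    min_duration: float = 2.5

    def __post_init__(self) -> None:
        if self.window <= 0 or self.sd_multiplier <= 0 or self.min_duration < 0:
            raise ValueError("window and sd_multiplier must be positive, "
                             "min_duration non-negative")


@dataclass(frozen=True)
class EventCall:
    """One extension excursion above threshold.

    Rates are slopes of linear fits into (positive) and out of (negative,
    stored signed) the event's highest local maximum; lifetime is the time
    between the threshold-crossing points.
    """

    start: float  # s
    end: float  # s
    peak_amplitude: float  # µm above baseline mean
    positive_rate: float  # µm/s, >= 0
    negative_rate: float  # µm/s, signed (typically < 0)
    lifetime: float  # s
    censored: bool = False  # touches the end of the record


@dataclass(frozen=True)
class LifetimeFit:
    half_life: float  # s
    ci95: tuple[float, float]  # s
    n_events: int
    degenerate: bool = False  # all dwells identical


@dataclass(frozen=True)
class HatSlopeFit:
    slope: float  # µm/turn
    r2: float
    n_points: int
    mixed_regime: bool  # poor linearity: window likely spans the apex


def smooth(trace: Trace, window: float = 5.0) -> Trace:
    """Centered moving average over ``window`` seconds.

    The output grid equals the input grid; endpoints use truncated windows.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if window > trace.duration:
        raise ValueError("window exceeds trace duration")
    n = max(1, int(round(window * trace.sample_rate)))
    sm = (pd.Series(trace.extension)
          .rolling(n, center=True, min_periods=1).mean().to_numpy())
    out = replace(trace)
    out.extension = sm
    out.smoothed = True
    return out


def _gaussian(x, amp, mu, sd):
    return amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)


def baseline_stats(dna_only: Trace, gof_threshold: float = 0.9
                   ) -> tuple[float, float]:
    """Baseline mean and SD (µm) from a protein-free tether record.

    Fits a Gaussian to the extension histogram; warns if the histogram is a
    poor Gaussian (e.g. bimodal plateaus), in which case the fitted moments
    are not a trustworthy baseline.
    """
    ext = dna_only.extension
    if ext.size < 100:
        raise ValueError(f"need >= 100 samples for a baseline, got {ext.size}")
    s_mean, s_sd = float(ext.mean()), float(ext.std(ddof=1))
    if s_sd == 0.0:
        raise ValueError("degenerate baseline: zero-variance trace")
    counts, edges = np.histogram(ext, bins=max(20, min(80, ext.size // 50)))
    centers = 0.5 * (edges[:-1] + edges[1:])
    try:
        popt, _ = curve_fit(_gaussian, centers, counts,
                            p0=[counts.max(), s_mean, s_sd], maxfev=10000)
    except RuntimeError:
        warnings.warn("baseline Gaussian fit failed; using sample moments")
        return s_mean, s_sd
    _, mu, sd = popt
    sd = abs(float(sd))
    resid = counts - _gaussian(centers, *popt)
    ss_tot = float(((counts - counts.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 0.0
    if r2 < gof_threshold:
        warnings.warn(
            f"baseline histogram is a poor Gaussian (r2={r2:.2f}); the trace "
            "may be multimodal")
    return float(mu), sd


def detect_events(trace: Trace, baseline: tuple[float, float],
                  config: EventDetectionConfig = EventDetectionConfig()
                  ) -> list[EventCall]:
    """Call extension events above ``mean + k·SD`` lasting > min_duration.

    The trace is smoothed first if it has not been already. Per event the
    highest local maximum (minimum prominence of one baseline SD) anchors the
    rate fits: positive rate from the rising segment into it, negative rate
    from the falling segment out of it. Events reaching the end of the record
    are flagged right-censored.
    """
    b_mean, b_sd = baseline
    if b_sd <= 0:
        raise ValueError("baseline SD must be positive")
    tr = trace if trace.smoothed else smooth(trace, config.window)
    thr = b_mean + config.sd_multiplier * b_sd
    above = tr.extension > thr
    if not above.any():
        return []
    # contiguous runs above threshold
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1  # exclusive
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    events: list[EventCall] = []
    for i0, i1 in zip(starts, ends):
        t0, t1 = tr.time[i0], tr.time[i1 - 1]
        lifetime = float(t1 - t0)
        censored = i1 == above.size
        if lifetime <= config.min_duration:
            continue
        seg = tr.extension[i0:i1]
        peaks, _ = find_peaks(seg, prominence=b_sd)
        peak_idx = (i0 + peaks[np.argmax(seg[peaks])]) if peaks.size \
            else i0 + int(np.argmax(seg))
        peak_amp = float(tr.extension[peak_idx] - b_mean)
        # rising segment: from run start into the maximum
        pos_rate = 0.0
        if peak_idx > i0:
            p = np.polyfit(tr.time[i0:peak_idx + 1],
                           tr.extension[i0:peak_idx + 1], 1)
            pos_rate = max(float(p[0]), 0.0)
        neg_rate = 0.0
        if i1 - 1 > peak_idx:
            p = np.polyfit(tr.time[peak_idx:i1],
                           tr.extension[peak_idx:i1], 1)
            neg_rate = float(p[0])
        events.append(EventCall(start=float(t0), end=float(t1),
                                peak_amplitude=peak_amp,
                                positive_rate=pos_rate, negative_rate=neg_rate,
                                lifetime=lifetime, censored=censored))
    return events


def fit_lifetimes(events, method: str = "mle") -> LifetimeFit:
    """Exponential half-life of event lifetimes with a 95% CI.

    ``method="mle"`` (default): maximum-likelihood exponential rate; the CI
    is the exact chi-square interval for the rate of an exponential sample
    (the sum of n dwells is Gamma(n, 1/λ)). ``method="survival"``:
    least-squares fit of the empirical survival curve to exp(−t ln2 / t½).
    """
    dwell = np.asarray([e.lifetime if isinstance(e, EventCall) else float(e)
                        for e in events], dtype=float)
    if dwell.size < 10:
        raise ValueError(f"need >= 10 events for a lifetime fit, got {dwell.size}")
    if np.any(dwell <= 0):
        raise ValueError("lifetimes must be positive")
    degenerate = bool(np.ptp(dwell) == 0.0)
    if degenerate:
        warnings.warn("all dwell times identical; exponential fit is degenerate")
    n = dwell.size
    if method == "mle":
        mean = dwell.mean()
        half = float(np.log(2) * mean)
        total = dwell.sum()
        # rate CI: lambda in [chi2(0.025;2n), chi2(0.975;2n)] / (2*sum)
        lo_rate = stats.chi2.ppf(0.025, 2 * n) / (2 * total)
        hi_rate = stats.chi2.ppf(0.975, 2 * n) / (2 * total)
        ci = (float(np.log(2) / hi_rate), float(np.log(2) / lo_rate))
    elif method == "survival":
        t_sorted = np.sort(dwell)
        surv = 1.0 - np.arange(n) / n
        if degenerate:
            half = float(np.log(2) * dwell.mean())
            return LifetimeFit(half, (half, half), n, True)
        popt, pcov = curve_fit(lambda t, th: np.exp(-t * np.log(2) / th),
                               t_sorted, surv, p0=[dwell.mean()])
        half = float(popt[0])
        se = float(np.sqrt(pcov[0, 0]))
        ci = (half - 1.96 * se, half + 1.96 * se)
    else:
        raise ValueError("method must be 'mle' or 'survival'")
    return LifetimeFit(half_life=half, ci95=ci, n_events=n,
                       degenerate=degenerate)


def hat_slope(hat: HatCurve, turn_lo: float = -70.0, turn_hi: float = -20.0,
              r2_threshold: float = 0.8) -> HatSlopeFit:
    """Least-squares slope (µm/turn) of the hat curve on [turn_lo, turn_hi].

    The default window (−70 to −20 turns) sits on the negative buckling arm;
    a low r² flags a mixed-regime window (one that spans the apex or a
    melting plateau boundary).
    """
    if turn_lo >= turn_hi:
        raise ValueError("need turn_lo < turn_hi")
    mask = (hat.turns >= turn_lo) & (hat.turns <= turn_hi)
    if mask.sum() < 3:
        raise ValueError(f"need >= 3 points in [{turn_lo}, {turn_hi}], "
                         f"got {int(mask.sum())}")
    res = stats.linregress(hat.turns[mask], hat.extension[mask])
    r2 = float(res.rvalue ** 2) if np.isfinite(res.rvalue) else 1.0
    return HatSlopeFit(slope=float(res.slope), r2=r2,
                       n_points=int(mask.sum()),
                       mixed_regime=r2 < r2_threshold)


def screen_compaction(trace: Trace, baseline: tuple[float, float],
                      window: float = 5.0, tol_sd: float = 0.0
                      ) -> tuple[Trace, bool]:
    """Censor a trace once the bead compacts below its initial extension.

    The smoothed trace is truncated at the first sample falling more than
    ``tol_sd`` baseline SDs below the initial (smoothed) extension; data past
    that point are discarded even if the bead later recovers. Returns the
    kept portion of the *original* trace and a censored flag.
    """
    b_mean, b_sd = baseline
    sm = trace if trace.smoothed else smooth(trace, window)
    initial = sm.extension[0]
    below = sm.extension < initial - tol_sd * b_sd
    below[0] = False
    if not below.any():
        return trace, False
    cut = int(np.argmax(below))
    kept = replace(trace)
    kept.time = trace.time[:cut]
    kept.extension = trace.extension[:cut]
    if isinstance(trace.force, np.ndarray):
        kept.force = trace.force[:cut]
    return kept, True
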