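"""Seeded synthetic-data generators emulating the instrument records.

Every generator is a pure function of its configuration and seed and returns
ground truth alongside the data, so the whole analysis pipeline can be
exercised and scored without instrument files:

- magnetic-tweezer bead traces: Gaussian baseline noise plus trapezoidal
  (linear rise, exponential-dwell plateau, linear fall) extension events;
- rotation–extension hat curves with linear buckling arms;
- re-extension force–extension curves whose sawtooth comes from programmed
  loop ruptures against the extensible-WLC theory curve;
- qPCR Cp tables with multiplicative per-cycle efficiency structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mechanics import (HatCurveModel, WLCParams, hat_extension,
                        wlc_extension_to_force, wlc_force_to_extension)
from .mt import HatCurve, Trace
from .trap import FECurve

__all__ = ["TraceGenConfig", "GroundTruth", "gen_mt_trace", "gen_hat_curve",
           "gen_fe_curve", "gen_dlc_table", "gen_clamp_trace"]


@dataclass(frozen=True)
class TraceGenConfig:
    """Magnetic-tweezer trace generator settings.

    Defaults emulate a 10 min monitor at 50 Hz of a ~4 µm tether whose
    extension events rise at ~0.3 µm/s to ~1 µm above baseline and dwell
    with a 20 s half-life over 0.1 µm baseline noise (SNR 10).
    """

    duration: float = 600.0  # s
    sample_rate: float = 50.0  # Hz
    baseline_extension: float = 3.0  # µm
    noise_sd: float = 0.1  # µm
    event_count: int = 3
    event_amplitude_mean: float = 1.0  # µm
    event_amplitude_sd: float = 0.1  # µm
    event_rise_rate: float = 0.3  # µm/s
    lifetime_half_life: float = 20.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sample_rate <= 0 or self.noise_sd <= 0:
            raise ValueError("duration, sample_rate, noise_sd must be positive")
        if min(self.event_count, self.event_amplitude_mean,
               self.event_amplitude_sd, self.event_rise_rate,
               self.lifetime_half_life) < 0:
            raise ValueError("event parameters must be non-negative")
        if self.sample_rate * self.duration > 1e8:
            raise ValueError("trace too large (> 1e8 samples)")


@dataclass
class GroundTruth:
    """Programmed truth attached to generated data.

    events : (start_s, amplitude_um, rise_rate_um_s, lifetime_s) per event
        (non-overlapping; overlapping draws are merged and counted).
    loops : (size_bp, rupture_force_pN) in rupture order.
    dlc_true_signal : programmed chimera-to-ligation ratio.
    """

    events: list = field(default_factory=list)
    loops: list = field(default_factory=list)
    dlc_true_signal: float | None = None
    n_merged: int = 0
    initial_constrained_bp: float | None = None

    @staticmethod
    def threshold_dwell(event, threshold_above_baseline: float) -> float:
        """Noise-free time a trapezoid event spends above a threshold.

        Detection reports lifetimes between threshold crossings, which for a
        rise–plateau–fall event exceed the plateau dwell by the ramp time
        spent above the threshold on each side.
        """
        _, amp, rise_rate, dwell = event
        if amp <= threshold_above_baseline:
            return 0.0
        if rise_rate <= 0:
            return float(dwell)
        return float(dwell + 2.0 * (amp - threshold_above_baseline) / rise_rate)


def gen_mt_trace(config: TraceGenConfig) -> tuple[Trace, GroundTruth]:
    """Synthesize a bead-extension trace with trapezoidal events.

    Event starts are uniform over the record; each event rises linearly at
    ``event_rise_rate`` to a normal amplitude (floored at 0), dwells for an
    exponential time (rate ln2 / half-life), and returns linearly. Draws
    whose rise would overlap the previous event are merged into it (counted
    in ``n_merged``); events are truncated at the record end.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.sample_rate))
    t = np.arange(n) / config.sample_rate
    ext = np.full(n, config.baseline_extension)
    truth = GroundTruth()

    starts = np.sort(rng.uniform(0, config.duration, config.event_count))
    prev_end = -np.inf
    for s in starts:
        amp = max(rng.normal(config.event_amplitude_mean,
                             config.event_amplitude_sd), 0.0)
        dwell = rng.exponential(config.lifetime_half_life / np.log(2))
        rise = amp / config.event_rise_rate if config.event_rise_rate > 0 else 0.0
        if s < prev_end:
            truth.n_merged += 1
            continue
        end = s + 2 * rise + dwell
        prev_end = end
        # trapezoid: rise [s, s+rise], plateau, fall [end-rise, end]
        up = (t >= s) & (t < s + rise)
        ext[up] += config.event_rise_rate * (t[up] - s)
        flat = (t >= s + rise) & (t < s + rise + dwell)
        ext[flat] += amp
        down = (t >= s + rise + dwell) & (t < end)
        ext[down] += amp - config.event_rise_rate * (t[down] - (s + rise + dwell))
        truth.events.append((float(s), float(amp),
                             float(config.event_rise_rate), float(dwell)))
    ext += rng.normal(0.0, config.noise_sd, n)
    trace = Trace(time=t, extension=ext, condition="synthetic",
                  bead_id=f"sim-{config.seed}")
    return trace, truth


def gen_hat_curve(model: HatCurveModel, noise_sd: float = 0.0,
                  n_points: int = 141, seed: int = 0,
                  turn_lo: float = -70.0, turn_hi: float = 70.0) -> HatCurve:
    """Hat-curve samples on a uniform turn grid plus Gaussian noise."""
    if n_points < 5:
        raise ValueError("need >= 5 points")
    rng = np.random.default_rng(seed)
    turns = np.linspace(turn_lo, turn_hi, n_points)
    ext = hat_extension(model, turns)
    if noise_sd > 0:
        ext = ext + rng.normal(0.0, noise_sd, n_points)
    return HatCurve(turns=turns, extension=ext)


def gen_fe_curve(wlc: WLCParams, loops, initial_constrained_bp: float,
                 pulling_rate: float = 0.1, noise_sd_force: float = 0.25,
                 seed: int = 0, sample_rate: float = 100.0,
                 start_fraction: float = 0.4, f_max: float = 45.0
                 ) -> tuple[FECurve, GroundTruth]:
    """Synthesize a re-extension pull with programmed loop ruptures.

    The imposed extension rises at ``pulling_rate``; the force at each point
    is the WLC force of an effective contour equal to the full template minus
    the currently constrained bp. When the (noise-free) force reaches the
    next loop's rupture force, that loop's bp rejoin the contour and the
    force drops back toward theory. Gaussian force noise is added on top.
    """
    loops = [(float(b), float(f)) for b, f in loops]
    if initial_constrained_bp < sum(b for b, _ in loops):
        raise ValueError("initial_constrained_bp must cover the loop sizes")
    if any(f >= wlc.force_cap for _, f in loops):
        raise ValueError("rupture force above the configured force cap")
    if any(f >= f_max for _, f in loops):
        raise ValueError("rupture force above the pull's maximum force")
    rng = np.random.default_rng(seed)
    total_bp = wlc.contour_length_bp
    constrained = float(initial_constrained_bp)
    eff = wlc.with_contour_bp(int(round(total_bp - constrained)))
    final_eff = wlc.with_contour_bp(
        int(round(total_bp - (constrained - sum(b for b, _ in loops)))))
    dx = pulling_rate / sample_rate
    x0 = start_fraction * eff.contour_um
    x_end = wlc_force_to_extension(final_eff, f_max)
    xs = np.arange(x0, x_end + dx, dx)
    force = np.empty_like(xs)
    queue = list(loops)
    truth = GroundTruth(loops=[], initial_constrained_bp=initial_constrained_bp)
    i = 0
    while i < xs.size:
        if queue:
            # extend this contour state until the next programmed rupture
            x_rupt = wlc_force_to_extension(eff, queue[0][1])
            j = int(np.searchsorted(xs, x_rupt, side="right"))
            j = max(j, i + 1)
        else:
            j = xs.size
        j = min(j, xs.size)
        force[i:j] = wlc_extension_to_force(eff, xs[i:j])
        i = j
        while queue and i < xs.size and \
                wlc_extension_to_force(eff, xs[i]) >= queue[0][1]:
            size, rupt = queue.pop(0)
            truth.loops.append((size, rupt))
            constrained -= size
            eff = wlc.with_contour_bp(int(round(total_bp - constrained)))
    xs = xs[force <= f_max] if force.size else xs
    force = force[force <= f_max] if force.size else force
    if noise_sd_force > 0:
        force = force + rng.normal(0.0, noise_sd_force, force.size)
    curve = FECurve(extension=np.asarray(xs), force=np.clip(force, 0.0, None),
                    pull_rate=pulling_rate)
    return curve, truth


def gen_clamp_trace(velocity_bp_s: float, duration: float, force: float,
                    wlc: WLCParams = WLCParams(), start_extension: float = 10.0,
                    noise_sd: float = 0.02, sample_rate: float = 50.0,
                    compaction: bool = True, seed: int = 0) -> Trace:
    """Constant-force record of steady compaction (or translocation).

    Bead separation changes linearly at ``velocity_bp_s`` (through the
    helical rise) with Gaussian read noise; used to score the clamp-velocity
    recovery.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    v_um = velocity_bp_s * wlc.rise_per_bp / 1000.0
    sign = -1.0 if compaction else 1.0
    ext = start_extension + sign * v_um * t + rng.normal(0, noise_sd, n)
    return Trace(time=t, extension=ext, force=force, condition="clamp")


def gen_dlc_table(true_signal: float, eff_dlc: float = 2.0,
                  eff_lig: float = 2.0, cp_noise_sd: float = 0.0,
                  replicates: int = 3, seed: int = 0, strain: str = "WT",
                  timepoint_h: float = 3.0,
                  cp_lig_range: tuple[float, float] = (14.0, 16.0)
                  ) -> pd.DataFrame:
    """Synthesize a qPCR Cp table encoding a programmed DLC signal.

    Cp_lig is drawn uniformly from ``cp_lig_range`` per replicate; Cp_dlc is
    set so eff_dlc^(−Cp_dlc) / eff_lig^(−Cp_lig) equals ``true_signal``,
    then Gaussian cycle noise is added to both channels.
    """
    if true_signal <= 0:
        raise ValueError("true_signal must be positive")
    for eff in (eff_dlc, eff_lig):
        if not 1.0 < eff <= 2.0:
            raise ValueError("efficiencies must be in (1, 2]")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(replicates):
        cp_lig = rng.uniform(*cp_lig_range)
        # eff_dlc^(-cp_dlc) = signal * eff_lig^(-cp_lig)
        cp_dlc = -np.log(true_signal * eff_lig ** (-cp_lig)) / np.log(eff_dlc)
        rows.append({
            "strain": strain, "timepoint_h": timepoint_h, "replicate": rep,
            "eff_dlc": eff_dlc,
            "cp_dlc": cp_dlc + rng.normal(0, cp_noise_sd) if cp_noise_sd else cp_dlc,
            "eff_lig": eff_lig,
            "cp_lig": cp_lig + rng.normal(0, cp_noise_sd) if cp_noise_sd else cp_lig,
        })
    return pd.DataFrame(rows)
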