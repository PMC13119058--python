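"""Optical-trap analyses: force–extension sawtooth decomposition, force-clamp
velocities, and maximum force output during translocation.

A protein-compacted tether pulled at constant rate deviates from the bare-DNA
worm-like-chain curve because part of the contour is sequestered in loops.
Each loop rupture returns a block of contour, dropping the force back toward
theory and producing a sawtooth. The contour deficit at a given force F is

    Δbp = (x_theory(F) − x_measured) × 1000 / rise_nm

evaluated at rupture forces, where the tether is near full fractional
extension and the extension deficit approximates the contour deficit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, medfilt

from .mechanics import WLCParams, wlc_extension_to_force, wlc_force_to_extension
from .mt import Trace, smooth

__all__ = ["FECurve", "DeviationSet", "ClampResult", "compare_to_theory",
           "clamp_velocity", "max_force", "percent_extension"]


@dataclass
class FECurve:
    """A re-extension pull: force (pN) sampled on a rising extension grid."""

    extension: np.ndarray  # µm
    force: np.ndarray  # pN
    pull_rate: float = 0.1  # µm/s

    def __post_init__(self) -> None:
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.extension.shape != self.force.shape:
            raise ValueError("extension and force must have the same shape")
        if np.any(np.diff(self.extension) < 0):
            raise ValueError("extension must be monotone non-decreasing "
                             "within a pull segment")


@dataclass(frozen=True)
class DeviationSet:
    """Decomposition of a pull against the bare-DNA theory curve.

    first_deviation_bp : contour initially sequestered by the protein.
    final_deviation_bp : residual sequestered contour at the end of the pull
        (a lower bound when the curve never rejoins theory).
    intermediates : (loop_size_bp, rupture_force_pN) per rupture, in
        increasing-extension order.
    """

    first_deviation_bp: float
    final_deviation_bp: float
    intermediates: tuple[tuple[float, float], ...]
    rejoined: bool  # curve returned to within threshold of theory at the end

    @property
    def n_intermediates(self) -> int:
        return len(self.intermediates)


@dataclass(frozen=True)
class ClampResult:
    """Constant-force activity: velocity and whether the tether shortened."""

    velocity_bp_s: float
    mode: str  # "compaction" or "translocation"
    force: float  # pN


def _contour_deficit_bp(wlc: WLCParams, extension: float, force: float) -> float:
    """Sequestered contour (bp) from the extension deficit at ``force``.

    At force F a tether of contour L sits at extension L·g(F) with g the
    fractional extension, so a contour deficit ΔL shows up as an extension
    deficit ΔL·g(F); dividing the raw deficit by g(F) (≈0.94–1.0 at rupture
    forces) removes that bias before converting through the helical rise.
    """
    x_th = wlc_force_to_extension(wlc, max(force, 0.0))
    g = max(x_th / wlc.contour_um, 0.1)
    return (x_th - extension) * 1000.0 / (wlc.rise_per_bp * g)


def compare_to_theory(curve: FECurve, wlc: WLCParams,
                      dev_threshold: float = 0.5,
                      min_extent: float = 0.05,
                      rupture_prominence: float = 1.0,
                      min_loop_bp: float = 250.0) -> DeviationSet:
    """Score a pull against the bare-DNA WLC and size the loop intermediates.

    Parameters
    ----------
    dev_threshold : pN the measured force must exceed theory by, sustained
        over ``min_extent`` µm of extension, to count as a deviation.
    rupture_prominence : pN prominence for rupture peaks on the (lightly
        median-filtered) force channel.
    min_loop_bp : ruptures releasing less than this are discarded as noise
        (force noise near a rupture can split one peak in two; the default
        sits far below the kb-scale loops of interest but above the bp
        equivalent of the force noise).

    A theory-matching curve yields an empty set. If the curve still deviates
    at its last point, ``final_deviation_bp`` is the deficit there and is
    flagged as a lower bound via ``rejoined=False``.
    """
    f_max = float(np.max(curve.force))
    if f_max < 5.0:
        raise ValueError("curve must reach at least 5 pN")
    # deviation is measured in force space: measured force minus the theory
    # force at each measured extension
    x_cap = wlc_force_to_extension(wlc, wlc.force_cap)
    f_th = wlc_extension_to_force(wlc, np.clip(curve.extension, 0.0, x_cap))
    dev = curve.force - f_th
    above = dev > dev_threshold

    # sustained-deviation mask: a run must span >= min_extent of extension
    def _runs(mask):
        e = np.diff(mask.astype(np.int8))
        s = np.flatnonzero(e == 1) + 1
        t = np.flatnonzero(e == -1) + 1
        if mask[0]:
            s = np.r_[0, s]
        if mask[-1]:
            t = np.r_[t, mask.size]
        return list(zip(s, t))

    first_idx = None
    for i0, i1 in _runs(above) if above.any() else []:
        if curve.extension[i1 - 1] - curve.extension[i0] >= min_extent:
            first_idx = i0
            break
    if first_idx is None:
        return DeviationSet(0.0, 0.0, (), rejoined=True)

    # rupture peaks: local force maxima followed by a drop back toward theory
    width = max(3, min(11, (curve.force.size // 200) * 2 + 1))
    f_sm = medfilt(curve.force, kernel_size=width)
    peaks, _ = find_peaks(f_sm, prominence=rupture_prominence)
    peaks = peaks[(peaks > first_idx) | (peaks == first_idx)]
    peaks = [p for p in peaks if dev[p] > dev_threshold]

    intermediates = []
    prev_after = None
    first_bp = None
    for k, p in enumerate(peaks):
        # trough: minimum of the smoothed force before the next peak (or end)
        nxt = peaks[k + 1] if k + 1 < len(peaks) else curve.force.size
        if nxt - p < 2:
            continue
        trough = p + int(np.argmin(f_sm[p:nxt]))
        before = _contour_deficit_bp(wlc, float(curve.extension[p]),
                                     float(f_sm[p]))
        after = _contour_deficit_bp(wlc, float(curve.extension[trough]),
                                    float(f_sm[trough]))
        loop_bp = before - after
        if first_bp is None:
            first_bp = before
        if loop_bp < min_loop_bp:
            continue
        intermediates.append((float(loop_bp), float(f_sm[p])))
        prev_after = after
    if first_bp is None:
        # deviation without a resolvable rupture: size it at the force maximum
        imax = int(np.argmax(f_sm))
        first_bp = _contour_deficit_bp(wlc, float(curve.extension[imax]),
                                       float(f_sm[imax]))

    rejoined = dev[-1] <= dev_threshold
    if rejoined:
        final_bp = 0.0 if prev_after is None else float(prev_after)
        final_bp = max(0.0, min(final_bp, first_bp))
    else:
        final_bp = max(0.0, _contour_deficit_bp(
            wlc, float(curve.extension[-1]), float(f_sm[-1])))
        warnings.warn("curve never rejoins theory; final deviation is a "
                      "lower bound")
    return DeviationSet(first_deviation_bp=float(max(first_bp, 0.0)),
                        final_deviation_bp=float(final_bp),
                        intermediates=tuple(intermediates),
                        rejoined=bool(rejoined))


def clamp_velocity(extension_vs_time: Trace, wlc: WLCParams) -> ClampResult:
    """Activity velocity from a constant-force record.

    Linear fit of bead separation over the supplied (active) segment,
    converted to bp/s through the helical rise. Mode is ``compaction`` when
    the separation shrinks, ``translocation`` otherwise.
    """
    tr = extension_vs_time
    if tr.duration < 2.0:
        raise ValueError(f"segment too short ({tr.duration:.2f} s < 2 s)")
    slope_um_s = float(np.polyfit(tr.time, tr.extension, 1)[0])
    v_bp = abs(slope_um_s) * 1000.0 / wlc.rise_per_bp
    mode = "compaction" if slope_um_s < 0 else "translocation"
    force = float(np.mean(tr.force)) if isinstance(tr.force, np.ndarray) \
        else float(tr.force)
    return ClampResult(velocity_bp_s=v_bp, mode=mode, force=force)


def max_force(force_vs_time: Trace, window: float = 5.0,
              baseline_return: float = 1.0) -> list[float]:
    """Per-event maximum force (pN) during translocation.

    The force channel is smoothed with the standard window; events are
    delimited by the force returning to within ``baseline_return`` pN of the
    pre-event baseline (the median of the first window). A featureless trace
    yields a single value, its global maximum.
    """
    tr = force_vs_time
    if tr.time.size == 0:
        raise ValueError("empty trace")
    f = np.asarray(tr.force, dtype=float)
    if f.ndim == 0:
        raise ValueError("trace has no force channel")
    f_tr = Trace(time=tr.time, extension=f)
    f_sm = smooth(f_tr, min(window, max(f_tr.duration, 1e-9))).extension \
        if tr.time.size > 1 else f
    n0 = max(1, int(round(window * tr.sample_rate))) if tr.time.size > 1 else 1
    base = float(np.median(f_sm[:n0]))
    above = f_sm > base + baseline_return
    if not above.any():
        return [float(np.max(f_sm))]
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    return [float(np.max(f_sm[i0:i1])) for i0, i1 in zip(starts, ends)]


def percent_extension(load_extension: float, full_length: float) -> int:
    """Loading extension as an integer percent of the full contour length."""
    if full_length <= 0:
        raise ValueError("full_length must be positive")
    return int(round(100.0 * load_extension / full_length))
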