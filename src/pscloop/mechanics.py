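"""Polymer-mechanics primitives for double-stranded DNA under force and torque.

Units are fixed package-wide: extension in µm, force in pN, torque in pN·nm,
time in s, sequence length in bp. All conversions between those unit systems
live here so the downstream trace analyses never carry unit logic of their own.

The force–extension model is the extensible worm-like chain (Marko–Siggia
interpolation plus an enthalpic stretch term)::

    F * Lp / kT = 1/4 * (1 - x/L + F/K)^-2 - 1/4 + x/L - F/K

with persistence length ``Lp``, contour length ``L``, stretch modulus ``K``
and thermal energy ``kT``. Neither direction is closed-form; both are solved
by bracketed root finding on the strictly monotone residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KT_PN_NM",
    "LAMBDA_DNA_BP",
    "WLCParams",
    "TorqueModel",
    "CouplingModel",
    "HatCurveModel",
    "contour_length",
    "template_length_bp",
    "wlc_force_to_extension",
    "wlc_extension_to_force",
    "force_to_torque",
    "turns_rate_to_bp_rate",
    "hat_extension",
]

#: Thermal energy at 25 °C, pN·nm.
KT_PN_NM = 4.114

#: Length of the bacteriophage λ genome, bp (the optical-trap substrate).
LAMBDA_DNA_BP = 48_502


def contour_length(bp: float, rise_per_bp: float = 0.338) -> float:
    """B-form contour length in µm of ``bp`` base pairs.

    Parameters
    ----------
    bp : number of base pairs (>= 0).
    rise_per_bp : helical rise, nm/bp (default 0.338 for B-DNA).
    """
    if bp < 0:
        raise ValueError(f"bp must be non-negative, got {bp}")
    if rise_per_bp <= 0:
        raise ValueError(f"rise_per_bp must be positive, got {rise_per_bp}")
    return bp * rise_per_bp / 1000.0


def template_length_bp(center_bp: int, adapter_bp: int, n_adapters: int = 2) -> int:
    """Total length of a tweezer template: center fragment plus end adapters."""
    if center_bp < 0 or adapter_bp < 0 or n_adapters < 0:
        raise ValueError("lengths and adapter count must be non-negative")
    return center_bp + n_adapters * adapter_bp


@dataclass(frozen=True)
class WLCParams:
    """Extensible worm-like-chain elasticity of a dsDNA tether.

    Defaults are canonical values for λ-DNA in near-physiological buffer:
    persistence length 43.3 nm, stretch modulus 1205 pN, rise 0.338 nm/bp.
    """

    contour_length_bp: int = LAMBDA_DNA_BP
    rise_per_bp: float = 0.338  # nm/bp
    persistence_length: float = 43.3  # nm
    stretch_modulus: float = 1205.0  # pN
    kT: float = KT_PN_NM  # pN·nm
    force_cap: float = 200.0  # pN, upper bracket for inversion

    def __post_init__(self) -> None:
        for name in ("contour_length_bp", "rise_per_bp", "persistence_length",
                     "stretch_modulus", "kT", "force_cap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def contour_um(self) -> float:
        """Contour length in µm."""
        return contour_length(self.contour_length_bp, self.rise_per_bp)

    def with_contour_bp(self, bp: int) -> "WLCParams":
        """Same elastic constants on a different contour length."""
        return WLCParams(bp, self.rise_per_bp, self.persistence_length,
                         self.stretch_modulus, self.kT, self.force_cap)


@dataclass(frozen=True)
class TorqueModel:
    """Empirical force→torque conversion for a buckled, twisted tether.

    torque = coefficient × force^exponent (pN·nm), valid post-buckling where
    the torque is pinned by plectoneme growth.
    """

    coefficient: float = 12.7825  # pN·nm at 1 pN
    exponent: float = 0.63447

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise ValueError("coefficient must be positive")
        if not 0 < self.exponent <= 1:
            raise ValueError("exponent must be in (0, 1]")


@dataclass(frozen=True)
class CouplingModel:
    """Twist–translocation coupling: bp translocated per net turn added.

    ``coupling_efficiency`` is the fraction of translocated helical repeats
    converted into net turns on the tether's superhelical axis; at 1.0 every
    10.5 bp of motor travel adds exactly one turn.
    """

    bp_per_turn: float = 10.5
    coupling_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.bp_per_turn <= 0:
            raise ValueError("bp_per_turn must be positive")
        if not 0 < self.coupling_efficiency <= 1:
            raise ValueError("coupling_efficiency must be in (0, 1]")


@dataclass(frozen=True)
class HatCurveModel:
    """Piecewise-linear rotation–extension (hat) curve of a torsionally
    constrained tether.

    Extension is maximal (``apex_extension``) on the torsionally relaxed
    plateau between the two buckling transitions and decreases linearly on
    both plectonemic arms. ``slope_pos`` is the (negative-valued) µm/turn
    descent past the positive buckling turn; ``slope_neg`` the
    (positive-valued) slope below the negative buckling turn, i.e. extension
    still falls as turns grow more negative.
    """

    apex_turn: float = 0.0
    apex_extension: float = 4.0  # µm
    buckling_turn_pos: float = 15.0
    buckling_turn_neg: float = -15.0
    slope_pos: float = -0.045  # µm/turn, descent for turns > buckling_turn_pos
    slope_neg: float = 0.045   # µm/turn, ascent toward the apex from below

    def __post_init__(self) -> None:
        if not self.buckling_turn_neg < self.apex_turn < self.buckling_turn_pos:
            raise ValueError("need buckling_turn_neg < apex_turn < buckling_turn_pos")
        if self.slope_pos > 0 or self.slope_neg < 0:
            raise ValueError("slope_pos must be <= 0 and slope_neg >= 0 "
                             "(extension falls away from the apex)")
        if self.apex_extension < 0:
            raise ValueError("apex_extension must be non-negative")


def _wlc_root_w(phi):
    """Largest real root of w^3 + (phi - 3/4) w^2 - 1/4 = 0, vectorized.

    With w = 1 - u (u the entropic fractional extension) the Marko–Siggia
    interpolation ``phi = 1/(4 w^2) - 1/4 + 1 - w`` rearranges to this cubic;
    the physical branch (w -> 1 at phi = 0, w -> 0 as phi -> inf) is its
    largest real root. Solved by Cardano with the trigonometric three-root
    branch where the discriminant is negative.
    """
    phi = np.asarray(phi, dtype=float)
    b = phi - 0.75
    p = -b * b / 3.0
    q = 2.0 * b ** 3 / 27.0 - 0.25
    disc = (q / 2.0) ** 2 + (p / 3.0) ** 3
    w = np.empty_like(phi)

    one_real = disc >= 0
    if np.any(one_real):
        s = np.sqrt(disc[one_real])
        y = np.cbrt(-q[one_real] / 2.0 + s) + np.cbrt(-q[one_real] / 2.0 - s)
        w[one_real] = y - b[one_real] / 3.0
    three = ~one_real
    if np.any(three):
        pp, qq, bb = p[three], q[three], b[three]
        m = 2.0 * np.sqrt(-pp / 3.0)
        theta = np.arccos(np.clip(3.0 * qq / (pp * m), -1.0, 1.0)) / 3.0
        w[three] = m * np.cos(theta) - bb / 3.0  # k = 0 gives the largest root
    return w


def wlc_force_to_extension(params: WLCParams, force):
    """Extension (µm) of an extensible WLC at ``force`` (pN).

    Strictly increasing in force; 0 at zero force; approaches
    ``contour × (1 + F/K)`` in the enthalpic limit. Accepts a scalar or array.
    """
    force_arr = np.asarray(force, dtype=float)
    if np.any(force_arr < 0):
        raise ValueError("force must be non-negative")
    a = params.kT / params.persistence_length  # pN
    u = 1.0 - _wlc_root_w(force_arr / a)  # entropic fractional extension
    rel = np.where(force_arr == 0.0, 0.0,
                   u + force_arr / params.stretch_modulus)
    out = rel * params.contour_um
    return float(out) if np.isscalar(force) or force_arr.ndim == 0 else out


def wlc_extension_to_force(params: WLCParams, extension):
    """Force (pN) holding an extensible WLC at ``extension`` (µm).

    Inverse of :func:`wlc_force_to_extension` by bracketed root finding up to
    ``params.force_cap``; raises if the extension exceeds the enthalpic reach
    at the cap. Accepts a scalar or array.
    """
    ext_arr = np.atleast_1d(np.asarray(extension, dtype=float))
    if np.any(ext_arr < 0):
        raise ValueError("extension must be non-negative")
    x_max = wlc_force_to_extension(params, params.force_cap)
    if np.any(ext_arr > x_max):
        raise ValueError(
            f"extension exceeds the enthalpic cap {x_max:.4f} µm at "
            f"force_cap={params.force_cap} pN")
    L = params.contour_um
    a = params.kT / params.persistence_length
    K = params.stretch_modulus
    rel = ext_arr / L
    # safeguarded Newton on the closed-form forward curve; the bracket
    # [lo, hi] always contains the root since x(F) is strictly increasing
    lo = np.zeros_like(rel)
    hi = np.full_like(rel, params.force_cap)
    r = np.minimum(rel, 0.999)
    f = np.clip(a * (0.25 / (1.0 - r) ** 2 - 0.25 + rel), 1e-9,
                params.force_cap)
    for _ in range(80):
        w = _wlc_root_w(f / a)
        x_rel = (1.0 - w) + f / K
        fx = x_rel - rel
        lo = np.where(fx < 0, f, lo)
        hi = np.where(fx > 0, f, hi)
        # dx_rel/dF = (du/dphi)/a + 1/K with du/dphi = 2 w^3 / (1 + 2 w^3)
        deriv = (2.0 * w ** 3 / (1.0 + 2.0 * w ** 3)) / a + 1.0 / K
        step = f - fx / deriv
        inside = (step > lo) & (step < hi)
        f = np.where(inside, step, 0.5 * (lo + hi))
        if np.all(hi - lo < 1e-12) or np.all(np.abs(fx) < 1e-15):
            break
    f = np.where(ext_arr == 0.0, 0.0, f)
    if np.isscalar(extension) or np.asarray(extension).ndim == 0:
        return float(f[0])
    return f


def force_to_torque(model: TorqueModel, force):
    """Post-buckling torque (pN·nm) on the tether at ``force`` (pN)."""
    force_arr = np.asarray(force, dtype=float)
    if np.any(force_arr < 0):
        raise ValueError("force must be non-negative")
    out = model.coefficient * force_arr ** model.exponent
    return float(out) if np.isscalar(force) or force_arr.ndim == 0 else out


def turns_rate_to_bp_rate(turn_rate: float, model: CouplingModel) -> float:
    """Convert a twisting rate (turns/s) to motor translocation (bp/s).

    At coupling 1.0 each 10.5 bp step adds one turn, so bp/s = turns/s × 10.5;
    a motor that converts only a fraction ``c`` of its steps into turns must
    travel 1/c as far per observed turn, hence the division by the coupling
    efficiency.
    """
    if turn_rate < 0:
        raise ValueError("turn_rate must be non-negative")
    return turn_rate * model.bp_per_turn / model.coupling_efficiency


def hat_extension(model: HatCurveModel, turns):
    """Tether extension (µm) at applied magnet ``turns``.

    Flat at ``apex_extension`` across the torsion-absorbing plateau, linear
    descent on the plectonemic arms, clamped at zero. Accepts scalar or array.
    """
    t = np.asarray(turns, dtype=float)
    ext = np.full(t.shape, model.apex_extension)
    pos = t > model.buckling_turn_pos
    neg = t < model.buckling_turn_neg
    ext = np.where(pos, model.apex_extension
                   + model.slope_pos * (t - model.buckling_turn_pos), ext)
    ext = np.where(neg, model.apex_extension
                   + model.slope_neg * (t - model.buckling_turn_neg), ext)
    ext = np.clip(ext, 0.0, None)
    return float(ext) if np.isscalar(turns) or t.ndim == 0 else ext
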