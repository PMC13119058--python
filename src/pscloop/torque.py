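"""Torque plots, stall-torque extrapolation, and force–velocity fits.

Mean extension rates measured at several clamp forces are plotted against
the post-buckling torque (empirical power-law conversion) and fit by
ordinary least squares. Because the rate falls with torque, the line crosses
zero rate at the stall torque; its rate at zero torque is the unresisted
("no torque") velocity. Both intercepts are reported explicitly since plots
differ on which axis carries the rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import curve_fit

from .mechanics import CouplingModel, TorqueModel, force_to_torque

__all__ = ["TorquePoint", "LineFit", "FVFit", "build_torque_plot",
           "fit_stall", "convert_plot_units", "fit_force_velocity"]


@dataclass(frozen=True)
class TorquePoint:
    """Mean activity rate at one clamp force, with its torque coordinate."""

    force: float  # pN
    torque: float  # pN·nm
    mean_rate: float  # µm/s (or bp/s after conversion)
    ci95: tuple[float, float]
    n: int


@dataclass(frozen=True)
class LineFit:
    """OLS rate-vs-torque line and its two named intercepts."""

    slope: float  # rate per pN·nm
    intercept_rate_at_zero_torque: float  # "no torque" velocity
    intercept_torque_at_zero_rate: float | None  # stall torque, None if slope >= 0
    r2: float
    _ols_result: object = None

    def ci_band(self, torques) -> tuple[np.ndarray, np.ndarray]:
        """95% confidence band of the mean fitted rate at ``torques``."""
        if self._ols_result is None:
            raise ValueError("fit carries no OLS result")
        X = sm.add_constant(np.asarray(torques, dtype=float))
        pred = self._ols_result.get_prediction(X).conf_int(alpha=0.05)
        return pred[:, 0], pred[:, 1]


@dataclass(frozen=True)
class FVFit:
    """Nonlinear force–velocity fit.

    model "rectangular_hyperbola": v = Vmax·F/(K+F) (rate rises with force,
    as for linear translocation); "single_exp_decay": v = v0·exp(−F/tau)+c
    (rate falls with force, as for twist-coupled loop extrusion).
    """

    model: str
    params: dict
    r2: float
    converged: bool = True


def build_torque_plot(per_force_rates, model: TorqueModel = TorqueModel()
                      ) -> list[TorquePoint]:
    """Mean rate ± 95% CI per clamp force, with torque coordinates.

    ``per_force_rates`` is an iterable of (force_pN, rates) pairs.
    """
    items = [(float(f), np.asarray(r, dtype=float)) for f, r in per_force_rates]
    if len({f for f, _ in items}) < 2:
        raise ValueError("need rates at >= 2 distinct forces")
    points = []
    for f, rates in sorted(items):
        mean = float(rates.mean())
        n = rates.size
        if n > 1 and rates.std(ddof=1) > 0:
            half = stats.t.ppf(0.975, n - 1) * rates.std(ddof=1) / np.sqrt(n)
        else:
            half = 0.0
        points.append(TorquePoint(force=f, torque=force_to_torque(model, f),
                                  mean_rate=mean, ci95=(mean - half, mean + half),
                                  n=n))
    return points


def fit_stall(points) -> LineFit:
    """OLS of mean rate against torque; extrapolate the stall torque.

    The stall torque is the torque-axis crossing of the line; extrapolating
    it assumes the rate–torque relation stays linear beyond the measured
    range, which is a simplification. Undefined (None, with a warning) when
    the fitted slope is non-negative.
    """
    points = list(points)
    if len(points) < 3:
        raise ValueError("need >= 3 torque points")
    rates = np.array([p.mean_rate for p in points])
    torques = np.array([p.torque for p in points])
    if np.ptp(rates) == 0:
        warnings.warn("rates identical at all forces; stall torque undefined")
        return LineFit(0.0, float(rates[0]), None, 0.0, None)
    X = sm.add_constant(torques)
    res = sm.OLS(rates, X).fit()
    intercept, slope = float(res.params[0]), float(res.params[1])
    if slope >= 0:
        warnings.warn("non-negative slope: no stall torque on this plot")
        stall = None
    else:
        stall = -intercept / slope
    return LineFit(slope=slope, intercept_rate_at_zero_torque=intercept,
                   intercept_torque_at_zero_rate=stall,
                   r2=float(res.rsquared), _ols_result=res)


def convert_plot_units(points, hat_slope: float,
                       coupling: CouplingModel = CouplingModel()
                       ) -> list[TorquePoint]:
    """Convert torque-plot rates from µm/s to bp/s.

    The buckling-arm slope of each tether's hat curve (µm/turn) converts
    extension change to turns; 10.5 bp/turn and the coupling efficiency then
    convert turns to motor travel: bp/s = (µm/s / |hat_slope|) × bp_per_turn
    / coupling_efficiency.
    """
    if hat_slope == 0:
        raise ValueError("hat slope must be non-zero")
    scale = (1.0 / abs(hat_slope)) * coupling.bp_per_turn / coupling.coupling_efficiency
    return [TorquePoint(force=p.force, torque=p.torque,
                        mean_rate=p.mean_rate * scale,
                        ci95=(p.ci95[0] * scale, p.ci95[1] * scale), n=p.n)
            for p in points]


def _hyperbola(f, vmax, k):
    return vmax * f / (k + f)


def _exp_decay(f, v0, tau, c):
    return v0 * np.exp(-f / tau) + c


def fit_force_velocity(data, model: str = "rectangular_hyperbola") -> FVFit:
    """Nonlinear least-squares force–velocity fit.

    ``data`` is an iterable of (force_pN, velocity) pairs; >= 4 points.
    A poor r² (< 0.5) or a degenerate parameter flags the fit rather than
    raising, so model mismatch can be inspected.
    """
    arr = np.asarray([(float(f), float(v)) for f, v in data])
    if arr.shape[0] < 4:
        raise ValueError("need >= 4 points")
    f, v = arr[:, 0], arr[:, 1]
    vspan = float(np.ptp(v))
    try:
        if model == "rectangular_hyperbola":
            popt, _ = curve_fit(_hyperbola, f, v,
                                p0=[max(v.max(), 1e-6), max(np.median(f), 1e-3)],
                                bounds=([0, 0], [np.inf, np.inf]), maxfev=20000)
            params = {"vmax": float(popt[0]), "k": float(popt[1])}
            fitted = _hyperbola(f, *popt)
        elif model == "single_exp_decay":
            popt, _ = curve_fit(_exp_decay, f, v,
                                p0=[max(vspan, 1e-6), max(np.median(f), 1e-3),
                                    float(v.min())], maxfev=20000)
            params = {"v0": float(popt[0]), "tau_f": float(popt[1]),
                      "c": float(popt[2])}
            fitted = _exp_decay(f, *popt)
        else:
            raise ValueError("model must be 'rectangular_hyperbola' or "
                             "'single_exp_decay'")
    except RuntimeError as exc:
        resid = None
        raise RuntimeError(f"force-velocity fit did not converge: {exc}")
    ss_tot = float(((v - v.mean()) ** 2).sum())
    r2 = 1.0 - float(((v - fitted) ** 2).sum()) / ss_tot if ss_tot > 0 else 0.0
    converged = True
    if r2 < 0.5:
        warnings.warn(f"poor {model} fit (r2={r2:.2f}); likely model mismatch")
        converged = False
    if model == "rectangular_hyperbola" and params["k"] < 1e-6:
        warnings.warn("hyperbola degenerated (K -> 0); data look constant")
        converged = False
    return FVFit(model=model, params=params, r2=r2, converged=converged)
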