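"""Inverse estimation of CN and the MUSS C-factor from seasonal totals.

Two sequential one-dimensional fits, mirroring the regulatory calibration
workflow:

1. The curve number is the smallest integer in [30, 100] whose simulated
   seasonal runoff total reaches *at least* the measured total ("at least"
   because the fitted CN must not under-predict exposure).  The seasonal
   total is monotone in CN, so a grid scan is exact; a continuous root is
   also returned for diagnostics.
2. With that CN fixed, the C-factor follows in closed form from the exact
   linearity of MUSS in C: ``C = measured / simulated_at_C=1`` — the fit
   reproduces the measured eroded mass to machine precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .cn_hydrology import CN_MAX, CN_MIN, WeatherSeries
from .muss import FieldPlot
from .season import simulate_season

__all__ = [
    "CalibrationError",
    "CalibrationResult",
    "calibrate_cn",
    "calibrate_c_factor",
    "calibrate_plot",
]

logger = logging.getLogger(__name__)


class CalibrationError(RuntimeError):
    """The measured target cannot be reached anywhere in the parameter domain."""


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted (CN, C) pair with the totals they reproduce."""

    fitted_cn: int
    fitted_cn_continuous: float
    fitted_c: float
    simulated_runoff_mm: float
    simulated_erosion_kg_ha: float
    target_runoff_mm: float
    target_erosion_kg_ha: float


def _total_runoff(weather: WeatherSeries, plot: FieldPlot, cn: float) -> float:
    return simulate_season(weather, plot.with_(curve_number=cn)).total_runoff_mm


def calibrate_cn(
    weather: WeatherSeries,
    plot: FieldPlot,
    measured_runoff_total: float,
    return_continuous: bool = False,
) -> int | tuple[int, float]:
    """Smallest integer CN whose seasonal runoff total >= the measured total.

    Parameters
    ----------
    measured_runoff_total
        Seasonal runoff total, mm.  Zero returns the lower grid bound (with
        a warning): any sufficiently low CN produces no runoff.
    return_continuous
        Also return the continuous CN at which the simulated total equals
        the target exactly (diagnostic; NaN if the target is zero).

    Raises
    ------
    CalibrationError
        If even CN = 100 (total runoff = total rainfall) cannot reach the
        target.
    """
    target = float(measured_runoff_total)
    if target < 0:
        raise ValueError("measured runoff total must be >= 0")
    grid = np.arange(int(CN_MIN), int(CN_MAX) + 1)
    totals = np.array([_total_runoff(weather, plot, cn) for cn in grid])
    if target == 0.0:
        logger.warning("zero runoff target: returning lower CN bound %d", grid[0])
        return (int(grid[0]), float("nan")) if return_continuous else int(grid[0])
    # tiny relative slack so that a target equal to a simulated total up to
    # float summation order still selects that CN
    eps = 1e-9 * target
    if totals[-1] < target - eps:
        raise CalibrationError(
            f"measured runoff {target} mm exceeds the {totals[-1]:.3f} mm "
            "attainable at CN=100 (total rainfall)"
        )
    idx = int(np.searchsorted(totals, target - eps, side="left"))
    fitted = int(grid[idx])
    if not return_continuous:
        return fitted
    if totals[0] >= target:
        continuous = float(grid[0])
    else:
        continuous = float(
            brentq(
                lambda cn: _total_runoff(weather, plot, cn) - target,
                grid[idx - 1],
                grid[idx],
                xtol=1e-6,
            )
        )
    return fitted, continuous


def calibrate_c_factor(
    weather: WeatherSeries, plot: FieldPlot, measured_erosion_total: float
) -> float:
    """C-factor that reproduces the measured seasonal eroded mass exactly.

    Closed form by linearity: simulate once at C = 1 and scale.  The plot's
    CN is taken as given (calibrate CN first).

    Raises
    ------
    CalibrationError
        If no simulated runoff event erodes anything at C = 1 while the
        measured mass is nonzero.
    """
    target = float(measured_erosion_total)
    if target < 0:
        raise ValueError("measured erosion total must be >= 0")
    if target == 0.0:
        return 0.0
    base = simulate_season(weather, plot.with_(c_factor=1.0)).total_erosion_kg_ha
    if base <= 0.0:
        raise CalibrationError(
            "no erosive events simulated at this CN; C-factor not identifiable"
        )
    return target / base


def calibrate_plot(
    weather: WeatherSeries,
    plot: FieldPlot,
    measured_runoff_total: float,
    measured_erosion_total: float,
) -> CalibrationResult:
    """Sequential CN-then-C calibration against seasonal totals."""
    fitted_cn, continuous = calibrate_cn(
        weather, plot, measured_runoff_total, return_continuous=True
    )
    plot_cn = plot.with_(curve_number=fitted_cn)
    fitted_c = calibrate_c_factor(weather, plot_cn, measured_erosion_total)
    final = simulate_season(plot=plot_cn.with_(c_factor=fitted_c), weather=weather)
    return CalibrationResult(
        fitted_cn=fitted_cn,
        fitted_cn_continuous=continuous,
        fitted_c=fitted_c,
        simulated_runoff_mm=final.total_runoff_mm,
        simulated_erosion_kg_ha=final.total_erosion_kg_ha,
        target_runoff_mm=float(measured_runoff_total),
        target_erosion_kg_ha=float(measured_erosion_total),
    )
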