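"""MUSS event soil-loss equation and the 2-mm daily rainfall segmentation.

MUSS is the small-watershed variant of the Modified Universal Soil Loss
Equation used by field-scale pesticide fate models.  Event soil loss is

    Xe = 0.79 (Vr * qp)^0.65 * A^0.009 * K * LS * C * P      [t/event]

with Vr the daily runoff volume (mm), qp the peak storm runoff rate (mm/h),
A the field area (ha) and K, LS, C, P the usual (M)USLE factors.  Xe is
exactly linear in each of K, LS, C and P — the property that later makes the
C-factor calibration a one-step closed form.

The daily rainfall is treated as a sequence of hourly 2-mm segments
(``n = min(24, ceil(P / 2))``); the peak runoff rate is approximated by the
uniform rate ``qp = Vr / n`` over those segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "FieldPlot",
    "ErosionEvent",
    "n_segments",
    "peak_runoff_rate",
    "event_soil_loss",
    "soil_loss_per_area",
]

#: kg per tonne; conversions between t/event and kg/ha are always explicit.
KG_PER_TONNE = 1000.0


@dataclass(frozen=True)
class FieldPlot:
    """Plot geometry, curve number and (M)USLE factors.

    ``c_factor`` is deliberately not clamped to <= 1: calibrated values for
    bare-ridged maize plots can far exceed the handbook range because the
    factor absorbs everything the simplified event model leaves out.
    """

    area_ha: float
    curve_number: float
    k_factor: float
    ls_factor: float
    c_factor: float = 1.0
    p_factor: float = 1.0
    slope_pct: float | None = None
    ia_ratio: float = 0.2

    def __post_init__(self) -> None:
        if self.area_ha <= 0:
            raise ValueError(f"area must be > 0 ha, got {self.area_ha}")
        for name in ("k_factor", "ls_factor", "c_factor", "p_factor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.curve_number <= 100.0:
            raise ValueError(f"curve number out of (0, 100]: {self.curve_number}")

    def with_(self, **changes) -> "FieldPlot":
        """Copy with selected fields replaced (e.g. ``plot.with_(c_factor=1)``)."""
        return replace(self, **changes)


@dataclass(frozen=True)
class ErosionEvent:
    """One computed erosion event: runoff volume, peak rate and soil loss."""

    runoff_volume_mm: float
    peak_rate_mm_h: float
    soil_loss_t: float
    soil_loss_kg_ha: float


def n_segments(precipitation: float) -> int:
    """Number of hourly 2-mm rainfall segments for a day with P mm of rain.

    ``n = min(24, ceil(P / 2))``; a 19.9 mm day has n = 10, and anything
    beyond 48 mm saturates the 24 hours of the day.
    """
    p = float(precipitation)
    if p <= 0:
        raise ValueError(f"precipitation must be > 0 to segment, got {p}")
    return min(24, math.ceil(p / 2.0))


def peak_runoff_rate(runoff_volume: float, precipitation: float) -> float:
    """Peak storm runoff rate qp (mm/h) under the uniform 2-mm-segment rule.

    qp = Vr / n_segments(P); the runoff volume spread evenly over the hours
    the rain occupies.
    """
    vr = float(runoff_volume)
    if vr < 0:
        raise ValueError(f"runoff volume must be >= 0, got {vr}")
    return vr / n_segments(precipitation)


def event_soil_loss(vr: float, qp: float, plot: FieldPlot) -> float:
    """MUSS event soil loss Xe in tonnes for the whole plot.

    Zero runoff gives zero loss; otherwise the runoff "energy" term
    (Vr*qp)^0.65 is scaled by the area and factor product.
    """
    vr = float(vr)
    qp = float(qp)
    if vr < 0 or qp < 0:
        raise ValueError("runoff volume and peak rate must be >= 0")
    if vr == 0.0 or qp == 0.0:
        return 0.0
    return (
        0.79
        * (vr * qp) ** 0.65
        * plot.area_ha**0.009
        * plot.k_factor
        * plot.ls_factor
        * plot.c_factor
        * plot.p_factor
    )


def soil_loss_per_area(soil_loss_t: float, area_ha: float) -> float:
    """Convert a whole-plot loss (t) to a per-area loss (kg/ha)."""
    if area_ha <= 0:
        raise ValueError("area must be > 0 ha")
    return soil_loss_t / area_ha * KG_PER_TONNE
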