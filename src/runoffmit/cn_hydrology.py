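"""SCS curve-number rainfall–runoff model and its event-wise inversion.

The USDA-SCS curve number CN (dimensionless, ``30 < CN <= 100``) relates a
daily rainfall depth P (mm) to a direct-runoff depth Q (mm) through the
potential maximum retention

    S = 25400 / CN - 254        [mm]

and the initial abstraction ``Ia = ia_ratio * S`` (the share of rain that
infiltrates before any runoff starts; the standard ratio is 0.2):

    Q = (P - Ia)^2 / (P - Ia + S)   for P > Ia,  else 0.

Given a measured (P, Q) pair with Q > 0 the relation inverts in closed form,
which is how a curve number is back-calculated from each observed runoff
event of a field trial.  Per-event CNs are then combined into a single
seasonal value by precipitation-weighted averaging.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CN_MIN",
    "CN_MAX",
    "NotInvertibleError",
    "RainfallEvent",
    "WeatherSeries",
    "retention_from_cn",
    "runoff_depth",
    "invert_cn",
    "weighted_mean_cn",
    "events_to_mean_cn",
]

logger = logging.getLogger(__name__)

#: Curve numbers reported for real fields live in (30, 100]; 30 is also the
#: lower bound of the calibration grid.
CN_MIN = 30.0
CN_MAX = 100.0


class NotInvertibleError(ValueError):
    """A curve number cannot be back-calculated from the event (Q = 0)."""


@dataclass(frozen=True)
class RainfallEvent:
    """One observed runoff event of a field trial.

    Parameters
    ----------
    precipitation
        Collected rainfall depth for the event, mm (>= 0).
    runoff
        Measured runoff depth, mm; ``None`` if not measured.
    erosion
        Measured eroded mass, kg/ha; ``None`` if not measured.
    excluded
        Quality-control flag.  Events are flagged when the measurement is
        known to be invalid (e.g. an overflown collection reservoir) and
        then never enter any average.
    date
        Calendar day, optional.
    """

    precipitation: float
    runoff: float | None = None
    erosion: float | None = None
    excluded: bool = False
    date: pd.Timestamp | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.precipitation < 0:
            raise ValueError(f"negative precipitation: {self.precipitation}")
        if self.runoff is not None:
            if self.runoff < 0:
                raise ValueError(f"negative runoff: {self.runoff}")
            if self.runoff > self.precipitation + 1e-9:
                raise ValueError(
                    f"runoff {self.runoff} mm exceeds precipitation "
                    f"{self.precipitation} mm"
                )
        if self.erosion is not None and self.erosion < 0:
            raise ValueError(f"negative erosion: {self.erosion}")


class WeatherSeries:
    """Ordered daily precipitation record driving the season simulator.

    Wraps a two-column table (``date``, ``precip_mm``) and validates that
    dates strictly increase and depths are non-negative.
    """

    def __init__(self, dates: Iterable, precip_mm: Iterable[float]) -> None:
        dates = pd.DatetimeIndex(pd.to_datetime(list(dates)))
        precip = np.asarray(list(precip_mm), dtype=float)
        if len(dates) != len(precip):
            raise ValueError("dates and precipitation differ in length")
        if len(dates) == 0:
            raise ValueError("empty weather series")
        if not dates.is_monotonic_increasing or dates.has_duplicates:
            raise ValueError("weather dates must be strictly increasing")
        if np.any(precip < 0) or not np.all(np.isfinite(precip)):
            raise ValueError("precipitation depths must be finite and >= 0")
        self.dates = dates
        self.precip_mm = precip

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "WeatherSeries":
        missing = {"date", "precip_mm"} - set(frame.columns)
        if missing:
            raise ValueError(f"weather table missing columns: {sorted(missing)}")
        return cls(frame["date"], frame["precip_mm"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, "precip_mm": self.precip_mm})

    def __len__(self) -> int:
        return len(self.precip_mm)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"WeatherSeries({len(self)} days, "
            f"{self.precip_mm.sum():.1f} mm total)"
        )


def _check_cn(cn: float) -> float:
    cn = float(cn)
    if not 0.0 < cn <= CN_MAX:
        raise ValueError(f"curve number must be in (0, 100], got {cn}")
    return cn


def retention_from_cn(cn: float) -> float:
    """Potential maximum retention S (mm) for a curve number.

    ``S = 25400/CN - 254`` (metric form).  S is strictly decreasing in CN
    and vanishes at CN = 100 (a fully impervious surface).
    """
    cn = _check_cn(cn)
    return 25400.0 / cn - 254.0


def runoff_depth(
    precipitation: float | np.ndarray,
    cn: float,
    ia_ratio: float = 0.2,
) -> float | np.ndarray:
    """Direct runoff depth Q (mm) for daily rainfall P under a given CN.

    Vectorised over ``precipitation``.  Q is zero until P exceeds the
    initial abstraction ``Ia = ia_ratio * S`` and approaches P - Ia - S for
    large storms.
    """
    p = np.asarray(precipitation, dtype=float)
    if np.any(p < 0):
        raise ValueError("precipitation must be >= 0")
    if not 0.0 <= ia_ratio < 1.0:
        raise ValueError(f"ia_ratio must be in [0, 1), got {ia_ratio}")
    s = retention_from_cn(cn)
    ia = ia_ratio * s
    excess = p - ia
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(excess > 0, excess**2 / np.where(excess > 0, excess + s, 1.0), 0.0)
    if np.isscalar(precipitation) or np.ndim(precipitation) == 0:
        return float(q)
    return q


def invert_cn(precipitation: float, runoff: float, ia_ratio: float = 0.2) -> float:
    """Back-calculate the curve number from one (P, Q) event.

    Solves the SCS relation for the retention S.  For the standard
    ``ia_ratio = 0.2`` this reduces to the familiar closed form
    ``S = 5 (P + 2Q - sqrt(4 Q^2 + 5 P Q))``; the general quadratic in S is
    solved here so that any abstraction ratio round-trips exactly.

    Raises
    ------
    NotInvertibleError
        If ``runoff == 0`` — any CN low enough gives zero runoff, so the
        event carries no CN information and is excluded from averages.
    ValueError
        If runoff exceeds precipitation or inputs are out of domain.
    """
    p = float(precipitation)
    q = float(runoff)
    if p <= 0:
        raise ValueError(f"precipitation must be > 0, got {p}")
    if q < 0:
        raise ValueError(f"runoff must be >= 0, got {q}")
    if q == 0:
        raise NotInvertibleError(
            f"event with P={p} mm produced no runoff; CN not identifiable"
        )
    if q > p + 1e-12:
        raise ValueError(f"runoff {q} mm exceeds precipitation {p} mm")
    if not 0.0 < ia_ratio < 1.0:
        # ia_ratio = 0 makes the quadratic degenerate; handle linearly.
        if ia_ratio == 0.0:
            s = (p - q) * p / q
            return 25400.0 / (s + 254.0)
        raise ValueError(f"ia_ratio must be in [0, 1), got {ia_ratio}")
    a = ia_ratio
    # (P - aS)^2 = Q (P - aS + S)  =>  a^2 S^2 - (2aP + Q(1-a)) S + P^2 - PQ = 0
    b = 2.0 * a * p + q * (1.0 - a)
    c = p * p - p * q
    disc = b * b - 4.0 * a * a * c
    if disc < 0:  # numerically impossible for valid (P, Q); guard anyway
        disc = 0.0
    s = (b - math.sqrt(disc)) / (2.0 * a * a)
    s = max(s, 0.0)
    return 25400.0 / (s + 254.0)


def weighted_mean_cn(events: Sequence[tuple[float, float]]) -> float:
    """Precipitation-weighted mean of per-event curve numbers.

    ``events`` is a sequence of ``(precipitation_mm, cn)`` pairs; the mean is
    ``sum(P_i * CN_i) / sum(P_i)`` so that large storms dominate the seasonal
    value.  The result always lies between the smallest and largest event CN.
    """
    if len(events) == 0:
        raise ValueError("no events to average")
    p = np.asarray([e[0] for e in events], dtype=float)
    cn = np.asarray([e[1] for e in events], dtype=float)
    if np.any(p <= 0):
        raise ValueError("event precipitation weights must be > 0")
    return float(np.average(cn, weights=p))


def events_to_mean_cn(
    events: Iterable[RainfallEvent], ia_ratio: float = 0.2
) -> tuple[float, pd.DataFrame]:
    """Event-wise CN inversion and precipitation-weighted averaging.

    QC-flagged events and events with zero measured runoff are excluded
    (and logged); the remaining events are inverted individually.

    Returns
    -------
    (mean_cn, table)
        The weighted mean CN and a per-event table with columns
        ``precip_mm, runoff_mm, cn, used`` (``cn`` is NaN for unused rows).
    """
    rows = []
    usable: list[tuple[float, float]] = []
    for i, ev in enumerate(events):
        cn_val = np.nan
        used = False
        if ev.excluded:
            logger.info("event %d excluded by QC flag", i)
        elif ev.runoff is None:
            logger.info("event %d has no runoff measurement; skipped", i)
        else:
            try:
                cn_val = invert_cn(ev.precipitation, ev.runoff, ia_ratio)
                usable.append((ev.precipitation, cn_val))
                used = True
            except NotInvertibleError:
                logger.info(
                    "event %d (P=%.2f mm) produced no runoff; "
                    "excluded from CN averaging",
                    i,
                    ev.precipitation,
                )
        rows.append(
            {
                "date": ev.date,
                "precip_mm": ev.precipitation,
                "runoff_mm": ev.runoff,
                "cn": cn_val,
                "used": used,
            }
        )
    if not usable:
        raise ValueError("no invertible, non-excluded events")
    table = pd.DataFrame(rows)
    return weighted_mean_cn(usable), table
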