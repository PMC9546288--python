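"""Synthetic weather and mitigation-trial generator with known ground truth.

Emulates the structure of a small-plot mitigation trial: all treatments of
one trial share a single daily rainfall series; a treatment differs from
the control only through its true curve number (runoff lever) and true
MUSS C-factor (erosion lever).  Event tables are produced by running the
season simulator at the true parameters, so every downstream stage —
event-wise CN inversion, seasonal calibration, treatment comparison — can
be tested for exact parameter recovery.

Rainfall is a wet-day Bernoulli process with gamma-distributed depths, the
simplest generator reproducing the episodic 5–20+ mm storms such trials
see.  Defaults: a 180-day season, wet-day probability 0.15, gamma(shape
0.8, scale 12 mm).  Optional multiplicative log-normal noise perturbs the
*measured* runoff/erosion (volumetric sampling error); it is off by
default so recovery tests are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cn_hydrology import WeatherSeries
from .muss import FieldPlot
from .season import SeasonResult, simulate_season

__all__ = ["Treatment", "TrialDesign", "TrialData", "generate_weather", "generate_trial"]


@dataclass(frozen=True)
class Treatment:
    """A trial arm: label plus the true (CN, C) it imposes on the shared plot."""

    label: str
    true_cn: float
    true_c: float


@dataclass(frozen=True)
class TrialDesign:
    """Design of one synthetic trial (shared weather, per-arm parameters)."""

    treatments: tuple[Treatment, ...]
    n_days: int = 180
    wet_day_prob: float = 0.15
    gamma_shape: float = 0.8
    gamma_scale: float = 12.0  # mm
    noise_rel: float = 0.0  # relative SD of multiplicative measurement noise
    seed: int = 0
    start_date: str = "2018-04-01"
    control_label: str = "CvT"
    plot: FieldPlot = field(
        default_factory=lambda: FieldPlot(
            area_ha=0.0072, curve_number=80.0, k_factor=0.12, ls_factor=1.05
        )
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.wet_day_prob <= 1.0:
            raise ValueError("wet-day probability must be in [0, 1]")
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise ValueError("gamma parameters must be > 0")
        if self.noise_rel < 0:
            raise ValueError("noise must be >= 0")
        if self.n_days < 1:
            raise ValueError("need at least one day")


@dataclass(frozen=True)
class TrialData:
    """Generated trial: shared weather, per-arm event tables and ground truth."""

    design: TrialDesign
    weather: WeatherSeries
    seasons: dict[str, SeasonResult]  # noiseless simulated seasons per arm
    events: dict[str, pd.DataFrame]  # measured event tables per arm
    totals: pd.DataFrame  # label, runoff_mm, erosion_kg_ha (measured)
    truth: dict[str, tuple[float, float]]  # label -> (true_cn, true_c)


def generate_weather(design: TrialDesign) -> WeatherSeries:
    """Daily rainfall for one season; reproducible for a fixed seed."""
    rng = np.random.default_rng(design.seed)
    wet = rng.random(design.n_days) < design.wet_day_prob
    depths = np.zeros(design.n_days)
    n_wet = int(wet.sum())
    if n_wet:
        depths[wet] = rng.gamma(design.gamma_shape, design.gamma_scale, size=n_wet)
    dates = pd.date_range(design.start_date, periods=design.n_days, freq="D")
    return WeatherSeries(dates, depths)


def generate_trial(design: TrialDesign) -> TrialData:
    """Simulate every treatment arm on the shared weather.

    Event tables list the runoff days (collected rain, runoff depth, eroded
    mass, ``excluded = 0``); measured totals get the optional multiplicative
    log-normal noise.  The true parameters travel with the result.
    """
    if len(design.treatments) < 2:
        raise ValueError("a trial needs a control and at least one treatment")
    labels = [t.label for t in design.treatments]
    if design.control_label not in labels:
        raise ValueError(
            f"control arm {design.control_label!r} missing from {labels}"
        )
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate treatment labels")

    weather = generate_weather(design)
    # Separate stream for the noise so the weather is identical with/without it.
    noise_rng = np.random.default_rng(design.seed + 1)

    seasons: dict[str, SeasonResult] = {}
    events: dict[str, pd.DataFrame] = {}
    truth: dict[str, tuple[float, float]] = {}
    totals_rows = []
    for arm in design.treatments:
        plot = design.plot.with_(curve_number=arm.true_cn, c_factor=arm.true_c)
        season = simulate_season(weather, plot)
        daily = season.daily
        ev = daily[daily["runoff_mm"] > 0].copy()
        ev = ev.rename(columns={"soil_loss_kg_ha": "erosion_kg_ha"})
        if design.noise_rel > 0:
            sigma = design.noise_rel
            ev["runoff_mm"] = ev["runoff_mm"] * noise_rng.lognormal(
                0.0, sigma, size=len(ev)
            )
            ev["erosion_kg_ha"] = ev["erosion_kg_ha"] * noise_rng.lognormal(
                0.0, sigma, size=len(ev)
            )
            # Measured runoff cannot exceed the collected rain.
            ev["runoff_mm"] = np.minimum(ev["runoff_mm"], ev["precip_mm"])
        ev["excluded"] = 0
        seasons[arm.label] = season
        events[arm.label] = ev.reset_index(drop=True)
        truth[arm.label] = (arm.true_cn, arm.true_c)
        totals_rows.append(
            {
                "label": arm.label,
                "runoff_mm": float(ev["runoff_mm"].sum()),
                "erosion_kg_ha": float(ev["erosion_kg_ha"].sum()),
            }
        )
    return TrialData(
        design=design,
        weather=weather,
        seasons=seasons,
        events=events,
        totals=pd.DataFrame(totals_rows),
        truth=truth,
    )
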