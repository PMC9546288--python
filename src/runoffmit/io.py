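"""CSV readers/writers, packaged fixture tables and config parsing.

All interfaces are plain CSV with required headers (ISO dates, depths in
mm, masses in kg/ha):

* weather:  ``date, precip_mm``
* events:   ``date, precip_mm, runoff_mm, erosion_kg_ha, excluded``
* exposure: ``date, rflx_mg_m2_d, runf_L_m2_d, infl_L_m2_d, precip_mm``

A thin optional reader maps whitespace-delimited field-model daily output
columns (PRCP, RUNF, RFLX, INFL) by name; bit-exact compatibility with any
particular model's file dialect is not promised.

The packaged fixture tables carry the measured seasonal totals, event-wise
curve numbers and whole-season (CN, C) fits of the three Belgian maize
mitigation trials the package was built around.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .cn_hydrology import RainfallEvent, WeatherSeries
from .muss import FieldPlot
from .pec import ExposureDay

__all__ = [
    "read_weather",
    "write_weather",
    "read_events",
    "write_events",
    "read_exposure",
    "read_przm_daily",
    "read_plot_config",
    "write_report",
    "load_trial_totals",
    "load_season_fits",
    "load_plot_factors",
]

EVENT_COLUMNS = ["date", "precip_mm", "runoff_mm", "erosion_kg_ha", "excluded"]
EXPOSURE_COLUMNS = ["date", "rflx_mg_m2_d", "runf_L_m2_d", "infl_L_m2_d", "precip_mm"]


def _read_csv(path, required: Iterable[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, comment="#")
    missing = set(required) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame


def _numeric(frame: pd.DataFrame, path, columns: Iterable[str]) -> pd.DataFrame:
    for col in columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            # +2: one for the header line, one for 0- vs 1-based rows
            lines = [str(i + 2) for i in frame.index[bad]]
            raise ValueError(
                f"{path}: non-numeric values in column {col!r} "
                f"(lines {', '.join(lines)})"
            )
        frame[col] = converted
    return frame


def read_weather(path) -> WeatherSeries:
    """Read a daily weather CSV (``date, precip_mm``)."""
    frame = _read_csv(path, ["date", "precip_mm"])
    frame = _numeric(frame, path, ["precip_mm"])
    try:
        return WeatherSeries(frame["date"], frame["precip_mm"])
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


def write_weather(weather: WeatherSeries, path) -> None:
    weather.to_frame().to_csv(path, index=False, date_format="%Y-%m-%d")


def read_events(path) -> list[RainfallEvent]:
    """Read an event table; ``excluded`` must be 0 or 1."""
    frame = _read_csv(path, EVENT_COLUMNS)
    frame = _numeric(frame, path, EVENT_COLUMNS[1:])
    if not frame["excluded"].isin([0, 1]).all():
        raise ValueError(f"{path}: 'excluded' flag must be 0 or 1")
    events = []
    for row in frame.itertuples():
        events.append(
            RainfallEvent(
                date=pd.Timestamp(row.date),
                precipitation=row.precip_mm,
                runoff=None if pd.isna(row.runoff_mm) else row.runoff_mm,
                erosion=None if pd.isna(row.erosion_kg_ha) else row.erosion_kg_ha,
                excluded=bool(row.excluded),
            )
        )
    return events


def write_events(events: Iterable[RainfallEvent] | pd.DataFrame, path) -> None:
    if isinstance(events, pd.DataFrame):
        frame = events[[c for c in EVENT_COLUMNS if c in events.columns]]
    else:
        frame = pd.DataFrame(
            {
                "date": [e.date for e in events],
                "precip_mm": [e.precipitation for e in events],
                "runoff_mm": [e.runoff for e in events],
                "erosion_kg_ha": [e.erosion for e in events],
                "excluded": [int(e.excluded) for e in events],
            }
        )
    frame.to_csv(path, index=False, date_format="%Y-%m-%d")


def read_exposure(path) -> list[ExposureDay]:
    """Read a daily exposure CSV for the PEC post-processing."""
    frame = _read_csv(path, EXPOSURE_COLUMNS)
    frame = _numeric(frame, path, EXPOSURE_COLUMNS[1:])
    return [
        ExposureDay(
            date=pd.Timestamp(r.date),
            rflx=r.rflx_mg_m2_d,
            runf=r.runf_L_m2_d,
            inflmon=r.infl_L_m2_d,
            precipitation=r.precip_mm,
        )
        for r in frame.itertuples()
    ]


#: column aliases for whitespace-delimited field-model daily output
_PRZM_ALIASES = {
    "DATE": "date",
    "PRCP": "precip_mm",
    "RUNF": "runf_L_m2_d",
    "RFLX": "rflx",
    "INFL": "infl_L_m2_d",
}


def read_przm_daily(path, rflx_in_g_cm2: bool = False) -> pd.DataFrame:
    """Read whitespace-delimited daily model output mapped by column name.

    Recognised headers: DATE, PRCP (mm), RUNF (L/m²/day), RFLX, INFL
    (L/m²/day).  With ``rflx_in_g_cm2`` the raw flux is converted to
    mg/m²/day (×1e7).
    """
    from .pec import GCM2_TO_MGM2

    frame = pd.read_csv(path, sep=r"\s+", comment="#")
    frame = frame.rename(columns=_PRZM_ALIASES)
    if "rflx" in frame.columns:
        scale = GCM2_TO_MGM2 if rflx_in_g_cm2 else 1.0
        frame["rflx_mg_m2_d"] = frame.pop("rflx") * scale
    return frame


def read_plot_config(path) -> FieldPlot:
    """Read a YAML plot block: area_ha, slope_pct, k, ls, c, p, cn [, ia_ratio]."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a mapping of plot parameters")
    block = cfg.get("plot", cfg)
    try:
        return FieldPlot(
            area_ha=float(block["area_ha"]),
            curve_number=float(block["cn"]),
            k_factor=float(block["k"]),
            ls_factor=float(block["ls"]),
            c_factor=float(block.get("c", 1.0)),
            p_factor=float(block.get("p", 1.0)),
            slope_pct=float(block["slope_pct"]) if "slope_pct" in block else None,
            ia_ratio=float(block.get("ia_ratio", 0.2)),
        )
    except KeyError as err:
        raise ValueError(f"{path}: missing plot parameter {err}") from err


def write_report(result, path) -> None:
    """Write any mapping / dataclass-like result as a two-column CSV."""
    if hasattr(result, "__dataclass_fields__"):
        import dataclasses

        items = dataclasses.asdict(result).items()
    elif isinstance(result, dict):
        items = result.items()
    else:
        raise TypeError(f"cannot report a {type(result).__name__}")
    pd.DataFrame(
        {"key": [k for k, _ in items], "value": [v for _, v in items]}
    ).to_csv(path, index=False)


def _load_fixture(name: str) -> pd.DataFrame:
    with resources.files("runoffmit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


def load_trial_totals() -> pd.DataFrame:
    """Measured seasonal totals + event-wise CNs of the packaged trials."""
    return _load_fixture("field_trial_totals.csv")


def load_season_fits() -> pd.DataFrame:
    """Whole-season fitted (CN, C-factor) table of the packaged trials."""
    return _load_fixture("season_fits.csv")


def load_plot_factors() -> pd.DataFrame:
    """USLE/MUSS plot factors (area, K, LS, P) of the packaged trials."""
    return _load_fixture("plot_factors.csv")
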