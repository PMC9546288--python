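"""Treatment-comparison statistics for mitigation trials.

Percent reductions of runoff/erosion totals, curve-number point deltas,
relative C-factors, and mean ± SD summary blocks over sets of
control/treated pairs.  Conventions follow how such trial tables are
printed: the SD is the *population* form (divisor n, not n-1), quantities
in mm, kg/ha, CN points and percent are rounded to integers in report
views, relative C-factors to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TreatmentPair",
    "SummaryBlock",
    "percent_reduction",
    "cn_point_reduction",
    "relative_c_factor",
    "summarize",
    "reduction_table",
    "season_fit_blocks",
]


@dataclass(frozen=True)
class TreatmentPair:
    """A control/treated pair of one quantity (runoff, erosion, CN or C)."""

    label: str
    control_value: float
    treated_value: float


@dataclass(frozen=True)
class SummaryBlock:
    """Mean ± population SD of a set of reductions."""

    label: str
    n: int
    mean: float
    sd: float
    unit: str  # "points" | "%" | "relative"

    def report(self, decimals: int = 0) -> str:
        if decimals == 0:
            return f"{round(self.mean):.0f} (±{self.sd:.1f})"
        return f"{self.mean:.{decimals}f} (±{self.sd:.{decimals}f})"


def percent_reduction(control: float, treated: float) -> float:
    """Reduction of a quantity by a treatment, percent of the control.

    ``100 * (control - treated) / control``; negative when the treatment
    increased the quantity.  Unrounded — round only in report views.
    """
    control = float(control)
    treated = float(treated)
    if control <= 0:
        raise ValueError(f"control value must be > 0, got {control}")
    if treated < 0:
        raise ValueError(f"treated value must be >= 0, got {treated}")
    return 100.0 * (control - treated) / control


def cn_point_reduction(control_cn: float, treated_cn: float) -> tuple[float, float]:
    """Curve-number reduction as (points, percent of the control CN)."""
    points = float(control_cn) - float(treated_cn)
    return points, 100.0 * points / float(control_cn)


def relative_c_factor(control_c: float, treated_c: float) -> tuple[float, float]:
    """(ratio, relative reduction) of a treated C-factor versus its control.

    ``ratio = treated / control``; ``reduction = 1 - ratio`` may be negative
    when the calibrated C rose under treatment (a strong runoff reduction
    must be compensated in C to still match the observed sediment).
    """
    control_c = float(control_c)
    if control_c <= 0:
        raise ValueError(f"control C-factor must be > 0, got {control_c}")
    ratio = float(treated_c) / control_c
    return ratio, 1.0 - ratio


def summarize(label: str, values: Sequence[float], unit: str = "%") -> SummaryBlock:
    """Mean and population SD (divisor n) of a set of reductions."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("nothing to summarize")
    return SummaryBlock(
        label=label,
        n=int(vals.size),
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=0)),
        unit=unit,
    )


def reduction_table(pairs: Sequence[TreatmentPair]) -> pd.DataFrame:
    """Per-pair percent reductions as a table (unrounded and report view)."""
    rows = []
    for pair in pairs:
        red = percent_reduction(pair.control_value, pair.treated_value)
        rows.append(
            {
                "label": pair.label,
                "control": pair.control_value,
                "treated": pair.treated_value,
                "reduction_pct": red,
                "reduction_pct_report": int(round(red)),
            }
        )
    return pd.DataFrame(rows)


# --- summary blocks over a table of fitted season parameters ----------------

#: (block label, treated label, control label) — the comparison sets used for
#: the seasonal-fit summaries.  "MD" entries pool every micro-dam device
#: (disc and drum plow count as separate setups).
_BLOCKS = [
    ("MD+CvT vs CvT", "MD+CvT", "CvT"),
    ("MD+CsT vs CsT", "MD+CsT", "CsT"),
    ("CsT vs CvT", "CsT", "CvT"),
    ("MD+CsT vs CvT", "MD+CsT", "CvT"),
    ("MD+CsT vs MD+CvT", "MD+CsT", "MD+CvT"),
]

#: Treatment labels that count as "micro-dams on conventional tillage".
MD_ON_CVT = ("MD+CvT", "MD_disc", "MD_drum")


def _pairs(fits: pd.DataFrame, treated: str, control: str) -> list[tuple[pd.Series, pd.Series]]:
    out = []
    for _, grp in fits.groupby(["trial", "slope_pct"], sort=False):
        by_label = grp.set_index("treatment")
        if control not in by_label.index:
            continue
        ctrl = by_label.loc[control]
        labels = MD_ON_CVT if treated == "MD+CvT" else (treated,)
        for lab in labels:
            if lab in by_label.index:
                out.append((ctrl, by_label.loc[lab]))
    return out


def season_fit_blocks(fits: pd.DataFrame) -> pd.DataFrame:
    """Mean-reduction summary blocks from a table of fitted (CN, C) values.

    ``fits`` needs columns ``trial, slope_pct, treatment, cn, c_factor``
    with treatment labels CvT, CsT, MD+CvT, MD+CsT (2013-style micro-dam
    setups MD_disc / MD_drum pool into the MD+CvT comparisons).  Returns one
    row per comparison block with n, mean/SD of CN point reductions, CN
    percent reductions, and relative C-factor reductions — population SDs
    throughout.
    """
    rows = []
    for label, treated, control in _BLOCKS:
        pairs = _pairs(fits, treated, control)
        if not pairs:
            continue
        pts, pcts, creds = [], [], []
        for ctrl, trt in pairs:
            p, pct = cn_point_reduction(ctrl["cn"], trt["cn"])
            pts.append(p)
            pcts.append(pct)
            if "c_factor" in ctrl and np.isfinite(ctrl["c_factor"]):
                creds.append(relative_c_factor(ctrl["c_factor"], trt["c_factor"])[1])
        pt_block = summarize(label, pts, "points")
        rows.append(
            {
                "comparison": label,
                "n": len(pairs),
                "cn_points_mean": pt_block.mean,
                "cn_points_sd": pt_block.sd,
                "cn_pct_mean": float(np.mean(pcts)),
                "cn_pct_sd": float(np.std(pcts)),
                "c_reduction_mean": float(np.mean(creds)) if creds else np.nan,
                "c_reduction_sd": float(np.std(creds)) if creds else np.nan,
            }
        )
    return pd.DataFrame(rows)
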