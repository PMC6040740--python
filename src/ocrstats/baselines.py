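"""Extreme Differences (ED) baseline and its Wilcoxon tests.

The vendor-style default analysis picks, per well and on raw data, a single
OCR value per interval: the last time point of interval 1, the minimum of
intervals 2 and 4, and the maximum of interval 3.  The six natural-scale
bioenergetic measures are then differences of these extremes, summarized per
(plate, biosample) as mean, sd and sem across wells.

Two tests accompany it for benchmarking:

* within-plate: a two-sided Wilcoxon rank-sum test on the per-well measures of
  a biosample vs the control wells of the same plate;
* across-plate ("multi-plate averaging"): a paired Wilcoxon signed-rank test
  on the per-plate means of biosample vs control — note the exact signed-rank
  null makes two-sided p < 0.05 unreachable with fewer than five plates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import MEASURES

__all__ = [
    "EDMeasures",
    "ed_measures",
    "ed_within_plate_test",
    "ed_across_plate_test",
]


@dataclass
class EDMeasures:
    """Per-well extremes/measures and per-(plate, biosample) summaries."""

    wells: pd.DataFrame
    summary: pd.DataFrame
    skipped_wells: list[tuple[str, str]]


def _extremes(sub: pd.DataFrame) -> dict[str, float] | None:
    """Per-well extreme OCR per interval; None if an interval is missing."""
    out: dict[str, float] = {}
    for i in (1, 2, 3, 4):
        vals = sub[sub["interval"] == i]
        if vals.empty:
            return None
        if i == 1:
            out["ocr1"] = float(vals.loc[vals["time_point"].idxmax(), "ocr"])
        elif i == 3:
            out["ocr3"] = float(vals["ocr"].max())
        else:
            out[f"ocr{i}"] = float(vals["ocr"].min())
    return out


def ed_measures(data: pd.DataFrame) -> EDMeasures:
    """Extreme-Differences bioenergetic measures on raw per-well data.

    ``data`` is long-format, typically QC-filtered but *not* outlier-cleaned
    (ED is defined on raw series).  Wells missing an interval are skipped and
    listed.
    """
    assay = data[~data.get("is_blank", pd.Series(False, index=data.index))]
    rows = []
    skipped: list[tuple[str, str]] = []
    for (pid, well, bios), sub in assay.groupby(["plate_id", "well", "biosample"]):
        ext = _extremes(sub)
        if ext is None:
            skipped.append((str(pid), str(well)))
            continue
        rows.append(
            {
                "plate_id": pid,
                "well": well,
                "biosample": bios,
                **ext,
                "basal": ext["ocr1"] - ext["ocr4"],
                "atp_linked": ext["ocr1"] - ext["ocr2"],
                "proton_leak": ext["ocr2"] - ext["ocr4"],
                "spare": ext["ocr3"] - ext["ocr1"],
                "maximal": ext["ocr3"] - ext["ocr4"],
                "nonmito": ext["ocr4"],
            }
        )
    wells = pd.DataFrame(rows)
    if wells.empty:
        return EDMeasures(wells=wells, summary=pd.DataFrame(), skipped_wells=skipped)
    agg = wells.groupby(["plate_id", "biosample"])[list(MEASURES)].agg(
        ["mean", "std", "sem", "size"]
    )
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    summary = agg.reset_index().rename(columns={f"{MEASURES[0]}_size": "n_wells"})
    summary = summary.drop(
        columns=[c for c in summary.columns if c.endswith("_size")], errors="ignore"
    )
    summary["n_wells"] = (
        wells.groupby(["plate_id", "biosample"]).size().to_numpy()
    )
    return EDMeasures(wells=wells, summary=summary, skipped_wells=skipped)


def ed_within_plate_test(
    ed: EDMeasures, plate_id: str, biosample: str, control: str, measure: str
) -> float:
    """Two-sided Wilcoxon rank-sum test on per-well measures within a plate.

    Returns NaN when either group has fewer than 2 wells.
    """
    w = ed.wells
    sub = w[w["plate_id"] == plate_id]
    a = sub.loc[sub["biosample"] == biosample, measure].to_numpy(float)
    b = sub.loc[sub["biosample"] == control, measure].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.pvalue)


def ed_across_plate_test(
    ed: EDMeasures, biosample: str, control: str, measure: str
) -> dict:
    """Paired Wilcoxon signed-rank test on per-plate ED means across plates.

    Pairs the biosample's per-plate mean with the control's on shared plates.
    Uses the exact signed-rank distribution for n <= 25 and the normal
    approximation above.  With fewer than five plates the exact two-sided
    floor (2 / 2^n) exceeds 0.05, so the result is flagged ``underpowered``.
    """
    s = ed.summary
    col = f"{measure}_mean"
    a = s[s["biosample"] == biosample].set_index("plate_id")[col]
    b = s[s["biosample"] == control].set_index("plate_id")[col]
    shared = a.index.intersection(b.index)
    if len(shared) < 2:
        return {"p_value": float("nan"), "n_plates": len(shared),
                "underpowered": True, "mean_difference": float("nan")}
    x = a.loc[shared].to_numpy(float)
    y = b.loc[shared].to_numpy(float)
    diff = x - y
    if np.allclose(diff, 0):
        p = 1.0
    else:
        method = "exact" if len(shared) <= 25 and not np.any(diff == 0) else "approx"
        res = stats.wilcoxon(x, y, alternative="two-sided", method=method)
        p = float(res.pvalue)
    return {
        "p_value": p,
        "n_plates": int(len(shared)),
        "underpowered": len(shared) < 5,
        "mean_difference": float(diff.mean()),
    }
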