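"""Iterative two-level outlier removal for within-plate fits.

Two kinds of aberrant data occur in stress-test plates: whole wells whose
entire series is off (e.g. a seeding or sensor failure) and single hot/cold
time points.  Both are screened on the squared deviations ``d**2`` from the
within-plate fit, with robust thresholds of the form

    median(x) + k * mad(x)

where ``mad`` is the median absolute deviation scaled by 1.4826 to estimate a
standard deviation.  The well screen uses ``k = 5`` on the per-well mean of
``d**2``; the point screen uses ``k = 7`` on individual ``d**2``.  Robust
statistics are computed per biological sample within the plate (configurable
to per-plate pooling).  After each removal the model is refit and the screen
repeated until an iteration flags nothing; convergence is guaranteed because
the included set strictly shrinks.

Both comparisons are strict, so for a constant deviation vector (mad = 0)
nothing above the median is spared but equality never flags.

Safety floors keep the design estimable: a biosample is never reduced below
``min_wells`` wells by the well screen, and the point screen never empties a
(biosample, interval) cell.  A tiny absolute guard (``ATOL``) is added to the
thresholds so that numerically-zero deviations on noise-free data are never
flagged (log-scale deviations that small are physically meaningless).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .within_plate import WithinPlateFit, fit_log_linear

__all__ = [
    "OutlierReport",
    "mad",
    "robust_threshold",
    "detect_well_outliers",
    "detect_point_outliers",
    "remove_outliers",
]

#: Consistency constant making the MAD estimate the standard deviation of a
#: normal sample (R's default).
MAD_CONSTANT = 1.4826

#: Absolute guard added to outlier thresholds: squared log deviations below
#: this are floating-point noise, never outliers.
ATOL = 1e-12


def mad(x: np.ndarray, constant: float = MAD_CONSTANT) -> float:
    """Median absolute deviation, scaled to estimate sigma."""
    x = np.asarray(x, float)
    return constant * float(np.median(np.abs(x - np.median(x))))


def robust_threshold(x: np.ndarray, mult: float, constant: float = MAD_CONSTANT) -> float:
    """``median(x) + mult * mad(x)``."""
    x = np.asarray(x, float)
    return float(np.median(x)) + mult * mad(x, constant)


@dataclass
class OutlierReport:
    """Record of which wells/points were flagged, and when."""

    plate_id: str
    well_outliers: list[tuple[str, str, int]] = field(default_factory=list)
    point_outliers: list[tuple[str, str, int, int]] = field(default_factory=list)
    n_iterations_well: int = 0
    n_iterations_point: int = 0
    n_wells_initial: int = 0
    n_points_initial: int = 0
    notes: list[str] = field(default_factory=list)

    @property
    def fractions(self) -> dict[str, float]:
        return {
            "well": len(self.well_outliers) / self.n_wells_initial
            if self.n_wells_initial
            else 0.0,
            "point": len(self.point_outliers) / self.n_points_initial
            if self.n_points_initial
            else 0.0,
        }

    def to_records(self) -> list[dict]:
        recs = [
            {"plate_id": p, "well": w, "time_point": None, "level": "well",
             "iteration": it}
            for p, w, it in self.well_outliers
        ]
        recs += [
            {"plate_id": p, "well": w, "time_point": t, "level": "point",
             "iteration": it}
            for p, w, t, it in self.point_outliers
        ]
        return recs


def _groups(df: pd.DataFrame, grouping: str) -> pd.Series:
    if grouping == "biosample":
        return df["biosample"]
    if grouping == "plate":
        return pd.Series("__plate__", index=df.index)
    raise ValueError(f"unknown grouping {grouping!r}")


def detect_well_outliers(
    plate_df: pd.DataFrame,
    *,
    mad_mult: float = 5.0,
    grouping: str = "biosample",
    min_wells: int = 3,
    mad_constant: float = MAD_CONSTANT,
    report: OutlierReport | None = None,
    fit_kwargs: dict | None = None,
) -> tuple[WithinPlateFit, OutlierReport, pd.DataFrame]:
    """Iteratively flag and drop whole-well outliers of one plate.

    Per iteration: fit the log-linear model, compute per well ``s_w``, the
    mean over time points of the squared deviations, and flag wells with
    ``s_w`` strictly above ``median(s) + mad_mult * mad(s)`` within the
    grouping unit.  Flagged wells are dropped and the model refit until an
    iteration flags nothing.  If flagging would leave a biosample with fewer
    than ``min_wells`` wells, removal halts for that biosample.

    Returns the final fit, the report, and the retained measurements.
    """
    fit_kwargs = fit_kwargs or {}
    included = plate_df[~plate_df.get("is_blank", pd.Series(False, index=plate_df.index))].copy()
    if report is None:
        report = OutlierReport(plate_id=str(included["plate_id"].iloc[0]))
    report.n_wells_initial = included["well"].nunique()
    report.n_points_initial = len(included)

    halted: set[str] = set()
    max_iter = report.n_wells_initial + 1
    it = 0
    while True:
        it += 1
        fit = fit_log_linear(included, **fit_kwargs)
        d2 = fit.obs["deviation"] ** 2
        per_well = (
            fit.obs.assign(d2=d2)
            .groupby(["biosample", "well"])["d2"]
            .mean()
        )
        flagged: list[str] = []
        for bios, s in per_well.groupby(level=0):
            if bios in halted:
                continue
            vals = s.droplevel(0)
            thr = robust_threshold(vals.to_numpy(), mad_mult, mad_constant) + ATOL
            hits = list(vals.index[vals.to_numpy() > thr])
            if not hits:
                continue
            if len(vals) - len(hits) < min_wells:
                halted.add(str(bios))
                report.notes.append(
                    f"well-outlier removal halted for biosample {bios!r}: "
                    f"flagging {len(hits)} of {len(vals)} wells would leave "
                    f"fewer than {min_wells}"
                )
                continue
            flagged.extend(hits)
        if not flagged or it >= max_iter:
            report.n_iterations_well = it
            return fit, report, included
        for w in flagged:
            report.well_outliers.append((report.plate_id, str(w), it))
        included = included[~included["well"].isin(flagged)]


def detect_point_outliers(
    plate_df: pd.DataFrame,
    *,
    mad_mult: float = 7.0,
    grouping: str = "biosample",
    mad_constant: float = MAD_CONSTANT,
    report: OutlierReport | None = None,
    fit_kwargs: dict | None = None,
) -> tuple[WithinPlateFit, OutlierReport, pd.DataFrame]:
    """Iteratively flag and drop single-point outliers of one plate.

    Run after the well-level pass, on the retained wells.  Per iteration:
    fit, flag points whose squared deviation strictly exceeds
    ``median(d^2) + mad_mult * mad(d^2)`` over all remaining points of the
    same grouping unit, drop, refit, until none are flagged.  The last
    remaining point of a (biosample, interval) cell is never removed.
    """
    fit_kwargs = fit_kwargs or {}
    included = plate_df[~plate_df.get("is_blank", pd.Series(False, index=plate_df.index))].copy()
    if report is None:
        report = OutlierReport(plate_id=str(included["plate_id"].iloc[0]))
    if report.n_points_initial == 0:
        report.n_points_initial = len(included)
    if report.n_wells_initial == 0:
        report.n_wells_initial = included["well"].nunique()

    max_iter = len(included) + 1
    it = 0
    while True:
        it += 1
        fit = fit_log_linear(included, **fit_kwargs)
        obs = fit.obs.assign(d2=fit.obs["deviation"] ** 2)
        obs["group"] = _groups(obs, grouping)
        flag = pd.Series(False, index=obs.index)
        for _, sub in obs.groupby("group"):
            thr = robust_threshold(sub["d2"].to_numpy(), mad_mult, mad_constant) + ATOL
            flag.loc[sub.index[sub["d2"].to_numpy() > thr]] = True
        # floor: never empty a (biosample, interval) cell
        for (bios, interv), sub in obs.groupby(["biosample", "interval"]):
            cell_flags = flag.loc[sub.index]
            if cell_flags.all():
                keep = sub["d2"].idxmin()
                flag.loc[keep] = False
                report.notes.append(
                    f"kept one point in cell (biosample={bios!r}, interval={interv}) "
                    "to preserve estimability"
                )
        if not flag.any() or it >= max_iter:
            report.n_iterations_point = it
            return fit, report, included
        hit = obs[flag]
        for w, t in zip(hit["well"], hit["time_point"]):
            report.point_outliers.append((report.plate_id, str(w), int(t), it))
        drop_keys = set(zip(hit["well"], hit["time_point"]))
        keys = list(zip(included["well"], included["time_point"].astype(int)))
        included = included[[k not in drop_keys for k in keys]]


def remove_outliers(
    plate_df: pd.DataFrame,
    *,
    well_mad_mult: float = 5.0,
    point_mad_mult: float = 7.0,
    grouping: str = "biosample",
    min_wells: int = 3,
    mad_constant: float = MAD_CONSTANT,
    fit_kwargs: dict | None = None,
) -> tuple[WithinPlateFit, OutlierReport, pd.DataFrame]:
    """Full two-pass outlier removal (wells, then points) for one plate."""
    _, report, kept = detect_well_outliers(
        plate_df,
        mad_mult=well_mad_mult,
        grouping=grouping,
        min_wells=min_wells,
        mad_constant=mad_constant,
        fit_kwargs=fit_kwargs,
    )
    fit, report, kept = detect_point_outliers(
        kept,
        mad_mult=point_mad_mult,
        grouping=grouping,
        mad_constant=mad_constant,
        report=report,
        fit_kwargs=fit_kwargs,
    )
    return fit, report, kept
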