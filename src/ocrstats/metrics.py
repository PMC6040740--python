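"""Bioenergetic metrics, coefficient-of-variation summaries, diagnostics.

With ``OCR_i = exp(theta_i)`` the expected OCR level of interval ``i``, two
families of summaries are computed per (plate, biosample):

Ratio metrics (log-scale differences, natural-scale ratios) — robust to
multiplicative well and plate effects, hence the recommended basis for
cross-plate comparison:

* ``EI_prop  = 1 - exp(theta_Ei - theta_I)``   ETC-dependent OCR proportion
* ``AI_prop  = 1 - exp(theta_Ai - theta_I)``   ATPase-dependent OCR proportion
* ``EAi_prop = 1 - exp(theta_Ei - theta_Ai)``  ETC-dep. proportion of ATPase-indep. OCR
* ``MI_fold  = exp(theta_M - theta_I)``        maximal / initial fold change
* ``MEi_fold = exp(theta_M - theta_Ei)``       maximal / ETC-independent fold change

Natural-scale bioenergetic measures (pmol/min), the classical literature
quantities:

* basal        = OCR1 - OCR4
* atp_linked   = OCR1 - OCR2
* proton_leak  = OCR2 - OCR4
* spare        = OCR3 - OCR1
* maximal      = OCR3 - OCR4
* nonmito      = OCR4

Here interval 1 = I (initial), 2 = Ai (ATPase-independent), 3 = M (maximal),
4 = Ei (ETC-independent).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import PlateSet, parse_well
from .within_plate import WithinPlateFit

__all__ = [
    "RATIO_METRICS",
    "MEASURES",
    "compute_ratio_metrics",
    "compute_bioenergetic_measures",
    "metric_table",
    "log_sd_to_cv",
    "within_plate_cv",
    "across_plate_cv",
    "compare_cv",
    "positional_diagnostics",
]

RATIO_METRICS = ("EI_prop", "AI_prop", "EAi_prop", "MI_fold", "MEi_fold")
MEASURES = ("basal", "atp_linked", "proton_leak", "spare", "maximal", "nonmito")


def _ratio_row(theta: np.ndarray) -> dict[str, float]:
    t1, t2, t3, t4 = theta
    return {
        "EI_prop": 1.0 - np.exp(t4 - t1),
        "AI_prop": 1.0 - np.exp(t2 - t1),
        "EAi_prop": 1.0 - np.exp(t4 - t2),
        "MI_fold": np.exp(t3 - t1),
        "MEi_fold": np.exp(t3 - t4),
    }


def _measure_row(theta: np.ndarray) -> dict[str, float]:
    ocr = np.exp(theta)
    return {
        "basal": ocr[0] - ocr[3],
        "atp_linked": ocr[0] - ocr[1],
        "proton_leak": ocr[1] - ocr[3],
        "spare": ocr[2] - ocr[0],
        "maximal": ocr[2] - ocr[3],
        "nonmito": ocr[3],
    }


def compute_ratio_metrics(fit: WithinPlateFit) -> pd.DataFrame:
    """Five ratio metrics per biosample of one fitted plate."""
    rows = []
    for bios in fit.biosamples:
        theta = fit.theta_of(bios)
        rows.append({"plate_id": fit.plate_id, "biosample": bios, **_ratio_row(theta)})
    return pd.DataFrame(rows)


def compute_bioenergetic_measures(fit: WithinPlateFit) -> pd.DataFrame:
    """Six natural-scale bioenergetic measures per biosample of one plate."""
    rows = []
    for bios in fit.biosamples:
        theta = fit.theta_of(bios)
        rows.append({"plate_id": fit.plate_id, "biosample": bios, **_measure_row(theta)})
    return pd.DataFrame(rows)


def metric_table(fits: Iterable[WithinPlateFit]) -> pd.DataFrame:
    """Combined ratio metrics + bioenergetic measures across plates."""
    rows = []
    for fit in fits:
        for bios in fit.biosamples:
            theta = fit.theta_of(bios)
            rows.append(
                {
                    "plate_id": fit.plate_id,
                    "biosample": bios,
                    **_ratio_row(theta),
                    **_measure_row(theta),
                }
            )
    return pd.DataFrame(rows)


def log_sd_to_cv(sigma: float | np.ndarray) -> float | np.ndarray:
    """Natural-scale CV approximated from a log-scale standard deviation.

    Uses ``exp(sigma) - 1``; for small sigma this is close to the exact
    lognormal CV ``sqrt(exp(sigma^2) - 1)`` and is the convention adopted
    for reporting per-interval well variability.
    """
    return np.expm1(sigma)


def within_plate_cv(
    plates: PlateSet | pd.DataFrame, biosample: str
) -> pd.DataFrame:
    """Between-well variability of one biosample, per interval.

    For each plate and interval, the standard deviation of log OCR across all
    included (well, time point) observations of ``biosample``; then the
    median across plates, converted to a natural-scale CV via
    ``exp(sigma) - 1``.  Plates with fewer than 2 wells of the biosample are
    skipped.
    """
    data = plates.assay_data if isinstance(plates, PlateSet) else plates
    sub = data[data["biosample"] == biosample]
    if sub.empty:
        raise ValueError(f"biosample {biosample!r} not present")
    sigmas = []
    skipped = []
    for (pid, interv), grp in sub.groupby(["plate_id", "interval"]):
        if grp["well"].nunique() < 2:
            skipped.append((pid, interv))
            continue
        sigmas.append(
            {"plate_id": pid, "interval": int(interv),
             "sigma": float(np.std(np.log(grp["ocr"].to_numpy(float)), ddof=1))}
        )
    sig = pd.DataFrame(sigmas)
    out = (
        sig.groupby("interval")["sigma"]
        .median()
        .rename("median_sigma")
        .reset_index()
    )
    out["cv"] = log_sd_to_cv(out["median_sigma"])
    out["cv_percent"] = np.round(100 * out["cv"]).astype(int)
    out.attrs["skipped"] = skipped
    return out


def across_plate_cv(
    measures: pd.DataFrame,
    value_cols: Sequence[str] = MEASURES,
    method: str | None = None,
) -> pd.DataFrame:
    """CV (sd/mean) of each natural-scale measure across plates, per biosample.

    ``measures`` is a metric table with one row per (plate, biosample).
    Biosamples on fewer than 2 plates are dropped; a non-positive mean yields
    a missing CV for that (biosample, measure).
    """
    rows = []
    for bios, sub in measures.groupby("biosample"):
        if sub["plate_id"].nunique() < 2:
            continue
        row: dict = {"biosample": bios, "n_plates": sub["plate_id"].nunique()}
        for col in value_cols:
            vals = sub[col].to_numpy(float)
            m = vals.mean()
            row[col] = float(np.std(vals, ddof=1) / m) if m > 0 else np.nan
        if method is not None:
            row["method"] = method
        rows.append(row)
    return pd.DataFrame(rows)


def compare_cv(
    cv_a: pd.DataFrame, cv_b: pd.DataFrame, measure: str
) -> tuple[float, int]:
    """One-sided paired Wilcoxon test that method A's CVs are lower than B's.

    Pairs by biosample; returns (p-value, number of pairs).
    """
    merged = cv_a[["biosample", measure]].merge(
        cv_b[["biosample", measure]], on="biosample", suffixes=("_a", "_b")
    ).dropna()
    a = merged[f"{measure}_a"].to_numpy(float)
    b = merged[f"{measure}_b"].to_numpy(float)
    if len(a) < 2 or np.allclose(a, b):
        return float("nan"), len(a)
    res = stats.wilcoxon(a, b, alternative="less")
    return float(res.pvalue), len(a)


def positional_diagnostics(fits: Iterable[WithinPlateFit]) -> pd.DataFrame:
    """Median deviation (y - theta_hat) per plate row and per column.

    Pools all fitted plates; an edge effect (e.g. evaporation cooling the
    plate rim) shows up as negative medians in outer rows/columns.  Single-row
    plates yield a degenerate but defined row summary.
    """
    recs = []
    for fit in fits:
        for well, dev in zip(fit.obs["well"], fit.obs["deviation"]):
            r, c = parse_well(well)
            recs.append({"row": r, "column": c, "deviation": dev})
    df = pd.DataFrame(recs)
    rows = (
        df.groupby("row")["deviation"]
        .agg(median_deviation="median", n="size")
        .reset_index()
        .rename(columns={"row": "label"})
        .assign(axis="row")
    )
    cols = (
        df.groupby("column")["deviation"]
        .agg(median_deviation="median", n="size")
        .reset_index()
        .rename(columns={"column": "label"})
        .assign(axis="column")
    )
    cols["label"] = cols["label"].astype(str)
    return pd.concat([rows, cols], ignore_index=True)[
        ["axis", "label", "median_deviation", "n"]
    ]
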