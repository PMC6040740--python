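"""Power analysis: minimal detectable effects and well subsampling.

Given the pooled standard deviation of the cross-plate residuals
``eps[b, p]`` for a log-ratio metric, the minimal relative difference
detectable at significance level ``alpha`` with ``n`` plates per comparison is

    mde = exp(z * sd / sqrt(n)) - 1

with ``z = 1.96`` (the 97.5-percent normal quantile) at alpha = 0.05 and the
convention n = 3 plates.  The subsampling experiment estimates how that
residual sd depends on the number of wells seeded per biosample per plate: the
wells of each non-control biosample are subsampled without replacement to 4,
6, ..., 16 wells, the full pipeline (outlier removal, fitting, cross-plate
testing) is re-run, and the residual sd per metric is recorded for each of the
random samplings.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import PlateSet
from .outliers import remove_outliers
from .testing import compute_ddtheta, test_biosamples

__all__ = ["minimal_detectable_effect", "subsample_power_curve"]


def minimal_detectable_effect(
    sd_resid: float,
    n_plates: int,
    alpha: float = 0.05,
    exact_t: bool = False,
    df: int | None = None,
) -> float:
    """Minimal detectable relative difference for a log-ratio metric.

    Parameters
    ----------
    sd_resid
        Standard deviation of the cross-plate residuals (log scale).
    n_plates
        Plates per comparison (>= 1).
    exact_t, df
        Replace the fixed 1.96-type normal quantile with the t quantile on
        ``df`` degrees of freedom.
    """
    if n_plates < 1:
        raise ValueError("n_plates must be >= 1")
    if sd_resid < 0:
        raise ValueError("sd_resid must be >= 0")
    if exact_t:
        if df is None or df < 1:
            raise ValueError("exact_t requires df >= 1")
        z = stats.t.ppf(1 - alpha / 2, df)
    else:
        z = stats.norm.ppf(1 - alpha / 2)
    return float(np.expm1(z * sd_resid / np.sqrt(n_plates)))


def _subsample_wells(
    data: pd.DataFrame, control: str, n_wells: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Subsample each non-control biosample to n_wells per plate (w/o repl.)."""
    keep_idx = []
    flags = []
    for (pid, bios), sub in data.groupby(["plate_id", "biosample"]):
        wells = sorted(sub["well"].unique())
        if bios == control or len(wells) <= n_wells:
            if bios != control and len(wells) < n_wells:
                flags.append((pid, bios, len(wells)))
            keep_idx.append(sub.index)
            continue
        chosen = set(rng.choice(wells, size=n_wells, replace=False))
        keep_idx.append(sub.index[sub["well"].isin(chosen)])
    out = data.loc[np.concatenate([np.asarray(ix) for ix in keep_idx])]
    out.attrs["short_groups"] = flags
    return out


def subsample_power_curve(
    plates: PlateSet | pd.DataFrame,
    control: str,
    wells_grid: Sequence[int] = (4, 6, 8, 10, 12, 14, 16),
    reps: int = 10,
    seed: int = 0,
    n_plates_mde: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Residual sd and minimal detectable effect vs wells per biosample.

    For every well count in ``wells_grid`` and each of ``reps`` random
    subsamplings (without replacement), runs outlier removal and the
    cross-plate test on the subsampled dataset and records the pooled residual
    standard deviation per ratio metric, together with the implied minimal
    detectable effect at ``n_plates_mde`` plates.  Control wells are never
    subsampled (they anchor the plate contrasts); biosamples with fewer wells
    than requested keep all their wells.

    Deterministic given ``seed``.
    """
    data = plates.assay_data if isinstance(plates, PlateSet) else plates
    rng = np.random.default_rng(seed)
    rows = []
    for n_wells in wells_grid:
        for rep in range(reps):
            sub = _subsample_wells(data, control, int(n_wells), rng)
            fits = {}
            for pid, pdata in sub.groupby("plate_id"):
                fit, _, _ = remove_outliers(pdata)
                fits[str(pid)] = fit
            dd = compute_ddtheta(fits, control)
            res = test_biosamples(dd, alpha=alpha)
            for metric, sd in res.sd_residuals().items():
                rows.append(
                    {
                        "n_wells": int(n_wells),
                        "rep": rep,
                        "metric": metric,
                        "sd_resid": float(sd),
                        "mde": minimal_detectable_effect(
                            float(sd), n_plates_mde, alpha=alpha
                        ),
                    }
                )
    return pd.DataFrame(rows)
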