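"""Within-plate log-linear model of OCR.

OCR noise is multiplicative, so the model works on the natural logarithm of
OCR.  For a single plate, the log OCR ``y[w, t]`` of well ``w`` at time point
``t`` is modelled as an interval effect of the well's biological sample plus a
well effect plus noise::

    y[w, t] = theta[biosample(w), interval(t)] + beta[w] + eps[w, t]

``theta`` carries the four log OCR levels per biosample (basal,
ATPase-independent, maximal, non-mitochondrial); ``beta`` absorbs systematic
per-well shifts (cell number, sensor calibration, position).  The model is fit
by exact linear least squares jointly over all biosamples of the plate.

Identifiability: because wells are nested in biosamples, a constant can be
moved between a biosample's four interval effects and the well effects of its
wells — one aliasing direction per biosample.  We therefore constrain the well
effects to mean zero within each biosample (which implies mean zero across the
plate's included wells), so ``theta`` is the average log level of the
biosample's own wells and the per-point deviation

    d[w, t] = y[w, t] - theta_hat - mean(beta_hat)

reduces to ``y - theta_hat``.  Fitted values, ratio metrics and cross-plate
tests are invariant to the identifiability choice (see the reference-well
parameterization test); the natural-scale measures require a convention and
this is it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["EstimationError", "WithinPlateFit", "fit_log_linear", "compute_deviations"]

INTERVALS = (1, 2, 3, 4)


class EstimationError(RuntimeError):
    """Raised when the within-plate model cannot be estimated."""


@dataclass
class WithinPlateFit:
    """Least-squares fit of the within-plate log-linear model.

    Attributes
    ----------
    plate_id
        Identifier of the plate this fit belongs to.
    theta
        Interval effects, indexed by (biosample, interval); log scale.
    beta
        Well effects, indexed by well; mean zero within each biosample's
        included wells (hence mean zero over the plate).
    obs
        Per-observation table with columns ``well, biosample, time_point,
        interval, y, offset, fitted, resid, deviation``.  ``y`` is log OCR
        minus any supplied offset; ``deviation`` is ``y - theta_hat``.
    n_obs
        Number of observations entering the fit.
    notes
        Fit log (degenerate designs, single-well biosamples, ...).
    """

    plate_id: str
    theta: pd.Series
    beta: pd.Series
    obs: pd.DataFrame
    n_obs: int
    notes: list[str] = field(default_factory=list)

    def deviations(self) -> pd.Series:
        """Deviations ``d[w, t]`` indexed by (well, time_point)."""
        return self.obs.set_index(["well", "time_point"])["deviation"]

    def theta_of(self, biosample: str) -> np.ndarray:
        """The four interval effects of one biosample, ordered 1..4."""
        try:
            return np.array([self.theta[(biosample, i)] for i in INTERVALS])
        except KeyError as exc:
            raise EstimationError(
                f"missing interval effect for (biosample={biosample!r}, "
                f"interval={exc.args[0][1]}) on plate {self.plate_id!r}"
            ) from exc

    @property
    def biosamples(self) -> list[str]:
        return sorted(self.theta.index.get_level_values(0).unique())


def _build_offset(
    df: pd.DataFrame,
    interval_offsets: Mapping[int, float] | None,
    row_offsets: pd.Series | None,
    cell_count_offset: bool,
) -> np.ndarray:
    offset = np.zeros(len(df))
    if interval_offsets is not None:
        offset += df["interval"].map(lambda i: interval_offsets.get(int(i), 0.0)).to_numpy()
    if row_offsets is not None:
        keyed = df.set_index(["well", "time_point"]).index
        offset += row_offsets.reindex(keyed, fill_value=0.0).to_numpy()
    if cell_count_offset:
        if "cell_count" not in df.columns or df["cell_count"].isna().any():
            raise EstimationError("cell_count_offset requires a cell count for every well")
        if not (df["cell_count"] > 0).all():
            raise EstimationError("cell counts must be positive for the log offset")
        offset += np.log(df["cell_count"].to_numpy(float))
    return offset


def fit_log_linear(
    plate_df: pd.DataFrame,
    *,
    interval_offsets: Mapping[int, float] | None = None,
    row_offsets: pd.Series | None = None,
    cell_count_offset: bool = False,
) -> WithinPlateFit:
    """Fit the within-plate model by exact least squares.

    Parameters
    ----------
    plate_df
        Long-format measurements of a single plate (blank wells are ignored).
        Must contain only positive OCR values.
    interval_offsets
        Optional per-interval offsets (log scale) subtracted from ``y`` before
        fitting — used to remove estimated plate-interval effects.
    row_offsets
        Optional per-(well, time_point) offsets (log scale).
    cell_count_offset
        If set, additionally subtract ``log(cell_count)`` per well, modelling
        designs in which different cell numbers were seeded.

    Returns
    -------
    WithinPlateFit
        With well effects constrained to mean zero within each biosample's
        included wells.

    Raises
    ------
    EstimationError
        If a biosample lacks observations in one of the four intervals.
    """
    df = plate_df[~plate_df.get("is_blank", pd.Series(False, index=plate_df.index))]
    if df.empty:
        raise EstimationError("no non-blank observations to fit")
    plate_ids = df["plate_id"].unique()
    if len(plate_ids) != 1:
        raise EstimationError(f"fit_log_linear expects a single plate, got {list(plate_ids)}")
    plate_id = str(plate_ids[0])
    if not (df["ocr"] > 0).all():
        raise EstimationError("non-positive OCR encountered; log is undefined")

    notes: list[str] = []
    offset = _build_offset(df, interval_offsets, row_offsets, cell_count_offset)
    y = np.log(df["ocr"].to_numpy(float)) - offset

    cells = sorted(set(zip(df["biosample"], df["interval"].astype(int))))
    for bios in sorted(df["biosample"].unique()):
        present = {i for b, i in cells if b == bios}
        missing = [i for i in INTERVALS if i not in present]
        if missing:
            raise EstimationError(
                f"empty design cell: biosample {bios!r}, interval(s) {missing} "
                f"on plate {plate_id!r}"
            )
    wells = sorted(df["well"].unique())
    well_bios = df.drop_duplicates("well").set_index("well")["biosample"]
    bios_wells: dict[str, list[str]] = {}
    for w in wells:
        bios_wells.setdefault(str(well_bios[w]), []).append(w)
    for bios, ws in bios_wells.items():
        if len(ws) == 1:
            notes.append(f"biosample {bios!r} has a single well; its well effect "
                         "is pinned to zero by the within-biosample constraint")

    n = len(df)
    cell_index = {c: j for j, c in enumerate(cells)}
    n_cells = len(cells)

    # theta dummies + well effects sum-coded within each biosample (the last
    # well of a biosample = -sum of its others); wells are nested in
    # biosamples, so one constraint per biosample is required for full rank
    well_col: dict[str, int] = {}
    well_block: dict[str, tuple[list[str], int]] = {}
    col = n_cells
    for bios, ws in bios_wells.items():
        well_block[bios] = (ws, col)
        for w in ws[:-1]:
            well_col[w] = col
            col += 1
    n_params = col

    X = np.zeros((n, n_params))
    rows = np.arange(n)
    cell_col = np.fromiter(
        (cell_index[(b, int(i))] for b, i in zip(df["biosample"], df["interval"])),
        int, count=n,
    )
    X[rows, cell_col] = 1.0
    for r, (w, b) in enumerate(zip(df["well"], df["biosample"])):
        ws, start = well_block[str(b)]
        if len(ws) == 1:
            continue
        if w == ws[-1]:
            X[r, start: start + len(ws) - 1] = -1.0
        else:
            X[r, well_col[w]] = 1.0

    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    theta_vals = coef[:n_cells]
    beta_map: dict[str, float] = {}
    for bios, (ws, start) in well_block.items():
        if len(ws) == 1:
            beta_map[ws[0]] = 0.0
            continue
        head = coef[start: start + len(ws) - 1]
        for w, v in zip(ws[:-1], head):
            beta_map[w] = float(v)
        beta_map[ws[-1]] = float(-head.sum())
    beta_vals = np.array([beta_map[w] for w in wells])

    theta = pd.Series(
        theta_vals,
        index=pd.MultiIndex.from_tuples(cells, names=["biosample", "interval"]),
        name="theta",
    )
    beta = pd.Series(beta_vals, index=pd.Index(wells, name="well"), name="beta")

    fitted = theta_vals[cell_col] + np.fromiter(
        (beta_map[w] for w in df["well"]), float, count=n
    )
    # d = y - theta_hat - mean(beta_hat); the last term vanishes under the
    # mean-zero constraint but is kept for literal fidelity to the formula.
    deviation = y - theta_vals[cell_col] - beta_vals.mean()
    obs = pd.DataFrame(
        {
            "well": df["well"].to_numpy(),
            "biosample": df["biosample"].to_numpy(),
            "time_point": df["time_point"].astype(int).to_numpy(),
            "interval": df["interval"].astype(int).to_numpy(),
            "y": y,
            "offset": offset,
            "fitted": fitted,
            "resid": y - fitted,
            "deviation": deviation,
        }
    )
    return WithinPlateFit(
        plate_id=plate_id, theta=theta, beta=beta, obs=obs, n_obs=n, notes=notes
    )


def compute_deviations(fit: WithinPlateFit) -> pd.Series:
    """Log OCR deviations ``d[w, t] = y - theta_hat - mean(beta_hat)``.

    Under the mean-zero well-effect constraint the last term vanishes, so the
    deviation keeps each well's effect in — by design: a whole-well shift must
    remain visible to the well-level outlier screen.
    """
    return fit.deviations()
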