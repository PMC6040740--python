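"""Control-anchored plate-interval effect estimation and correction.

Treatment efficiency and instrument conditions vary between plates, and can
vary per interval (e.g. a weaker rotenone batch lowers only interval 4).
Because the control biosample is seeded on every plate, its log OCR identifies
these shifts.  The control observations are modelled as

    y[control, t, p] = theta_control[interval(t)] + beta[interval(t), p] + eps

and solved by least squares with the per-interval plate effects ``beta[i, p]``
constrained to mean zero over plates (only contrasts between plates matter).
Since the model saturates the (interval, plate) cells, the least-squares
solution is closed form: fitted cell values are the cell means of log OCR and
``theta_control[i]`` is their unweighted mean over plates.

The estimated effects are then used as per-(plate, interval) offsets when
refitting the within-plate model, yielding plate-corrected interval effects
for all biosamples (the "OCR-PE" variant of the pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .within_plate import WithinPlateFit, fit_log_linear

__all__ = [
    "PlateIntervalEffects",
    "estimate_plate_interval_effects",
    "apply_plate_correction",
]


@dataclass
class PlateIntervalEffects:
    """Log-scale plate-interval offsets anchored on the control biosample.

    ``beta`` is indexed by (interval, plate_id) and is mean zero over the
    plates carrying the control, per interval.  Plates without control data
    get no offset and are listed in ``missing_plates``.
    """

    beta: pd.Series
    theta_control: pd.Series
    missing_plates: list[str] = field(default_factory=list)

    def offsets_for(self, plate_id: str) -> dict[int, float]:
        """Per-interval offset mapping for one plate (zeros if missing)."""
        out: dict[int, float] = {}
        for (interv, pid), val in self.beta.items():
            if pid == plate_id:
                out[int(interv)] = float(val)
        return out

    def to_records(self) -> list[dict]:
        return [
            {"plate_id": pid, "interval": int(i), "beta": float(v)}
            for (i, pid), v in self.beta.items()
        ]


def estimate_plate_interval_effects(
    data: pd.DataFrame, control: str
) -> PlateIntervalEffects:
    """Estimate per-(interval, plate) effects from the control's log OCR.

    ``data`` should be outlier-cleaned, non-blank measurements across plates.
    Returns effects with mean zero over plates per interval.
    """
    all_plates = sorted(data["plate_id"].astype(str).unique())
    ctl = data[(data["biosample"] == control) & ~data.get("is_blank", False)]
    if ctl.empty:
        raise ValueError(f"control biosample {control!r} not present in data")
    logy = ctl.assign(y=np.log(ctl["ocr"].to_numpy(float)))
    cell_means = logy.groupby(["interval", "plate_id"])["y"].mean()
    theta = cell_means.groupby(level="interval").mean().rename("theta_control")
    beta = (cell_means - theta.reindex(cell_means.index.get_level_values(0)).to_numpy()
            ).rename("beta")
    have_control = set(ctl["plate_id"].astype(str).unique())
    missing = [p for p in all_plates if p not in have_control]
    return PlateIntervalEffects(beta=beta, theta_control=theta, missing_plates=missing)


def apply_plate_correction(
    data: pd.DataFrame,
    effects: PlateIntervalEffects,
    *,
    fit_kwargs: Mapping | None = None,
) -> dict[str, WithinPlateFit]:
    """Refit each plate with the estimated plate-interval offsets removed.

    The offset ``beta[interval, plate]`` is subtracted from log OCR before
    fitting, so the returned interval effects are plate-corrected for every
    biosample.  Plates without estimated effects are fitted uncorrected.
    """
    fit_kwargs = dict(fit_kwargs or {})
    fits: dict[str, WithinPlateFit] = {}
    for pid, sub in data.groupby("plate_id"):
        offsets = effects.offsets_for(str(pid))
        fits[str(pid)] = fit_log_linear(
            sub, interval_offsets=offsets or None, **fit_kwargs
        )
    return fits
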