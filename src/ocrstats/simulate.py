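"""Synthetic stress-test plates with ground truth.

The generator emulates the statistical structure the estimation pipeline
assumes: log OCR is the sum of a per-(biosample, interval) level, a mean-zero
per-well effect, a per-(plate, interval) batch effect, and Gaussian noise —
i.e. multiplicative lognormal variation on the natural scale::

    log OCR[w, t] = theta[biosample(w), interval(t)] + beta[w]
                    + gamma[plate, interval(t)] + eps[w, t]

On top of the clean signal it can inject the artefacts the pipeline must
handle: whole-well outliers (every point of a well shifted by a log
magnitude), single-point outliers, and non-responder wells with a flat
interval profile (to exercise the QC ordering filter).  The control biosample
is placed on every plate and the four corner wells are blank (medium only),
mirroring the standard plate layout.

Defaults reflect typical fibroblast stress tests: 12 time points in 4
intervals of 3; interval levels around (100, 40, 150, 20) pmol/min (so
maximal > initial > ATPase-independent > non-mitochondrial); log-scale noise
sd 0.1 between time points, well-effect sd 0.1, and plate-interval sd 0.15 —
between-plate variability exceeding within-plate variability, as observed in
real multi-plate datasets.

Every draw comes from one seeded generator, so a config (including its seed)
fixes the output bit-exactly, and the emitted :class:`SimTruth` carries all
latent parameters and outlier masks for recovery tests.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import PlateSet
from .testing import DDTHETA_DEFS

__all__ = ["SimConfig", "SimTruth", "simulate_plates", "write_truth"]

DEFAULT_THETA = (np.log(100.0), np.log(40.0), np.log(150.0), np.log(20.0))


@dataclass
class SimConfig:
    """Parameters of the plate simulator (log scale unless noted)."""

    n_plates: int = 3
    biosamples_per_plate: int = 5  # including the control
    wells_per_biosample: int = 12
    points_per_interval: int = 3
    theta_base: Sequence[float] = DEFAULT_THETA
    #: optional per-biosample 4-vector of interval levels; biosamples not
    #: listed use ``theta_base`` (then their true effect vs control is zero).
    theta_profiles: Mapping[str, Sequence[float]] | None = None
    sigma_noise: float = 0.1
    sigma_well: float = 0.1
    sigma_plate_interval: float = 0.15
    #: sd of a per-(biosample, plate, interval) random level, emulating
    #: growth-replicate variability of the same line across plates; this is
    #: what keeps cross-plate residuals from vanishing as wells increase.
    sigma_interaction: float = 0.0
    outlier_well_rate: float = 0.0
    outlier_point_rate: float = 0.0
    outlier_well_magnitude: float = 0.5
    outlier_point_magnitude: float = 1.0
    non_responder_rate: float = 0.0
    control: str = "NHDF"
    layout: tuple[int, int] = (8, 12)
    blank_corners: bool = True
    with_cell_counts: bool = True
    seed: int = 0

    def validate(self) -> None:
        rows, cols = self.layout
        capacity = rows * cols - (4 if self.blank_corners else 0)
        needed = self.biosamples_per_plate * self.wells_per_biosample
        if needed > capacity:
            raise ValueError(
                f"{self.biosamples_per_plate} biosamples x "
                f"{self.wells_per_biosample} wells = {needed} exceeds plate "
                f"capacity {capacity}"
            )
        for s in (self.sigma_noise, self.sigma_well, self.sigma_plate_interval,
                  self.sigma_interaction):
            if s < 0:
                raise ValueError("noise standard deviations must be >= 0")
        for r in (self.outlier_well_rate, self.outlier_point_rate,
                  self.non_responder_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")

    @property
    def biosamples(self) -> list[str]:
        others = [f"S{k}" for k in range(1, self.biosamples_per_plate)]
        return [self.control] + others

    def theta_of(self, biosample: str) -> np.ndarray:
        if self.theta_profiles and biosample in self.theta_profiles:
            return np.asarray(self.theta_profiles[biosample], float)
        return np.asarray(self.theta_base, float)


@dataclass
class SimTruth:
    """Latent parameters and masks emitted alongside simulated data."""

    theta: dict[str, list[float]]
    beta: pd.DataFrame  # plate_id, well, beta (mean zero per plate)
    gamma: pd.DataFrame  # plate_id, interval, gamma
    well_outliers: list[tuple[str, str]]
    point_outliers: list[tuple[str, str, int]]
    non_responders: list[tuple[str, str]]
    mu_true: pd.DataFrame  # biosample, metric, mu (log-ratio diff vs control)
    config: SimConfig = field(repr=False, default=None)


def _well_names(layout: tuple[int, int]) -> list[str]:
    rows, cols = layout
    letters = string.ascii_uppercase[:rows]
    return [f"{r}{c}" for r in letters for c in range(1, cols + 1)]


def _corners(layout: tuple[int, int]) -> set[str]:
    rows, cols = layout
    letters = string.ascii_uppercase
    return {
        f"{letters[0]}1",
        f"{letters[0]}{cols}",
        f"{letters[rows - 1]}1",
        f"{letters[rows - 1]}{cols}",
    }


def _true_mu(config: SimConfig) -> pd.DataFrame:
    theta_c = config.theta_of(config.control)
    rows = []
    for bios in config.biosamples:
        if bios == config.control:
            continue
        theta_b = config.theta_of(bios)
        for metric, (a, b2) in DDTHETA_DEFS.items():
            rows.append(
                {
                    "biosample": bios,
                    "metric": metric,
                    "mu": float(
                        (theta_b[a - 1] - theta_b[b2 - 1])
                        - (theta_c[a - 1] - theta_c[b2 - 1])
                    ),
                }
            )
    return pd.DataFrame(rows)


def simulate_plates(config: SimConfig) -> tuple[PlateSet, SimTruth]:
    """Generate a multi-plate dataset plus ground truth.

    Wells are assigned to biosamples in row-major blocks over the non-corner
    wells; corners (if blank) carry a small medium-only OCR and are flagged
    ``is_blank``.  Well outliers shift every point of a well by +/- the well
    magnitude; point outliers shift single points; non-responder wells use a
    flat profile at the mean interval level (keeping well effect and noise).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_pts = 4 * config.points_per_interval
    intervals = np.repeat([1, 2, 3, 4], config.points_per_interval)
    time_points = np.arange(1, n_pts + 1)

    all_wells = _well_names(config.layout)
    corners = _corners(config.layout) if config.blank_corners else set()
    usable = [w for w in all_wells if w not in corners]

    records = []
    beta_rows = []
    gamma_rows = []
    well_out: list[tuple[str, str]] = []
    point_out: list[tuple[str, str, int]] = []
    nonresp: list[tuple[str, str]] = []

    for p in range(1, config.n_plates + 1):
        pid = f"P{p:02d}"
        gamma = rng.normal(0.0, config.sigma_plate_interval, size=4)
        for i in range(4):
            gamma_rows.append({"plate_id": pid, "interval": i + 1,
                               "gamma": float(gamma[i])})
        eta = {
            bios: (
                rng.normal(0.0, config.sigma_interaction, size=4)
                if config.sigma_interaction > 0
                else np.zeros(4)
            )
            for bios in config.biosamples
        }

        assignment: dict[str, str] = {}
        idx = 0
        for bios in config.biosamples:
            for _ in range(config.wells_per_biosample):
                assignment[usable[idx]] = bios
                idx += 1
        wells = list(assignment)

        beta = rng.normal(0.0, config.sigma_well, size=len(wells))
        beta -= beta.mean()
        for w, b in zip(wells, beta):
            beta_rows.append({"plate_id": pid, "well": w, "beta": float(b)})

        for w, b in zip(wells, beta):
            bios = assignment[w]
            theta = config.theta_of(bios)
            is_nonresp = rng.random() < config.non_responder_rate
            is_well_out = (not is_nonresp) and rng.random() < config.outlier_well_rate
            well_shift = 0.0
            if is_nonresp:
                nonresp.append((pid, w))
            if is_well_out:
                well_out.append((pid, w))
                well_shift = config.outlier_well_magnitude * rng.choice([-1.0, 1.0])
            eps = rng.normal(0.0, config.sigma_noise, size=n_pts)
            if is_nonresp:
                level = np.full(n_pts, theta.mean())
                logy = level + b + eps
            else:
                logy = (theta[intervals - 1] + b + gamma[intervals - 1]
                        + eta[bios][intervals - 1] + eps)
            logy = logy + well_shift
            if config.outlier_point_rate > 0 and not (is_nonresp or is_well_out):
                hits = rng.random(n_pts) < config.outlier_point_rate
                signs = rng.choice([-1.0, 1.0], size=n_pts)
                logy = logy + hits * signs * config.outlier_point_magnitude
                for t in time_points[hits]:
                    point_out.append((pid, w, int(t)))
            cell_count = (
                float(np.round(20000 * np.exp(b + rng.normal(0.0, 0.15))))
                if config.with_cell_counts
                else np.nan
            )
            for t, yv in zip(time_points, logy):
                records.append(
                    {
                        "plate_id": pid,
                        "well": w,
                        "biosample": bios,
                        "time_point": int(t),
                        "interval": int(intervals[t - 1]),
                        "ocr": float(np.exp(yv)),
                        "cell_count": cell_count,
                        "is_blank": False,
                    }
                )
        for w in sorted(corners):
            blank_log = rng.normal(np.log(2.0), 0.3, size=n_pts)
            for t, yv in zip(time_points, blank_log):
                records.append(
                    {
                        "plate_id": pid,
                        "well": w,
                        "biosample": "__blank__",
                        "time_point": int(t),
                        "interval": int(intervals[t - 1]),
                        "ocr": float(np.exp(yv)),
                        "cell_count": np.nan,
                        "is_blank": True,
                    }
                )

    data = pd.DataFrame.from_records(records)
    if not config.with_cell_counts:
        data = data.drop(columns=["cell_count"])
    plates = PlateSet(data=data, layout=config.layout, control=config.control)
    truth = SimTruth(
        theta={b: list(config.theta_of(b)) for b in config.biosamples},
        beta=pd.DataFrame(beta_rows),
        gamma=pd.DataFrame(gamma_rows),
        well_outliers=well_out,
        point_outliers=point_out,
        non_responders=nonresp,
        mu_true=_true_mu(config),
        config=config,
    )
    return plates, truth


def write_truth(truth: SimTruth, path) -> None:
    """Serialize ground truth to JSON."""
    payload = {
        "theta": truth.theta,
        "beta": truth.beta.to_dict("records"),
        "gamma": truth.gamma.to_dict("records"),
        "well_outliers": [list(t) for t in truth.well_outliers],
        "point_outliers": [list(t) for t in truth.point_outliers],
        "non_responders": [list(t) for t in truth.non_responders],
        "mu_true": truth.mu_true.to_dict("records"),
        "config": {
            k: (list(v) if isinstance(v, (tuple, np.ndarray)) else v)
            for k, v in asdict(truth.config).items()
            if k != "theta_profiles"
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
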