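"""Data model, long-format CSV I/O, and well-level quality control.

The central container is :class:`PlateSet`, a thin wrapper around a long-format
:class:`pandas.DataFrame` with one row per (plate, well, time point).  A
mitochondrial stress test produces, per well, a time series of oxygen
consumption rates (OCR, pmol/min) partitioned into four intervals by the
injections of oligomycin, FCCP and rotenone:

* interval 1 — basal respiration (before any injection),
* interval 2 — ATPase-independent respiration (after oligomycin),
* interval 3 — maximal, uncoupled respiration (after FCCP),
* interval 4 — non-mitochondrial respiration (after rotenone).

A well that responded to the treatments shows per-interval median OCR in the
strict order ``median(I3) > median(I1) > median(I2) > median(I4)``; wells that
do not are discarded by :func:`qc_filter_wells` before any model fitting.
Blank (medium-only) corner wells are carried in the data model, flagged via
``is_blank``, and never fitted.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "FormatConfig",
    "PlateSet",
    "QCReport",
    "read_plates",
    "write_plates",
    "qc_filter_wells",
    "parse_well",
    "DEFAULT_INTERVAL_MAP",
]


class FormatError(ValueError):
    """Raised when an input table cannot be interpreted as plate data."""


#: Default mapping of the 12 time points to the 4 injection-delimited
#: intervals (3 time points per interval).
DEFAULT_INTERVAL_MAP: dict[int, int] = {t: (t - 1) // 3 + 1 for t in range(1, 13)}

REQUIRED_COLUMNS = ("plate_id", "well", "biosample", "time_point", "ocr")
OPTIONAL_COLUMNS = ("interval", "cell_count", "is_blank")


@dataclass(frozen=True)
class FormatConfig:
    """Column naming and time-point → interval mapping for CSV ingestion.

    Parameters
    ----------
    columns
        Mapping from canonical column names (``plate_id``, ``well``, ...) to
        the names used in the file.  Identity by default.
    interval_map
        Mapping from time point (1-based) to interval (1..4).  Must be a
        non-decreasing step function of the time point.
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    interval_map: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_INTERVAL_MAP)
    )

    def resolve(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


def parse_well(well: str) -> tuple[str, int]:
    """Split a well label like ``"C6"`` into row letter and 1-based column."""
    well = str(well).strip()
    if not well or well[0].upper() not in string.ascii_uppercase:
        raise FormatError(f"malformed well label: {well!r}")
    row = well[0].upper()
    try:
        col = int(well[1:])
    except ValueError as exc:
        raise FormatError(f"malformed well label: {well!r}") from exc
    return row, col


@dataclass
class PlateSet:
    """A collection of plates in long format.

    Attributes
    ----------
    data
        One row per measurement with columns ``plate_id, well, biosample,
        time_point, interval, ocr, is_blank`` and optionally ``cell_count``.
    layout
        Plate dimensions as (rows, cols); (8, 12) for a 96-well plate.
    control
        Label of the control biosample (e.g. NHDF) seeded on every plate,
        required for cross-plate testing and plate-effect correction.
    load_report
        Records from ingestion (e.g. rows dropped for non-positive OCR).
    """

    data: pd.DataFrame
    layout: tuple[int, int] = (8, 12)
    control: str | None = None
    load_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"missing required columns: {missing}")
        if "is_blank" not in self.data.columns:
            self.data = self.data.assign(is_blank=False)
        if "interval" not in self.data.columns:
            raise FormatError("interval column must be present or assigned on load")

    @property
    def plate_ids(self) -> list[str]:
        return sorted(self.data["plate_id"].unique())

    def plate(self, plate_id: str) -> pd.DataFrame:
        """All rows of one plate."""
        return self.data[self.data["plate_id"] == plate_id]

    @property
    def assay_data(self) -> pd.DataFrame:
        """Non-blank measurements (the rows that enter any fit)."""
        return self.data[~self.data["is_blank"]]

    def with_data(self, data: pd.DataFrame) -> "PlateSet":
        return replace(self, data=data.reset_index(drop=True))


@dataclass
class QCReport:
    """Outcome of well-level quality control.

    The two discard categories are disjoint: manual exclusions are applied
    first, the interval-ordering test runs on the remaining wells.
    """

    discarded_order_violation: list[tuple[str, str]] = field(default_factory=list)
    discarded_manual: list[tuple[str, str]] = field(default_factory=list)
    n_assay_wells: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def fractions(self) -> dict[str, float]:
        n = self.n_assay_wells
        return {
            "order_violation": len(self.discarded_order_violation) / n if n else 0.0,
            "manual": len(self.discarded_manual) / n if n else 0.0,
        }


def _assign_intervals(
    df: pd.DataFrame, interval_map: Mapping[int, int]
) -> pd.DataFrame:
    mapped = df["time_point"].map(interval_map)
    if mapped.isna().any():
        bad = sorted(df.loc[mapped.isna(), "time_point"].unique())
        raise FormatError(f"time points {bad} not covered by interval mapping")
    if "interval" in df.columns:
        mismatch = df["interval"].astype(int) != mapped.astype(int)
        if mismatch.any():
            row = df[mismatch].iloc[0]
            raise FormatError(
                "interval column inconsistent with time-point mapping, e.g. "
                f"plate {row['plate_id']} well {row['well']} t={row['time_point']} "
                f"has interval {row['interval']} (expected {mapped[mismatch].iloc[0]})"
            )
    return df.assign(interval=mapped.astype(int))


def read_plates(
    path,
    format_config: FormatConfig | None = None,
    control: str | None = None,
    layout: tuple[int, int] = (8, 12),
) -> PlateSet:
    """Read a long-format OCR CSV into a :class:`PlateSet`.

    Intervals are assigned from time points according to the configured
    mapping (default: points 1–3 → interval 1, ..., 10–12 → interval 4); if
    the file carries an ``interval`` column it is validated against the
    mapping.  Non-positive OCR in a non-blank well is excluded with a warning
    (its log is undefined) and listed in ``load_report``.
    """
    cfg = format_config or FormatConfig()
    raw = pd.read_csv(path)
    rename = {cfg.resolve(c): c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS
              if cfg.resolve(c) in raw.columns}
    df = raw.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required columns: {missing}")
    df = df.copy()
    df["time_point"] = df["time_point"].astype(int)
    df["ocr"] = pd.to_numeric(df["ocr"], errors="raise").astype(float)
    if "is_blank" not in df.columns:
        df["is_blank"] = False
    df["is_blank"] = df["is_blank"].astype(bool)
    df = _assign_intervals(df, cfg.interval_map)
    for well in df["well"].unique():
        parse_well(well)  # validates coordinate convention

    bad = (~df["is_blank"]) & ~(df["ocr"] > 0)
    dropped: list[dict] = []
    if bad.any():
        dropped = df.loc[bad, ["plate_id", "well", "time_point", "ocr"]].to_dict(
            "records"
        )
        warnings.warn(
            f"excluding {int(bad.sum())} non-blank records with non-positive OCR",
            stacklevel=2,
        )
        df = df[~bad]
    cols = ["plate_id", "well", "biosample", "time_point", "interval", "ocr"]
    if "cell_count" in df.columns:
        cols.append("cell_count")
    cols.append("is_blank")
    return PlateSet(
        data=df[cols].reset_index(drop=True),
        layout=layout,
        control=control,
        load_report={"dropped_nonpositive": dropped},
    )


def write_plates(plates: PlateSet, path) -> None:
    """Write a :class:`PlateSet` to the canonical long CSV."""
    plates.data.to_csv(path, index=False)


def _ordering_ok(medians: pd.Series) -> bool:
    """Strict expected response: med(I3) > med(I1) > med(I2) > med(I4)."""
    try:
        m1, m2, m3, m4 = (medians.get(i, np.nan) for i in (1, 2, 3, 4))
    except Exception:  # pragma: no cover - defensive
        return False
    if any(np.isnan(m) for m in (m1, m2, m3, m4)):
        return False
    return m3 > m1 > m2 > m4


def qc_filter_wells(
    plates: PlateSet,
    manual_exclusions: Iterable[tuple[str, str]] | None = None,
) -> tuple[PlateSet, QCReport]:
    """Remove wells that did not respond as expected to the injections.

    A well is retained only if its per-interval median OCR satisfies the
    strict ordering median(I3) > median(I1) > median(I2) > median(I4); ties
    count as violations.  ``manual_exclusions`` models microscope-based
    removal of contaminated/detached wells and is applied first, so the two
    discard categories in the report are disjoint.  Blank wells are untouched.
    """
    data = plates.data
    assay = data[~data["is_blank"]]
    report = QCReport(n_assay_wells=assay.groupby(["plate_id", "well"]).ngroups)

    manual = {(str(p), str(w)) for p, w in (manual_exclusions or [])}
    keys = list(zip(assay["plate_id"].astype(str), assay["well"].astype(str)))
    manual_mask = pd.Series([k in manual for k in keys], index=assay.index)
    report.discarded_manual = sorted(
        set(k for k, m in zip(keys, manual_mask) if m)
    )
    remaining = assay[~manual_mask]

    med = remaining.groupby(["plate_id", "well", "interval"])["ocr"].median()
    violations: list[tuple[str, str]] = []
    for (pid, well), sub in med.groupby(level=[0, 1]):
        if not _ordering_ok(sub.droplevel([0, 1])):
            violations.append((str(pid), str(well)))
    report.discarded_order_violation = sorted(violations)

    removed = manual | set(violations)
    keep_mask = data["is_blank"] | ~pd.Series(
        list(zip(data["plate_id"].astype(str), data["well"].astype(str))),
        index=data.index,
    ).isin(removed)
    filtered = data[keep_mask]

    # warn if a (plate, biosample) lost all its wells
    before = assay.groupby(["plate_id", "biosample"]).ngroups
    after_assay = filtered[~filtered["is_blank"]]
    kept = set(map(tuple, after_assay[["plate_id", "biosample"]].drop_duplicates()
                   .itertuples(index=False)))
    for pid, bios in map(tuple, assay[["plate_id", "biosample"]].drop_duplicates()
                         .itertuples(index=False)):
        if (pid, bios) not in kept:
            msg = f"biosample {bios!r} lost all wells on plate {pid!r} during QC"
            report.warnings.append(msg)
            warnings.warn(msg, stacklevel=2)
    del before
    return plates.with_data(filtered), report
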