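"""Observed growth/senescence time series and their CSV round trip.

A :class:`GrowthDataset` holds, for one cell subpopulation, the observation
days, cumulative population doublings (CPD, ``log2`` of the cell count
relative to day 0) and/or the fraction of senescence-marker-positive
(SA-beta-gal) cells, with optional per-point standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GrowthDataset",
    "DatasetValidationError",
    "read_growth_dataset",
    "write_growth_dataset",
]

_COLUMNS = ("day", "cpd", "senescent_fraction", "sd_cpd", "sd_fraction")


class DatasetValidationError(ValueError):
    """A dataset file or array failed validation."""


def _opt(x) -> np.ndarray | None:
    if x is None:
        return None
    arr = np.asarray(x, dtype=float)
    return None if arr.size == 0 else arr


@dataclass
class GrowthDataset:
    """Time series of growth and senescence observations for one subpopulation."""

    label: str
    days: np.ndarray
    cpd: np.ndarray | None = None
    senescent_fraction: np.ndarray | None = None
    sd_cpd: np.ndarray | None = None
    sd_fraction: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.cpd = _opt(self.cpd)
        self.senescent_fraction = _opt(self.senescent_fraction)
        self.sd_cpd = _opt(self.sd_cpd)
        self.sd_fraction = _opt(self.sd_fraction)
        if self.days.ndim != 1 or self.days.size == 0:
            raise DatasetValidationError("days must be a non-empty 1-D vector")
        if np.any(np.diff(self.days) <= 0):
            raise DatasetValidationError("days must be strictly increasing")
        for name in ("cpd", "senescent_fraction", "sd_cpd", "sd_fraction"):
            v = getattr(self, name)
            if v is not None and v.shape != self.days.shape:
                raise DatasetValidationError(
                    f"{name} must match days in length "
                    f"({v.shape[0]} vs {self.days.shape[0]})"
                )
        if self.cpd is None and self.senescent_fraction is None:
            raise DatasetValidationError(
                "dataset needs at least one of cpd or senescent_fraction"
            )
        frac = self.senescent_fraction
        if frac is not None:
            bad = np.flatnonzero((frac < 0) | (frac > 1))
            if bad.size:
                raise DatasetValidationError(
                    f"senescent_fraction outside [0, 1] at rows {bad.tolist()}"
                )

    @property
    def n_points(self) -> int:
        n = 0
        if self.cpd is not None:
            n += self.cpd.size
        if self.senescent_fraction is not None:
            n += self.senescent_fraction.size
        return n

    def to_frame(self) -> pd.DataFrame:
        data = {"day": self.days}
        for name in ("cpd", "senescent_fraction", "sd_cpd", "sd_fraction"):
            v = getattr(self, name)
            if v is not None:
                data[name] = v
        return pd.DataFrame(data)


def read_growth_dataset(
    path, label: str | None = None, percent_fraction: bool = False
) -> GrowthDataset:
    """Read and validate a growth dataset CSV.

    Expected header: ``day,cpd,senescent_fraction[,sd_cpd,sd_fraction]``;
    every column but ``day`` is optional.  Fractions must lie in [0, 1]
    unless ``percent_fraction`` declares the column to be on the 0-100
    scale, in which case it is divided by 100 on input.  Validation errors
    name the offending (0-based data) rows.
    """
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - passthrough message
        raise DatasetValidationError(f"cannot parse {path}: {exc}") from exc
    if "day" not in frame.columns:
        raise DatasetValidationError(f"{path}: missing required column 'day'")
    unknown = set(frame.columns) - set(_COLUMNS)
    if unknown:
        raise DatasetValidationError(f"{path}: unknown columns {sorted(unknown)}")
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = np.flatnonzero(coerced.isna() & frame[col].notna())
        if bad.size:
            raise DatasetValidationError(
                f"{path}: unparseable values in column '{col}' at rows {bad.tolist()}"
            )
        frame[col] = coerced
    if frame["day"].isna().any():
        bad = np.flatnonzero(frame["day"].isna())
        raise DatasetValidationError(f"{path}: missing day at rows {bad.tolist()}")
    dup = frame["day"].duplicated()
    if dup.any():
        raise DatasetValidationError(
            f"{path}: duplicate days at rows {np.flatnonzero(dup).tolist()}"
        )
    frame = frame.sort_values("day").reset_index(drop=True)

    def col(name):
        if name not in frame.columns or frame[name].isna().all():
            return None
        return frame[name].to_numpy(dtype=float)

    frac = col("senescent_fraction")
    sd_frac = col("sd_fraction")
    if frac is not None and percent_fraction:
        frac = frac / 100.0
        if sd_frac is not None:
            sd_frac = sd_frac / 100.0
    return GrowthDataset(
        label=label if label is not None else str(path),
        days=frame["day"].to_numpy(dtype=float),
        cpd=col("cpd"),
        senescent_fraction=frac,
        sd_cpd=col("sd_cpd"),
        sd_fraction=sd_frac,
    )


def write_growth_dataset(dataset: GrowthDataset, path) -> None:
    """Write a dataset as CSV (inverse of :func:`read_growth_dataset`)."""
    dataset.to_frame().to_csv(path, index=False)
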