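"""Deformability analysis: normalized area curves and their pressure slopes.

A trapped cell (or hydrogel sphere) projected onto the focal plane grows in
area as the acoustic trapping pressure is stepped up.  The deformability
index used throughout this package is the ordinary-least-squares slope of
the baseline-normalized projected area against acoustic pressure (units:
per MPa).  Softer objects deform more and have larger slopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "DeformationSeries",
    "DeformabilityFit",
    "GroupDeformability",
    "normalize",
    "fit_slope",
    "summarize_group",
    "read_area_table",
    "write_fit_table",
]


@dataclass
class DeformationSeries:
    """One sample's projected areas over an increasing pressure ramp.

    Parameters
    ----------
    sample_id, group_label
        Identifiers carried through to fit tables and reports.
    pressures_mpa
        Acoustic pressure at each step, strictly increasing, starting at 0
        (the trap-off baseline frame).
    areas_um2
        Projected area at each step in µm².  For pre-normalized published
        series these may already be dimensionless ratios; the slope is
        invariant to the overall scale.
    normalized_areas
        ``areas_um2 / areas_um2[0]``; filled by :func:`normalize`.
    truncated
        True when the ramp ended early (e.g. the object burst mid-ramp) and
        the series carries fewer steps than its group's full ramp.
    metadata
        Free-form provenance (synthetic ground truth, source paths, ...).
    """

    sample_id: str
    group_label: str
    pressures_mpa: np.ndarray
    areas_um2: np.ndarray
    normalized_areas: np.ndarray | None = None
    truncated: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pressures_mpa = np.asarray(self.pressures_mpa, dtype=float)
        self.areas_um2 = np.asarray(self.areas_um2, dtype=float)
        if self.pressures_mpa.ndim != 1 or self.pressures_mpa.shape != self.areas_um2.shape:
            raise ValidationError(
                f"{self.sample_id}: pressures and areas must be equal-length 1-D arrays"
            )
        if self.pressures_mpa.size == 0:
            raise ValidationError(f"{self.sample_id}: empty series")
        if self.pressures_mpa[0] != 0.0:
            raise ValidationError(
                f"{self.sample_id}: first pressure must be 0 (baseline), got "
                f"{self.pressures_mpa[0]!r}"
            )
        if np.any(np.diff(self.pressures_mpa) <= 0):
            raise ValidationError(f"{self.sample_id}: pressures must be strictly increasing")
        if np.any(self.areas_um2 <= 0):
            raise ValidationError(f"{self.sample_id}: areas must be positive")
        if self.normalized_areas is not None:
            self.normalized_areas = np.asarray(self.normalized_areas, dtype=float)

    @property
    def n_steps(self) -> int:
        return int(self.pressures_mpa.size)


@dataclass(frozen=True)
class DeformabilityFit:
    """OLS fit of normalized area on pressure for one sample."""

    sample_id: str
    group_label: str
    slope: float  # per MPa
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValidationError(f"{self.sample_id}: a reported fit needs >=3 points")
        if not (-1e-9 <= self.r_squared <= 1 + 1e-9):
            raise ValidationError(f"{self.sample_id}: R² out of [0, 1]: {self.r_squared}")


@dataclass(frozen=True)
class GroupDeformability:
    """Per-group summary of per-sample deformability slopes."""

    group_label: str
    per_sample_fits: tuple[DeformabilityFit, ...]
    slope_mean: float
    slope_sd: float
    single_sample: bool = False

    @property
    def n_samples(self) -> int:
        return len(self.per_sample_fits)

    @property
    def slopes(self) -> np.ndarray:
        return np.array([f.slope for f in self.per_sample_fits])


def normalize(series: DeformationSeries) -> DeformationSeries:
    """Divide every area by the zero-pressure baseline area.

    The baseline (trap-off) frame anchors the curve at exactly 1, matching
    how deformation ramps are reported: the ratio at 0 MPa is 1 by
    construction and grows with pressure.
    """
    if series.areas_um2[0] <= 0:
        raise ValidationError(f"{series.sample_id}: non-positive baseline area")
    norm = series.areas_um2 / series.areas_um2[0]
    return replace(series, normalized_areas=norm)


def fit_slope(series: DeformationSeries) -> DeformabilityFit:
    """Fit normalized area vs pressure by OLS with a free intercept.

    The baseline point is included in the regression.  Normalization is
    applied first if the series does not yet carry normalized areas.
    """
    if series.normalized_areas is None:
        series = normalize(series)
    x = series.pressures_mpa
    y = series.normalized_areas
    if x.size < 3:
        raise ValidationError(
            f"{series.sample_id}: need >=3 points to fit a slope, got {x.size}"
        )
    if np.ptp(x) == 0:
        raise ValidationError(f"{series.sample_id}: zero pressure variance")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return DeformabilityFit(
        sample_id=series.sample_id,
        group_label=series.group_label,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        n_points=int(x.size),
    )


def summarize_group(fits: Sequence[DeformabilityFit], label: str) -> GroupDeformability:
    """Arithmetic mean and sample standard deviation (ddof=1) of slopes."""
    if len(fits) == 0:
        raise ValidationError(f"group {label!r}: no fits to summarize")
    slopes = np.array([f.slope for f in fits])
    single = slopes.size == 1
    sd = 0.0 if single else float(np.std(slopes, ddof=1))
    return GroupDeformability(
        group_label=label,
        per_sample_fits=tuple(fits),
        slope_mean=float(slopes.mean()),
        slope_sd=sd,
        single_sample=single,
    )


def read_area_table(path: str | Path) -> list[DeformationSeries]:
    """Read a long-format area table (sample_id, group, pressure_mpa, area_um2)."""
    df = pd.read_csv(path)
    required = {"sample_id", "group", "pressure_mpa", "area_um2"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    out: list[DeformationSeries] = []
    for (sid, grp), sub in df.groupby(["sample_id", "group"], sort=False):
        sub = sub.sort_values("pressure_mpa")
        out.append(
            DeformationSeries(
                sample_id=str(sid),
                group_label=str(grp),
                pressures_mpa=sub["pressure_mpa"].to_numpy(),
                areas_um2=sub["area_um2"].to_numpy(),
            )
        )
    return out


def write_fit_table(fits: Iterable[DeformabilityFit], path: str | Path) -> pd.DataFrame:
    """Write per-sample fits as CSV; returns the DataFrame written."""
    fits = list(fits)
    df = pd.DataFrame(
        {
            "sample_id": [f.sample_id for f in fits],
            "group": [f.group_label for f in fits],
            "slope": [f.slope for f in fits],
            "intercept": [f.intercept for f in fits],
            "r2": [f.r_squared for f in fits],
            "n_points": [f.n_points for f in fits],
        }
    )
    df.to_csv(path, index=False)
    return df
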