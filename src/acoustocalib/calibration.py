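"""Slope→Young's-modulus calibration using hydrogel-sphere surrogates.

Agarose hydrogel spheres (AHSs) of graded concentration are measured twice:
their deformability slope under the acoustic trap, and their Young's modulus
by micropipette aspiration.  The paired (slope, E) points form a monotone
calibration curve — stiffer spheres deform less — and a cell's slope is
converted to an absolute modulus by interpolating on that curve.

Interpolation is piecewise linear in (slope, E) by default; a log-E variant
is available for sensitivity analysis.  No extrapolation: outside the knot
range the surrogate calibration is unsupported by data and the query is
refused.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .deformability import GroupDeformability
from .errors import CalibrationRangeError, ValidationError

__all__ = [
    "CalibrationKnot",
    "CalibrationCurve",
    "CellModulus",
    "build_curve",
    "interpolate_modulus",
    "cell_modulus",
]


@dataclass(frozen=True)
class CalibrationKnot:
    label: str
    slope: float  # per MPa
    E_kpa: float
    E_sd_kpa: float = 0.0


@dataclass(frozen=True)
class CalibrationCurve:
    """Ordered (slope, E) knots; slope strictly increasing, E strictly decreasing."""

    knots: tuple[CalibrationKnot, ...]
    scheme: str = "linear"  # "linear" | "log"

    def __post_init__(self) -> None:
        if len(self.knots) < 2:
            raise ValidationError("a calibration curve needs >=2 knots")
        slopes = self.slopes
        if np.any(np.diff(slopes) <= 0):
            raise ValidationError("knot slopes must be strictly increasing")
        E = self.moduli_kpa
        bad = np.nonzero(np.diff(E) >= 0)[0]
        if bad.size:
            i = int(bad[0])
            raise ValidationError(
                "modulus must decrease as slope increases; violated between "
                f"{self.knots[i].label!r} (E={E[i]} kPa) and "
                f"{self.knots[i + 1].label!r} (E={E[i + 1]} kPa)"
            )
        if self.scheme not in ("linear", "log"):
            raise ValidationError(f"unknown interpolation scheme {self.scheme!r}")

    @property
    def slopes(self) -> np.ndarray:
        return np.array([k.slope for k in self.knots])

    @property
    def moduli_kpa(self) -> np.ndarray:
        return np.array([k.E_kpa for k in self.knots])

    @property
    def slope_range(self) -> tuple[float, float]:
        return float(self.knots[0].slope), float(self.knots[-1].slope)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "scheme": self.scheme,
            "knots": [
                {"label": k.label, "slope": k.slope, "E_kpa": k.E_kpa, "E_sd_kpa": k.E_sd_kpa}
                for k in self.knots
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationCurve":
        payload = json.loads(Path(path).read_text())
        knots = tuple(
            CalibrationKnot(
                label=k["label"],
                slope=k["slope"],
                E_kpa=k["E_kpa"],
                E_sd_kpa=k.get("E_sd_kpa", 0.0),
            )
            for k in payload["knots"]
        )
        return cls(knots=knots, scheme=payload.get("scheme", "linear"))


@dataclass(frozen=True)
class CellModulus:
    """Interpolated Young's modulus for one cell group."""

    group_label: str
    E_mean_kpa: float
    E_sd_kpa: float
    per_sample_E_kpa: tuple[float, ...]
    out_of_range_count: int = 0

    def __post_init__(self) -> None:
        if self.E_mean_kpa <= 0:
            raise ValidationError(f"{self.group_label}: non-positive modulus")


def build_curve(
    ahs_slopes: Sequence[tuple[str, float]],
    ahs_moduli: Sequence[tuple[str, float, float]],
    scheme: str = "linear",
) -> CalibrationCurve:
    """Join slope and modulus measurements by surrogate label into a curve.

    Parameters
    ----------
    ahs_slopes
        ``(label, slope_per_mpa)`` pairs from the deformability assay.
    ahs_moduli
        ``(label, E_kpa, E_sd_kpa)`` triples from aspiration measurements.
    """
    slope_by_label = dict(ahs_slopes)
    moduli_by_label = {lab: (E, sd) for lab, E, sd in ahs_moduli}
    if len(slope_by_label) != len(ahs_slopes) or len(moduli_by_label) != len(ahs_moduli):
        raise ValidationError("duplicate surrogate labels")
    if set(slope_by_label) != set(moduli_by_label):
        only_s = sorted(set(slope_by_label) - set(moduli_by_label))
        only_m = sorted(set(moduli_by_label) - set(slope_by_label))
        raise ValidationError(
            f"slope/modulus label mismatch: slopes-only {only_s}, moduli-only {only_m}"
        )
    knots = sorted(
        (
            CalibrationKnot(
                label=lab,
                slope=float(slope_by_label[lab]),
                E_kpa=float(moduli_by_label[lab][0]),
                E_sd_kpa=float(moduli_by_label[lab][1]),
            )
            for lab in slope_by_label
        ),
        key=lambda k: k.slope,
    )
    return CalibrationCurve(knots=tuple(knots), scheme=scheme)


def interpolate_modulus(curve: CalibrationCurve, slope: float) -> float:
    """Map a deformability slope to a modulus (kPa) on the curve.

    Exact knot slopes return the knot modulus; queries outside the knot
    range raise :class:`CalibrationRangeError` (callers that want clamping
    must clamp explicitly).
    """
    lo, hi = curve.slope_range
    if not (lo <= slope <= hi):
        raise CalibrationRangeError(
            f"slope {slope:.4g} outside calibrated range [{lo:.4g}, {hi:.4g}]; "
            "extrapolation is refused"
        )
    xs = curve.slopes
    if curve.scheme == "log":
        return float(np.exp(np.interp(slope, xs, np.log(curve.moduli_kpa))))
    return float(np.interp(slope, xs, curve.moduli_kpa))


def cell_modulus(group: GroupDeformability, curve: CalibrationCurve) -> CellModulus:
    """Interpolate every per-sample slope of a group and summarize.

    Samples whose slopes fall outside the calibrated range are counted,
    excluded from the mean/sd, and reported via a warning; if every sample
    is out of range the conversion fails.
    """
    per_E: list[float] = []
    out_of_range = 0
    for fit in group.per_sample_fits:
        try:
            per_E.append(interpolate_modulus(curve, fit.slope))
        except CalibrationRangeError:
            out_of_range += 1
    if not per_E:
        raise CalibrationRangeError(
            f"group {group.group_label!r}: all {group.n_samples} sample slopes "
            "outside the calibrated range"
        )
    if out_of_range:
        warnings.warn(
            f"group {group.group_label!r}: {out_of_range} of {group.n_samples} "
            "samples outside the calibrated slope range were excluded",
            stacklevel=2,
        )
    E = np.array(per_E)
    sd = float(np.std(E, ddof=1)) if E.size > 1 else 0.0
    return CellModulus(
        group_label=group.group_label,
        E_mean_kpa=float(E.mean()),
        E_sd_kpa=sd,
        per_sample_E_kpa=tuple(float(v) for v in E),
        out_of_range_count=out_of_range,
    )
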