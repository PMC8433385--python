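"""Young's modulus from micropipette aspiration via the punch model.

A sphere held at a micropipette tip is aspirated by suction pressure ΔP,
pulling a tongue of length D into the pipette of inner radius R.  For a
continuous, isotropic, homogeneous elastic sphere the punch model gives

    E = 3 R ΔP φ(η) / (2 π D)

where φ(η) is a wall function set by pipette geometry (η = inner/outer
radius ratio).  φ is treated here as a configured scalar; 2.014 is the
default (the mean over the pipette geometries used to calibrate the
hydrogel-sphere moduli; ~2.05 is the common literature value and may be
set instead).

Since R and D both enter as lengths, expressing them in the same unit
(µm here) leaves E in the unit of ΔP (Pa).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "MATConfig",
    "AspirationTrace",
    "ModulusEstimate",
    "young_modulus_point",
    "fit_young_modulus",
    "summarize_moduli",
    "read_aspiration_table",
]

#: default wall function value φ(η) for η in the realistic 0.4–0.6 range
DEFAULT_PHI = 2.014


@dataclass(frozen=True)
class MATConfig:
    """Micropipette geometry for the aspiration measurement.

    ``eta`` (inner/outer pipette radius ratio) is recorded for provenance
    only; the wall function φ(η) itself is supplied as a number because the
    punch-model functional form is not part of this package.
    """

    pipette_inner_radius_um: float
    phi: float = DEFAULT_PHI
    eta: float | None = None
    allow_unusual_phi: bool = False

    def __post_init__(self) -> None:
        if self.pipette_inner_radius_um <= 0:
            raise ValidationError("pipette inner radius must be positive")
        if not self.allow_unusual_phi and not (1.9 <= self.phi <= 2.2):
            raise ValidationError(
                f"phi={self.phi} outside the realistic punch-model range [1.9, 2.2]; "
                "pass allow_unusual_phi=True to override"
            )
        if self.eta is not None and not (0.0 < self.eta < 1.0):
            raise ValidationError("eta must lie in (0, 1)")


@dataclass
class AspirationTrace:
    """Suction-pressure steps and aspirated lengths for one sphere."""

    sphere_id: str
    group_label: str
    config: MATConfig
    pressure_steps_pa: np.ndarray
    aspirated_lengths_um: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pressure_steps_pa = np.asarray(self.pressure_steps_pa, dtype=float)
        self.aspirated_lengths_um = np.asarray(self.aspirated_lengths_um, dtype=float)
        if self.pressure_steps_pa.shape != self.aspirated_lengths_um.shape:
            raise ValidationError(f"{self.sphere_id}: step arrays differ in length")
        if np.any(self.pressure_steps_pa < 0):
            raise ValidationError(f"{self.sphere_id}: negative suction pressure")
        if np.any(np.diff(self.pressure_steps_pa) <= 0):
            raise ValidationError(f"{self.sphere_id}: pressures must be increasing")
        if np.any(self.aspirated_lengths_um < 0):
            raise ValidationError(f"{self.sphere_id}: negative aspirated length")


@dataclass(frozen=True)
class ModulusEstimate:
    """Young's modulus for one sphere, with the estimator recorded."""

    sphere_id: str
    group_label: str
    E_pa: float
    E_sd_pa: float
    n: int
    method: str  # "regression" | "pointwise"
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if self.E_pa <= 0:
            raise ValidationError(f"{self.sphere_id}: non-positive modulus")
        if self.E_sd_pa < 0:
            raise ValidationError(f"{self.sphere_id}: negative modulus sd")

    @property
    def E_kpa(self) -> float:
        return self.E_pa / 1000.0


def young_modulus_point(
    R_um: float, delta_p_pa: float, D_um: float, phi: float = DEFAULT_PHI
) -> float:
    """Single-step punch-model modulus E = 3 R ΔP φ / (2 π D), in Pa."""
    if R_um <= 0:
        raise ValidationError("pipette radius must be positive")
    if delta_p_pa <= 0:
        raise ValidationError("pressure difference must be positive")
    if D_um <= 0:
        raise ValidationError("no aspiration: aspirated length must be positive")
    return 3.0 * R_um * delta_p_pa * phi / (2.0 * np.pi * D_um)


def fit_young_modulus(trace: AspirationTrace, method: str = "regression") -> ModulusEstimate:
    """Estimate E from a multi-step trace.

    regression (default)
        The model implies D = (3 R φ / 2πE) ΔP, a line through the origin;
        the slope is fit by least squares through the origin and inverted:
        E = 3 R φ / (2π slope).  R² is reported against the origin-line
        prediction so that flat (non-proportional) traces flag a poor fit.
    pointwise
        The single-step formula evaluated at every usable step; mean and
        sample sd over steps are reported.
    """
    usable = (trace.pressure_steps_pa > 0) & (trace.aspirated_lengths_um > 0)
    dp = trace.pressure_steps_pa[usable]
    d = trace.aspirated_lengths_um[usable]
    if dp.size < 3:
        raise ValidationError(
            f"{trace.sphere_id}: need >=3 steps with positive pressure and "
            f"aspiration, got {dp.size}"
        )
    R = trace.config.pipette_inner_radius_um
    phi = trace.config.phi
    if method == "regression":
        slope = float((dp @ d) / (dp @ dp))  # µm per Pa, through origin
        if slope <= 0:
            raise ValidationError(f"{trace.sphere_id}: non-physical (non-positive) slope")
        resid = d - slope * dp
        ss_res = float(resid @ resid)
        # uncentered R² — the model has no intercept, so a flat trace
        # (aspiration not proportional to suction) must score poorly
        ss_tot = float(d @ d)
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        E = 3.0 * R * phi / (2.0 * np.pi * slope)
        # delta-method sd from the slope's standard error
        dof = dp.size - 1
        slope_var = ss_res / dof / float(dp @ dp) if dof > 0 else 0.0
        E_sd = E * np.sqrt(slope_var) / slope
        return ModulusEstimate(
            sphere_id=trace.sphere_id,
            group_label=trace.group_label,
            E_pa=float(E),
            E_sd_pa=float(E_sd),
            n=int(dp.size),
            method="regression",
            r_squared=r2,
        )
    elif method == "pointwise":
        E_steps = np.array(
            [young_modulus_point(R, p, length, phi) for p, length in zip(dp, d)]
        )
        return ModulusEstimate(
            sphere_id=trace.sphere_id,
            group_label=trace.group_label,
            E_pa=float(E_steps.mean()),
            E_sd_pa=float(np.std(E_steps, ddof=1)) if E_steps.size > 1 else 0.0,
            n=int(E_steps.size),
            method="pointwise",
        )
    raise ValidationError(f"unknown method {method!r}")


def summarize_moduli(
    estimates: Sequence[ModulusEstimate], label: str
) -> tuple[float, float, bool]:
    """Group mean and sample sd (ddof=1) of per-sphere moduli, in Pa.

    Returns ``(mean, sd, single_sample)``; sd is 0 with the flag set when
    only one estimate is available.
    """
    if len(estimates) == 0:
        raise ValidationError(f"group {label!r}: no modulus estimates")
    E = np.array([e.E_pa for e in estimates])
    single = E.size == 1
    sd = 0.0 if single else float(np.std(E, ddof=1))
    return float(E.mean()), sd, single


def read_aspiration_table(
    path: str | Path, config: MATConfig
) -> list[AspirationTrace]:
    """Read long-format traces (sphere_id, group, step, delta_p_pa, aspirated_len_um)."""
    df = pd.read_csv(path)
    required = {"sphere_id", "group", "step", "delta_p_pa", "aspirated_len_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    out: list[AspirationTrace] = []
    for (sid, grp), sub in df.groupby(["sphere_id", "group"], sort=False):
        sub = sub.sort_values("step")
        out.append(
            AspirationTrace(
                sphere_id=str(sid),
                group_label=str(grp),
                config=config,
                pressure_steps_pa=sub["delta_p_pa"].to_numpy(),
                aspirated_lengths_um=sub["aspirated_len_um"].to_numpy(),
            )
        )
    return out
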