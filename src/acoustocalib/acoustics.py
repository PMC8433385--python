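"""Focused-transducer utilities: lateral beam width and the drive table.

The trapping transducer is a press-focused single element.  Two small
computations support the deformability assay:

* the theoretical lateral beam width LBW = N c / (D f), with N the focal
  distance, c the sound speed, D the element (aperture) diameter and f the
  excitation frequency — used to confirm the focal spot is subcellular;
* the hydrophone-calibrated mapping from peak-to-peak drive voltage to
  focal acoustic pressure, used to label deformation steps in MPa.

The shipped default spec describes a 50 MHz, f-number 0.8 device (4 mm
focal distance, 5 mm aperture).  The same element driven at 70 MHz gives a
~17 µm spot, small enough to target one cell; the drive voltages at which
membrane disruption (63.2 Vpp) and dish marking (69.5 Vpp) were observed
are kept as documented constants only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError

__all__ = [
    "TransducerSpec",
    "lateral_beam_width",
    "pressure_from_voltage",
    "default_transducer",
    "MEMBRANE_DISRUPTION_VPP",
    "DISH_DAMAGE_VPP",
]

#: drive voltage at which single-cell membrane disruption was observed (70 MHz)
MEMBRANE_DISRUPTION_VPP = 63.2
#: drive voltage at which the focal spot marked the Petri dish (70 MHz)
DISH_DAMAGE_VPP = 69.5


@dataclass(frozen=True)
class TransducerSpec:
    """Geometry, drive frequency and calibrated voltage→pressure table."""

    center_frequency_hz: float
    element_diameter_m: float
    focal_distance_m: float
    sound_speed_m_s: float = 1500.0  # water at room temperature
    voltage_pressure_table: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for name in (
            "center_frequency_hz",
            "element_diameter_m",
            "focal_distance_m",
            "sound_speed_m_s",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        table = self.voltage_pressure_table
        if table:
            v = np.array([row[0] for row in table])
            p = np.array([row[1] for row in table])
            if v[0] != 0.0 or p[0] != 0.0:
                raise ValidationError("voltage→pressure table must start at (0, 0)")
            if np.any(np.diff(v) <= 0):
                raise ValidationError("table voltages must be strictly increasing")
            if np.any(np.diff(p) < 0):
                raise ValidationError("table pressures must be non-decreasing")

    @property
    def f_number(self) -> float:
        return self.focal_distance_m / self.element_diameter_m

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "center_frequency_hz": self.center_frequency_hz,
                    "element_diameter_m": self.element_diameter_m,
                    "focal_distance_m": self.focal_distance_m,
                    "sound_speed_m_s": self.sound_speed_m_s,
                    "voltage_pressure_table": [list(row) for row in self.voltage_pressure_table],
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TransducerSpec":
        d = json.loads(Path(path).read_text())
        return cls(
            center_frequency_hz=d["center_frequency_hz"],
            element_diameter_m=d["element_diameter_m"],
            focal_distance_m=d["focal_distance_m"],
            sound_speed_m_s=d.get("sound_speed_m_s", 1500.0),
            voltage_pressure_table=tuple(
                (float(v), float(p)) for v, p in d.get("voltage_pressure_table", [])
            ),
        )


def default_transducer() -> TransducerSpec:
    """The 50 MHz trapping device with its calibrated six-step drive table."""
    return TransducerSpec(
        center_frequency_hz=50e6,
        element_diameter_m=5e-3,
        focal_distance_m=4e-3,
        sound_speed_m_s=1500.0,
        voltage_pressure_table=(
            (0.00, 0.000),
            (4.74, 0.234),
            (9.48, 0.431),
            (14.22, 0.627),
            (18.96, 0.824),
            (23.70, 1.000),
        ),
    )


def lateral_beam_width(spec: TransducerSpec, frequency_hz: float | None = None) -> float:
    """Theoretical lateral beam width N·c/(D·f) in metres.

    ``frequency_hz`` overrides the spec's center frequency, e.g. to evaluate
    the focal spot when the same element is driven at a harmonic.  The focal
    distance is used for N: for a strongly focused (low f-number) element
    the focus sits at the geometric focal distance.
    """
    f = spec.center_frequency_hz if frequency_hz is None else frequency_hz
    if f <= 0:
        raise ValidationError("frequency must be positive")
    return spec.focal_distance_m * spec.sound_speed_m_s / (spec.element_diameter_m * f)


def pressure_from_voltage(spec: TransducerSpec, v_pp: float) -> float:
    """Focal acoustic pressure (MPa) for a drive voltage, from the table.

    Exact table voltages return the tabulated pressure; values between
    entries are linearly interpolated.  Queries outside the table range are
    refused — the calibration does not extrapolate (higher drive levels
    need an extended hydrophone table supplied by the user).
    """
    if not spec.voltage_pressure_table:
        raise ValidationError("transducer spec has no voltage→pressure table")
    v = np.array([row[0] for row in spec.voltage_pressure_table])
    p = np.array([row[1] for row in spec.voltage_pressure_table])
    if v_pp < v[0] or v_pp > v[-1]:
        raise ValidationError(
            f"v_pp={v_pp} outside calibrated table range [{v[0]}, {v[-1]}]"
        )
    return float(np.interp(v_pp, v, p))
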