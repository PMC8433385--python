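"""Seeded synthetic inputs with the statistical structure the analysis assumes.

Every downstream stage — segmentation, slope fitting, aspiration fitting,
calibration, statistics — can be exercised against generated data whose
ground truth is known and stored.  The generators implement the same
phenomenological models the analysis fits:

* deformation: normalized projected area grows linearly with trap pressure,
  ``A(P)/A(0) = 1 + s·P``, with a per-sample slope s drawn from a Gaussian
  truncated at zero and i.i.d. Gaussian measurement noise on the normalized
  area at P > 0 (the baseline point is the normalization anchor and stays
  exactly 1);
* aspiration: the punch model inverted, ``D = 3 R ΔP φ / (2π E)`` plus
  Gaussian length noise floored at zero;
* viability: paired Gaussian fluorescence samples before/after trapping.

Fixed seeds give bit-identical outputs.  Soft objects that burst mid-ramp
are emulated by a truncation pressure after which no measurements exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .deformability import DeformationSeries
from .errors import ValidationError
from .micropipette import AspirationTrace, MATConfig

__all__ = [
    "DeformationGroundTruth",
    "SyntheticFrameSpec",
    "generate_deformation_series",
    "render_frames",
    "generate_aspiration_trace",
    "generate_viability_samples",
]

#: default pressure ramp of the trapping assay (MPa)
DEFAULT_PRESSURES_MPA = (0.000, 0.234, 0.431, 0.627, 0.824, 1.000)


@dataclass(frozen=True)
class DeformationGroundTruth:
    """Generative parameters for one group of trapped objects.

    Defaults describe a ~20 µm-diameter object measured over the six-step
    0–1 MPa ramp with 20 samples per group.
    """

    group_label: str
    true_slope_mean: float  # per MPa
    true_slope_sd: float = 0.0
    area_noise_sd: float = 0.005  # on normalized area, per measurement
    baseline_radius_mean_um: float = 10.0
    baseline_radius_sd_um: float = 1.0
    n_samples: int = 20
    pressures_mpa: tuple[float, ...] = DEFAULT_PRESSURES_MPA
    burst_pressure_mpa: float | None = None  # no measurements above this
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.pressures_mpa, dtype=float)
        if p.size < 2 or p[0] != 0.0 or np.any(np.diff(p) <= 0):
            raise ValidationError(
                "pressures must be strictly increasing and start at 0.0"
            )
        if self.true_slope_mean < 0:
            raise ValidationError("true_slope_mean must be >= 0")
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if self.true_slope_sd < 0 or self.area_noise_sd < 0:
            raise ValidationError("spread parameters must be >= 0")
        if self.baseline_radius_mean_um <= 0:
            raise ValidationError("baseline radius must be positive")


@dataclass(frozen=True)
class SyntheticFrameSpec:
    """Rendering parameters for bright-field-like frames of one object."""

    image_size: tuple[int, int] = (160, 160)  # (H, W) pixels
    pixel_size_um: float = 0.2
    background_level: float = 180.0
    object_level: float = 80.0
    blur_sigma_px: float = 1.0
    noise_sd: float = 4.0
    eccentricity: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.object_level - self.background_level) <= 3 * self.noise_sd:
            raise ValidationError(
                "object/background contrast must exceed 3x the noise sd"
            )
        if self.blur_sigma_px < 0 or self.noise_sd < 0:
            raise ValidationError("blur_sigma_px and noise_sd must be >= 0")
        if not (0.0 <= self.eccentricity < 1.0):
            raise ValidationError("eccentricity must be in [0, 1)")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel size must be positive")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Gaussian truncated at zero by rejection; exact for sd = 0."""
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    while np.any(out < 0):
        bad = out < 0
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    return out


def generate_deformation_series(gt: DeformationGroundTruth) -> list[DeformationSeries]:
    """Draw one group of deformation ramps; ground truth stored per sample.

    Each series carries ``metadata["true_slope"]`` (the drawn per-sample
    slope) and ``metadata["true_baseline_area_um2"]`` so recovery tests can
    compare fitted values against the exact generative truth.
    """
    rng = np.random.default_rng(gt.seed)
    pressures = np.asarray(gt.pressures_mpa, dtype=float)
    if gt.burst_pressure_mpa is not None:
        pressures = pressures[pressures <= gt.burst_pressure_mpa]
        if pressures.size < 2:
            raise ValidationError("burst pressure leaves fewer than 2 steps")
    slopes = _truncated_normal(rng, gt.true_slope_mean, gt.true_slope_sd, gt.n_samples)
    radii = _truncated_normal(
        rng, gt.baseline_radius_mean_um, gt.baseline_radius_sd_um, gt.n_samples
    )
    out: list[DeformationSeries] = []
    truncated = gt.burst_pressure_mpa is not None and pressures.size < len(
        gt.pressures_mpa
    )
    for i in range(gt.n_samples):
        norm = 1.0 + slopes[i] * pressures
        if gt.area_noise_sd > 0:
            noise = rng.normal(0.0, gt.area_noise_sd, pressures.size)
            noise[0] = 0.0  # baseline is the normalization anchor
            norm = norm + noise
        norm = np.maximum(norm, 1e-6)
        baseline_area = np.pi * radii[i] ** 2
        out.append(
            DeformationSeries(
                sample_id=f"{gt.group_label}_{i:03d}",
                group_label=gt.group_label,
                pressures_mpa=pressures.copy(),
                areas_um2=baseline_area * norm,
                truncated=truncated,
                metadata={
                    "true_slope": float(slopes[i]),
                    "true_baseline_area_um2": float(baseline_area),
                },
            )
        )
    return out


def render_frames(
    series: DeformationSeries, spec: SyntheticFrameSpec, seed: int = 0
) -> np.ndarray:
    """Render one bright-field-like frame per pressure step.

    The object is drawn as a filled, centred ellipse of fixed eccentricity
    whose pixel area matches the series area at that step (rasterization
    error is sub-percent at the default ≥ 25 px radii), then Gaussian blur
    and pixel noise are applied.  Deterministic under a fixed seed.
    """
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    H, W = spec.image_size
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    yy, xx = np.mgrid[0:H, 0:W]
    axis_ratio = np.sqrt(1.0 - spec.eccentricity**2)  # b/a
    frames = np.empty((series.n_steps, H, W), dtype=float)
    for j, area_um2 in enumerate(series.areas_um2):
        area_px = area_um2 / spec.pixel_size_um**2
        a = np.sqrt(area_px / (np.pi * axis_ratio))  # semi-major, px
        b = a * axis_ratio
        if cy - b < 1 or cx - a < 1:
            raise ValidationError(
                f"{series.sample_id}, step {j}: object (a={a:.1f} px) exceeds frame"
            )
        mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
        img = np.where(mask, spec.object_level, spec.background_level).astype(float)
        if spec.blur_sigma_px > 0:
            img = ndimage.gaussian_filter(img, spec.blur_sigma_px)
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, img.shape)
        frames[j] = img
    return frames


def generate_aspiration_trace(
    true_E_pa: float,
    pipette_inner_radius_um: float = 2.0,
    phi: float = 2.014,
    pressure_steps_pa: Sequence[float] = tuple(np.linspace(500, 5000, 10)),
    length_noise_sd_um: float = 0.0,
    seed: int = 0,
    sphere_id: str = "sphere",
    group_label: str = "",
) -> AspirationTrace:
    """Invert the punch model to simulate an aspiration trace.

    Aspirated length at each suction step is ``3 R ΔP φ / (2π E)`` plus
    Gaussian noise, floored at zero (the tongue cannot have negative
    length).  The true modulus is stored in the trace metadata.
    """
    if true_E_pa <= 0:
        raise ValidationError("true Young's modulus must be positive")
    dp = np.asarray(pressure_steps_pa, dtype=float)
    if np.any(dp < 0) or np.any(np.diff(dp) <= 0):
        raise ValidationError("pressure steps must be non-negative and increasing")
    rng = np.random.default_rng(seed)
    D = 3.0 * pipette_inner_radius_um * dp * phi / (2.0 * np.pi * true_E_pa)
    if length_noise_sd_um > 0:
        D = D + rng.normal(0.0, length_noise_sd_um, D.size)
    D = np.maximum(D, 0.0)
    config = MATConfig(pipette_inner_radius_um=pipette_inner_radius_um, phi=phi)
    return AspirationTrace(
        sphere_id=sphere_id,
        group_label=group_label,
        config=config,
        pressure_steps_pa=dp,
        aspirated_lengths_um=D,
        metadata={"true_E_pa": float(true_E_pa)},
    )


def generate_viability_samples(
    mean_before: float,
    mean_after: float,
    sd: float,
    n: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired calcein-AM fluorescence samples before/after trapping."""
    if n < 2:
        raise ValidationError("need n >= 2 samples per arm")
    rng = np.random.default_rng(seed)
    before = rng.normal(mean_before, sd, n)
    after = rng.normal(mean_after, sd, n)
    return before, after
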