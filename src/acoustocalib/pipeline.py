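"""End-to-end orchestration: areas → slopes → calibration → moduli → stats.

The pipeline composes the per-stage modules into one reproducible run:

1. cell deformation input, either image stacks (segmented per frame) or
   area tables;
2. per-sample slope fits and group summaries;
3. hydrogel-surrogate (AHS) side: deformability slopes plus aspiration
   moduli, joined into the slope→modulus calibration curve;
4. interpolation of every cell sample's slope into an absolute Young's
   modulus;
5. group statistics (one-way ANOVA + Scheffé) on slopes and moduli.

Everything is deterministic given the configuration and seed; warnings
(truncated ramps, out-of-range slopes) are collected into the report, never
dropped.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .calibration import CalibrationCurve, CellModulus, build_curve, cell_modulus
from .deformability import (
    DeformationSeries,
    GroupDeformability,
    fit_slope,
    read_area_table,
    summarize_group,
    write_fit_table,
)
from .errors import ValidationError
from .micropipette import MATConfig, fit_young_modulus, read_aspiration_table, summarize_moduli
from .stats import AnovaResult, ScheffePair, one_way_anova, scheffe_posthoc

__all__ = ["RunConfig", "AnalysisReport", "run_pipeline", "run_published_analysis", "make_fixtures"]


@dataclass
class RunConfig:
    """File-based configuration for one pipeline run.

    Cell input is either ``cell_areas_csv`` (long-format area table) or
    ``image_root`` + ``pixel_size_um`` + ``pressures_mpa`` (one multi-page
    TIFF per sample, laid out as ``<image_root>/<group>/<sample>.tif``).
    The AHS side takes either pre-fitted slopes (``ahs_slopes_csv``) or an
    area table (``ahs_areas_csv``), and either summarized moduli
    (``ahs_moduli_csv``) or raw aspiration traces (``aspiration_csv`` with
    pipette geometry).
    """

    out_dir: str | None = None
    cell_areas_csv: str | None = None
    image_root: str | None = None
    pixel_size_um: float | None = None
    pressures_mpa: tuple[float, ...] | None = None
    ahs_areas_csv: str | None = None
    ahs_slopes_csv: str | None = None
    ahs_moduli_csv: str | None = None
    aspiration_csv: str | None = None
    pipette_inner_radius_um: float = 2.0
    phi: float = 2.014
    interpolation_scheme: str = "linear"
    alpha_posthoc: float = 0.05
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        if "pressures_mpa" in d and d["pressures_mpa"] is not None:
            d["pressures_mpa"] = tuple(d["pressures_mpa"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=list))


@dataclass
class AnalysisReport:
    """All pipeline outputs plus provenance; serializable to JSON."""

    cell_groups: dict[str, GroupDeformability]
    ahs_slopes: dict[str, float]
    ahs_moduli: list[tuple[str, float, float]]
    curve: CalibrationCurve
    cell_moduli: dict[str, CellModulus]
    anova_slopes: AnovaResult | None
    scheffe_slopes: list[ScheffePair]
    anova_moduli: AnovaResult | None
    scheffe_moduli: list[ScheffePair]
    warnings: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _anova(a: AnovaResult | None) -> dict | None:
            return None if a is None else asdict(a)

        return {
            "cell_groups": {
                label: {
                    "slope_mean": g.slope_mean,
                    "slope_sd": g.slope_sd,
                    "n_samples": g.n_samples,
                    "slopes": [f.slope for f in g.per_sample_fits],
                }
                for label, g in self.cell_groups.items()
            },
            "ahs_slopes": self.ahs_slopes,
            "ahs_moduli": [
                {"label": lab, "E_kpa": E, "E_sd_kpa": sd} for lab, E, sd in self.ahs_moduli
            ],
            "calibration_curve": {
                "scheme": self.curve.scheme,
                "knots": [asdict(k) for k in self.curve.knots],
            },
            "cell_moduli": {label: asdict(m) for label, m in self.cell_moduli.items()},
            "anova_slopes": _anova(self.anova_slopes),
            "scheffe_slopes": [asdict(p) for p in self.scheffe_slopes],
            "anova_moduli": _anova(self.anova_moduli),
            "scheffe_moduli": [asdict(p) for p in self.scheffe_moduli],
            "warnings": self.warnings,
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _group_series(series: Sequence[DeformationSeries]) -> dict[str, list[DeformationSeries]]:
    groups: dict[str, list[DeformationSeries]] = {}
    for s in series:
        groups.setdefault(s.group_label, []).append(s)
    return groups


def analyze_tables(
    cell_series: Sequence[DeformationSeries],
    ahs_slopes: Mapping[str, float],
    ahs_moduli: Sequence[tuple[str, float, float]],
    scheme: str = "linear",
    alpha_posthoc: float = 0.05,
    provenance: dict | None = None,
) -> AnalysisReport:
    """Core analysis on in-memory inputs; all file-based entry points call this."""
    if not cell_series:
        raise ValidationError("no cell deformation series supplied")
    collected: list[str] = []
    cell_groups: dict[str, GroupDeformability] = {}
    for label, group_series in _group_series(cell_series).items():
        fits = [fit_slope(s) for s in group_series]
        truncated = sum(s.truncated for s in group_series)
        if truncated:
            collected.append(
                f"group {label!r}: {truncated} truncated (burst) series included "
                "with fewer ramp points"
            )
        cell_groups[label] = summarize_group(fits, label)

    curve = build_curve(list(ahs_slopes.items()), list(ahs_moduli), scheme=scheme)

    cell_moduli: dict[str, CellModulus] = {}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for label, group in cell_groups.items():
            cell_moduli[label] = cell_modulus(group, curve)
    collected.extend(str(w.message) for w in caught)

    # group statistics need >=2 samples everywhere; single-series (e.g.
    # published group-mean) runs skip them
    anova_s = anova_e = None
    scheffe_s: list[ScheffePair] = []
    scheffe_e: list[ScheffePair] = []
    if len(cell_groups) >= 2 and all(g.n_samples >= 2 for g in cell_groups.values()):
        slope_samples = {label: g.slopes for label, g in cell_groups.items()}
        anova_s = one_way_anova(slope_samples)
        scheffe_s = scheffe_posthoc(slope_samples, anova_s, alpha=alpha_posthoc)
        e_samples = {
            label: np.array(m.per_sample_E_kpa) for label, m in cell_moduli.items()
        }
        if all(v.size >= 2 for v in e_samples.values()):
            anova_e = one_way_anova(e_samples)
            scheffe_e = scheffe_posthoc(e_samples, anova_e, alpha=alpha_posthoc)
    else:
        collected.append("group statistics skipped: need >=2 samples per group")

    return AnalysisReport(
        cell_groups=cell_groups,
        ahs_slopes=dict(ahs_slopes),
        ahs_moduli=list(ahs_moduli),
        curve=curve,
        cell_moduli=cell_moduli,
        anova_slopes=anova_s,
        scheffe_slopes=scheffe_s,
        anova_moduli=anova_e,
        scheffe_moduli=scheffe_e,
        warnings=collected,
        provenance=provenance or {},
    )


def _load_cell_series(config: RunConfig) -> list[DeformationSeries]:
    if config.cell_areas_csv:
        return read_area_table(config.cell_areas_csv)
    if config.image_root:
        from .imaging import measure_stack, read_stack

        if config.pixel_size_um is None or config.pressures_mpa is None:
            raise ValidationError("image mode needs pixel_size_um and pressures_mpa")
        root = Path(config.image_root)
        series = []
        for group_dir in sorted(p for p in root.iterdir() if p.is_dir()):
            for tif in sorted(group_dir.glob("*.tif")):
                stack = read_stack(
                    tif,
                    pixel_size_um=config.pixel_size_um,
                    pressures_mpa=np.asarray(config.pressures_mpa),
                    sample_id=tif.stem,
                    group_label=group_dir.name,
                )
                series.append(measure_stack(stack))
        if not series:
            raise ValidationError(f"{root}: no <group>/<sample>.tif stacks found")
        return series
    raise ValidationError("config needs cell_areas_csv or image_root")


def _load_ahs_side(
    config: RunConfig,
) -> tuple[dict[str, float], list[tuple[str, float, float]], list[str]]:
    notes: list[str] = []
    if config.ahs_slopes_csv:
        df = pd.read_csv(config.ahs_slopes_csv)
        slopes = dict(zip(df["label"].astype(str), df["slope"].astype(float)))
    elif config.ahs_areas_csv:
        series = read_area_table(config.ahs_areas_csv)
        slopes = {}
        for label, group_series in _group_series(series).items():
            fits = [fit_slope(s) for s in group_series]
            slopes[label] = summarize_group(fits, label).slope_mean
    else:
        raise ValidationError("config needs ahs_slopes_csv or ahs_areas_csv")

    if config.ahs_moduli_csv:
        df = pd.read_csv(config.ahs_moduli_csv)
        moduli = [
            (str(r.label), float(r.E_kpa), float(r.E_sd_kpa)) for r in df.itertuples()
        ]
    elif config.aspiration_csv:
        mat = MATConfig(
            pipette_inner_radius_um=config.pipette_inner_radius_um, phi=config.phi
        )
        traces = read_aspiration_table(config.aspiration_csv, mat)
        by_group: dict[str, list] = {}
        for t in traces:
            by_group.setdefault(t.group_label, []).append(fit_young_modulus(t))
        moduli = []
        for label, ests in by_group.items():
            mean_pa, sd_pa, single = summarize_moduli(ests, label)
            if single:
                notes.append(f"AHS group {label!r}: single sphere, sd reported as 0")
            moduli.append((label, mean_pa / 1000.0, sd_pa / 1000.0))
    else:
        raise ValidationError("config needs ahs_moduli_csv or aspiration_csv")
    return slopes, moduli, notes


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Run the full analysis described by ``config``; optionally write outputs."""
    cell_series = _load_cell_series(config)
    ahs_slopes, ahs_moduli, notes = _load_ahs_side(config)
    cfg_json = json.dumps(asdict(config), sort_keys=True, default=list)
    provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
    }
    report = analyze_tables(
        cell_series,
        ahs_slopes,
        ahs_moduli,
        scheme=config.interpolation_scheme,
        alpha_posthoc=config.alpha_posthoc,
        provenance=provenance,
    )
    report.warnings.extend(notes)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "report.json")
        all_fits = [f for g in report.cell_groups.values() for f in g.per_sample_fits]
        write_fit_table(all_fits, out / "slopes.csv")
        pd.DataFrame(
            [
                {
                    "group": label,
                    "E_mean_kpa": m.E_mean_kpa,
                    "E_sd_kpa": m.E_sd_kpa,
                    "n_in_range": len(m.per_sample_E_kpa),
                    "out_of_range": m.out_of_range_count,
                }
                for label, m in report.cell_moduli.items()
            ]
        ).to_csv(out / "moduli.csv", index=False)
        stats_payload = {
            "anova_slopes": None if report.anova_slopes is None else asdict(report.anova_slopes),
            "scheffe_slopes": [asdict(p) for p in report.scheffe_slopes],
            "anova_moduli": None if report.anova_moduli is None else asdict(report.anova_moduli),
            "scheffe_moduli": [asdict(p) for p in report.scheffe_moduli],
        }
        (out / "anova.json").write_text(json.dumps(stats_payload, indent=2))
    return report


def run_published_analysis(scheme: str = "linear") -> AnalysisReport:
    """Run the table pipeline on the packaged published group-mean ramps.

    Fits the published six-step (three-step for the burst AHS_0.1) ramps,
    builds the calibration curve from the published AHS slopes and
    aspiration moduli, and interpolates the three cell lines' moduli.
    Group statistics are skipped (the published ramps are group means, one
    series per group).
    """
    from . import datasets

    cell_series = [
        s for s in datasets.load_published_deformation()
        if s.group_label in datasets.CELL_GROUPS
    ]
    return analyze_tables(
        cell_series,
        datasets.load_published_ahs_slopes(),
        datasets.load_published_ahs_moduli(),
        scheme=scheme,
        provenance={"package_version": __version__, "input": "published tables"},
    )


# ---------------------------------------------------------------------------
# synthetic study fixtures

#: generative defaults for the synthetic study: published group slope means;
#: cell slope spread 0.02 per MPa between samples, AHS spread 10% of the
#: mean (manufactured spheres are more uniform than cells)
CELL_TRUTH = {"MDA-MB-231": 0.209, "MCF-7": 0.099, "SKBR-3": 0.090}
AHS_TRUTH = {
    "AHS_0.1": {"slope": 0.728, "E_kpa": 0.214, "E_sd_kpa": 0.082, "burst_mpa": 0.431},
    "AHS_0.3": {"slope": 0.168, "E_kpa": 1.603, "E_sd_kpa": 0.242, "burst_mpa": None},
    "AHS_0.6": {"slope": 0.075, "E_kpa": 2.995, "E_sd_kpa": 0.573, "burst_mpa": None},
    "AHS_0.9": {"slope": 0.043, "E_kpa": 6.401, "E_sd_kpa": 1.089, "burst_mpa": None},
    "AHS_1.2": {"slope": 0.016, "E_kpa": 9.235, "E_sd_kpa": 1.634, "burst_mpa": None},
}
CELL_SLOPE_SD = 0.02
AHS_SLOPE_CV = 0.10


def make_fixtures(
    seed: int,
    out_dir: str | Path,
    n_samples: int = 20,
    n_image_samples: int = 2,
) -> RunConfig:
    """Write a complete small synthetic study to ``out_dir``.

    Produces area tables for three cell-like and five AHS-like groups,
    multi-page TIFF stacks for the first ``n_image_samples`` cell samples
    per group, aspiration traces for every AHS sphere, a ground-truth JSON
    sidecar, and a ready-to-run pipeline config (table input mode).
    Deterministic per seed.
    """
    import tifffile

    from .synthetic_data import (
        DEFAULT_PRESSURES_MPA,
        DeformationGroundTruth,
        SyntheticFrameSpec,
        generate_aspiration_trace,
        generate_deformation_series,
        render_frames,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    truth: dict = {"seed": seed, "groups": {}}

    frame_spec = SyntheticFrameSpec(image_size=(192, 192), pixel_size_um=0.25)
    cell_rows = []
    (out / "images").mkdir(exist_ok=True)
    for label, slope_mean in CELL_TRUTH.items():
        gt = DeformationGroundTruth(
            group_label=label,
            true_slope_mean=slope_mean,
            true_slope_sd=CELL_SLOPE_SD,
            n_samples=n_samples,
            seed=int(master.integers(2**31)),
        )
        series = generate_deformation_series(gt)
        truth["groups"][label] = {
            "kind": "cell",
            "true_slope_mean": slope_mean,
            "true_slope_sd": CELL_SLOPE_SD,
            "per_sample_true_slopes": [s.metadata["true_slope"] for s in series],
        }
        gdir = out / "images" / label
        gdir.mkdir(parents=True, exist_ok=True)
        for i, s in enumerate(series):
            for p, a in zip(s.pressures_mpa, s.areas_um2):
                cell_rows.append(
                    {"sample_id": s.sample_id, "group": label, "pressure_mpa": p, "area_um2": a}
                )
            if i < n_image_samples:
                frames = render_frames(s, frame_spec, seed=int(master.integers(2**31)))
                tifffile.imwrite(
                    gdir / f"{s.sample_id}.tif", frames.astype(np.float32)
                )
    pd.DataFrame(cell_rows).to_csv(out / "cell_areas.csv", index=False)

    ahs_rows = []
    asp_rows = []
    for label, info in AHS_TRUTH.items():
        gt = DeformationGroundTruth(
            group_label=label,
            true_slope_mean=info["slope"],
            true_slope_sd=AHS_SLOPE_CV * info["slope"],
            n_samples=n_samples,
            burst_pressure_mpa=info["burst_mpa"],
            seed=int(master.integers(2**31)),
        )
        series = generate_deformation_series(gt)
        for s in series:
            for p, a in zip(s.pressures_mpa, s.areas_um2):
                ahs_rows.append(
                    {"sample_id": s.sample_id, "group": label, "pressure_mpa": p, "area_um2": a}
                )
        true_E_pa = 1000.0 * np.maximum(
            master.normal(info["E_kpa"], info["E_sd_kpa"], n_samples), 0.02
        )
        truth["groups"][label] = {
            "kind": "ahs",
            "true_slope_mean": info["slope"],
            "true_E_mean_kpa": info["E_kpa"],
            "per_sample_true_slopes": [s.metadata["true_slope"] for s in series],
            "per_sphere_true_E_kpa": list(true_E_pa / 1000.0),
        }
        for i, E in enumerate(true_E_pa):
            # suction ramp scaled per sphere so the tongue reaches ~3 µm,
            # capped at the controller's 33.3 kPa ceiling
            dp_max = min(33300.0, 3.0 * 2.0 * np.pi * E / (3.0 * 2.0 * 2.014))
            steps = np.linspace(dp_max / 10, dp_max, 10)
            trace = generate_aspiration_trace(
                true_E_pa=float(E),
                pressure_steps_pa=steps,
                length_noise_sd_um=0.05,
                seed=int(master.integers(2**31)),
                sphere_id=f"{label}_{i:03d}",
                group_label=label,
            )
            for k, (dp, d) in enumerate(
                zip(trace.pressure_steps_pa, trace.aspirated_lengths_um)
            ):
                asp_rows.append(
                    {
                        "sphere_id": trace.sphere_id,
                        "group": label,
                        "step": k,
                        "delta_p_pa": dp,
                        "aspirated_len_um": d,
                    }
                )
    pd.DataFrame(ahs_rows).to_csv(out / "ahs_areas.csv", index=False)
    pd.DataFrame(asp_rows).to_csv(out / "aspiration.csv", index=False)
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))

    config = RunConfig(
        out_dir=str(out / "results"),
        cell_areas_csv=str(out / "cell_areas.csv"),
        image_root=str(out / "images"),
        pixel_size_um=frame_spec.pixel_size_um,
        pressures_mpa=tuple(DEFAULT_PRESSURES_MPA),
        ahs_areas_csv=str(out / "ahs_areas.csv"),
        aspiration_csv=str(out / "aspiration.csv"),
        seed=seed,
    )
    config.to_json(out / "config.json")
    return config
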