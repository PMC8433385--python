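"""Loaders for the small reference tables shipped with the package.

These are the published group-mean deformation ramps, deformability slopes
and hydrogel-sphere (AHS) aspiration moduli of the acoustic-tweezers breast
cancer study the pipeline reproduces, plus the matching 50 MHz transducer
description.  They let the full table-input pipeline run with no external
data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .acoustics import TransducerSpec
from .deformability import DeformationSeries

__all__ = [
    "load_published_deformation",
    "load_published_cell_slopes",
    "load_published_ahs_slopes",
    "load_published_ahs_moduli",
    "load_default_transducer",
]

CELL_GROUPS = ("MDA-MB-231", "MCF-7", "SKBR-3")
AHS_GROUPS = ("AHS_0.1", "AHS_0.3", "AHS_0.6", "AHS_0.9", "AHS_1.2")


def _data_path(name: str):
    return resources.files("acoustocalib.data").joinpath(name)


def load_published_deformation() -> list[DeformationSeries]:
    """Group-mean normalized area ramps (one series per group).

    The soft AHS_0.1 spheres burst at 0.43 MPa, so their ramp has only
    three points and is flagged truncated.  Areas are the published
    normalized ratios (slope fitting is scale invariant).
    """
    with resources.as_file(_data_path("published_normalized_areas.csv")) as p:
        df = pd.read_csv(p)
    out = []
    for group, sub in df.groupby("group", sort=False):
        sub = sub.sort_values("pressure_mpa")
        out.append(
            DeformationSeries(
                sample_id=f"{group}_mean",
                group_label=str(group),
                pressures_mpa=sub["pressure_mpa"].to_numpy(),
                areas_um2=sub["normalized_area"].to_numpy(),
                truncated=len(sub) < 6,
                metadata={"source": "published group mean"},
            )
        )
    return out


def load_published_cell_slopes() -> dict[str, float]:
    """Published cell-line deformability slopes (per MPa)."""
    with resources.as_file(_data_path("published_cell_slopes.csv")) as p:
        df = pd.read_csv(p)
    return dict(zip(df["label"], df["slope"]))


def load_published_ahs_slopes() -> dict[str, float]:
    """Published AHS deformability slopes by agarose concentration."""
    with resources.as_file(_data_path("published_ahs_slopes.csv")) as p:
        df = pd.read_csv(p)
    return dict(zip(df["label"], df["slope"]))


def load_published_ahs_moduli() -> list[tuple[str, float, float]]:
    """Published AHS aspiration moduli as (label, E_kPa, sd_kPa) triples."""
    with resources.as_file(_data_path("published_ahs_moduli.csv")) as p:
        df = pd.read_csv(p)
    return [
        (str(r.label), float(r.E_kpa), float(r.E_sd_kpa)) for r in df.itertuples()
    ]


def load_default_transducer() -> TransducerSpec:
    """The 50 MHz trapping transducer with its calibrated drive table."""
    with resources.as_file(_data_path("transducer_50mhz.json")) as p:
        return TransducerSpec.from_json(p)
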