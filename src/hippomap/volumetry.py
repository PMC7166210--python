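"""Cavalieri volumetry, shrinkage correction, normalization and
cohort summary tables.

Volumes are estimated from the traced contours of the mapped section
subset by Cavalieri's principle: the sum of a region's profile areas on
the mapped sections, multiplied by the inter-section spacing
d = section thickness × mapping interval.  This is the unbiased design
for systematically sampled serial sections; no coefficient-of-error
prediction is attempted.

Shrinkage during histological processing is compensated per brain by a
single multiplicative factor — the ratio of a fresh reference volume to
the measured histological volume.  Because the same factor applies to a
region and to the whole brain, correction commutes with expressing
volumes as fractions of total brain volume.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon as ShapelyPolygon

from .core_io import ContourStack, RegionCodebook, SubjectRecord, VolumeTable

__all__ = [
    "cavalieri_volume",
    "section_area",
    "shrinkage_correct",
    "normalize_volumes",
    "aggregate_table",
    "mean_sd",
    "format_summary",
]


def section_area(contours: Sequence) -> float:
    """Planimetric area of one region's contours on one section (mm²).

    Uses even-odd containment parity so that a ring nested inside
    another (a hole) subtracts instead of double-counting.  With no
    nesting this reduces to the plain sum of polygon areas.
    """
    polys = [ShapelyPolygon(c.polygon) for c in contours]
    order = np.argsort([-p.area for p in polys])
    total = 0.0
    for pos, i in enumerate(order):
        depth = sum(1 for j in order[:pos] if polys[j].contains(polys[i]))
        total += polys[i].area * (1 if depth % 2 == 0 else -1)
    return float(total)


def cavalieri_volume(stack: ContourStack, codebook: Optional[RegionCodebook] = None) -> dict:
    """Estimate per-region volume (mm³) from a mapped contour stack.

    V(r) = d × Σ_sections area(r, section), with d the mapped-section
    spacing.  If a codebook is supplied, regions with no contours are
    reported as 0 mm³ with a warning.
    """
    d = stack.section_spacing_mm
    if d <= 0:
        raise ValueError("section spacing must be positive")
    volumes: dict = {}
    for code in stack.region_codes():
        per_section = stack.by_section(code)
        volumes[code] = d * sum(section_area(cs) for cs in per_section.values())
    if codebook is not None:
        for code in codebook.codes:
            if code not in volumes:
                warnings.warn(f"region {code} has zero contours; volume set to 0")
                volumes[code] = 0.0
    return volumes


def shrinkage_correct(
    table: VolumeTable,
    fresh_reference_volume: float,
    histological_volume: float,
) -> VolumeTable:
    """Rescale all volumes by f = fresh reference / histological volume.

    Both region volumes and the recorded total brain volumes are scaled,
    so fractional (normalized) volumes are unchanged by correction.
    Raises if the table is already corrected.
    """
    if fresh_reference_volume <= 0 or histological_volume <= 0:
        raise ValueError("reference volumes must be positive")
    if table.df["shrinkage_corrected"].any():
        raise ValueError("table already shrinkage-corrected; refusing double correction")
    f = fresh_reference_volume / histological_volume
    df = table.df.copy()
    df["volume_mm3"] = df["volume_mm3"] * f
    df["total_brain_volume_mm3"] = df["total_brain_volume_mm3"] * f
    df["shrinkage_corrected"] = True
    return VolumeTable(df)


def normalize_volumes(table: VolumeTable) -> pd.DataFrame:
    """Express each region volume as a fraction of its subject's total
    brain volume (adjusting for overall brain-size differences).

    Returns the table's rows with an added dimensionless ``fraction``
    column.  Raises, naming the subject, if a total brain volume is
    missing.
    """
    df = table.df.copy()
    missing = df.loc[df["total_brain_volume_mm3"].isna(), "subject_id"].unique()
    if len(missing):
        raise ValueError(f"missing total brain volume for subject(s): {sorted(missing)}")
    if (df["total_brain_volume_mm3"] <= 0).any():
        raise ValueError("total brain volumes must be positive")
    df["fraction"] = df["volume_mm3"] / df["total_brain_volume_mm3"]
    return df


def mean_sd(values: Iterable[float]) -> tuple:
    """Sample mean and sd (n−1 denominator) of a value sequence."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty value sequence")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def aggregate_table(table: VolumeTable, subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Cohort summary: per region, mean ± sd in total, per hemisphere
    and per sex.

    Hemisphere groups pool one value per subject and side; the total and
    sex groups use each subject's mean of left and right, so with
    equal-sized sex groups the grand mean equals the average of the two
    sex-group means.  Requires every (subject, hemisphere, region) cell.
    """
    sex_of = {s.subject_id: s.sex for s in subjects}
    df = table.df
    ids = sorted(df.subject_id.unique())
    regions = sorted(df.region_code.unique())
    unknown = [i for i in ids if i not in sex_of]
    if unknown:
        raise ValueError(f"no SubjectRecord for subject(s): {unknown}")

    missing = [
        (s, h, r)
        for s in ids
        for h in ("left", "right")
        for r in regions
        if df[(df.subject_id == s) & (df.hemisphere == h) & (df.region_code == r)].empty
    ]
    if missing:
        raise ValueError(f"missing (subject, hemisphere, region) cells: {missing}")

    wide = df.pivot_table(
        index=["subject_id", "region_code"], columns="hemisphere", values="volume_mm3"
    ).reset_index()
    wide["subject_mean"] = (wide["left"] + wide["right"]) / 2.0
    wide["sex"] = wide["subject_id"].map(sex_of)

    rows = []
    for r in regions:
        g = wide[wide.region_code == r]
        row = {"region_code": r}
        row["total_mean"], row["total_sd"] = mean_sd(g["subject_mean"])
        row["left_mean"], row["left_sd"] = mean_sd(g["left"])
        row["right_mean"], row["right_sd"] = mean_sd(g["right"])
        for sex in ("male", "female"):
            vals = g.loc[g.sex == sex, "subject_mean"]
            if len(vals):
                row[f"{sex}_mean"], row[f"{sex}_sd"] = mean_sd(vals)
            else:
                row[f"{sex}_mean"] = row[f"{sex}_sd"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("region_code")


def format_summary(summary: pd.DataFrame, codebook: Optional[RegionCodebook] = None) -> pd.DataFrame:
    """Render a summary as integer-mm³ 'mean ± sd' strings for display."""
    out = pd.DataFrame(index=summary.index)
    if codebook is not None:
        out["region"] = [codebook.name_for(c) for c in summary.index]
    for grp, label in [
        ("total", "Total"),
        ("left", "Left"),
        ("right", "Right"),
        ("male", "Male"),
        ("female", "Female"),
    ]:
        out[label] = [
            f"{m:.0f} ± {s:.0f}" if np.isfinite(m) else "-"
            for m, s in zip(summary[f"{grp}_mean"], summary[f"{grp}_sd"])
        ]
    return out
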