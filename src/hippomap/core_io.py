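"""Shared data model, on-disk formats and configuration.

The pipeline works on four kinds of objects:

* :class:`LabelVolume` — a 3-D integer grid of region labels with a
  voxel-to-world affine (RAS, mm; the affine maps voxel *centres*).
* :class:`ContourStack` — closed region outlines traced on a subset of
  serial sections, the input to Cavalieri volumetry.
* :class:`VolumeTable` — tidy (subject, hemisphere, region) → mm³ rows.
* :class:`RegionCodebook` — the mapping between integer label codes and
  region names; ten hippocampal regions by default.

Label volumes are stored as integer NIfTI-1, contours as a small JSON
schema (one feature per closed ring), tables as CSV with a header row.
Label 0 is reserved for background everywhere.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from shapely.geometry import Polygon as ShapelyPolygon

logger = logging.getLogger("hippomap")

SEXES = ("male", "female")
HEMISPHERES = ("left", "right", "both")
COHORTS = ("cytoarchitecture", "autoradiography")

#: Canonical region order: hippocampus proper from the innermost layer
#: (fascia dentata) outwards through the CA fields, then the subicular
#: complex out to the transsubicular region.
CANONICAL_REGIONS: tuple[tuple[int, str], ...] = (
    (1, "FD"),
    (2, "CA4"),
    (3, "CA3"),
    (4, "CA2"),
    (5, "CA1"),
    (6, "ProS"),
    (7, "Sub"),
    (8, "PreS"),
    (9, "PaS"),
    (10, "TrS"),
)


class HippomapError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HippomapError):
    """Raised when an on-disk file violates the expected format."""


@dataclass(frozen=True)
class SubjectRecord:
    """One post-mortem brain: demographics and which hemispheres exist."""

    subject_id: str
    age: int
    sex: str
    fresh_weight: float
    hemispheres_available: frozenset = frozenset({"left", "right"})
    cohort: str = "cytoarchitecture"

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.fresh_weight <= 0:
            raise ValueError(f"fresh_weight must be positive, got {self.fresh_weight}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.cohort not in COHORTS:
            raise ValueError(f"cohort must be one of {COHORTS}, got {self.cohort!r}")
        hemis = frozenset(self.hemispheres_available)
        if not hemis or not hemis <= {"left", "right"}:
            raise ValueError("hemispheres_available must be a non-empty subset of {left, right}")
        object.__setattr__(self, "hemispheres_available", hemis)


@dataclass(frozen=True)
class RegionCodebook:
    """Ordered mapping of positive integer label codes to region names."""

    entries: tuple = CANONICAL_REGIONS

    def __post_init__(self) -> None:
        entries = tuple((int(c), str(n)) for c, n in self.entries)
        codes = [c for c, _ in entries]
        if any(c <= 0 for c in codes):
            raise ValueError("region codes must be positive (0 is background)")
        if len(set(codes)) != len(codes):
            raise ValueError("region codes must be unique")
        object.__setattr__(self, "entries", entries)

    @classmethod
    def canonical(cls) -> "RegionCodebook":
        return cls(CANONICAL_REGIONS)

    @property
    def codes(self) -> tuple:
        return tuple(c for c, _ in self.entries)

    @property
    def names(self) -> tuple:
        return tuple(n for _, n in self.entries)

    def name_for(self, code: int) -> str:
        for c, n in self.entries:
            if c == code:
                return n
        raise KeyError(f"unknown region code {code}")

    def code_for(self, name: str) -> int:
        for c, n in self.entries:
            if n == name:
                return c
        raise KeyError(f"unknown region name {name!r}")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class LabelVolume:
    """3-D integer region-label grid with voxel-centre-to-world affine.

    ``space_tag`` distinguishes subject-native grids from grids already
    resampled onto the common template.
    """

    voxels: np.ndarray
    affine: np.ndarray
    space_tag: str = "native"
    subject_id: str = ""
    hemisphere: str = "both"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D, got ndim={self.voxels.ndim}")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise FormatError("non-integer labels: label volumes must have integer dtype")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("degenerate affine: voxel-to-world map is not invertible")
        if self.space_tag not in ("native", "template"):
            raise ValueError(f"space_tag must be 'native' or 'template', got {self.space_tag!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}")

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge length of a voxel along each grid axis (mm)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def labels_present(self) -> np.ndarray:
        vals = np.unique(self.voxels)
        return vals[vals != 0]

    def world_coordinates(self, idx: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to (n, 3) world mm coordinates."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass(frozen=True)
class Contour:
    """One closed planar outline of a region on one section.

    ``polygon`` is an (n, 2) array of in-plane mm coordinates; the ring is
    implicitly closed (first point is not repeated).
    """

    section_index: int
    region_code: int
    polygon: np.ndarray

    def __post_init__(self) -> None:
        poly = np.asarray(self.polygon, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
            raise ValueError("polygon must be an (n>=3, 2) point array")
        if np.allclose(poly[0], poly[-1]):
            poly = poly[:-1]
        object.__setattr__(self, "polygon", poly)
        shp = ShapelyPolygon(poly)
        if not shp.is_valid or shp.area <= 0:
            raise ValueError(
                f"contour (section {self.section_index}, region {self.region_code}) "
                "must be a simple closed polygon with positive area"
            )
        if self.section_index < 0:
            raise ValueError("section_index must be >= 0")
        if self.region_code <= 0:
            raise ValueError("region_code must be positive")

    @property
    def area_mm2(self) -> float:
        return ShapelyPolygon(self.polygon).area


@dataclass
class ContourStack:
    """Region outlines on the mapped subset of a serial section series.

    ``section_thickness`` is the physical thickness of one section (mm);
    every ``mounting_interval``-th section was mounted and every
    ``mapping_interval``-th section carries traced borders, so the
    inter-contour spacing is ``section_thickness * mapping_interval``.
    """

    contours: list
    section_thickness: float
    mounting_interval: int = 15
    mapping_interval: int = 60

    def __post_init__(self) -> None:
        if self.section_thickness <= 0:
            raise ValueError("section_thickness must be positive")
        if self.mounting_interval < 1 or self.mapping_interval < 1:
            raise ValueError("sampling intervals must be >= 1")
        if self.mapping_interval % self.mounting_interval != 0:
            raise ValueError(
                "mapping_interval must be divisible by mounting_interval "
                f"({self.mapping_interval} % {self.mounting_interval} != 0)"
            )
        self.contours = list(self.contours)

    @property
    def section_spacing_mm(self) -> float:
        """Distance between consecutive mapped sections (mm)."""
        return self.section_thickness * self.mapping_interval

    def region_codes(self) -> tuple:
        return tuple(sorted({c.region_code for c in self.contours}))

    def by_section(self, region_code: int) -> dict:
        out: dict = {}
        for c in self.contours:
            if c.region_code == region_code:
                out.setdefault(c.section_index, []).append(c)
        return out


VOLUME_COLUMNS = [
    "subject_id",
    "hemisphere",
    "region_code",
    "volume_mm3",
    "shrinkage_corrected",
    "total_brain_volume_mm3",
]


@dataclass
class VolumeTable:
    """Tidy per-(subject, hemisphere, region) volume rows in mm³."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.df).copy()
        missing = [c for c in VOLUME_COLUMNS if c not in df.columns and c != "total_brain_volume_mm3"]
        if missing:
            raise ValueError(f"VolumeTable missing columns: {missing}")
        if "total_brain_volume_mm3" not in df.columns:
            df["total_brain_volume_mm3"] = np.nan
        df = df[VOLUME_COLUMNS]
        df["region_code"] = df["region_code"].astype(int)
        df["shrinkage_corrected"] = df["shrinkage_corrected"].astype(bool)
        if (df["volume_mm3"] < 0).any():
            raise ValueError("volumes must be non-negative")
        dup = df.duplicated(subset=["subject_id", "hemisphere", "region_code"])
        if dup.any():
            rows = df.loc[dup, ["subject_id", "hemisphere", "region_code"]]
            raise ValueError(f"duplicate (subject, hemisphere, region) rows:\n{rows}")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "VolumeTable":
        return cls(pd.DataFrame(list(records)))

    def volume(self, subject_id: str, hemisphere: str, region_code: int) -> float:
        m = (
            (self.df.subject_id == subject_id)
            & (self.df.hemisphere == hemisphere)
            & (self.df.region_code == region_code)
        )
        sub = self.df[m]
        if len(sub) != 1:
            raise KeyError(f"no unique row for ({subject_id}, {hemisphere}, {region_code})")
        return float(sub.volume_mm3.iloc[0])


# ---------------------------------------------------------------------------
# On-disk formats
# ---------------------------------------------------------------------------

def write_label_volume(volume: LabelVolume, path) -> Path:
    """Write a label volume as integer NIfTI-1 (.nii / .nii.gz)."""
    path = Path(path)
    data = np.asarray(volume.voxels)
    if data.max(initial=0) < 2**15 and data.min(initial=0) >= -(2**15):
        data = data.astype(np.int16)
    else:
        data = data.astype(np.int32)
    img = nib.Nifti1Image(data, volume.affine)
    img.header["descrip"] = f"{volume.space_tag}|{volume.subject_id}|{volume.hemisphere}".encode()[:80]
    nib.save(img, str(path))
    return path


def read_label_volume(path) -> LabelVolume:
    """Read an integer NIfTI-1 label volume.

    Raises distinct diagnostics for a missing file, non-integer voxel data
    and a degenerate affine.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label volume not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        raise FormatError(f"non-integer labels: {path} has dtype {data.dtype}")
    descrip = img.header["descrip"].item().decode(errors="replace")
    parts = descrip.split("|")
    space_tag, subject_id, hemisphere = "native", "", "both"
    if len(parts) == 3 and parts[0] in ("native", "template"):
        space_tag, subject_id, hemisphere = parts
        if hemisphere not in HEMISPHERES:
            hemisphere = "both"
    return LabelVolume(
        voxels=data,
        affine=np.asarray(img.affine),
        space_tag=space_tag,
        subject_id=subject_id,
        hemisphere=hemisphere,
    )


def write_contours(stack: ContourStack, path) -> Path:
    """Write a contour stack as JSON (one feature per closed ring).

    Schema: top-level ``section_thickness_mm``, ``mounting_interval``,
    ``mapping_interval`` and a ``contours`` list whose items carry
    ``section_index``, ``region_code`` and ``ring`` — an [[x, y], ...] list
    of in-plane mm coordinates, implicitly closed.
    """
    path = Path(path)
    doc = {
        "format": "hippomap-contours-v1",
        "section_thickness_mm": stack.section_thickness,
        "mounting_interval": stack.mounting_interval,
        "mapping_interval": stack.mapping_interval,
        "contours": [
            {
                "section_index": c.section_index,
                "region_code": c.region_code,
                "ring": np.asarray(c.polygon).tolist(),
            }
            for c in stack.contours
        ],
    }
    path.write_text(json.dumps(doc))
    return path


def read_contours(path) -> ContourStack:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"contour file not found: {path}")
    doc = json.loads(path.read_text())
    if doc.get("format") != "hippomap-contours-v1":
        raise FormatError(f"{path}: not a hippomap contour file")
    contours = [
        Contour(
            section_index=int(c["section_index"]),
            region_code=int(c["region_code"]),
            polygon=np.asarray(c["ring"], dtype=float),
        )
        for c in doc["contours"]
    ]
    return ContourStack(
        contours=contours,
        section_thickness=float(doc["section_thickness_mm"]),
        mounting_interval=int(doc["mounting_interval"]),
        mapping_interval=int(doc["mapping_interval"]),
    )


def write_volume_table(table: VolumeTable, path) -> Path:
    path = Path(path)
    table.df.to_csv(path, index=False)
    return path


def read_volume_table(path) -> VolumeTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume table not found: {path}")
    df = pd.read_csv(path)
    return VolumeTable(df)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodebookReport:
    """Outcome of checking a label volume against a region codebook."""

    unknown_codes: tuple
    passed: bool

    def __str__(self) -> str:
        if self.passed:
            return "codebook check passed: all labels are in the codebook"
        return f"codebook check failed: unknown label codes {list(self.unknown_codes)}"


def validate_codebook(volume: LabelVolume, codebook: RegionCodebook) -> CodebookReport:
    """Report any label present in the volume but absent from the codebook."""
    present = set(int(v) for v in volume.labels_present())
    unknown = tuple(sorted(present - set(codebook.codes)))
    return CodebookReport(unknown_codes=unknown, passed=not unknown)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Declarative run configuration; every CLI run logs the resolved values."""

    section_thickness_mm: float = 0.020
    mounting_interval: int = 15
    mapping_interval: int = 60
    n_permutations: int = 1_000_000
    family_alpha: float = 0.05
    alternative: str = "two_sided"
    mpm_threshold: float = 0.0
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        doc = json.loads(Path(path).read_text())
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def log_resolved(self) -> None:
        logger.info("resolved config: %s", dataclasses.asdict(self))
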