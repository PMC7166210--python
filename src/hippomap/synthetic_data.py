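"""Phantom cohorts: labeled brain volumes, serial-section contours and
synthetic autoradiographs with co-exposed calibration standards.

The phantom stands in for a mapped hippocampal formation.  In every
section plane it shows two interlocking C-shaped band stacks around a
common centre: the inner C carries the hippocampus proper (FD innermost,
then CA4, CA3, CA2, CA1) and the outer C the subicular complex (ProS,
Sub, PreS, PaS, TrS outermost).  The band pattern is swept along the
sectioning axis with an ellipsoidal taper so cross-section areas vary
smoothly and vanish at the poles, mimicking the rostro-caudal extent of
a real structure.  No anatomical realism is claimed beyond region count,
adjacency order and plausible volume magnitudes.

Inter-subject variability is a random similarity transform (small
rotation, isotropic scale, translation) plus a per-brain shrinkage
factor emulating volume loss during histological processing.  All
generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation
from skimage import measure

from .core_io import (
    CANONICAL_REGIONS,
    Contour,
    ContourStack,
    LabelVolume,
    RegionCodebook,
    SubjectRecord,
)

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "FilmModel",
    "AutoradiographTruth",
    "StandardPatch",
    "make_phantom_subject",
    "make_cohort",
    "slice_to_contours",
    "simulate_autoradiograph",
]


#: Radial band thicknesses (mm), codebook order FD → TrS.  Chosen so the
#: ten regions span roughly the relative sizes seen in human material
#: (CA1 and FD large, CA4/PaS/TrS small) while every band stays at least
#: two voxels wide at the default grid resolution.
DEFAULT_BAND_THICKNESS = (1.2, 0.5, 0.6, 0.5, 1.8, 0.7, 0.9, 0.7, 0.5, 0.5)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and variability parameters of the phantom cohort."""

    grid_shape: tuple = (128, 128, 128)
    voxel_size_mm: float = 0.25
    n_regions: int = 10
    inner_radius_mm: float = 2.0
    band_thickness_mm: tuple = DEFAULT_BAND_THICKNESS
    half_length_mm: float = 12.0
    gap_degrees: float = 60.0
    max_rotation_deg: float = 5.0
    max_scale: float = 0.05
    max_translation_mm: float = 2.0
    shrinkage_factor_range: tuple = (0.7, 0.9)
    brain_semiaxes_mm: tuple = (13.0, 13.0, 13.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if len(self.band_thickness_mm) != self.n_regions:
            raise ValueError("band_thickness_mm must have one entry per region")
        if min(self.max_rotation_deg, self.max_scale, self.max_translation_mm) < 0:
            raise ValueError("jitter bounds must be >= 0")
        lo, hi = self.shrinkage_factor_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("shrinkage factors must lie in (0, 1]")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")

    @property
    def outer_radius_mm(self) -> float:
        return self.inner_radius_mm + float(np.sum(self.band_thickness_mm))

    def codebook(self) -> RegionCodebook:
        if self.n_regions == 10:
            return RegionCodebook.canonical()
        entries = tuple((i + 1, f"R{i + 1:02d}") for i in range(self.n_regions))
        return RegionCodebook(entries)


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth stored alongside each generated subject.

    ``region_volumes_mm3`` are voxel-count volumes of the generated
    (shrunken, "histological") grid; ``fresh_volumes_mm3`` divide out the
    shrinkage factor.  ``to_template`` is the similarity transform mapping
    this subject's world coordinates back to the canonical (template)
    frame, for use with :func:`hippomap.atlas_maps.to_template`.
    """

    region_volumes_mm3: dict
    fresh_volumes_mm3: dict
    shrinkage_factor: float
    total_brain_volume_mm3: float
    fresh_total_brain_volume_mm3: float
    to_template: np.ndarray


def _subject_rng(spec_seed: int, subject_id: str) -> np.random.Generator:
    # stable per-subject stream: spec seed mixed with a CRC of the id
    return np.random.default_rng(np.random.SeedSequence([spec_seed, zlib.crc32(subject_id.encode())]))


def _wrapped_angle(phi: np.ndarray, centre: float) -> np.ndarray:
    d = np.abs(phi - centre) % (2 * np.pi)
    return np.minimum(d, 2 * np.pi - d)


def _canonical_labels(u: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Evaluate the canonical phantom label field at world points u (n, 3)."""
    half = spec.half_length_mm
    taper = 1.0 - (u[:, 0] / half) ** 2
    inside_len = taper > 0
    w = np.sqrt(np.clip(taper, 1e-12, None))
    v1 = u[:, 1] / w
    v2 = u[:, 2] / w
    rho = np.hypot(v1, v2)
    phi = np.arctan2(v2, v1)

    bounds = spec.inner_radius_mm + np.concatenate([[0.0], np.cumsum(spec.band_thickness_mm)])
    band = np.searchsorted(bounds, rho, side="right") - 1  # -1 below inner radius
    in_band = (band >= 0) & (band < spec.n_regions)

    gap_half = np.deg2rad(spec.gap_degrees) / 2.0
    n_inner = (spec.n_regions + 1) // 2  # inner C: FD + CA fields
    # inner C opens towards +phi/2 pole, outer C towards the opposite pole
    inner_open = _wrapped_angle(phi, np.pi / 2) < gap_half
    outer_open = _wrapped_angle(phi, -np.pi / 2) < gap_half
    open_gap = np.where(band < n_inner, inner_open, outer_open)

    labels = np.zeros(u.shape[0], dtype=np.int16)
    keep = inside_len & in_band & ~open_gap
    labels[keep] = band[keep].astype(np.int16) + 1
    return labels


def _brain_mask(u: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    a = np.asarray(spec.brain_semiaxes_mm, dtype=float)
    return np.sum((u / a) ** 2, axis=1) <= 1.0


def _grid_world_coords(spec: PhantomSpec) -> tuple:
    shape = tuple(spec.grid_shape)
    vs = spec.voxel_size_mm
    # voxel centres, grid centred on world origin
    origin = -(np.asarray(shape, dtype=float) - 1) / 2.0 * vs
    affine = np.eye(4)
    affine[:3, :3] = np.eye(3) * vs
    affine[:3, 3] = origin
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    world = idx * vs + origin
    return world, affine


def make_phantom_subject(
    spec: PhantomSpec,
    subject_id: str,
    sex: str,
    hemisphere: str = "both",
    age: int = 65,
    fresh_weight: float = 1250.0,
):
    """Generate one phantom brain.

    Returns ``(LabelVolume, SubjectRecord, PhantomTruth)``.  The label
    volume is the subject's "histological" grid: the canonical phantom
    under a random similarity jitter and an isotropic shrinkage.  Region
    ground truth is computed by voxel count × voxel volume.
    """
    # the jittered, shrunken structure must still fit the grid
    fov_half = min(spec.grid_shape) * spec.voxel_size_mm / 2.0
    reach = max(spec.outer_radius_mm, spec.half_length_mm) * (1 + spec.max_scale) + spec.max_translation_mm
    if reach >= fov_half:
        raise ValueError(
            f"grid too small to hold all layers: structure reach {reach:.1f} mm "
            f"exceeds half field of view {fov_half:.1f} mm"
        )

    rng = _subject_rng(spec.seed, subject_id)
    angle = np.deg2rad(rng.uniform(-spec.max_rotation_deg, spec.max_rotation_deg))
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    R = Rotation.from_rotvec(angle * axis).as_matrix()
    jitter_scale = rng.uniform(1 - spec.max_scale, 1 + spec.max_scale)
    translation = rng.uniform(-spec.max_translation_mm, spec.max_translation_mm, size=3)
    shrink = float(rng.uniform(*spec.shrinkage_factor_range))
    lin = jitter_scale * shrink ** (1.0 / 3.0)

    # subject world x = lin * R @ u + t  ⇒  u = R.T @ (x − t) / lin
    world, affine = _grid_world_coords(spec)
    u = (world - translation) @ R / lin
    labels = _canonical_labels(u, spec).reshape(spec.grid_shape)
    mask = _brain_mask(u, spec).reshape(spec.grid_shape)

    vv = spec.voxel_size_mm ** 3
    counts = np.bincount(labels.ravel(), minlength=spec.n_regions + 1)
    hist_volumes = {code: float(counts[code]) * vv for code in range(1, spec.n_regions + 1)}
    fresh_volumes = {c: v / shrink for c, v in hist_volumes.items()}
    brain_hist = float(mask.sum()) * vv

    to_template = np.eye(4)
    to_template[:3, :3] = R.T / lin
    to_template[:3, 3] = -(R.T @ translation) / lin

    volume = LabelVolume(
        voxels=labels,
        affine=affine,
        space_tag="native",
        subject_id=subject_id,
        hemisphere=hemisphere,
    )
    record = SubjectRecord(
        subject_id=subject_id,
        age=age,
        sex=sex,
        fresh_weight=fresh_weight,
        hemispheres_available=frozenset({hemisphere} if hemisphere != "both" else {"left", "right"}),
    )
    truth = PhantomTruth(
        region_volumes_mm3=hist_volumes,
        fresh_volumes_mm3=fresh_volumes,
        shrinkage_factor=shrink,
        total_brain_volume_mm3=brain_hist,
        fresh_total_brain_volume_mm3=brain_hist / shrink,
        to_template=to_template,
    )
    return volume, record, truth


def make_cohort(spec: PhantomSpec, n_subjects: int = 10) -> list:
    """Generate the default mapping cohort: n subjects, sexes balanced.

    Returns a list of ``(LabelVolume, SubjectRecord, PhantomTruth)``
    tuples.  Ages and fresh weights are drawn once per subject from the
    ranges seen in adult post-mortem material (37–86 years, 1100–1450 g).
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC04027]))
    out = []
    for i in range(n_subjects):
        sex = "male" if i % 2 == 0 else "female"
        out.append(
            make_phantom_subject(
                spec,
                subject_id=f"P{i + 1:02d}",
                sex=sex,
                age=int(rng.integers(37, 87)),
                fresh_weight=float(rng.integers(1100, 1451)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Serial sectioning
# ---------------------------------------------------------------------------

def slice_to_contours(
    volume: LabelVolume,
    thickness: float = 0.020,
    mounting_interval: int = 15,
    mapping_interval: int = 60,
) -> ContourStack:
    """Cut a label volume into serial sections and trace mapped ones.

    Sections are perpendicular to the first grid axis and numbered from
    the low-index face; every ``mapping_interval``-th section is "mapped":
    each region's cross-section boundary on that plane is traced as closed
    polygons in section-plane mm coordinates (marching squares at the 0.5
    iso-level of the binary region mask).  Regions absent from every
    mapped plane are omitted with a warning.
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    if mounting_interval < 1 or mapping_interval < 1:
        raise ValueError("intervals must be >= 1")
    vs = volume.voxel_size
    spacing = thickness * mapping_interval
    if spacing < vs[0] - 1e-9:
        warnings.warn(
            f"mapped spacing {spacing:.3f} mm is finer than the voxel size {vs[0]:.3f} mm; "
            "contours on coincident voxel planes would be double-counted"
        )

    n_sections = int(round(volume.voxels.shape[0] * vs[0] / thickness))
    contours: list = []
    seen: set = set()
    for k in range(0, n_sections, mapping_interval):
        z_mm = (k + 0.5) * thickness
        plane = int(z_mm / vs[0])
        if plane >= volume.voxels.shape[0]:
            break
        sl = volume.voxels[plane]
        for code in np.unique(sl):
            if code == 0:
                continue
            mask = np.pad((sl == code).astype(float), 1)
            for ring in measure.find_contours(mask, 0.5):
                pts = (ring[:, :2] - 1.0) * np.array([vs[1], vs[2]])
                if np.allclose(pts[0], pts[-1]):
                    pts = pts[:-1]
                if len(pts) < 3:
                    continue
                try:
                    contours.append(Contour(section_index=k, region_code=int(code), polygon=pts))
                except ValueError:
                    continue  # degenerate sliver below the area floor
            seen.add(int(code))
    missing = set(int(c) for c in volume.labels_present()) - seen
    for code in sorted(missing):
        warnings.warn(f"region {code} absent at all mapped planes; omitted from contour stack")
    return ContourStack(
        contours=contours,
        section_thickness=thickness,
        mounting_interval=mounting_interval,
        mapping_interval=mapping_interval,
    )


# ---------------------------------------------------------------------------
# Autoradiograph simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilmModel:
    """Saturating film response: gray = g0 + g_max·(1 − exp(−gain·activity)).

    Strictly increasing for positive gain; ``standard_activities`` are the
    known radioactivity levels of the co-exposed plastic standards.
    Activity is taken proportional to binding-site density with unit
    proportionality, so standards are expressed directly in fmol/mg
    protein equivalents.
    """

    g_max: float = 200.0
    gain: float = 0.002
    g0: float = 10.0
    noise_sd: float = 2.0
    standard_activities: tuple = (0.0, 50.0, 100.0, 200.0, 300.0, 450.0, 600.0, 800.0)

    def __post_init__(self) -> None:
        if self.g_max <= 0 or self.gain <= 0:
            raise ValueError("film response must be strictly increasing (g_max, gain > 0)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        acts = tuple(float(a) for a in self.standard_activities)
        if len(acts) < 4 or any(b <= a for a, b in zip(acts, acts[1:])):
            raise ValueError("need >= 4 strictly increasing standard activities")
        object.__setattr__(self, "standard_activities", acts)

    def response(self, activity) -> np.ndarray:
        a = np.asarray(activity, dtype=float)
        return self.g0 + self.g_max * (1.0 - np.exp(-self.gain * a))

    def inverse_response(self, gray) -> np.ndarray:
        g = np.asarray(gray, dtype=float)
        x = np.clip(1.0 - (g - self.g0) / self.g_max, 1e-12, None)
        return -np.log(x) / self.gain

    @property
    def saturation_activity(self) -> float:
        """Activity at which the response reaches 98% of its asymptote."""
        return -np.log(0.02) / self.gain


@dataclass(frozen=True)
class StandardPatch:
    """Location and known activity of one co-exposed standard."""

    activity: float
    rows: tuple  # (start, stop)
    cols: tuple


@dataclass(frozen=True)
class AutoradiographTruth:
    """What the simulator actually rendered, for recovery tests."""

    region_densities: dict
    film: FilmModel
    saturation_warning: bool


def simulate_autoradiograph(
    section_labels: np.ndarray,
    true_density: Mapping[int, float],
    film: FilmModel,
    seed: int = 0,
    patch_size: int = 12,
):
    """Render a synthetic autoradiograph of one labeled section.

    The tissue area maps per-region densities through the film response;
    a margin strip on the right carries one square patch per co-exposed
    standard, rendered through the same response.  Gaussian gray-value
    noise (``film.noise_sd``) is added everywhere.

    Returns ``(gray_image, standards, truth)`` where ``standards`` is a
    list of :class:`StandardPatch` and ``truth`` records the rendered
    densities for recovery tests.
    """
    labels = np.asarray(section_labels)
    if labels.ndim != 2:
        raise ValueError("section_labels must be a 2-D grid")
    if any(d < 0 for d in true_density.values()):
        raise ValueError("densities must be >= 0")

    density = np.zeros(labels.shape, dtype=float)
    for code, d in true_density.items():
        density[labels == code] = d

    saturated = any(d > film.saturation_activity for d in true_density.values())
    if saturated:
        warnings.warn("some densities exceed the film saturation range; recovery will be poor")

    n_std = len(film.standard_activities)
    margin = patch_size + 8
    height = max(labels.shape[0], n_std * (patch_size + 4) + 4)
    width = labels.shape[1] + margin
    gray = np.full((height, width), film.response(0.0), dtype=float)
    gray[: labels.shape[0], : labels.shape[1]] = film.response(density)

    standards = []
    for i, act in enumerate(film.standard_activities):
        r0 = 4 + i * (patch_size + 4)
        c0 = labels.shape[1] + 4
        gray[r0 : r0 + patch_size, c0 : c0 + patch_size] = film.response(act)
        standards.append(StandardPatch(activity=act, rows=(r0, r0 + patch_size), cols=(c0, c0 + patch_size)))

    rng = np.random.default_rng(seed)
    if film.noise_sd > 0:
        gray = gray + rng.normal(0.0, film.noise_sd, size=gray.shape)
    gray = np.clip(gray, 0.0, film.g0 + film.g_max)

    truth = AutoradiographTruth(
        region_densities=dict(true_density),
        film=film,
        saturation_warning=saturated,
    )
    return gray, standards, truth
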