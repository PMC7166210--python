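"""Probabilistic maps and maximum probability parcellation in template space.

Subjects' label volumes are brought onto a common template grid by
nearest-neighbour resampling (labels are categorical; interpolation would
invent values and destroy the exact k/N quantization of overlap
fractions).  A region's continuous probability map stores, per voxel, the
fraction of subjects whose region covers that voxel.  The maximum
probability map assigns each voxel to the region with the highest
probability there; ties go first to the region with the larger mean
probability over the voxel's 26-neighbourhood, then to the lower region
code, yielding a deterministic, non-overlapping parcellation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import ndimage

from .core_io import LabelVolume

__all__ = [
    "ProbabilityMap",
    "MaxProbabilityMap",
    "OverlapStats",
    "to_template",
    "compute_pmap",
    "compute_mpm",
    "overlap_stats",
]


@dataclass
class ProbabilityMap:
    """Per-voxel overlap fraction of one region across N subjects."""

    region_code: int
    values: np.ndarray
    n_subjects: int
    affine: np.ndarray
    space_tag: str = "template"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("probability map must be 3-D")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))


@dataclass
class MaxProbabilityMap:
    """Argmax parcellation with per-voxel winning probability."""

    labels: np.ndarray
    winning_probability: np.ndarray
    threshold_used: float
    affine: np.ndarray
    n_subjects: int


@dataclass(frozen=True)
class OverlapStats:
    """Suprathreshold summary of one probability map."""

    region_code: int
    cut: float
    n_voxels: int
    volume_mm3: float
    centroid_mm: Optional[tuple]

    @property
    def defined(self) -> bool:
        return self.centroid_mm is not None


def to_template(
    volume: LabelVolume,
    transform: np.ndarray,
    template_affine: Optional[np.ndarray] = None,
    template_shape: Optional[tuple] = None,
) -> LabelVolume:
    """Resample a label volume onto the template grid.

    ``transform`` is the 4×4 world-to-world affine mapping subject-native
    mm coordinates to template mm coordinates.  Labels are pulled back by
    nearest-neighbour lookup, so the output label set is a subset of the
    input's.  The template grid defaults to the subject's own grid.
    """
    transform = np.asarray(transform, dtype=float)
    if transform.shape != (4, 4) or abs(np.linalg.det(transform[:3, :3])) < 1e-12:
        raise ValueError("transform must be an invertible 4x4 affine")
    if template_affine is None:
        template_affine = volume.affine
    if template_shape is None:
        template_shape = volume.voxels.shape
    # template voxel -> template world -> native world -> native voxel
    M = np.linalg.inv(volume.affine) @ np.linalg.inv(transform) @ np.asarray(template_affine, float)
    out = ndimage.affine_transform(
        volume.voxels,
        matrix=M[:3, :3],
        offset=M[:3, 3],
        output_shape=tuple(template_shape),
        order=0,
        mode="grid-constant",
        cval=0,
        prefilter=False,
    )
    return LabelVolume(
        voxels=out.astype(volume.voxels.dtype),
        affine=np.asarray(template_affine, float),
        space_tag="template",
        subject_id=volume.subject_id,
        hemisphere=volume.hemisphere,
    )


def compute_pmap(volumes: Sequence[LabelVolume], region_code: int) -> ProbabilityMap:
    """Voxelwise overlap fraction of one region over a subject cohort.

    All volumes must share the template grid; one volume per subject.
    The value at a voxel is (# subjects whose region covers it) / N,
    hence exactly quantized to multiples of 1/N.
    """
    if not volumes:
        raise ValueError("need at least one subject volume")
    ref = volumes[0]
    ids = [v.subject_id for v in volumes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject_id in cohort")
    counts = np.zeros(ref.voxels.shape, dtype=np.int32)
    for v in volumes:
        if v.voxels.shape != ref.voxels.shape or not np.allclose(v.affine, ref.affine):
            raise ValueError(f"grid mismatch for subject {v.subject_id!r}")
        counts += v.voxels == region_code
    n = len(volumes)
    return ProbabilityMap(
        region_code=region_code,
        values=counts / n,
        n_subjects=n,
        affine=ref.affine.copy(),
    )


def _neighbourhood_count_sum(values: np.ndarray, n_subjects: int) -> np.ndarray:
    """Summed subject counts over the 26-neighbourhood (centre excluded,
    zero-padded edges).

    Probabilities are exact multiples of 1/N, so the tie-break statistic
    is computed on integer counts: ordering by this sum is identical to
    ordering by the neighbourhood mean probability, but immune to
    float summation-order effects.
    """
    counts = np.rint(values * n_subjects)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    return np.rint(ndimage.correlate(counts, kernel, mode="constant", cval=0.0))


def compute_mpm(pmaps: Mapping[int, ProbabilityMap], threshold: float = 0.0) -> MaxProbabilityMap:
    """Maximum probability map: per-voxel argmax over region maps.

    A voxel is assigned iff some region has probability > 0 there and the
    maximum is ≥ ``threshold``.  Ties on the maximum are broken by the
    larger 26-neighbourhood mean probability, then by the lower region
    code.  The result is a non-overlapping parcellation (label 0 where
    unassigned).
    """
    if not pmaps:
        raise ValueError("empty probability map set")
    codes = np.array(sorted(pmaps.keys()))
    maps = [pmaps[int(c)] for c in codes]
    ref = maps[0]
    for m in maps[1:]:
        if m.values.shape != ref.values.shape or m.n_subjects != ref.n_subjects:
            raise ValueError("probability maps must share grid and subject count")
    stack = np.stack([m.values for m in maps])  # (R, X, Y, Z), code-ascending
    maxp = stack.max(axis=0)
    assigned = (maxp > 0) & (maxp >= threshold)

    neigh = np.stack([_neighbourhood_count_sum(m.values, m.n_subjects) for m in maps])
    # score: neighbourhood count sum where the region attains the max,
    # else -1; argmax returns the first (= lowest-code) among remaining ties
    score = np.where(stack == maxp, neigh, -1.0)
    winner = np.argmax(score, axis=0)
    labels = np.where(assigned, codes[winner], 0).astype(np.int32)
    return MaxProbabilityMap(
        labels=labels,
        winning_probability=np.where(assigned, maxp, 0.0),
        threshold_used=float(threshold),
        affine=ref.affine.copy(),
        n_subjects=ref.n_subjects,
    )


def overlap_stats(pmap: ProbabilityMap, cut: float) -> OverlapStats:
    """Size and probability-weighted centre of gravity of the set of
    voxels with overlap fraction ≥ ``cut`` (restricted to positive
    support), in template world mm.
    """
    if not 0.0 <= cut <= 1.0:
        raise ValueError("cut must lie in [0, 1]")
    sel = (pmap.values >= cut) & (pmap.values > 0)
    n = int(sel.sum())
    volume = n * pmap.voxel_volume_mm3
    if n == 0:
        return OverlapStats(pmap.region_code, cut, 0, 0.0, None)
    idx = np.argwhere(sel).astype(float)
    w = pmap.values[sel]
    world = idx @ pmap.affine[:3, :3].T + pmap.affine[:3, 3]
    cog = tuple((world * w[:, None]).sum(axis=0) / w.sum())
    return OverlapStats(pmap.region_code, cut, n, volume, cog)
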