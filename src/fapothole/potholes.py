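"""Pothole detection: z-maps, sub-threshold cluster labeling, summaries,
and group prevalence maps.

A "pothole" is a contiguous cluster of white-matter voxels whose FA z-score
against the control normative template falls strictly below a fixed negative
threshold (default z < −3) and whose extent reaches a minimum size. The size
filter defaults to 10 voxels; a mm³ variant is available, but at DTI-scale
voxel volumes (~12 mm³ here) a 10 mm³ filter is sub-voxel and inert, which is
why voxels are the operative default unit.

Contiguity is configurable as 6- (faces), 18- (faces+edges) or
26-connectivity (faces+edges+corners); the default is 26, the common default
of 3D cluster tools. Clusters are ordered by descending voxel count with ties
broken by ascending lexicographic peak index, so outputs are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .normative import NormativeTemplate
from .volume_io import (
    AtlasVolume,
    FAVolume,
    MaskVolume,
    VoxelGrid,
    check_grid_compatible,
)

__all__ = [
    "ZMap",
    "PotholeCluster",
    "PotholeSummary",
    "compute_zmap",
    "detect_potholes",
    "summarize_potholes",
    "prevalence_map",
]

DEFAULT_Z_THRESHOLD = -3.0
DEFAULT_MIN_SIZE = 10

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class ZMap:
    """Per-subject deviation map; NaN outside the valid voxels."""

    grid: VoxelGrid
    z: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.z.shape != self.grid.shape or self.valid_mask.shape != self.grid.shape:
            raise ValueError("z / valid_mask shape does not match grid")
        self.valid_mask = self.valid_mask.astype(bool)
        if not np.isfinite(self.z[self.valid_mask]).all():
            raise ValueError("non-finite z on valid voxels")


@dataclass
class PotholeCluster:
    """One contiguous sub-threshold cluster."""

    cluster_id: int
    voxel_indices: set[tuple[int, int, int]]
    n_voxels: int
    volume_mm3: float
    min_z: float
    peak_index: tuple[int, int, int]
    roi_overlap: dict[int, int] = field(default_factory=dict)


@dataclass
class PotholeSummary:
    """Per-subject aggregate pothole burden."""

    subject_id: str
    n_potholes: int
    total_pothole_volume_mm3: float
    mean_cluster_volume_mm3: float


def compute_zmap(subject: FAVolume, subject_mask: MaskVolume,
                 template: NormativeTemplate) -> ZMap:
    """z = (FA − template mean)/template SD on template-valid ∩ subject-mask voxels."""
    check_grid_compatible([subject, subject_mask])
    check_grid_compatible([subject.grid, template.grid])
    valid = template.valid_mask & subject_mask.values
    if not valid.any():
        raise ValueError("empty intersection of template valid mask and subject mask")
    z = np.full(subject.grid.shape, np.nan)
    z[valid] = (subject.values[valid] - template.mean[valid]) / template.sd[valid]
    return ZMap(grid=subject.grid, z=z, valid_mask=valid)


def detect_potholes(
    zmap: ZMap,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    min_size: float = DEFAULT_MIN_SIZE,
    size_units: str = "voxels",
    connectivity: int = 26,
    atlas: AtlasVolume | None = None,
) -> list[PotholeCluster]:
    """Label contiguous clusters of voxels with z strictly below the threshold.

    Components are kept when ``n_voxels >= min_size`` (``size_units="voxels"``)
    or ``volume_mm3 >= min_size`` (``size_units="mm3"``). Voxels flagged
    missing in the z-map can never join a cluster. When an atlas is supplied,
    each cluster's per-label overlapping voxel counts are recorded.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    if size_units not in {"voxels", "mm3"}:
        raise ValueError("size_units must be 'voxels' or 'mm3'")
    if atlas is not None:
        check_grid_compatible([zmap.grid, atlas.grid])

    below = zmap.valid_mask & (np.nan_to_num(zmap.z, nan=np.inf) < z_threshold)
    labeled, n_comp = ndimage.label(below, structure=_STRUCTURES[connectivity])
    voxel_volume = zmap.grid.voxel_volume_mm3

    raw: list[PotholeCluster] = []
    for comp in range(1, n_comp + 1):
        idx = np.argwhere(labeled == comp)
        n_vox = len(idx)
        vol = n_vox * voxel_volume
        if size_units == "voxels":
            if n_vox < min_size:
                continue
        elif vol < min_size:
            continue
        zvals = zmap.z[tuple(idx.T)]
        # peak = location of the minimum z; ties broken lexicographically
        zmin = float(zvals.min())
        at_min = idx[zvals == zmin]
        order = np.lexsort((at_min[:, 2], at_min[:, 1], at_min[:, 0]))
        peak = tuple(int(c) for c in at_min[order[0]])
        overlap: dict[int, int] = {}
        if atlas is not None:
            labels_here = atlas.labels[tuple(idx.T)]
            for lab, cnt in zip(*np.unique(labels_here, return_counts=True)):
                if lab != 0:
                    overlap[int(lab)] = int(cnt)
        raw.append(PotholeCluster(
            cluster_id=-1,
            voxel_indices={tuple(int(c) for c in v) for v in idx},
            n_voxels=n_vox,
            volume_mm3=vol,
            min_z=zmin,
            peak_index=peak,
            roi_overlap=overlap,
        ))

    raw.sort(key=lambda c: (-c.n_voxels, c.peak_index))
    for i, c in enumerate(raw, start=1):
        c.cluster_id = i
    return raw


def summarize_potholes(subject_id: str, clusters: Sequence[PotholeCluster],
                       voxel_volume: float | None = None) -> PotholeSummary:
    """Aggregate one subject's cluster list into count and volume totals."""
    n = len(clusters)
    total = float(sum(c.volume_mm3 for c in clusters))
    mean = total / n if n else 0.0
    return PotholeSummary(subject_id=subject_id, n_potholes=n,
                          total_pothole_volume_mm3=total,
                          mean_cluster_volume_mm3=mean)


def prevalence_map(
    cluster_sets: Sequence[Sequence[PotholeCluster]],
    atlas: AtlasVolume,
) -> tuple[dict[int, float], np.ndarray]:
    """Group prevalence of potholes, per atlas label and per voxel.

    For each label: the percentage of the group's subjects having at least
    one pothole voxel inside that label. Also returns a voxel-wise map of the
    percentage of subjects whose pothole set contains each voxel.
    """
    n_subjects = len(cluster_sets)
    if n_subjects == 0:
        raise ValueError("empty group")
    voxel_counts = np.zeros(atlas.grid.shape, dtype=np.float64)
    label_hits: dict[int, int] = {lab: 0 for lab in atlas.present_labels()}
    for clusters in cluster_sets:
        subject_voxels = np.zeros(atlas.grid.shape, dtype=bool)
        for c in clusters:
            for v in c.voxel_indices:
                subject_voxels[v] = True
        voxel_counts += subject_voxels
        hit_labels = np.unique(atlas.labels[subject_voxels])
        for lab in hit_labels:
            if lab != 0:
                label_hits[int(lab)] += 1
    per_label = {lab: 100.0 * hits / n_subjects for lab, hits in label_hits.items()}
    return per_label, 100.0 * voxel_counts / n_subjects
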