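"""Voxel-wise normative FA template from a control cohort.

The template holds, per voxel, the control-sample mean and SD of FA over the
white matter common to all controls. Subject deviation maps are then
z = (FA − mean)/SD on the valid voxels. Two scoring modes exist for control
subjects themselves: leave-one-out (default — each control is scored against
a template built from the remaining controls, avoiding self-deflation of its
own z-scores) and full-template (strict replication of scoring everyone
against one fixed template).

Sample SD uses denominator n−1. Voxels whose SD falls below ``sd_floor``
(default 1e-6, excluding exactly-constant voxels) are dropped from the valid
mask to keep z-maps finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .volume_io import FAVolume, MaskVolume, VoxelGrid, check_grid_compatible

__all__ = ["NormativeTemplate", "build_template", "build_template_loo", "CohortMoments"]

DEFAULT_SD_FLOOR = 1e-6


@dataclass
class NormativeTemplate:
    """Per-voxel control mean/SD with the valid-voxel mask."""

    grid: VoxelGrid
    mean: np.ndarray
    sd: np.ndarray
    valid_mask: np.ndarray
    n_controls: int

    def __post_init__(self) -> None:
        for name in ("mean", "sd", "valid_mask"):
            arr = getattr(self, name)
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape {arr.shape} != grid {self.grid.shape}")
        self.valid_mask = self.valid_mask.astype(bool)
        if self.n_controls < 2:
            raise ValueError("template requires n_controls >= 2")
        if (self.sd[self.valid_mask] < 0).any():
            raise ValueError("negative SD on valid voxels")


@dataclass
class CohortMoments:
    """Running sums over a control cohort, enabling O(n) leave-one-out.

    Holds Σx and Σx² per voxel plus the common mask, from which the full
    template and any held-out template are derived without re-reading data.
    """

    grid: VoxelGrid
    n: int
    sum_: np.ndarray
    sumsq: np.ndarray
    common_mask: np.ndarray
    volumes: list[np.ndarray]

    @classmethod
    def from_controls(cls, controls: Sequence[tuple[FAVolume, MaskVolume]]
                      ) -> "CohortMoments":
        if len(controls) < 2:
            raise ValueError("need at least 2 controls")
        check_grid_compatible([fa for fa, _ in controls] + [m for _, m in controls])
        grid = controls[0][0].grid
        common = np.ones(grid.shape, dtype=bool)
        for _, m in controls:
            common &= m.values
        if not common.any():
            raise ValueError("controls share no white-matter voxels")
        vols = [fa.values for fa, _ in controls]
        stack_sum = np.zeros(grid.shape)
        stack_sq = np.zeros(grid.shape)
        for v in vols:
            stack_sum += v
            stack_sq += v * v
        return cls(grid=grid, n=len(controls), sum_=stack_sum, sumsq=stack_sq,
                   common_mask=common, volumes=vols)

    def _template_from(self, s: np.ndarray, sq: np.ndarray, n: int,
                       sd_floor: float) -> NormativeTemplate:
        mean = s / n
        # sample variance with denominator n-1; clamp tiny negatives from rounding
        var = np.maximum(sq - n * mean * mean, 0.0) / (n - 1)
        sd = np.sqrt(var)
        valid = self.common_mask & (sd >= sd_floor)
        if not valid.any():
            raise ValueError("empty valid mask: all voxels below sd_floor")
        return NormativeTemplate(grid=self.grid, mean=mean, sd=sd,
                                 valid_mask=valid, n_controls=n)

    def full(self, sd_floor: float = DEFAULT_SD_FLOOR) -> NormativeTemplate:
        return self._template_from(self.sum_, self.sumsq, self.n, sd_floor)

    def leave_one_out(self, held_out: int,
                      sd_floor: float = DEFAULT_SD_FLOOR) -> NormativeTemplate:
        if not (0 <= held_out < self.n):
            raise IndexError(f"held_out {held_out} out of range for n={self.n}")
        if self.n < 3:
            raise ValueError("leave-one-out needs at least 3 controls")
        v = self.volumes[held_out]
        return self._template_from(self.sum_ - v, self.sumsq - v * v, self.n - 1,
                                   sd_floor)


def build_template(controls: Sequence[tuple[FAVolume, MaskVolume]],
                   sd_floor: float = DEFAULT_SD_FLOOR) -> NormativeTemplate:
    """Build the normative template from ≥2 co-registered controls.

    The valid mask is the intersection of all control white-matter masks minus
    voxels with sample SD below ``sd_floor``.
    """
    return CohortMoments.from_controls(controls).full(sd_floor)


def build_template_loo(controls: Sequence[tuple[FAVolume, MaskVolume]],
                       held_out_index: int,
                       sd_floor: float = DEFAULT_SD_FLOOR) -> NormativeTemplate:
    """Template from all controls except ``held_out_index`` (needs ≥3 controls)."""
    return CohortMoments.from_controls(controls).leave_one_out(held_out_index, sd_floor)
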