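"""Synthetic cohorts for exercising the pothole pipeline end to end.

The generator emulates the study design the pipeline was built for: a
reference cohort of 21 uninjured controls and two injured groups (52 mild,
17 moderate-to-severe) on a common registered grid. Control FA volumes are a
smooth region-wise mean field plus voxel-wise Gaussian noise inside a shared
white-matter mask; injured subjects are fresh control draws with planted
contiguous hypo-FA lesions whose voxel sets are recorded as ground truth, so
detection can be scored as a parameter-recovery problem. Metadata tables are
drawn from the printed group summaries (age, education, symptom inventories,
injury history, cause-of-injury proportions).

Lesion FA is defined against the *true* generating mean/SD, not the estimated
template, so recovery error isolates the pipeline's own estimation noise.
Truncation (FA to [0, 1], scores to their floors) is by clipping; at the
default noise levels it is a negligible perturbation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import cohort_reference as ref
from .volume_io import AtlasVolume, FAVolume, MaskVolume, VoxelGrid

__all__ = [
    "CohortSpec",
    "LesionSpec",
    "GroundTruth",
    "MetadataSpec",
    "default_grid",
    "make_toy_anatomy",
    "generate_control_cohort",
    "generate_tbi_subject",
    "generate_metadata",
]

# offsets of the 6-neighborhood, used for contiguous blob growth
_FACE_NEIGHBORS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def default_grid() -> VoxelGrid:
    """Desk-scale default grid: 32³ voxels at the study's 2 × 2.04 × 3 mm."""
    return VoxelGrid(shape=(32, 32, 32), voxel_size=(2.0, 2.04, 3.0),
                     orientation_tag="synthetic")


@dataclass(frozen=True)
class CohortSpec:
    """Control-cohort generating conditions.

    ``noise_sd`` is the voxel-wise between-subject SD of FA; 0.05 is a
    realistic figure for registered white matter. Region mean FA values are
    spread over ``base_fa_range`` across the toy atlas regions.
    """

    n_control: int = 21
    n_mtbi: int = 52
    n_mstbi: int = 17
    grid: VoxelGrid = field(default_factory=default_grid)
    base_fa_range: tuple[float, float] = (0.35, 0.60)
    noise_sd: float = 0.05
    n_regions: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_control, 1) < 1 or self.n_control < 2:
            raise ValueError("need at least 2 controls")
        if self.n_mtbi < 0 or self.n_mstbi < 0:
            raise ValueError("group sizes must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.base_fa_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("base_fa_range must lie in [0, 1]")
        if hi + 4.0 * self.noise_sd > 1.0:
            raise ValueError("base FA + 4·noise_sd must stay within [0, 1]")
        if min(self.grid.shape) < 4:
            raise ValueError("degenerate grid: need >= 4 voxels per axis")


@dataclass(frozen=True)
class LesionSpec:
    """Planted-lesion parameters.

    ``depth`` is in units of the voxel's generating SD: lesion FA is set to
    mean − depth·SD (clipped at 0). ``size_range_voxels`` bounds the lesion
    extent; shapes are 6-connected blobs or axis-aligned cuboids.
    """

    n_lesions: int = 3
    size_range_voxels: tuple[int, int] = (20, 40)
    depth: float = 6.0
    shape: str = "blob"

    def __post_init__(self) -> None:
        lo, hi = self.size_range_voxels
        if not (1 <= lo <= hi):
            raise ValueError("size range must satisfy 1 <= min <= max")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.shape not in {"blob", "cuboid"}:
            raise ValueError("shape must be 'blob' or 'cuboid'")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be non-negative")


@dataclass
class GroundTruth:
    """Planted lesion voxel sets for one subject."""

    lesions: list[set[tuple[int, int, int]]]

    @property
    def n_lesions(self) -> int:
        return len(self.lesions)

    @property
    def total_voxels(self) -> int:
        return sum(len(s) for s in self.lesions)

    def all_voxels(self) -> set[tuple[int, int, int]]:
        out: set[tuple[int, int, int]] = set()
        for s in self.lesions:
            out |= s
        return out

    def to_jsonable(self) -> list[list[list[int]]]:
        return [sorted([list(v) for v in s]) for s in self.lesions]

    @classmethod
    def from_jsonable(cls, data: Sequence[Sequence[Sequence[int]]]) -> "GroundTruth":
        return cls([{tuple(int(c) for c in v) for v in lesion} for lesion in data])


def make_toy_anatomy(spec: CohortSpec) -> tuple[MaskVolume, AtlasVolume, np.ndarray]:
    """Build the shared white-matter mask, toy atlas and true mean-FA field.

    The mask is a centered ellipsoid (semi-axes 0.42 of each dimension); the
    atlas splits its bounding box into octants, yielding up to ``n_regions``
    labels; the mean field is constant per region, spread evenly over
    ``base_fa_range``.
    """
    nx, ny, nz = spec.grid.shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    rx, ry, rz = 0.42 * nx, 0.42 * ny, 0.42 * nz
    mask = ((ii - cx) / rx) ** 2 + ((jj - cy) / ry) ** 2 + ((kk - cz) / rz) ** 2 <= 1.0

    # octant partition of the grid, intersected with the mask
    oct_id = ((ii >= cx).astype(int) * 4 + (jj >= cy).astype(int) * 2
              + (kk >= cz).astype(int))
    labels = np.where(mask, (oct_id % spec.n_regions) + 1, 0)

    lo, hi = spec.base_fa_range
    region_fa = np.linspace(lo, hi, spec.n_regions)
    base = np.zeros(spec.grid.shape, dtype=np.float64)
    for r in range(spec.n_regions):
        base[labels == r + 1] = region_fa[r]

    names = {r + 1: f"wm_region_{r + 1}" for r in range(spec.n_regions)}
    return (
        MaskVolume(grid=spec.grid, values=mask),
        AtlasVolume(grid=spec.grid, labels=labels, label_names=names),
        base,
    )


def _draw_control(base: np.ndarray, mask: np.ndarray, noise_sd: float,
                  grid: VoxelGrid, rng: np.random.Generator) -> FAVolume:
    noise = rng.normal(0.0, noise_sd, size=grid.shape)
    values = np.where(mask, np.clip(base + noise, 0.0, 1.0), 0.0)
    return FAVolume(grid=grid, values=values)


def generate_control_cohort(
    spec: CohortSpec,
) -> tuple[list[tuple[FAVolume, MaskVolume]], AtlasVolume, np.ndarray]:
    """Draw the control cohort.

    Returns ``(subjects, atlas, true_mean_field)`` where each subject is an
    ``(FAVolume, MaskVolume)`` pair sharing the cohort mask. Fully determined
    by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    mask_vol, atlas, base = make_toy_anatomy(spec)
    subjects = [
        (_draw_control(base, mask_vol.values, spec.noise_sd, spec.grid, rng), mask_vol)
        for _ in range(spec.n_control)
    ]
    return subjects, atlas, base


def _grow_blob(start: tuple[int, int, int], size: int, allowed: np.ndarray,
               rng: np.random.Generator) -> set[tuple[int, int, int]] | None:
    """Grow a 6-connected blob of `size` voxels inside `allowed`; None if stuck."""
    shape = allowed.shape
    blob = {start}
    frontier = [start]
    while len(blob) < size:
        if not frontier:
            return None
        idx = int(rng.integers(len(frontier)))
        v = frontier[idx]
        candidates = []
        for off in _FACE_NEIGHBORS:
            w = (v[0] + int(off[0]), v[1] + int(off[1]), v[2] + int(off[2]))
            if (0 <= w[0] < shape[0] and 0 <= w[1] < shape[1] and 0 <= w[2] < shape[2]
                    and allowed[w] and w not in blob):
                candidates.append(w)
        if not candidates:
            frontier.pop(idx)
            continue
        w = candidates[int(rng.integers(len(candidates)))]
        blob.add(w)
        frontier.append(w)
    return blob


def _cuboid_at(start: tuple[int, int, int], dims: tuple[int, int, int],
               allowed: np.ndarray) -> set[tuple[int, int, int]] | None:
    i0, j0, k0 = start
    di, dj, dk = dims
    shape = allowed.shape
    if i0 + di > shape[0] or j0 + dj > shape[1] or k0 + dk > shape[2]:
        return None
    block = allowed[i0:i0 + di, j0:j0 + dj, k0:k0 + dk]
    if not block.all():
        return None
    return {(i, j, k) for i in range(i0, i0 + di) for j in range(j0, j0 + dj)
            for k in range(k0, k0 + dk)}


def _cuboid_dims(size: int, rng: np.random.Generator) -> tuple[int, int, int]:
    """Near-isotropic factorization of `size` (product may undershoot slightly)."""
    a = max(1, round(size ** (1 / 3)))
    b = max(1, round((size / a) ** 0.5))
    c = max(1, size // (a * b))
    dims = [a, b, c]
    rng.shuffle(dims)
    return tuple(dims)  # type: ignore[return-value]


def generate_tbi_subject(
    base_draw: FAVolume,
    mask: MaskVolume,
    lesions: LesionSpec,
    true_mean: np.ndarray,
    true_sd: float | np.ndarray,
    seed: int | np.random.Generator,
    max_retries: int = 200,
) -> tuple[FAVolume, GroundTruth]:
    """Plant non-overlapping hypo-FA lesions into a control draw.

    Lesion voxels are set to ``true_mean − depth·true_sd`` (clipped at 0).
    Lesions are separated by at least one background voxel in the
    26-neighborhood sense, so each remains a distinct connected component.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = base_draw.values.copy()
    sd_field = np.broadcast_to(np.asarray(true_sd, dtype=np.float64), values.shape)

    allowed = mask.values.copy()
    placed: list[set[tuple[int, int, int]]] = []
    lo, hi = lesions.size_range_voxels
    mask_idx = np.argwhere(mask.values)

    for _ in range(lesions.n_lesions):
        target = int(rng.integers(lo, hi + 1))
        lesion = None
        for _attempt in range(max_retries):
            start = tuple(int(c) for c in mask_idx[int(rng.integers(len(mask_idx)))])
            if not allowed[start]:
                continue
            if lesions.shape == "blob":
                lesion = _grow_blob(start, target, allowed, rng)
            else:
                lesion = _cuboid_at(start, _cuboid_dims(target, rng), allowed)
            if lesion is not None:
                break
        if lesion is None:
            raise RuntimeError(
                f"could not place a {target}-voxel lesion after {max_retries} retries"
            )
        placed.append(lesion)
        # forbid the lesion and its 26-neighborhood for subsequent lesions
        for (i, j, k) in lesion:
            allowed[max(0, i - 1):i + 2, max(0, j - 1):j + 2, max(0, k - 1):k + 2] = False

    for lesion in placed:
        for v in lesion:
            values[v] = max(0.0, true_mean[v] - lesions.depth * sd_field[v])

    return FAVolume(grid=base_draw.grid, values=values), GroundTruth(placed)


# ---------------------------------------------------------------------------
# metadata tables


@dataclass(frozen=True)
class MetadataSpec:
    """Generating distributions for the subject metadata table.

    Defaults mirror the reference cohort's printed summaries: group sizes
    21/52/17, Normal(mean, SD) per measure truncated to plausible floors
    (age ≥ 18, scores ≥ 0, lifetime TBIs ≥ 1), and cause-of-injury categories
    drawn with the observed proportions.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(ref.GROUP_SIZES))
    three_group: dict[str, "GroupSummaryLike"] = field(
        default_factory=lambda: dict(ref.THREE_GROUP_SUMMARIES))
    tbi_only: dict[str, "GroupSummaryLike"] = field(
        default_factory=lambda: dict(ref.TBI_GROUP_SUMMARIES))
    cause_categories: tuple[str, ...] = ref.CAUSE_CATEGORIES
    seed: int = 0


GroupSummaryLike = object  # GroupSummary; alias avoids a circular annotation


_FLOORS = {"age_years": 18.0, "lifetime_tbis": 1.0}


def _truncated_normal(mean: float, sd: float, floor: float, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    draws = rng.normal(mean, sd, size=n) if sd > 0 else np.full(n, mean)
    return np.maximum(draws, floor)


def generate_metadata(spec: MetadataSpec | None = None) -> pd.DataFrame:
    """Simulate the subject metadata table; deterministic given ``spec.seed``."""
    spec = spec or MetadataSpec()
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    cause_probs = {}
    table = ref.CAUSE_OF_INJURY_TABLE.as_array().astype(float)
    for gi, g in enumerate(("mTBI", "msTBI")):
        cause_probs[g] = table[gi] / table[gi].sum()

    sid = 0
    for group, n in spec.group_sizes.items():
        for _ in range(n):
            row = {"subject_id": f"sub-{sid:03d}", "group": group}
            sid += 1
            rows.append(row)

    df = pd.DataFrame(rows)
    for measure, summary in spec.three_group.items():
        floor = _FLOORS.get(measure, 0.0)
        col = np.empty(len(df))
        for label, n, mean, sd in zip(summary.labels, summary.ns, summary.means,
                                      summary.sds):
            sel = (df["group"] == label).to_numpy()
            col[sel] = _truncated_normal(mean, sd, floor, int(sel.sum()), rng)
        df[measure] = col
    for measure, summary in spec.tbi_only.items():
        floor = _FLOORS.get(measure, 0.0)
        col = np.full(len(df), np.nan)
        for label, n, mean, sd in zip(summary.labels, summary.ns, summary.means,
                                      summary.sds):
            sel = (df["group"] == label).to_numpy()
            col[sel] = _truncated_normal(mean, sd, floor, int(sel.sum()), rng)
        df[measure] = col

    causes = np.array([""] * len(df), dtype=object)
    for g, probs in cause_probs.items():
        sel = (df["group"] == g).to_numpy()
        causes[sel] = rng.choice(spec.cause_categories, size=int(sel.sum()), p=probs)
    df["cause_of_injury"] = causes
    return df


def write_ground_truth(truths: dict[str, GroundTruth], path: str | Path) -> Path:
    """Serialize per-subject ground-truth lesion sets to JSON."""
    path = Path(path)
    payload = {sid: gt.to_jsonable() for sid, gt in truths.items()}
    path.write_text(json.dumps(payload, indent=0, sort_keys=True))
    return path


def read_ground_truth(path: str | Path) -> dict[str, GroundTruth]:
    payload = json.loads(Path(path).read_text())
    return {sid: GroundTruth.from_jsonable(data) for sid, data in payload.items()}
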