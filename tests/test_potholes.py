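import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fapothole.normative import NormativeTemplate, build_template
from fapothole.potholes import (
    ZMap,
    compute_zmap,
    detect_potholes,
    prevalence_map,
    summarize_potholes,
)
from fapothole.volume_io import AtlasVolume, FAVolume, MaskVolume, VoxelGrid

from cc_oracle import flood_fill_components
from conftest import constant_volume, full_mask


def make_zmap(z: np.ndarray, voxel_size=(2.0, 2.04, 3.0)) -> ZMap:
    grid = VoxelGrid(shape=z.shape, voxel_size=voxel_size, orientation_tag="test")
    return ZMap(grid=grid, z=z.astype(float), valid_mask=np.isfinite(z))


def uniform_template(grid, mean=0.5, sd=0.05) -> NormativeTemplate:
    return NormativeTemplate(grid=grid, mean=np.full(grid.shape, mean),
                             sd=np.full(grid.shape, sd),
                             valid_mask=np.ones(grid.shape, bool), n_controls=10)


class TestComputeZmap:
    def test_subject_equal_to_mean_gives_zero(self, small_grid):
        tpl = uniform_template(small_grid)
        zmap = compute_zmap(constant_volume(small_grid, 0.5),
                            full_mask(small_grid), tpl)
        assert np.abs(zmap.z[zmap.valid_mask]).max() == 0.0

    def test_exact_arithmetic(self, small_grid):
        tpl = uniform_template(small_grid, mean=0.50, sd=0.05)
        zmap = compute_zmap(constant_volume(small_grid, 0.35),
                            full_mask(small_grid), tpl)
        assert zmap.z[3, 3, 3] == pytest.approx(-3.0, abs=1e-12)

    def test_matches_scalar_loop_oracle(self, small_grid, rng):
        vols = [rng.random(small_grid.shape) for _ in range(8)]
        controls = [(FAVolume(grid=small_grid, values=v), full_mask(small_grid))
                    for v in vols]
        tpl = build_template(controls)
        subject = FAVolume(grid=small_grid, values=rng.random(small_grid.shape))
        zmap = compute_zmap(subject, full_mask(small_grid), tpl)
        for idx in rng.integers(0, 8, size=(30, 3)):
            i, j, k = map(int, idx)
            if zmap.valid_mask[i, j, k]:
                expected = (subject.values[i, j, k] - tpl.mean[i, j, k]) \
                    / tpl.sd[i, j, k]
                assert zmap.z[i, j, k] == pytest.approx(expected, abs=1e-12)

    def test_restricted_to_subject_mask(self, small_grid):
        tpl = uniform_template(small_grid)
        mvals = np.ones(small_grid.shape, bool)
        mvals[0] = False
        zmap = compute_zmap(constant_volume(small_grid, 0.4),
                            MaskVolume(grid=small_grid, values=mvals), tpl)
        assert not zmap.valid_mask[0].any()
        assert np.isnan(zmap.z[0]).all()

    def test_empty_intersection_raises(self, small_grid):
        tpl = uniform_template(small_grid)
        tpl.valid_mask[:] = False
        with pytest.raises(ValueError, match="empty"):
            compute_zmap(constant_volume(small_grid, 0.4),
                         full_mask(small_grid), tpl)


class TestDetectPotholes:
    def test_flat_zero_map_gives_no_clusters(self):
        assert detect_potholes(make_zmap(np.zeros((8, 8, 8)))) == []

    def test_planted_block_detected(self):
        z = np.zeros((10, 10, 10))
        z[2:5, 2:5, 2:5] = -5.0
        clusters = detect_potholes(make_zmap(z), min_size=10)
        assert len(clusters) == 1
        c = clusters[0]
        assert c.n_voxels == 27
        assert c.min_z == -5.0
        assert c.volume_mm3 == pytest.approx(27 * 2.0 * 2.04 * 3.0)

    def test_size_filter_boundary(self):
        z = np.zeros((8, 8, 8))
        z[1:4, 1:4, 1] = -5.0  # 9 voxels
        assert detect_potholes(make_zmap(z), min_size=10) == []
        assert len(detect_potholes(make_zmap(z), min_size=9)) == 1

    def test_threshold_is_strict(self):
        z = np.zeros((8, 8, 8))
        z[2:4, 2:4, 2:4] = -3.0  # exactly at the threshold: excluded
        assert detect_potholes(make_zmap(z), min_size=1) == []

    def test_corner_touching_blocks_connectivity_semantics(self):
        z = np.zeros((10, 10, 10))
        z[2:4, 2:4, 2:4] = -5.0
        z[4:6, 4:6, 4:6] = -5.0  # touches only at the (4,4,4)/(3,3,3) corner
        got26 = detect_potholes(make_zmap(z), min_size=1, connectivity=26)
        got6 = detect_potholes(make_zmap(z), min_size=1, connectivity=6)
        assert len(got26) == 1 and got26[0].n_voxels == 16
        assert len(got6) == 2 and {c.n_voxels for c in got6} == {8}

    def test_mm3_units(self):
        z = np.zeros((8, 8, 8))
        z[1:3, 1:3, 1:3] = -4.0  # 8 voxels x 12.24 mm^3 = 97.92 mm^3
        got = detect_potholes(make_zmap(z), min_size=100, size_units="mm3")
        assert got == []
        got = detect_potholes(make_zmap(z), min_size=90, size_units="mm3")
        assert len(got) == 1

    def test_missing_voxels_never_join_clusters(self):
        z = np.full((8, 8, 8), -5.0)
        z[4] = np.nan  # invalid plane splits the volume
        clusters = detect_potholes(make_zmap(z), min_size=1, connectivity=6)
        assert len(clusters) == 2
        assert all((v[0] != 4) for c in clusters for v in c.voxel_indices)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        for _ in range(20):
            shape = tuple(rng.integers(5, 13, size=3))
            z = np.where(rng.random(shape) < 0.3, -5.0, 0.0)
            got = detect_potholes(make_zmap(z), min_size=1,
                                  connectivity=connectivity)
            expected = flood_fill_components(z < -3, connectivity)
            assert sorted(len(c) for c in expected) \
                == sorted(c.n_voxels for c in got)
            assert {frozenset(c.voxel_indices) for c in got} \
                == {frozenset(c) for c in expected}

    def test_cluster_partition_invariants(self, rng):
        z = np.where(rng.random((12, 12, 12)) < 0.35, -5.0, 0.0)
        zmap = make_zmap(z)
        clusters = detect_potholes(zmap, min_size=2)
        seen = set()
        for c in clusters:
            assert all(zmap.z[v] < -3 for v in c.voxel_indices)
            assert not (c.voxel_indices & seen)
            seen |= c.voxel_indices
        # union of reported clusters == size-filtered thresholded set
        union_expected = set()
        for comp in flood_fill_components(z < -3, 26):
            if len(comp) >= 2:
                union_expected |= comp
        assert seen == union_expected

    def test_deterministic_ordering(self, rng):
        z = np.where(rng.random((12, 12, 12)) < 0.3, -5.0, 0.0)
        a = detect_potholes(make_zmap(z), min_size=1)
        b = detect_potholes(make_zmap(z), min_size=1)
        sizes = [c.n_voxels for c in a]
        assert sizes == sorted(sizes, reverse=True)
        assert [c.peak_index for c in a] == [c.peak_index for c in b]
        assert [c.cluster_id for c in a] == list(range(1, len(a) + 1))

    def test_bad_parameters(self):
        zm = make_zmap(np.zeros((6, 6, 6)))
        with pytest.raises(ValueError):
            detect_potholes(zm, min_size=0)
        with pytest.raises(ValueError):
            detect_potholes(zm, connectivity=4)
        with pytest.raises(ValueError):
            detect_potholes(zm, size_units="liters")

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_threshold_and_size_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        z = rng.normal(-1.5, 1.5, size=(10, 10, 10))
        zmap = make_zmap(z)
        # relaxing the threshold never shrinks the sub-threshold voxel pool
        vox_strict = sum(c.n_voxels for c in detect_potholes(zmap, -3, min_size=1))
        vox_loose = sum(c.n_voxels for c in detect_potholes(zmap, -2, min_size=1))
        assert vox_loose >= vox_strict
        # growing min_size never increases the cluster count
        counts = [len(detect_potholes(zmap, -2, min_size=s)) for s in (1, 3, 9, 27)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestSummaries:
    def test_empty(self):
        s = summarize_potholes("sub-000", [])
        assert (s.n_potholes, s.total_pothole_volume_mm3,
                s.mean_cluster_volume_mm3) == (0, 0.0, 0.0)

    def test_arithmetic(self):
        z = np.zeros((12, 12, 12))
        z[1:6, 1:3, 1] = -5.0   # 10 voxels
        z[8:11, 6:11, 2:4] = -5.0  # 30 voxels
        grid = VoxelGrid(shape=z.shape, voxel_size=(2.0, 2.0, 3.0))
        zmap = ZMap(grid=grid, z=z, valid_mask=np.ones_like(z, bool))
        clusters = detect_potholes(zmap, min_size=10)
        s = summarize_potholes("s", clusters)
        assert s.n_potholes == 2
        assert s.total_pothole_volume_mm3 == pytest.approx(40 * 12.0)
        assert s.mean_cluster_volume_mm3 == pytest.approx(20 * 12.0)

    def test_totals_equal_independent_summation(self, rng):
        z = np.where(rng.random((14, 14, 14)) < 0.3, -5.0, 0.0)
        clusters = detect_potholes(make_zmap(z), min_size=2)
        s = summarize_potholes("s", clusters)
        assert s.total_pothole_volume_mm3 == pytest.approx(
            sum(c.volume_mm3 for c in clusters))
        assert s.n_potholes == len(clusters)


class TestPrevalence:
    def _atlas(self, shape=(10, 10, 10)):
        grid = VoxelGrid(shape=shape, voxel_size=(2.0, 2.04, 3.0),
                         orientation_tag="test")
        labels = np.zeros(shape, dtype=np.int32)
        labels[:5] = 3
        labels[5:] = 5
        return AtlasVolume(grid=grid, labels=labels)

    def _clusters_at(self, voxels, shape=(10, 10, 10)):
        z = np.zeros(shape)
        for v in voxels:
            z[v] = -5.0
        return detect_potholes(make_zmap(z), min_size=1)

    def test_no_potholes_gives_zero_everywhere(self):
        atlas = self._atlas()
        per_label, voxelwise = prevalence_map([[], [], []], atlas)
        assert per_label == {3: 0.0, 5: 0.0}
        assert voxelwise.max() == 0.0

    def test_shared_cluster_gives_full_prevalence(self):
        atlas = self._atlas()
        block = [(1, j, k) for j in range(3) for k in range(3)]
        groups = [self._clusters_at(block) for _ in range(4)]
        per_label, voxelwise = prevalence_map(groups, atlas)
        assert per_label[3] == 100.0 and per_label[5] == 0.0
        assert voxelwise[1, 0, 0] == 100.0

    def test_partial_overlap_counting(self):
        # 7 of 20 subjects have a pothole voxel inside label 5
        atlas = self._atlas()
        inside = [(7, 7, 7)]
        outside = [(1, 1, 1)]
        groups = [self._clusters_at(inside) for _ in range(7)] \
            + [self._clusters_at(outside) for _ in range(13)]
        per_label, _ = prevalence_map(groups, atlas)
        assert per_label[5] == pytest.approx(35.0)
        assert per_label[3] == pytest.approx(65.0)
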