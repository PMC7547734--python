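"""Streamline voxelization and disconnectome maps against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from disconnectomics import disconnectome as dc
from disconnectomics import synthetic_data as sd
from disconnectomics.datatypes import LesionMask, Tractogram
from disconnectomics.grids import default_affine, world_to_voxel


def dense_sampling_oracle(streamline, shape, affine, step=0.01):
    """Independent reference: voxels containing densely sampled segment points.

    A finite step can miss a sliver where a segment clips a cube corner, so
    this oracle is a guaranteed *subset* of the true traversal.
    """
    pts = world_to_voxel(np.asarray(streamline, float), affine) + 0.5
    vox = set()
    for p, q in zip(pts[:-1], pts[1:]):
        length = np.linalg.norm(q - p)
        n = max(2, int(np.ceil(length / step)))
        for t in np.linspace(0.0, 1.0, n):
            c = np.floor(p + t * (q - p)).astype(int)
            if np.all(c >= 0) and np.all(c < shape):
                vox.add(tuple(c))
    for end in (pts[0], pts[-1]):
        c = np.floor(end).astype(int)
        if np.all(c >= 0) and np.all(c < shape):
            vox.add(tuple(c))
    return vox


def _segment_enters_cube(p, q, cube):
    """Liang–Barsky slab clipping: does segment p→q spend positive length
    inside the unit cube at `cube`?"""
    t0, t1 = 0.0, 1.0
    for ax in range(3):
        d = q[ax] - p[ax]
        lo, hi = cube[ax], cube[ax] + 1.0
        if d == 0.0:
            if not (lo <= p[ax] < hi):
                return False
        else:
            ta, tb = (lo - p[ax]) / d, (hi - p[ax]) / d
            if ta > tb:
                ta, tb = tb, ta
            t0, t1 = max(t0, ta), min(t1, tb)
            if t0 >= t1:
                return False
    return True


def clipping_oracle(streamline, shape, affine):
    """Exact reference: scan every grid voxel with a segment-cube clip test,
    plus the voxels containing the polyline's vertices."""
    pts = world_to_voxel(np.asarray(streamline, float), affine) + 0.5
    vox = set()
    for c in pts:
        v = np.floor(c).astype(int)
        if np.all(v >= 0) and np.all(v < shape):
            vox.add(tuple(v))
    for p, q in zip(pts[:-1], pts[1:]):
        lo = np.maximum(np.floor(np.minimum(p, q)).astype(int) - 1, 0)
        hi = np.minimum(np.floor(np.maximum(p, q)).astype(int) + 1, np.array(shape) - 1)
        for i in range(lo[0], hi[0] + 1):
            for j in range(lo[1], hi[1] + 1):
                for k in range(lo[2], hi[2] + 1):
                    if (i, j, k) not in vox and _segment_enters_cube(p, q, (i, j, k)):
                        vox.add((i, j, k))
    return vox


GRID = (10, 10, 10)
AFFINE = default_affine(GRID, (1.0, 1.0, 1.0))


def _world(*voxels):
    """World coordinates of voxel centres on the unit test grid."""
    from disconnectomics.grids import voxel_to_world

    return voxel_to_world(np.array(voxels, dtype=float), AFFINE)


class TestStreamlineVoxels:
    def test_axis_aligned_segment(self):
        s = _world((0, 0, 0), (2, 0, 0))
        assert dc.streamline_voxels(s, GRID, AFFINE) == {(0, 0, 0), (1, 0, 0), (2, 0, 0)}

    def test_single_point_streamline(self):
        s = _world((3, 4, 5))
        assert dc.streamline_voxels(s, GRID, AFFINE) == {(3, 4, 5)}

    def test_oblique_segments_match_oracles(self, rng):
        for _ in range(30):
            pts = rng.uniform(-4.4, 4.4, size=(3, 3))  # world coords within grid
            got = dc.streamline_voxels(pts, GRID, AFFINE)
            assert got == clipping_oracle(pts, GRID, AFFINE)
            assert dense_sampling_oracle(pts, GRID, AFFINE) <= got

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        coords=st.lists(
            st.tuples(*[st.floats(-4.45, 4.45, allow_nan=False) for _ in range(3)]),
            min_size=1,
            max_size=4,
        )
    )
    def test_supercover_equals_clipping_oracle_property(self, coords):
        pts = np.array(coords, dtype=float)
        got = dc.streamline_voxels(pts, GRID, AFFINE)
        assert got == clipping_oracle(pts, GRID, AFFINE)
        assert dense_sampling_oracle(pts, GRID, AFFINE, step=0.002) <= got

    def test_out_of_grid_points_clipped(self):
        s = np.array([[100.0, 0, 0], [120.0, 0, 0]])
        assert dc.streamline_voxels(s, GRID, AFFINE) == set()


def _lesion_from_voxels(voxels, shape=GRID):
    vol = np.zeros(shape, dtype=bool)
    for v in voxels:
        vol[v] = True
    return LesionMask(
        volume=vol, hemisphere="left", size_vox=len(voxels), source="observed", id="les"
    )


def _tractogram(streamlines):
    return Tractogram(subject_id="s0", streamlines=streamlines, affine=AFFINE, shape=GRID)


class TestSelectStreamlines:
    def test_endpoint_hit_selects_only_that_streamline(self):
        tg = _tractogram([_world((0, 0, 0), (3, 0, 0)), _world((0, 5, 5), (3, 5, 5))])
        lesion = _lesion_from_voxels([(0, 0, 0)])
        assert dc.select_streamlines(tg, lesion) == [0]

    def test_empty_lesion_selects_nothing(self):
        tg = _tractogram([_world((0, 0, 0), (3, 0, 0))])
        assert dc.select_streamlines(tg, _lesion_from_voxels([])) == []

    def test_matches_per_streamline_brute_force(self, rng):
        streamlines = [rng.uniform(-4.4, 4.4, size=(3, 3)) for _ in range(40)]
        tg = _tractogram(streamlines)
        lesion_vox = {tuple(v) for v in rng.integers(0, 10, size=(12, 3))}
        lesion = _lesion_from_voxels(lesion_vox)
        got = dc.select_streamlines(tg, lesion)
        want = [
            i
            for i, s in enumerate(streamlines)
            if dense_sampling_oracle(s, GRID, AFFINE) & lesion_vox
        ]
        assert got == want

    def test_grid_mismatch_rejected(self):
        tg = _tractogram([_world((0, 0, 0), (1, 0, 0))])
        bad = _lesion_from_voxels([(0, 0, 0)], shape=(8, 8, 8))
        with pytest.raises(ValueError, match="grid mismatch"):
            dc.select_streamlines(tg, bad)


class TestVisitationAndMap:
    def test_no_intersection_gives_zero_map(self):
        tg = _tractogram([_world((0, 0, 0), (3, 0, 0))])
        vis = dc.subject_visitation_map(tg, _lesion_from_voxels([(9, 9, 9)]))
        assert not vis.any()

    def test_single_streamline_visitation_is_its_supercover(self):
        s = _world((0, 0, 0), (4, 3, 2))
        tg = _tractogram([s])
        lesion = _lesion_from_voxels([(0, 0, 0)])
        vis = dc.subject_visitation_map(tg, lesion)
        assert set(map(tuple, np.argwhere(vis))) == dc.streamline_voxels(s, GRID, AFFINE)

    def test_overlapping_streamlines_stay_binary(self):
        s = _world((0, 0, 0), (4, 0, 0))
        tg = _tractogram([s, s])
        vis = dc.subject_visitation_map(tg, _lesion_from_voxels([(0, 0, 0)]))
        assert set(np.unique(vis)) <= {False, True}

    def test_single_subject_map_is_binary(self):
        tg = _tractogram([_world((0, 0, 0), (4, 0, 0))])
        dmap = dc.disconnectome_map(_lesion_from_voxels([(0, 0, 0)]), [tg])
        assert set(np.unique(dmap.volume)) <= {0.0, 1.0}

    def test_fraction_of_subjects_visiting(self):
        hit = _world((0, 0, 0), (2, 0, 0))
        miss = _world((0, 9, 9), (2, 9, 9))
        tgs = [_tractogram([hit]), _tractogram([hit]), _tractogram([hit]), _tractogram([miss])]
        dmap = dc.disconnectome_map(_lesion_from_voxels([(0, 0, 0)]), tgs)
        assert dmap.volume[1, 0, 0] == pytest.approx(0.75)

    def test_values_on_lattice_and_in_unit_interval(self, toy_brain, planted):
        lesion = planted["cohort"][0]
        dmap = dc.disconnectome_map(lesion, planted["tractograms"])
        dmap.validate()

    def test_empty_tractogram_list_rejected(self):
        with pytest.raises(ValueError):
            dc.disconnectome_map(_lesion_from_voxels([(0, 0, 0)]), [])

    def test_monotone_under_lesion_growth(self, rng):
        streamlines = [rng.uniform(-4.4, 4.4, size=(3, 3)) for _ in range(25)]
        tgs = [_tractogram(streamlines[:12]), _tractogram(streamlines[12:])]
        small_vox = {tuple(v) for v in rng.integers(2, 8, size=(4, 3))}
        big_vox = small_vox | {tuple(v) for v in rng.integers(0, 10, size=(8, 3))}
        small = dc.disconnectome_map(_lesion_from_voxels(small_vox), tgs)
        big = dc.disconnectome_map(_lesion_from_voxels(big_vox), tgs)
        assert np.all(big.volume >= small.volume)

    def test_mirror_symmetry_about_midsagittal_plane(self, rng):
        streamlines = [rng.uniform(-4.3, 4.3, size=(3, 3)) for _ in range(20)]
        mirrored = [s * np.array([-1.0, 1.0, 1.0]) for s in streamlines]
        vox = [tuple(v) for v in rng.integers(1, 9, size=(6, 3))]
        vox_m = [(9 - i, j, k) for i, j, k in vox]
        a = dc.disconnectome_map(_lesion_from_voxels(vox), [_tractogram(streamlines)])
        b = dc.disconnectome_map(_lesion_from_voxels(vox_m), [_tractogram(mirrored)])
        np.testing.assert_array_equal(b.volume, a.volume[::-1, :, :])

    def test_cohort_helper_equals_per_lesion_maps(self, toy_brain, planted):
        lesions = planted["cohort"][:5]
        tgs = planted["tractograms"]
        batch = dc.disconnectome_cohort(lesions, tgs)
        for les, got in zip(lesions, batch):
            want = dc.disconnectome_map(les, tgs)
            np.testing.assert_array_equal(got.volume, want.volume)

    def test_vertex_mode_subset_of_supercover(self, rng):
        s = rng.uniform(-4.4, 4.4, size=(4, 3))
        vertex = dc.streamline_voxels(s, GRID, AFFINE, mode="vertex")
        sup = dc.streamline_voxels(s, GRID, AFFINE, mode="supercover")
        assert vertex <= sup
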