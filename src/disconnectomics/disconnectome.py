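"""Per-lesion disconnection probability maps from healthy tractograms.

For each lesion, the streamlines of every subject's tractogram that pass
through the lesion are selected; the voxels those streamlines traverse form a
binary per-subject visitation map; averaging the binary maps across subjects
yields a voxelwise probability of disconnection in [0, 1].

"Passes through" is decided by segment-supercover traversal: a streamline
visits every voxel whose cube any of its segments crosses (plus the voxels
containing its vertices). A vertex-only mode is kept for cross-checks.
"""

from __future__ import annotations

import math

import numpy as np

from .datatypes import DisconnectomeMap, LesionMask, Tractogram
from .grids import check_affine, world_to_voxel

__all__ = [
    "streamline_voxels",
    "select_streamlines",
    "subject_visitation_map",
    "disconnectome_map",
    "disconnectome_cohort",
]


def _segment_voxels(p: np.ndarray, q: np.ndarray, shape, out: set) -> None:
    """Voxels visited by the segment p→q given in *cube* coordinates.

    Cube coordinates place voxel v on [v, v+1)^3; crossings of integer planes
    partition the segment into intervals, each lying inside one voxel, which
    is read off at the interval midpoint.
    """
    d = q - p
    ts = [0.0, 1.0]
    for ax in range(3):
        if d[ax] != 0.0:
            lo = math.ceil(min(p[ax], q[ax]))
            hi = math.floor(max(p[ax], q[ax]))
            for plane in range(lo, hi + 1):
                t = (plane - p[ax]) / d[ax]
                if 0.0 < t < 1.0:
                    ts.append(t)
    ts.sort()
    prev = ts[0]
    for t in ts[1:]:
        if t <= prev:
            continue
        mid = p + 0.5 * (prev + t) * d
        vox = (math.floor(mid[0]), math.floor(mid[1]), math.floor(mid[2]))
        if 0 <= vox[0] < shape[0] and 0 <= vox[1] < shape[1] and 0 <= vox[2] < shape[2]:
            out.add(vox)
        prev = t


def streamline_voxels(streamline, shape, affine, mode: str = "supercover") -> set:
    """Set of 0-based voxel indices a polyline traverses on the given grid.

    Points mapping outside the grid are clipped out of the result.
    """
    affine = check_affine(affine)
    pts = world_to_voxel(np.atleast_2d(np.asarray(streamline, dtype=float)), affine) + 0.5
    out: set = set()

    def add_vertex(c):
        vox = (math.floor(c[0]), math.floor(c[1]), math.floor(c[2]))
        if 0 <= vox[0] < shape[0] and 0 <= vox[1] < shape[1] and 0 <= vox[2] < shape[2]:
            out.add(vox)

    for c in pts:
        add_vertex(c)
    if mode == "vertex" or len(pts) < 2:
        return out
    if mode != "supercover":
        raise ValueError(f"unknown traversal mode {mode!r}")
    for p, q in zip(pts[:-1], pts[1:]):
        _segment_voxels(p, q, shape, out)
    return out


def _tractogram_voxel_sets(tractogram: Tractogram, shape, mode: str) -> list:
    """Per-streamline voxel sets, memoised on the tractogram."""
    key = (tuple(shape), mode)
    cached = tractogram._voxel_cache.get(key)
    if cached is None:
        cached = [
            frozenset(streamline_voxels(s, shape, tractogram.affine, mode=mode))
            for s in tractogram.streamlines
        ]
        tractogram._voxel_cache[key] = cached
    return cached


def _check_grid(tractogram: Tractogram, lesion: LesionMask) -> None:
    if tractogram.shape is not None and tuple(tractogram.shape) != lesion.volume.shape:
        raise ValueError(
            f"grid mismatch: lesion {lesion.volume.shape} vs tractogram {tractogram.shape}"
        )


def select_streamlines(
    tractogram: Tractogram, lesion: LesionMask, mode: str = "supercover"
) -> list[int]:
    """Indices of streamlines whose traversed voxels intersect the lesion."""
    _check_grid(tractogram, lesion)
    lesion_vox = set(map(tuple, np.argwhere(lesion.volume)))
    sets = _tractogram_voxel_sets(tractogram, lesion.volume.shape, mode)
    return [i for i, s in enumerate(sets) if not lesion_vox.isdisjoint(s)]


def subject_visitation_map(
    tractogram: Tractogram, lesion: LesionMask, mode: str = "supercover"
) -> np.ndarray:
    """Binary union of traversed voxels over the selected streamlines."""
    _check_grid(tractogram, lesion)
    sets = _tractogram_voxel_sets(tractogram, lesion.volume.shape, mode)
    vis = np.zeros(lesion.volume.shape, dtype=bool)
    for i in select_streamlines(tractogram, lesion, mode=mode):
        for vox in sets[i]:
            vis[vox] = True
    return vis


def disconnectome_map(
    lesion: LesionMask, tractograms: list[Tractogram], mode: str = "supercover"
) -> DisconnectomeMap:
    """Mean of the per-subject binary visitation maps."""
    if not tractograms:
        raise ValueError("need at least one tractogram")
    acc = np.zeros(lesion.volume.shape, dtype=float)
    for tg in tractograms:
        acc += subject_visitation_map(tg, lesion, mode=mode)
    return DisconnectomeMap(
        volume=acc / len(tractograms), lesion_id=lesion.id, n_subjects=len(tractograms)
    )


def disconnectome_cohort(
    lesions: list[LesionMask], tractograms: list[Tractogram], mode: str = "supercover"
) -> list[DisconnectomeMap]:
    """Disconnectome maps for a whole cohort, sharing per-streamline voxel sets.

    An inverted voxel → streamline index is built once per subject so each
    lesion only touches the streamlines that can intersect it.
    """
    if not lesions:
        return []
    if not tractograms:
        raise ValueError("need at least one tractogram")
    shape = lesions[0].volume.shape
    inverted = []
    all_sets = []
    for tg in tractograms:
        sets = _tractogram_voxel_sets(tg, shape, mode)
        index: dict = {}
        for i, s in enumerate(sets):
            for vox in s:
                index.setdefault(vox, []).append(i)
        inverted.append(index)
        all_sets.append(sets)
    out = []
    for lesion in lesions:
        if lesion.volume.shape != shape:
            raise ValueError(f"lesion {lesion.id} is on a different grid")
        lesion_vox = list(map(tuple, np.argwhere(lesion.volume)))
        acc = np.zeros(shape, dtype=float)
        for index, sets in zip(inverted, all_sets):
            hit: set = set()
            for vox in lesion_vox:
                hit.update(index.get(vox, ()))
            if not hit:
                continue
            vis = np.zeros(shape, dtype=bool)
            for i in hit:
                for vox in sets[i]:
                    vis[vox] = True
            acc += vis
        out.append(
            DisconnectomeMap(
                volume=acc / len(tractograms), lesion_id=lesion.id, n_subjects=len(tractograms)
            )
        )
    return out
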