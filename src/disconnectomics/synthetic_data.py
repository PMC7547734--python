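"""Self-contained toy inputs with planted statistical structure.

Everything downstream — synthetic-lesion pairing, disconnectome mapping,
component modelling, term association, voxelwise statistics — is testable on
the volumes, tractograms, lesion cohorts and term matrices produced here.

The toy brain is a two-hemisphere box split at the mid-sagittal world plane.
Each hemisphere carries a front and a back grey slab tiled into contiguous
parcels, separated by an interior white-matter band through which all
simulated fibre bundles run. Lesion cohorts are drawn either from a small
number of recurrent spatial clusters (the stereotyped, stroke-like regime) or
uniformly over the brain; cognitive term maps are noisy linear mixtures of
planted disconnection patterns so that recovery can be checked exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import HEMI_CODES, LEFT, RIGHT, LesionMask, Tractogram
from .grids import default_affine, voxel_to_world, world_to_voxel
from .term_association import TermMatrix

__all__ = [
    "ToyBrainSpec",
    "PlantedStructure",
    "make_toy_brain",
    "make_toy_tractograms",
    "plant_lesion_cohort",
    "make_toy_term_maps",
    "bundle_waypoint",
    "planted_bundle_structure",
]


@dataclass
class ToyBrainSpec:
    """Simulated common space: grid, masks, parcellation and region table."""

    grid_shape: tuple
    voxel_size: tuple
    affine: np.ndarray
    brain_mask: np.ndarray
    hemisphere_labels: np.ndarray
    parcellation: np.ndarray
    region_table: pd.DataFrame
    wm_mask: np.ndarray

    @property
    def region_ids(self) -> np.ndarray:
        return self.region_table["region_id"].to_numpy()

    @property
    def n_regions(self) -> int:
        return len(self.region_table)

    def region_mask(self, region_id: int) -> np.ndarray:
        if region_id not in set(self.region_table["region_id"]):
            raise KeyError(f"unknown region id {region_id}")
        return self.parcellation == region_id

    def region_centroid_world(self, region_id: int) -> np.ndarray:
        idx = np.argwhere(self.region_mask(region_id))
        if idx.size == 0:
            raise ValueError(f"region {region_id} is empty")
        return voxel_to_world(idx.mean(axis=0), self.affine)[0]

    def hemisphere_mask(self, hemisphere: str) -> np.ndarray:
        return self.hemisphere_labels == HEMI_CODES[hemisphere]

    def validate(self) -> None:
        """Exhaustive scan of the geometric invariants."""
        if np.any((self.parcellation > 0) & ~self.brain_mask):
            raise ValueError("parcel voxel outside brain mask")
        if np.any((self.hemisphere_labels > 0) != self.brain_mask):
            raise ValueError("hemisphere labels inconsistent with brain mask")
        ids = self.region_ids
        if not np.array_equal(ids, np.arange(1, len(ids) + 1)):
            raise ValueError("region ids are not consecutive from 1")
        for _, row in self.region_table.iterrows():
            hemi_in_vol = np.unique(self.hemisphere_labels[self.parcellation == row.region_id])
            if len(hemi_in_vol) != 1 or hemi_in_vol[0] != HEMI_CODES[row.hemisphere]:
                raise ValueError(f"region {row.region_id} spans hemispheres")
        if np.any(self.wm_mask & ~self.brain_mask):
            raise ValueError("white-matter voxel outside brain mask")


@dataclass
class PlantedStructure:
    """Ground truth planted into a toy study.

    ``pattern_region_profiles`` holds the K region-wise disconnection
    signatures that the stereotyped cohort should express;
    ``pattern_lesion_seeds`` the world-space cluster centres the lesions recur
    at; ``term_mixing`` how each synthetic cognitive term blends the patterns.
    """

    n_patterns: int
    pattern_region_profiles: np.ndarray  # K x n_regions, nonnegative, unit max
    pattern_lesion_seeds: np.ndarray  # K x 3 world mm
    term_mixing: np.ndarray  # n_terms x K
    noise_sd: float = 0.0
    pattern_pairs: list = field(default_factory=list)  # bookkeeping: bundle per pattern

    def __post_init__(self):
        self.pattern_region_profiles = np.atleast_2d(
            np.asarray(self.pattern_region_profiles, dtype=float)
        )
        self.pattern_lesion_seeds = np.atleast_2d(
            np.asarray(self.pattern_lesion_seeds, dtype=float)
        )
        self.term_mixing = np.atleast_2d(np.asarray(self.term_mixing, dtype=float))
        if self.pattern_region_profiles.shape[0] != self.n_patterns:
            raise ValueError("pattern_region_profiles rows must equal n_patterns")
        if np.any(self.pattern_region_profiles < 0):
            raise ValueError("pattern profiles must be nonnegative")
        maxima = self.pattern_region_profiles.max(axis=1)
        if np.any(maxima <= 0):
            raise ValueError("each pattern profile needs a positive entry")
        # unit-maximum normalisation is part of the contract
        self.pattern_region_profiles = self.pattern_region_profiles / maxima[:, None]
        if self.term_mixing.shape[1] != self.n_patterns:
            raise ValueError("term_mixing columns must equal n_patterns")
        if np.any(np.all(self.term_mixing == 0, axis=1)):
            raise ValueError("term_mixing rows must not be all-zero")


# ---------------------------------------------------------------------------
# toy brain


def make_toy_brain(grid_shape, regions_per_hemisphere: int, seed: int = 0) -> ToyBrainSpec:
    """Build the deterministic two-hemisphere toy brain.

    The brain is the box one voxel in from every face. Interior y-thirds give
    a front grey slab, a white-matter band, and a back grey slab; each grey
    slab is tiled along z into contiguous parcels, per hemisphere. Hemispheres
    split at the mid-sagittal world plane (x = 0); a voxel exactly on the
    plane counts as left.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    if len(grid_shape) != 3 or any(g < 8 for g in grid_shape):
        raise ValueError(f"grid_shape must be three dims each >= 8, got {grid_shape}")
    if regions_per_hemisphere < 2:
        raise ValueError("regions_per_hemisphere must be >= 2")
    del seed  # construction is deterministic; kept for a uniform generator API

    nx, ny, nz = grid_shape
    voxel_size = (2.0, 2.0, 2.0)
    affine = default_affine(grid_shape, voxel_size)

    brain = np.zeros(grid_shape, dtype=bool)
    brain[1 : nx - 1, 1 : ny - 1, 1 : nz - 1] = True

    # hemisphere split at world x = 0 (voxels on the plane -> left)
    xs_world = voxel_to_world(
        np.stack([np.arange(nx), np.zeros(nx), np.zeros(nx)], axis=1), affine
    )[:, 0]
    hemi = np.zeros(grid_shape, dtype=np.int8)
    left_cols = xs_world <= 0.0
    hemi[left_cols, :, :] = 1
    hemi[~left_cols, :, :] = 2
    hemi[~brain] = 0

    # interior y-thirds: front grey / white-matter band / back grey
    y_interior = np.arange(1, ny - 1)
    front_y, wm_y, back_y = np.array_split(y_interior, 3)
    wm = np.zeros(grid_shape, dtype=bool)
    wm[1 : nx - 1, wm_y[0] : wm_y[-1] + 1, 1 : nz - 1] = True
    wm &= brain

    parcellation = np.zeros(grid_shape, dtype=np.int32)
    rows = []
    z_interior = np.arange(1, nz - 1)
    n_front = int(np.ceil(regions_per_hemisphere / 2))
    n_back = regions_per_hemisphere - n_front
    if n_front > len(z_interior) or (n_back and n_back > len(z_interior)):
        raise ValueError("too many regions per hemisphere for this grid")

    next_id = 1
    for hemi_name in (LEFT, RIGHT):
        code = HEMI_CODES[hemi_name]
        for slab_name, y_slab, n_blocks in (
            ("front", front_y, n_front),
            ("back", back_y, n_back),
        ):
            if n_blocks == 0:
                continue
            for bi, z_block in enumerate(np.array_split(z_interior, n_blocks)):
                sel = np.zeros(grid_shape, dtype=bool)
                sel[:, y_slab[0] : y_slab[-1] + 1, z_block[0] : z_block[-1] + 1] = True
                sel &= brain & (hemi == code)
                if not sel.any():
                    raise ValueError("empty parcel block; grid too small")
                parcellation[sel] = next_id
                rows.append(
                    {
                        "region_id": next_id,
                        "name": f"{hemi_name[0].upper()}_{slab_name}_{bi}",
                        "hemisphere": hemi_name,
                    }
                )
                next_id += 1

    spec = ToyBrainSpec(
        grid_shape=grid_shape,
        voxel_size=voxel_size,
        affine=affine,
        brain_mask=brain,
        hemisphere_labels=hemi,
        parcellation=parcellation,
        region_table=pd.DataFrame(rows),
        wm_mask=wm,
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# tractograms


def _wm_band_centre_y(spec: ToyBrainSpec) -> float:
    idx = np.argwhere(spec.wm_mask)
    return float(voxel_to_world(idx.mean(axis=0), spec.affine)[0][1])


def bundle_waypoint(spec: ToyBrainSpec, region_a: int, region_b: int) -> np.ndarray:
    """World-space mid-course point of the (a, b) bundle, inside the wm band."""
    ca = spec.region_centroid_world(region_a)
    cb = spec.region_centroid_world(region_b)
    way = (ca + cb) / 2.0
    way[1] = _wm_band_centre_y(spec)
    return way


def _draw_point_in_region(
    spec: ToyBrainSpec, region_id: int, jitter_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Region centroid jittered by N(0, jitter_sd) mm, rejection-kept in-region."""
    centre = spec.region_centroid_world(region_id)
    if jitter_sd == 0:
        return centre
    mask = spec.region_mask(region_id)
    for _ in range(50):
        candidate = centre + rng.normal(0.0, jitter_sd, size=3)
        v = np.floor(world_to_voxel(candidate, spec.affine)[0] + 0.5).astype(int)
        if np.all(v >= 0) and np.all(v < mask.shape) and mask[tuple(v)]:
            return candidate
    return centre


def make_toy_tractograms(
    spec: ToyBrainSpec,
    connection_pairs,
    n_subjects: int,
    streamlines_per_pair: int,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> list[Tractogram]:
    """Simulate per-subject bundles: 3-point polylines endpoint → wm band → endpoint."""
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    known = set(spec.region_table["region_id"])
    for a, b in connection_pairs:
        if a not in known or b not in known:
            raise KeyError(f"unknown region id in pair ({a}, {b})")
    rng = np.random.default_rng(seed)
    wm_idx = np.argwhere(spec.wm_mask)
    wm_lo = voxel_to_world(wm_idx.min(axis=0), spec.affine)[0]
    wm_hi = voxel_to_world(wm_idx.max(axis=0), spec.affine)[0]

    tractograms = []
    for s in range(n_subjects):
        streamlines = []
        for a, b in connection_pairs:
            way0 = bundle_waypoint(spec, a, b)
            for _ in range(streamlines_per_pair):
                pa = _draw_point_in_region(spec, a, jitter_sd, rng)
                pb = _draw_point_in_region(spec, b, jitter_sd, rng)
                way = way0 + (rng.normal(0.0, jitter_sd, size=3) if jitter_sd else 0.0)
                way = np.clip(way, wm_lo, wm_hi)
                way[1] = np.clip(way0[1] + (rng.normal(0.0, jitter_sd) if jitter_sd else 0.0),
                                 wm_lo[1], wm_hi[1])
                streamlines.append(np.stack([pa, way, pb]))
        tractograms.append(
            Tractogram(
                subject_id=f"sub-{s:03d}",
                streamlines=streamlines,
                affine=spec.affine,
                shape=spec.grid_shape,
            )
        )
    return tractograms


# ---------------------------------------------------------------------------
# lesion cohorts


def _grow_blob(
    allowed: np.ndarray, start: tuple, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Seeded region growing: connected, exactly `size` voxels inside `allowed`."""
    blob = np.zeros(allowed.shape, dtype=bool)
    blob[start] = True
    frontier = [start]
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    while blob.sum() < size:
        if not frontier:
            raise ValueError("region growing exhausted the reachable volume")
        i = int(rng.integers(len(frontier)))
        vox = frontier.pop(i)
        for off in offsets:
            nb = (vox[0] + off[0], vox[1] + off[1], vox[2] + off[2])
            if (
                0 <= nb[0] < allowed.shape[0]
                and 0 <= nb[1] < allowed.shape[1]
                and 0 <= nb[2] < allowed.shape[2]
                and allowed[nb]
                and not blob[nb]
            ):
                blob[nb] = True
                frontier.append(nb)
                if blob.sum() >= size:
                    break
    return blob


def _nearest_in_mask(mask_idx: np.ndarray, voxel: np.ndarray) -> tuple:
    d = ((mask_idx - voxel[None, :]) ** 2).sum(axis=1)
    return tuple(mask_idx[int(np.argmin(d))])


def plant_lesion_cohort(
    spec: ToyBrainSpec,
    structure: PlantedStructure | None,
    n_lesions: int,
    mode: str,
    size_range,
    seed: int = 0,
    dispersion_mm: float = 2.0,
    source: str = "observed",
    id_prefix: str = "lesion",
) -> list[LesionMask]:
    """Draw a cohort of connected one-hemisphere lesion blobs.

    ``clustered`` re-uses the planted seeds (stroke-like spatial redundancy);
    ``uniform`` scatters centres over the whole brain mask.
    """
    if mode not in ("clustered", "uniform"):
        raise ValueError(f"mode must be clustered or uniform, got {mode!r}")
    if mode == "clustered" and (structure is None or structure.pattern_lesion_seeds.shape[0] < 1):
        raise ValueError("clustered mode needs a PlantedStructure with >= 1 seed")
    lo, hi = int(size_range[0]), int(size_range[1])
    hemi_sizes = {h: int(spec.hemisphere_mask(h).sum()) for h in (LEFT, RIGHT)}
    if lo < 1 or lo > hi or lo > min(hemi_sizes.values()):
        raise ValueError(f"infeasible size_range {size_range} for hemisphere volumes {hemi_sizes}")

    rng = np.random.default_rng(seed)
    brain_idx = np.argwhere(spec.brain_mask)
    lesions = []
    for i in range(n_lesions):
        if mode == "uniform":
            centre_vox = tuple(brain_idx[int(rng.integers(len(brain_idx)))])
        else:
            k = int(rng.integers(structure.n_patterns))
            centre_world = structure.pattern_lesion_seeds[k] + (
                rng.normal(0.0, dispersion_mm, size=3) if dispersion_mm > 0 else 0.0
            )
            v = np.round(world_to_voxel(centre_world, spec.affine)[0]).astype(int)
            v = np.clip(v, 0, np.asarray(spec.grid_shape) - 1)
            centre_vox = tuple(v) if spec.brain_mask[tuple(v)] else _nearest_in_mask(brain_idx, v)
        hemi_code = int(spec.hemisphere_labels[centre_vox])
        hemisphere = LEFT if hemi_code == 1 else RIGHT
        allowed = spec.brain_mask & (spec.hemisphere_labels == hemi_code)
        size = int(rng.integers(lo, hi + 1))
        size = min(size, int(allowed.sum()))
        blob = _grow_blob(allowed, centre_vox, size, rng)
        lesions.append(
            LesionMask(
                volume=blob,
                hemisphere=hemisphere,
                size_vox=int(blob.sum()),
                source=source,
                id=f"{id_prefix}-{i:04d}",
            )
        )
    return lesions


# ---------------------------------------------------------------------------
# planted structure + term maps


def planted_bundle_structure(
    spec: ToyBrainSpec,
    pattern_pairs,
    n_terms: int,
    noise_sd: float = 0.05,
    mixing: str = "dominant",
    seed: int = 0,
) -> PlantedStructure:
    """Plant K disconnection patterns, one per bundle.

    Pattern k's region profile is the indicator of its bundle's two endpoint
    regions, and its lesion seed sits on the bundle's white-matter waypoint —
    so clustered lesions drawn from the structure actually disconnect the
    pattern they encode. Term mixing rows are one-hot on a pattern plus small
    uniform leakage ("dominant") or fully random positive ("random").
    """
    rng = np.random.default_rng(seed)
    k = len(pattern_pairs)
    profiles = np.zeros((k, spec.n_regions))
    seeds = np.zeros((k, 3))
    id_to_col = {rid: j for j, rid in enumerate(spec.region_ids)}
    for i, (a, b) in enumerate(pattern_pairs):
        profiles[i, id_to_col[a]] = 1.0
        profiles[i, id_to_col[b]] = 1.0
        seeds[i] = bundle_waypoint(spec, a, b)
    if mixing == "dominant":
        # every pattern is covered by terms (cycled), as a functional corpus
        # covers every system; small uniform leakage onto the others
        mix = 0.1 * rng.uniform(0, 1, size=(n_terms, k))
        mix[np.arange(n_terms), np.arange(n_terms) % k] = 1.0
    elif mixing == "random":
        mix = rng.uniform(0.1, 1.0, size=(n_terms, k))
    else:
        raise ValueError(f"unknown mixing scheme {mixing!r}")
    return PlantedStructure(
        n_patterns=k,
        pattern_region_profiles=profiles,
        pattern_lesion_seeds=seeds,
        term_mixing=mix,
        noise_sd=noise_sd,
        pattern_pairs=list(pattern_pairs),
    )


def make_toy_term_maps(
    structure: PlantedStructure, n_regions: int, seed: int = 0
) -> TermMatrix:
    """Terms × regions average-z matrix: mixing · profiles + Gaussian noise."""
    if structure.pattern_region_profiles.shape[1] != n_regions:
        raise ValueError(
            f"pattern profiles have {structure.pattern_region_profiles.shape[1]} regions, "
            f"expected {n_regions}"
        )
    rng = np.random.default_rng(seed)
    values = structure.term_mixing @ structure.pattern_region_profiles
    if structure.noise_sd > 0:
        values = values + rng.normal(0.0, structure.noise_sd, size=values.shape)
    names = [f"term_{t:03d}" for t in range(values.shape[0])]
    return TermMatrix(
        values=values, term_names=names, region_ids=list(range(1, n_regions + 1))
    )


def default_connection_pairs(spec: ToyBrainSpec) -> list[tuple[int, int]]:
    """A richer-than-planted bundle set over the toy parcellation.

    Ordered so a prefix makes good planted patterns: first the matched
    front–back pairs (front block i with back block i), alternating
    hemispheres — these bundles have spatially distinct corridors — then the
    remaining within-hemisphere crossings, then homotopic interhemispheric
    pairs.
    """
    tbl = spec.region_table
    matched, crossed = [], []
    per_hemi = {}
    for hemi in (LEFT, RIGHT):
        sub = tbl[tbl.hemisphere == hemi]
        front = sub[sub.name.str.contains("front")]["region_id"].tolist()
        back = sub[sub.name.str.contains("back")]["region_id"].tolist()
        per_hemi[hemi] = (front, back)
    n_match = min(
        len(per_hemi[LEFT][0]), len(per_hemi[LEFT][1]),
        len(per_hemi[RIGHT][0]), len(per_hemi[RIGHT][1]),
    )
    for i in range(n_match):
        matched.append((per_hemi[LEFT][0][i], per_hemi[LEFT][1][i]))
        matched.append((per_hemi[RIGHT][0][i], per_hemi[RIGHT][1][i]))
    for hemi in (LEFT, RIGHT):
        front, back = per_hemi[hemi]
        for f, b in itertools.product(front, back):
            if (f, b) not in matched:
                crossed.append((f, b))
    left = tbl[tbl.hemisphere == LEFT]["region_id"].tolist()
    right = tbl[tbl.hemisphere == RIGHT]["region_id"].tolist()
    homotopic = list(zip(left, right))
    return [tuple(p) for p in matched + crossed + homotopic]
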