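"""Synthetic lesion pool and size/hemisphere pairing.

A pool of pseudo-random lesion shapes is produced by repeatedly partitioning
each hemisphere mask with k-means on voxel coordinates (k swept over a
ladder), then smoothing every cluster with a Gaussian kernel (FWHM in mm),
thresholding and binarizing. Each observed lesion is then paired with one
pool mask of the same hemisphere and (near-)identical size, yielding a
synthetic cohort matched in size and lateralisation but pseudo-randomly
placed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .datatypes import HEMI_CODES, LEFT, RIGHT, LesionMask
from .grids import voxel_to_world

__all__ = [
    "SynthPoolConfig",
    "kmeans_partition_hemisphere",
    "polish_mask",
    "build_synthetic_pool",
    "match_lesions",
    "fwhm_to_sigma",
]

#: reference cluster ladder at full scale: 2 .. 50,000 (doubling sweep)
FULL_SCALE_K_LADDER = [2 ** i for i in range(1, 17) if 2 ** i <= 50_000]
#: desk-scale default: every k from 2 to 64 — on toy grids a dense ladder is
#: needed for the pool to cover all lesion sizes
DEFAULT_K_LADDER = list(range(2, 65))


@dataclass
class SynthPoolConfig:
    k_values: list = field(default_factory=lambda: list(DEFAULT_K_LADDER))
    fwhm_mm: float = 10.0
    threshold: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if any(k < 1 for k in self.k_values):
            raise ValueError("k_values must all be >= 1")
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must be in (0, 1)")
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be >= 0")


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """sigma = FWHM / (2 * sqrt(2 ln 2)) in the same units."""
    return fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def kmeans_partition_hemisphere(
    hemisphere_mask: np.ndarray, k: int, seed: int = 0, affine: np.ndarray | None = None
) -> np.ndarray:
    """Partition in-mask voxels into k clusters by k-means on their coordinates.

    Returns an integer volume with labels 1..k inside the mask, 0 outside.
    k-means++ with 10 restarts, seeded.
    """
    mask = np.asarray(hemisphere_mask).astype(bool)
    idx = np.argwhere(mask)
    if idx.shape[0] == 0:
        raise ValueError("empty hemisphere mask")
    if k > idx.shape[0]:
        raise ValueError(f"k={k} exceeds the {idx.shape[0]} in-mask voxels")
    out = np.zeros(mask.shape, dtype=np.int32)
    if k == 1:
        out[mask] = 1
        return out
    coords = voxel_to_world(idx, affine) if affine is not None else idx.astype(float)
    if k == idx.shape[0]:
        out[tuple(idx.T)] = np.arange(1, k + 1)
        return out
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(coords)
    out[tuple(idx.T)] = labels + 1
    return out


def polish_mask(
    raw_mask: np.ndarray, fwhm_mm: float, threshold: float, voxel_size
) -> np.ndarray:
    """Gaussian-smooth a binary mask (FWHM in mm), then threshold and binarize."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    vs = np.asarray(voxel_size, dtype=float)
    if np.any(vs <= 0):
        raise ValueError("voxel sizes must be positive")
    sigma_vox = fwhm_to_sigma(fwhm_mm) / vs
    smoothed = ndimage.gaussian_filter(np.asarray(raw_mask, dtype=float), sigma=sigma_vox)
    return smoothed > threshold


def build_synthetic_pool(
    brain_mask: np.ndarray,
    hemisphere_labels: np.ndarray,
    config: SynthPoolConfig,
    voxel_size=(2.0, 2.0, 2.0),
    affine: np.ndarray | None = None,
) -> list[LesionMask]:
    """Sweep the k ladder over both hemispheres and polish every cluster.

    Post-smoothing masks are clipped back to their source hemisphere (the
    kernel otherwise bleeds across the midline); empty masks are discarded.
    """
    brain_mask = np.asarray(brain_mask).astype(bool)
    hemisphere_labels = np.asarray(hemisphere_labels)
    pool: list[LesionMask] = []
    counter = 0
    for hemi_name in (LEFT, RIGHT):
        hemi_mask = brain_mask & (hemisphere_labels == HEMI_CODES[hemi_name])
        n_vox = int(hemi_mask.sum())
        if n_vox == 0:
            raise ValueError(f"{hemi_name} hemisphere is empty")
        for k in config.k_values:
            if k > n_vox:
                continue
            labeled = kmeans_partition_hemisphere(hemi_mask, k, seed=config.seed, affine=affine)
            for label in range(1, k + 1):
                cluster = labeled == label
                polished = polish_mask(cluster, config.fwhm_mm, config.threshold, voxel_size)
                polished &= hemi_mask
                size = int(polished.sum())
                if size == 0:
                    continue
                pool.append(
                    LesionMask(
                        volume=polished,
                        hemisphere=hemi_name,
                        size_vox=size,
                        source="synthetic",
                        id=f"pool-{hemi_name[0]}-k{k}-{counter:06d}",
                    )
                )
                counter += 1
    if not pool:
        raise ValueError(
            "synthetic pool is empty after polishing; threshold too aggressive for this grid"
        )
    return pool


def match_lesions(
    observed: list[LesionMask],
    pool: list[LesionMask],
    size_tolerance: float = 0.1,
    seed: int = 0,
) -> list[LesionMask]:
    """Pair one pool mask to every observed lesion by hemisphere and size.

    Exact size matches are preferred; otherwise the candidate with the
    smallest relative size gap within ``size_tolerance`` is taken, sampling
    uniformly (seeded) among equally good candidates, with replacement across
    observed lesions. Raises a pairing error naming the lesion when no
    candidate is close enough.
    """
    if not observed:
        return []
    rng = np.random.default_rng(seed)
    by_hemi: dict[str, list[LesionMask]] = {LEFT: [], RIGHT: []}
    for mask in pool:
        by_hemi[mask.hemisphere].append(mask)
    for hemi in {les.hemisphere for les in observed}:
        if not by_hemi[hemi]:
            raise ValueError(f"pool has no {hemi}-hemisphere masks")
    matched = []
    for les in observed:
        candidates = by_hemi[les.hemisphere]
        sizes = np.array([c.size_vox for c in candidates], dtype=float)
        gaps = np.abs(sizes - les.size_vox) / max(les.size_vox, 1)
        best = gaps.min()
        if best > size_tolerance:
            raise ValueError(
                f"no synthetic candidate within {size_tolerance:.0%} of lesion "
                f"{les.id} (size {les.size_vox}, best gap {best:.0%})"
            )
        ties = np.flatnonzero(gaps == best)
        pick = candidates[int(ties[rng.integers(len(ties))])]
        matched.append(
            LesionMask(
                volume=pick.volume.copy(),
                hemisphere=pick.hemisphere,
                size_vox=pick.size_vox,
                source="synthetic",
                id=f"{pick.id}~{les.id}",
            )
        )
    mismatch = np.mean(
        [abs(m.size_vox - o.size_vox) / max(o.size_vox, 1) for m, o in zip(matched, observed)]
    )
    if mismatch > size_tolerance / 2:
        warnings.warn(f"mean relative size mismatch {mismatch:.1%} after pairing")
    return matched
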