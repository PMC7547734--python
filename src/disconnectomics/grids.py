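"""Voxel-grid conventions shared by every stage.

One convention, stated once: the affine maps *integer voxel indices* to world
(mm) coordinates — the NIfTI convention — so voxel ``(i, j, k)`` occupies the
half-open cube ``[i - 1/2, i + 1/2)`` along each axis in voxel space. All
streamline coordinates are kept in world mm and mapped through the inverse
affine when rasterised.
"""

from __future__ import annotations

import numpy as np


def default_affine(shape, voxel_size=(2.0, 2.0, 2.0)) -> np.ndarray:
    """Diagonal affine centring the grid so the mid-sagittal plane is world x = 0.

    Parameters
    ----------
    shape : triple of int
        Grid dimensions in voxels.
    voxel_size : triple of float
        Voxel edge lengths in mm (default the 2 mm isotropic common space).
    """
    shape = np.asarray(shape, dtype=float)
    vs = np.asarray(voxel_size, dtype=float)
    aff = np.eye(4)
    aff[:3, :3] = np.diag(vs)
    aff[:3, 3] = -(shape - 1.0) / 2.0 * vs
    return aff


def voxel_sizes(affine: np.ndarray) -> np.ndarray:
    """Voxel edge lengths in mm implied by an affine (column norms)."""
    return np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))


def voxel_to_world(indices, affine) -> np.ndarray:
    """Map voxel indices (n, 3) to world mm coordinates."""
    idx = np.atleast_2d(np.asarray(indices, dtype=float))
    aff = np.asarray(affine)
    return idx @ aff[:3, :3].T + aff[:3, 3]


def world_to_voxel(points, affine) -> np.ndarray:
    """Map world mm coordinates (n, 3) to continuous voxel coordinates."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    aff = np.asarray(affine)
    inv = np.linalg.inv(aff)
    return pts @ inv[:3, :3].T + inv[:3, 3]


def check_affine(affine: np.ndarray) -> np.ndarray:
    aff = np.asarray(affine, dtype=float)
    if aff.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {aff.shape}")
    if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
        raise ValueError("affine is not invertible")
    return aff
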