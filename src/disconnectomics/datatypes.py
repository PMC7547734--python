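"""Core in-memory containers passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LEFT = "left"
RIGHT = "right"
HEMI_CODES = {LEFT: 1, RIGHT: 2}


@dataclass
class LesionMask:
    """A single binary lesion on the common grid.

    ``source`` distinguishes the observed (stroke-like) cohort from masks drawn
    out of the synthetic pool.
    """

    volume: np.ndarray
    hemisphere: str
    size_vox: int
    source: str
    id: str

    def __post_init__(self):
        self.volume = np.asarray(self.volume).astype(bool)
        if self.hemisphere not in HEMI_CODES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        if self.source not in ("observed", "synthetic"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.size_vox != int(self.volume.sum()):
            raise ValueError(
                f"lesion {self.id}: size_vox={self.size_vox} but mask has "
                f"{int(self.volume.sum())} voxels"
            )

    def validate(self, brain_mask=None, hemisphere_labels=None) -> None:
        """Check the mask against the brain geometry; raises on violation."""
        if brain_mask is not None and np.any(self.volume & ~np.asarray(brain_mask, bool)):
            raise ValueError(f"lesion {self.id} leaves the brain mask")
        if hemisphere_labels is not None:
            labels = np.unique(np.asarray(hemisphere_labels)[self.volume])
            if labels.size and not np.array_equal(labels, [HEMI_CODES[self.hemisphere]]):
                raise ValueError(f"lesion {self.id} is not confined to {self.hemisphere}")


@dataclass
class Tractogram:
    """One subject's streamlines as polylines in world (mm) coordinates."""

    subject_id: str
    streamlines: list
    affine: np.ndarray
    shape: tuple | None = None
    _voxel_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.affine = np.asarray(self.affine, dtype=float)
        clean = []
        for i, s in enumerate(self.streamlines):
            arr = np.asarray(s, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 1:
                raise ValueError(f"streamline {i} must be an (n>=1, 3) polyline")
            if not np.isfinite(arr).all():
                raise ValueError(f"streamline {i} has non-finite coordinates")
            clean.append(arr)
        self.streamlines = clean

    def __len__(self) -> int:
        return len(self.streamlines)


@dataclass
class DisconnectomeMap:
    """Per-lesion voxelwise probability of disconnection in [0, 1]."""

    volume: np.ndarray
    lesion_id: str
    n_subjects: int

    def __post_init__(self):
        self.volume = np.asarray(self.volume, dtype=float)
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    def validate(self) -> None:
        v = self.volume
        if v.min() < 0 or v.max() > 1:
            raise ValueError("probabilities outside [0, 1]")
        lattice = np.round(v * self.n_subjects)
        if not np.allclose(v * self.n_subjects, lattice, atol=1e-9):
            raise ValueError("values not on the k/n_subjects lattice")
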