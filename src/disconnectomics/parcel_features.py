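"""Region-wise quantification of lesions and disconnectome maps.

Each lesion reduces to the proportion of every parcel it damages; each
disconnectome map to the mean disconnection probability over every parcel.
Stacking a cohort gives one observations × regions feature matrix per
condition (stroke/synthetic × lesion/disconnectome).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import DisconnectomeMap, LesionMask

__all__ = ["FeatureMatrix", "lesion_load", "disconnection_profile", "build_feature_matrix"]

CONDITIONS = (
    "stroke_lesion",
    "stroke_disconnectome",
    "synthetic_lesion",
    "synthetic_disconnectome",
)


@dataclass
class FeatureMatrix:
    values: np.ndarray
    observation_ids: list
    region_ids: list
    condition: str

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.observation_ids), len(self.region_ids)):
            raise ValueError("values shape inconsistent with id lists")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix has missing entries")
        if self.values.min() < 0 or self.values.max() > 1 + 1e-12:
            raise ValueError("feature values must lie in [0, 1]")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.observation_ids, columns=self.region_ids)


def _region_info(parcellation: np.ndarray, region_ids):
    parcellation = np.asarray(parcellation)
    if region_ids is None:
        region_ids = [int(r) for r in np.unique(parcellation) if r != 0]
    flat = parcellation.ravel()
    counts = np.bincount(flat, minlength=max(region_ids) + 1)[region_ids]
    if np.any(counts == 0):
        empty = [r for r, c in zip(region_ids, counts) if c == 0]
        raise ValueError(f"regions with zero voxels: {empty}")
    return flat, list(region_ids), counts


def lesion_load(lesion: LesionMask, parcellation: np.ndarray, region_ids=None) -> np.ndarray:
    """Per region r: |lesion ∩ r| / |r|."""
    if lesion.volume.shape != np.asarray(parcellation).shape:
        raise ValueError("lesion and parcellation grids differ")
    flat, ids, counts = _region_info(parcellation, region_ids)
    hits = np.bincount(flat, weights=lesion.volume.ravel().astype(float), minlength=max(ids) + 1)
    return hits[ids] / counts


def disconnection_profile(
    dmap: DisconnectomeMap, parcellation: np.ndarray, region_ids=None
) -> np.ndarray:
    """Per region r: mean disconnection probability over r's voxels."""
    if dmap.volume.shape != np.asarray(parcellation).shape:
        raise ValueError("map and parcellation grids differ")
    flat, ids, counts = _region_info(parcellation, region_ids)
    sums = np.bincount(flat, weights=dmap.volume.ravel(), minlength=max(ids) + 1)
    return sums[ids] / counts


def build_feature_matrix(
    items, parcellation: np.ndarray, condition: str, region_ids=None
) -> FeatureMatrix:
    """Stack per-item region vectors, preserving input order."""
    if not items:
        raise ValueError("empty item list")
    kinds = {type(it) for it in items}
    if len(kinds) != 1:
        raise ValueError(f"mixed item kinds: {sorted(k.__name__ for k in kinds)}")
    _, ids, _ = _region_info(parcellation, region_ids)
    rows, obs_ids = [], []
    for it in items:
        if isinstance(it, LesionMask):
            rows.append(lesion_load(it, parcellation, ids))
            obs_ids.append(it.id)
        elif isinstance(it, DisconnectomeMap):
            rows.append(disconnection_profile(it, parcellation, ids))
            obs_ids.append(it.lesion_id)
        else:
            raise TypeError(f"unsupported item type {type(it).__name__}")
    return FeatureMatrix(
        values=np.array(rows), observation_ids=obs_ids, region_ids=ids, condition=condition
    )
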