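"""Winner-take-all atlas, effect-size lookup and versatility counts.

Per voxel: the functional term with the highest statistic wins the label
(if it clears a display threshold), the winning term's goodness-of-fit R is
the effect size, and versatility counts how many terms exceed a moderate
effect cutoff (strictly R > threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AtlasSummary", "find_the_biggest", "effect_size_map", "versatility_map", "build_atlas"]


@dataclass
class AtlasSummary:
    label_volume: np.ndarray  # winning term index, 0 = none
    label_legend: dict  # index -> term name
    r_volume: np.ndarray
    versatility_volume: np.ndarray


def _stack(volumes) -> np.ndarray:
    arr = np.stack([np.asarray(v, dtype=float) for v in volumes])
    if arr.ndim != 4:
        raise ValueError("expected a stack of 3-D volumes")
    return arr


def find_the_biggest(term_stat_volumes, display_threshold: float, term_names=None):
    """Per-voxel argmax label over term statistics, thresholded.

    A voxel is labeled with the 1-based index of the term whose statistic is
    maximal there, provided that maximum reaches ``display_threshold``;
    otherwise 0. Ties break to the lowest term index. NaN statistics never win.
    """
    stats = _stack(term_stat_volumes)
    shapes = {v.shape for v in stats}
    if len(shapes) != 1:
        raise ValueError("inconsistent grids across term volumes")
    filled = np.where(np.isfinite(stats), stats, -np.inf)
    winner = filled.argmax(axis=0)
    peak = filled.max(axis=0)
    labels = np.where(np.isfinite(peak) & (peak >= display_threshold), winner + 1, 0)
    if term_names is None:
        term_names = [f"term_{i:03d}" for i in range(stats.shape[0])]
    legend = {i + 1: name for i, name in enumerate(term_names)}
    return labels.astype(np.int32), legend


def effect_size_map(term_r_volumes, label_volume: np.ndarray) -> np.ndarray:
    """Winning term's R at every labeled voxel; 0 where unlabeled."""
    rs = _stack(term_r_volumes)
    labels = np.asarray(label_volume)
    if labels.max() > rs.shape[0]:
        raise ValueError("label without a matching r volume")
    out = np.zeros(labels.shape, dtype=float)
    lab = labels > 0
    idx = labels[lab] - 1
    vox = np.nonzero(lab)
    out[lab] = np.nan_to_num(rs[idx, vox[0], vox[1], vox[2]])
    return out


def versatility_map(term_r_volumes, threshold: float = 0.3) -> np.ndarray:
    """Per voxel, the number of terms with R strictly greater than threshold."""
    rs = _stack(term_r_volumes)
    with np.errstate(invalid="ignore"):
        return np.sum(np.nan_to_num(rs, nan=-np.inf) > threshold, axis=0).astype(np.int32)


def build_atlas(
    term_maps,
    display_threshold: float | None = None,
    display_p: float = 0.05,
    versatility_threshold: float = 0.3,
) -> AtlasSummary:
    """Summarise a term-level StatMapSet into the three atlas volumes.

    By default a voxel may only be labeled by a term whose permutation p is at
    most ``display_p`` there; passing ``display_threshold`` switches to a raw
    statistic cutoff instead.
    """
    stats = term_maps.stat.copy()
    if display_threshold is None:
        stats = np.where(term_maps.p <= display_p, stats, np.nan)
        display_threshold = -np.inf
    labels, legend = find_the_biggest(stats, display_threshold, term_maps.unit_names)
    r_vol = effect_size_map(term_maps.r, labels)
    versa = versatility_map(term_maps.r, versatility_threshold)
    return AtlasSummary(
        label_volume=labels, label_legend=legend, r_volume=r_vol, versatility_volume=versa
    )
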