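"""Permutation-based voxelwise regressions and split-half replication.

Level 1 regresses every white-matter voxel's disconnection probability on a
component score across the cohort; level 2 regresses every voxel of the
component-map stack on a term's component-association vector. Null
distributions come from seeded permutations of the predictor, shared across
voxels so the response's spatial covariance is preserved.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .components import fit_component_model
from .datatypes import DisconnectomeMap
from .parcel_features import build_feature_matrix

__all__ = [
    "StatMapSet",
    "permuted_regression",
    "component_voxel_maps",
    "term_voxel_maps",
    "split_half_replicate",
    "SplitHalfResult",
]


@dataclass
class StatMapSet:
    """Stacked per-unit (component or term) statistic volumes.

    ``stat``, ``p`` and ``r`` are (n_units, *grid) arrays, NaN outside the
    analysis mask; p-values live on [1/(n_perm+1), 1].
    """

    stat: np.ndarray
    p: np.ndarray
    r: np.ndarray
    n_perm: int
    seed: int | None
    analysis_mask: np.ndarray
    unit_names: list

    def masked(self, field: str, unit: int) -> np.ndarray:
        """In-mask vector of one unit's volume."""
        return getattr(self, field)[unit][self.analysis_mask]


def _slope_t_and_r(xs: np.ndarray, Ys: np.ndarray, df: int):
    """t of the simple-regression slope and Pearson r, per response column.

    xs (possibly a stack of permuted copies) and the columns of Ys are
    standardized (ddof=1); r = xs·Ys/(n-1).
    """
    n = Ys.shape[0]
    r = (xs @ Ys) / (n - 1)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    return t, r


def permuted_regression(
    Y: np.ndarray,
    x: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    method: str = "sample",
):
    """Voxelwise slope test of Y (observations × voxels) on x, permutation null.

    Returns (t, p, r) per voxel. Constant-response voxels are flagged missing
    (NaN). With ``method="exhaustive"`` all n! orderings of x are enumerated
    (n ≤ 8) and p = #{|t*| >= |t|}/n!, the identity included; sampled
    permutations use p = (1 + #{|t*| >= |t|})/(n_perm + 1).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if Y.shape[0] != n:
        raise ValueError("Y rows must match the predictor length")
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0:
        raise ValueError("constant predictor")
    df = n - 2

    xs = (x - x.mean()) / x.std(ddof=1)
    ymean = Y.mean(axis=0)
    ysd = Y.std(axis=0, ddof=1)
    ok = ysd > 0
    Ys = np.zeros_like(Y)
    Ys[:, ok] = (Y[:, ok] - ymean[ok]) / ysd[ok]

    t_obs, r_obs = _slope_t_and_r(xs, Ys, df)

    if method == "exhaustive":
        if n > 8:
            raise ValueError("exhaustive enumeration limited to n <= 8")
        perms = np.array(list(itertools.permutations(range(n))))
        denom = math.factorial(n)
        count_offset = 0
    elif method == "sample":
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        denom = n_perm + 1
        count_offset = 1
    else:
        raise ValueError(f"unknown permutation method {method!r}")

    T_null, _ = _slope_t_and_r(xs[perms], Ys, df)
    # numerical tie guard: the observed statistic recomputed inside a matmul
    # can differ by an ulp, so ties count conservatively (valid direction)
    abs_obs = np.abs(t_obs)
    with np.errstate(invalid="ignore"):
        thresh = abs_obs - 1e-9 * (1.0 + abs_obs)
        thresh[np.isinf(abs_obs)] = np.inf
        counts = np.sum(np.abs(T_null) >= thresh[None, :], axis=0)
    p = (count_offset + counts) / denom

    t_obs[~ok] = np.nan
    p = p.astype(float)
    p[~ok] = np.nan
    r_obs[~ok] = np.nan
    return t_obs, p, r_obs


def _fill_volumes(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.full(mask.shape, np.nan)
    out[mask] = values
    return out


def component_voxel_maps(
    disconnectomes: list[DisconnectomeMap],
    scores: np.ndarray,
    mask: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    component_names=None,
) -> StatMapSet:
    """Level-1 maps: one permuted simple regression per component score."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if len(disconnectomes) != scores.shape[0]:
        raise ValueError(
            f"{len(disconnectomes)} maps but {scores.shape[0]} score rows; "
            "observation order misaligned"
        )
    mask = np.asarray(mask).astype(bool)
    Y = np.stack([d.volume[mask] for d in disconnectomes])
    m = scores.shape[1]
    if component_names is None:
        component_names = [f"component_{c + 1:02d}" for c in range(m)]
    seeds = np.random.SeedSequence(seed).spawn(m)
    t_vols, p_vols, r_vols = [], [], []
    for c in range(m):
        sub_seed = int(seeds[c].generate_state(1)[0] % (2**31))
        t, p, r = permuted_regression(Y, scores[:, c], n_perm=n_perm, seed=sub_seed)
        t_vols.append(_fill_volumes(t, mask))
        p_vols.append(_fill_volumes(p, mask))
        r_vols.append(_fill_volumes(r, mask))
    return StatMapSet(
        stat=np.stack(t_vols),
        p=np.stack(p_vols),
        r=np.stack(r_vols),
        n_perm=n_perm,
        seed=seed,
        analysis_mask=mask,
        unit_names=list(component_names),
    )


def term_voxel_maps(
    component_maps: StatMapSet,
    assoc,
    n_perm: int = 1000,
    seed: int | None = None,
    source: str = "stat",
) -> StatMapSet:
    """Level-2 maps: regress component-map voxels on each term's association vector.

    The m components act as observations; a term's predictor is its column of
    component–term correlations.
    """
    R = np.asarray(assoc.r, dtype=float)  # components x terms
    m = R.shape[0]
    if m < 3:
        raise ValueError("need at least 3 components for the level-2 regression")
    if m != component_maps.stat.shape[0]:
        raise ValueError("one component map per association row required")
    mask = component_maps.analysis_mask
    vols = getattr(component_maps, source)
    Y = np.stack([vols[c][mask] for c in range(m)])
    # component maps can be NaN at degenerate voxels: drop them from the analysis
    good = np.isfinite(Y).all(axis=0)
    mask_eff = mask.copy()
    mask_eff[mask] = good
    Y = Y[:, good]
    n_terms = R.shape[1]
    seeds = np.random.SeedSequence(seed).spawn(n_terms)
    t_vols, p_vols, r_vols = [], [], []
    for ti in range(n_terms):
        x = R[:, ti]
        if np.any(~np.isfinite(x)):
            raise ValueError(f"term {assoc.term_names[ti]} has missing associations")
        sub_seed = int(seeds[ti].generate_state(1)[0] % (2**31))
        t, p, r = permuted_regression(Y, x, n_perm=n_perm, seed=sub_seed)
        t_vols.append(_fill_volumes(t, mask_eff))
        p_vols.append(_fill_volumes(p, mask_eff))
        r_vols.append(_fill_volumes(r, mask_eff))
    return StatMapSet(
        stat=np.stack(t_vols),
        p=np.stack(p_vols),
        r=np.stack(r_vols),
        n_perm=n_perm,
        seed=seed,
        analysis_mask=mask_eff,
        unit_names=list(assoc.term_names),
    )


def _match_components(load_a: np.ndarray, load_b: np.ndarray):
    """Pair components across fits by maximal |loading correlation|, sign-aligned."""
    m = min(load_a.shape[1], load_b.shape[1])
    A = load_a[:, :m]
    B = load_b[:, :m]
    corr = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            c = np.corrcoef(A[:, i], B[:, j])[0, 1]
            corr[i, j] = 0.0 if not np.isfinite(c) else c
    rows, cols = linear_sum_assignment(-np.abs(corr))
    signs = np.sign(corr[rows, cols])
    signs[signs == 0] = 1.0
    return rows, cols, signs


@dataclass
class SplitHalfResult:
    r_values: np.ndarray
    mean: float
    sd: float
    pairing: list  # (component in half A, component in half B, sign)


def split_half_replicate(
    disconnectomes: list[DisconnectomeMap],
    parcellation: np.ndarray,
    mask: np.ndarray,
    condition: str = "stroke_disconnectome",
    n_perm: int = 100,
    seed: int | None = 0,
    retention: str = "kaiser_mean",
    m: int | None = None,
    halves=None,
    map_field: str = "stat",
) -> SplitHalfResult:
    """Fit the component-map pipeline independently on two cohort halves.

    Halves are a seeded random split unless explicit index pairs are given.
    Components are matched across halves by loading correlation and each
    matched pair's maps are Pearson-correlated over in-mask voxels.
    """
    n = len(disconnectomes)
    if n < 6:
        raise ValueError("cohort too small to split")
    if halves is None:
        order = np.random.default_rng(seed).permutation(n)
        halves = (order[: n // 2], order[n // 2 :])
    idx_a, idx_b = (np.asarray(h, dtype=int) for h in halves)
    maps_sets = []
    models = []
    for idx in (idx_a, idx_b):
        sub = [disconnectomes[i] for i in idx]
        fm = build_feature_matrix(sub, parcellation, condition)
        model = fit_component_model(fm, retention=retention, m=m)
        maps = component_voxel_maps(sub, model.scores, mask, n_perm=n_perm, seed=seed)
        models.append(model)
        maps_sets.append(maps)
    rows, cols, signs = _match_components(models[0].loadings, models[1].loadings)
    rs, pairing = [], []
    for i, j, s in zip(rows, cols, signs):
        va = maps_sets[0].stat[i][mask] if map_field == "stat" else maps_sets[0].r[i][mask]
        vb = maps_sets[1].stat[j][mask] if map_field == "stat" else maps_sets[1].r[j][mask]
        vb = s * vb
        good = np.isfinite(va) & np.isfinite(vb)
        if good.sum() < 3 or va[good].std() == 0 or vb[good].std() == 0:
            continue
        rs.append(float(np.corrcoef(va[good], vb[good])[0, 1]))
        pairing.append((int(i), int(j), float(s)))
    rs = np.array(rs)
    if rs.size == 0:
        raise ValueError("no comparable component maps across halves")
    return SplitHalfResult(
        r_values=rs, mean=float(rs.mean()), sd=float(rs.std(ddof=1)) if rs.size > 1 else 0.0,
        pairing=pairing,
    )
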