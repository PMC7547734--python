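"""Association between disconnection components and meta-analytic term maps.

Each cognitive term is summarised as its average z over every parcel; every
component's per-region score-coefficient profile is then Pearson-correlated
with every term row, Bonferroni-corrected over all component × term tests.
Condition-level strength (how much of a cohort's component structure the term
corpus explains) is the per-component r², aggregated either over the best
term or over all terms, and conditions are compared with a bootstrapped
two-sample t-test under an enforced null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TermMatrix",
    "AssociationTable",
    "term_parcel_matrix",
    "component_term_correlations",
    "condition_summary",
    "bootstrap_ttest",
]


@dataclass
class TermMatrix:
    """Terms × regions matrix of average z-scores."""

    values: np.ndarray
    term_names: list
    region_ids: list

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.isfinite(self.values).all():
            raise ValueError("term matrix has non-finite values")
        if len(self.term_names) != self.values.shape[0]:
            raise ValueError("term_names length mismatch")
        if len(set(self.term_names)) != len(self.term_names):
            raise ValueError("term names must be unique")
        if len(self.region_ids) != self.values.shape[1]:
            raise ValueError("region_ids length mismatch")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.term_names, columns=self.region_ids)


@dataclass
class AssociationTable:
    """Components × terms correlations with raw and Bonferroni p-values."""

    r: np.ndarray
    p: np.ndarray
    p_bonferroni: np.ndarray
    n_tests: int
    term_names: list
    component_names: list

    def to_dataframe(self):
        import pandas as pd

        frames = {}
        for name, arr in (("r", self.r), ("p", self.p), ("p_bonferroni", self.p_bonferroni)):
            frames[name] = pd.DataFrame(arr, index=self.component_names, columns=self.term_names)
        return frames


def term_parcel_matrix(term_maps, parcellation, term_names=None, region_ids=None) -> TermMatrix:
    """Average each z-map over every parcel → terms × regions matrix."""
    parcellation = np.asarray(parcellation)
    if region_ids is None:
        region_ids = [int(r) for r in np.unique(parcellation) if r != 0]
    flat_parc = parcellation.ravel()
    counts = np.bincount(flat_parc, minlength=max(region_ids) + 1)[region_ids]
    if np.any(counts == 0):
        empty = [r for r, c in zip(region_ids, counts) if c == 0]
        raise ValueError(f"empty regions in parcellation: {empty}")
    rows = []
    for i, vol in enumerate(term_maps):
        vol = np.asarray(vol, dtype=float)
        if vol.shape != parcellation.shape:
            raise ValueError(f"term map {i} not on the parcellation grid")
        sums = np.bincount(flat_parc, weights=vol.ravel(), minlength=max(region_ids) + 1)
        rows.append(sums[region_ids] / counts)
    if term_names is None:
        term_names = [f"term_{i:03d}" for i in range(len(rows))]
    return TermMatrix(values=np.array(rows), term_names=list(term_names), region_ids=list(region_ids))


def _standardize_columns(M: np.ndarray):
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    ok = sd > 0
    Z = np.zeros_like(M, dtype=float)
    Z[:, ok] = (M[:, ok] - mean[ok]) / sd[ok]
    return Z, ok


def component_term_correlations(
    score_coefficients: np.ndarray,
    terms: TermMatrix,
    component_names=None,
) -> AssociationTable:
    """Pearson r across regions between every component profile and term row.

    Two-sided p from the t distribution with n_regions - 2 df; Bonferroni over
    all m × n_terms tests. Zero-variance vectors give missing (NaN) entries.
    """
    C = np.atleast_2d(np.asarray(score_coefficients, dtype=float))  # regions x m
    T = terms.values  # terms x regions
    n_regions = C.shape[0]
    if T.shape[1] != n_regions:
        raise ValueError(
            f"region mismatch: coefficients have {n_regions}, terms have {T.shape[1]}"
        )
    m = C.shape[1]
    n_terms = T.shape[0]
    Zc, ok_c = _standardize_columns(C)
    Zt, ok_t = _standardize_columns(T.T)
    if not (ok_c.all() and ok_t.all()):
        warnings.warn("zero-variance profile(s); correlations recorded as missing")
    r = (Zc.T @ Zt) / (n_regions - 1)
    r = np.clip(r, -1.0, 1.0)
    r[~ok_c, :] = np.nan
    r[:, ~ok_t] = np.nan
    df = n_regions - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.isinf(t)] = 0.0
    n_tests = m * n_terms
    p_bonf = np.minimum(1.0, p * n_tests)
    if component_names is None:
        component_names = [f"component_{i + 1:02d}" for i in range(m)]
    return AssociationTable(
        r=r,
        p=p,
        p_bonferroni=p_bonf,
        n_tests=n_tests,
        term_names=list(terms.term_names),
        component_names=list(component_names),
    )


def condition_summary(assoc: AssociationTable, mode: str = "max_per_component"):
    """Per-component variance explained by the term corpus, and its mean.

    ``max_per_component`` takes the best term's r² per component (one number
    per component, its strongest functional match); ``mean_all_pairs`` averages
    r² over every term.
    """
    r2 = assoc.r**2
    if np.all(np.isnan(r2), axis=1).any():
        raise ValueError("a component has no defined correlations")
    if mode == "max_per_component":
        per_component = np.nanmax(r2, axis=1)
    elif mode == "mean_all_pairs":
        per_component = np.nanmean(r2, axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return per_component, float(per_component.mean())


def bootstrap_ttest(a, b, n_boot: int = 1000, seed: int | None = None):
    """Welch two-sample t with a bootstrap null.

    The null is enforced by mean-centring each group, pooling, and resampling
    groups of the original sizes with replacement ``n_boot`` times; the
    two-tailed p is (1 + #{|t*| >= |t|}) / (n_boot + 1).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    t_obs = float(stats.ttest_ind(a, b, equal_var=False).statistic)
    if not np.isfinite(t_obs):
        t_obs = 0.0
    pooled = np.concatenate([a - a.mean(), b - b.mean()])
    rng = np.random.default_rng(seed)
    na, nb = a.size, b.size
    idx = rng.integers(0, na + nb, size=(n_boot, na + nb))
    ra = pooled[idx[:, :na]]
    rb = pooled[idx[:, na:]]
    va = ra.var(axis=1, ddof=1) / na
    vb = rb.var(axis=1, ddof=1) / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = (ra.mean(axis=1) - rb.mean(axis=1)) / np.sqrt(va + vb)
    finite = np.isfinite(t_null)
    if not finite.any():
        raise ValueError("zero within-group variance in every resample")
    n_valid = int(finite.sum())
    count = int(np.sum(np.abs(t_null[finite]) >= abs(t_obs)))
    p_boot = (1 + count) / (n_valid + 1)
    return t_obs, float(p_boot)
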