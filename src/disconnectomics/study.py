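"""Reference toy studies: planted-pattern recovery and cohort-bias contrast.

These two designs fix the study conditions under which the pipeline's claims
are checked end to end:

* ``recovery_study`` — a 24³ toy brain with K = 4 disconnection patterns
  planted on spatially distinct bundles, a 200-lesion stereotyped cohort,
  10 subjects × ~400 streamlines, and 20 noise-mixed term maps. It measures
  how well the retained varimax components, term winners, and level-1
  white-matter corridors recover the plant, then carries the four-condition
  comparison (lesion vs disconnectome × stereotyped vs size/hemisphere-matched
  synthetic) through term association, bootstrap t-tests, level-2 term maps,
  the atlas summary and split-half replication.

* ``bias_contrast_study`` — repeated small cohorts contrasting the
  stereotyped (clustered) regime against a uniform one: embedding separation
  of each cohort from its matched synthetic partner, and the mean best-term
  r² of each cohort's components.

K is known by design here, so the recovery model retains exactly K
components; corridors are binarized at a goodness-of-fit r > 0.3 (the same
moderate-effect cutoff the versatility map uses).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .atlas_summary import build_atlas
from .components import fit_component_model, variance_curve
from .disconnectome import disconnectome_cohort, streamline_voxels
from .embedding_qc import flatten_maps, separation_statistic
from .lesion_synthesis import SynthPoolConfig, build_synthetic_pool, match_lesions
from .parcel_features import build_feature_matrix
from .synthetic_data import (
    default_connection_pairs,
    make_toy_brain,
    make_toy_term_maps,
    make_toy_tractograms,
    plant_lesion_cohort,
    planted_bundle_structure,
)
from .term_association import bootstrap_ttest, component_term_correlations, condition_summary
from .voxel_statistics import component_voxel_maps, split_half_replicate, term_voxel_maps

__all__ = ["RecoveryStudyResult", "recovery_study", "bias_contrast_study", "match_components_to_patterns"]

CORRIDOR_R_THRESHOLD = 0.3


def match_components_to_patterns(profiles: np.ndarray, component_vectors: np.ndarray):
    """Bipartite match planted profiles to component columns by |Pearson r|.

    Returns (pattern→component mapping, matched |r| per pattern).
    """
    K = profiles.shape[0]
    m = component_vectors.shape[1]
    C = np.zeros((K, m))
    for i in range(K):
        for j in range(m):
            c = np.corrcoef(profiles[i], component_vectors[:, j])[0, 1]
            C[i, j] = 0.0 if not np.isfinite(c) else abs(c)
    rows, cols = linear_sum_assignment(-C)
    return dict(zip(rows.tolist(), cols.tolist())), C[rows, cols]


@dataclass
class RecoveryStudyResult:
    recovery_abs_r: np.ndarray
    term_winner_accuracy: float
    corridor_dice: np.ndarray
    kaiser_m: int
    variance_r2_at_k: float
    best_term_r2: dict = field(default_factory=dict)  # condition -> per-component vector
    bootstrap: dict = field(default_factory=dict)
    split_half_mean: float = float("nan")
    split_half_sd: float = float("nan")
    atlas_labeled_voxels: int = 0
    versatility_max: int = 0
    n_lesions: int = 0


def recovery_study(
    seed: int = 0,
    grid: int = 24,
    regions_per_hemisphere: int = 4,
    n_patterns: int = 4,
    n_lesions: int = 200,
    n_subjects: int = 10,
    streamlines_per_pair: int = 33,
    jitter_sd: float = 1.5,
    n_terms: int = 20,
    term_noise_sd: float = 0.05,
    size_range=(10, 60),
    n_perm: int = 200,
    full_comparison: bool = True,
) -> RecoveryStudyResult:
    """Run the planted-pattern recovery design end to end."""
    rng_base = int(seed)
    spec = make_toy_brain((grid, grid, grid), regions_per_hemisphere, seed=rng_base)
    pairs = default_connection_pairs(spec)
    planted = pairs[:n_patterns]
    structure = planted_bundle_structure(
        spec, planted, n_terms=n_terms, noise_sd=term_noise_sd, seed=rng_base
    )
    tractograms = make_toy_tractograms(
        spec, pairs, n_subjects, streamlines_per_pair, jitter_sd, seed=rng_base + 1
    )
    cohort = plant_lesion_cohort(
        spec, structure, n_lesions, "clustered", size_range, seed=rng_base + 2
    )
    terms = make_toy_term_maps(structure, spec.n_regions, seed=rng_base + 3)

    dmaps = disconnectome_cohort(cohort, tractograms)
    fm = build_feature_matrix(dmaps, spec.parcellation, "stroke_disconnectome")
    model = fit_component_model(fm, retention="fixed", m=n_patterns)
    kaiser_m = fit_component_model(fm, retention="kaiser_mean").m
    curve = variance_curve(fm)

    pattern_to_comp, recovery = match_components_to_patterns(
        structure.pattern_region_profiles, model.loadings
    )

    assoc = component_term_correlations(model.score_coefficients, terms)
    dominant = structure.term_mixing.argmax(axis=1)
    hits = sum(
        int(np.nanargmax(np.abs(assoc.r[:, t])) == pattern_to_comp[int(dominant[t])])
        for t in range(n_terms)
    )

    level1 = component_voxel_maps(
        dmaps, model.scores, spec.brain_mask, n_perm=n_perm, seed=rng_base + 4
    )
    dice = []
    for k in range(n_patterns):
        union = np.zeros(spec.grid_shape, dtype=bool)
        lo, hi = k * streamlines_per_pair, (k + 1) * streamlines_per_pair
        for tg in tractograms:
            for s in tg.streamlines[lo:hi]:
                for vox in streamline_voxels(s, spec.grid_shape, spec.affine):
                    union[vox] = True
        corridor = np.nan_to_num(level1.r[pattern_to_comp[k]]) > CORRIDOR_R_THRESHOLD
        denom = corridor.sum() + union.sum()
        dice.append(2.0 * np.sum(corridor & union) / denom if denom else 0.0)

    result = RecoveryStudyResult(
        recovery_abs_r=recovery,
        term_winner_accuracy=hits / n_terms,
        corridor_dice=np.array(dice),
        kaiser_m=kaiser_m,
        variance_r2_at_k=float(curve.r2_by_m[n_patterns]),
        n_lesions=n_lesions,
    )
    if not full_comparison:
        return result

    pool = build_synthetic_pool(
        spec.brain_mask,
        spec.hemisphere_labels,
        SynthPoolConfig(k_values=list(range(2, 65)), fwhm_mm=10.0, threshold=0.3, seed=rng_base),
        voxel_size=spec.voxel_size,
        affine=spec.affine,
    )
    matched = match_lesions(cohort, pool, seed=rng_base + 5)
    dm_synth = disconnectome_cohort(matched, tractograms)
    for condition, items in (
        ("stroke_lesion", cohort),
        ("stroke_disconnectome", dmaps),
        ("synthetic_lesion", matched),
        ("synthetic_disconnectome", dm_synth),
    ):
        cfm = build_feature_matrix(items, spec.parcellation, condition)
        cmodel = fit_component_model(cfm, retention="fixed", m=n_patterns)
        cassoc = component_term_correlations(cmodel.score_coefficients, terms)
        per, _ = condition_summary(cassoc)
        result.best_term_r2[condition] = per
    for label, a, b in (
        ("disconnectome_vs_lesion", "stroke_disconnectome", "stroke_lesion"),
        ("stroke_vs_synthetic_disconnectome", "stroke_disconnectome", "synthetic_disconnectome"),
    ):
        t, p = bootstrap_ttest(
            result.best_term_r2[a], result.best_term_r2[b], n_boot=1000, seed=rng_base + 6
        )
        result.bootstrap[label] = {"t": t, "p_boot": p}

    level2 = term_voxel_maps(level1, assoc, n_perm=n_perm, seed=rng_base + 7)
    atlas = build_atlas(level2, display_p=0.05, versatility_threshold=CORRIDOR_R_THRESHOLD)
    result.atlas_labeled_voxels = int((atlas.label_volume > 0).sum())
    result.versatility_max = int(atlas.versatility_volume.max())

    rep = split_half_replicate(
        dmaps, spec.parcellation, spec.brain_mask,
        n_perm=min(n_perm, 100), seed=rng_base + 8, retention="fixed", m=n_patterns,
    )
    result.split_half_mean = rep.mean
    result.split_half_sd = rep.sd
    return result


def bias_contrast_study(
    seed: int = 0,
    n_replicates: int = 10,
    grid: int = 16,
    regions_per_hemisphere: int = 6,
    n_patterns: int = 4,
    n_lesions: int = 120,
    n_subjects: int = 6,
    streamlines_per_pair: int = 10,
    jitter_sd: float = 1.5,
    n_terms: int = 12,
    term_noise_sd: float = 0.05,
    size_range=(8, 30),
) -> dict:
    """Clustered-vs-uniform contrast over seeded replicates.

    Per replicate and cohort mode: the embedding separation statistic of the
    cohort against its size/hemisphere-matched synthetic partner, and the
    mean best-term r² of the cohort's disconnectome components.
    """
    base = int(seed)
    spec = make_toy_brain((grid, grid, grid), regions_per_hemisphere, seed=base)
    pairs = default_connection_pairs(spec)
    structure = planted_bundle_structure(
        spec, pairs[:n_patterns], n_terms=n_terms, noise_sd=term_noise_sd, seed=base
    )
    tractograms = make_toy_tractograms(
        spec, pairs, n_subjects, streamlines_per_pair, jitter_sd, seed=base + 1
    )
    terms = make_toy_term_maps(structure, spec.n_regions, seed=base + 2)
    pool = build_synthetic_pool(
        spec.brain_mask,
        spec.hemisphere_labels,
        SynthPoolConfig(k_values=list(range(2, 65)), fwhm_mm=10.0, threshold=0.3, seed=base),
        voxel_size=spec.voxel_size,
        affine=spec.affine,
    )
    out = {
        mode: {"separation": [], "mean_best_term_r2": []} for mode in ("clustered", "uniform")
    }
    for rep in range(n_replicates):
        for mode_i, mode in enumerate(("clustered", "uniform")):
            cohort = plant_lesion_cohort(
                spec, structure, n_lesions, mode, size_range,
                seed=base + 1000 + 100 * rep + mode_i,
            )
            matched = match_lesions(cohort, pool, seed=base + rep)
            X = flatten_maps(
                [c.volume for c in cohort] + [m.volume for m in matched], spec.brain_mask
            )
            labels = ["observed"] * len(cohort) + ["synthetic"] * len(matched)
            out[mode]["separation"].append(separation_statistic(X, labels))
            dmaps = disconnectome_cohort(cohort, tractograms)
            fm = build_feature_matrix(dmaps, spec.parcellation, "stroke_disconnectome")
            model = fit_component_model(fm, retention="fixed", m=n_patterns)
            assoc = component_term_correlations(model.score_coefficients, terms)
            _, mean_r2 = condition_summary(assoc)
            out[mode]["mean_best_term_r2"].append(mean_r2)
    for mode in out:
        for key in out[mode]:
            out[mode][key] = np.array(out[mode][key])
    return out
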