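# Methods

This note documents the models, conventions and design choices behind
`disconnectomics`, in the order the pipeline runs them.

## Grid conventions

All volumes share one convention: the affine maps *integer voxel indices*
to world (mm) coordinates (the NIfTI convention), so voxel `(i, j, k)`
occupies the half-open cube `[i − ½, i + ½)` per axis in voxel space.
Streamlines are held in world mm throughout and pushed through the inverse
affine only when rasterised. The toy brain uses 2 mm isotropic voxels with
the grid centred so the mid-sagittal plane is world `x = 0`; a voxel whose
centre lies exactly on the plane counts as left (deterministic labeling —
with even grids no centre lies on the plane).

## Synthetic data: what it emulates, and what it does not

`make_toy_brain` builds a box brain one voxel in from each face, split into
hemispheres at the midline. The interior y-thirds give a front grey slab, a
white-matter band, and a back grey slab; each grey slab is tiled along z
into contiguous parcels. This emulates the essentials the analysis needs —
a common space, a parcellation whose regions are hemisphere-pure, and a
white-matter compartment through which bundles run — and nothing else: no
cortical folding, no vascular territories, no diffusion signal.

Streamlines are 3-point polylines (endpoint in region A, waypoint in the
white-matter band, endpoint in region B) with Gaussian positional jitter
(default 1.5 mm) rejection-kept inside the endpoint regions. The default
bundle set contains the matched front–back pair of every z-block in each
hemisphere, the remaining within-hemisphere crossings, and homotopic
interhemispheric pairs, so cohorts can disconnect many more bundle systems
than are planted.

`plant_lesion_cohort` grows connected, exactly-sized, single-hemisphere
blobs by seeded region growing (random frontier expansion), guaranteeing
connectedness and exact voxel counts. Clustered mode draws centres from the
planted pattern seeds with 2 mm dispersion (stroke-like spatial
stereotypy); uniform mode scatters centres over the whole brain. Lesion
sizes are uniform over the configured range — real stroke sizes are
heavier-tailed, which is one reason toy eigenvalue spectra are flatter than
clinical ones.

`planted_bundle_structure` defines K ground-truth patterns: pattern k's
region profile is the indicator of its bundle's two endpoint regions and
its lesion seed sits on the bundle's white-matter waypoint, so clustered
lesions really do disconnect the pattern they encode. Term maps are
`mixing · profiles + N(0, σ)` with σ = 0.05 by default; "dominant" mixing
cycles the dominant pattern over terms (every planted system is covered by
some terms, as a curated functional corpus covers every system) with
uniform leakage ≤ 0.1 onto the rest.

Because the generator's geometry is deliberately minimal, passing tests
demonstrate the *correctness of the machinery and the recoverability of
planted structure*, not clinical generalisation: real lesions are not
blob-shaped, real tractograms are not three-point polylines, and real term
maps are not linear in disconnection profiles.

## Synthetic lesion pool and pairing

Each hemisphere mask is partitioned by k-means (k-means++ initialisation,
10 restarts, seeded) on voxel coordinates, for every k in a ladder. At
desk scale the default ladder is every integer 2–64: a geometric ladder
leaves unmatchable gaps in the achievable mask sizes on small grids, and a
dense sweep is also closer in spirit to the reference 2–50,000 sweep (kept
as `FULL_SCALE_K_LADDER`). Every cluster is smoothed with a Gaussian of
FWHM 10 mm (σ = FWHM / (2√(2 ln 2)), converted to voxels per axis, so
anisotropic grids are handled), thresholded at 0.3 (strictly greater),
binarized, and clipped back to its source hemisphere — smoothing otherwise
bleeds across the midline and would break the single-hemisphere contract.

Pairing measures size *after* polishing (the paired object is the final
mask), prefers exact size matches, otherwise takes the candidate with the
smallest relative gap within a 10 % tolerance, sampling uniformly (seeded)
among ties, with replacement across observed lesions. A lesion with no
candidate in tolerance raises an error naming it. On very small grids
(≤ 12³) achievable sizes are coarsely quantized and a wider tolerance must
be configured.

## Disconnectome

"Passes through" is decided by segment-supercover traversal: for every
polyline segment, the crossings of integer grid planes partition it into
intervals, each interval lying inside one voxel (read off at its midpoint);
vertex voxels are always included; points outside the grid are clipped. A
vertex-only mode exists for cross-checks. Selection, per-subject
binarization (any visit counts once — no streamline-count weighting) and
averaging across subjects give probabilities on the k/n lattice. The
cohort API builds a per-subject inverted voxel → streamline index once, so
large cohorts reuse the per-streamline voxel sets.

## Components

PCA is computed on the sample covariance (ddof 1); loadings are
eigenvectors scaled by √eigenvalue. Varimax uses the SVD sweep algorithm
with Kaiser row-normalisation on by default, tolerance 1e-6, at most 500
iterations; rotated components are ordered by explained sum of squares and
signed so the largest-|loading| entry is positive. Score coefficients
solve `S·W = Λ` (`assume_a="pos"`); a singular covariance falls back to a
ridge solve (λ = 1e-8 · trace/p) with a warning. Scores are
`(X − X̄)·W`, so the mean observation scores zero.

Retention rules: `kaiser_mean` (eigenvalues strictly above the spectrum
mean — the covariance analogue of Kaiser's criterion, and the default),
`target_r2(θ)` on the variance curve, and `fixed(m)`. The variance curve
is the squared Pearson correlation between the vectorised data and its
rank-m′ reconstruction from unrotated components; m′ = 0 is defined as 0.
In the reference recovery study the component count is fixed at the
planted K: K is known there by design, and the common-amplitude direction
of a K-cluster cohort carries little variance, so mean-based retention
keeps K − 1 and forces mixtures.

## Term association

Terms × regions values are average z per parcel. Correlations are Pearson
across regions between each component's score-coefficient column (the only
parcel-indexed component object the model produces) and each term row;
two-sided p from the t distribution with n_regions − 2 df; Bonferroni over
all m × n_terms tests, capped at 1. Zero-variance vectors yield missing
entries with a warning.

Condition summaries aggregate r² per component either over its best term
(`max_per_component`, the default — each component's strongest functional
match) or over all terms. The bootstrap t-test enforces the null by
mean-centring both groups, pooling, resampling groups of the original
sizes with replacement n_boot = 1000 times, and reporting the two-tailed
`p = (1 + #{|t*| ≥ |t|}) / (n_boot + 1)` around Welch's t.

## Voxelwise permutation statistics

Level-1 regressions are run one component at a time (simple regression of
each in-mask voxel's disconnection probability on the component score);
level 2 regresses, at each voxel, the m component-map values on a term's
component-association vector (m ≥ 3 required). Permutations shuffle the
predictor and are shared across voxels, preserving the response's spatial
covariance. Sampled permutations give `p = (1 + #{|t*| ≥ |t|})/(n_perm+1)`;
an exhaustive mode enumerates all n! orderings (n ≤ 8) with the identity
included. Ties are counted with a 1e-9 relative guard because the observed
statistic recomputed inside the permutation matmul can differ by an ulp;
the guard is conservative (p never shrinks) and is verified against
exhaustive enumeration. Constant-response voxels are flagged missing;
constant predictors are rejected.

Split-half replication randomly halves the cohort (or accepts explicit
halves), refits features → components → maps per half, matches components
across halves by maximal |loading correlation| (Hungarian assignment) with
sign alignment, and reports the per-pair Pearson r of the maps over
in-mask voxels, with mean ± sd.

## Atlas summary

`find_the_biggest` labels each voxel with the 1-based index of the term
whose statistic is maximal there, if that maximum clears the display rule
(default: permutation p ≤ 0.05 for the winning term; a raw statistic
cutoff is available); ties break to the lowest index; NaN never wins. The
effect-size map looks up the winning term's goodness-of-fit R; versatility
counts terms with R strictly greater than 0.3. The moderate-effect 0.3
cutoff is also used to binarize level-1 corridors in the recovery study;
0.5 ("large effect") is kept in the configuration for display.

## Embedding QC

Cohorts are flattened over the brain mask and embedded with t-SNE at
perplexity 30, early exaggeration 12 (the standard scheme for the stated
"exaggeration"), learning rate 200, 1000 iterations, PCA initialisation,
seeded. Perplexity auto-shrinks with a warning for small cohorts. The
separation statistic is the mean silhouette of a two-group labeling on
Euclidean distances — higher means each group clusters more tightly apart
from the other; a stereotyped cohort against its matched synthetic partner
scores higher than a uniform cohort does.

## Pipeline driver

`run_pipeline` executes simulate → synth-lesions → disconnectomes →
features → components → associations → component maps → term maps → atlas
→ embedding, writing artefacts under `out/<stage>/` with a completion
marker of output checksums; re-runs load cached stages and recompute only
from the first missing stage. The manifest holds the config echo,
per-stage parameters and output checksums and deliberately no wall-clock
data, so same-seed runs are byte-identical; timing goes to `run.log`.
One global seed determines every stochastic stage. External (non-simulated)
data enter through NIfTI lesions/parcellation, TRK/TCK tractograms and a
TSV term matrix.

## Reference study sizes

The recovery study uses a 24³ grid, 8 parcels, K = 4 planted patterns,
200 clustered lesions of 10–60 voxels, 10 subjects × 396 streamlines
(12 bundles × 33), 20 term maps at σ = 0.05, and 200 permutations for the
map stages; the bias-contrast study uses a 16³ grid, 12 parcels, and 10
replicates of 120-lesion cohorts per regime. These sizes were chosen so
the planted structure is comfortably identifiable while the whole suite
runs in well under a minute per study on one CPU.

## Known limitations

- Toy lesion sizes are uniform, not heavy-tailed; toy streamlines carry no
  curvature or crossing-fibre ambiguity.
- The bias contrast's per-replicate term-variance margin is directional
  but noisy at desk scale; its test asserts the margin in ≥ 8 of 10
  replicates plus a positive mean, while the embedding separation margin
  holds strictly per replicate.
- Perfectly collinear voxels produce infinite t statistics (r = ±1);
  permutation p-values remain valid there.
- The external-data path of the driver recomputes all stages on every run
  (inputs are not checksum-tracked).
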