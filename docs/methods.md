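# Methods

This note documents the models, defaults and numerical choices behind
`mesoproj`, and what the synthetic tests do and do not establish about
real tracer data.

## Data model

A cohort is a dense animals × regions matrix of projection fractions with
per-animal metadata (condition ±1, sex, injection volume, injection
centroid distances in µm) and a region ontology (id, abbreviation, name,
one of 11 macro-categories). Matrices carry a stage tag —
`raw → thresholded → volume_normalized → unit_mean` — and each operation
checks the stage of its input, so the canonical processing order is
enforced by construction. Raw values must lie in [0, 1] (a voxel ratio);
after volume normalization values may exceed 1; at `unit_mean` every
column mean is 1 within 1e−12. Missing values are not supported: the
matrices this pipeline consumes are dense by construction, so absence is
treated as a data error rather than silently imputed.

Files are plain CSV (values, ontology) and JSON (metadata), one fixed
dialect (UTF-8, comma, `.` decimal, mandatory header). Floats are written
in shortest round-trip form and read with round-trip precision, so
write → load is value-exact and repeated writes are byte-identical.
Region identity is keyed by abbreviation; numeric ids may have gaps.
Subsetting animals never alters retained values; because a subset of a
unit-mean table generally violates the unit-mean invariant, stratified
reanalyses (e.g. per sex) subset at `raw` and re-run the chain — the same
order of operations a stratified wet-lab reanalysis implies.

## Thresholding

Regions with across-animal mean projection fraction < 0.1% are removed;
the boundary value 0.001 is retained (removal is strict `<`). The
threshold is applied per hemisphere table independently.

## Injection-volume normalization

Total projection ∑PF (over retained regions) is modelled as
∑PF = A·InjVol<sup>n</sup> with intercept fixed at zero, because zero
injected volume yields zero fluorescence. The fit is ordinary least
squares of log ∑PF on log InjVol (natural logs; the base cancels in n);
A = exp(intercept), and the log–log R² is reported. Preconditions: ≥ 3
animals, non-constant volumes, strictly positive totals. All values are
then divided by InjVol<sup>n</sup>. Whether the injected region itself
should be excluded from ∑PF is a judgment call; the default includes all
retained regions, and callers can subset regions upstream if they prefer
exclusion.

## Per-region GLM

With a Gaussian likelihood and identity link, maximum likelihood is OLS,
and all regions share one design matrix [1, x̃, ỹ, z̃, c], so the fit is
a single shared-design least-squares solve (tested to equal per-region
OLS to 1e−12). Covariates are centered across the fitted animals;
condition is coded +1 control / −1 treated. Residual variance uses the
unbiased n − p denominator. Degenerate (zero-residual) regions keep their
coefficients; nothing is dropped after thresholding. Rank-deficient
designs (collinear centroids, single condition) are an error, not a
warning.

Residualization for classification fits the condition-free variant and
subtracts the covariate contribution kx·x̃ + ky·ỹ + kz·z̃ from every
animal, using the fitted subset's centering constants for outsiders. By
default the fit uses only each training fold (no leakage into the
held-out animal); `residualize_once=True` reproduces the
fit-on-everyone variant, which is simpler but lets the held-out animal
influence the geometry model. Note one consequence tested explicitly: the
condition-free fit absorbs the OLS projection of the condition code onto
the covariates, so residual features carry (c − ĉ)·kc rather than c·kc —
an animal whose injection geometry happens to predict its group label
loses margin. This is a property of the method, not of the
implementation.

## Bootstrap test of μ_kc

Each group is resampled with replacement R times (default 50) preserving
group size; every one of the R² cross pairings is refit in full —
condition included, covariates re-centered on the resampled animals — and
the tail fraction of μ_kc (strictly < 0 for the positive tail, > 0 for
the negative tail; exact zeros count against rejection) is the p value,
floored at 1/R². Thresholding and volume normalization are treated as
fixed upstream steps; only the GLMs are refit per resample. The R² fits
are vectorized as batched 5×5 normal-equation solves; numerically
singular resampled designs (smallest singular value ≤ 1e−10 of the
largest) are redrawn and logged, never skipped. Each group's resampling
stream is keyed on the group's membership rather than its label, which
makes label-flip symmetry exact: swapping labels and flipping the tail
reproduces the identical p value.

Calibration under the no-effect generator (rejection rate at α = 0.05
within 0.05 ± 0.03 over 200 cohorts) is verified in the acceptance suite.

## Markov-stability clustering

The region graph is the positive part of the region × region Pearson
correlation matrix (negatives and diagonal zeroed), computed from
geometry-residualized features. Partition quality at Markov time t is
continuous-time stability with the random-walk Laplacian L = I − D⁻¹W,
stationary distribution π = d/Σd:

r(t, P) = Σ_clusters Σ_{i,j∈cluster} [(Π e^{−tL})_{ij} − π_i π_j].

The full matrix exponential is used rather than the linearized
approximation: graphs at this scale (a few hundred nodes) make exactness
affordable, and the all-in-one partition then scores exactly 0 at every t
(verified to 1e−10). Optimization is Louvain-style: greedy single-node
moves (including split-off into a new singleton), aggregation, a greedy
pairwise cluster-merge refinement, and a final move pass, restarted
`n_restarts` times (default 20) from seeded random node orders. Ties
break to fewer clusters, then lexicographically smallest canonical
labels, so scans are deterministic. On a 20-graph suite of ≤ 7-node
graphs the scan equals exhaustive maximization over all partitions
(Bell(7) = 877). Defaults: 20 log-spaced times on [10⁻², 10²]. Isolated
nodes stay singletons at every scale. Negative correlations are discarded
by design; signed-network variants are out of scope.

Cluster merging sums the member regions' features per animal, conserving
each animal's total mass exactly.

## LogitBoost classification

The base learner is a weighted least-squares regression tree (depth 1 —
a stump — by default). Each boosting round computes p = 1/(1+e^{−2F}),
weights w = p(1−p) floored at 1e−10, working responses
z = (y* − p)/w clipped at ±4, fits the tree to (z, w) and adds half its
prediction to F. There is no internal randomness; split ties break to the
lowest feature index then the lowest threshold, and an ensemble score of
exactly 0 predicts the majority training class. Defaults rounds = 100,
depth = 1 were chosen for stability at cohort sizes near 28 samples with
hundreds of features.

Leave-one-out: for each animal, residualization and the classifier are
refit on the other N−1 (verified leak-free by hashing fold models under
perturbations of the held-out animal). Scale selection among hierarchy
levels is, by default, a nested leave-one-out on the N−1 training animals
(`inner`), avoiding the optimism of picking the best scale after seeing
all folds; `per-scale` reports every scale's accuracy and headlines the
best one, which is documented as optimistic; `fixed` pins one scale.
Significance of the error count E is the exact binomial cumulative
probability P(X ≤ E), X ~ Binomial(N, 0.5), computed by exact rational
summation — no normal approximation.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with defaults chosen as the study-like conditions:

| parameter | default | meaning |
| --- | --- | --- |
| group sizes | 14 / 14 | control / treated animals (8M+6F, 6M+8F) |
| regions | 293 | across 11 macro-categories, fixed proportions |
| baseline b_j | log-normal, median 0.002, log10-sd 1.0, capped at 0.8 | spans orders of magnitude; a realistic share falls below the 0.1% threshold |
| exponent n | 0.216 | power-law volume scaling |
| injection volume | log-normal, median 1, log-sd 0.4 | arbitrary units |
| centroids (µm) | N(826,140²), N(1771,262²), N(636,60²), truncated at 0 | ML / AP / DV spread |
| covariate slopes | 0.05 per centroid SD | per-region geometry sensitivity |
| condition schemes | null / homogeneous / heterogeneous | heterogeneous default: 30% of regions, effects N(0.03, 0.05²) |
| noise σ | 0.3 | multiplicative log-normal |

The model is PF = clip₀¹(b_j · V^n · (1 + slopes·x̃ + kc·c) · e^{σε})
with covariates centered exactly as the GLM centers them, so in the σ = 0
limit the downstream linear model is correctly specified and recovery of
every coefficient is exact (≤ 1e−8 end-to-end; observed at machine
precision). The default heterogeneous effects are individually
non-significant but have a positive mean, mirroring the weak brain-wide
shifts this analysis is built to detect. Generation refuses
configurations where clipping to [0, 1] would touch ≥ 1% of entries;
under defaults the clipped fraction is below 0.2% across seeds. The
baseline cap at 0.8 truncates the log-normal's extreme upper tail —
baselines near 1 are anatomically implausible for any structure other
than the injection site and would otherwise make the clipping fraction
seed-dependent.

The distributional family of projection fractions is not established
empirically; log-normal is a modeling choice. The generator emulates no
spatial/voxel structure, no registration error beyond the centroid
covariates, and no region-to-region anatomical correlation beyond what
the shared animal factors induce. Passing the synthetic suite therefore
demonstrates correctness of the statistical machinery under the assumed
generative family — not that the assumptions hold for any particular
real dataset.

## Problem sizes and reproducibility

Ensemble checks use 200 null cohorts for bootstrap calibration and 100
for classifier calibration, with the full 50 × 50 bootstrap per cohort
and rounds = 100 boosting — sizes at which the Monte-Carlo bands
(±0.03 and ±0.05 on a 0.05 rate) are meaningful while an ensemble run
completes in minutes on one CPU. One master seed fans out to per-stage
seeds via named `SeedSequence([master, stage_code])` derivations; a
pipeline config plus one integer reproduces every artifact bit-for-bit
(up to platform floating-point determinism). All bundled randomness —
generator, bootstrap resampling, Louvain restarts — is explicit; the
classifier is deterministic by construction.

## Known limitations

- The power-law exponent is fitted once on the full cohort and treated as
  fixed inside the bootstrap; resampling does not propagate normalization
  uncertainty.
- Unit-mean normalization uses all animals, so fold-level feature values
  are not fully independent of the held-out animal at the normalization
  stage (only the geometry model and classifier are refit per fold).
- Region ontology is flat: no parent/child aggregation of structures.
- No robust or regularized GLM variants; no permutation-test alternative
  to the bootstrap; no signed-network stability.
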