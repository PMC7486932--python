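# Methods

This note documents the statistical models implemented in `structkit`,
the choices made where conventions were genuinely open, and what the
synthetic-data generator does and does not emulate.

## Coancestry matrices and copying vectors

The substrate is a square recipient-by-donor matrix of donated genetic
map length (cM) produced by a haplotype-copying ("painting") model. Rows
sum to the genome map length; the diagonal is zero because an individual
never copies from itself. The copying vector of a cluster *A* has one
component per cluster: the mean over recipients in *A* of the total cM
donated to them by members of that cluster. A cluster's own component
includes donations from its *other* members — self-copying is excluded
only through the zero diagonal.

PCA of coancestry centres columns and does not variance-scale, the
default convention of R's `prcomp` on which the established painting
tool-chains rely. Whether rows, columns or both should be centred is not
fixed by any convention we know of; column-centring is our documented
choice. Component signs are made deterministic by forcing the
largest-magnitude loading of each component positive.

## TVD and its permutation test

For normalized copying vectors the total variation distance is
`½ Σ_k |v_A,k − v_B,k| ∈ [0, 1]`. Some of the originating literature
reports the unhalved L1 sum; both are exposed (`raw=True` / `--raw-l1`),
and the permutation p-value is invariant to the factor. The test pools
the members of the two clusters, reassigns them to pseudo-clusters of the
original sizes, and recomputes the TVD. Only the two pseudo-clusters'
vectors enter the statistic and no other cluster's membership changes, so
the recomputation is restricted to the affected rows and columns; the
result equals a full recomputation. When the number of distinct splits
C(|A|+|B|, |A|) is at most `n_perm`, all splits are enumerated and the
result flagged exhaustive. The p-value is the plain ratio
(count ≥ observed)/total, using ≥ for the exceedance rule. A plain ratio
can be zero only in Monte-Carlo mode; such results are reported as the
upper bound 1/n_perm (never 0) and flagged. An optional (+1)/(n+1)
smoothing exists but is off by default. The TVD tree merges the
lowest-TVD pair in k−1 steps, recomputing copying vectors over the
reduced cluster set each step; ties break on the lexicographically
smallest label pair (the convention is arbitrary but deterministic).
Newick branch lengths are differences of merge heights, floored at zero
since TVD merge heights are not guaranteed monotone.

A finite-size caveat verified by the tests: for two equal-size clusters
of n/2 exchangeable individuals the expected TVD is not 0 but ≈ 1/(n−1),
because the excluded self leaves each cluster's own column one donor
short. The permutation test is unaffected (pseudo-clusters share the same
bias), but raw TVD values between small clusters should be read with this
floor in mind.

## Ancestry profiles

The donor copy matrix X is built from a donors-vs-donors painting: rows
normalized to 1, columns aggregated by donor group, rows averaged within
group. A target's normalized copying vector Y is decomposed by
non-negative least squares (`scipy.optimize.nnls`); the sum-to-one
constraint is enforced by rescaling the unconstrained solution, the
approach of the originating ancestry-profile literature. An alternative
penalty-row formulation (a heavily weighted all-ones row appended to the
design) is provided, and the two agree within 1e−3 on the test fixtures.

The 5% rule ("discard groups contributing less than 5% to any
individual") is ambiguous between per-individual and cohort-wide
exclusion, and between a single refit and iteration. We implement
per-individual pruning iterated to convergence: drop retained groups with
β below the threshold, refit on the survivors, repeat until all retained
shares meet the threshold or one group remains. Country aggregation sums
β over groups sharing a country label and conserves the total share of 1.

## Spatial statistics

Coordinates are planar longitude/latitude degrees with no cos-latitude
correction by default (a `cos_lat` flag applies one); this matches the
flat lat/lon plane convention of the analyses this package mirrors, and
is adequate at the ~3° spatial extent of a single small country.
Bearings are compass degrees clockwise from north; the projection of
(lon, lat) on bearing θ is `lon·sinθ + lat·cosθ`. The gradient scan
regresses the ancestry share on this projection for every integer
bearing and reports the bearing of maximum r² restricted to positive
slope (θ and θ+180° carry the same r² with opposite slope). Regression
p-values are the raw simple-regression p-values, unadjusted for spatial
autocorrelation of the residuals — they overstate significance when
residuals are spatially correlated, which is why Moran's I and the
Mantel test are reported alongside.

Moran's I uses inverse-Euclidean-distance weights by default (zero
diagonal); k-nearest-neighbour (k = 5) and Gaussian-kernel weights are
alternatives, needed e.g. when multiple individuals share a town's
coordinates. Its p-value is two-sided against the permutation
distribution (values permuted over locations); the Mantel p-value is the
one-sided proportion of joint row/column permutations with r at least
the observed. Both default to 10,000 permutations and are
seed-deterministic.

## IBD length bins and dating

Bins are half-open [L1, L2) cM so that a partition of the length axis
yields disjoint bins whose sharing matrices sum exactly to the total
matrix ("1–3, 3–5, 5–7 cM" notation does not fix boundary handling; this
choice does). Lengths arrive in cM; the recombination-rate rescaling
needed for bp-denominated segment bounds is therefore never a runtime
parameter.

In the large-population limit, segments retained in [L1, L2] date to

    E[T | L1 ≤ l ≤ L2] = 75 (1/L1 + 1/L2) generations.

Derivation, which also fixes the generator's length law: take
l | t ~ Erlang(shape 2, rate t/50 per cM) — two endpoints of the shared
segment each terminated by recombination at combined rate t/50 per cM —
and an improper uniform prior on t. Then

    ∫₀^∞ t·(t/50)² l e^{−tl/50} dt = 15000/l³,
    ∫₀^∞ (t/50)² l e^{−tl/50} dt = 100/l²,

so E[t | l] = 150/l, and integrating over the bin,

    E[T | bin] = ∫ 15000/l³ dl / ∫ 100/l² dl = 75(1/L1 + 1/L2).

The Monte-Carlo oracle `eq2_oracle` draws t uniform on (0, T_max],
requires T_max ≥ 100·50/L1 (a shorter range truncates the heavy time
tail and biases the mean down), and matches the closed form within 2% at
10⁶ draws. With a 28-year generation time the 3–5 and 5–7 cM bins date
to 1120 and 720 years. Note that direct substitution for the 1–3 cM bin
gives 100 generations = 2800 years, whereas the figure legend of the
analysis this mirrors prints "~2700"; the rounding or assumption behind
that printed value is not stated anywhere we can find, and the package
reports the formula value. Ages are returned as durations
(years before present); anchoring to a cohort birth year is left to the
caller.

Per-bin clustering reduces the symmetric sharing matrix with the same
column-centred PCA and fits Gaussian mixtures for k = 1..k_max over
diagonal and full covariance families with 10 fixed-seed EM restarts,
selecting the lowest BIC. Restricting to two covariance families keeps
model selection deterministic and is sufficient to distinguish "one
blob" from genuine multi-cluster structure; richer families (as in
mclust's full search) would mainly refine cluster shapes, not counts.
Mean pairwise sharing between groups uses the exact pair-count
denominators: (N²−N)/2 for a group with itself, NM for two groups; the
within-group mean of a singleton is undefined and an error.

## Nagelkerke R²

For a binary phenotype and covariate matrix, logistic models are fit by
statsmodels; with intercept-only log-likelihood ℓ0 and full-model ℓ1,

    R² = (1 − exp((2/n)(ℓ0 − ℓ1))) / (1 − exp((2/n) ℓ0)).

Marginal (each covariate alone) and cumulative (covariates added in
order) values are reported alongside the full-model value.
Zero-variance covariates are dropped (they add nothing and would make
the design singular); perfect separation saturates the likelihood, caps
R² at 1 and flags the result with a warning.

## The synthetic generator

The generator emulates the *statistical shape* of the matrices and
segment lists the analyses consume, not the biology that produces them:
no coalescent genealogies, no sequence, no recombination maps.

* **Geography.** Demes at fixed (lon, lat) centres — the defaults are
  three Dutch towns spanning the north–south axis — with individuals
  scattered by Gaussian jitter (`coord_jitter_sd`, default 0.15°,
  roughly the footprint of a sampling municipality).
* **Coancestry.** Expected donation from j to i ∝
  `exp(−d_ij/ρ)·(1 + κ·[same deme])`; each row is genome_length ×
  Dirichlet(α·expectation). α (default 1000) controls row noise; κ
  (default 5) the block structure; ρ (default 1°) isolation by distance.
  Rows sum exactly to the genome length (3500 cM ≈ the autosomal map)
  and the diagonal is exactly zero. No painting model is run — the
  Dirichlet-decay form is an artifact of this package, chosen to
  reproduce the qualitative features (block structure, spatial decay,
  compositional noise) the downstream statistics are sensitive to.
* **IBD.** Per pair: event count ~ Poisson(λ_class), coalescence time
  t ~ Gamma(shape, scale) per pair class, length ~ Erlang(2, t/50 per
  cM), truncated at the 1 cM detection floor. Defaults: λ = 20 events
  per pair for both classes; within-deme times Gamma(4, 10) (mean 40
  generations), between-deme Gamma(4, 30) (mean 120) — recent common
  ancestry inside demes, ancient between, the regime in which long
  segments are confined within demes. A separate validation mode draws
  t uniform on (0, T_max] to check the dating formula; the two modes
  are never mixed. Segments are placed on a synthetic map of 22
  autosomes with linearly decreasing lengths summing to the genome
  length, chromosome drawn proportional to map length, start uniform,
  and 1 cM = 1 Mb for bp coordinates — enough for format validity, with
  no pretence of a real genetic map.
* **Ancestry.** True source shares follow
  `intercept + slope·(projection on the source's bearing)` of
  centroid-centred coordinates, clipped at 0 and renormalized; observed
  targets are β·X plus optional Gaussian noise on the target vector
  (clipped, renormalized). The synthetic donor matrix copies 0.8 of a
  group's genome from itself and the rest evenly — strongly diagonal,
  as painting of well-separated donor groups is in practice. The
  recovery benchmarks use five sources with bearings spread at 72°
  intervals, low intercepts (0.05) and strong slopes (0.25 per degree),
  giving sparse profiles (typically 2–3 active sources per individual)
  like real border-gradient profiles; recovery tolerances are evaluated
  under target noise sd 0.005 per component.
* **Phenotype.** P(case | deme d) = logistic(b0 + s_d); `phenotype_base`
  is b0 and `phenotype_intercepts` the per-deme offsets, so structure
  confounds case/control status exactly when the offsets differ.

One master seed expands via `SeedSequence.spawn` into independent
substreams (geography, coancestry, IBD, ancestry, phenotype), so
changing one component's parameters never shifts another's draws, and
identical config + seed yields byte-identical output files.

What passing these tests does **not** show: the generator has no linkage
between coancestry and IBD components (they are drawn independently
given the deme structure, whereas in real data both derive from one
genealogy), no haplotype-level noise, no relatedness outliers, no
genotyping artefacts, and planar geography. Results on real painting/IBD
output can differ for all of those reasons; the tests establish the
correctness of the statistics, not the realism of any particular
dataset.

## Problem sizes and numerical choices

Test and benchmark sizes are chosen so every property is measurable with
comfortable statistical margin at interactive runtimes: cohorts of
40–200 individuals, 200-replicate null calibrations, 10⁶-draw
Monte-Carlo checks, 20-replicate clustering comparisons. Tolerances:
normalized vectors must sum to 1 within 1e−9; exhaustive/Monte-Carlo
agreement is asserted within 3 binomial standard errors; the
Monte-Carlo dating oracle within 2%; NNLS recovery to 1e−8 noiseless.
Degenerate inputs (constant values, singleton groups, rank-deficient
donor matrices, coincident coordinates under inverse-distance weights)
raise errors naming the remedy rather than returning silently wrong
numbers.
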