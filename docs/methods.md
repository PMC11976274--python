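# Methods

## Shape space and superimposition

All analyses operate on 11 two-dimensional landmarks per wing. Generalized
Procrustes analysis (GPA) centres each configuration, scales it to unit
centroid size, and rotates it to the consensus, iterating until the
consensus changes by less than 1e-10; centroid sizes are recorded before
scaling. Four degrees of freedom (x/y translation, rotation, scale) are
removed, leaving an 18-dimensional shape space inside the 22 Procrustes
coordinates. Procrustes distance is the Euclidean norm between aligned
coordinate vectors (the partial-Procrustes convention); since every rate
and divergence measure is relative, the choice of convention does not
affect any comparison, only the absolute scale of distances.

Two conventions matter in practice:

- **Reflection.** When pairing left and right wings for the asymmetry
  analysis, right configurations are mirrored and the superimposition is
  allowed to reflect; everywhere else reflection is disallowed.
- **Common frame.** A GPA consensus is only defined up to rotation.
  Covariance matrices estimated from different datasets are therefore
  only comparable along a shared basis if all superimpositions are
  aligned to one reference configuration. The pipeline aligns every
  dataset to the macroevolutionary mean shape; `gpa(..., reference=...)`
  and `estimate_D(..., reference=...)` expose this.

## Covariance matrices

- **D** (developmental): right wings are reflected, all wings jointly
  superimposed, and per-individual left-minus-right coordinate vectors
  collected. The mean asymmetry vector — directional asymmetry — is
  subtracted, so D is the covariance of fluctuating asymmetry only.
  Because left and right develop from the same genome in the same
  environment, this covariance is a readout of developmental noise.
- **G** (genetic): covariance of isofemale-line mean shapes after
  centring by population. Line means act as breeding-value proxies; the
  estimate carries an attenuation term of order Σ_within/m for m
  individuals per line, which is reported, not corrected (the unit of
  analysis throughout is the line).
- **P** (phenotypic): pooled within-population covariance.
- **M** (mutational) is an external input, read from a plain matrix file.

Effective rank is chosen by AIC over factor-analytic approximations of
the estimate under a Wishart likelihood (leading k eigenpairs plus an
isotropic remainder; parameters counted as kp − k(k−1)/2 + 1), capped at
18. This plays the role of reduced-rank model selection in a mixed-model
engine without requiring one; the rank is also user-overridable, and all
cross-matrix comparisons default to k = 10 dimensions.

## Common-subspace comparison

Matrices X (predictor) and Y (response) are compared along the
eigenvectors of an independently estimated reference matrix — P by
default, exposed as a parameter — by OLS regression and Pearson
correlation of the natural-log variances `log diag(KᵀYK)` on
`log diag(KᵀXK)` over the first k dimensions. Using an independent
reference avoids the upward bias that comes from projecting a matrix on
its own estimated eigenvectors. Confidence intervals resample each matrix
from Wishart(df = n_units, scale = estimate/df) — the normal-theory
sampling distribution of a (co)variance estimate — realized through the
PSD square root so rank-deficient estimates need no jitter. Slope and
correlation are invariant to trace-scaling of either matrix. Note one
honest caveat: because resampling adds independent noise to both
matrices, a near-degenerate correlation (r ≈ 1) is attenuated in every
draw and its CI sits below the point estimate; slope CIs do not have this
problem.

## Rate matrix and phylogenetic heritability

Family-level tips on a calibrated ultrametric tree (branch lengths in
Myr) carry replicated species observations; only families with ≥5
species are analysed. Per dimension the model is y_fs = μ + u_f + e_fs
with cov(u) = σ²_phylo·S (S the shared-path-length matrix) and e iid.
Estimation is two-stage:

1. σ²_species per dimension from pooled within-family scatter (high df);
2. the family means are whitened by the generalized eigendecomposition of
   (S, diag(1/n_f)) and projected onto contrasts orthogonal to the mean;
   in that space the phylogenetic part is diagonal and the species part
   isotropic, so a one-parameter REML per dimension (optimized on the log
   scale, with an explicit boundary check at zero) gives σ²_phylo.

The full 22×22 R comes from a method-of-moments estimator in the same
contrast space — cross-products of contrasts minus the species-noise
contribution, divided by the summed contrast eigenvalues — then
symmetrized and projected onto the PSD cone. Moments rather than BLUP
cross-products were chosen because BLUP shrinkage attenuates
off-diagonals and would bias the subspace slope below 1 even under the
true model; the moment estimator is unbiased up to the PSD projection.
At 40 families the Wishart sampling floor on R is ~30% in relative
Frobenius norm — irreducible by any estimator — which is why recovery is
validated on the eigenvalue-regression slope and the common-subspace
statistics rather than on elementwise error.

Phylogenetic heritability per dimension is
mean over tips of σ²_phylo·S_tt / (σ²_phylo·S_tt + σ²_species), and the
reported summary is the mean across dimensions weighted by each
dimension's total species-level variance.

## Branch analysis

Ancestral states under Brownian motion minimize the sum over edges of
squared change divided by branch length; the minimizer is a linear map of
the tip values (a weighted graph Laplacian solve), independent of the
rate matrix, and is precomputed once per tree so thousands of null
replicates are cheap. Per edge, β = child − parent state, rate = |β| /
branch length, and e_β = βᵀC′β/|β|² for a trace-scaled reference C (D or
M). Edges with |β| = 0 have no direction and are excluded with a count.

The constraint test correlates e_β with rate across edges and compares
the observed correlation to simulated Brownian motion with Σ = C scaled
to the trace of R (the overall scale cancels in the correlation). Each
replicate reruns the identical reconstruction → branch-change pipeline.
P_RAND is the lower-tail fraction of null correlations at or below the
observed one, because the constraint hypothesis predicts evolution to be
*faster* when aligned, making a low observed correlation the departure of
interest. One structural caveat discovered during validation: on trees
with strongly heterogeneous edge lengths (any birth–death tree), the
1/√length component of the rate dominates its variance and dilutes the
e_β–rate correlation toward zero under aligned and misaligned evolution
alike; the null distribution inherits the same dilution, so the test
stays calibrated, but its power is far higher on trees with comparable
edge lengths.

The neutral-drift expectation is expected divergence = 2 × mutational
variance × generations, per dimension along the comparison basis, with
generations per year a parameter (default one). The divergence profile
tabulates all cross-family species pair (divergence time, Procrustes
distance) pairs, binned by time; under BM the mean squared distance grows
linearly at twice the summed rate.

## Allometry

The evolutionary allometric vector is the multivariate OLS slope of shape
on log centroid size; R² sums model over total sums of squares across
coordinates, F uses the (1, n−2) structure, and significance permutes
sizes across rows. Alignment of the (unit-normalized) vector with a
trace-scaled matrix is vᵀC′v, tested against uniformly random directions
in the 18-dimensional shape subspace — the geometric question is whether
this particular direction is special in C, which permutations of data
rows would not address. Removing allometry regresses a single common
slope out of all shapes and re-adds the grand mean; the operation is a
projection (idempotent). The phylogenetic variant of the regression (GLS
with covariance S on family means) is available; the ordinary regression
is the primary estimator.

## Fitness battery

Five traits per line × treatment × replicate: longevity (right-censored),
developmental rate, juvenile survival, body size, early reproductive
success (females dead before day 15 and zero-layers excluded, both
flagged). For the four uncensored traits a linear mixed model with fixed
treatment × population effects (cell-means coding), one random line
intercept, and residual variances free per treatment is fitted by REML —
implemented directly via per-line rank-one Woodbury blocks and quasi-
Newton optimization of the profiled likelihood. The line effect is tested
by LRT; since the null pins a variance at the boundary, the halved-χ²₁
mixture p is primary and the plain χ²₁ p is reported alongside. Shrinkage
BLUPs feed the downstream analyses. Longevity uses a rank-based censored
model: martingale residuals under the pooled Nelson–Aalen cumulative
hazard, summed per line, negated and shrunk by line size — a deliberately
simple estimator, since only the line *ranking* feeds the downstream
analyses — with a permutation test for the line effect. Line-by-treatment
interactions are deliberately not modelled; the target is overall genetic
quality.

Genetic quality is PC1 of the 5×5 BLUP correlation matrix, oriented so
the loading sum is positive, with two nulls for its variance share: iid
standard-normal matrices of the same shape, and independent per-trait
permutation of BLUPs across lines. The shape–fitness two-block PLS first
residualizes line mean shapes on centroid size and population; the
stabilizing-selection test correlates each fitness score with the
Procrustes distance of the residualized line mean from the grand mean,
with an outlier-excluded rerun produced alongside.

All permutation and randomization p-values use (b+1)/(m+1) smoothing, and
every stochastic operation takes an explicit seed.

## Synthetic data: what it emulates and what it does not

The generator reproduces the empirical design sizes: 43 family tips on a
pure-birth tree rescaled to 185 Myr depth, ~10 species per family, 71
isofemale lines across 7 populations with 6 individuals per line and a
left and right wing each, 3 temperature treatments with heteroscedastic
residuals, and 17% right-censoring of longevity. Shape covariance inputs
are built strictly inside the 18-dimensional tangent space of a fixed
wing-like consensus, so simulated variation never excites the Procrustes
null directions. Spectra decay geometrically with ratio 0.5 per dimension
(leading eigenvalue ≈ half the trace, ~3 orders of magnitude across ten
dimensions), matching the strongly anisotropic spectra of real landmark
covariance matrices. Default traces — developmental 2e-4, among-line
1e-4, species scatter 1e-3, BM rate 2e-5 per Myr, in squared Procrustes
units — put family divergence over the tree depth at a few times the
within-family scatter, and by default the BM rate matrix is proportional
to the developmental matrix (evolution along the developmental line of
least resistance) with a size–shape coupling along its leading axis
(allometry R² ≈ 0.13 at log-size SD 0.4).

Raw line-level configurations are exported with random rotation,
translation, digitizing scale, and mirrored right sides, so the
Procrustes machinery is genuinely exercised. What the generator does not
emulate: realistic vein geometry, landmark-level digitizing error
structure, missing landmarks, unequal species sampling across families,
non-Brownian (e.g., Ornstein–Uhlenbeck) macroevolution, and genotype-by-
environment interaction in fitness. Passing tests therefore certify the
estimators and their calibration under the stated generative model, not
robustness to those real-data complications.

## Numerical choices

- GPA convergence 1e-10 on the consensus; degenerate (zero-size)
  configurations rejected.
- CVA inverts the within-group covariance after projecting onto
  principal components explaining 99% of variance; leave-one-out refits
  the axes without the held-out row and classifies by nearest group
  centroid; groups under five observations are dropped first.
- Wishart draws via the symmetric PSD square root (no jitter on
  rank-deficient scales); resampling redraws on the rare nonpositive
  projected variance.
- Per-dimension REML optimizations run on the log-variance scale with an
  explicit boundary comparison at zero (a plain bounded search on the
  natural scale cannot resolve variances orders of magnitude below its
  absolute tolerance).
- PSD projection clips negative eigenvalues at zero after symmetrizing.
- Ultrametricity is checked to 1% relative tolerance; zero or missing
  branch lengths are errors.
- Effect sizes Z standardize the raw statistic against its permutation
  distribution (not a log transform of it).

## Known limitations

- G from line means understates the genetic covariance by the within-line
  term; with the default 6 individuals per line the attenuation is ~8% of
  the developmental trace.
- The branch-alignment test has low power on trees with wide edge-length
  variation (see above); this mirrors the method itself, not a defect of
  the implementation.
- The censored longevity score preserves ranking, not hazard-scale effect
  sizes; mixed-model χ² values for it are not comparable across engines.
- Mixed-model likelihoods (and hence LRT χ² magnitudes) depend on the
  residual-variance structure; significance patterns, not χ² values, are
  the supported output.
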