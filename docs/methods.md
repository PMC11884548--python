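# Methods

This package implements a whole-brain excitation/inhibition (E/I) analysis
pipeline on synthetic cohorts: Hurst-exponent estimation from parcellated
BOLD-like time series, parametric mean-field circuit modeling fitted to
static and dynamic functional connectivity, region-wise case-control
statistics, network spreading and epicenter mapping under spatial and
topological nulls, and leakage-free case-control classification. This note
records the models, the choices that were genuinely open, and what the
synthetic experiments do and do not establish.

## Hurst exponent as an E/I proxy

Each region's series is modeled as fractionally integrated (long-memory)
noise with memory parameter d; the Hurst exponent is H = d + 1/2. Under
the wavelet-Whittle approximation, orthonormal Haar detail coefficients at
level j are treated as independent zero-mean Gaussians with variance
sigma^2 * 2^(2 d j). sigma^2 is profiled out in closed form, and d is
found by bounded scalar search (tolerance 1e-6) inside a configurable box,
default d in [-0.5, 1.5]. An optimum on the box edge sets a `boundary`
flag rather than raising, because heavily low-pass signals (e.g., pure
hemodynamic convolutions) legitimately pin d at the edge. Series are
mean-centered and variance-normalized before estimation; H is invariant to
both under the model, so this only stabilizes the profiled variance.

Two estimator properties are enforced by tests: near-unbiasedness
(|bias| < 0.05 for H in {0.6, 0.7, 0.8} at n = 4096) against exact
fractional Gaussian noise, and agreement with an independent log2-variance
regression estimator (slope beta maps to H = (beta + 1)/2).

The wavelet decomposition itself is delegated to PyWavelets
(`mode="periodization"`, orthonormal), and the number of levels defaults
to floor(log2 T) - 3 so the coarsest level keeps at least 8 coefficients.

The interpretation of the box constraints of the reference MATLAB
estimator this mirrors is not published; the reading adopted here — the
two-parameter bounds act on (d, sigma^2), of which only the d box binds
after profiling — is an assumption, not a verified equivalence.

## Exact fractional Gaussian noise

The synthetic generator uses Davies-Harte circulant embedding: the fGn
autocovariance gamma(k) = sigma^2/2 (|k+1|^2H - 2|k|^2H + |k-1|^2H) is
embedded in a circulant matrix whose eigenvalues are nonnegative for this
autocovariance, giving sample paths with exactly the target second-order
structure. Lengths are padded to the next power of two and truncated, so
the embedding stays exact at any requested length. Tests verify the
sample autocovariance at lags 0-5 against gamma(k) to within three
standard errors over 200 replicates; the known-zero process mean is used
in that check, because subtracting a sample mean biases long-memory
autocovariance estimates by ~ n^(2H-2).

## Synthetic cohorts

A cohort is a parcellation + connectome + per-subject time series with
covariates and recorded ground truth.

* **Geometry.** Each hemisphere's region centroids cover a full unit
  sphere, as on the per-hemisphere spherical projections used in
  surface-based neuroimaging; the right hemisphere is the x-mirror of the
  left, so region i and i + N/2 are homotopic twins. Full-sphere coverage
  per hemisphere is load-bearing: rotation-based (spin) surrogates are
  only exchangeable with the original map when the rotated point cloud
  covers the same support.
* **Connectome.** Edge existence probability decays as
  exp(-dist/decay_length); the distance minimum spanning tree is always
  included (connectivity guarantee), edge count is calibrated to the
  requested density in expectation, and weights are log-normal.
* **Annotation maps.** Isotropic Gaussian random fields per hemisphere
  from real spherical harmonics of orders 1-4 with 1/l amplitude decay
  plus 1/smoothness white noise; the right hemisphere is a noisy copy of
  the left with homotopic correlation 0.7. Isotropy within each
  hemisphere is again what makes spin surrogates exchangeable; an earlier
  draft that evaluated one global field at both hemispheres' positions
  produced midline-dependent homotopic structure that no rotation can
  reproduce, and miscalibrated the spin test badly.
* **Subjects.** Regions are independent fGn processes (Hurst estimation
  is per-region; the within-subject spatial correlation of H is not a
  quantity the analysis depends on, and independence is the conservative
  choice). Controls sit at a baseline Hurst map; patients have H reduced
  by delta_h in a designated region set on the focus hemisphere, with
  focus side sampled 50/50 unless fixed, and an optional milder homotopic
  effect. Age is uniform over a stated range, sex Bernoulli(0.5), with no
  covariate-group confounding by default. The cognitive score is a stated
  linear function of the subject's mean true H plus Gaussian noise.

Serialization is plain TSV/JSON, written with `%.17g` floats and read
with round-trip parsing so matrices survive a write-read cycle exactly.

## Connectivity dynamics

Static FC is the Pearson correlation matrix. FCD follows the
sliding-window construction: windowed FC upper triangles (window 100
samples, step 1, matching a 695-sample acquisition that yields 596
windows) are vectorized and pairwise correlated. Windowed correlations
are computed from cumulative sums, verified against per-window
`corrcoef`. Group FC averages Fisher-z transformed matrices (the source
analysis says only "averaged"; the z-average is recorded here because it
changes third-decimal behavior); group FCD distributions average
participant CDFs pointwise on a 1000-point grid over [-1, 1]. The KS
distance is the sup-norm on the union grid. Windowed FC vectors are
cross-correlated raw (not Fisher-transformed) — the construction the FCD
definition states.

## Parametric mean-field model

Each region has one excitatory gating variable S_i:

    dS_i = [-S_i/tau_s + gamma (1 - S_i) r(x_i)] dt + sigma_i dW_i
    x_i  = w_i J S_i + G J sum_j C_ij S_j + I_i
    r(x) = (a x - b) / (1 - exp(-d (a x - b)))

with regional parameters linear in two annotation maps,
w_i = a_w Mye_i + b_w Grad_i + c_w (likewise I_i, sigma_i), leaving ten
global unknowns (nine coefficients + G). Transfer and gating constants
(a = 270 Hz/nA, b = 108 Hz, d = 0.154 s, tau_s = 0.1 s, gamma = 0.641,
J = 0.2609 nA) are the standard reduced-model values of this model
lineage — configuration, not fitted or source-verified quantities.

Numerics: Euler-Maruyama at dt = 10 ms (a hard upper bound — the high
firing-rate branch is stiff); S clamped to [0, 1] with clamp events
counted (< 0.1% of steps at the default operating points, enforced by
test); non-finite states raise with the offending step. The coupling
matrix C is the SC normalized per `sc_norm`: default **row
normalization** (each region receives unit total long-range input).
Max-normalization is available but not default, because under it the
critical coupling G* depends strongly on the realized degree
distribution, which makes synthetic experiments unstable across
connectome draws.

BOLD comes from the Balloon-Windkessel model (kappa = 0.65/s,
gamma_h = 0.41/s, tau = 0.98 s, alpha = 0.32, E0 = 0.34, V0 = 0.02)
integrated at the same dt, sampled every TR = 0.6 s; the first 30 s of
BOLD (hemodynamic settling) are discarded in the theta-to-BOLD path, and
the gating burn-in (30 s) separately before that.

### Fitting

Cost = (1 - r) + KS, where r is the Pearson correlation of simulated vs
empirical static FC upper triangles and KS the distance between FCD CDFs.
Invalid parameter sets — induced sigma_i <= 0, w_i < 0, w_i > 1.5,
sigma_i > 0.02, numerical blow-up, degenerate output — cost +infinity.
The optimizer is a self-contained (mu/mu_w, lambda) CMA-ES (Hansen's
standard formulation: rank-one + rank-mu covariance updates, cumulative
step-size adaptation), population 8 in a 10-dimensional affine
reparameterization theta = base + scales * z chosen so z ~ N(0, I) gives
mid-range regional maps. Per split: 50 iterations x 5 restarts (desk
scale: 20 x 3) with the per-generation best kept as a candidate; all
candidates re-scored on validation data; the top 10 re-scored on test;
best test cost wins; winners averaged across subject splits (15:15:10
ratios). Restarts start in different sign quadrants of (a_w, b_w): the
cost surface can hold a separate basin for the spatial inversion of a
regional pattern, and deterministic sign-diverse multistart covers both.
Candidate evaluations use a fixed noise path per split (common random
numbers), so the search surface is deterministic; `n_avg` > 1 averages
several paths per evaluation (the recovery study uses 3), which was
necessary for the cost minimum to sit at the generating parameters.

### The two simulation studies

**E/I premise.** All regions share a hyperexcitable saturated operating
point (w = 0.9, I = 0.325 nA, G = 0.3, sigma = 0.005); half have w scaled
by 1.3. Deeper saturation shrinks and speeds a region's BOLD
fluctuations, so against a fixed scanner-level measurement noise (5e-6,
chosen so the slow band sits near unit SNR) the estimated Hurst exponent
of the perturbed regions drops. A paired one-sided test over 10
simulation seeds rejects at p < 0.05. This realizes, in the model, the
claim that elevated recurrent excitation manifests as a lower Hurst
exponent; the mechanism here runs through fluctuation amplitude and
speed, not through any fitted relationship to data.

**Parameter recovery.** Ground truth spreads w across the bistable
threshold (a_w = 0.25, b_w = -0.1, c_w = 0.95, I = 0.31 nA, sigma = 0.01,
G = 0.3) on a fixed 40-region reference substrate, so the partition of
regions into low/high-activity states — and through it FC — is shaped by
the w map. The substrate is a reference object, like an atlas: its maps
must spread w across the threshold with a noise-path-invariant partition
(verified by test), otherwise group-averaged targets mix partitions and
the fit is unidentifiable. Train/validation/test targets are group
averages over 10 model-generated pseudo-subjects (400 TR each). Success
is Spearman(true w map, recovered w map) > 0.8 with budget 20 x 3 over 2
splits. Recovered coefficient *values* are not claimed — only the
regional pattern.

## Group statistics

Patient and control maps are z-scored to the control distribution per
region, hemisphere-sorted so indices mean ipsi/contralateral to the
focus (right-focus subjects get their hemispheres swapped; the transform
is an involution), and compared per region with OLS
`value ~ group + age + sex`. Cohen's d is the adjusted group coefficient
over the residual SD (patients coded 1, so lower-in-patients gives
d < 0). Multiple comparisons use Benjamini-Hochberg FDR across regions
(the random-field-theory correction of vertex-level surface analyses does
not apply to parcel-level synthetic data); the BH implementation is
statsmodels', cross-checked against a brute-force step-up in tests.
Summary-statistic t-tests use the Welch form (identical to pooled at
equal n, which covers the printed values); the 2x2 chi-square is Pearson
without continuity correction. Partial correlations residualize both
variables on the covariates and expose one-sided alternatives for
directional clinical hypotheses.

## Network spreading, epicenters, nulls

Neighbor alteration D_i averages d_j * SC_ij (optionally * FC_ij) over
the structurally connected neighbors of i, normalized by the *neighbor
count* (node degree), not the weight sum — the definition is implemented
literally and checked against a brute-force double loop to 1e-12.
Isolated nodes get NaN. Epicenter likelihood is the Spearman correlation
of each region's connectivity profile (self-entry excluded) with the
alteration map, ranked descending, optionally with per-region spin
p-values.

**Spin test:** per iteration one uniform random rotation is applied to
the left hemisphere's spherical centroids and its x-mirrored counterpart
to the right; each region takes the value of the nearest rotated source
within its hemisphere (so values never cross hemispheres and homotopic
pairing is preserved — both hemispheres share one source index set).
Two-sided p with the +1 permutation correction. Calibration (type-I error
in [0.02, 0.08] on independent smooth maps) holds because of the
generator's per-hemisphere isotropy; parcel-level nearest-neighbor
reassignment attenuates map autocorrelation by ~10% on average, which the
tests bound at 25%.

**Rewired null:** edges binned into 10 equal-count distance bins;
degree-preserving double-edge swaps within bins (10x edge count attempted
swaps), weights traveling with edges; a swap is accepted only when both
replacement edges fall within one bin of the pair they replace. Strict
same-bin acceptance under-mixes on sparse desk-scale graphs (most edges
never move, making the test conservative), while unconstrained within-bin
swaps erode the length distribution; the one-bin slack preserves the mean
edge length to < 0.1% while keeping type-I error in band. The p-value is
one-sided exceedance, as the statistic is "does the observed coupling
exceed what topology-free geometry produces".

## Classification

Linear-kernel SVC, C = 1 (algorithm family fixed; kernel and C are
config), 4-fold stratified CV repeated n_iterations times. Feature
selection — top ceil(k% x N_cortical) regions by |Cohen's d| plus an
always-include set — happens inside each training fold. Accuracy is the
fold mean; AUC pools decision values per iteration. Permutation
significance reruns the whole pipeline per shuffled labeling at a reduced
iteration count (default 10; calibration uses 2 and gives the observed
run the same count, because exchangeability of observed and permuted
metrics requires identical configurations). sklearn's per-call input
validation is skipped inside the CV loop (trusted arrays, hot path);
accuracy and AUC are computed directly from decision values.

## Problem sizes

The bundled studies run at desk scale by design: 40-68 regions, 256-1024
samples, 10-seed replications, CMA-ES budget 20 x 3 over 2 splits.
These sizes make every experiment reproducible in minutes while keeping
each effect detectable at its stated threshold; all are configurable
upward.

## What passing tests do and do not show

The synthetic generator emulates the *structure* of a clinical resting-
state study (group labels, focus lateralization, covariates, regional
effect topography, connectome geometry), not its content: fGn is not
BOLD, independent regions understate spatial correlation, annotation maps
are random fields rather than real myelin/gradient maps, and the
mean-field operating points are chosen for identifiability rather than
fitted to any human data. Green tests certify internal correctness and
calibration of the machinery — estimator bias, null uniformity,
sensitivity at stated effect sizes, parameter recoverability — not any
clinical claim about epilepsy.

## Known limitations

* The Hurst estimator treats wavelet coefficients as independent across
  and within scales (Whittle approximation); exact FIN likelihood is out
  of scope.
* Parcel-level spin tests are approximate; at very low region counts or
  extreme smoothness they drift anticonservative.
* CMA-ES recovery is demonstrated for the w-map pattern on the reference
  substrate, not for all ten coefficients individually (several are
  weakly identified at desk scale, notably the sigma coefficients).
* The premise experiment's measurement-noise level is part of the
  experimental design; at much higher or lower scanner noise the Hurst
  contrast between saturation depths vanishes.
* No feedback inhibition or multi-population variants; no tapered FCD
  windows; no longitudinal mixed-effects modeling.
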