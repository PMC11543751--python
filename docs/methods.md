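# Methods

## Model

`glmmtree` fits growth-curve partition models of the form

```
y_i = X_i β_j + Z_i b_i + ε_i
```

with `X_i = (1, t_i)` per subject `i`, node-specific fixed effects `β_j`
(intercept and time slope) indexed by the terminal node `j` into which the
subject's time-constant covariates route it, random effects `b_i ~ N(0, Σ)`
with design `Z_i` a column subset of `X_i` (none, intercept, or intercept
and slope), and i.i.d. Gaussian residuals.  The scope is a continuous
response with identity link; subjects may differ in the number and spacing
of observations.  Fixed effects are local to nodes, random-effect
(co)variances are global — the tree explains between-subject heterogeneity
in the mean trajectory, the random effects absorb what remains.

## Estimation

The alternating algorithm is: initialize `b̂ = 0` (or, under
`init_mode="random_effects"`, with the BLUPs of the one-group mixed model
fitted to the full sample); then repeat (1) grow an LM tree on the response
with `Z_i b̂_i` as a fixed offset, (2) refit the mixed model with
node-specific fixed effects for the partition found, extract new BLUPs,
until the partition repeats (primary criterion), the mixed-model
log-likelihood changes by less than `loglik_tol = 1e-4`, or
`max_iterations = 25` is reached.  If the alternation revisits an earlier,
non-adjacent partition (a cycle — behavior genuinely undefined in the
underlying algorithm), the higher-log-likelihood model is kept and the fit
is flagged `converged_by="cycle"`.  A mixed-model failure mid-alternation
keeps the previous iteration's model with a warning; a failure of the
full-sample initialization fit is fatal.

Mixed models are estimated by ML by default: the alternation compares
log-likelihoods across partitions with different fixed-effects dimensions,
which REML likelihoods do not support coherently.  REML is available as an
option for final fits.  The solver profiles the fixed effects and residual
variance out of the likelihood and optimizes the 1–3 free entries of the
relative Cholesky factor `L` of `Σ = σ²_ε L L'` (L-BFGS-B / bounded Brent,
lower bounds 0, so variance estimates may sit exactly on the boundary;
non-convergence is flagged, not fatal).  Each likelihood evaluation reduces
to vectorized 2×2 operations on per-subject cross-products, so a fit takes
milliseconds; agreement with statsmodels `MixedLM` and lme4 is verified to
~1e-3 in log-likelihood in the test suite.  The intercept+slope covariance
is diagonal by default (matching the simulation design); an unstructured
2×2 is available for data analysis.

## Parameter-stability tests

In each node the least-squares scores `ψ̂_i = x_i (y_i − offset_i − x_i'β̂)`
are cumulated in the order of a candidate covariate and decorrelated,

```
W_k(t) = Ĵ^{-1/2} n^{-1/2} Σ_{i ≤ [nt]} ψ̂_{σ(u_ik)},
```

and a parameter change along `u_k` shows up as excess fluctuation of `W_k`.
Continuous covariates use `supLM = max_t ‖W(t)‖² / (t(1−t))` over the
trimmed interval `t ∈ [0.1, 0.9]` (standard structural-change practice;
configurable), evaluated only at boundaries between distinct covariate
values so ties can never host a maximum.  Unordered factors use the
chi-square statistic `Σ_l ‖Ĵ^{-1/2} n^{-1/2} S_l‖² / t_l` on level-wise
score sums `S_l` with reference df `k(L−1)`, which is invariant to level
order.  Only the `k = 2` fixed-effect parameters are tested; the
residual-variance score is excluded.  Scores omit the `1/σ²` factor of the
exact Gaussian gradient — every statistic is invariant to that scaling
because `Ĵ` is built from the same scores.

`Ĵ` is the outer-product-of-gradients ("meat"-only) estimator.  In
`observation` mode it averages per-observation outer products; in
`clustered` mode scores are summed within subject first and `n` counts
subjects — since candidate covariates are time-constant, the clustered
cumulative process is evaluated at subject boundaries, making the test a
subject-level test.  `Ĵ^{-1/2}` uses a symmetric eigendecomposition with an
eigenvalue floor of 1e-10; a floored (rank-deficient) covariance is flagged
as a pseudo-inverse path.

supLM p-values come from a Monte-Carlo sample of the limiting
Brownian-bridge functional `sup_t ‖B(t)‖²/(t(1−t))`: 50,000 replicates of
`k` independent bridges on a 1,000-point grid, simulated once per
`(k, trim)` with a fixed internal seed and cached, giving
`p = (1 + #{null ≥ stat})/(R + 1)`.  The Monte-Carlo error near p = 0.05 is
about ±0.002; determinism does not depend on any user seed.  A
response-surface approximation to the same distribution exists in the
literature, but its fitted coefficient tables are not redistributable here,
and the direct simulation is exact in the limit of replications, trivially
cacheable, and covers any `k` and trimming.

## Tree growing

Per node: fit, test all candidates (constant-in-node candidates are
untestable and skipped), Bonferroni-adjust by the number of testable
candidates, select the smallest adjusted p-value if ≤ α = 0.05 (ties:
larger statistic, then candidate order — fully deterministic).  The
cutpoint then minimizes the summed residual sum of squares of the two
child least-squares fits, searched over midpoints between adjacent distinct
subject-level values (exhaustive binary level partitions for factors with
≤ 10 levels, a greedy scan over levels ordered by mean response beyond).
Separating variable selection (score tests) from cutpoint selection (RSS
scan) avoids the selection bias toward many-cutpoint covariates that
exhaustive-search trees suffer from.  Children must hold at least
`min_subjects_per_node = 10` subjects (counted in subjects, not
observations, because splits act on subjects); `max_depth` optionally
bounds the tree; a node with numerically constant response is terminal.

## The synthetic-data generator

The generator emulates a four-subgroup linear growth-curve study: three
true partitioning variables (`u1` binary, splitting first; `u2` within
`u1 = 0`; `u3` within `u1 = 1`, thresholds at the covariate mean 0) plus
5 or 25 independent noise covariates; all covariates have variance 25 and
`u1` is binarized at its population mean (deterministic, and at μ = 0
practically identical to the sample mean).  An intercorrelation ρ ∈
{0, 0.3} couples the three true variables through a Gaussian copula applied
before binarizing; noise covariates stay independent (chosen
interpretation: the correlated block is "between partitioning variables").
All subjects share timepoints 0–4; random intercept/slope are independent
with variances from the grid; residual variance is 5 (implied intra-class
correlations 0.167 and 0.444 at `σ²_b0` = 1 and 4).  The factorial grid
crosses N ∈ {100, 250}, `σ²_b0` ∈ {1, 4}, `σ²_b1` ∈ {0.1, 0.4}, noise
count ∈ {5, 25}, ρ ∈ {0, 0.3} — 32 cells.

The node coefficients `(β0, β1)` are configuration values; the defaults
(0, 0.75), (1.5, 1.5), (3, 2.25), (4.5, 3) were fixed once by a power
analysis so that the design reproduces the operating characteristics this
class of algorithms exhibits on such designs: equal steps of 1.5 in
intercept and 0.75 in slope between adjacent subgroups make the root
contrast (`u1`: Δβ0 = 3, Δβ1 = 1.5) overwhelmingly detectable at N = 100
(near-certain first-split recovery), the child contrasts borderline at
N = 100 and solid at N = 250 (so calibrated tests land near the true three
splits), and the post-BLUP residual signal near the Bonferroni threshold
when a freely estimated random slope absorbs subgroup differences (so
random-effects initialization with random slopes fails to split in a large
fraction of datasets).  They were not adjusted afterwards.

What the generator does *not* emulate: missing visits and dropout,
subject-specific observation times, non-Gaussian or heteroscedastic errors,
covariate measurement error, and correlated noise covariates.  Passing
recovery tests therefore demonstrates correctness of the algorithms under
the stated design, not robustness to those real-data complications.

## Evaluation harness

`run_study` applies any subset of ten named approaches — LM tree ×
{observation, clustered} covariances; LMM tree (intercepts, or
intercepts+slopes) × {default, clustered covariances, random-effects
initialization, both} — to every generated dataset, with per-dataset
random streams derived from `(master seed, cell, rep)`; rows stream to CSV
and a rerun resumes.  Metrics per tree: number of splits (true size 3;
more = type I, fewer = type II), mean/SD/mean-absolute-deviation of the
split count, and the first-split variable grouped as u1/u2/u3/noise/no
split.  The acceptance script and test suite run reduced replication
counts — 4 per cell, i.e. 128 datasets per study — chosen so each check
completes in well under a minute per approach while binomial Monte-Carlo
bands at n = 128 remain tight enough to discriminate the qualitative
outcomes (rates near 1, near 0.5, and near 0.9 are separated by many
standard errors).

## Known limitations

* Gaussian responses only; no crossed random effects, serial correlation,
  or non-diagonal residual structures.
* The full sandwich covariance (bread × meat × bread) is deliberately not
  implemented; the tests use the meat-only OPG estimator.
* No post-pruning, surrogate splits for missing covariates, or multiway
  splits; no random-effect-based prediction for unseen subjects
  (`predict_fixed` uses fixed effects only).
* Honest (sample-split) standard errors for node coefficients are out of
  scope.
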