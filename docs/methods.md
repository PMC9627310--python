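# Methods

## Problem and model

`bym2map` estimates small-area disease risk from registry-style count data.
For areas i = 1..n with observed counts O_i and indirectly age-standardized
expected counts E_i, the model is a Poisson log-linear model with a
convolution random effect in the BYM2 parameterization:

    O_i ~ Poisson(E_i * exp(mu + b_i))
    b_i = sigma * ( sqrt(1 - phi) * v_i + sqrt(phi) * u*_i )

* `v` — i.i.d. standard-normal unstructured heterogeneity;
* `u*` — intrinsic CAR (ICAR) spatial field over the queen-contiguity graph,
  scaled so the geometric mean of its sum-to-zero-constrained marginal
  variances is 1 within each connected component;
* `phi` in [0, 1] — the mixing parameter, interpretable as the share of the
  latent variance that is spatially structured;
* `sigma` > 0 — the overall marginal standard deviation of the latent field;
* `mu` — intercept. The reported relative risk is RR_i = exp(mu + b_i), so a
  risk is expressed relative to the expected counts; under internal
  standardization (reference rates pooled from the data themselves)
  sum(E) = sum(O) and mu sits near 0.

The scaling step makes `sigma` comparable across graphs: the ICAR precision
Q = D − A is improper (one null direction per connected component), and the
constrained covariance of each non-singleton component equals the
Moore–Penrose pseudo-inverse of its precision submatrix; the scaling factor
kappa_c is the geometric mean of that matrix's diagonal, and the field is
divided by sqrt(kappa_c). Areas with no neighbours (islands) carry no
structured effect — u*_i = 0 — and their latent variance is
sigma^2 (1 − phi).

## Priors

Penalized-complexity (PC) priors, with the tail calibrations used in the
study this package operationalizes:

* `sigma`: exponential with rate lambda = −ln(alpha)/U, so
  P(sigma > U) = alpha exactly. Default (U, alpha) = (0.2/0.31, 0.01); the
  quotient is taken literally, U ≈ 0.6452.
* `phi`: the PC prior built from the distance
  d(phi) = sqrt(2 KLD(phi)) between the latent field at mixing `phi` and the
  unstructured base model (phi = 0). The KLD is evaluated through the
  positive eigenvalues gamma_j of the scaled structured covariance on the
  constrained subspace:
  KLD(phi) = 0.5 * sum_j [ phi (gamma_j − 1) − ln(1 + phi (gamma_j − 1)) ].
  An exponential density on d, truncated to its attainable range, gives the
  prior on phi after a change of variables; its rate is solved numerically
  (Brent) so that P(phi < U) = alpha. Default (U, alpha) = (0.5, 2/3).
  Two properties worth noting:
  - d(phi) is strictly increasing (each KLD term has derivative
    (gamma−1)^2 phi / s ≥ 0), so the tail condition has a closed-form CDF
    given the rate and the solve is one-dimensional and monotone.
  - the rate *increases* with alpha: P(phi < U) = alpha places mass near the
    base model, so more mass below U demands a stronger pull toward phi = 0.
    Alphas below the rate→0 limit d(U)/d(1) admit no positive rate; the
    constructor raises with diagnostics rather than silently extrapolating.
  Islands are excluded from the spectrum: they carry no structured field,
  and treating them as zero eigenvalues makes d'(phi) diverge at phi → 1,
  which produces a heavy tail in logit space that traps gradient-based
  samplers. On a graph with no non-singleton components at all, phi only
  rescales the unstructured term and receives a flat prior.
* `mu`: Normal(0, 5^2) — weakly informative, keeps the sampler stable while
  being effectively flat on the scale of log relative risks.

## Inference

The posterior is sampled with a self-contained No-U-Turn Sampler
(multinomial variant, Stan-style: dual-averaging step-size adaptation to a
target acceptance of 0.9, diagonal mass matrix estimated by Welford
accumulation over the middle half of warmup, divergence flagged at an energy
error of 1000). Defaults: 4 chains, 1000 warmup, 1000 kept draws. Everything
is deterministic given the seed.

The latent field is fully non-centered. The structured component uses a
spectral parameterization: z is standard normal in the positive-eigenvalue
eigenbasis of each component's ICAR precision and
u* = V diag(1/sqrt(kappa * lambda)) z. This reproduces the constrained
scaled ICAR distribution exactly — sum-to-zero and island zeros hold by
construction — and every sampled coordinate has a unit-normal prior, which
keeps the posterior well conditioned for a diagonal mass matrix. A soft
sum-to-zero penalty was evaluated first and rejected: the penalty introduces
a stiff collective mode (penalty sd of order 0.06 against O(1) coordinates)
that a diagonal metric cannot rescale, and measured tree depths saturated at
the maximum.

Eigendecompositions are dense per component; for the few-hundred-area graphs
this package targets (the motivating study has 218 areas) this costs
milliseconds and is done once per model build.

Convergence diagnostics (rank-normalized split R-hat, bulk/tail effective
sample size) come from ArviZ; fits attach warnings when the divergence rate
exceeds 1% or any scalar R-hat exceeds 1.01. Prior-only sampling (the
likelihood switched off) is part of the test suite and reproduces both PC
tail probabilities within Monte Carlo error.

## Reporting

* RR per area: posterior median and equal-tail 95% credible interval
  (linear-interpolation quantiles over all kept draws).
* Exceedance: P(RR_i > threshold), default threshold 1.1 (10% excess risk);
  an area is "elevated" when this probability is >= 0.8. The comparison is
  strict (>) for the threshold and inclusive (>=) for the cutoff.
* Spatial fraction: posterior median of phi with a 95%
  highest-posterior-density interval (shortest interval over sorted draws),
  since the posterior of phi is typically right-skewed.
* Excess cases: sum of (O_i − E_i) over elevated areas, computed at full
  precision and rounded once at the end — rounding E per row first can shift
  the tally by a case.
* Suppression is strictly post-inference: suppressed areas keep their data's
  influence on the fit (their neighbours still borrow strength) and only
  have modelled fields masked in rendered outputs; rows are never dropped.
  Rendered tables round E to integers and ratio fields to 2 decimals; all
  computation is at full precision.

## Predictive checking

CPO (leave-one-out predictive density at the observation) and PIT
(leave-one-out predictive CDF) are estimated from the full posterior by
importance sampling with weights proportional to 1/p(O_i | lambda_i^(s)),
accumulated in log space. For count data the reported PIT is the adjusted
value pit − 0.5 * cpo (half the predictive mass at the observed count),
whose distribution across areas should be near-uniform under a
well-specified model; the package provides a Kolmogorov–Smirnov uniformity
check at level 0.01 alongside the raw values for plotting. An area is
flagged as a failure when the largest normalized importance weight exceeds
0.5 (a single draw dominating the estimate) and can be recomputed exactly by
refitting with that area's likelihood term masked — the graph structure is
retained so the held-out area is still predicted from its neighbours.
Pearson residuals are (O_i − fitted_i)/sqrt(fitted_i) with fitted_i the
posterior mean of E_i RR_i.

## Synthetic registry

The generator draws study frames matching the analysis assumptions exactly,
with ground truth recorded in a sidecar:

* geometry: an nx x ny unit-square lattice plus optional detached island
  squares (queen contiguity, so diagonal cells are neighbours);
* populations: log-uniform per area over (400, 80 000) by default, spanning
  the sparse-to-large range of real community health areas;
* age structure: 19 five-year strata (0–4 … 90+); population weights decay
  geometrically (factor 0.93) and age-specific rates rise geometrically
  (factor 1.25, cancer-like), rescaled so the crude rate is 4 per 1000
  person-years — area expected counts then span roughly 3–300;
* counts: stratum-level Poisson draws with mean PY_{i,a} r_a exp(mu + b_i),
  where b is built from a scaled-ICAR draw (exact eigenbasis sampling) and
  i.i.d. noise at the scenario's (phi, sigma); optional planted hotspots
  multiply an area's risk by a stated factor.

What the generator does *not* emulate: realistic geography (boundary jitter,
wildly varying polygon sizes), geocoding/assignment error, covariate
confounding, temporal trends, or age-by-area interactions (risk acts
proportionally on all strata of an area). Passing recovery and detection
tests therefore demonstrates correctness of the estimation machinery under
the model's own assumptions, not robustness to real-data violations of them.

## Problem sizes used in the test suite

Simulation-based checks are sized to run on a single CPU: parameter-recovery
coverage uses 20 replicates of an 8x8 lattice with E ≈ 30 and 2 chains of
500 kept draws; hotspot detection and predictive calibration use a 10x10
lattice with E ≈ 50; the Moran type-I-error suite uses 500 replicates at
199 permutations. These are the package's own test conditions; the pipeline
defaults (4 chains, 1000/1000 iterations, 999 permutations) are what an
analysis run uses.

## Known limitations

* GeoJSON is the supported boundary format; coordinates are assumed planar
  (no reprojection). Shapefile input is not implemented.
* No covariates/fixed effects; no spatio-temporal terms; no alternative CAR
  families (Leroux, Dean) — the model is exactly the convolution model above.
* The exceedance machinery targets elevated risk; low-incidence flagging
  would be symmetric but is not implemented.
* Exact leave-one-out refits re-run the full sampler per area; they are
  intended for the handful of importance-weight failures, not for all areas.
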