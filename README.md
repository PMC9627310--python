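# bym2map

Small-area disease mapping for registry count data: indirect
age-standardization, spatial-autocorrelation testing, Bayesian spatial
smoothing with the BYM2 model, exceedance-probability flagging of
elevated-risk areas, and posterior predictive checks. Written for
epidemiologists and surveillance analysts who need stable risk estimates
over many small administrative areas where raw rates are dominated by
Poisson noise.

## The model

For areas i with observed counts O_i and age-standardized expected counts
E_i (indirect method: E_i = Σ_a PY_{i,a} r_a with reference rates r_a pooled
over the study region), the package reports the standardized incidence
ratio SIR_i = O_i/E_i and then smooths it through the BYM2 convolution
model:

    O_i ~ Poisson(E_i · exp(μ + b_i)),   b = σ(√(1−φ) v + √φ u*)

where v is i.i.d. Gaussian noise, u* is an intrinsic CAR field over the
queen-contiguity graph scaled to geometric-mean marginal variance 1, φ is
the share of latent variance that is spatially structured and σ the overall
latent standard deviation. Hyperpriors are penalized-complexity priors with
the calibrations P(σ > 0.2/0.31) = 0.01 and P(φ < 0.5) = 2/3. The posterior
is drawn by a built-in No-U-Turn sampler (analytic gradients, non-centered
spectral parameterization of the constrained ICAR field). Per-area results
are the posterior median relative risk RR_i = exp(μ + b_i) with an
equal-tail 95% credible interval and the exceedance probability
P(RR_i > 1.1); areas with exceedance ≥ 80% are flagged as elevated.
Clustering of the SIR surface is tested beforehand with Moran's I and a
Monte Carlo permutation test (999 permutations). Model fit is checked with
leave-one-out CPO/PIT (discrete-response adjustment pit − 0.5·cpo) and
Pearson residuals. See `docs/methods.md` for the full account.

Because real registry extracts are confidential, the package includes a
synthetic registry generator (`bym2map.synthetic`) that reproduces the
statistical frame — lattice plus islands, 19 five-year age strata, area
populations from ~400 to ~80,000 — with recorded ground truth for recovery
tests.

## Worked example

```python
import numpy as np
from bym2map import (
    FitConfig, build_queen_adjacency, fit_bym2, make_spec,
    moran_permutation_test, area_report, excess_cases,
    spatial_fraction_summary,
)
from bym2map.standardize import area_summary
from bym2map.synthetic import SyntheticScenario, simulate_registry

# a 10x10 synthetic registry with a spatially structured risk field
sc = SyntheticScenario(nx=10, ny=10, phi_true=0.5, sigma_true=0.4,
                       pop_range=(11_000, 14_000), seed=42)
areas, data, truth = simulate_registry(sc)
graph = build_queen_adjacency(areas)
sir = area_summary(data).reindex(graph.nodes)

moran = moran_permutation_test(sir["sir"].to_numpy(), graph, n_sim=999, seed=1)
print(f"Moran's I = {moran.statistic:.3f}, pseudo-p = {moran.pseudo_p:.3f}")

spec = make_spec(sir["observed"].to_numpy(), sir["expected"].to_numpy(), graph)
samples = fit_bym2(spec, FitConfig(chains=2, warmup=300, samples=300, seed=7))
report = area_report(graph.nodes, sir, samples)
frac = spatial_fraction_summary(samples)
print(f"spatial fraction: {frac.median:.3f} "
      f"(95% HPD {frac.hpd_low:.3f}-{frac.hpd_high:.3f})")
print(f"elevated areas: {int(report.elevated.sum())}, "
      f"excess cases: {excess_cases(report)}")
```

Output:

```
Moran's I = 0.266, pseudo-p = 0.001
spatial fraction: 0.783 (95% HPD 0.396-1.000)
elevated areas: 19, excess cases: 505
```

The Moran test rejects spatial randomness at the permutation floor
(p = 1/1000); most of the latent variance is attributed to spatial structure
in this realization (the interval is wide — φ is weakly identified at this
size); 19 of 100 areas are flagged as elevated, jointly observing ~505 more
cases than their age structure predicts.

The same pipeline runs from the shell against CSV + GeoJSON inputs:

```
bym2map simulate demo --nx 10 --ny 10 --phi 0.5 --sigma 0.4 --seed 42
bym2map run --config pipeline.yaml --seed 7 --outdir out/
```

writing the per-area report (CSV/GeoJSON), Moran result, spatial-fraction
summary, predictive-check table, convergence diagnostics and a manifest.

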