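"""Posterior predictive checking: CPO, PIT, refits, Pearson residuals.

The conditional predictive ordinate CPO_i is the leave-one-out predictive
density of observation i; the probability integral transform PIT_i is the
leave-one-out predictive CDF at the observation. Both are estimated from the
full posterior by importance sampling with weights proportional to
1 / p(O_i | lambda_i^(s)); areas where the weights are unstable (one weight
dominating) are flagged and should be recomputed by an exact refit that
removes the area's likelihood term. For discrete responses the PIT is
adjusted by half the predictive mass at the observed count,
adjusted_pit = pit - 0.5 * cpo, whose distribution across areas should be
approximately uniform when the model fits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .model import BYM2Spec
from .sampling import FitConfig, PosteriorSamples, fit_bym2

__all__ = [
    "cpo_pit",
    "loo_refit",
    "pearson_residuals",
    "pit_uniformity",
    "check_report",
]

_MAX_WEIGHT_SHARE = 0.5


def _rates(samples: PosteriorSamples, spec: BYM2Spec) -> np.ndarray:
    """(draws, areas) Poisson rates lambda = E * exp(mu + b), chains merged."""
    return spec.expected[None, :] * samples.flat(samples.rr())


def cpo_pit(samples: PosteriorSamples, spec: BYM2Spec) -> pd.DataFrame:
    """Importance-sampling CPO/PIT per area with a weight-stability flag.

    Columns: cpo, pit, adjusted_pit, max_weight, failed. ``failed`` is True
    when the largest normalized importance weight exceeds 0.5 (one draw
    dominating the leave-one-out estimate) or the predictive mass underflows;
    such rows should be recomputed with :func:`loo_refit`.
    """
    lam = _rates(samples, spec)
    n_draws, n = lam.shape
    obs = spec.observed
    logpmf = stats.poisson.logpmf(obs[None, :], lam)        # (draws, areas)
    cdf = stats.poisson.cdf(obs[None, :], lam)
    # log CPO_i = log S - logsumexp_s(-logpmf_si)
    neg = -logpmf
    lse = logsumexp(neg, axis=0)
    cpo = np.exp(np.log(n_draws) - lse)
    # normalized importance weights w ~ 1/pmf
    logw = neg - lse[None, :]
    w = np.exp(logw)
    max_w = w.max(axis=0)
    pit = (w * cdf).sum(axis=0)
    adjusted = pit - 0.5 * cpo
    failed = (max_w > _MAX_WEIGHT_SHARE) | ~np.isfinite(cpo) | (cpo <= 0)
    return pd.DataFrame(
        {
            "cpo": cpo,
            "pit": pit,
            "adjusted_pit": adjusted,
            "max_weight": max_w,
            "failed": failed,
        }
    )


def loo_refit(
    spec: BYM2Spec, area_index: int, config: FitConfig | None = None
) -> dict:
    """Exact leave-one-out CPO/PIT for one area by refitting without it.

    The model is refitted with area i's likelihood term removed (the graph
    and ICAR structure are retained, so the area still borrows strength from
    its neighbours); CPO and PIT come from the refit posterior predictive at
    that area.
    """
    if not (0 <= area_index < spec.n):
        raise IndexError(f"area_index {area_index} out of range")
    mask = np.ones(spec.n)
    mask[area_index] = 0.0
    samples = fit_bym2(spec, config=config, likelihood_mask=mask)
    lam = _rates(samples, spec)[:, area_index]
    o = spec.observed[area_index]
    cpo = float(np.mean(stats.poisson.pmf(o, lam)))
    pit = float(np.mean(stats.poisson.cdf(o, lam)))
    return {
        "area_index": area_index,
        "cpo": cpo,
        "pit": pit,
        "adjusted_pit": pit - 0.5 * cpo,
    }


def pearson_residuals(samples: PosteriorSamples, spec: BYM2Spec) -> pd.DataFrame:
    """Pearson residuals r_i = (O_i - fitted_i) / sqrt(fitted_i).

    ``fitted_i`` is the posterior mean of E_i * exp(mu + b_i).
    """
    fitted = _rates(samples, spec).mean(axis=0)
    if (fitted <= 0).any():
        raise ValueError("non-positive fitted value")
    resid = (spec.observed - fitted) / np.sqrt(fitted)
    return pd.DataFrame({"fitted": fitted, "pearson_residual": resid})


def pit_uniformity(adjusted_pit: np.ndarray) -> dict:
    """Kolmogorov-Smirnov test of the adjusted PIT values against Uniform(0,1)."""
    x = np.asarray(adjusted_pit, dtype=float)
    x = x[np.isfinite(x)]
    res = stats.kstest(x, "uniform")
    return {"statistic": float(res.statistic), "pvalue": float(res.pvalue), "n": len(x)}


def plot_long_format(check: pd.DataFrame, spec: BYM2Spec) -> pd.DataFrame:
    """Long-format export for the standard diagnostic plots.

    Rows carry (plot, area_index, x, y): the adjusted-PIT values for the
    uniformity histogram, and observed-vs-fitted counts for the scatter.
    """
    pit_rows = pd.DataFrame(
        {
            "plot": "pit_histogram",
            "area_index": np.arange(len(check)),
            "x": check["adjusted_pit"].to_numpy(),
            "y": np.nan,
        }
    )
    scatter_rows = pd.DataFrame(
        {
            "plot": "observed_vs_fitted",
            "area_index": np.arange(len(check)),
            "x": check["fitted"].to_numpy(),
            "y": spec.observed,
        }
    )
    return pd.concat([pit_rows, scatter_rows], ignore_index=True)


def check_report(
    samples: PosteriorSamples,
    spec: BYM2Spec,
    refit_failed: bool = False,
    refit_config: FitConfig | None = None,
) -> pd.DataFrame:
    """Full posterior predictive check table per area.

    Combines importance-sampling CPO/PIT, fitted values and Pearson
    residuals; with ``refit_failed=True`` any weight-unstable rows are
    recomputed by exact leave-one-out refits before the table is returned.
    """
    rep = cpo_pit(samples, spec)
    pr = pearson_residuals(samples, spec)
    rep["fitted"] = pr["fitted"]
    rep["pearson_residual"] = pr["pearson_residual"]
    if refit_failed and rep["failed"].any():
        for i in np.flatnonzero(rep["failed"].to_numpy()):
            exact = loo_refit(spec, int(i), refit_config)
            rep.loc[i, ["cpo", "pit", "adjusted_pit"]] = (
                exact["cpo"], exact["pit"], exact["adjusted_pit"],
            )
    return rep
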