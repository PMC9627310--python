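"""Posterior reporting: RR medians and intervals, exceedance flags, excess cases.

Relative risk per area is RR_i = exp(mu + b_i), summarized by the posterior
median and an equal-tail 95% credible interval. An area is flagged as
elevated when the posterior probability that RR exceeds the risk threshold
(default 1.1, i.e. 10% excess risk) is at least the probability cutoff
(default 80%). The spatially structured fraction phi is summarized by its
median and a 95% highest-posterior-density interval, since its posterior is
typically right-skewed. Suppression is strictly post-inference: suppressed
areas keep their influence on the fit and only have modelled fields masked
in outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import AreaPolygonSet
from .sampling import PosteriorSamples

__all__ = [
    "SpatialFractionSummary",
    "rr_summary",
    "exceedance_probs",
    "spatial_fraction_summary",
    "hpd_interval",
    "area_report",
    "excess_cases",
    "apply_suppression",
    "report_to_geojson",
    "render_report",
]

_MASKED_COLS = ["rr_median", "rr_ci_low", "rr_ci_high", "exceedance_prob", "elevated"]


@dataclass(frozen=True)
class SpatialFractionSummary:
    """Posterior median and 95% HPD interval of the mixing parameter phi."""

    median: float
    hpd_low: float
    hpd_high: float

    def to_dict(self) -> dict:
        return {"median": self.median, "hpd_low": self.hpd_low, "hpd_high": self.hpd_high}


def _require_draws(n: int, minimum: int = 400) -> None:
    if n < minimum:
        raise ValueError(f"need at least {minimum} posterior draws, got {n}")


def rr_summary(samples: PosteriorSamples) -> pd.DataFrame:
    """Per-area posterior median and equal-tail 95% interval of RR."""
    rr = samples.flat(samples.rr())
    _require_draws(rr.shape[0])
    med = np.median(rr, axis=0)
    lo, hi = np.percentile(rr, [2.5, 97.5], axis=0)
    return pd.DataFrame({"rr_median": med, "rr_ci_low": lo, "rr_ci_high": hi})


def exceedance_probs(
    samples: PosteriorSamples, threshold: float = 1.1, prob_cutoff: float = 0.8
) -> pd.DataFrame:
    """P(RR_i > threshold) per area and the elevated flag (prob >= cutoff)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    rr = samples.flat(samples.rr())
    prob = (rr > threshold).mean(axis=0)
    return pd.DataFrame({"exceedance_prob": prob, "elevated": prob >= prob_cutoff})


def hpd_interval(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the draws (over sorted draws)."""
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = len(x)
    k = max(int(np.ceil(mass * n)), 1)
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


def spatial_fraction_summary(samples: PosteriorSamples) -> SpatialFractionSummary:
    """Median and 95% HPD of phi, the spatially structured variance share."""
    phi = samples.flat(samples.phi)
    _require_draws(len(phi))
    lo, hi = hpd_interval(phi, 0.95)
    return SpatialFractionSummary(median=float(np.median(phi)), hpd_low=lo, hpd_high=hi)


def area_report(
    area_ids: list[str],
    sir_table: pd.DataFrame,
    samples: PosteriorSamples,
    threshold: float = 1.1,
    prob_cutoff: float = 0.8,
) -> pd.DataFrame:
    """Assemble the per-area report: O, E, SIR, RR summaries, exceedance, flags.

    ``sir_table`` is the output of the standardization step indexed by
    area_id; ``samples`` must cover the same areas in the same order.
    """
    if samples.n_areas != len(area_ids):
        raise ValueError("posterior and area list disagree in length")
    rep = sir_table.reindex(area_ids).copy()
    rr = rr_summary(samples)
    exc = exceedance_probs(samples, threshold, prob_cutoff)
    for col in rr.columns:
        rep[col] = rr[col].to_numpy()
    for col in exc.columns:
        rep[col] = exc[col].to_numpy()
    rep["suppressed"] = False
    return rep


def excess_cases(report: pd.DataFrame) -> int:
    """Total excess cases over elevated areas: round(sum over flagged of O - E).

    Computed at full precision and rounded once at the end.
    """
    sel = report["elevated"].fillna(False).astype(bool)
    diff = (report.loc[sel, "observed"] - report.loc[sel, "expected"]).sum()
    return int(np.rint(diff))


def apply_suppression(
    report: pd.DataFrame, suppression_list: list[str]
) -> pd.DataFrame:
    """Mask modelled fields for listed areas; rows are kept, never dropped.

    Unknown ids trigger a warning and are ignored. Observed/expected columns
    are retained (the disclosure policy applies to modelled risks).
    """
    rep = report.copy()
    unknown = [a for a in suppression_list if a not in rep.index]
    if unknown:
        warnings.warn(f"suppression ids not in report: {unknown}", stacklevel=2)
    hit = [a for a in suppression_list if a in rep.index]
    if hit:
        rep["elevated"] = rep["elevated"].astype(object)
        rep.loc[hit, _MASKED_COLS] = np.nan
        rep.loc[hit, "suppressed"] = True
    return rep


def report_to_geojson(
    report: pd.DataFrame, areas: AreaPolygonSet, path: str | Path
) -> None:
    """Write the report as a GeoJSON FeatureCollection for choropleth use."""
    from shapely.geometry import mapping

    idx = {a: i for i, a in enumerate(areas.area_ids)}
    feats = []
    for aid, row in report.iterrows():
        props = {"area_id": aid}
        for k, val in row.items():
            if isinstance(val, (np.floating, float)):
                props[k] = None if np.isnan(val) else float(val)
            elif isinstance(val, (np.bool_, bool)):
                props[k] = bool(val)
            elif val is np.nan or (isinstance(val, float) and np.isnan(val)):
                props[k] = None
            else:
                props[k] = val
        feats.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": mapping(areas.geometries[idx[str(aid)]]),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def render_report(report: pd.DataFrame) -> pd.DataFrame:
    """Presentation copy: E rounded to integers, SIR/RR fields to 2 decimals."""
    out = report.copy()
    out["expected"] = out["expected"].round().astype("Int64")
    for col in ["sir", "rr_median", "rr_ci_low", "rr_ci_high", "exceedance_prob"]:
        if col in out:
            out[col] = out[col].astype(float).round(2)
    return out
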