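"""Configuration-driven pipeline: standardize -> adjacency -> Moran -> fit ->
summaries -> checks -> suppression, with a reproducibility manifest.

All stages consume and produce the package's standard artifacts; a YAML
config collects the study settings (risk threshold 1.1, probability cutoff
0.8, 999 Moran permutations, the PC prior calibrations) as defaults. Stage
failures abort with the stage name and partial outputs are removed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import checks as _checks
from . import standardize as _std
from . import summaries as _sum
from .geometry import build_queen_adjacency, read_area_polygons
from .model import HyperPriors, make_spec
from .moran import moran_permutation_test
from .sampling import FitConfig, convergence_diagnostics, fit_bym2

logger = logging.getLogger("bym2map")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    counts_csv: str
    boundaries: str
    outdir: str
    suppression_list: list[str] = field(default_factory=list)
    id_field: str = "area_id"
    snap_tolerance: float = 0.0
    moran_n_sim: int = 999
    moran_weight_style: str = "row-standardized"
    threshold: float = 1.1
    prob_cutoff: float = 0.8
    hyperpriors: HyperPriors = field(default_factory=HyperPriors)
    fit: FitConfig = field(default_factory=FitConfig)
    seed: int = 0
    refit_failed_cpo: bool = False

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if not (0 < self.prob_cutoff < 1):
            raise ValueError("prob_cutoff must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        hp = raw.pop("hyperpriors", None)
        fit = raw.pop("fit", None)
        cfg = cls(**raw)
        if hp:
            cfg.hyperpriors = HyperPriors(**hp)
        if fit:
            cfg.fit = FitConfig(**fit)
        if "seed" in overrides or "seed" in raw:
            cfg.fit = FitConfig(**{**asdict(cfg.fit), "seed": cfg.seed})
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(name, str(exc)) from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run all stages and write the output bundle; returns artifact paths.

    Artifacts: area_report.csv, area_report.geojson, moran.json,
    spatial_fraction.json, check_report.csv, diagnostics.csv, manifest.json.
    On any stage failure, partial outputs are removed and a
    :class:`PipelineError` naming the stage is raised.
    """
    for p, what in [(config.counts_csv, "counts CSV"), (config.boundaries, "boundary file")]:
        if not Path(p).exists():
            raise PipelineError("config", f"{what} not found: {p}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "area_report": outdir / "area_report.csv",
        "area_report_geojson": outdir / "area_report.geojson",
        "moran": outdir / "moran.json",
        "spatial_fraction": outdir / "spatial_fraction.json",
        "check_report": outdir / "check_report.csv",
        "diagnostics": outdir / "diagnostics.csv",
        "manifest": outdir / "manifest.json",
    }
    try:
        areas = _stage("read_boundaries")(read_area_polygons)(
            config.boundaries, config.id_field
        )
        graph = _stage("adjacency")(build_queen_adjacency)(
            areas, config.snap_tolerance
        )
        data = _stage("read_counts")(pd.read_csv)(config.counts_csv)
        sir = _stage("standardize")(_std.area_summary)(data)
        sir = sir.reindex(graph.nodes)
        if sir["observed"].isna().any():
            missing = sir.index[sir["observed"].isna()].tolist()
            raise PipelineError(
                "standardize", f"areas missing from counts: {missing[:5]}"
            )

        moran = _stage("moran")(moran_permutation_test)(
            sir["sir"].to_numpy(),
            graph,
            n_sim=config.moran_n_sim,
            seed=config.seed,
            weight_style=config.moran_weight_style,
        )

        usable = sir["expected"].to_numpy() > 0
        if not usable.all():
            raise PipelineError(
                "fit",
                "areas with zero expected counts are not supported by the "
                f"model stage: {list(sir.index[~usable])[:5]}",
            )
        spec = _stage("fit")(make_spec)(
            sir["observed"].to_numpy(),
            sir["expected"].to_numpy(),
            graph,
            hyperpriors=config.hyperpriors,
        )
        samples = _stage("fit")(fit_bym2)(spec, config.fit)
        for w in samples.warnings:
            logger.warning("sampler: %s", w)

        report = _stage("summarize")(_sum.area_report)(
            graph.nodes, sir, samples, config.threshold, config.prob_cutoff
        )
        frac = _sum.spatial_fraction_summary(samples)
        diag = _stage("diagnostics")(convergence_diagnostics)(samples)
        check = _stage("check")(_checks.check_report)(
            samples, spec, refit_failed=config.refit_failed_cpo
        )
        report = _stage("suppress")(_sum.apply_suppression)(
            report, config.suppression_list
        )

        report.to_csv(paths["area_report"])
        _sum.report_to_geojson(report, areas, paths["area_report_geojson"])
        with open(paths["moran"], "w") as fh:
            json.dump(moran.to_dict(), fh, indent=1)
        with open(paths["spatial_fraction"], "w") as fh:
            json.dump(frac.to_dict(), fh, indent=1)
        check.insert(0, "area_id", graph.nodes)
        check.to_csv(paths["check_report"], index=False)
        diag.to_csv(paths["diagnostics"])
        manifest = {
            "config": config.to_dict(),
            "config_digest": config.digest(),
            "seed": config.seed,
            "fit_seed": config.fit.seed,
            "n_areas": graph.n,
            "n_elevated": int(report["elevated"].fillna(False).astype(bool).sum()),
            "excess_cases": _sum.excess_cases(report),
            "sampler_warnings": samples.warnings,
            "divergence_rate": samples.divergence_rate(),
        }
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
    except PipelineError:
        for p in paths.values():
            p.unlink(missing_ok=True)
        raise
    return paths
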