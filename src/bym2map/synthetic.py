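"""Synthetic registry generator with recorded ground truth.

Emulates the statistical frame of a provincial small-area cancer registry:
a contiguous lattice of unit-square areas plus a few detached islands,
19 five-year age strata, area populations spanning roughly 400-80,000
persons, and Poisson stratum counts driven by a latent log-risk field

    b_i = sigma * (sqrt(1-phi) * v_i + sqrt(phi) * u*_i)

mixing a scaled ICAR field u* with i.i.d. noise v. The default age profile
is a geometrically decaying population pyramid with incidence rates rising
steeply with age (cancer-like), scaled to a configurable crude rate so that
per-area expected counts span roughly 3-300. Ground truth (mu, phi, sigma,
b, u*, v) is recorded alongside the data so recovery tests never re-derive
it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping

from .geometry import AdjacencyGraph, AreaPolygonSet, build_queen_adjacency
from .model import _EIG_TOL, scaled_structure
from .standardize import default_age_groups

__all__ = [
    "SyntheticScenario",
    "make_lattice",
    "sample_scaled_icar",
    "simulate_registry",
    "write_scenario_files",
]


def _default_age_weights() -> np.ndarray:
    w = 0.93 ** np.arange(19)
    return w / w.sum()


def _default_age_rate_shape() -> np.ndarray:
    # incidence rising ~exponentially with age, as for most adult cancers
    return 1.25 ** np.arange(19)


@dataclass
class SyntheticScenario:
    """Study conditions for one synthetic registry draw."""

    nx: int = 10
    ny: int = 10
    n_islands: int = 0
    mu_true: float = 0.0
    phi_true: float = 0.5
    sigma_true: float = 0.5
    pop_range: tuple[float, float] = (400.0, 80_000.0)
    crude_rate: float = 4e-3          # overall cases per person-year equivalent
    age_weights: np.ndarray = dc_field(default_factory=_default_age_weights)
    age_rate_shape: np.ndarray = dc_field(default_factory=_default_age_rate_shape)
    hotspot: dict[str, float] | None = None   # area_id -> planted RR multiplier
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nx * self.ny < 4:
            raise ValueError("lattice must have at least 4 cells")
        if not (0.0 <= self.phi_true <= 1.0):
            raise ValueError("phi_true must lie in [0, 1]")
        if self.sigma_true < 0:
            raise ValueError("sigma_true must be >= 0")
        self.age_weights = np.asarray(self.age_weights, dtype=float)
        self.age_rate_shape = np.asarray(self.age_rate_shape, dtype=float)
        if len(self.age_weights) != len(self.age_rate_shape):
            raise ValueError("age profile length mismatch")

    @property
    def n_areas(self) -> int:
        return self.nx * self.ny + self.n_islands

    def age_groups(self) -> list[str]:
        if len(self.age_weights) == 19:
            return default_age_groups()
        return [f"stratum_{k}" for k in range(len(self.age_weights))]

    def baseline_rates(self) -> np.ndarray:
        """Age-specific rates r_a scaled so the crude rate matches ``crude_rate``."""
        shape = self.age_rate_shape
        crude_unscaled = float(self.age_weights @ shape)
        return shape * (self.crude_rate / crude_unscaled)


def make_lattice(
    nx: int, ny: int, n_islands: int = 0, seed: int = 0
) -> AreaPolygonSet:
    """Unit-square grid of nx*ny cells plus detached island squares.

    Cell (i, j) has id "Gi-j"; islands ("I0", "I1", ...) are placed on a row
    well outside the grid envelope with unit gaps so they touch nothing.
    Deterministic given the seed (which only perturbs island placement order).
    """
    ids, geoms = [], []
    for j in range(ny):
        for i in range(nx):
            ids.append(f"G{i}-{j}")
            geoms.append(box(i, j, i + 1, j + 1))
    rng = np.random.default_rng(seed)
    offsets = rng.permutation(max(n_islands, 1))[:n_islands]
    for k, off in enumerate(offsets):
        x0 = 2 * int(off) + nx + 3
        ids.append(f"I{k}")
        geoms.append(box(x0, ny + 3, x0 + 1, ny + 4))
    return AreaPolygonSet(ids, geoms)


def sample_scaled_icar(
    graph: AdjacencyGraph, seed: int = 0, size: int = 1
) -> np.ndarray:
    """Draws from the sum-to-zero-constrained scaled ICAR field.

    Sampling is by eigen-decomposition per non-singleton component: the field
    is a Gaussian with precision kappa_c * Q_c restricted to the orthogonal
    complement of the constant vector. Islands get exactly 0. Returns an
    array of shape (size, n) (or (n,) when size == 1).
    """
    st = scaled_structure(graph)
    if not st.components:
        raise ValueError("graph has no non-singleton component")
    rng = np.random.default_rng(seed)
    out = np.zeros((size, graph.n))
    for idx, lam, vec, kap in zip(st.components, st.eigvals, st.eigvecs, st.kappa):
        pos = lam > _EIG_TOL * max(1.0, lam[-1])
        sd = 1.0 / np.sqrt(kap * lam[pos])
        z = rng.standard_normal((size, int(pos.sum())))
        out[:, idx] = (z * sd) @ vec[:, pos].T
    return out[0] if size == 1 else out


def simulate_registry(
    scenario: SyntheticScenario,
) -> tuple[AreaPolygonSet, pd.DataFrame, dict]:
    """Generate geometry, a stratified count table, and the ground truth.

    Populations are drawn log-uniformly over ``pop_range`` and spread over
    the age strata by the age profile; stratum counts are Poisson with mean
    PY_{i,a} * r_a * exp(mu + b_i). Returns (areas, stratified data, truth).
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    areas = make_lattice(sc.nx, sc.ny, sc.n_islands, seed=sc.seed)
    graph = build_queen_adjacency(areas)
    n = graph.n

    if sc.sigma_true > 0 and sc.phi_true > 0:
        u_star = sample_scaled_icar(graph, seed=int(rng.integers(2**31)))
    else:
        u_star = np.zeros(n)
    v = rng.standard_normal(n)
    b = sc.sigma_true * (
        np.sqrt(1.0 - sc.phi_true) * v + np.sqrt(sc.phi_true) * u_star
    )

    lo, hi = sc.pop_range
    pops = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    rates = sc.baseline_rates()
    groups = sc.age_groups()

    rows = []
    rel_risk = np.exp(sc.mu_true + b)
    if sc.hotspot:
        unknown = set(sc.hotspot) - set(graph.nodes)
        if unknown:
            raise ValueError(f"hotspot ids not on the lattice: {sorted(unknown)}")
        for aid, mult in sc.hotspot.items():
            rel_risk[graph.nodes.index(aid)] *= mult
    for i, aid in enumerate(graph.nodes):
        py = pops[i] * sc.age_weights
        lam = py * rates * rel_risk[i]
        cases = rng.poisson(lam)
        for a, g in enumerate(groups):
            rows.append((aid, g, int(cases[a]), float(py[a])))
    data = pd.DataFrame(rows, columns=["area_id", "age_group", "cases", "person_years"])
    truth = {
        "mu": sc.mu_true,
        "phi": sc.phi_true,
        "sigma": sc.sigma_true,
        "b": b.tolist(),
        "u_star": u_star.tolist(),
        "v": v.tolist(),
        "area_ids": list(graph.nodes),
        "populations": pops.tolist(),
        "hotspot": sc.hotspot or {},
        "seed": sc.seed,
    }
    return areas, data, truth


def write_scenario_files(
    scenario: SyntheticScenario, outdir: str | Path
) -> dict[str, Path]:
    """Emit the CSV + GeoJSON + truth-sidecar files the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    areas, data, truth = simulate_registry(scenario)
    paths = {
        "counts": outdir / "counts.csv",
        "boundaries": outdir / "areas.geojson",
        "truth": outdir / "truth.json",
    }
    data.to_csv(paths["counts"], index=False)
    feats = [
        {
            "type": "Feature",
            "properties": {"area_id": aid},
            "geometry": mapping(geom),
        }
        for aid, geom in zip(areas.area_ids, areas.geometries)
    ]
    with open(paths["boundaries"], "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh)
    return paths
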