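"""Area polygons and queen-contiguity adjacency.

Reads area boundaries from GeoJSON (coordinates are assumed to be planar /
projected; no reprojection is attempted) and builds the queen-contiguity
neighbour structure used as the spatial weights graph: two areas are
neighbours when their boundaries intersect in at least one point — a shared
edge or a single shared vertex both count. Areas with no neighbours are
flagged as islands and each forms its own connected component.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc
from shapely.geometry import MultiPolygon, Polygon, shape

__all__ = [
    "AreaPolygonSet",
    "AdjacencyGraph",
    "read_area_polygons",
    "build_queen_adjacency",
    "connected_components",
]


@dataclass
class AreaPolygonSet:
    """Ordered collection of area polygons with unique string identifiers."""

    area_ids: list[str]
    geometries: list[Polygon | MultiPolygon]
    display_names: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.area_ids) != len(self.geometries):
            raise ValueError("area_ids and geometries differ in length")
        if len(self.area_ids) == 0:
            raise ValueError("empty area set")
        dupes = _duplicates(self.area_ids)
        if dupes:
            raise ValueError(f"duplicate area ids: {sorted(dupes)}")
        for aid, geom in zip(self.area_ids, self.geometries):
            if geom is None or geom.is_empty:
                raise ValueError(f"empty geometry for area {aid!r}")
            if not isinstance(geom, (Polygon, MultiPolygon)):
                raise TypeError(
                    f"area {aid!r}: expected Polygon/MultiPolygon, got {geom.geom_type}"
                )

    def __len__(self) -> int:
        return len(self.area_ids)


@dataclass
class AdjacencyGraph:
    """Symmetric queen-contiguity graph over an ordered node list.

    ``neighbor_lists[i]`` holds the sorted indices adjacent to node ``i``;
    islands have an empty list. ``component_id`` labels connected components
    (each island is a singleton component).
    """

    nodes: list[str]
    neighbor_lists: list[list[int]]
    is_island: np.ndarray = field(default=None)  # type: ignore[assignment]
    component_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if len(self.neighbor_lists) != n:
            raise ValueError("neighbor_lists length mismatch")
        for i, nbrs in enumerate(self.neighbor_lists):
            if i in nbrs:
                raise ValueError(f"self-loop at node {self.nodes[i]!r}")
            for j in nbrs:
                if i not in self.neighbor_lists[j]:
                    raise ValueError(
                        f"asymmetric adjacency: {self.nodes[i]!r} -> {self.nodes[j]!r}"
                    )
        if self.is_island is None:
            self.is_island = np.array([len(nb) == 0 for nb in self.neighbor_lists])
        if self.component_id is None:
            self.component_id = connected_components(self)

    @property
    def n(self) -> int:
        return len(self.nodes)

    def degree(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbor_lists])

    def edge_index(self) -> tuple[np.ndarray, np.ndarray]:
        """Directed edge arrays (i, j) with every undirected edge listed twice."""
        ii = [i for i, nb in enumerate(self.neighbor_lists) for _ in nb]
        jj = [j for nb in self.neighbor_lists for j in nb]
        return np.asarray(ii, dtype=int), np.asarray(jj, dtype=int)

    def adjacency_matrix(self) -> coo_matrix:
        ii, jj = self.edge_index()
        return coo_matrix(
            (np.ones(len(ii)), (ii, jj)), shape=(self.n, self.n)
        )

    def to_edge_csv(self, path: str | Path) -> None:
        """Write the undirected edge list (id_i, id_j), each pair once."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id_i", "id_j"])
            for i, nbrs in enumerate(self.neighbor_lists):
                for j in nbrs:
                    if i < j:
                        w.writerow([self.nodes[i], self.nodes[j]])

    def to_node_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["area_id", "degree", "is_island", "component"])
            deg = self.degree()
            for i, aid in enumerate(self.nodes):
                w.writerow([aid, deg[i], bool(self.is_island[i]), int(self.component_id[i])])


def _duplicates(ids: list[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in ids:
        (dup if x in seen else seen).add(x)
    return dup


def read_area_polygons(path: str | Path, id_field: str = "area_id") -> AreaPolygonSet:
    """Read area polygons from a GeoJSON FeatureCollection.

    Geometries are validated and repaired with ``shapely.make_valid`` where
    needed; ids are coerced to strings. Duplicate ids, a missing ``id_field``,
    empty geometries, or zero features raise ``ValueError``.
    """
    path = Path(path)
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj.get("features", [])
    if not feats:
        raise ValueError(f"{path}: no features")
    ids: list[str] = []
    geoms: list[Polygon | MultiPolygon] = []
    names: list[str] = []
    for k, feat in enumerate(feats):
        props = feat.get("properties") or {}
        if id_field not in props:
            raise ValueError(f"{path}: feature {k} lacks id field {id_field!r}")
        aid = str(props[id_field])
        raw = feat.get("geometry")
        if raw is None:
            raise ValueError(f"{path}: feature {aid!r} has null geometry")
        geom = shape(raw)
        if geom.is_empty:
            raise ValueError(f"{path}: feature {aid!r} has empty geometry")
        if not geom.is_valid:
            geom = shapely.make_valid(geom)
        ids.append(aid)
        geoms.append(geom)
        names.append(str(props.get("name", aid)))
    dupes = _duplicates(ids)
    if dupes:
        raise ValueError(f"{path}: duplicate area ids: {sorted(dupes)}")
    return AreaPolygonSet(ids, geoms, names)


def build_queen_adjacency(
    areas: AreaPolygonSet, snap_tolerance: float = 0.0
) -> AdjacencyGraph:
    """Queen-contiguity adjacency: boundaries sharing an edge *or* a vertex.

    Two areas are adjacent when their geometries intersect in at least one
    point. With ``snap_tolerance > 0`` the test becomes ``distance <= tol``,
    tolerating vertex jitter in real boundary files. Multipolygon areas are
    adjacent when any of their parts touch.
    """
    if snap_tolerance < 0:
        raise ValueError("snap_tolerance must be >= 0")
    geoms = np.array(areas.geometries, dtype=object)
    tree = shapely.STRtree(geoms)
    if snap_tolerance > 0:
        pairs = tree.query(geoms, predicate="dwithin", distance=snap_tolerance)
    else:
        pairs = tree.query(geoms, predicate="intersects")
    n = len(areas)
    nbrs: list[set[int]] = [set() for _ in range(n)]
    for i, j in zip(*pairs):
        if i != j:
            nbrs[int(i)].add(int(j))
            nbrs[int(j)].add(int(i))
    return AdjacencyGraph(
        nodes=list(areas.area_ids),
        neighbor_lists=[sorted(s) for s in nbrs],
    )


def connected_components(graph: AdjacencyGraph) -> np.ndarray:
    """Connected-component labels per node; islands are singleton components."""
    adj = graph.adjacency_matrix()
    _, labels = _cc(adj.tocsr(), directed=False)
    return labels
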