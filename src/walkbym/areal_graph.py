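"""Areal contiguity structures for conditional autoregressive (CAR) models.

The neighbourhood system of an intrinsic CAR prior is a symmetric, irreflexive
adjacency over areal units (here, postal areas).  This module builds that
structure from regular lattices (test fixtures), GAL neighbour-list files, or
polygon boundaries; validates it; and applies the pre-fit exclusion filter
(areas with no respondents or no neighbours cannot enter the spatial model:
the ICAR conditional mean is undefined for k = 0).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np
from shapely.geometry import shape as _shapely_shape

logger = logging.getLogger(__name__)

__all__ = [
    "AdjacencyGraph",
    "GraphFormatError",
    "build_grid_lattice",
    "read_gal",
    "write_gal",
    "polygons_to_adjacency",
    "connected_components",
    "exclusion_filter",
]


class GraphFormatError(ValueError):
    """Malformed GAL/GeoJSON input (bad header, unknown id, asymmetry ...)."""


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric binary contiguity over an ordered set of areas.

    Attributes
    ----------
    area_ids : tuple of str
        Opaque area labels in a fixed order; all indices refer to this order.
    neighbors : tuple of frozenset of int
        ``neighbors[i]`` is the set of indices contiguous with area ``i``.
    """

    area_ids: tuple[str, ...]
    neighbors: tuple[frozenset[int], ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.area_ids) != len(self.neighbors):
            raise ValueError("area_ids and neighbors must have equal length")
        if len(set(self.area_ids)) != len(self.area_ids):
            raise ValueError("duplicate area ids")
        n = len(self.area_ids)
        for i, nb in enumerate(self.neighbors):
            if i in nb:
                raise ValueError(f"area {self.area_ids[i]!r} is its own neighbor")
            for j in nb:
                if not 0 <= j < n:
                    raise ValueError(f"neighbor index {j} out of range")
                if i not in self.neighbors[j]:
                    raise ValueError(
                        f"asymmetric adjacency: {self.area_ids[i]!r} lists "
                        f"{self.area_ids[j]!r} but not vice versa"
                    )
        object.__setattr__(self, "_index", {a: i for i, a in enumerate(self.area_ids)})

    # -- basic queries ----------------------------------------------------

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def k(self) -> np.ndarray:
        """Neighbour count per area (the k of the ICAR conditional variance)."""
        return np.array([len(nb) for nb in self.neighbors], dtype=int)

    def index_of(self, area_id: str) -> int:
        return self._index[area_id]

    def edges(self) -> Iterator[tuple[int, int]]:
        """Undirected edges as (i, j) with i < j, each listed once."""
        for i, nb in enumerate(self.neighbors):
            for j in nb:
                if i < j:
                    yield (i, j)

    @property
    def n_edges(self) -> int:
        return sum(len(nb) for nb in self.neighbors) // 2

    def edge_array(self) -> np.ndarray:
        """(m, 2) int array of undirected edges, i < j. Empty graphs give (0, 2)."""
        e = list(self.edges())
        return np.array(e, dtype=int).reshape(len(e), 2)

    def laplacian(self) -> np.ndarray:
        """Dense graph Laplacian L = diag(k) - A (the ICAR precision scaffold)."""
        n = self.n_areas
        L = np.zeros((n, n))
        for i, j in self.edges():
            L[i, j] = L[j, i] = -1.0
        np.fill_diagonal(L, self.k.astype(float))
        return L

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_areas))
        g.add_edges_from(self.edges())
        return g

    def subgraph(self, keep: Sequence[str]) -> "AdjacencyGraph":
        """Induced subgraph on ``keep`` (order of ``keep`` is preserved)."""
        keep_idx = [self.index_of(a) for a in keep]
        remap = {old: new for new, old in enumerate(keep_idx)}
        nbrs = tuple(
            frozenset(remap[j] for j in self.neighbors[old] if j in remap)
            for old in keep_idx
        )
        return AdjacencyGraph(tuple(keep), nbrs)


def _from_edge_list(area_ids: Sequence[str], edges: Iterable[tuple[int, int]]) -> AdjacencyGraph:
    nbrs: list[set[int]] = [set() for _ in area_ids]
    for i, j in edges:
        if i == j:
            continue
        nbrs[i].add(j)
        nbrs[j].add(i)
    return AdjacencyGraph(tuple(area_ids), tuple(frozenset(s) for s in nbrs))


# -- constructors ---------------------------------------------------------


def build_grid_lattice(rows: int, cols: int, rule: str = "rook") -> AdjacencyGraph:
    """Regular ``rows x cols`` lattice with rook (edge) or queen (edge-or-corner)
    contiguity.  Area ids are ``"r{r}c{c}"`` in row-major order."""
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be positive")
    if rows * cols < 2:
        raise ValueError("lattice must contain at least 2 areas")
    if rule not in ("rook", "queen"):
        raise ValueError(f"unknown contiguity rule {rule!r}")
    ids = [f"r{r}c{c}" for r in range(rows) for c in range(cols)]
    steps = [(0, 1), (1, 0)]
    if rule == "queen":
        steps += [(1, 1), (1, -1)]
    edges = []
    for r in range(rows):
        for c in range(cols):
            for dr, dc in steps:
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    edges.append((r * cols + c, rr * cols + cc))
    return _from_edge_list(ids, edges)


# -- GAL dialect ----------------------------------------------------------
#
# header line: the area count; then per area a "id k" line followed by a line
# of k whitespace-separated neighbour ids (empty line when k = 0).


def read_gal(path) -> AdjacencyGraph:
    """Read a GAL neighbour-list file.  Asymmetric lists are an error, not
    silently symmetrised."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = fh.read().splitlines()
    if not raw or not raw[0].split():
        raise GraphFormatError(f"{path}: missing GAL header line")
    header = raw[0].split()
    try:
        n = int(header[-1] if len(header) > 1 else header[0])
    except ValueError:
        raise GraphFormatError(f"{path}: malformed header {raw[0]!r}") from None
    if n < 0:
        raise GraphFormatError(f"{path}: negative area count in header")

    ids: list[str] = []
    neighbor_names: list[list[str]] = []
    lineno = 1
    for _ in range(n):
        if lineno >= len(raw):
            raise GraphFormatError(f"{path}: truncated file, expected {n} records")
        head = raw[lineno].split()
        if len(head) != 2:
            raise GraphFormatError(
                f"{path}:{lineno + 1}: expected 'id k' record, got {raw[lineno]!r}"
            )
        aid, k_str = head
        try:
            k = int(k_str)
        except ValueError:
            raise GraphFormatError(
                f"{path}:{lineno + 1}: neighbor count {k_str!r} is not an integer"
            ) from None
        if k < 0:
            raise GraphFormatError(f"{path}:{lineno + 1}: negative neighbor count")
        lineno += 1
        if lineno >= len(raw):
            raise GraphFormatError(f"{path}: truncated file after record for {aid!r}")
        nbrs = raw[lineno].split()
        if len(nbrs) != k:
            raise GraphFormatError(
                f"{path}:{lineno + 1}: area {aid!r} declares k={k} but lists "
                f"{len(nbrs)} neighbors"
            )
        ids.append(aid)
        neighbor_names.append(nbrs)
        lineno += 1

    if len(set(ids)) != len(ids):
        raise GraphFormatError(f"{path}: duplicate area ids")
    index = {a: i for i, a in enumerate(ids)}
    nbr_sets: list[frozenset[int]] = []
    for i, names in enumerate(neighbor_names):
        s = set()
        for name in names:
            if name not in index:
                raise GraphFormatError(
                    f"{path}: area {ids[i]!r} lists unknown neighbor id {name!r}"
                )
            if index[name] == i:
                raise GraphFormatError(f"{path}: area {ids[i]!r} lists itself")
            s.add(index[name])
        nbr_sets.append(frozenset(s))
    for i, s in enumerate(nbr_sets):
        for j in s:
            if i not in nbr_sets[j]:
                raise GraphFormatError(
                    f"{path}: asymmetric adjacency: {ids[i]!r} lists {ids[j]!r} "
                    f"but not vice versa"
                )
    return AdjacencyGraph(tuple(ids), tuple(nbr_sets))


def write_gal(graph: AdjacencyGraph, path) -> None:
    """Write a GAL neighbour-list file (each edge appears in both records)."""
    lines = [str(graph.n_areas)]
    for i, aid in enumerate(graph.area_ids):
        nb = sorted(graph.neighbors[i])
        lines.append(f"{aid} {len(nb)}")
        lines.append(" ".join(graph.area_ids[j] for j in nb))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


# -- polygon contiguity ---------------------------------------------------


def polygons_to_adjacency(feature_collection: Mapping, rule: str = "queen") -> AdjacencyGraph:
    """Derive contiguity from a GeoJSON FeatureCollection.

    Queen contiguity joins polygons sharing any boundary point; rook requires a
    shared boundary segment of positive length.  Each feature must carry a
    unique ``id`` property (or top-level ``id``).
    """
    if rule not in ("rook", "queen"):
        raise ValueError(f"unknown contiguity rule {rule!r}")
    feats = feature_collection.get("features")
    if feats is None:
        raise GraphFormatError("not a FeatureCollection: no 'features' member")
    ids: list[str] = []
    geoms = []
    for pos, feat in enumerate(feats):
        props = feat.get("properties") or {}
        fid = props.get("id", feat.get("id"))
        if fid is None:
            raise GraphFormatError(f"feature {pos} has no 'id' property")
        fid = str(fid)
        if fid in ids:
            raise GraphFormatError(f"duplicate feature id {fid!r}")
        try:
            geom = _shapely_shape(feat["geometry"])
        except Exception as exc:
            raise GraphFormatError(f"feature {fid!r}: invalid geometry ({exc})") from exc
        if geom.is_empty or not geom.is_valid:
            raise GraphFormatError(f"feature {fid!r}: invalid or empty geometry")
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise GraphFormatError(
                f"feature {fid!r}: expected polygon geometry, got {geom.geom_type}"
            )
        ids.append(fid)
        geoms.append(geom)

    edges = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            inter = geoms[i].boundary.intersection(geoms[j].boundary)
            if inter.is_empty:
                continue
            if rule == "queen" or inter.length > 0:
                edges.append((i, j))
    return _from_edge_list(ids, edges)


# -- components & exclusion filter ----------------------------------------


def connected_components(graph: AdjacencyGraph) -> list[set[int]]:
    """Partition of area indices into connected components (isolated areas are
    singletons).  Components are ordered by their smallest member index."""
    comps = [set(c) for c in nx.connected_components(graph.to_networkx())]
    return sorted(comps, key=min)


def component_labels(graph: AdjacencyGraph) -> np.ndarray:
    """Integer component label per area, consistent with connected_components."""
    labels = np.empty(graph.n_areas, dtype=int)
    for lab, comp in enumerate(connected_components(graph)):
        for i in comp:
            labels[i] = lab
    return labels


def exclusion_filter(
    graph: AdjacencyGraph,
    respondent_counts: Mapping[str, int] | None = None,
) -> tuple[AdjacencyGraph, list[str]]:
    """Drop areas that cannot enter the spatial model and log them.

    An area is excluded when it has zero respondents (if counts are given) or
    zero neighbours.  Removing an area can isolate another, so the neighbour
    rule is applied to a fixed point.  Returns the filtered graph and the list
    of excluded area ids.
    """
    keep = list(graph.area_ids)
    excluded: list[str] = []
    if respondent_counts is not None:
        empty = [a for a in keep if respondent_counts.get(a, 0) <= 0]
        if empty:
            logger.info("excluding %d area(s) with zero respondents: %s", len(empty), empty)
            excluded.extend(empty)
            keep = [a for a in keep if a not in set(empty)]
    sub = graph.subgraph(keep)
    while True:
        isolated = [sub.area_ids[i] for i in range(sub.n_areas) if len(sub.neighbors[i]) == 0]
        if not isolated:
            break
        logger.info("excluding %d isolated area(s): %s", len(isolated), isolated)
        excluded.extend(isolated)
        keep = [a for a in keep if a not in set(isolated)]
        sub = graph.subgraph(keep)
    return sub, excluded


def load_geojson(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
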