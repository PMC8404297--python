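"""Areal adjacency structures for spatial disease-mapping models.

The geographical backbone of every CAR-type smoothing model used in this
package is a symmetric, binary adjacency matrix ``W`` over ``n`` areas:
``W[i, k] = 1`` if areas ``i`` and ``k`` share a common border, 0 otherwise,
with a zero diagonal.  Areas that are islands (degree 0, e.g. municipalities
without land borders) can be linked explicitly to the area they are connected
to by ferry or bridge, so that the smoothing field is defined on a connected
graph.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AdjacencyGraph",
    "build_adjacency",
    "link_islands",
    "neighbour_counts",
    "read_edge_csv",
    "read_geojson_polygons",
    "write_adjacency",
    "read_adjacency",
]


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric binary neighbour structure over an ordered set of areas.

    Attributes
    ----------
    area_ids:
        Ordered, unique area labels.  All matrices and vectors produced by
        this package index areas in this order, fixed at construction.
    W:
        ``(n, n)`` symmetric binary matrix with zero diagonal.
    island_links:
        ``(island_id, linked_id)`` pairs added beyond shared borders.
    """

    area_ids: tuple
    W: np.ndarray
    island_links: tuple = field(default_factory=tuple)

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def index(self) -> dict:
        return {a: i for i, a in enumerate(self.area_ids)}

    def degrees(self) -> np.ndarray:
        return self.W.sum(axis=1).astype(int)

    def validate(self) -> None:
        W = self.W
        n = self.n_areas
        if W.shape != (n, n):
            raise ValueError(f"W has shape {W.shape}, expected ({n}, {n})")
        if len(set(self.area_ids)) != n:
            raise ValueError("area_ids contains duplicates")
        if not np.array_equal(W, W.T):
            raise ValueError("W is not symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("W has nonzero diagonal entries")
        if not np.isin(W, (0, 1)).all():
            raise ValueError("W entries must be 0 or 1")
        idx = self.index
        for a, b in self.island_links:
            if W[idx[a], idx[b]] != 1:
                raise ValueError(f"island link {(a, b)} not present in W")


def build_adjacency(edges: Iterable[tuple], area_ids: Sequence) -> AdjacencyGraph:
    """Build an :class:`AdjacencyGraph` from an unordered edge list.

    Parameters
    ----------
    edges:
        Unordered pairs of area ids sharing a border.
    area_ids:
        Ordered list of all area labels; fixes the matrix ordering.

    Raises
    ------
    ValueError
        If an edge references an unknown id or is a self-pair.
    """
    ids = tuple(area_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("area_ids contains duplicates")
    idx = {a: i for i, a in enumerate(ids)}
    W = np.zeros((len(ids), len(ids)), dtype=np.int8)
    for a, b in edges:
        if a not in idx:
            raise ValueError(f"unknown area id in edge list: {a!r}")
        if b not in idx:
            raise ValueError(f"unknown area id in edge list: {b!r}")
        if a == b:
            raise ValueError(f"self-pair in edge list: {a!r}")
        W[idx[a], idx[b]] = 1
        W[idx[b], idx[a]] = 1
    graph = AdjacencyGraph(area_ids=ids, W=W)
    if (graph.degrees() == 0).any():
        isolated = [ids[i] for i in np.flatnonzero(graph.degrees() == 0)]
        warnings.warn(
            f"areas with no neighbours (islands?): {isolated}; "
            "link them with link_islands() before fitting spatial models "
            "with rho close to 1",
            stacklevel=2,
        )
    return graph


def link_islands(graph: AdjacencyGraph, links: Iterable[tuple]) -> AdjacencyGraph:
    """Connect degree-0 areas (islands) to a chosen mainland area.

    Mirrors the treatment of island municipalities: areas without any shared
    land border are linked to the area they are connected to by ferry or
    bridge.  Only true islands (degree 0) may be linked this way.
    """
    idx = graph.index
    W = graph.W.copy()
    deg = W.sum(axis=1)
    recorded = list(graph.island_links)
    for island, mainland in links:
        if island not in idx or mainland not in idx:
            raise ValueError(f"unknown area id in island link {(island, mainland)}")
        if island == mainland:
            raise ValueError(f"island {island!r} cannot be linked to itself")
        i = idx[island]
        if deg[i] > 0:
            raise ValueError(
                f"area {island!r} has degree {int(deg[i])}; only degree-0 areas "
                "may be ferry-linked"
            )
        k = idx[mainland]
        W[i, k] = W[k, i] = 1
        deg = W.sum(axis=1)
        recorded.append((island, mainland))
    out = replace(graph, W=W, island_links=tuple(recorded))
    if (out.degrees() == 0).any():
        isolated = [graph.area_ids[i] for i in np.flatnonzero(out.degrees() == 0)]
        warnings.warn(f"areas still without neighbours: {isolated}", stacklevel=2)
    return out


def neighbour_counts(graph: AdjacencyGraph) -> np.ndarray:
    """Per-area neighbour counts (the diagonal of D in the CAR precision)."""
    return graph.degrees()


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_edge_csv(path) -> list:
    """Read an edge list CSV with required header columns area_a, area_b."""
    df = pd.read_csv(path, dtype=str)
    missing = {"area_a", "area_b"} - set(df.columns)
    if missing:
        raise ValueError(f"edge CSV missing columns: {sorted(missing)}")
    return list(zip(df["area_a"], df["area_b"]))


def read_geojson_polygons(path, id_property: str = "area_id"):
    """Build an adjacency graph from a GeoJSON FeatureCollection of polygons.

    Two areas are neighbours iff their polygons share a boundary of nonzero
    length (rook-style contiguity); point-touching corners do not count.
    """
    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    ids, geoms = [], []
    for feat in gj["features"]:
        props = feat.get("properties") or {}
        if id_property not in props:
            raise ValueError(f"feature missing id property {id_property!r}")
        ids.append(props[id_property])
        geoms.append(shape(feat["geometry"]))
    edges = []
    for i in range(len(ids)):
        for k in range(i + 1, len(ids)):
            inter = geoms[i].boundary.intersection(geoms[k].boundary)
            if inter.length > 0:
                edges.append((ids[i], ids[k]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_adjacency(edges, ids)


def write_adjacency(graph: AdjacencyGraph, edge_path, sidecar_path) -> None:
    """Write the graph as a CSV edge list plus a JSON sidecar.

    The sidecar carries the area ordering and the island links, which the
    edge list alone cannot represent (ordering) or distinguish (links).
    """
    ii, kk = np.nonzero(np.triu(graph.W, k=1))
    pd.DataFrame(
        {
            "area_a": [graph.area_ids[i] for i in ii],
            "area_b": [graph.area_ids[k] for k in kk],
        }
    ).to_csv(edge_path, index=False)
    sidecar = {
        "area_ids": list(graph.area_ids),
        "island_links": [list(p) for p in graph.island_links],
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2))


def read_adjacency(edge_path, sidecar_path) -> AdjacencyGraph:
    """Inverse of :func:`write_adjacency`."""
    sidecar = json.loads(Path(sidecar_path).read_text())
    edges = read_edge_csv(edge_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        graph = build_adjacency(edges, [str(a) for a in sidecar["area_ids"]])
    links = tuple((str(a), str(b)) for a, b in sidecar["island_links"])
    out = replace(graph, island_links=links)
    out.validate()
    return out
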