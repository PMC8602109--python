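"""Correlation-weighted communication paths between residues.

Residues become graph nodes at their center of mass; an edge between i
and j carries weight ``w_ij = -log(|C_ij|)`` so that strongly correlated
or anticorrelated pairs are cheap to traverse.  Optimal and near-optimal
simple paths between a source and a sink are enumerated exactly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .dcc import DccMatrix
from .model import StructureModel
from .pertnet import ContactNetwork

__all__ = [
    "CorrelationGraph",
    "PathSet",
    "NoPathError",
    "build_graph",
    "optimal_path",
    "suboptimal_paths",
]

_TIE_EPS = 1e-12


class NoPathError(ValueError):
    """Source and sink are disconnected in the correlation graph."""


@dataclass
class CorrelationGraph:
    """networkx graph over residues with ``-log|C|`` edge weights."""

    graph: nx.Graph
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def edge_weight(self, i: int, j: int) -> float:
        return self.graph.edges[i, j]["weight"]


@dataclass
class PathSet:
    """Simple paths between source and sink, sorted by cumulative weight."""

    source: int
    sink: int
    paths: list[tuple[float, tuple[int, ...]]]  # (weight, nodes) ascending
    mode: str = "within_delta"
    parameter: float = 0.0

    @property
    def optimal(self) -> tuple[float, tuple[int, ...]]:
        return self.paths[0]

    def to_dataframe(self, structure: StructureModel | None = None) -> pd.DataFrame:
        rows = []
        for rank, (w, nodes) in enumerate(self.paths, start=1):
            if structure is not None:
                labels = "-".join(
                    f"{structure.residue_chains[n]}{structure.residue_ids[n]}"
                    for n in nodes
                )
            else:
                labels = "-".join(str(n) for n in nodes)
            rows.append({"rank": rank, "weight": w, "path": labels})
        return pd.DataFrame(rows, columns=["rank", "weight", "path"])

    def to_records(self) -> list[dict]:
        return [
            {"rank": r + 1, "weight": w, "nodes": list(nodes)}
            for r, (w, nodes) in enumerate(self.paths)
        ]


def residue_centers_of_mass(
    structure: StructureModel, coords: np.ndarray
) -> np.ndarray:
    """Mass-weighted residue centers for one coordinate frame."""
    coords = np.asarray(coords)
    out = np.empty((structure.n_residues, 3))
    for r in range(structure.n_residues):
        atoms = structure.residue_atoms(r)
        m = structure.atom_masses[atoms]
        out[r] = (coords[atoms] * m[:, None]).sum(axis=0) / m.sum()
    return out


def build_graph(
    dcc: DccMatrix,
    structure: StructureModel | None = None,
    reference_coords: np.ndarray | None = None,
    mask: ContactNetwork | None = None,
    mask_min_weight: float = 1.0,
) -> CorrelationGraph:
    """Correlation graph with ``-log|C|`` weights and optional contact mask.

    With a mask only residue pairs whose average contact weight reaches
    ``mask_min_weight`` receive an edge (physically proximal pairs, as in
    the original suboptimal-path protocol).  Pairs with ``C = 0`` carry
    infinite weight and are omitted.
    """
    if mask_min_weight < 0:
        raise ValueError("mask_min_weight must be >= 0")
    n = dcc.n_residues
    g = nx.Graph()
    positions = None
    if structure is not None and reference_coords is not None:
        positions = residue_centers_of_mass(structure, reference_coords)
    for a in range(n):
        node = int(dcc.residue_indices[a])
        attrs = {}
        if positions is not None:
            attrs["pos"] = tuple(positions[node])
        g.add_node(node, **attrs)
    for a in range(n):
        for b in range(a + 1, n):
            i = int(dcc.residue_indices[a])
            j = int(dcc.residue_indices[b])
            c = abs(dcc.matrix[a, b])
            if c == 0.0:
                continue
            if mask is not None and mask.weight(i, j) < mask_min_weight:
                continue
            g.add_edge(i, j, weight=-math.log(c), correlation=dcc.matrix[a, b])
    return CorrelationGraph(
        graph=g,
        meta={"masked": mask is not None, "mask_min_weight": mask_min_weight},
    )


def optimal_path(
    graph: CorrelationGraph, source: int, sink: int
) -> tuple[tuple[int, ...], float]:
    """Minimum-cumulative-weight simple path (Dijkstra)."""
    if source == sink:
        raise ValueError("source and sink must differ")
    g = graph.graph
    if source not in g or sink not in g:
        raise ValueError("source or sink not in graph")
    try:
        weight, nodes = nx.bidirectional_dijkstra(g, source, sink, weight="weight")
    except nx.NetworkXNoPath as exc:
        raise NoPathError(f"no path from {source} to {sink}") from exc
    return tuple(nodes), float(weight)


def _path_weight(g: nx.Graph, nodes) -> float:
    return float(
        sum(g.edges[a, b]["weight"] for a, b in zip(nodes, nodes[1:]))
    )


def suboptimal_paths(
    graph: CorrelationGraph,
    source: int,
    sink: int,
    mode: str = "within_delta",
    k_or_delta: float = 0.0,
) -> PathSet:
    """Exact enumeration of near-optimal simple paths.

    ``mode="within_delta"`` returns every simple path with weight at most
    ``optimal + delta``; ``mode="top_k"`` returns the k lowest-weight
    simple paths.  Ties are broken lexicographically on the node
    sequence, so results are fully deterministic.
    """
    g = graph.graph
    _, opt_weight = optimal_path(graph, source, sink)  # validates endpoints
    if mode == "within_delta":
        delta = float(k_or_delta)
        if delta < 0:
            raise ValueError("delta must be >= 0")
        bound = opt_weight + delta + _TIE_EPS
        collected = _paths_within_bound(g, source, sink, bound)
        collected.sort(key=lambda item: (item[0], item[1]))
        return PathSet(source, sink, collected, mode=mode, parameter=delta)
    if mode == "top_k":
        k = int(k_or_delta)
        if k < 1:
            raise ValueError("k must be >= 1")
        collected: list[tuple[float, tuple[int, ...]]] = []
        # Yen-style generator yields simple paths in non-decreasing weight;
        # keep going past the k-th to absorb weight ties, then tie-break.
        kth = math.inf
        for nodes in nx.shortest_simple_paths(g, source, sink, weight="weight"):
            w = _path_weight(g, nodes)
            if len(collected) >= k and w > kth + _TIE_EPS:
                break
            collected.append((w, tuple(nodes)))
            if len(collected) == k:
                kth = collected[-1][0]
        collected.sort(key=lambda item: (item[0], item[1]))
        return PathSet(source, sink, collected[:k], mode=mode, parameter=float(k))
    raise ValueError(f"unknown mode {mode!r}")


def _paths_within_bound(
    g: nx.Graph, source: int, sink: int, bound: float
) -> list[tuple[float, tuple[int, ...]]]:
    """Depth-first enumeration of simple paths with weight <= bound.

    Pruned with single-source shortest distances to the sink, so branches
    that cannot finish under the bound are abandoned early.
    """
    dist_to_sink = nx.single_source_dijkstra_path_length(g, sink, weight="weight")
    out: list[tuple[float, tuple[int, ...]]] = []
    path = [source]
    on_path = {source}

    def extend(node: int, acc: float) -> None:
        if node == sink:
            out.append((acc, tuple(path)))
            return
        for nbr in sorted(g.neighbors(node)):
            if nbr in on_path:
                continue
            w = acc + g.edges[node, nbr]["weight"]
            if w + dist_to_sink.get(nbr, math.inf) > bound:
                continue
            path.append(nbr)
            on_path.add(nbr)
            extend(nbr, w)
            path.pop()
            on_path.remove(nbr)

    extend(source, 0.0)
    return out
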