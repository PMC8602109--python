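"""Dynamical weighted contact networks and signed perturbation networks.

Residues are nodes; an edge weight is the time-and-replica-averaged
number of heavy-atom pairs (one atom from each residue) closer than the
cutoff (default 5 A, strict inequality).  Subtracting the networks of two
states and thresholding yields the signed perturbation network: positive
edges are contact gains in state B, negative edges losses.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .model import Ensemble, StructureModel

__all__ = [
    "ContactNetwork",
    "PerturbationNetwork",
    "contact_counts_frame",
    "dynamical_contact_network",
    "perturbation",
]

DEFAULT_CUTOFF = 5.0  # A, heavy-atom contact condition
DEFAULT_THRESHOLD = 5.0  # minimum |weight change| kept in a perturbation net


@dataclass
class ContactNetwork:
    """Undirected residue graph with non-negative contact-count weights."""

    n_residues: int
    weights: dict[tuple[int, int], float]
    cutoff: float = DEFAULT_CUTOFF
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (i, j), w in self.weights.items():
            if i == j:
                raise ValueError("self-edges are not allowed")
            if i > j:
                raise ValueError("edge keys must be ordered (i < j)")
            if w < 0:
                raise ValueError("contact weights must be >= 0")

    def weight(self, i: int, j: int) -> float:
        key = (i, j) if i < j else (j, i)
        return self.weights.get(key, 0.0)

    def to_networkx(self, structure: StructureModel | None = None):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_residues))
        for (i, j), w in sorted(self.weights.items()):
            g.add_edge(i, j, weight=w)
        if structure is not None:
            for r in range(self.n_residues):
                g.nodes[r]["chain"] = str(structure.residue_chains[r])
                g.nodes[r]["resid"] = int(structure.residue_ids[r])
        return g


@dataclass
class PerturbationNetwork:
    """Signed thresholded difference of two contact networks (B minus A)."""

    n_residues: int
    deltas: dict[tuple[int, int], float]
    threshold: float = DEFAULT_THRESHOLD
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (i, j), d in self.deltas.items():
            if abs(d) <= self.threshold:
                raise ValueError("retained edges must exceed the threshold")

    @property
    def nodes(self) -> list[int]:
        """Residues touched by at least one surviving edge (others pruned)."""
        seen: set[int] = set()
        for i, j in self.deltas:
            seen.update((i, j))
        return sorted(seen)

    def gains(self) -> dict[tuple[int, int], float]:
        return {k: v for k, v in self.deltas.items() if v > 0}

    def losses(self) -> dict[tuple[int, int], float]:
        return {k: v for k, v in self.deltas.items() if v < 0}

    def to_networkx(self, structure: StructureModel | None = None):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (i, j), d in sorted(self.deltas.items()):
            # sign colors follow the gain=red / loss=blue convention
            g.add_edge(
                i, j, weight=abs(d), delta=d,
                sign="gain" if d > 0 else "loss",
                color="red" if d > 0 else "blue",
            )
        if structure is not None:
            for r in g.nodes:
                g.nodes[r]["chain"] = str(structure.residue_chains[r])
                g.nodes[r]["resid"] = int(structure.residue_ids[r])
        return g

    def write_graphml(self, path, structure: StructureModel | None = None) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(structure), path)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"res_i": i, "res_j": j, "weight": abs(d),
             "sign": "gain" if d > 0 else "loss"}
            for (i, j), d in sorted(self.deltas.items())
        ]
        return pd.DataFrame(rows, columns=["res_i", "res_j", "weight", "sign"])

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _heavy_info(structure: StructureModel) -> tuple[np.ndarray, np.ndarray]:
    heavy = np.nonzero(structure.is_heavy)[0]
    if heavy.size == 0:
        raise ValueError("structure has no heavy atoms flagged")
    return heavy, structure.atom_residue[heavy]


def _pair_counts(
    frame_heavy: np.ndarray,
    res_of_heavy: np.ndarray,
    n_residues: int,
    cutoff: float,
    exclude_bonded: int,
) -> np.ndarray:
    """Dense residue-pair contact-count matrix for one frame."""
    d = cdist(frame_heavy, frame_heavy)
    close = d < cutoff  # strict inequality per the contact condition
    ind = np.zeros((len(res_of_heavy), n_residues))
    ind[np.arange(len(res_of_heavy)), res_of_heavy] = 1.0
    counts = ind.T @ close @ ind
    np.fill_diagonal(counts, 0.0)
    if exclude_bonded > 0:
        for off in range(1, exclude_bonded + 1):
            i = np.arange(n_residues - off)
            counts[i, i + off] = 0.0
            counts[i + off, i] = 0.0
    return counts


def contact_counts_frame(
    frame: np.ndarray,
    structure: StructureModel,
    cutoff: float = DEFAULT_CUTOFF,
    exclude_bonded: int = 1,
) -> dict[tuple[int, int], int]:
    """Heavy-atom pair counts under the cutoff for every residue pair.

    ``exclude_bonded`` drops sequence-adjacent pairs ``|i-j| <= n`` whose
    covalent contacts are constant and uninformative; pass 0 to keep all.
    """
    heavy, res_of_heavy = _heavy_info(structure)
    counts = _pair_counts(
        np.asarray(frame)[heavy], res_of_heavy, structure.n_residues,
        cutoff, exclude_bonded,
    )
    out: dict[tuple[int, int], int] = {}
    ii, jj = np.nonzero(np.triu(counts, k=1))
    for i, j in zip(ii, jj):
        out[(int(i), int(j))] = int(counts[i, j])
    return out


def _ensemble_mean_counts(
    ensemble: Ensemble,
    cutoff: float,
    exclude_bonded: int,
    start: int | None,
    stop: int | None,
) -> np.ndarray:
    win = ensemble.window(start, stop)
    heavy, res_of_heavy = _heavy_info(win.structure)
    n_res = win.structure.n_residues
    acc = np.zeros((n_res, n_res))
    for f in range(win.n_frames):
        acc += _pair_counts(
            win.coords[f, heavy], res_of_heavy, n_res, cutoff, exclude_bonded
        )
    return acc / win.n_frames


def dynamical_contact_network(
    replicas: list[Ensemble],
    cutoff: float = DEFAULT_CUTOFF,
    start: int | None = None,
    stop: int | None = None,
    exclude_bonded: int = 1,
) -> ContactNetwork:
    """Time-averaged contact network, then averaged over replicas.

    Per-frame residue-pair counts are averaged over the frames of each
    replica's window, then the replica averages are combined with equal
    weight.
    """
    if not replicas:
        raise ValueError("need at least one replica")
    n_res = replicas[0].structure.n_residues
    mean = np.zeros((n_res, n_res))
    for rep in replicas:
        if rep.structure.n_residues != n_res:
            raise ValueError("replicas have mismatched residue universes")
        mean += _ensemble_mean_counts(rep, cutoff, exclude_bonded, start, stop)
    mean /= len(replicas)
    weights: dict[tuple[int, int], float] = {}
    ii, jj = np.nonzero(np.triu(mean, k=1))
    for i, j in zip(ii, jj):
        weights[(int(i), int(j))] = float(mean[i, j])
    return ContactNetwork(
        n_residues=n_res,
        weights=weights,
        cutoff=cutoff,
        meta={
            "n_replicas": len(replicas),
            "exclude_bonded": exclude_bonded,
            "states": sorted({r.state_label for r in replicas}),
        },
    )


def perturbation(
    net_a: ContactNetwork,
    net_b: ContactNetwork,
    threshold: float = DEFAULT_THRESHOLD,
) -> PerturbationNetwork:
    """Signed thresholded difference network (state B minus state A).

    Edges with ``|delta| <= threshold`` are dropped; nodes left without
    edges are pruned (they simply do not appear in ``nodes``).
    """
    if net_a.n_residues != net_b.n_residues:
        raise ValueError("contact networks cover different residue universes")
    deltas: dict[tuple[int, int], float] = {}
    for key in set(net_a.weights) | set(net_b.weights):
        d = net_b.weights.get(key, 0.0) - net_a.weights.get(key, 0.0)
        if abs(d) > threshold:
            deltas[key] = d
    return PerturbationNetwork(
        n_residues=net_a.n_residues,
        deltas=deltas,
        threshold=threshold,
        meta={"cutoff": net_a.cutoff},
    )
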