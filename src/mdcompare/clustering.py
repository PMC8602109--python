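"""Conformational K-means under the superposed coordinate-RMSD metric.

The distance between a frame and a centroid is the minimum RMSD over
rigid motions on the chosen selection; centroids are coordinate means of
their superposed members.  A sieve reduces cost: every sieve-th frame is
clustered iteratively, then the remaining frames are added to the
resulting clusters by a single nearest-centroid pass.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import kabsch_batch
from .model import Ensemble, SelectionSpec

__all__ = ["ClusterResult", "kmeans_rmsd", "populations", "representative_frame"]


@dataclass
class ClusterResult:
    """Frame partition with centroids and diagnostics."""

    labels: np.ndarray  # per-frame cluster id in [0, k)
    centroids: np.ndarray  # (k, n_sel_atoms, 3)
    distances: np.ndarray  # per-frame RMSD to its assigned centroid
    k: int
    sieve: int
    seed: int
    objective_history: list[float] = field(default_factory=list)
    metric: str = "rmsd"

    @property
    def n_frames(self) -> int:
        return len(self.labels)

    def population_percentages(self) -> np.ndarray:
        counts = np.bincount(self.labels, minlength=self.k)
        return 100.0 * counts / counts.sum()

    def members(self, cluster_id: int) -> np.ndarray:
        if not 0 <= cluster_id < self.k:
            raise ValueError("bad cluster id")
        return np.nonzero(self.labels == cluster_id)[0]


def _fit_rmsd_many(frames: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    """Superposed RMSD of each frame against one centroid."""
    return kabsch_batch(frames, centroid)[2]


def _assign(frames: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.stack([_fit_rmsd_many(frames, c) for c in centroids], axis=1)
    labels = np.argmin(d, axis=1)
    return labels, d[np.arange(len(frames)), labels]


def _update_centroid(frames: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    """Coordinate mean of members after superposition onto the centroid."""
    R, t, _ = kabsch_batch(frames, centroid)
    fitted = np.einsum("nmi,nji->nmj", frames, R) + t[:, None, :]
    return fitted.mean(axis=0)


def _kmeanspp_init(
    frames: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """k-means++ style seeding in RMSD space."""
    n = len(frames)
    chosen = [int(rng.integers(n))]
    d2 = _fit_rmsd_many(frames, frames[chosen[0]]) ** 2
    while len(chosen) < k:
        total = d2.sum()
        if total <= 0:
            # degenerate data: all remaining frames coincide with a center
            pool = [i for i in range(n) if i not in chosen]
            chosen.append(int(rng.choice(pool)))
            continue
        probs = d2 / total
        pick = int(rng.choice(n, p=probs))
        chosen.append(pick)
        d2 = np.minimum(d2, _fit_rmsd_many(frames, frames[pick]) ** 2)
    return frames[chosen].copy()


def kmeans_rmsd(
    ensemble: Ensemble,
    selection: SelectionSpec | str = "backbone",
    k: int = 4,
    sieve: int = 10,
    seed: int = 0,
    max_iter: int = 100,
    n_init: int = 8,
) -> ClusterResult:
    """Sieved K-means over frames with superposed RMSD distances.

    Initial clustering runs on every ``sieve``-th frame (``n_init``
    k-means++ restarts, keeping the lowest-objective run); the sieved-out
    frames are then added to the initial clusters by one nearest-centroid
    assignment without further centroid refinement.  Deterministic for a
    given (data, k, sieve, seed).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if sieve < 1:
        raise ValueError("sieve must be >= 1")
    idx = ensemble.structure.select(selection)
    frames = ensemble.coords[:, idx, :]
    n = len(frames)
    init_idx = np.arange(0, n, sieve)
    if len(init_idx) < k:
        raise ValueError("fewer sieved frames than clusters")
    work = frames[init_idx]
    best: tuple[float, np.ndarray, list[float]] | None = None
    # restart from several seedings; keep the lowest-objective run
    for child in np.random.SeedSequence(seed).spawn(n_init):
        rng = np.random.default_rng(child)
        centroids = _kmeanspp_init(work, k, rng)
        labels_prev = None
        history: list[float] = []
        for _ in range(max_iter):
            labels, dist = _assign(work, centroids)
            history.append(float(np.sum(dist ** 2)))
            if labels_prev is not None and np.array_equal(labels, labels_prev):
                break
            labels_prev = labels
            for c in range(k):
                members = work[labels == c]
                if len(members):
                    centroids[c] = _update_centroid(members, centroids[c])
                # empty cluster keeps its previous centroid
        if best is None or history[-1] < best[0]:
            best = (history[-1], centroids.copy(), history)
    _, centroids, history = best
    full_labels, full_dist = _assign(frames, centroids)
    return ClusterResult(
        labels=full_labels,
        centroids=centroids,
        distances=full_dist,
        k=k,
        sieve=sieve,
        seed=seed,
        objective_history=history,
    )


def populations(result: ClusterResult) -> list[tuple[int, float]]:
    """Cluster populations in percent, sorted descending, stable ids.

    Ties are resolved by cluster id so the ordering is deterministic.
    """
    pct = result.population_percentages()
    order = sorted(range(result.k), key=lambda c: (-pct[c], c))
    return [(c, float(pct[c])) for c in order]


def representative_frame(result: ClusterResult, cluster_id: int) -> int:
    """Member frame closest to the centroid; ties go to the lowest index."""
    members = result.members(cluster_id)
    if members.size == 0:
        raise ValueError(f"cluster {cluster_id} is empty")
    d = result.distances[members]
    return int(members[np.argmin(d)])
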