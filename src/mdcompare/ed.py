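"""Essential dynamics: positional covariance eigenmodes and similarity.

The positional covariance of the superposed, mean-centered selection is
diagonalized; eigenvectors are the collective deformation modes and the
eigenvalues their variance contributions.  Cross-replica/window agreement
is quantified with RMSIP over the leading modes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Ensemble, SelectionSpec

__all__ = [
    "EdResult",
    "compute_ed",
    "variance_fractions",
    "variance_total",
    "mode_similarity",
    "mode_overlap_table",
    "project_frames",
]


@dataclass
class EdResult:
    """Mean structure plus eigenpairs of the positional covariance."""

    mean_coords: np.ndarray  # 3N vector (A)
    eigenvalues: np.ndarray  # A^2, non-increasing, >= 0
    eigenvectors: np.ndarray  # (3N, n_modes), orthonormal columns
    degenerate: bool = False  # all-zero spectrum flag
    meta: dict = field(default_factory=dict)

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def variance_fraction(self) -> np.ndarray:
        """Per-mode contribution to the total variance, in percent."""
        trace = self.eigenvalues.sum()
        if trace == 0:
            return np.zeros_like(self.eigenvalues)
        return 100.0 * self.eigenvalues / trace


def compute_ed(
    ensemble: Ensemble,
    selection: SelectionSpec | str = "backbone",
    start: int | None = None,
    stop: int | None = None,
    fit: bool = True,
) -> EdResult:
    """Eigendecomposition of the 3N x 3N positional covariance.

    Frames in the window are superposed on the selection to the first
    window frame before the covariance is accumulated (mass-unweighted).
    Modes are sorted by decreasing eigenvalue; tiny negative eigenvalues
    from round-off are clipped to zero.
    """
    from .trajectory import superpose

    win = ensemble.window(start, stop)
    if win.n_frames < 2:
        raise ValueError("need at least 2 frames for a covariance")
    idx = win.structure.select(selection)
    if fit:
        win = superpose(win, reference=0, selection=selection)
    X = win.coords[:, idx, :].reshape(win.n_frames, -1)
    mean = X.mean(axis=0)
    dev = X - mean
    cov = dev.T @ dev / win.n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    degenerate = bool(evals.sum() <= 1e-12)
    return EdResult(
        mean_coords=mean,
        eigenvalues=evals,
        eigenvectors=evecs,
        degenerate=degenerate,
        meta={
            "selection": str(selection),
            "n_frames": win.n_frames,
            "replica_id": ensemble.replica_id,
            "state": ensemble.state_label,
        },
    )


def variance_fractions(ed: EdResult, k: int) -> tuple[np.ndarray, float]:
    """First ``k`` per-mode variance percentages plus their total.

    The total is the reported "sum of the first k projections" column.
    """
    if k > ed.n_modes:
        raise ValueError("k exceeds the number of modes")
    trace = ed.eigenvalues.sum()
    if trace == 0:
        raise ValueError("zero trace: degenerate spectrum")
    fracs = 100.0 * ed.eigenvalues[:k] / trace
    return fracs, float(fracs.sum())


def variance_total(fractions, ndigits: int | None = 1) -> float:
    """Reporting-layer total of per-projection percentages.

    Sums already-computed (or printed) per-projection contributions and
    rounds to ``ndigits`` decimals, exactly as the summary table does.
    """
    total = float(np.sum(np.asarray(fractions, dtype=np.float64)))
    if ndigits is not None:
        total = round(total, ndigits)
    return total


def mode_overlap_table(ed_a: EdResult, ed_b: EdResult, k: int) -> np.ndarray:
    """k x k matrix of absolute inner products between leading modes."""
    if ed_a.eigenvectors.shape[0] != ed_b.eigenvectors.shape[0]:
        raise ValueError("mode dimension mismatch")
    if k > min(ed_a.n_modes, ed_b.n_modes):
        raise ValueError("k exceeds available modes")
    A = ed_a.eigenvectors[:, :k]
    B = ed_b.eigenvectors[:, :k]
    return np.abs(A.T @ B)


def mode_similarity(ed_a: EdResult, ed_b: EdResult, k: int = 1) -> float:
    """RMSIP over the first ``k`` modes, in [0, 1].

    ``sqrt( (1/k) sum_{i<=k} sum_{j<=k} (v_i^a . v_j^b)^2 )``; symmetric
    and invariant to eigenvector sign flips.  ``k=1`` compares the first
    essential motion only.
    """
    dots = mode_overlap_table(ed_a, ed_b, k)
    return float(np.sqrt((dots ** 2).sum() / k))


def project_frames(
    ensemble: Ensemble,
    ed: EdResult,
    mode_index: int,
    selection: SelectionSpec | str = "backbone",
    start: int | None = None,
    stop: int | None = None,
    fit: bool = True,
) -> np.ndarray:
    """Scalar projection of mean-centered frames on one eigenvector."""
    from .trajectory import superpose

    if not 0 <= mode_index < ed.n_modes:
        raise ValueError("mode index out of range")
    win = ensemble.window(start, stop)
    idx = win.structure.select(selection)
    if fit:
        win = superpose(win, reference=0, selection=selection)
    X = win.coords[:, idx, :].reshape(win.n_frames, -1)
    if X.shape[1] != ed.eigenvectors.shape[0]:
        raise ValueError("selection dimension mismatch with EdResult")
    dev = X - X.mean(axis=0)
    return dev @ ed.eigenvectors[:, mode_index]
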