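"""Dynamic cross-correlation matrices and Tanimoto comparison.

``C_ij = <dr_i . dr_j> / (<dr_i^2> <dr_j^2>)^(1/2)`` over one
representative atom (CA) per residue, with displacements taken about the
time mean after a least-squares CA fit to a reference frame.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Ensemble, SelectionSpec

__all__ = ["DccMatrix", "DccError", "compute_dcc", "tanimoto_similarity"]


class DccError(ValueError):
    """Raised for undefined correlation entries (zero-variance residues)."""


@dataclass
class DccMatrix:
    """Symmetric per-residue correlation matrix with unit diagonal."""

    residue_indices: np.ndarray
    matrix: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.residue_indices = np.asarray(self.residue_indices)
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        n = len(self.residue_indices)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape mismatch with residue list")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("matrix must be symmetric")
        if np.any(np.abs(self.matrix) > 1 + 1e-9):
            raise ValueError("correlation entries must lie in [-1, 1]")

    @property
    def n_residues(self) -> int:
        return len(self.residue_indices)

    def upper_triangle(self) -> np.ndarray:
        """Flattened strict upper triangle (diagonal excluded)."""
        iu = np.triu_indices(self.n_residues, k=1)
        return self.matrix[iu]

    def to_dataframe(self) -> pd.DataFrame:
        labels = [str(r) for r in self.residue_indices]
        return pd.DataFrame(self.matrix, index=labels, columns=labels)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    @staticmethod
    def read_csv(path) -> "DccMatrix":
        df = pd.read_csv(path, index_col=0)
        return DccMatrix(
            residue_indices=np.array([int(c) for c in df.columns]),
            matrix=df.to_numpy(),
        )


def compute_dcc(
    ensemble: Ensemble,
    selection: SelectionSpec | str = "ca",
    start: int | None = None,
    stop: int | None = None,
    fit: bool = True,
    reference: np.ndarray | int = 0,
) -> DccMatrix:
    """Per-residue dynamic cross-correlation matrix of an ensemble window.

    Frames are least-squares fitted on the selection to the reference
    frame (default: the first frame, standing in for the equilibrated
    starting configuration), then ``C_ij`` is formed from displacements
    about the time mean of each representative atom.  A residue whose
    representative atom has zero variance makes the entry undefined and
    raises :class:`DccError` naming the offending residues.
    """
    from .trajectory import superpose

    win = ensemble.window(start, stop)
    idx = win.structure.select(selection)
    res_idx = win.structure.atom_residue[idx]
    if len(np.unique(res_idx)) != len(res_idx):
        raise ValueError("selection must resolve to one atom per residue")
    if fit:
        win = superpose(win, reference=reference, selection=selection)
    X = win.coords[:, idx, :]  # frames x residues x 3
    disp = X - X.mean(axis=0, keepdims=True)
    n_frames = disp.shape[0]
    flat = disp.reshape(n_frames, -1)
    n_res = len(idx)
    # <dr_i . dr_j> as a sum of the three per-axis covariance contributions
    inner = np.zeros((n_res, n_res))
    for ax in range(3):
        comp = disp[:, :, ax]
        inner += comp.T @ comp / n_frames
    var = np.diag(inner).copy()
    dead = np.nonzero(var <= 0)[0]
    if dead.size:
        raise DccError(
            "zero-variance residues make C undefined: "
            f"{[int(res_idx[i]) for i in dead]}"
        )
    denom = np.sqrt(np.outer(var, var))
    matrix = inner / denom
    matrix = 0.5 * (matrix + matrix.T)
    np.clip(matrix, -1.0, 1.0, out=matrix)
    np.fill_diagonal(matrix, 1.0)
    return DccMatrix(
        residue_indices=np.unique(res_idx),
        matrix=matrix,
        meta={
            "selection": str(selection),
            "n_frames": n_frames,
            "replica_id": ensemble.replica_id,
            "state": ensemble.state_label,
        },
    )


def tanimoto_similarity(a: DccMatrix, b: DccMatrix) -> float:
    """Continuous Tanimoto index between two correlation matrices.

    Computed on the flattened strict upper triangles x, y as
    ``T = x.y / (x.x + y.y - x.y)``.  The constant unit diagonal is
    excluded because it carries no information and would inflate the
    similarity.
    """
    if not np.array_equal(a.residue_indices, b.residue_indices):
        raise ValueError("matrices cover different residue sets")
    x = a.upper_triangle()
    y = b.upper_triangle()
    xx = float(x @ x)
    yy = float(y @ y)
    xy = float(x @ y)
    denom = xx + yy - xy
    if denom == 0:
        raise ValueError("Tanimoto undefined for two all-zero matrices")
    return xy / denom
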