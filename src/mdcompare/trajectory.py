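"""Frame superposition, RMSD/RMSF series and replica aggregation.

These are the workhorse operations behind per-system structural tables:
per-frame backbone RMSD against a common reference (with the cross-replica
average column) and per-residue RMSF profiles averaged over replicas with
SD error bars.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import kabsch_batch, rmsd
from .model import Ensemble, SelectionSpec, StructureModel

__all__ = [
    "RmsdSeries",
    "RmsfProfile",
    "superpose",
    "rmsd_series",
    "average_structure",
    "rmsf_profile",
    "replica_average",
]


@dataclass
class RmsdSeries:
    """Per-frame RMSD (angstrom) against a named reference."""

    values: np.ndarray
    reference_name: str = "reference"
    selection: SelectionSpec | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        # population SD over the frames of the stated window
        return float(np.std(self.values))


@dataclass
class RmsfProfile:
    """Per-residue fluctuation per replica with cross-replica mean/SD."""

    residue_indices: np.ndarray  # positional indices of profiled residues
    per_replica: np.ndarray  # (n_replicas, n_residues)

    @property
    def mean(self) -> np.ndarray:
        return self.per_replica.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.per_replica.std(axis=0)


def _resolve_reference(
    ensemble: Ensemble, reference: np.ndarray | int
) -> np.ndarray:
    if isinstance(reference, (int, np.integer)):
        return ensemble.coords[int(reference)]
    reference = np.asarray(reference, dtype=np.float64)
    if reference.shape != (ensemble.n_atoms, 3):
        raise ValueError("reference frame has wrong shape")
    return reference


def superpose(
    ensemble: Ensemble,
    reference: np.ndarray | int = 0,
    selection: SelectionSpec | str = "ca",
) -> Ensemble:
    """Least-squares fit every frame onto the reference on a selection.

    The optimal proper rotation/translation is computed on the selected
    atoms of each frame and applied to *all* atoms of that frame.
    """
    ref = _resolve_reference(ensemble, reference)
    idx = ensemble.structure.select(selection)
    if idx.size < 3:
        raise ValueError("selection must contain at least 3 atoms for fitting")
    R, t, _ = kabsch_batch(ensemble.coords[:, idx], ref[idx])
    out = np.einsum("nmi,nji->nmj", ensemble.coords, R) + t[:, None, :]
    return replace(ensemble, coords=out)


def rmsd_series(
    ensemble: Ensemble,
    reference: np.ndarray | int = 0,
    selection: SelectionSpec | str = "backbone",
    fit: bool = True,
    reference_name: str = "reference",
) -> RmsdSeries:
    """Per-frame RMSD over a selection, after per-frame superposition.

    With ``fit=False`` the raw coordinate RMSD is reported instead.
    """
    ref = _resolve_reference(ensemble, reference)
    idx = ensemble.structure.select(selection)
    ref_sel = ref[idx]
    if fit:
        values = kabsch_batch(ensemble.coords[:, idx], ref_sel)[2]
    else:
        diff = ensemble.coords[:, idx] - ref_sel[None]
        values = np.sqrt(np.mean(np.sum(diff ** 2, axis=2), axis=1))
    sel = selection if isinstance(selection, SelectionSpec) else SelectionSpec(atom_class=str(selection))
    return RmsdSeries(values=values, reference_name=reference_name, selection=sel)


def average_structure(
    ensemble: Ensemble,
    start: int | None = None,
    stop: int | None = None,
    selection: SelectionSpec | str = "ca",
    fit: bool = True,
) -> np.ndarray:
    """Per-atom coordinate mean over a frame window.

    Frames are first superposed (on ``selection``) to the first frame of
    the window, then averaged.  This replaces an energy-minimized average
    with a plain coordinate average.
    """
    win = ensemble.window(start, stop)
    if fit:
        win = superpose(win, reference=0, selection=selection)
    return win.coords.mean(axis=0)


def rmsf_profile(
    replicas: list[Ensemble],
    selection: SelectionSpec | str = "backbone",
    start: int | None = None,
    stop: int | None = None,
    fit_selection: SelectionSpec | str | None = None,
) -> RmsfProfile:
    """Per-residue RMSF about each replica's window-average structure.

    For every replica the window frames are superposed (on
    ``fit_selection``, default the profiled selection) to the window
    average, then the per-residue root-mean-square fluctuation is taken
    over the selected atoms of each residue.  The cross-replica mean and
    SD come from exactly the provided replicas.
    """
    if not replicas:
        raise ValueError("need at least one replica")
    structure = replicas[0].structure
    idx = structure.select(selection)
    res_idx = structure.residues_of(idx)
    for rep in replicas[1:]:
        other = rep.structure.residues_of(rep.structure.select(selection))
        if not np.array_equal(other, res_idx):
            raise ValueError("replicas have mismatched residue sets")
    fit_sel = selection if fit_selection is None else fit_selection
    per_replica = np.empty((len(replicas), len(res_idx)))
    atom_groups = [
        np.intersect1d(structure.residue_atoms(r), idx) for r in res_idx
    ]
    for ri, rep in enumerate(replicas):
        win = rep.window(start, stop)
        # two-pass fit: to the first frame, then to the resulting average
        win = superpose(win, reference=0, selection=fit_sel)
        avg = win.coords.mean(axis=0)
        win = superpose(win, reference=avg, selection=fit_sel)
        avg = win.coords.mean(axis=0)
        dev2 = np.sum((win.coords - avg[None]) ** 2, axis=2)  # frames x atoms
        for gi, atoms in enumerate(atom_groups):
            per_replica[ri, gi] = np.sqrt(np.mean(dev2[:, atoms]))
    return RmsfProfile(residue_indices=res_idx, per_replica=per_replica)


def replica_average(values, ndigits: int | None = 1) -> float:
    """Aggregate per-replica means into the reported cross-replica average.

    This is the single aggregation rule used by every reporting table:
    plain mean of the replica means, rounded to ``ndigits`` decimals
    (``None`` disables rounding).
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("no replica values")
    out = float(np.mean(values))
    if ndigits is not None:
        out = round(out, ndigits)
    return out
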