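"""Core data model: structures, atom selections and coordinate ensembles.

A :class:`StructureModel` is the static topology (atoms grouped into
residues with chain/subunit tags); an :class:`Ensemble` couples one
structure with a stack of coordinate frames in angstrom.  All analysis
modules operate on these two objects plus :class:`SelectionSpec`.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BACKBONE_NAMES",
    "StructureModel",
    "SelectionSpec",
    "Ensemble",
    "ModelError",
    "SelectionError",
]

#: Atom names making up the peptide backbone (standard convention).
BACKBONE_NAMES = ("N", "CA", "C", "O")

#: Default masses for the elements the synthetic systems use.
_ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}


class ModelError(ValueError):
    """Raised for inconsistent topology input."""


class SelectionError(ValueError):
    """Raised when a selection does not resolve to a usable atom set."""


class StructureModel:
    """Atoms grouped into residues with chain (subunit) labels.

    Parameters
    ----------
    atom_names, atom_elements :
        Per-atom name (e.g. ``CA``) and element symbol.
    atom_residue :
        Per-atom index into the residue tables (0-based, positional).
    residue_names, residue_ids, residue_chains :
        Per-residue name, author numbering and chain/subunit tag.
    atom_masses :
        Optional per-atom masses; derived from the element when omitted.
    """

    def __init__(
        self,
        atom_names: Sequence[str],
        atom_elements: Sequence[str],
        atom_residue: Sequence[int],
        residue_names: Sequence[str],
        residue_ids: Sequence[int],
        residue_chains: Sequence[str],
        atom_masses: Sequence[float] | None = None,
    ) -> None:
        self.atom_names = np.asarray(atom_names, dtype=object)
        self.atom_elements = np.asarray(atom_elements, dtype=object)
        self.atom_residue = np.asarray(atom_residue, dtype=np.intp)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.residue_ids = np.asarray(residue_ids, dtype=np.int64)
        self.residue_chains = np.asarray(residue_chains, dtype=object)
        if atom_masses is None:
            atom_masses = [
                _ELEMENT_MASSES.get(str(e).upper(), 12.0) for e in self.atom_elements
            ]
        self.atom_masses = np.asarray(atom_masses, dtype=np.float64)
        self._validate()

    # -- invariants ------------------------------------------------------
    def _validate(self) -> None:
        n_at = len(self.atom_names)
        if not (
            len(self.atom_elements)
            == len(self.atom_residue)
            == len(self.atom_masses)
            == n_at
        ):
            raise ModelError("per-atom arrays have inconsistent lengths")
        n_res = len(self.residue_names)
        if not (len(self.residue_ids) == len(self.residue_chains) == n_res):
            raise ModelError("per-residue arrays have inconsistent lengths")
        if n_at == 0 or n_res == 0:
            raise ModelError("empty structure")
        if self.atom_residue.min() < 0 or self.atom_residue.max() >= n_res:
            raise ModelError("atom_residue indices out of range")
        # residue indices contiguous per chain (atoms ordered by residue)
        if np.any(np.diff(self.atom_residue) < 0):
            raise ModelError("atoms must be ordered by residue")

    # -- basic queries ---------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    @property
    def is_heavy(self) -> np.ndarray:
        """Boolean per-atom mask, true for non-hydrogen atoms."""
        return np.array([str(e).upper() != "H" for e in self.atom_elements])

    def residue_atoms(self, residue: int) -> np.ndarray:
        """Atom indices belonging to one residue (positional index)."""
        return np.nonzero(self.atom_residue == residue)[0]

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.residue_chains:
            seen.setdefault(str(c))
        return list(seen)

    # -- selections ------------------------------------------------------
    def select(self, spec: "SelectionSpec | str") -> np.ndarray:
        """Resolve a selection to a sorted, duplicate-free atom index array."""
        if isinstance(spec, str):
            spec = SelectionSpec(atom_class=spec)
        mask = np.ones(self.n_atoms, dtype=bool)
        res_of_atom = self.atom_residue
        if spec.chain is not None:
            chain_mask = self.residue_chains == spec.chain
            mask &= chain_mask[res_of_atom]
        if spec.residues is not None:
            residues = np.asarray(sorted(set(int(r) for r in spec.residues)))
            if residues.size and (
                residues.min() < 0 or residues.max() >= self.n_residues
            ):
                raise SelectionError("residue index out of range")
            res_mask = np.zeros(self.n_residues, dtype=bool)
            res_mask[residues] = True
            mask &= res_mask[res_of_atom]
        cls = spec.atom_class
        if cls == "all":
            pass
        elif cls == "heavy":
            mask &= self.is_heavy
        elif cls == "backbone":
            mask &= np.isin(self.atom_names, BACKBONE_NAMES)
        elif cls in ("ca", "CA"):
            mask &= self.atom_names == "CA"
        else:
            raise SelectionError(f"unknown atom class {cls!r}")
        if spec.atom_names is not None:
            mask &= np.isin(self.atom_names, list(spec.atom_names))
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise SelectionError(f"selection {spec} resolves to no atoms")
        return idx

    def residues_of(self, atom_indices: np.ndarray) -> np.ndarray:
        """Sorted unique residue indices covered by an atom index set."""
        return np.unique(self.atom_residue[np.asarray(atom_indices)])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<StructureModel {self.n_residues} residues / {self.n_atoms} atoms, "
            f"chains {self.chains()}>"
        )


@dataclass(frozen=True)
class SelectionSpec:
    """Declarative atom selection over chain tag, residues and atom class.

    ``atom_class`` is one of ``all``, ``heavy``, ``backbone``, ``ca``;
    ``atom_names`` further restricts to explicit atom names.
    ``residues`` are 0-based positional residue indices.
    """

    chain: str | None = None
    residues: tuple[int, ...] | None = None
    atom_class: str = "all"
    atom_names: tuple[str, ...] | None = None

    @staticmethod
    def backbone(chain: str | None = None) -> "SelectionSpec":
        return SelectionSpec(chain=chain, atom_class="backbone")

    @staticmethod
    def calpha(chain: str | None = None) -> "SelectionSpec":
        return SelectionSpec(chain=chain, atom_class="ca")


@dataclass
class Ensemble:
    """Ordered coordinate frames (angstrom) for one replica of one state."""

    structure: StructureModel
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    frame_stride: float = 1.0  # time per frame, arbitrary units
    replica_id: int = 0
    state_label: str = "custom"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ModelError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.structure.n_atoms:
            raise ModelError(
                f"coords have {self.coords.shape[1]} atoms, structure has "
                f"{self.structure.n_atoms}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ModelError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def window(self, start: int | None = None, stop: int | None = None) -> "Ensemble":
        """Half-open frame-index window ``[start, stop)`` as a new Ensemble."""
        start = 0 if start is None else int(start)
        stop = self.n_frames if stop is None else int(stop)
        if start < 0:
            start += self.n_frames
        if stop < 0:
            stop += self.n_frames
        if not (0 <= start < stop <= self.n_frames):
            raise ValueError(f"empty or invalid window [{start}, {stop})")
        return replace(self, coords=self.coords[start:stop])

    def last_fraction(self, fraction: float) -> "Ensemble":
        """Trailing fraction of the trajectory (e.g. 0.5 = 'last half')."""
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        n = max(1, int(round(self.n_frames * fraction)))
        return self.window(self.n_frames - n, self.n_frames)

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]


def concatenate(ensembles: Iterable[Ensemble]) -> Ensemble:
    """Stack several ensembles (same structure) into one frame sequence."""
    ensembles = list(ensembles)
    if not ensembles:
        raise ValueError("no ensembles to concatenate")
    first = ensembles[0]
    for e in ensembles[1:]:
        if e.structure.n_atoms != first.structure.n_atoms:
            raise ModelError("ensembles have mismatched atom counts")
    coords = np.concatenate([e.coords for e in ensembles], axis=0)
    return replace(first, coords=coords)
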