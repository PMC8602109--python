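"""Structure/trajectory I/O backed by MDAnalysis.

PDB files carry topology and reference coordinates; trajectories may be
DCD, XTC or multi-model PDB.  MDAnalysis normalizes units on read (XTC
nanometres become angstrom), so every Ensemble in memory is in angstrom.
"""
from __future__ import annotations

import warnings

import numpy as np

from .model import Ensemble, ModelError, StructureModel

__all__ = [
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "make_universe",
]


def _mda():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


def _guess_element(name: str) -> str:
    stripped = name.strip()
    for ch in stripped:
        if ch.isalpha():
            # two-letter guesses are not needed for the fixtures used here
            return ch.upper()
    return "C"


def read_structure(path, chain_map: dict[str, str] | None = None) -> StructureModel:
    """Read a PDB into a StructureModel.

    ``chain_map`` renames chain identifiers to subunit tags (e.g.
    ``{"A": "alpha"}``).  HETATM records are retained as their own
    residues; hydrogens are flagged non-heavy via the element.
    """
    mda = _mda()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    atoms = u.atoms
    if not hasattr(atoms, "positions"):
        raise ModelError("file has no coordinates")
    try:
        elements = [str(e) if str(e).strip() else _guess_element(n)
                    for e, n in zip(atoms.elements, atoms.names)]
    except Exception:
        elements = [_guess_element(n) for n in atoms.names]
    residues = u.residues
    try:
        # chainIDs is a per-atom attribute; take each residue's first atom
        chains = [str(res.atoms.chainIDs[0]) for res in residues]
    except Exception:
        chains = [str(s) for s in residues.segids]
    if chain_map:
        chains = [chain_map.get(c, c) for c in chains]
    return StructureModel(
        atom_names=[str(n) for n in atoms.names],
        atom_elements=elements,
        atom_residue=atoms.resindices,
        residue_names=[str(n) for n in residues.resnames],
        residue_ids=residues.resids,
        residue_chains=chains,
    )


def make_universe(structure: StructureModel, coords: np.ndarray | None = None):
    """Build an in-memory MDAnalysis Universe mirroring a StructureModel."""
    mda = _mda()
    n_res = structure.n_residues
    u = mda.Universe.empty(
        n_atoms=structure.n_atoms,
        n_residues=n_res,
        n_segments=len(structure.chains()),
        atom_resindex=structure.atom_residue,
        residue_segindex=[
            structure.chains().index(str(c)) for c in structure.residue_chains
        ],
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(n) for n in structure.atom_names])
    u.add_TopologyAttr("elements", [str(e) for e in structure.atom_elements])
    u.add_TopologyAttr("masses", structure.atom_masses)
    u.add_TopologyAttr("resnames", [str(n) for n in structure.residue_names])
    u.add_TopologyAttr("resids", structure.residue_ids)
    u.add_TopologyAttr("segids", structure.chains())
    u.add_TopologyAttr(
        "chainIDs",
        [str(structure.residue_chains[r])[:1] for r in structure.atom_residue],
    )
    if coords is not None:
        u.atoms.positions = np.asarray(coords, dtype=np.float32)
    return u


def read_trajectory(
    structure: StructureModel,
    path,
    replica_id: int = 0,
    state_label: str = "custom",
    frame_stride: float = 1.0,
) -> Ensemble:
    """Read a DCD/XTC/multi-model-PDB trajectory against a topology."""
    u = make_universe(structure)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.load_new(str(path))
    if u.atoms.n_atoms != structure.n_atoms:
        raise ModelError("trajectory atom count does not match structure")
    frames = [u.atoms.positions.astype(np.float64).copy() for _ in u.trajectory]
    if not frames:
        raise ModelError("trajectory contains no frames")
    return Ensemble(
        structure=structure,
        coords=np.stack(frames),
        frame_stride=frame_stride,
        replica_id=replica_id,
        state_label=state_label,
    )


def write_structure(structure: StructureModel, coords: np.ndarray, path) -> None:
    """Write one frame as PDB."""
    u = make_universe(structure, coords)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory(ensemble: Ensemble, path) -> None:
    """Write all frames as DCD, XTC or multi-model PDB (by extension)."""
    mda = _mda()
    u = make_universe(ensemble.structure, ensemble.coords[0])
    path = str(path)
    kwargs = {"multiframe": True} if path.lower().endswith(".pdb") else {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(path, n_atoms=ensemble.n_atoms, **kwargs) as w:
            for frame in ensemble.coords:
                u.atoms.positions = frame.astype(np.float32)
                w.write(u.atoms)
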