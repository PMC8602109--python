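"""Synthetic backbone ensembles with analytically known dynamics.

Every downstream analysis stage is validated against ensembles generated
here, because their covariance structure, contact rearrangements,
communication chains and conformer mixtures are planted by construction:

* :func:`make_gaussian_ensemble` — frames drawn from a low-rank Gaussian
  model ``reference + sum_k sqrt(lam_k) z_k v_k + noise``;
* :func:`make_two_state_pair` — a base ensemble and a copy with a residue
  block rigidly displaced (ground truth for perturbation networks);
* :func:`make_conformer_mixture` — discrete conformer mixture with known
  per-frame labels (ground truth for clustering);
* :func:`make_chain_spec` — a planted residue communication chain with a
  squared-exponential correlation profile, so the chain is the strictly
  optimal ``-log|C|`` path between its endpoints;
* :func:`analytic_dcc` — closed-form per-residue cross-correlation of a
  Gaussian spec, the independent oracle for the trajectory-based DCC.

Residues are miniature: a configurable number of pseudo-atoms (default 3,
one CA plus two side-chain heavy atoms; with >= 4 atoms per residue the
first four are named N, CA, C, O so backbone selections resolve too).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dcc import DccMatrix
from .model import Ensemble, ModelError, StructureModel

__all__ = [
    "GaussianEnsembleSpec",
    "TwoStateContactSpec",
    "ConformerMixtureSpec",
    "linear_structure",
    "make_gaussian_ensemble",
    "analytic_dcc",
    "make_two_state_pair",
    "static_contact_difference",
    "make_conformer_mixture",
    "spec_from_covariance",
    "residue_mode",
    "make_chain_spec",
    "SpecError",
]


class SpecError(ValueError):
    """Raised for invalid synthetic specs (e.g. non-orthonormal modes)."""


# --------------------------------------------------------------------------
# structure scaffolds
# --------------------------------------------------------------------------

def linear_structure(
    n_residues: int,
    atoms_per_residue: int = 3,
    spacing: float = 4.0,
    chain_split: int | None = None,
) -> tuple[StructureModel, np.ndarray]:
    """A miniature poly-residue chain laid out along x.

    Consecutive residues sit ``spacing`` angstrom apart, so with the
    default 4 A spacing every sequence-adjacent residue pair is in 5 A
    contact and non-adjacent pairs are not.  ``chain_split`` assigns
    residues ``[0, chain_split)`` to subunit tag ``"A"`` and the rest to
    ``"B"``; default is a single chain ``"A"``.

    Returns the :class:`StructureModel` and the reference coordinates.
    """
    if n_residues < 1 or atoms_per_residue < 1:
        raise SpecError("need at least one residue and one atom per residue")
    if atoms_per_residue >= 4:
        base_names = ["N", "CA", "C", "O"] + [
            f"CB{i}" for i in range(atoms_per_residue - 4)
        ]
        base_elems = ["N", "C", "C", "O"] + ["C"] * (atoms_per_residue - 4)
    else:
        base_names = ["CA", "CB", "CG"][:atoms_per_residue]
        base_elems = ["C"] * atoms_per_residue
    # local offsets keep all atoms of a residue within ~1.3 A of its CA
    local = np.array(
        [
            [0.0, 0.0, 0.0],
            [0.0, 1.2, 0.0],
            [0.0, 0.0, 1.2],
            [0.0, -1.2, 0.0],
            [0.0, 0.0, -1.2],
            [0.0, 0.85, 0.85],
        ]
    )
    if atoms_per_residue > len(local):
        raise SpecError("atoms_per_residue too large for the scaffold")
    atom_names: list[str] = []
    atom_elems: list[str] = []
    atom_residue: list[int] = []
    coords = np.empty((n_residues * atoms_per_residue, 3))
    for r in range(n_residues):
        for a in range(atoms_per_residue):
            atom_names.append(base_names[a])
            atom_elems.append(base_elems[a])
            atom_residue.append(r)
            coords[r * atoms_per_residue + a] = [r * spacing, 0.0, 0.0] + local[a]
    split = n_residues if chain_split is None else int(chain_split)
    chains = ["A" if r < split else "B" for r in range(n_residues)]
    structure = StructureModel(
        atom_names=atom_names,
        atom_elements=atom_elems,
        atom_residue=atom_residue,
        residue_names=["GLY"] * n_residues,
        residue_ids=list(range(1, n_residues + 1)),
        residue_chains=chains,
    )
    return structure, coords


def _rep_atoms(structure: StructureModel) -> np.ndarray:
    """One representative atom per residue: the CA, else the first atom."""
    reps = np.empty(structure.n_residues, dtype=np.intp)
    for r in range(structure.n_residues):
        atoms = structure.residue_atoms(r)
        named_ca = atoms[structure.atom_names[atoms] == "CA"]
        reps[r] = named_ca[0] if named_ca.size else atoms[0]
    return reps


# --------------------------------------------------------------------------
# Gaussian ensembles
# --------------------------------------------------------------------------

@dataclass
class GaussianEnsembleSpec:
    """Low-rank Gaussian fluctuation model around a reference frame.

    ``modes`` is a sequence of ``(direction, amplitude)`` pairs where each
    direction is a unit 3N vector over all atoms and the amplitude is the
    mode variance (A^2).  Directions must be mutually orthonormal and the
    amplitudes positive and non-increasing.  ``noise_sigma`` adds
    independent isotropic per-coordinate noise.
    """

    structure: StructureModel
    reference_coords: np.ndarray
    modes: tuple[tuple[np.ndarray, float], ...] = ()
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.reference_coords = np.asarray(self.reference_coords, dtype=np.float64)
        if self.reference_coords.shape != (self.structure.n_atoms, 3):
            raise SpecError("reference_coords shape mismatch with structure")
        self.modes = tuple(
            (np.asarray(v, dtype=np.float64).ravel(), float(lam))
            for v, lam in self.modes
        )
        dim = 3 * self.structure.n_atoms
        lams = [lam for _, lam in self.modes]
        if any(lam <= 0 for lam in lams):
            raise SpecError("mode amplitudes must be positive")
        if any(b > a + 1e-12 for a, b in zip(lams, lams[1:])):
            raise SpecError("mode amplitudes must be non-increasing")
        if self.noise_sigma < 0:
            raise SpecError("noise_sigma must be >= 0")
        if self.modes:
            V = np.stack([v for v, _ in self.modes], axis=1)
            if V.shape[0] != dim:
                raise SpecError("mode vectors must have length 3*n_atoms")
            gram = V.T @ V
            if not np.allclose(gram, np.eye(V.shape[1]), atol=1e-8):
                raise SpecError("mode direction-fields must be orthonormal")

    @property
    def n_residues(self) -> int:
        return self.structure.n_residues

    @property
    def atoms_per_residue(self) -> int:
        return self.structure.n_atoms // self.structure.n_residues

    def model_covariance(self) -> np.ndarray:
        """Dense 3N x 3N covariance implied by the spec."""
        dim = 3 * self.structure.n_atoms
        cov = (self.noise_sigma ** 2) * np.eye(dim)
        for v, lam in self.modes:
            cov += lam * np.outer(v, v)
        return cov


def _sample_gaussian(
    spec: GaussianEnsembleSpec, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    dim = 3 * spec.structure.n_atoms
    disp = np.zeros((n_frames, dim))
    if spec.modes:
        V = np.stack([v for v, _ in spec.modes], axis=1)
        scale = np.sqrt(np.array([lam for _, lam in spec.modes]))
        z = rng.standard_normal((n_frames, len(spec.modes)))
        disp += (z * scale) @ V.T
    if spec.noise_sigma > 0:
        disp += spec.noise_sigma * rng.standard_normal((n_frames, dim))
    return spec.reference_coords[None] + disp.reshape(n_frames, -1, 3)


def make_gaussian_ensemble(
    spec: GaussianEnsembleSpec,
    n_frames: int,
    seed: int,
    replica_id: int = 0,
    state_label: str = "custom",
) -> Ensemble:
    """Draw an ensemble from the Gaussian spec; pure in (spec, n, seed)."""
    if n_frames < 2:
        raise SpecError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    coords = _sample_gaussian(spec, n_frames, rng)
    return Ensemble(
        structure=spec.structure,
        coords=coords,
        replica_id=replica_id,
        state_label=state_label,
    )


def analytic_dcc(spec: GaussianEnsembleSpec) -> DccMatrix:
    """Closed-form per-residue cross-correlation matrix of the spec.

    Restricted to one representative atom per residue (the CA), with
    ``C_ij = tr(Sigma_ij) / sqrt(tr(Sigma_ii) tr(Sigma_jj))`` where
    ``Sigma_ij`` is the 3x3 cross-covariance block of the model.
    """
    reps = _rep_atoms(spec.structure)
    n = len(reps)
    # trace of the 3x3 block between rep atoms i and j
    tr = np.zeros((n, n))
    for v, lam in spec.modes:
        comp = v.reshape(-1, 3)[reps]  # n x 3
        tr += lam * (comp @ comp.T)
    tr += np.eye(n) * 3.0 * spec.noise_sigma ** 2
    diag = np.diag(tr).copy()
    zero = np.nonzero(diag <= 0)[0]
    if zero.size:
        raise SpecError(
            f"residues with zero total variance: {zero.tolist()}"
        )
    denom = np.sqrt(np.outer(diag, diag))
    matrix = tr / denom
    np.fill_diagonal(matrix, 1.0)
    return DccMatrix(
        residue_indices=np.arange(n),
        matrix=matrix,
        meta={"source": "analytic"},
    )


def spec_from_covariance(
    structure: StructureModel,
    reference_coords: np.ndarray,
    covariance: np.ndarray,
    noise_sigma: float = 0.0,
    tol: float = 1e-10,
) -> GaussianEnsembleSpec:
    """Build a spec whose mode stack reproduces a target 3N covariance.

    The covariance is eigendecomposed; eigenpairs with eigenvalue below
    ``tol * max`` are dropped.  Isotropic noise is added on top (it is
    not part of the decomposed covariance).
    """
    cov = np.asarray(covariance, dtype=np.float64)
    dim = 3 * structure.n_atoms
    if cov.shape != (dim, dim):
        raise SpecError("covariance must be 3N x 3N")
    cov = 0.5 * (cov + cov.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    floor = tol * max(evals.max(), 1.0)
    keep = evals > floor
    modes = tuple(
        (evecs[:, i].copy(), float(evals[i])) for i in np.nonzero(keep)[0]
    )
    return GaussianEnsembleSpec(
        structure=structure,
        reference_coords=reference_coords,
        modes=modes,
        noise_sigma=noise_sigma,
    )


def residue_mode(
    structure: StructureModel,
    directions: dict[int, np.ndarray],
    atoms: str = "rep",
) -> np.ndarray:
    """Unit 3N mode vector moving whole residues along given directions.

    ``directions`` maps residue index to a 3-vector; ``atoms`` selects
    whether only the representative atom moves (``"rep"``) or all atoms
    of the residue move together (``"all"``).
    """
    vec = np.zeros((structure.n_atoms, 3))
    reps = _rep_atoms(structure)
    for res, d in directions.items():
        d = np.asarray(d, dtype=np.float64)
        targets = [reps[res]] if atoms == "rep" else structure.residue_atoms(res)
        for a in targets:
            vec[a] = d
    flat = vec.ravel()
    norm = np.linalg.norm(flat)
    if norm == 0:
        raise SpecError("mode has zero norm")
    return flat / norm


# --------------------------------------------------------------------------
# two-state contact rearrangement
# --------------------------------------------------------------------------

@dataclass
class TwoStateContactSpec:
    """Base ensemble plus a rigid block displacement defining state B."""

    base: GaussianEnsembleSpec
    displaced_block: tuple[int, ...]
    displacement: np.ndarray

    def __post_init__(self) -> None:
        self.displaced_block = tuple(sorted(set(int(r) for r in self.displaced_block)))
        self.displacement = np.asarray(self.displacement, dtype=np.float64)
        n_res = self.base.structure.n_residues
        if not self.displaced_block:
            raise SpecError("displaced_block must be non-empty")
        if len(self.displaced_block) >= n_res:
            raise SpecError("displaced_block must be a strict subset of residues")
        if min(self.displaced_block) < 0 or max(self.displaced_block) >= n_res:
            raise SpecError("displaced_block out of range")
        if self.displacement.shape != (3,):
            raise SpecError("displacement must be a 3-vector")

    def reference_b(self) -> np.ndarray:
        ref = self.base.reference_coords.copy()
        structure = self.base.structure
        for r in self.displaced_block:
            ref[structure.residue_atoms(r)] += self.displacement
        return ref


def make_two_state_pair(
    spec: TwoStateContactSpec, n_frames: int, seed: int
) -> tuple[Ensemble, Ensemble]:
    """Independent draws of state A (base) and state B (block displaced)."""
    if n_frames < 2:
        raise SpecError("n_frames must be >= 2")
    ss = np.random.SeedSequence(seed)
    child_a, child_b = ss.spawn(2)
    base = spec.base
    coords_a = _sample_gaussian(base, n_frames, np.random.default_rng(child_a))
    spec_b = GaussianEnsembleSpec(
        structure=base.structure,
        reference_coords=spec.reference_b(),
        modes=base.modes,
        noise_sigma=base.noise_sigma,
    )
    coords_b = _sample_gaussian(spec_b, n_frames, np.random.default_rng(child_b))
    ens_a = Ensemble(structure=base.structure, coords=coords_a, state_label="A")
    ens_b = Ensemble(structure=base.structure, coords=coords_b, state_label="B")
    return ens_a, ens_b


def static_contact_difference(
    spec: TwoStateContactSpec,
    cutoff: float = 5.0,
    exclude_bonded: int = 1,
) -> dict[tuple[int, int], float]:
    """Ground-truth contact-count changes (B minus A) from static geometry."""
    from .pertnet import contact_counts_frame

    a = contact_counts_frame(
        spec.base.reference_coords, spec.base.structure, cutoff, exclude_bonded
    )
    b = contact_counts_frame(
        spec.reference_b(), spec.base.structure, cutoff, exclude_bonded
    )
    diff: dict[tuple[int, int], float] = {}
    for key in set(a) | set(b):
        d = b.get(key, 0) - a.get(key, 0)
        if d != 0:
            diff[key] = float(d)
    return diff


# --------------------------------------------------------------------------
# conformer mixtures
# --------------------------------------------------------------------------

@dataclass
class ConformerMixtureSpec:
    """Discrete mixture of reference conformers with isotropic jitter."""

    structure: StructureModel
    conformers: tuple[np.ndarray, ...]
    weights: tuple[float, ...]
    jitter_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.conformers = tuple(
            np.asarray(c, dtype=np.float64) for c in self.conformers
        )
        if len(self.conformers) < 2:
            raise SpecError("need at least 2 conformers")
        for c in self.conformers:
            if c.shape != (self.structure.n_atoms, 3):
                raise SpecError("conformer shape mismatch with structure")
        self.weights = tuple(float(w) for w in self.weights)
        if len(self.weights) != len(self.conformers):
            raise SpecError("weights/conformers length mismatch")
        if any(w < 0 for w in self.weights) or abs(sum(self.weights) - 1) > 1e-9:
            raise SpecError("weights must be non-negative and sum to 1")
        if self.jitter_sigma < 0:
            raise SpecError("jitter_sigma must be >= 0")

    def min_pairwise_rmsd(self) -> float:
        from .geometry import rmsd

        vals = [
            rmsd(self.conformers[i], self.conformers[j])
            for i in range(len(self.conformers))
            for j in range(i + 1, len(self.conformers))
        ]
        return min(vals)

    def is_separable(self) -> bool:
        """Separability rule used by clustering test fixtures."""
        return self.min_pairwise_rmsd() > 3 * self.jitter_sigma


def make_conformer_mixture(
    spec: ConformerMixtureSpec, n_frames: int, seed: int
) -> tuple[Ensemble, np.ndarray]:
    """Sample frames from the mixture; returns ground-truth labels too."""
    m = len(spec.conformers)
    if n_frames < m:
        raise SpecError("n_frames must be >= number of conformers")
    rng = np.random.default_rng(seed)
    labels = rng.choice(m, size=n_frames, p=np.asarray(spec.weights))
    stack = np.stack(spec.conformers)
    coords = stack[labels].astype(np.float64)
    if spec.jitter_sigma > 0:
        coords = coords + spec.jitter_sigma * rng.standard_normal(coords.shape)
    ens = Ensemble(structure=spec.structure, coords=coords, state_label="mixture")
    return ens, labels


# --------------------------------------------------------------------------
# planted communication chain
# --------------------------------------------------------------------------

def make_chain_spec(
    structure: StructureModel,
    reference_coords: np.ndarray,
    chain_residues: list[int],
    corr: float = 0.9,
    amplitude: float = 1.0,
    noise_sigma: float = 0.05,
    axis: int = 1,
) -> GaussianEnsembleSpec:
    """Plant a communication chain with squared-exponential correlations.

    The representative atoms of the chain residues move along one axis
    with correlation ``corr ** (step**2)`` between chain positions, a
    positive-definite profile whose pairwise ``-log|C|`` edge weights make
    the consecutive chain the strictly cheapest path between the chain
    endpoints (a skip of s residues costs ~ s^2 unit steps).
    """
    if not 0 < corr < 1:
        raise SpecError("corr must be in (0, 1)")
    chain = [int(r) for r in chain_residues]
    if len(chain) < 2 or len(set(chain)) != len(chain):
        raise SpecError("chain must list >= 2 distinct residues")
    pos = np.arange(len(chain), dtype=np.float64)
    K = amplitude * corr ** ((pos[:, None] - pos[None, :]) ** 2)
    reps = _rep_atoms(structure)
    dim = 3 * structure.n_atoms
    cov = np.zeros((dim, dim))
    flat = [3 * reps[r] + axis for r in chain]
    for a, ia in enumerate(flat):
        for b, ib in enumerate(flat):
            cov[ia, ib] = K[a, b]
    return spec_from_covariance(
        structure, reference_coords, cov, noise_sigma=noise_sigma
    )
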