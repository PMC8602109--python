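import numpy as np
import pytest

from mdcompare import (
    GaussianEnsembleSpec,
    SelectionSpec,
    StructureModel,
    linear_structure,
    residue_mode,
)


@pytest.fixture
def small_structure():
    structure, ref = linear_structure(n_residues=6, atoms_per_residue=3)
    return structure, ref


@pytest.fixture
def backbone_structure():
    # 4 atoms per residue -> N, CA, C, O so backbone selections resolve
    structure, ref = linear_structure(n_residues=8, atoms_per_residue=4, chain_split=4)
    return structure, ref


@pytest.fixture
def noise_spec(small_structure):
    structure, ref = small_structure
    return GaussianEnsembleSpec(
        structure=structure, reference_coords=ref, noise_sigma=0.2
    )


@pytest.fixture
def one_mode_spec(small_structure):
    """Single planted mode moving residues 1 and 4 together along y."""
    structure, ref = small_structure
    v = residue_mode(structure, {1: [0, 1, 0], 4: [0, 1, 0]})
    return GaussianEnsembleSpec(
        structure=structure,
        reference_coords=ref,
        modes=((v, 1.0),),
        noise_sigma=0.0,
    )


def two_residue_toy():
    """Two 2-atom residues with hand-placed coordinates.

    Heavy-atom pair distances (res0 x res1):
      a-c = 4.0, a-d = 4.940..., b-c = 5.0 (exactly), b-d = 4.00125...
    so exactly 3 pairs satisfy the strict < 5 A contact condition.
    """
    structure = StructureModel(
        atom_names=["CA", "CB", "CA", "CB"],
        atom_elements=["C", "C", "C", "C"],
        atom_residue=[0, 0, 1, 1],
        residue_names=["GLY", "GLY"],
        residue_ids=[1, 2],
        residue_chains=["A", "A"],
    )
    coords = np.array(
        [
            [0.0, 0.0, 0.0],  # a
            [0.0, 0.0, 3.0],  # b
            [4.0, 0.0, 0.0],  # c
            [4.0, 0.0, 2.9],  # d
        ]
    )
    return structure, coords
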