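import numpy as np
import pytest

from wsilk.io import Model
from wsilk.synthetic import ALPHA_PHI, ALPHA_PSI, _build_backbone

BACKBONE = ("N", "CA", "C", "O")


def backbone_model(coords, first_residue=1, residue_names=None):
    """Wrap an (n_res, 4, 3) backbone coordinate block into a Model."""
    n_res = coords.shape[0]
    atom_name = np.tile(np.array(BACKBONE), n_res)
    residue_number = np.repeat(np.arange(first_residue, first_residue + n_res), 4)
    if residue_names is None:
        residue_names = ["GLY"] * n_res
    residue_name = np.repeat(np.array(residue_names), 4)
    element = np.tile(np.array(["N", "C", "C", "O"]), n_res)
    return Model(
        coords=coords.reshape(-1, 3),
        atom_name=atom_name,
        residue_number=residue_number,
        residue_name=residue_name,
        chain_id=np.full(4 * n_res, "A"),
        element=element,
    )


@pytest.fixture(scope="session")
def ideal_helix_model():
    """20-residue ideal α-helix (φ = -57°, ψ = -47°), backbone only."""
    n = 20
    coords = _build_backbone(np.full(n, ALPHA_PHI), np.full(n, ALPHA_PSI))
    return backbone_model(coords)


@pytest.fixture(scope="session")
def extended_model():
    """20-residue fully extended chain (φ = ψ = 180°)."""
    n = 20
    coords = _build_backbone(np.full(n, 180.0), np.full(n, 180.0))
    return backbone_model(coords)


@pytest.fixture(scope="session")
def small_ensemble():
    """Seeded 4-model beads-on-a-string ensemble of one W unit."""
    from wsilk.synthetic import gen_beads_on_string_ensemble

    return gen_beads_on_string_ensemble(seed=11, n_models=4)


TOY_PDB = """\
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       0.100   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.558   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.100   1.400   0.000  1.00  0.00           C
ENDMDL
END
"""

SINGLE_MODEL_PDB = """\
ATOM      1  N   GLY A   5       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   5       1.458   0.000   0.000  1.00  0.00           C
END
"""

RAGGED_PDB = """\
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ENDMDL
END
"""
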