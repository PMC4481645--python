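"""Benchmark of structural metrics against the deposited W-unit ensemble.

Runs the package's superposition, secondary-structure and dihedral
analyses on a locally available copy of the deposited 20-model ensemble
(PDB 2MU3) and reports the quantities published with it: pairwise core
r.m.s.d., helix/strand percentages and the α-region φ/ψ fraction of the
non-canonical 40-60 stretch.  The coordinate file is not distributed with
the package; download ``2MU3.pdb`` from the wwPDB and pass its path.
"""

from __future__ import annotations

from . import reference_data as ref
from .io import read_pdb_ensemble
from .metrics import ensemble_alpha_fraction, ensemble_rmsd, ss_fractions

__all__ = ["deposited_ensemble_report"]


def deposited_ensemble_report(pdb_path) -> dict:
    """Compute the published ensemble statistics from a local 2MU3 file."""
    ensemble = read_pdb_ensemble(pdb_path)
    bb_mean, bb_sd = ensemble_rmsd(
        ensemble, atom_class="backbone", residue_range=ref.RMSD_CORE, mode="pairwise"
    )
    hv_mean, hv_sd = ensemble_rmsd(
        ensemble, atom_class="heavy", residue_range=ref.RMSD_CORE, mode="pairwise"
    )
    fractions = ss_fractions(ensemble)
    alpha_40_60 = ensemble_alpha_fraction(ensemble, (40, 60))
    return {
        "n_models": ensemble.n_models,
        "pairwise_backbone_rmsd_A": (bb_mean, bb_sd),
        "pairwise_heavy_rmsd_A": (hv_mean, hv_sd),
        "helix_percent": fractions["H"],
        "strand_percent": fractions["E"],
        "alpha_fraction_40_60_percent": alpha_40_60,
    }
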