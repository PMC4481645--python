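"""Published reference statistics for the AcSp1 W-unit NMR ensemble.

Values are those reported alongside the deposited 20-member solution
ensemble of the Argiope trifasciata aciniform spidroin repeat unit
(PDB 2MU3; assignments BMRB 17899/25197).  They serve as benchmark targets
and internal-consistency checks, never as computed results.
"""

from __future__ import annotations

PDB_ACCESSION = "2MU3"
BMRB_ACCESSIONS = ("17899", "25197")

W1_LENGTH = 199
CORE_RESIDUES = (12, 149)
RMSD_CORE = (12, 140)  # superposition range used for the r.m.s.d. statistic
HELIX5 = (135, 149)

# NOE distance restraint census of the final refinement
RESTRAINT_COUNTS = {
    "total_noe": 5241,
    "intra": 1470,
    "sequential": 1368,
    "medium": 908,
    "long": 846,
    "ambiguous": 649,
    "hydrogen_bond": 25,
    "dihedral_total": 201,
    "phi": 107,
    "psi": 94,
}

# ensemble violation statistics (mean, s.d.)
VIOLATION_STATS = {
    "distance_A": (0.07, 0.05),
    "dihedral_deg": (1.22, 1.01),
    "max_dihedral_deg": (4.38, 1.20),
    "max_distance_A": (0.49, 0.16),
}

# average pairwise r.m.s.d. over the 12-140 core of the 20-member ensemble
PAIRWISE_RMSD = {
    "backbone_A": (0.88, 0.18),
    "heavy_A": (1.32, 0.15),
}

# secondary structure of the soluble state (ensemble) and of drawn fibres,
# percent; fibre values from amide I Raman decomposition, uncertainty ±3
SECONDARY_STRUCTURE = {
    "dope_alpha": 40.0,
    "dope_beta": 0.0,
    "fibre_alpha": 32.0,
    "fibre_beta": 28.0,
    "uncertainty": 3.0,
}

# fraction of residues 40-60 with α-region φ/ψ over the ensemble (~65%)
ALPHA_FRACTION_40_60 = 65.0

# two-unit concatemer fibre tensile metrics (mean, s.d.), non-spliced
TENSILE_W2 = {
    "breaking_strength_MPa": (66.7, 15.8),
    "breaking_strain": (0.31, 0.11),
    "toughness_J_per_cm3": (18.4, 10.4),
    "youngs_modulus_GPa": (1.69, 0.68),
}
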