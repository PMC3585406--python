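"""Bundled atomic parameter tables.

A deliberately small, documented parameter set: van der Waals radii
(Bondi-style), a coarse partial-charge assignment that reproduces formal
side-chain charges and the backbone amide dipole, and per-residue maximum
solvent-accessible areas (Gly-X-Gly reference) for relative SASA.
"""

from __future__ import annotations

# --- van der Waals radii, Angstrom (Bondi-style, H slightly reduced) -------
VDW_RADII = {
    "H": 1.10,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}
VDW_DEFAULT = 1.70

# --- coarse partial charges (e) ---------------------------------------------
# Backbone amide dipole + formal charges on ionizable side-chain termini.
# Neutral residues sum to 0; Asp/Glu to -1; Lys/Arg to +1; His neutral.
BACKBONE_CHARGES = {"N": -0.30, "H": 0.30, "C": 0.50, "O": -0.50}

SIDECHAIN_CHARGES = {
    "ASP": {"OD1": -0.50, "OD2": -0.50},
    "GLU": {"OE1": -0.50, "OE2": -0.50},
    "LYS": {"NZ": 1.00},
    "ARG": {"NH1": 0.50, "NH2": 0.50},
    # polar but neutral groups carry a small dipole
    "SER": {"OG": -0.40, "HG": 0.40},
    "THR": {"OG1": -0.40, "HG1": 0.40},
    "TYR": {"OH": -0.40, "HH": 0.40},
    "ASN": {"OD1": -0.40, "ND2": 0.40},
    "GLN": {"OE1": -0.40, "NE2": 0.40},
    "HIS": {"ND1": -0.20, "NE2": 0.20},
    "CYS": {"SG": -0.10, "HG": 0.10},
    "TRP": {"NE1": 0.0},
}

# --- Gly-X-Gly maximum accessible areas, Angstrom^2 (Tien et al. style) -----
MAX_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET21 = AMINO_ACIDS + GAP  # gap treated as a 21st symbol


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper().strip(), VDW_DEFAULT)


def partial_charge(res_name: str, atom_name: str) -> float:
    """Coarse partial charge for a named atom of a named residue."""
    if atom_name in BACKBONE_CHARGES:
        return BACKBONE_CHARGES[atom_name]
    return SIDECHAIN_CHARGES.get(res_name, {}).get(atom_name, 0.0)
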