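"""Amino-acid templates: bonds, idealised side-chain internal coordinates,
chi-angle definitions, hydrogen counts and protonation bookkeeping.

Side-chain template rows are internal-coordinate placements
``(name, bond_ref, angle_ref, dihedral_ref, r, theta, tau)`` where ``tau`` is
either a number (degrees) or ``("chi", k, offset)`` meaning "the k-th
side-chain torsion plus a fixed offset".  The first row of every template
places CB from the backbone frame (CA, N, C); the +122.5 degree branch
dihedral yields L-configuration at CA.
"""

BACKBONE_BONDS = [("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "OXT")]

SIDECHAIN_BONDS = {
    "ALA": [("CA", "CB")],
    "ARG": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"),
            ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")],
    "ASN": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "ASP": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "CYS": [("CA", "CB"), ("CB", "SG")],
    "GLN": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "NE2")],
    "GLU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")],
    "GLY": [],
    "HIS": [("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"),
            ("ND1", "CE1"), ("CD2", "NE2"), ("CE1", "NE2")],
    "ILE": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "LEU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "LYS": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ")],
    "MET": [("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PHE": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
    "PRO": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "SER": [("CA", "CB"), ("CB", "OG")],
    "THR": [("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")],
    "TRP": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "NE1"), ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"),
            ("CE2", "CZ2"), ("CZ2", "CH2"), ("CE3", "CZ3"), ("CZ3", "CH2")],
    "TYR": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"),
            ("CZ", "OH")],
    "VAL": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")],
}

_CB = ("CB", "CA", "N", "C", 1.526, 110.5, 122.5)

SIDECHAIN_TEMPLATES = {
    "GLY": [],
    "ALA": [_CB],
    "SER": [_CB, ("OG", "CB", "CA", "N", 1.417, 110.8, ("chi", 1, 0.0))],
    "CYS": [_CB, ("SG", "CB", "CA", "N", 1.808, 114.4, ("chi", 1, 0.0))],
    "THR": [("CB", "CA", "N", "C", 1.540, 111.5, 122.5),
            ("OG1", "CB", "CA", "N", 1.433, 109.6, ("chi", 1, 0.0)),
            ("CG2", "CB", "CA", "N", 1.521, 110.5, ("chi", 1, -120.0))],
    "VAL": [("CB", "CA", "N", "C", 1.540, 111.5, 122.5),
            ("CG1", "CB", "CA", "N", 1.521, 110.5, ("chi", 1, 0.0)),
            ("CG2", "CB", "CA", "N", 1.521, 110.5, ("chi", 1, -120.0))],
    "LEU": [_CB, ("CG", "CB", "CA", "N", 1.530, 116.3, ("chi", 1, 0.0)),
            ("CD1", "CG", "CB", "CA", 1.521, 110.7, ("chi", 2, 0.0)),
            ("CD2", "CG", "CB", "CA", 1.521, 110.7, ("chi", 2, 120.0))],
    "ILE": [("CB", "CA", "N", "C", 1.540, 111.5, 122.5),
            ("CG1", "CB", "CA", "N", 1.530, 110.4, ("chi", 1, 0.0)),
            ("CG2", "CB", "CA", "N", 1.521, 110.5, ("chi", 1, -120.0)),
            ("CD1", "CG1", "CB", "CA", 1.513, 113.8, ("chi", 2, 0.0))],
    "MET": [_CB, ("CG", "CB", "CA", "N", 1.520, 114.1, ("chi", 1, 0.0)),
            ("SD", "CG", "CB", "CA", 1.803, 112.7, ("chi", 2, 0.0)),
            ("CE", "SD", "CG", "CB", 1.791, 100.9, ("chi", 3, 0.0))],
    "ASP": [_CB, ("CG", "CB", "CA", "N", 1.516, 112.6, ("chi", 1, 0.0)),
            ("OD1", "CG", "CB", "CA", 1.249, 118.4, ("chi", 2, 0.0)),
            ("OD2", "CG", "CB", "CA", 1.249, 118.4, ("chi", 2, 180.0))],
    "ASN": [_CB, ("CG", "CB", "CA", "N", 1.516, 112.6, ("chi", 1, 0.0)),
            ("OD1", "CG", "CB", "CA", 1.231, 120.8, ("chi", 2, 0.0)),
            ("ND2", "CG", "CB", "CA", 1.328, 116.4, ("chi", 2, 180.0))],
    "GLU": [_CB, ("CG", "CB", "CA", "N", 1.526, 114.1, ("chi", 1, 0.0)),
            ("CD", "CG", "CB", "CA", 1.516, 112.6, ("chi", 2, 0.0)),
            ("OE1", "CD", "CG", "CB", 1.249, 118.4, ("chi", 3, 0.0)),
            ("OE2", "CD", "CG", "CB", 1.249, 118.4, ("chi", 3, 180.0))],
    "GLN": [_CB, ("CG", "CB", "CA", "N", 1.526, 114.1, ("chi", 1, 0.0)),
            ("CD", "CG", "CB", "CA", 1.516, 112.6, ("chi", 2, 0.0)),
            ("OE1", "CD", "CG", "CB", 1.231, 120.8, ("chi", 3, 0.0)),
            ("NE2", "CD", "CG", "CB", 1.328, 116.4, ("chi", 3, 180.0))],
    "LYS": [_CB, ("CG", "CB", "CA", "N", 1.526, 114.1, ("chi", 1, 0.0)),
            ("CD", "CG", "CB", "CA", 1.526, 111.3, ("chi", 2, 0.0)),
            ("CE", "CD", "CG", "CB", 1.526, 111.3, ("chi", 3, 0.0)),
            ("NZ", "CE", "CD", "CG", 1.489, 111.7, ("chi", 4, 0.0))],
    "ARG": [_CB, ("CG", "CB", "CA", "N", 1.526, 114.1, ("chi", 1, 0.0)),
            ("CD", "CG", "CB", "CA", 1.526, 111.3, ("chi", 2, 0.0)),
            ("NE", "CD", "CG", "CB", 1.463, 112.0, ("chi", 3, 0.0)),
            ("CZ", "NE", "CD", "CG", 1.340, 124.2, ("chi", 4, 0.0)),
            ("NH1", "CZ", "NE", "CD", 1.330, 120.0, 0.0),
            ("NH2", "CZ", "NE", "CD", 1.330, 120.0, 180.0)],
    "HIS": [_CB, ("CG", "CB", "CA", "N", 1.504, 113.8, ("chi", 1, 0.0)),
            ("ND1", "CG", "CB", "CA", 1.385, 122.7, ("chi", 2, 0.0)),
            ("CD2", "CG", "CB", "CA", 1.357, 129.7, ("chi", 2, 180.0)),
            ("CE1", "ND1", "CG", "CB", 1.321, 109.0, 180.0),
            ("NE2", "CE1", "ND1", "CG", 1.321, 111.7, 0.0)],
    "PHE": [_CB, ("CG", "CB", "CA", "N", 1.509, 114.0, ("chi", 1, 0.0)),
            ("CD1", "CG", "CB", "CA", 1.390, 120.0, ("chi", 2, 0.0)),
            ("CD2", "CG", "CB", "CA", 1.390, 120.0, ("chi", 2, 180.0)),
            ("CE1", "CD1", "CG", "CB", 1.390, 120.0, 180.0),
            ("CE2", "CD2", "CG", "CB", 1.390, 120.0, 180.0),
            ("CZ", "CE1", "CD1", "CG", 1.390, 120.0, 0.0)],
    "TYR": [_CB, ("CG", "CB", "CA", "N", 1.509, 114.0, ("chi", 1, 0.0)),
            ("CD1", "CG", "CB", "CA", 1.390, 120.0, ("chi", 2, 0.0)),
            ("CD2", "CG", "CB", "CA", 1.390, 120.0, ("chi", 2, 180.0)),
            ("CE1", "CD1", "CG", "CB", 1.390, 120.0, 180.0),
            ("CE2", "CD2", "CG", "CB", 1.390, 120.0, 180.0),
            ("CZ", "CE1", "CD1", "CG", 1.390, 120.0, 0.0),
            ("OH", "CZ", "CE1", "CD1", 1.376, 120.0, 180.0)],
    "TRP": [_CB, ("CG", "CB", "CA", "N", 1.498, 114.0, ("chi", 1, 0.0)),
            ("CD1", "CG", "CB", "CA", 1.365, 127.0, ("chi", 2, 0.0)),
            ("CD2", "CG", "CB", "CA", 1.433, 126.6, ("chi", 2, 180.0)),
            ("NE1", "CD1", "CG", "CB", 1.374, 110.1, 180.0),
            ("CE2", "CD2", "CG", "CB", 1.409, 107.3, 180.0),
            ("CE3", "CD2", "CG", "CB", 1.398, 133.9, 0.0),
            ("CZ2", "CE2", "CD2", "CG", 1.394, 122.4, 180.0),
            ("CZ3", "CE3", "CD2", "CG", 1.382, 118.8, 180.0),
            ("CH2", "CZ2", "CE2", "CD2", 1.368, 117.5, 180.0)],
    "PRO": [("CB", "CA", "N", "C", 1.530, 103.0, 115.0),
            ("CG", "CB", "CA", "N", 1.492, 104.5, 30.0),
            ("CD", "CG", "CB", "CA", 1.503, 105.5, -35.0)],
}

# Side-chain torsion definitions, chi1..chi4, as atom-name quads.
CHI_ATOMS = {
    "SER": [("N", "CA", "CB", "OG")],
    "CYS": [("N", "CA", "CB", "SG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "GLY": [], "ALA": [], "PRO": [],
}

CHI_COUNTS = {name: len(v) for name, v in CHI_ATOMS.items()}

# Hydrogen counts and hybridisation per side-chain heavy atom.
# Backbone N/CA are handled generically (N: 1 sp2 H except PRO; CA: 1 sp3 H,
# GLY: 2).  Entries: atom name -> (n_H, "sp2" | "sp3").
HYDROGEN_COUNTS = {
    "ALA": {"CB": (3, "sp3")},
    "ARG": {"CB": (2, "sp3"), "CG": (2, "sp3"), "CD": (2, "sp3"),
            "NE": (1, "sp2"), "NH1": (2, "sp2"), "NH2": (2, "sp2")},
    "ASN": {"CB": (2, "sp3"), "ND2": (2, "sp2")},
    "ASP": {"CB": (2, "sp3")},
    "CYS": {"CB": (2, "sp3"), "SG": (1, "sp3")},
    "GLN": {"CB": (2, "sp3"), "CG": (2, "sp3"), "NE2": (2, "sp2")},
    "GLU": {"CB": (2, "sp3"), "CG": (2, "sp3")},
    "GLY": {},
    "HIS": {"CB": (2, "sp3"), "CD2": (1, "sp2"), "CE1": (1, "sp2"),
            "NE2": (1, "sp2")},   # default epsilon-protonated tautomer
    "ILE": {"CB": (1, "sp3"), "CG1": (2, "sp3"), "CG2": (3, "sp3"),
            "CD1": (3, "sp3")},
    "LEU": {"CB": (2, "sp3"), "CG": (1, "sp3"), "CD1": (3, "sp3"),
            "CD2": (3, "sp3")},
    "LYS": {"CB": (2, "sp3"), "CG": (2, "sp3"), "CD": (2, "sp3"),
            "CE": (2, "sp3"), "NZ": (3, "sp3")},
    "MET": {"CB": (2, "sp3"), "CG": (2, "sp3"), "CE": (3, "sp3")},
    "PHE": {"CB": (2, "sp3"), "CD1": (1, "sp2"), "CD2": (1, "sp2"),
            "CE1": (1, "sp2"), "CE2": (1, "sp2"), "CZ": (1, "sp2")},
    "PRO": {"CB": (2, "sp3"), "CG": (2, "sp3"), "CD": (2, "sp3")},
    "SER": {"CB": (2, "sp3"), "OG": (1, "sp3")},
    "THR": {"CB": (1, "sp3"), "OG1": (1, "sp3"), "CG2": (3, "sp3")},
    "TRP": {"CB": (2, "sp3"), "CD1": (1, "sp2"), "NE1": (1, "sp2"),
            "CE3": (1, "sp2"), "CZ2": (1, "sp2"), "CZ3": (1, "sp2"),
            "CH2": (1, "sp2")},
    "TYR": {"CB": (2, "sp3"), "CD1": (1, "sp2"), "CD2": (1, "sp2"),
            "CE1": (1, "sp2"), "CE2": (1, "sp2"), "OH": (1, "sp3")},
    "VAL": {"CB": (1, "sp3"), "CG1": (3, "sp3"), "CG2": (3, "sp3")},
}

# His tautomer variants: H count overrides for ND1/NE2.
HIS_VARIANTS = {
    "HIE": {"ND1": (0, "sp2"), "NE2": (1, "sp2")},
    "HID": {"ND1": (1, "sp2"), "NE2": (0, "sp2")},
    "HIP": {"ND1": (1, "sp2"), "NE2": (1, "sp2")},
}

FORMAL_CHARGES = {
    "LYS": 1, "ARG": 1, "ASP": -1, "GLU": -1,
}

# Residues with a rotatable polar hydroxyl: (heavy atom, its bonded parent).
ROTATABLE_HYDROXYLS = {
    "SER": ("OG", "CB"),
    "THR": ("OG1", "CB"),
    "TYR": ("OH", "CZ"),
}

# Terminal-group flips evaluated during hydrogen optimisation: the torsion to
# rotate by 180 degrees, as an atom-name quad.
FLIPPABLE = {
    "ASN": ("CA", "CB", "CG", "OD1"),
    "GLN": ("CB", "CG", "CD", "OE1"),
    "HIS": ("CA", "CB", "CG", "ND1"),
}
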