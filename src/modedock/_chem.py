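"""Chemical reference data: element table, hydrogen-bond donor/acceptor
templates for the 20 standard residues (+ C-terminal amide cap), charged
groups, aromatic rings, and Gasteiger PEOE electronegativity parameters.

Element masses / van der Waals radii / covalent radii are shipped as a
plain-text table in ``data/elements.tsv``.
"""
from __future__ import annotations

import functools
from importlib import resources

import numpy as np

PROTEIN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT", "OT1", "OT2", "H", "H1", "H2", "H3", "HA"}
# occupancy-table label convention: backbone N/O (incl. terminal oxygens) = Main
MAINCHAIN_POLAR = {"N", "O", "OXT", "OT1", "OT2"}


@functools.lru_cache(maxsize=1)
def element_table() -> dict:
    """element symbol -> (mass, vdw_radius, covalent_radius)."""
    table = {}
    text = resources.files("modedock.data").joinpath("elements.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sym, mass, vdw, cov = line.split("\t")
        table[sym.upper()] = (float(mass), float(vdw), float(cov))
    return table


def element_mass(element: str) -> float:
    return element_table()[element.upper()][0]


def element_vdw(element: str) -> float:
    return element_table()[element.upper()][1]


def element_covalent(element: str) -> float:
    return element_table()[element.upper()][2]


def infer_element(atom_name: str, residue_name: str = "") -> str:
    """PDB-convention element inference from the atom name."""
    name = atom_name.strip()
    if not name:
        raise ValueError("cannot infer element from an empty atom name")
    tab = element_table()
    # two-letter element at the start (e.g. FE, ZN, CL) for het groups
    if len(name) >= 2 and name[:2].upper() in tab and not name[0].isdigit():
        two = name[:2].upper()
        # avoid misreading CA/CD etc. in amino acids as calcium/cadmium
        if residue_name.upper() not in PROTEIN_RESIDUES or two in ("CL", "BR", "SE"):
            if two not in ("CA", "CD", "CE", "CG", "CB", "CZ", "CH", "ND", "NE",
                           "NH", "NZ", "OD", "OE", "OG", "OH", "SD", "SG"):
                return two
    for ch in name:
        if ch.isalpha():
            sym = ch.upper()
            if sym in tab:
                return sym
            break
    raise ValueError(f"cannot resolve element for atom name {atom_name!r}")


# ---------------------------------------------------------------------------
# Hydrogen-bond donor / acceptor templates (heavy atoms).
# donor entry: atom -> (n_hydrogens, rotatable)
# A rotatable donor with no explicit hydrogen is treated as able to point its
# hydrogen at the acceptor (angle deviation 0); non-rotatable donors get
# ideally-placed sp2/sp3 hydrogens constructed from the bonded neighbours.
# ---------------------------------------------------------------------------
SIDECHAIN_DONORS = {
    "ARG": {"NE": (1, False), "NH1": (2, False), "NH2": (2, False)},
    "LYS": {"NZ": (3, True)},
    "SER": {"OG": (1, True)},
    "THR": {"OG1": (1, True)},
    "TYR": {"OH": (1, True)},
    "ASN": {"ND2": (2, False)},
    "GLN": {"NE2": (2, False)},
    "HIS": {"ND1": (1, False), "NE2": (1, False)},
    "TRP": {"NE1": (1, False)},
    "CYS": {"SG": (1, True)},
    "NH2": {"N": (2, False)},  # C-terminal amide cap
}

SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
    "MET": {"SD"},
    "CYS": {"SG"},
}

# Formally charged side-chain groups at pH 7 (His neutral by default).
CATIONIC_GROUPS = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
}
ANIONIC_GROUPS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
# Atom carrying the integer formal charge in each group (pH-7 protonation).
FORMAL_CHARGE_ATOM = {
    "ARG": ("NH1", +1),
    "LYS": ("NZ", +1),
    "ASP": ("OD2", -1),
    "GLU": ("OE2", -1),
}

AROMATIC_RINGS = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TRP": [("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"), ("CG", "CD1", "CD2", "NE1", "CE2")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
}

# ---------------------------------------------------------------------------
# Gasteiger-Marsili PEOE parameters: chi(q) = a + b q + c q^2 per atom type.
# Types resolved from element + heavy/total coordination number.
# ---------------------------------------------------------------------------
GASTEIGER_PARAMS = {
    "H": (7.17, 6.24, -0.56),
    "C.3": (7.98, 9.18, 1.88),
    "C.2": (8.79, 9.32, 1.51),
    "C.1": (10.39, 9.45, 0.73),
    "N.3": (11.54, 10.82, 1.36),
    "N.2": (12.87, 11.15, 0.85),
    "N.1": (15.68, 11.70, -0.27),
    "O.3": (14.18, 12.92, 1.39),
    "O.2": (17.07, 13.79, 0.47),
    "S.3": (10.14, 9.13, 1.38),
    "P.3": (8.90, 8.24, 0.96),
    "F": (14.66, 13.85, 2.31),
    "CL": (11.00, 9.69, 1.35),
    "BR": (10.08, 8.47, 1.16),
    "I": (9.90, 7.96, 0.96),
}
# Cation electronegativity used as the damping denominator; hydrogen's is
# the special value from the original parameterisation.
GASTEIGER_CHI_PLUS_H = 20.02


def gasteiger_type(element: str, n_bonds: int) -> str:
    """Map element + total coordination number to a PEOE parameter key."""
    el = element.upper()
    if el == "H":
        return "H"
    if el == "C":
        return {4: "C.3", 3: "C.2", 2: "C.1"}.get(n_bonds, "C.3")
    if el == "N":
        # amide/aromatic/planar N (3 bonds in a conjugated context) is N.2;
        # tetravalent ammonium and simple amines are N.3
        return {4: "N.3", 3: "N.3", 2: "N.2", 1: "N.1"}.get(n_bonds, "N.3")
    if el == "O":
        return "O.2" if n_bonds <= 1 else "O.3"
    if el == "S":
        return "S.3"
    if el == "P":
        return "P.3"
    if el in GASTEIGER_PARAMS:
        return el
    raise KeyError(f"no PEOE parameters for element {element!r}")


def detect_bonds(coords: np.ndarray, elements, tolerance: float = 0.45):
    """Covalent bonds by the covalent-radius distance heuristic.

    Returns a list of index pairs (i, j), i < j. A pair is bonded when
    0.4 A < d <= r_cov(i) + r_cov(j) + tolerance.
    """
    from scipy.spatial import cKDTree

    coords = np.asarray(coords, dtype=float)
    rcov = np.array([element_covalent(e) for e in elements])
    rmax = 2.0 * rcov.max() + tolerance
    tree = cKDTree(coords)
    pairs = tree.query_pairs(rmax, output_type="ndarray")
    if len(pairs) == 0:
        return []
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    limit = rcov[pairs[:, 0]] + rcov[pairs[:, 1]] + tolerance
    keep = (d > 0.4) & (d <= limit)
    return [tuple(p) for p in pairs[keep]]
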