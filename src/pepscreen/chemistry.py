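"""Per-residue chemistry tables: codes, polar-atom roles, charges, rings,
chi-angle definitions and van der Waals radii.

The heavy-atom connectivity and ideal coordinates for the 20 standard amino
acids are taken from the chemical component dictionary bundled with biotite;
everything layered on top (donor/acceptor/charge assignments, ring membership,
chi definitions) is a fixed table below.  Pseudo interaction-site "residues"
(single-atom probes plus a six-carbon ring) used by the synthetic pocket
generator are defined here as well so that structure I/O treats them
uniformly.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AAS = frozenset(THREE_TO_ONE)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: default substitution alphabet: 18 residues (no Pro -- backbone
#: incompatibility on a fixed scaffold; no Cys -- disulfide ambiguity)
DEFAULT_ALPHABET = tuple(sorted(STANDARD_AAS - {"PRO", "CYS"}))

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

# Side-chain hydrogen-bond roles (backbone N donor / O acceptor are implied
# for every residue and added during annotation).
SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TRP": {"NE1"},
    "TYR": {"OH"},
}
SIDECHAIN_ACCEPTORS = {
    "ASN": {"OD1"},
    "ASP": {"OD1", "OD2"},
    "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
}
SIDECHAIN_CHARGES = {
    "ARG": {"NE": 1, "NH1": 1, "NH2": 1},
    "ASP": {"OD1": -1, "OD2": -1},
    "GLU": {"OE1": -1, "OE2": -1},
    "LYS": {"NZ": 1},
}

AROMATIC_RINGS = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "TRP": [("CG", "CD1", "CD2", "NE1", "CE2"),
            ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")],
}

# chi dihedral definitions (heavy atoms); the number of entries doubles as the
# rotatable side-chain bond count used by the flexibility penalty
CHI_ATOMS = {
    "ALA": [],
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLY": [],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}


def n_chi(code: str) -> int:
    return len(CHI_ATOMS[code])


def rotatable_bond_count(code: str) -> int:
    """Side-chain rotatable bonds counted by the flexibility penalty."""
    return len(CHI_ATOMS[code])


# ---------------------------------------------------------------------------
# Pseudo interaction-site residues used by the synthetic pocket generator.
# Each value: list of (atom_name, element, is_donor, is_acceptor, charge,
# is_lipophilic).
# ---------------------------------------------------------------------------
PSEUDO_SITE_RESIDUES = {
    "PSD": [("PD", "N", True, False, 0, False)],    # H-bond donor probe
    "PSA": [("PA", "O", False, True, 0, False)],    # H-bond acceptor probe
    "PSP": [("PP", "N", True, False, 1, False)],    # cationic donor probe
    "PSN": [("PN", "O", False, True, -1, False)],   # anionic acceptor probe
    "PSL": [("PL", "C", False, False, 0, True)],    # lipophilic probe
    "PSR": [(f"C{i}", "C", False, False, 0, True) for i in range(1, 7)],
}
PSEUDO_CODES = frozenset(PSEUDO_SITE_RESIDUES)
PSEUDO_RINGS = {"PSR": [tuple(f"C{i}" for i in range(1, 7))]}

KNOWN_RESIDUE_CODES = STANDARD_AAS | PSEUDO_CODES

WATER_CODES = frozenset({"HOH", "WAT", "DOD"})


@lru_cache(maxsize=None)
def heavy_atom_template(code: str):
    """Ideal heavy-atom template from the bundled component dictionary.

    Returns (names, elements, coords, bonds) where ``bonds`` maps atom name to
    the set of bonded heavy-atom names.  OXT and hydrogens are dropped.
    """
    import biotite.structure.info as info

    res = info.residue(code)
    keep = (res.element != "H") & (res.atom_name != "OXT")
    idx = np.where(keep)[0]
    names = [str(n) for n in res.atom_name[idx]]
    elements = [str(e) for e in res.element[idx]]
    coords = np.array(res.coord[idx], dtype=float)
    index_of = {orig: new for new, orig in enumerate(idx)}
    bonds: dict[str, set[str]] = {n: set() for n in names}
    for a, b, _ in res.bonds.as_array():
        if a in index_of and b in index_of:
            na, nb = names[index_of[a]], names[index_of[b]]
            bonds[na].add(nb)
            bonds[nb].add(na)
    return names, elements, coords, bonds


@lru_cache(maxsize=None)
def lipophilic_atoms(code: str) -> frozenset[str]:
    """Carbon/sulfur heavy atoms not bonded to any (heavy) N or O."""
    if code in PSEUDO_CODES:
        return frozenset(a[0] for a in PSEUDO_SITE_RESIDUES[code] if a[5])
    names, elements, _, bonds = heavy_atom_template(code)
    elem_of = dict(zip(names, elements))
    out = set()
    for name, elem in zip(names, elements):
        if elem not in ("C", "S"):
            continue
        if any(elem_of[nb] in ("N", "O") for nb in bonds[name]):
            continue
        out.add(name)
    return frozenset(out)


def residue_rings(code: str) -> list[tuple[str, ...]]:
    if code in AROMATIC_RINGS:
        return AROMATIC_RINGS[code]
    return PSEUDO_RINGS.get(code, [])


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element, 1.70)
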