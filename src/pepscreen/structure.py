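"""Complex data model and PDB I/O.

A :class:`ComplexStructure` holds the receptor chains and the bound peptide
with per-atom interaction annotations (donor / acceptor / charge /
lipophilic), which is the substrate that all scoring operates on.  PDB
parsing and writing are delegated to biotite; this module only converts
between biotite's flat atom arrays and the residue-oriented model used by
the builders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from . import chemistry
from .geometry import normalize

DEFAULT_POCKET_CUTOFF = 4.5
#: larger cutoff used when deciding which peptide positions can reach the
#: receptor at all; must cover the longest side chain plus one H-bond beyond
#: the bare scaffold (Lys/Arg extend ~7 A past the backbone)
DEFAULT_REACH_CUTOFF = 11.0
#: minimum allowed receptor-peptide heavy atom separation in an input complex
HARD_CLASH_FLOOR = 2.2


class StructureError(ValueError):
    """Raised for malformed or inconsistent input structures."""


@dataclass
class Atom:
    """A heavy atom with interaction annotations.

    ``direction`` is the idealized interaction direction (unit vector away
    from the atom's bonded heavy neighbours) used to evaluate the angular
    hydrogen-bond penalty with implicit hydrogens; ``None`` means the angle
    is unconstrained (e.g. single-atom pseudo sites).
    """

    name: str
    element: str
    pos: np.ndarray
    is_donor: bool = False
    is_acceptor: bool = False
    charge: int = 0
    is_lipophilic: bool = False
    direction: np.ndarray | None = None

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)
        if not np.all(np.isfinite(self.pos)):
            raise StructureError(f"non-finite coordinates for atom {self.name}")
        if self.is_lipophilic and (self.is_donor or self.is_acceptor):
            raise StructureError(
                f"atom {self.name}: lipophilic flag is exclusive with donor/acceptor"
            )

    @property
    def radius(self) -> float:
        return chemistry.vdw_radius(self.element)

    def copy(self) -> "Atom":
        return replace(
            self,
            pos=self.pos.copy(),
            direction=None if self.direction is None else self.direction.copy(),
        )


@dataclass
class Residue:
    code: str
    position: int
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.code}{self.position}: no atom named {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def backbone(self) -> dict[str, Atom]:
        return {a.name: a for a in self.atoms if a.name in chemistry.BACKBONE_ATOMS}

    def backbone_complete(self) -> bool:
        return set(self.backbone) == set(chemistry.BACKBONE_ATOMS)

    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms])

    def copy(self) -> "Residue":
        return Residue(self.code, self.position, self.chain_id,
                       [a.copy() for a in self.atoms])


@dataclass
class PeptideChain:
    residues: list[Residue]

    def __post_init__(self):
        positions = [r.position for r in self.residues]
        if positions != sorted(positions) or len(set(positions)) != len(positions):
            raise StructureError("peptide residue positions must be strictly increasing")
        for r in self.residues:
            if r.code not in chemistry.STANDARD_AAS:
                raise StructureError(f"non-standard peptide residue {r.code}{r.position}")
            if not r.backbone_complete():
                missing = set(chemistry.BACKBONE_ATOMS) - set(r.backbone)
                raise StructureError(
                    f"peptide residue {r.code}{r.position} lacks backbone atom(s) "
                    f"{sorted(missing)}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(chemistry.THREE_TO_ONE[r.code] for r in self.residues)

    def residue_at(self, position: int) -> Residue:
        """1-based position lookup (positions are renumbered 1..L on read)."""
        for r in self.residues:
            if r.position == position:
                return r
        raise KeyError(f"no peptide residue at position {position}")

    def copy(self) -> "PeptideChain":
        return PeptideChain([r.copy() for r in self.residues])


@dataclass
class Site:
    """A receptor interaction site derived from an annotated atom."""

    kind: str  # 'donor' | 'acceptor' | 'charged+' | 'charged-' | 'lipophilic'
    chain_id: str
    residue_code: str
    residue_position: int
    atom: Atom
    area: float | None = None


@dataclass
class ReceptorPocket:
    residues: list[Residue]
    sites: list[Site]

    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def coords(self) -> np.ndarray:
        atoms = self.atoms()
        if not atoms:
            return np.zeros((0, 3))
        return np.array([a.pos for a in atoms])


@dataclass
class ComplexStructure:
    receptor_chains: dict[str, list[Residue]]
    peptide: PeptideChain
    source: str = ""

    def __post_init__(self):
        pep_chain_ids = {r.chain_id for r in self.peptide.residues}
        if pep_chain_ids & set(self.receptor_chains):
            raise StructureError("peptide chain id collides with a receptor chain")
        rec = self.receptor_coords()
        pep = np.array([a.pos for r in self.peptide.residues for a in r.atoms])
        if len(rec) and len(pep):
            tree = cKDTree(rec)
            dmin = tree.query(pep, k=1)[0].min()
            if dmin < HARD_CLASH_FLOOR:
                raise StructureError(
                    f"receptor-peptide hard clash: minimum separation {dmin:.2f} A "
                    f"is below the {HARD_CLASH_FLOOR} A floor"
                )

    def receptor_residues(self) -> list[Residue]:
        return [r for cid in sorted(self.receptor_chains)
                for r in self.receptor_chains[cid]]

    def receptor_atoms(self) -> list[Atom]:
        return [a for r in self.receptor_residues() for a in r.atoms]

    def receptor_coords(self) -> np.ndarray:
        atoms = self.receptor_atoms()
        if not atoms:
            return np.zeros((0, 3))
        return np.array([a.pos for a in atoms])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ComplexStructure":
        """Rigid-body transform of the whole complex (new object)."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)

        def _move(res: Residue) -> Residue:
            out = res.copy()
            for a in out.atoms:
                a.pos = rotation @ a.pos + translation
                if a.direction is not None:
                    a.direction = rotation @ a.direction
            return out

        chains = {cid: [_move(r) for r in residues]
                  for cid, residues in self.receptor_chains.items()}
        pep = PeptideChain([_move(r) for r in self.peptide.residues])
        return ComplexStructure(chains, pep, self.source)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def annotate_residue(residue: Residue) -> None:
    """Assign donor/acceptor/charge/lipophilic flags from the fixed
    per-residue chemistry table (in place)."""
    code = residue.code
    if code in chemistry.PSEUDO_CODES:
        spec = {a[0]: a for a in chemistry.PSEUDO_SITE_RESIDUES[code]}
        for atom in residue.atoms:
            _, _, don, acc, chg, lipo = spec[atom.name]
            atom.is_donor, atom.is_acceptor = don, acc
            atom.charge, atom.is_lipophilic = chg, lipo
            atom.direction = None
        return
    donors = chemistry.SIDECHAIN_DONORS.get(code, frozenset())
    acceptors = chemistry.SIDECHAIN_ACCEPTORS.get(code, frozenset())
    charges = chemistry.SIDECHAIN_CHARGES.get(code, {})
    lipo = chemistry.lipophilic_atoms(code)
    for atom in residue.atoms:
        atom.is_donor = atom.name == "N" or atom.name in donors
        atom.is_acceptor = atom.name == "O" or atom.name in acceptors
        atom.charge = charges.get(atom.name, 0)
        atom.is_lipophilic = atom.name in lipo and not (atom.is_donor or atom.is_acceptor)


def _polar_directions(residues: list[Residue]) -> None:
    """Compute idealized interaction directions for polar atoms of a chain of
    standard residues (in place).  The direction points away from the mean of
    the atom's bonded heavy neighbours; backbone N additionally uses the
    preceding residue's C."""
    by_position = {r.position: r for r in residues}
    for res in residues:
        if res.code not in chemistry.STANDARD_AAS:
            continue
        _, _, _, bonds = chemistry.heavy_atom_template(res.code)
        for atom in res.atoms:
            if not (atom.is_donor or atom.is_acceptor):
                atom.direction = None
                continue
            neighbours = [res.atom(nb).pos for nb in bonds.get(atom.name, ())
                          if nb != "OXT" and res.has_atom(nb)]
            if atom.name == "N":
                prev = by_position.get(res.position - 1)
                if prev is not None and prev.chain_id == res.chain_id and prev.has_atom("C"):
                    neighbours.append(prev.atom("C").pos)
            if not neighbours:
                atom.direction = None
                continue
            v = atom.pos - np.mean(neighbours, axis=0)
            atom.direction = normalize(v) if np.linalg.norm(v) > 1e-9 else None


def annotate_chain(residues: list[Residue]) -> None:
    for r in residues:
        annotate_residue(r)
    _polar_directions(residues)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_pdb(path, peptide_chain: str) -> ComplexStructure:
    """Read a complex from a PDB file.

    Waters and unknown heteroatoms are dropped; altlocs resolve to the
    highest-occupancy conformer; hydrogens are discarded.  Peptide residues
    are renumbered 1..L in file order.
    """
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    arr = pdb_file.get_structure(model=1, altloc="occupancy")
    keep = (
        (arr.element != "H")
        & (arr.element != "D")
        & ~np.isin(arr.res_name, list(chemistry.WATER_CODES))
        & np.isin(arr.res_name, list(chemistry.KNOWN_RESIDUE_CODES))
    )
    arr = arr[keep]
    chains = sorted(set(arr.chain_id))
    if peptide_chain not in chains:
        raise StructureError(
            f"peptide chain {peptide_chain!r} not found; available chains: "
            f"{', '.join(chains) or '(none)'}"
        )

    def _collect(chain_id: str) -> list[Residue]:
        mask = arr.chain_id == chain_id
        residues: list[Residue] = []
        sub = arr[mask]
        seen: dict[int, Residue] = {}
        for i in range(len(sub)):
            rid = int(sub.res_id[i])
            if rid not in seen:
                seen[rid] = Residue(str(sub.res_name[i]), rid, chain_id)
                residues.append(seen[rid])
            elem = str(sub.element[i]) or str(sub.atom_name[i])[0]
            seen[rid].atoms.append(Atom(str(sub.atom_name[i]), elem, sub.coord[i]))
        return residues

    pep_residues = _collect(peptide_chain)
    for new_pos, res in enumerate(pep_residues, start=1):
        res.position = new_pos
        if res.code not in chemistry.STANDARD_AAS:
            raise StructureError(
                f"peptide chain {peptide_chain} contains non-amino-acid residue "
                f"{res.code} at position {new_pos}"
            )
        if not res.backbone_complete():
            missing = set(chemistry.BACKBONE_ATOMS) - set(res.backbone)
            raise StructureError(
                f"peptide residue {res.code}{new_pos} is missing backbone "
                f"atom(s) {sorted(missing)}"
            )
    annotate_chain(pep_residues)

    receptor: dict[str, list[Residue]] = {}
    for cid in chains:
        if cid == peptide_chain:
            continue
        residues = _collect(cid)
        annotate_chain(residues)
        receptor[cid] = residues

    return ComplexStructure(receptor, PeptideChain(pep_residues), source=str(path))


def write_pdb(structure: ComplexStructure, path) -> None:
    """Write the complex as standard ATOM records (coordinates to 3 decimals)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    records = []
    for cid in sorted(structure.receptor_chains):
        for res in structure.receptor_chains[cid]:
            for a in res.atoms:
                records.append((cid, res.position, res.code, a))
    for res in structure.peptide.residues:
        for a in res.atoms:
            records.append((res.chain_id, res.position, res.code, a))

    n = len(records)
    arr = struc.AtomArray(n)
    arr.coord = np.array([r[3].pos for r in records])
    arr.chain_id = np.array([r[0] for r in records])
    arr.res_id = np.array([r[1] for r in records])
    arr.res_name = np.array([r[2] for r in records])
    arr.atom_name = np.array([r[3].name for r in records])
    arr.element = np.array([r[3].element for r in records])
    arr.hetero = np.zeros(n, dtype=bool)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# pocket extraction and contacts
# ---------------------------------------------------------------------------

def _derive_sites(residues: list[Residue]) -> list[Site]:
    from .surface import sasa_per_atom

    atoms = [a for r in residues for a in r.atoms]
    coords = np.array([a.pos for a in atoms]) if atoms else np.zeros((0, 3))
    radii = np.array([a.radius for a in atoms])
    lipo_idx = [i for i, a in enumerate(atoms) if a.is_lipophilic]
    areas = {}
    if lipo_idx:
        vals = sasa_per_atom(coords, radii, lipo_idx)
        areas = dict(zip(lipo_idx, vals))
    sites: list[Site] = []
    i = 0
    for res in residues:
        for a in res.atoms:
            meta = (res.chain_id, res.code, res.position)
            if a.charge > 0:
                sites.append(Site("charged+", *meta, atom=a))
            elif a.charge < 0:
                sites.append(Site("charged-", *meta, atom=a))
            elif a.is_donor and a.is_acceptor:
                sites.append(Site("donor", *meta, atom=a))
                sites.append(Site("acceptor", *meta, atom=a))
            elif a.is_donor:
                sites.append(Site("donor", *meta, atom=a))
            elif a.is_acceptor:
                sites.append(Site("acceptor", *meta, atom=a))
            if a.is_lipophilic:
                sites.append(Site("lipophilic", *meta, atom=a, area=float(areas.get(i, 0.0))))
            i += 1
    return sites


def extract_pocket(structure: ComplexStructure, cutoff: float = DEFAULT_POCKET_CUTOFF) -> ReceptorPocket:
    """Receptor residues with any atom within ``cutoff`` of any peptide atom."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pep_coords = np.array([a.pos for r in structure.peptide.residues for a in r.atoms])
    tree = cKDTree(pep_coords)
    selected: list[Residue] = []
    for res in structure.receptor_residues():
        dists = tree.query(res.coords(), k=1)[0]
        if np.min(dists) <= cutoff:
            selected.append(res)
    if not selected:
        warnings.warn("no receptor residues within cutoff of the peptide; empty pocket")
        return ReceptorPocket([], [])
    return ReceptorPocket(selected, _derive_sites(selected))


def peptide_position_contacts(
    structure: ComplexStructure,
    position: int,
    cutoff: float = DEFAULT_POCKET_CUTOFF,
) -> list[Site]:
    """Receptor sites within ``cutoff`` of any atom of the given peptide
    residue (1-based position)."""
    positions = [r.position for r in structure.peptide.residues]
    if position not in positions:
        raise ValueError(f"position {position} out of range 1..{max(positions)}")
    if cutoff <= 0:
        return []
    res = structure.peptide.residue_at(position)
    tree = cKDTree(res.coords())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pocket = extract_pocket(structure, cutoff)
    out = []
    for site in pocket.sites:
        d = tree.query(site.atom.pos.reshape(1, 3), k=1)[0][0]
        if d <= cutoff:
            out.append(site)
    return out
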