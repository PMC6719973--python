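"""Poly-Gly scaffold construction and fixed-backbone side-chain placement.

Side chains are instantiated from the ideal-geometry residue templates in
the bundled chemical component dictionary: the template backbone triad
(N, CA, C) is superposed onto the scaffold residue and the requested chi
dihedrals are then applied by rotating the distal subtree about each chi
bond.  Backbone atoms are never touched, so backbone coordinates stay
bit-identical to the template peptide through any chain of substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product

import numpy as np

from . import chemistry
from .geometry import dihedral, rotation_about_axis, superpose
from .structure import Atom, ComplexStructure, PeptideChain, Residue, StructureError, annotate_chain

DEFAULT_CHI_GRID = (-60.0, 60.0, 180.0)
DEFAULT_CLASH_TOLERANCE = 0.4


@dataclass
class RotamerSet:
    residue_code: str
    rotamers: list[tuple[float, ...]]


@dataclass
class Substitution:
    code: str
    rotamer: tuple[float, ...]
    rotamer_index: int
    sidechain_atoms: list[Atom]


@dataclass
class MutatedPeptide:
    """A scaffold plus side-chain substitutions; backbone belongs to ``base``."""

    base: PeptideChain
    substitutions: dict[int, Substitution] = field(default_factory=dict)
    _residues: list[Residue] | None = field(default=None, repr=False, compare=False)

    def residues(self) -> list[Residue]:
        if self._residues is None:
            out = []
            for res in self.base.residues:
                sub = self.substitutions.get(res.position)
                if sub is None or sub.code == "GLY":
                    out.append(res)
                else:
                    merged = Residue(sub.code, res.position, res.chain_id,
                                     [res.backbone[n] for n in chemistry.BACKBONE_ATOMS]
                                     + sub.sidechain_atoms)
                    out.append(merged)
            self._residues = out
        return self._residues

    @property
    def sequence(self) -> str:
        return "".join(chemistry.THREE_TO_ONE[r.code] for r in self.residues())

    def chain(self) -> PeptideChain:
        return PeptideChain(self.residues())


def enumerate_rotamers(code: str, grid: tuple[float, ...] = DEFAULT_CHI_GRID) -> RotamerSet:
    """Deterministic, ordered coarse chi grid; Gly/Ala yield one empty rotamer."""
    if code not in chemistry.STANDARD_AAS:
        raise ValueError(f"unknown residue code {code!r}")
    k = chemistry.n_chi(code)
    if k == 0:
        return RotamerSet(code, [()])
    return RotamerSet(code, [tuple(p) for p in product(grid, repeat=k)])


def build_gly_scaffold(peptide: PeptideChain) -> PeptideChain:
    """All-Gly copy of the peptide preserving the main chain bit-identically."""
    residues = []
    for res in peptide.residues:
        if not res.backbone_complete():
            missing = set(chemistry.BACKBONE_ATOMS) - set(res.backbone)
            raise StructureError(
                f"residue {res.code}{res.position} lacks backbone atom(s) {sorted(missing)}"
            )
        bb = res.backbone
        atoms = [Atom(n, bb[n].element, bb[n].pos.copy())
                 for n in chemistry.BACKBONE_ATOMS]
        residues.append(Residue("GLY", res.position, res.chain_id, atoms))
    annotate_chain(residues)
    return PeptideChain(residues)


@lru_cache(maxsize=None)
def _sidechain_template(code: str):
    """(names, elements, coords, moved_sets) for the side chain of ``code``.

    ``coords`` are template coordinates of N, CA, C followed by the
    side-chain atoms; ``moved_sets[j]`` lists side-chain coordinate rows
    rotated by chi_{j+1}.
    """
    names, elements, coords, bonds = chemistry.heavy_atom_template(code)
    index = {n: i for i, n in enumerate(names)}
    side_names = [n for n in names if n not in chemistry.BACKBONE_ATOMS]
    rows = [index["N"], index["CA"], index["C"]] + [index[n] for n in side_names]
    tcoords = coords[rows]
    row_of = {}
    for new, old in enumerate(rows):
        row_of[names[old]] = new
    moved_sets = []
    for (_, b, c, _) in chemistry.CHI_ATOMS[code]:
        # atoms distal to the b-c bond: reachable from c without crossing b
        seen = {b, c}
        stack = [c]
        distal = []
        while stack:
            cur = stack.pop()
            for nb in bonds[cur]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
                    if nb in row_of and nb not in chemistry.BACKBONE_ATOMS:
                        distal.append(row_of[nb])
        moved_sets.append(sorted(distal))
    side_elements = [elements[index[n]] for n in side_names]
    return side_names, side_elements, tcoords, moved_sets, row_of


def _build_sidechain_coords(code: str, rotamer: tuple[float, ...],
                            backbone_nca_c: np.ndarray) -> tuple[list[str], list[str], np.ndarray]:
    side_names, side_elements, tcoords, moved_sets, row_of = _sidechain_template(code)
    chi_defs = chemistry.CHI_ATOMS[code]
    if len(rotamer) != len(chi_defs):
        raise ValueError(
            f"{code} takes {len(chi_defs)} chi angle(s), got {len(rotamer)}"
        )
    coords = tcoords.copy()
    rot, trans = superpose(coords[:3], backbone_nca_c)
    coords = coords @ rot.T + trans
    coords[:3] = backbone_nca_c
    for j, ((a, b, c, d), target) in enumerate(zip(chi_defs, rotamer)):
        pa, pb, pc, pd = (coords[row_of[x]] for x in (a, b, c, d))
        delta = target - dihedral(pa, pb, pc, pd)
        # row-vector form: x @ R rotates by -theta about the axis, which is
        # the sense that advances the IUPAC dihedral by +delta
        rmat = rotation_about_axis(pc - pb, delta)
        rows = moved_sets[j]
        coords[rows] = (coords[rows] - pb) @ rmat + pb
    return side_names, side_elements, coords[3:]


def place_sidechain(
    scaffold: PeptideChain | MutatedPeptide,
    position: int,
    code: str,
    rotamer: tuple[float, ...] = (),
    rotamer_index: int = 0,
) -> MutatedPeptide:
    """Substitute ``code`` at ``position`` on the fixed backbone.

    Accepts a plain scaffold or an existing :class:`MutatedPeptide`, whose
    other substitutions are carried over unchanged.  Placing GLY is the
    identity (no side-chain atoms added).
    """
    if code not in chemistry.STANDARD_AAS:
        raise ValueError(f"unknown residue code {code!r}")
    if isinstance(scaffold, MutatedPeptide):
        base, subs = scaffold.base, dict(scaffold.substitutions)
    else:
        base, subs = scaffold, {}
    res = base.residue_at(position)
    if code == "GLY":
        subs[position] = Substitution("GLY", (), 0, [])
        return MutatedPeptide(base, subs)
    bb = res.backbone
    nca_c = np.array([bb["N"].pos, bb["CA"].pos, bb["C"].pos])
    names, elements, coords = _build_sidechain_coords(code, tuple(rotamer), nca_c)
    atoms = [Atom(n, e, c) for n, e, c in zip(names, elements, coords)]
    sub = Substitution(code, tuple(rotamer), rotamer_index, atoms)
    subs[position] = sub
    mutated = MutatedPeptide(base, subs)
    _annotate_substitution(mutated, position)
    return mutated


def _annotate_substitution(mutated: MutatedPeptide, position: int) -> None:
    """Annotate the freshly built residue (flags + polar directions)."""
    from .structure import annotate_residue, _polar_directions

    residues = mutated.residues()
    target = next(r for r in residues if r.position == position)
    annotate_residue(target)
    _polar_directions(residues)


def clash_check(
    structure: ComplexStructure,
    mutated: MutatedPeptide,
    tolerance: float = DEFAULT_CLASH_TOLERANCE,
) -> tuple[bool, float]:
    """Reject if any substituted side-chain atom overlaps a receptor atom or
    an atom of another peptide residue by more than ``tolerance`` below the
    vdW-radius sum.  Returns (accepted, worst_overlap)."""
    context: list[tuple[int, np.ndarray, float]] = []
    for res in mutated.residues():
        for a in res.atoms:
            context.append((res.position, a.pos, a.radius))
    for a in structure.receptor_atoms():
        context.append((-1, a.pos, a.radius))
    worst = 0.0
    for pos, sub in mutated.substitutions.items():
        for a in sub.sidechain_atoms:
            for other_pos, opos, orad in context:
                if other_pos == pos:
                    continue
                d = float(np.linalg.norm(a.pos - opos))
                overlap = (a.radius + orad) - d
                if overlap > worst:
                    worst = overlap
    return worst <= tolerance, worst


def sidechain_clashes(
    atoms: list[Atom],
    context_coords: np.ndarray,
    context_radii: np.ndarray,
    tolerance: float = DEFAULT_CLASH_TOLERANCE,
) -> tuple[bool, float]:
    """Fast array-based variant used by the screening loops."""
    if len(context_coords) == 0 or not atoms:
        return True, 0.0
    pos = np.array([a.pos for a in atoms])
    rad = np.array([a.radius for a in atoms])
    d = np.linalg.norm(pos[:, None, :] - context_coords[None, :, :], axis=2)
    overlap = (rad[:, None] + context_radii[None, :]) - d
    worst = float(overlap.max())
    return worst <= tolerance, max(0.0, worst)
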