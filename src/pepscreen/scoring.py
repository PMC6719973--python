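"""Five-term empirical binding free-energy function and score conversions.

dG_total = dG0 + dG_polar + dG_apolar + dG_solv + dG_flexi   [kcal/mol]

* polar:  hydrogen bonds and ionic pairs with piecewise-linear distance and
  angle penalties
* apolar: lipophilic contact area plus an aromatic ring-stacking bonus
* solv:   desolvation penalty for buried peptide polar atoms that gained no
  compensating hydrogen-bond partner
* flexi:  rotatable-bond fixation penalty

The dimensionless affinity score is -100/(ln10 * R * T) * dG, i.e. -100 *
log10(Ki); at 298 K the conversion coefficient is 73.33.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import chemistry
from .geometry import vector_angle
from .sidechain import MutatedPeptide
from .structure import Atom, PeptideChain, ReceptorPocket
from .surface import buried_area

#: gas constant in kcal mol^-1 K^-1 (CODATA, 8.31446... J / 4184 J per kcal)
GAS_CONSTANT = 8.31446261815324 / 4184.0


@dataclass
class ScoreModel:
    """Weights (kcal/mol), geometry tolerances and temperature."""

    dG0: float = 1.29
    w_hbond: float = -1.12
    w_ionic: float = -1.98
    w_lipo: float = -0.0406      # per A^2 of lipophilic contact
    w_aromatic: float = -0.17    # per ring-ring contact
    w_solv: float = 0.01         # per A^2 of buried uncompensated polar surface
    w_rot: float = 0.335         # per rotatable side-chain bond
    R_ideal: float = 2.9         # ideal donor-acceptor heavy-atom distance
    dR_tol: float = 0.2
    dR_max: float = 0.6
    dA_tol: float = 30.0
    dA_max: float = 80.0
    temperature: float = 298.0
    probe_radius: float = 1.4
    n_sphere_points: int = 144
    aromatic_cutoff: float = 5.0

    def __post_init__(self):
        if not (self.w_hbond <= 0 and self.w_ionic <= 0 and self.w_lipo <= 0):
            raise ValueError("interaction weights w_hbond/w_ionic/w_lipo must be <= 0")
        if self.w_rot < 0 or self.w_solv < 0:
            raise ValueError("penalty weights w_rot/w_solv must be >= 0")
        if not self.dR_tol < self.dR_max:
            raise ValueError("dR_tol must be < dR_max")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def score_coefficient(self) -> float:
        """100 / (ln10 * R * T); 73.337 at 298 K (printed elsewhere as 73.33)."""
        return 100.0 / (math.log(10.0) * GAS_CONSTANT * self.temperature)

    @classmethod
    def from_dict(cls, data: dict) -> "ScoreModel":
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "ScoreModel":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PolarContact:
    peptide_atom: Atom
    pocket_atom: Atom
    distance: float
    factor: float
    kind: str  # 'hbond' | 'ionic'
    energy: float


@dataclass
class EnergyBreakdown:
    dG0: float
    dG_polar: float
    dG_apolar: float
    dG_solv: float
    dG_flexi: float
    dG_total: float
    ludi_score: float
    n_hbonds: int
    n_ionic: int
    n_rotatable: int
    lipo_area: float
    n_aromatic: int = 0
    contacts: list[PolarContact] = field(default_factory=list)

    def to_tsv(self) -> str:
        rows = [
            ("dG0", f"{self.dG0:.6f}"),
            ("dG_polar", f"{self.dG_polar:.6f}"),
            ("dG_apolar", f"{self.dG_apolar:.6f}"),
            ("dG_solv", f"{self.dG_solv:.6f}"),
            ("dG_flexi", f"{self.dG_flexi:.6f}"),
            ("dG_total", f"{self.dG_total:.6f}"),
            ("ludi_score", f"{self.ludi_score:.4f}"),
            ("n_hbonds", str(self.n_hbonds)),
            ("n_ionic", str(self.n_ionic)),
            ("n_rotatable", str(self.n_rotatable)),
            ("lipo_area", f"{self.lipo_area:.4f}"),
            ("n_aromatic", str(self.n_aromatic)),
        ]
        lines = ["term\tvalue"] + [f"{k}\t{v}" for k, v in rows]
        for c in self.contacts:
            lines.append(
                f"contact\t{c.kind}:{c.peptide_atom.name}-{c.pocket_atom.name}"
                f":d={c.distance:.3f}:f={c.factor:.3f}:e={c.energy:.4f}"
            )
        return "\n".join(lines) + "\n"


def _peptide_residues(peptide) -> list:
    if isinstance(peptide, MutatedPeptide):
        return peptide.residues()
    if isinstance(peptide, PeptideChain):
        return peptide.residues
    raise TypeError("peptide must be a PeptideChain or MutatedPeptide")


def _pair_factor(distance: float, model: ScoreModel) -> float:
    dr = abs(distance - model.R_ideal)
    if dr <= model.dR_tol:
        return 1.0
    if dr >= model.dR_max:
        return 0.0
    return (model.dR_max - dr) / (model.dR_max - model.dR_tol)


def _angle_factor(dalpha: float, model: ScoreModel) -> float:
    if dalpha <= model.dA_tol:
        return 1.0
    if dalpha >= model.dA_max:
        return 0.0
    return (model.dA_max - dalpha) / (model.dA_max - model.dA_tol)


def _direction_factor(atom: Atom, partner_pos: np.ndarray, model: ScoreModel) -> float:
    if atom.direction is None:
        return 1.0
    return _angle_factor(vector_angle(atom.direction, partner_pos - atom.pos), model)


def _polar_contacts(pocket: ReceptorPocket, peptide, model: ScoreModel) -> list[PolarContact]:
    pocket_polar = [a for a in pocket.atoms() if a.is_donor or a.is_acceptor]
    if not pocket_polar:
        return []
    pocket_pos = np.array([a.pos for a in pocket_polar])
    reach = model.R_ideal + model.dR_max
    contacts: list[PolarContact] = []
    for res in _peptide_residues(peptide):
        for pa in res.atoms:
            if not (pa.is_donor or pa.is_acceptor):
                continue
            d = np.linalg.norm(pocket_pos - pa.pos, axis=1)
            for j in np.where(d < reach)[0]:
                qa = pocket_polar[j]
                pairing = (pa.is_donor and qa.is_acceptor) or (pa.is_acceptor and qa.is_donor)
                if not pairing:
                    continue
                f = (
                    _pair_factor(float(d[j]), model)
                    * _direction_factor(pa, qa.pos, model)
                    * _direction_factor(qa, pa.pos, model)
                )
                if f <= 0.0:
                    continue
                ionic = pa.charge * qa.charge < 0
                w = model.w_ionic if ionic else model.w_hbond
                contacts.append(
                    PolarContact(pa, qa, float(d[j]), f,
                                 "ionic" if ionic else "hbond", w * f)
                )
    return contacts


def polar_term(pocket: ReceptorPocket, peptide, model: ScoreModel) -> tuple[float, list[PolarContact]]:
    """Hydrogen-bond and ionic-pair energy with its contact list."""
    contacts = _polar_contacts(pocket, peptide, model)
    return sum(c.energy for c in contacts), contacts


def _ring_centroids(residues) -> list[np.ndarray]:
    centroids = []
    for res in residues:
        for ring in chemistry.residue_rings(res.code):
            if all(res.has_atom(n) for n in ring):
                centroids.append(np.mean([res.atom(n).pos for n in ring], axis=0))
    return centroids


def apolar_term(pocket: ReceptorPocket, peptide, model: ScoreModel) -> float:
    energy, _, _ = apolar_breakdown(pocket, peptide, model)
    return energy


def apolar_breakdown(pocket: ReceptorPocket, peptide, model: ScoreModel) -> tuple[float, float, int]:
    """(energy, lipophilic contact area, aromatic pair count)."""
    residues = _peptide_residues(peptide)
    pep_atoms = [a for r in residues for a in r.atoms]
    pocket_lipo = [a for a in pocket.atoms() if a.is_lipophilic]
    area = 0.0
    if pocket_lipo and pep_atoms:
        own_coords = np.array([a.pos for a in pep_atoms])
        own_radii = np.array([a.radius for a in pep_atoms])
        targets = [i for i, a in enumerate(pep_atoms) if a.is_lipophilic]
        if targets:
            other_coords = np.array([a.pos for a in pocket_lipo])
            other_radii = np.array([a.radius for a in pocket_lipo])
            area = float(
                buried_area(
                    own_coords, own_radii, other_coords, other_radii, targets,
                    probe=model.probe_radius, n_points=model.n_sphere_points,
                ).sum()
            )
    n_pairs = 0
    pep_rings = _ring_centroids(residues)
    pocket_rings = _ring_centroids(pocket.residues)
    for c1 in pep_rings:
        for c2 in pocket_rings:
            if np.linalg.norm(c1 - c2) < model.aromatic_cutoff:
                n_pairs += 1
    return model.w_lipo * area + model.w_aromatic * n_pairs, area, n_pairs


def solv_term(pocket: ReceptorPocket, peptide, model: ScoreModel,
              contacts: list[PolarContact] | None = None) -> float:
    """Desolvation penalty: buried polar surface of peptide atoms with no
    compensating hydrogen-bond partner (contact factor > 0)."""
    residues = _peptide_residues(peptide)
    pep_atoms = [a for r in residues for a in r.atoms]
    pocket_atoms = pocket.atoms()
    if not pocket_atoms or not pep_atoms:
        return 0.0
    if contacts is None:
        contacts = _polar_contacts(pocket, peptide, model)
    compensated = {id(c.peptide_atom) for c in contacts}
    targets = [
        i for i, a in enumerate(pep_atoms)
        if (a.is_donor or a.is_acceptor) and id(a) not in compensated
    ]
    if not targets:
        return 0.0
    own_coords = np.array([a.pos for a in pep_atoms])
    own_radii = np.array([a.radius for a in pep_atoms])
    other_coords = np.array([a.pos for a in pocket_atoms])
    other_radii = np.array([a.radius for a in pocket_atoms])
    buried = buried_area(
        own_coords, own_radii, other_coords, other_radii, targets,
        probe=model.probe_radius, n_points=model.n_sphere_points,
    ).sum()
    return model.w_solv * float(buried)


def flexi_term(peptide, model: ScoreModel) -> float:
    return model.w_rot * count_rotatable(peptide)


def count_rotatable(peptide) -> int:
    """Rotatable side-chain bonds over substituted (non-Gly) residues."""
    if isinstance(peptide, MutatedPeptide):
        return sum(
            chemistry.rotatable_bond_count(s.code)
            for s in peptide.substitutions.values()
        )
    return sum(chemistry.rotatable_bond_count(r.code) for r in _peptide_residues(peptide))


def score_complex(pocket: ReceptorPocket, peptide, model: ScoreModel) -> EnergyBreakdown:
    dg_polar, contacts = polar_term(pocket, peptide, model)
    dg_apolar, lipo_area, n_aromatic = apolar_breakdown(pocket, peptide, model)
    dg_solv = solv_term(pocket, peptide, model, contacts=contacts)
    dg_flexi = flexi_term(peptide, model)
    total = model.dG0 + dg_polar + dg_apolar + dg_solv + dg_flexi
    return EnergyBreakdown(
        dG0=model.dG0,
        dG_polar=dg_polar,
        dG_apolar=dg_apolar,
        dG_solv=dg_solv,
        dG_flexi=dg_flexi,
        dG_total=total,
        ludi_score=dg_to_score(total, model),
        n_hbonds=sum(1 for c in contacts if c.kind == "hbond"),
        n_ionic=sum(1 for c in contacts if c.kind == "ionic"),
        n_rotatable=count_rotatable(peptide),
        lipo_area=lipo_area,
        n_aromatic=n_aromatic,
        contacts=contacts,
    )


def dg_to_score(dg: float, model: ScoreModel | None = None) -> float:
    """Dimensionless affinity score; -73.33 * dG at 298 K."""
    model = model or ScoreModel()
    return -model.score_coefficient * dg


def score_to_ki(score: float, model: ScoreModel | None = None) -> float:
    """Dissociation constant in mol/L implied by the score.

    Convention: score = -100 * log10(Ki), so higher score means tighter
    binding (sub-molar Ki gives a positive score).
    """
    return 10.0 ** (-score / 100.0)
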