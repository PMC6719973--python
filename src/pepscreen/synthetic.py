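"""Toy pocket-peptide complexes with planted, analytically known
interactions, plus the packaged screening fixtures.

The generator builds an ideal extended 14-mer backbone and surrounds it with
disconnected single-site pseudo-residues (donor / acceptor / charged probes,
lipophilic patches, a stacking ring), each placed at ideal interaction
geometry for the side chain of the residue that is intended to win at that
position.  Ground truth is therefore provable rather than plausible, and
every pipeline stage can be exercised without downloading any structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import chemistry
from .geometry import normalize, place_atom
from .sidechain import place_sidechain
from .structure import (
    Atom,
    ComplexStructure,
    PeptideChain,
    Residue,
    annotate_chain,
)

def reference_rotamer(scaffold: PeptideChain, position: int, code: str) -> tuple[float, ...]:
    """Deterministic grid rotamer used to build side chains and to derive
    planted site geometry: the first rotamer in grid order whose side chain
    does not clash with the scaffold backbone, so the screening stage can
    always reproduce the planted geometry exactly."""
    from .sidechain import DEFAULT_CLASH_TOLERANCE, enumerate_rotamers, place_sidechain

    rotamers = enumerate_rotamers(code).rotamers
    # prefer the maximally extended conformer: it keeps planted sites far
    # from the backbone, where rival side chains cannot reach them
    all_trans = tuple(180.0 for _ in range(chemistry.n_chi(code)))
    rotamers = sorted(rotamers, key=lambda r: r != all_trans)
    backbone = np.array([
        a.pos for r in scaffold.residues if r.position != position for a in r.atoms
    ])
    radii = np.array([
        a.radius for r in scaffold.residues if r.position != position for a in r.atoms
    ])
    for rot in rotamers:
        mut = place_sidechain(scaffold, position, code, rot)
        atoms = mut.substitutions[position].sidechain_atoms
        if not atoms:
            return rot
        pos_arr = np.array([a.pos for a in atoms])
        rad_arr = np.array([a.radius for a in atoms])
        d = np.linalg.norm(pos_arr[:, None, :] - backbone[None, :, :], axis=2)
        overlap = (rad_arr[:, None] + radii[None, :]) - d
        if overlap.max() <= DEFAULT_CLASH_TOLERANCE:
            return rot
    return rotamers[-1]


SITE_KINDS = ("donor", "acceptor", "charged+", "charged-", "lipophilic", "ring")

#: ideal donor-acceptor heavy atom distance used for planted polar sites;
#: matches the scoring default R_ideal
PLANT_HBOND_DISTANCE = 2.9
PLANT_LIPO_DISTANCE = 4.2
PLANT_RING_DISTANCE = 3.7
#: jittered sites are pushed back out to at least this separation from the
#: peptide and from the intended winner's side chain: far enough that a
#: planted probe can never clash-reject the winner's rotamer (max vdW sum
#: 3.1 minus the 0.4 clash tolerance), and still inside the flat top of the
#: hydrogen-bond distance well
MIN_SITE_SEPARATION = 2.7


@dataclass
class PocketSpec:
    n_positions: int = 14
    planted_sites: dict[int, str] = field(default_factory=dict)   # position -> site kind
    intended_optimum: dict[int, str] = field(default_factory=dict)  # position -> 3-letter code
    seed: int = 0
    noise: float = 0.0
    peptide_sequence: str | None = None  # 1-letter; default poly-Gly

    def __post_init__(self):
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        for pos, kind in self.planted_sites.items():
            if kind not in SITE_KINDS:
                raise ValueError(f"unknown site kind {kind!r} at position {pos}")
            if pos not in self.intended_optimum:
                raise ValueError(f"planted site at {pos} has no intended optimum")


# ---------------------------------------------------------------------------
# ideal extended backbone
# ---------------------------------------------------------------------------

_BB = {
    "n_ca": 1.458, "ca_c": 1.525, "c_n": 1.329, "c_o": 1.231,
    "ang_n_ca_c": 111.2, "ang_ca_c_n": 116.2, "ang_c_n_ca": 121.7,
    "ang_ca_c_o": 120.8, "phi": -139.0, "psi": 135.0, "omega": 180.0,
}


def build_extended_backbone(n_residues: int) -> list[dict[str, np.ndarray]]:
    """Ideal-geometry extended (beta-strand) backbone, N/CA/C/O per residue."""
    b = _BB
    coords: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([b["n_ca"], 0.0, 0.0])
    theta = math.radians(180.0 - b["ang_n_ca_c"])
    c0 = ca0 + b["ca_c"] * np.array([math.cos(theta), math.sin(theta), 0.0])
    prev = {"N": n0, "CA": ca0, "C": c0}
    coords.append(prev)
    for _ in range(1, n_residues):
        n = place_atom(prev["N"], prev["CA"], prev["C"], b["c_n"], b["ang_ca_c_n"], b["psi"])
        ca = place_atom(prev["CA"], prev["C"], n, b["n_ca"], b["ang_c_n_ca"], b["omega"])
        c = place_atom(prev["C"], n, ca, b["ca_c"], b["ang_n_ca_c"], b["phi"])
        cur = {"N": n, "CA": ca, "C": c}
        coords.append(cur)
        prev = cur
    for i, res in enumerate(coords):
        # carbonyl O anti to the following N (psi + 180)
        res["O"] = place_atom(res["N"], res["CA"], res["C"], b["c_o"],
                              b["ang_ca_c_o"], b["psi"] + 180.0)
    return coords


def _gly_chain(n_residues: int, chain_id: str = "A") -> PeptideChain:
    residues = []
    for i, bb in enumerate(build_extended_backbone(n_residues), start=1):
        atoms = [Atom(name, "N" if name == "N" else ("O" if name == "O" else "C"), bb[name])
                 for name in chemistry.BACKBONE_ATOMS]
        residues.append(Residue("GLY", i, chain_id, atoms))
    annotate_chain(residues)
    return PeptideChain(residues)


def _materialize(scaffold: PeptideChain, codes: dict[int, str]) -> PeptideChain:
    """Peptide with side chains built at the reference rotamer."""
    mutated = None
    base = scaffold.copy()
    for pos, code in sorted(codes.items()):
        if code == "GLY":
            continue
        mutated = place_sidechain(mutated if mutated is not None else base,
                                  pos, code, reference_rotamer(base, pos, code))
    if mutated is None:
        return base
    chain = PeptideChain([r.copy() for r in mutated.residues()])
    annotate_chain(chain.residues)
    return chain


# ---------------------------------------------------------------------------
# site placement
# ---------------------------------------------------------------------------

def _first_sidechain_atom(residue: Residue, predicate) -> Atom:
    for a in residue.atoms:
        if a.name in chemistry.BACKBONE_ATOMS:
            continue
        if predicate(a):
            return a
    raise ValueError(
        f"no compatible side-chain atom on {residue.code} for the requested site"
    )


def _ring_geometry(residue: Residue) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rings = chemistry.residue_rings(residue.code)
    if not rings:
        raise ValueError(f"{residue.code} has no aromatic ring for a ring site")
    ring = rings[0]
    pts = np.array([residue.atom(n).pos for n in ring])
    centroid = pts.mean(axis=0)
    normal = np.zeros(3)
    for i in range(len(pts)):
        normal += np.cross(pts[i] - centroid, pts[(i + 1) % len(pts)] - centroid)
    normal = normalize(normal)
    ca = residue.atom("CA").pos
    if np.dot(normal, centroid - ca) < 0:
        normal = -normal
    in_plane = normalize(pts[0] - centroid)
    return centroid, normal, in_plane


def _tilted_directions(direction: np.ndarray, tilt_deg: float = 15.0) -> list[np.ndarray]:
    """Two unit vectors tilted +/-tilt about an axis perpendicular to
    ``direction`` (both stay within the angular H-bond tolerance)."""
    from .geometry import rotation_about_axis

    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(direction, ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    axis = normalize(np.cross(direction, ref))
    return [rotation_about_axis(axis, s * tilt_deg) @ direction for s in (1.0, -1.0)]


def _site_groups(kind: str, residue: Residue) -> list[list[tuple[str, np.ndarray]]]:
    """Pseudo-residue atom groups for a planted site.

    Each group becomes one pseudo-residue with its own jitter offset.  Polar
    sites plant two probes at +/-15 degrees so that positional noise rarely
    erases the whole interaction."""
    ca = residue.atom("CA").pos
    if kind in ("acceptor", "charged-"):
        donor = _first_sidechain_atom(
            residue,
            (lambda a: a.is_donor and a.charge > 0) if kind == "charged-" else (lambda a: a.is_donor),
        )
        if donor.direction is None:
            raise ValueError("donor atom lacks an interaction direction")
        name = "PN" if kind == "charged-" else "PA"
        return [
            [(name, donor.pos + PLANT_HBOND_DISTANCE * d)]
            for d in _tilted_directions(donor.direction)
        ]
    if kind in ("donor", "charged+"):
        acceptor = _first_sidechain_atom(
            residue,
            (lambda a: a.is_acceptor and a.charge < 0) if kind == "charged+" else (lambda a: a.is_acceptor),
        )
        if acceptor.direction is None:
            raise ValueError("acceptor atom lacks an interaction direction")
        name = "PP" if kind == "charged+" else "PD"
        return [
            [(name, acceptor.pos + PLANT_HBOND_DISTANCE * d)]
            for d in _tilted_directions(acceptor.direction)
        ]
    if kind == "lipophilic":
        lipo = [a for a in residue.atoms
                if a.is_lipophilic and a.name not in chemistry.BACKBONE_ATOMS]
        if not lipo:
            raise ValueError(f"{residue.code} has no lipophilic side-chain atom")
        tip = lipo[-1]
        out = normalize(tip.pos - ca)
        # a small patch of three carbons facing the side-chain tip
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(out, ref)) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        perp = normalize(np.cross(out, ref))
        base = tip.pos + PLANT_LIPO_DISTANCE * out
        return [[("PL", base + 1.5 * perp * s) for s in (-1.0, 0.0, 1.0)]]
    if kind == "ring":
        centroid, normal, in_plane = _ring_geometry(residue)
        perp = np.cross(normal, in_plane)
        center = centroid + PLANT_RING_DISTANCE * normal
        atoms = []
        for i in range(6):
            t = math.radians(60.0 * i)
            pos = center + 1.39 * (math.cos(t) * in_plane + math.sin(t) * perp)
            atoms.append((f"C{i + 1}", pos))
        return [atoms]
    raise ValueError(f"unknown site kind {kind!r}")


_SITE_RESIDUE_CODE = {
    "donor": "PSD", "acceptor": "PSA", "charged+": "PSP",
    "charged-": "PSN", "lipophilic": "PSL", "ring": "PSR",
}


def make_toy_complex(spec: PocketSpec) -> ComplexStructure:
    """Deterministic toy complex for the given spec (seeded jitter)."""
    rng = np.random.default_rng(spec.seed)
    scaffold = _gly_chain(spec.n_positions)
    if spec.peptide_sequence is not None:
        if len(spec.peptide_sequence) != spec.n_positions:
            raise ValueError("peptide_sequence length does not match n_positions")
        pep_codes = {i + 1: chemistry.ONE_TO_THREE[c]
                     for i, c in enumerate(spec.peptide_sequence)}
    else:
        pep_codes = {}
    peptide = _materialize(scaffold, pep_codes)
    pep_coords = np.array([a.pos for r in peptide.residues for a in r.atoms])

    receptor: list[Residue] = []
    res_id = 0
    for pos in sorted(spec.planted_sites):
        kind = spec.planted_sites[pos]
        code = spec.intended_optimum[pos]
        winner_chain = _materialize(scaffold, {pos: code})
        winner = winner_chain.residue_at(pos)
        clamp_ref = np.vstack([
            pep_coords,
            np.array([a.pos for a in winner.atoms]),
        ])
        rcode = _SITE_RESIDUE_CODE[kind]
        spec_atoms = {a[0]: a for a in chemistry.PSEUDO_SITE_RESIDUES[rcode]}
        for group in _site_groups(kind, winner):
            offset = rng.normal(0.0, spec.noise, 3) if spec.noise > 0 else np.zeros(3)
            res_id += 1
            placed = []
            for name, pos_vec in group:
                p = pos_vec + offset
                # keep sites from clash-rejecting the winner or the peptide
                for _ in range(20):
                    d = np.linalg.norm(clamp_ref - p, axis=1)
                    j = int(np.argmin(d))
                    if d[j] >= MIN_SITE_SEPARATION:
                        break
                    p = clamp_ref[j] + normalize(p - clamp_ref[j]) * MIN_SITE_SEPARATION
                placed.append((name, p))
            res = Residue(rcode, res_id, "B",
                          [Atom(name, spec_atoms[name][1], p) for name, p in placed])
            receptor.append(res)
    annotate_chain(receptor)
    return ComplexStructure({"B": receptor} if receptor else {}, peptide, source=f"toy:seed={spec.seed}")


def mutable_positions(spec: PocketSpec) -> tuple[int, ...]:
    """Positions with a planted site (the ones a recovery screen scans)."""
    return tuple(sorted(spec.planted_sites))


def recovery_frozen(spec: PocketSpec) -> tuple[int, ...]:
    """Complement of :func:`mutable_positions`: positions to freeze when
    screening a generated pocket, by analogy with freezing residues that do
    not face the receptor."""
    planted = set(spec.planted_sites)
    return tuple(p for p in range(1, spec.n_positions + 1) if p not in planted)


def planted_optimum(spec: PocketSpec) -> str:
    """Expected stage-2 winner: intended residues, Gly elsewhere."""
    letters = []
    for pos in range(1, spec.n_positions + 1):
        code = spec.intended_optimum.get(pos, "GLY")
        letters.append(chemistry.THREE_TO_ONE[code])
    return "".join(letters)


#: (code, site kind) pairs whose intended winner is uniquely optimal under
#: the default score model with a comfortable margin over its nearest rival
#: (no other residue type can reach the planted geometry while paying a
#: smaller flexibility penalty); used by the randomized recovery specs
RECOVERY_MENU = (
    ("ARG", "charged-"),
    ("TYR", "acceptor"),
    ("PHE", "ring"),
    ("ASP", "charged+"),
)


def random_pocket_spec(seed: int, n_sites: int = 4, noise: float = 0.0,
                       n_positions: int = 14) -> PocketSpec:
    """Randomized recovery spec: spaced positions, site/winner pairs drawn
    from :data:`RECOVERY_MENU`."""
    rng = np.random.default_rng(seed)
    candidates = list(range(3, n_positions - 1))
    positions: list[int] = []
    for p in rng.permutation(candidates):
        if all(abs(int(p) - q) >= 3 for q in positions):
            positions.append(int(p))
        if len(positions) == n_sites:
            break
    positions.sort()
    planted, intended = {}, {}
    for p in positions:
        code, kind = RECOVERY_MENU[int(rng.integers(len(RECOVERY_MENU)))]
        planted[p] = kind
        intended[p] = code
    return PocketSpec(
        n_positions=n_positions, planted_sites=planted,
        intended_optimum=intended, seed=seed, noise=noise,
    )


# ---------------------------------------------------------------------------
# packaged printed fixtures
# ---------------------------------------------------------------------------

OVA_SEQUENCE = "RGISQAVHAAHAEI"
PEPTIDE1_SEQUENCE = "RGIFFYVFAAYKEI"

# Per position: (original, [(candidate, beats_original, starred), ...]) in
# the published descending-score order.
_TABLE1 = {
    1: ("ARG", [("LYS", False, False), ("TRP", False, False),
                ("TYR", False, False), ("MET", False, False)]),
    2: ("GLY", [("TYR", True, False), ("PHE", True, False), ("MET", True, False),
                ("SER", False, False), ("THR", False, False)]),
    3: ("ILE", [("LYS", True, False), ("TYR", True, False), ("PHE", True, False),
                ("THR", True, False), ("SER", True, False), ("ILE", True, False),
                ("MET", True, False)]),
    4: ("SER", [("PHE", True, True), ("LEU", True, True), ("ILE", True, True),
                ("VAL", True, False)]),
    5: ("GLN", [("PHE", True, True), ("LYS", True, True), ("MET", True, False)]),
    6: ("ALA", [("TYR", True, True), ("GLN", True, True), ("MET", True, False)]),
    7: ("VAL", [("THR", True, True), ("SER", False, False)]),
    8: ("HIS", [("PHE", True, True), ("LYS", True, True), ("GLU", True, False),
                ("TRP", True, False), ("MET", True, False), ("ILE", True, False),
                ("VAL", True, False)]),
    9: ("ALA", []),
    10: ("ALA", []),
    11: ("HIS", [("TYR", True, True), ("PHE", True, False), ("MET", False, False),
                 ("ILE", False, False), ("LEU", False, False), ("VAL", False, False),
                 ("LYS", False, False)]),
    12: ("ALA", [("LYS", True, True)]),
    13: ("GLU", [("MET", True, False), ("ILE", True, False), ("LEU", True, False),
                 ("VAL", True, False)]),
    14: ("ILE", [("MET", False, False)]),
}

FIRST_SCREEN_COUNTS = (5, 6, 8, 5, 4, 4, 3, 8, 1, 1, 8, 2, 5, 2)
STAGE2_COUNTS = (1, 1, 1, 4, 3, 3, 2, 3, 2, 2, 2, 2, 1, 1)


@dataclass
class PrintedFixtures:
    ova_sequence: str
    peptide1_sequence: str
    table1_candidates: dict[int, tuple[str, list[tuple[str, bool, bool]]]]
    first_screen_counts: tuple[int, ...]
    stage2_counts: tuple[int, ...]


def load_printed_fixtures() -> PrintedFixtures:
    """Verbatim packaged fixture data with product self-checks."""
    fx = PrintedFixtures(
        ova_sequence=OVA_SEQUENCE,
        peptide1_sequence=PEPTIDE1_SEQUENCE,
        table1_candidates={k: (orig, list(cands)) for k, (orig, cands) in _TABLE1.items()},
        first_screen_counts=FIRST_SCREEN_COUNTS,
        stage2_counts=STAGE2_COUNTS,
    )
    if math.prod(fx.first_screen_counts) != 73_728_000:
        raise RuntimeError("corrupted fixture: first-screen count product mismatch")
    if math.prod(fx.stage2_counts) != 3456:
        raise RuntimeError("corrupted fixture: stage-2 count product mismatch")
    if len(fx.ova_sequence) != 14 or len(fx.peptide1_sequence) != 14:
        raise RuntimeError("corrupted fixture: sequence length mismatch")
    return fx


def table1_candidate_table():
    """The packaged per-position candidate lists as a CandidateTable."""
    from .pipeline import CandidateEntry, CandidateTable, PositionScan

    scans = []
    for pos in sorted(_TABLE1):
        original, cands = _TABLE1[pos]
        entries = [CandidateEntry(code, None, beats, starred)
                   for code, beats, starred in cands]
        scans.append(PositionScan(pos, original, None, entries))
    return CandidateTable(scans, gly_score=None, original_sequence=OVA_SEQUENCE)


def paper_selection_rule():
    """Selection rule reproducing the published stage-2 candidate sets."""
    from .pipeline import SelectionRule

    return SelectionRule(
        use_marked=True,
        frozen=(1, 2, 3, 13, 14),
        forced={9: ["GLY"], 10: ["GLY"]},
    )


def ova_toy_complex(seed: int = 0, noise: float = 0.0) -> ComplexStructure:
    """Packaged synthetic stand-in for the crystal template: the 14-mer
    template sequence on an ideal backbone inside a pocket whose planted
    sites favour the published top-ranked design."""
    spec = ova_pocket_spec(seed=seed, noise=noise)
    return make_toy_complex(spec)


def ova_pocket_spec(seed: int = 0, noise: float = 0.0) -> PocketSpec:
    intended = {4: "PHE", 5: "PHE", 6: "TYR", 7: "VAL", 8: "PHE",
                9: "ALA", 10: "ALA", 11: "TYR", 12: "LYS"}
    planted = {4: "ring", 5: "ring", 6: "acceptor", 7: "lipophilic", 8: "ring",
               9: "lipophilic", 10: "lipophilic", 11: "acceptor", 12: "charged-"}
    return PocketSpec(
        n_positions=14,
        planted_sites=planted,
        intended_optimum=intended,
        seed=seed,
        noise=noise,
        peptide_sequence=OVA_SEQUENCE,
    )
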