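"""Two-stage screening: positional scan on the poly-Gly scaffold, candidate
selection, then exhaustive combinatorial enumeration and ranking.

Stage 1 scores every alphabet residue one position at a time (all other
positions Gly) against the all-Gly baseline and keeps those that beat it.
Stage 2 builds every cross-product sequence of the selected per-position
candidate sets on the same fixed backbone and ranks the full-length peptides
by score.  Rotamers are chosen greedily: per (position, residue) the best
feasible grid rotamer in the single-substitution context, with a
deterministic left-to-right fallback when a previously placed side chain
clashes.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import chemistry
from .scoring import ScoreModel, score_complex
from .sidechain import (
    DEFAULT_CHI_GRID,
    DEFAULT_CLASH_TOLERANCE,
    MutatedPeptide,
    Substitution,
    build_gly_scaffold,
    enumerate_rotamers,
    place_sidechain,
    sidechain_clashes,
)
from .structure import (
    DEFAULT_REACH_CUTOFF,
    ComplexStructure,
    peptide_position_contacts,
    extract_pocket,
)

DEFAULT_ENUMERATION_CAP = 1_000_000
#: receptor extraction cutoff for the scoring context; wider than the bare
#: contact definition so that sites reachable only by substituted side
#: chains still enter the pocket
DEFAULT_SCORING_CUTOFF = 12.0


@dataclass
class CandidateEntry:
    code: str
    score: float | None
    beats_original: bool = False
    starred: bool = False


@dataclass
class PositionScan:
    position: int
    original_code: str
    original_score: float | None
    entries: list[CandidateEntry]
    frozen: bool = False


@dataclass
class CandidateTable:
    positions: list[PositionScan]
    gly_score: float | None = None
    original_sequence: str = ""

    def at(self, position: int) -> PositionScan:
        for p in self.positions:
            if p.position == position:
                return p
        raise KeyError(f"no scan for position {position}")


@dataclass
class SelectionRule:
    """Declarative stand-in for the manual candidate picking step."""

    top_k: int = 3
    per_position_k: dict[int, int] = field(default_factory=dict)
    forced: dict[int, list[str]] = field(default_factory=dict)
    frozen: tuple[int, ...] = ()
    use_marked: bool = False

    def k_for(self, position: int) -> int:
        return self.per_position_k.get(position, self.top_k)


@dataclass
class CandidateSets:
    """Per-position allowed residues for stage 2 (3-letter codes, sorted)."""

    sets: list[list[str]]
    frozen: list[bool]
    originals: list[str]

    def counts(self) -> list[int]:
        return [len(s) for s in self.sets]


@dataclass
class ScreenHit:
    rank: int
    sequence: str
    score: float


@dataclass
class ScreenResult:
    entries: list[ScreenHit]
    original_sequence: str
    original_rank: int | None

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# rotamer ranking with caching
# ---------------------------------------------------------------------------

class _Placer:
    """Caches placed side chains and their single-substitution rankings."""

    def __init__(self, complex_, model, pocket_cutoff, grid, clash_tolerance):
        self.complex = complex_
        self.model = model
        self.grid = tuple(grid)
        self.tol = clash_tolerance
        self.scaffold = build_gly_scaffold(complex_.peptide)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.pocket = extract_pocket(complex_, pocket_cutoff)
        # clash context: receptor atoms + scaffold backbone atoms (by position)
        ctx = [(a.pos, a.radius, -1) for a in complex_.receptor_atoms()]
        for res in self.scaffold.residues:
            for a in res.atoms:
                ctx.append((a.pos, a.radius, res.position))
        self._ctx_coords = np.array([c[0] for c in ctx])
        self._ctx_radii = np.array([c[1] for c in ctx])
        self._ctx_pos = np.array([c[2] for c in ctx])
        self._rank_cache: dict[tuple[int, str], list] = {}
        self.baseline = score_complex(
            self.pocket, MutatedPeptide(self.scaffold), model
        ).ludi_score

    def ranked_rotamers(self, position: int, code: str) -> list[tuple[float, int, Substitution]]:
        """Feasible rotamers sorted by descending single-substitution score
        (ties: lowest rotamer index).  Empty if every rotamer clashes; the
        least-overlapping clashing rotamer is appended as a last-resort entry
        with score -inf so enumeration can always emit a sequence."""
        key = (position, code)
        if key in self._rank_cache:
            return self._rank_cache[key]
        mask = self._ctx_pos != position
        ctx_coords = self._ctx_coords[mask]
        ctx_radii = self._ctx_radii[mask]
        scored: list[tuple[float, int, Substitution]] = []
        fallback = None
        for idx, rot in enumerate(enumerate_rotamers(code, self.grid).rotamers):
            mut = place_sidechain(self.scaffold, position, code, rot, idx)
            sub = mut.substitutions[position]
            ok, worst = sidechain_clashes(sub.sidechain_atoms, ctx_coords, ctx_radii, self.tol)
            if not ok:
                if fallback is None or worst < fallback[0]:
                    fallback = (worst, idx, sub)
                continue
            score = score_complex(self.pocket, mut, self.model).ludi_score
            scored.append((score, idx, sub))
        scored.sort(key=lambda t: (-t[0], t[1]))
        if not scored and fallback is not None:
            scored = [(-math.inf, fallback[1], fallback[2])]
        self._rank_cache[key] = scored
        return scored

    def best(self, position: int, code: str):
        ranked = self.ranked_rotamers(position, code)
        if not ranked or ranked[0][0] == -math.inf:
            return None
        return ranked[0]


# ---------------------------------------------------------------------------
# stage 1
# ---------------------------------------------------------------------------

def auto_frozen_positions(
    complex_: ComplexStructure, reach_cutoff: float = DEFAULT_REACH_CUTOFF
) -> tuple[int, ...]:
    """Positions whose residues have no receptor site within side-chain reach
    (the rationale for keeping terminal residues fixed)."""
    frozen = []
    for res in complex_.peptide.residues:
        if not peptide_position_contacts(complex_, res.position, reach_cutoff):
            frozen.append(res.position)
    return tuple(frozen)


def stage1_scan(
    complex_: ComplexStructure,
    model: ScoreModel,
    alphabet: tuple[str, ...] | None = None,
    frozen: tuple[int, ...] | None = None,
    pocket_cutoff: float = DEFAULT_SCORING_CUTOFF,
    grid: tuple[float, ...] = DEFAULT_CHI_GRID,
    clash_tolerance: float = DEFAULT_CLASH_TOLERANCE,
    reach_cutoff: float = DEFAULT_REACH_CUTOFF,
) -> CandidateTable:
    """Positional scan of substitutions against the all-Gly baseline."""
    alphabet = tuple(alphabet) if alphabet is not None else chemistry.DEFAULT_ALPHABET
    for code in alphabet:
        if code not in chemistry.STANDARD_AAS:
            raise ValueError(f"unknown alphabet residue {code!r}")
    if frozen is None:
        frozen = auto_frozen_positions(complex_, reach_cutoff)
    frozen = tuple(frozen)
    placer = _Placer(complex_, model, pocket_cutoff, grid, clash_tolerance)
    scans: list[PositionScan] = []
    for res in complex_.peptide.residues:
        pos = res.position
        original = res.code
        if pos in frozen:
            scans.append(PositionScan(pos, original, None, [], frozen=True))
            continue
        best_by_code: dict[str, float] = {}
        for code in sorted(set(alphabet) | {original}):
            if code == "GLY":
                continue
            best = placer.best(pos, code)
            if best is not None:
                best_by_code[code] = best[0]
        original_score = best_by_code.get(original)
        if original == "GLY":
            original_score = placer.baseline
        entries = [
            CandidateEntry(
                code,
                score,
                beats_original=(original_score is not None and score > original_score),
            )
            for code, score in best_by_code.items()
            if code in alphabet and score > placer.baseline
        ]
        entries.sort(key=lambda e: (-e.score, e.code))
        scans.append(PositionScan(pos, original, original_score, entries))
    return CandidateTable(
        scans, gly_score=placer.baseline,
        original_sequence=complex_.peptide.sequence,
    )


# ---------------------------------------------------------------------------
# stage 2
# ---------------------------------------------------------------------------

def select_candidates(table: CandidateTable, rule: SelectionRule) -> CandidateSets:
    """Apply the declarative selection rule to a candidate table."""
    if rule.top_k < 0 or any(k < 0 for k in rule.per_position_k.values()):
        raise ValueError("top-k must be non-negative")
    sets: list[list[str]] = []
    frozen_flags: list[bool] = []
    originals: list[str] = []
    for scan in table.positions:
        pos = scan.position
        original = scan.original_code
        originals.append(original)
        if pos in rule.frozen or scan.frozen:
            sets.append([original])
            frozen_flags.append(True)
            continue
        if rule.use_marked:
            chosen = [e.code for e in scan.entries if e.starred]
        else:
            above = [e for e in scan.entries if e.beats_original]
            chosen = [e.code for e in above[: rule.k_for(pos)]]
        members = {original, *chosen, *rule.forced.get(pos, [])}
        sets.append(sorted(members))
        frozen_flags.append(False)
    return CandidateSets(sets, frozen_flags, originals)


def library_size(sets_or_counts) -> int:
    """Exact number of cross-product sequences."""
    if isinstance(sets_or_counts, CandidateSets):
        counts = sets_or_counts.counts()
    else:
        counts = [int(c) for c in sets_or_counts]
    if not counts:
        raise ValueError("empty candidate sets")
    if any(c < 1 for c in counts):
        raise ValueError("per-position counts must be >= 1")
    return math.prod(counts)


def stage2_enumerate(
    complex_: ComplexStructure,
    sets: CandidateSets,
    model: ScoreModel,
    cap: int = DEFAULT_ENUMERATION_CAP,
    pocket_cutoff: float = DEFAULT_SCORING_CUTOFF,
    grid: tuple[float, ...] = DEFAULT_CHI_GRID,
    clash_tolerance: float = DEFAULT_CLASH_TOLERANCE,
) -> ScreenResult:
    """Exhaustively score every cross-product sequence and rank descending."""
    n = library_size(sets)
    if n > cap:
        raise ValueError(
            f"library size {n} exceeds the enumeration cap {cap}; "
            "tighten the candidate sets or raise the cap"
        )
    placer = _Placer(complex_, model, pocket_cutoff, grid, clash_tolerance)
    positions = [r.position for r in complex_.peptide.residues]
    gly_sub = Substitution("GLY", (), 0, [])
    results: list[tuple[str, float]] = []
    for combo in itertools.product(*(sorted(s) for s in sets.sets)):
        subs: dict[int, Substitution] = {}
        placed_coords: list[np.ndarray] = []
        placed_radii: list[np.ndarray] = []
        for pos, code in zip(positions, combo):
            if code == "GLY":
                subs[pos] = gly_sub
                continue
            ranked = placer.ranked_rotamers(pos, code)
            chosen = None
            if placed_coords:
                ctx_c = np.vstack(placed_coords)
                ctx_r = np.concatenate(placed_radii)
                for score, idx, sub in ranked:
                    ok, _ = sidechain_clashes(sub.sidechain_atoms, ctx_c, ctx_r, clash_tolerance)
                    if ok:
                        chosen = sub
                        break
            if chosen is None:
                chosen = ranked[0][2] if ranked else gly_sub
            subs[pos] = chosen
            if chosen.sidechain_atoms:
                placed_coords.append(np.array([a.pos for a in chosen.sidechain_atoms]))
                placed_radii.append(np.array([a.radius for a in chosen.sidechain_atoms]))
        mutated = MutatedPeptide(placer.scaffold, subs)
        breakdown = score_complex(placer.pocket, mutated, model)
        seq = "".join(chemistry.THREE_TO_ONE[c] for c in combo)
        results.append((seq, breakdown.ludi_score))
    results.sort(key=lambda t: (-t[1], t[0]))
    entries = [ScreenHit(i + 1, seq, score) for i, (seq, score) in enumerate(results)]
    original_seq = complex_.peptide.sequence
    original_rank = next((e.rank for e in entries if e.sequence == original_seq), None)
    return ScreenResult(entries, original_seq, original_rank)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(x != y for x, y in zip(a, b))


def top_peptides(result: ScreenResult, n: int) -> list[tuple[int, str, float, int]]:
    """First ``n`` ranked rows as (rank, sequence, score, hamming-to-original)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(result.entries):
        warnings.warn(
            f"requested {n} rows but only {len(result.entries)} available; returning all"
        )
        n = len(result.entries)
    return [
        (e.rank, e.sequence, e.score, hamming(e.sequence, result.original_sequence))
        for e in result.entries[:n]
    ]
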