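"""Shared fixtures and independent test oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from pepscreen import (
    ScoreModel,
    build_gly_scaffold,
    extract_pocket,
    stage1_scan,
)
from pepscreen.sidechain import MutatedPeptide, enumerate_rotamers, place_sidechain
from pepscreen.scoring import score_complex
from pepscreen.structure import Atom, ComplexStructure, Residue, annotate_chain
from pepscreen.synthetic import _gly_chain, ova_toy_complex

PAPER_FROZEN = (1, 2, 3, 13, 14)


@pytest.fixture(scope="session")
def model():
    return ScoreModel()


@pytest.fixture(scope="session")
def ova_complex():
    return ova_toy_complex()


@pytest.fixture(scope="session")
def ova_table(ova_complex, model):
    return stage1_scan(ova_complex, model, frozen=PAPER_FROZEN)


def make_probe_complex(n_res=5, sites=(), chain_id="B"):
    """Small complex: ideal-backbone poly-Gly peptide plus explicit pseudo-site
    residues given as (residue_code, [(atom_name, xyz), ...])."""
    from pepscreen.chemistry import PSEUDO_SITE_RESIDUES

    peptide = _gly_chain(n_res)
    receptor = []
    for i, (code, atoms) in enumerate(sites, start=1):
        spec = {a[0]: a for a in PSEUDO_SITE_RESIDUES[code]}
        receptor.append(
            Residue(code, i, chain_id,
                    [Atom(name, spec[name][1], np.asarray(xyz, float))
                     for name, xyz in atoms])
        )
    annotate_chain(receptor)
    chains = {chain_id: receptor} if receptor else {}
    return ComplexStructure(chains, peptide, source="probe")


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def mc_buried_area(target_pos, target_radius, own, others, probe=1.4,
                   n_samples=40000, seed=7):
    """Monte-Carlo rolling-probe area of one atom lost when ``others`` are
    added to the ``own`` context.  Both contexts are lists of (pos, radius)."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n_samples, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts = np.asarray(target_pos) + (target_radius + probe) * pts
    full = 4.0 * np.pi * (target_radius + probe) ** 2

    def exposed_fraction(context):
        mask = np.ones(len(pts), dtype=bool)
        for pos, rad in context:
            d2 = np.sum((pts - np.asarray(pos)) ** 2, axis=1)
            mask &= d2 >= (rad + probe) ** 2
        return mask.mean()

    return full * (exposed_fraction(own) - exposed_fraction(own + list(others)))


def brute_force_stage2(complex_, sets, model, grid=(-60.0, 60.0, 180.0), tol=0.4):
    """Independent enumerate-and-sort oracle implementing the documented
    greedy rotamer rule with plain loops and no caching."""
    scaffold = build_gly_scaffold(complex_.peptide)
    pocket = extract_pocket(complex_, 12.0)
    positions = [r.position for r in complex_.peptide.residues]
    rec = complex_.receptor_atoms()
    base_ctx = [(a.pos, a.radius, -1) for a in rec] + [
        (a.pos, a.radius, r.position)
        for r in scaffold.residues for a in r.atoms
    ]

    def rotamer_order(pos, code):
        order = []
        for idx, rot in enumerate(enumerate_rotamers(code, grid).rotamers):
            mut = place_sidechain(scaffold, pos, code, rot, idx)
            sub = mut.substitutions[pos]
            clash = False
            for a in sub.sidechain_atoms:
                for cpos, crad, owner in base_ctx:
                    if owner == pos:
                        continue
                    if np.linalg.norm(a.pos - cpos) < (a.radius + crad) - tol:
                        clash = True
                        break
                if clash:
                    break
            if clash:
                continue
            order.append((score_complex(pocket, mut, model).ludi_score, idx, sub))
        return sorted(order, key=lambda t: (-t[0], t[1]))

    orders = {}
    rows = []
    from pepscreen.chemistry import THREE_TO_ONE

    for combo in itertools.product(*[list(s) for s in sets.sets]):
        subs = {}
        placed = []
        for pos, code in zip(positions, combo):
            if code == "GLY":
                continue
            if (pos, code) not in orders:
                orders[(pos, code)] = rotamer_order(pos, code)
            chosen = None
            for score, idx, sub in orders[(pos, code)]:
                ok = True
                for a in sub.sidechain_atoms:
                    for ppos, prad in placed:
                        if np.linalg.norm(a.pos - ppos) < (a.radius + prad) - tol:
                            ok = False
                            break
                    if not ok:
                        break
                if ok:
                    chosen = sub
                    break
            if chosen is None and orders[(pos, code)]:
                chosen = orders[(pos, code)][0][2]
            if chosen is not None:
                subs[pos] = chosen
                for a in chosen.sidechain_atoms:
                    placed.append((a.pos, a.radius))
        mut = MutatedPeptide(scaffold, subs)
        seq = "".join(THREE_TO_ONE[c] for c in combo)
        rows.append((seq, score_complex(pocket, mut, model).ludi_score))
    rows.sort(key=lambda t: (-t[1], t[0]))
    return rows
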