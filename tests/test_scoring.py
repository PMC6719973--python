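import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepscreen import (
    ScoreModel,
    build_gly_scaffold,
    dg_to_score,
    extract_pocket,
    place_sidechain,
    score_complex,
    score_to_ki,
)
from pepscreen.geometry import rotation_about_axis
from pepscreen.scoring import (
    GAS_CONSTANT,
    apolar_breakdown,
    apolar_term,
    flexi_term,
    polar_term,
    solv_term,
)
from pepscreen.sidechain import MutatedPeptide
from pepscreen.structure import ReceptorPocket
from pepscreen.synthetic import PocketSpec, _gly_chain, make_toy_complex, random_pocket_spec

from conftest import make_probe_complex, mc_buried_area


def lys_probe_complex(offset_along=2.9, probe="PSA", n_res=7):
    """Lys at the middle of a poly-Gly chain with a probe placed on the NZ
    interaction axis; the probe is far from every other polar atom."""
    bare = make_probe_complex(n_res)
    scaffold = build_gly_scaffold(bare.peptide)
    mid = (n_res + 1) // 2
    mutated = place_sidechain(scaffold, mid, "LYS", (180.0,) * 4)
    nz = next(a for a in mutated.substitutions[mid].sidechain_atoms if a.name == "NZ")
    site_pos = nz.pos + offset_along * nz.direction
    structure = make_probe_complex(n_res, [(probe, [(probe_atom(probe), tuple(site_pos))])])
    return structure, mutated, mid


def probe_atom(code):
    from pepscreen.chemistry import PSEUDO_SITE_RESIDUES

    return PSEUDO_SITE_RESIDUES[code][0][0]


@pytest.fixture(scope="module")
def mdl():
    return ScoreModel()


class TestPolarTerm:
    def test_one_ideal_hbond_exactly_w_hbond(self, mdl):
        structure, mutated, _ = lys_probe_complex(2.9, "PSA")
        pocket = extract_pocket(structure, 12.0)
        energy, contacts = polar_term(pocket, mutated, mdl)
        assert energy == pytest.approx(mdl.w_hbond, abs=1e-12)
        assert len(contacts) == 1 and contacts[0].kind == "hbond"
        assert contacts[0].factor == pytest.approx(1.0)

    def test_pair_beyond_max_distance_contributes_zero(self, mdl):
        structure, mutated, _ = lys_probe_complex(2.9 + mdl.dR_max + 0.05, "PSA")
        pocket = extract_pocket(structure, 12.0)
        energy, contacts = polar_term(pocket, mutated, mdl)
        assert energy == 0.0
        assert contacts == []

    def test_ionic_pair_uses_ionic_weight(self, mdl):
        structure, mutated, _ = lys_probe_complex(2.9, "PSN")
        pocket = extract_pocket(structure, 12.0)
        energy, contacts = polar_term(pocket, mutated, mdl)
        assert energy == pytest.approx(mdl.w_ionic, abs=1e-12)
        assert contacts[0].kind == "ionic"

    def test_two_hbonds_plus_ionic_matches_bruteforce(self, mdl):
        """Independent per-pair summation oracle over the constructed list."""
        spec = PocketSpec(
            planted_sites={3: "acceptor", 7: "charged-"},
            intended_optimum={3: "TYR", 7: "LYS"},
            peptide_sequence="GGYGGGKGG", n_positions=9,
        )
        structure = make_toy_complex(spec)
        pocket = extract_pocket(structure, 12.0)
        energy, contacts = polar_term(pocket, structure.peptide, mdl)
        # brute force: iterate every peptide-atom/pocket-atom pair
        expected = 0.0
        from pepscreen.scoring import _direction_factor, _pair_factor

        for res in structure.peptide.residues:
            for pa in res.atoms:
                if not (pa.is_donor or pa.is_acceptor):
                    continue
                for pr in pocket.residues:
                    for qa in pr.atoms:
                        if not ((pa.is_donor and qa.is_acceptor)
                                or (pa.is_acceptor and qa.is_donor)):
                            continue
                        d = float(np.linalg.norm(pa.pos - qa.pos))
                        f = (_pair_factor(d, mdl)
                             * _direction_factor(pa, qa.pos, mdl)
                             * _direction_factor(qa, pa.pos, mdl))
                        if f > 0:
                            w = mdl.w_ionic if pa.charge * qa.charge < 0 else mdl.w_hbond
                            expected += w * f
        assert energy == pytest.approx(expected, rel=1e-12)
        kinds = sorted(c.kind for c in contacts)
        assert "ionic" in kinds and "hbond" in kinds


class TestApolarTerm:
    def test_polyser_peptide_scores_zero(self, mdl):
        # Ser side chains carry no lipophilic atom (CB is bonded to OG)
        scaffold = _gly_chain(5)
        mutated = None
        for pos in range(1, 6):
            mutated = place_sidechain(mutated or scaffold, pos, "SER", (-60.0,))
        lipo_site = make_probe_complex(
            5, [("PSL", [("PL", (0.0, 8.0, 0.0))])]
        )
        pocket = extract_pocket(lipo_site, 12.0)
        energy, area, n_rings = apolar_breakdown(pocket, mutated, mdl)
        assert (energy, area, n_rings) == (0.0, 0.0, 0)

    def test_separated_lipophilic_atom_zero(self, mdl):
        scaffold = _gly_chain(5)
        mutated = place_sidechain(scaffold, 3, "ALA", ())
        cb = mutated.substitutions[3].sidechain_atoms[0]
        far = cb.pos + np.array([0.0, 0.0, 2 * (1.7 + 1.7 + 2 * mdl.probe_radius)])
        structure = make_probe_complex(5, [("PSL", [("PL", tuple(far))])])
        pocket = extract_pocket(structure, 30.0)
        assert apolar_term(pocket, mutated, mdl) == 0.0

    def test_stacked_ring_matches_surface_oracle(self, mdl):
        spec = PocketSpec(planted_sites={3: "ring"}, intended_optimum={3: "PHE"},
                          peptide_sequence="GGFGG", n_positions=5)
        structure = make_toy_complex(spec)
        pocket = extract_pocket(structure, 12.0)
        energy, area, n_rings = apolar_breakdown(pocket, structure.peptide, mdl)
        assert n_rings == 1
        pep_atoms = [a for r in structure.peptide.residues for a in r.atoms]
        own = [(a.pos, a.radius) for a in pep_atoms]
        others = [(a.pos, a.radius) for r in pocket.residues
                  for a in r.atoms if a.is_lipophilic]
        oracle_area = sum(
            mc_buried_area(a.pos, a.radius, [o for o in own if o[0] is not a.pos],
                           others, probe=mdl.probe_radius)
            for a in pep_atoms if a.is_lipophilic
        )
        assert area == pytest.approx(oracle_area, rel=0.08, abs=1.0)
        assert energy == pytest.approx(mdl.w_aromatic + mdl.w_lipo * area, abs=1e-12)


class TestSolvTerm:
    def test_empty_pocket_zero(self, mdl):
        scaffold = _gly_chain(5)
        pocket = ReceptorPocket([], [])
        assert solv_term(pocket, scaffold, mdl) == 0.0

    def test_compensated_atom_contributes_zero(self, mdl):
        structure, mutated, _ = lys_probe_complex(2.9, "PSA")
        pocket = extract_pocket(structure, 12.0)
        # the probe only buries NZ, and NZ is hydrogen bonded to it
        assert solv_term(pocket, mutated, mdl) == 0.0

    def test_uncompensated_burial_matches_oracle(self, mdl):
        # acceptor-acceptor pairing is impossible, so burial is uncompensated
        bare = make_probe_complex(7)
        scaffold = build_gly_scaffold(bare.peptide)
        mutated = place_sidechain(scaffold, 4, "SER", (-60.0,))
        og = next(a for a in mutated.substitutions[4].sidechain_atoms
                  if a.name == "OG")
        # acceptor probe head-on against OG acting as acceptor: no pairing
        site = og.pos + 3.2 * og.direction
        structure = make_probe_complex(7, [("PSL", [("PL", tuple(site))])])
        pocket = extract_pocket(structure, 12.0)
        energy = solv_term(pocket, mutated, mdl)
        pep_atoms = [a for r in mutated.residues() for a in r.atoms]
        own = [(a.pos, a.radius) for a in pep_atoms]
        others = [(a.pos, a.radius) for a in pocket.atoms()]
        oracle = 0.0
        for a in pep_atoms:
            if a.is_donor or a.is_acceptor:
                oracle += max(0.0, mc_buried_area(
                    a.pos, a.radius, [o for o in own if o[0] is not a.pos],
                    others, probe=mdl.probe_radius))
        assert energy == pytest.approx(mdl.w_solv * oracle, rel=0.1, abs=5e-3)
        assert energy > 0.0


class TestFlexiTerm:
    def test_scaffold_zero(self, mdl):
        scaffold = _gly_chain(6)
        assert flexi_term(MutatedPeptide(scaffold), mdl) == 0.0

    def test_lys_four_rotatable_bonds(self, mdl):
        scaffold = _gly_chain(6)
        mutated = place_sidechain(scaffold, 3, "LYS", (180.0,) * 4)
        assert flexi_term(mutated, mdl) == pytest.approx(4 * mdl.w_rot, abs=1e-15)

    def test_ala_zero(self, mdl):
        scaffold = _gly_chain(6)
        mutated = place_sidechain(scaffold, 3, "ALA", ())
        assert flexi_term(mutated, mdl) == 0.0


class TestScoreComplex:
    def test_empty_pocket_gives_dg0(self, mdl):
        scaffold = _gly_chain(6)
        pocket = ReceptorPocket([], [])
        breakdown = score_complex(pocket, MutatedPeptide(scaffold), mdl)
        assert breakdown.dG_total == mdl.dG0
        assert breakdown.ludi_score == pytest.approx(-mdl.score_coefficient * mdl.dG0)

    @pytest.mark.parametrize("seed", range(5))
    def test_additivity_exact(self, mdl, seed):
        spec = random_pocket_spec(seed, noise=0.2)
        spec.peptide_sequence = None
        structure = make_toy_complex(spec)
        scaffold = build_gly_scaffold(structure.peptide)
        mutated = place_sidechain(scaffold, 5, "LYS", (180.0,) * 4)
        pocket = extract_pocket(structure, 12.0)
        b = score_complex(pocket, mutated, mdl)
        total = b.dG0 + b.dG_polar + b.dG_apolar + b.dG_solv + b.dG_flexi
        assert b.dG_total == pytest.approx(total, rel=1e-12)

    def test_terms_match_individual_operations(self, mdl):
        spec = PocketSpec(
            planted_sites={3: "acceptor", 6: "ring"},
            intended_optimum={3: "TYR", 6: "PHE"},
            peptide_sequence="GGYGGFGG", n_positions=8,
        )
        structure = make_toy_complex(spec)
        pocket = extract_pocket(structure, 12.0)
        peptide = structure.peptide
        b = score_complex(pocket, peptide, mdl)
        assert b.dG_polar == pytest.approx(polar_term(pocket, peptide, mdl)[0], rel=1e-12)
        assert b.dG_apolar == pytest.approx(apolar_term(pocket, peptide, mdl), rel=1e-12)
        assert b.dG_solv == pytest.approx(solv_term(pocket, peptide, mdl), rel=1e-12)
        assert b.dG_flexi == pytest.approx(flexi_term(peptide, mdl), rel=1e-12)

    def test_rigid_body_invariance(self, mdl):
        spec = random_pocket_spec(11, noise=0.1)
        structure = make_toy_complex(spec)
        rot = rotation_about_axis(np.array([0.3, -1.0, 2.0]), 119.0)
        moved = structure.transformed(rot, np.array([-8.0, 3.0, 12.5]))
        b1 = score_complex(extract_pocket(structure, 12.0), structure.peptide, mdl)
        b2 = score_complex(extract_pocket(moved, 12.0), moved.peptide, mdl)
        for term in ("dG_polar", "dG_apolar", "dG_solv", "dG_flexi", "dG_total"):
            assert abs(getattr(b1, term) - getattr(b2, term)) < 1e-6

    def test_adding_ideal_hbond_changes_dg_by_w_hbond(self, mdl):
        with_site, mutated, _ = lys_probe_complex(2.9, "PSA")
        without = make_probe_complex(7)
        b0 = score_complex(extract_pocket(without, 12.0) if without.receptor_chains
                           else ReceptorPocket([], []), mutated, mdl)
        b1 = score_complex(extract_pocket(with_site, 12.0), mutated, mdl)
        assert b1.dG_total - b0.dG_total == pytest.approx(mdl.w_hbond, abs=1e-9)
        assert b1.ludi_score > b0.ludi_score

    def test_rotatable_bonds_lower_score(self, mdl):
        pocket = ReceptorPocket([], [])
        scaffold = _gly_chain(6)
        b0 = score_complex(pocket, MutatedPeptide(scaffold), mdl)
        prev = b0.ludi_score
        for code, nchi in (("SER", 1), ("LEU", 2), ("MET", 3), ("LYS", 4)):
            mutated = place_sidechain(scaffold, 3, code,
                                      tuple(180.0 for _ in range(nchi)))
            b = score_complex(pocket, mutated, mdl)
            assert b.dG_total - b0.dG_total == pytest.approx(nchi * mdl.w_rot, abs=1e-12)
            assert b.ludi_score < prev
            prev = b.ludi_score

    def test_zero_weights_reduce_to_dg0(self):
        model = ScoreModel(w_hbond=0.0, w_ionic=0.0, w_lipo=0.0, w_aromatic=0.0,
                           w_solv=0.0, w_rot=0.0)
        spec = random_pocket_spec(3, noise=0.0)
        structure = make_toy_complex(spec)
        pocket = extract_pocket(structure, 12.0)
        b = score_complex(pocket, structure.peptide, model)
        assert b.dG_total == model.dG0
        assert b.ludi_score == pytest.approx(-model.score_coefficient * model.dG0)


class TestConversions:
    def test_zero_dg_zero_score(self, mdl):
        assert dg_to_score(0.0, mdl) == 0.0

    def test_minus_ten_kcal(self, mdl):
        assert dg_to_score(-10.0, mdl) == pytest.approx(733.3, abs=0.2)

    def test_coefficient_at_298(self, mdl):
        assert abs(mdl.score_coefficient - 73.33) < 0.01

    def test_score_zero_is_molar(self, mdl):
        assert score_to_ki(0.0, mdl) == 1.0

    def test_score_300_is_millimolar(self, mdl):
        assert score_to_ki(300.0, mdl) == pytest.approx(1e-3, rel=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(-30.0, 30.0))
    def test_round_trip_thermodynamic_identity(self, dg):
        model = ScoreModel()
        ki = score_to_ki(dg_to_score(dg, model), model)
        expected = math.exp(dg / (GAS_CONSTANT * model.temperature))
        assert ki == pytest.approx(expected, rel=1e-9)

    def test_model_validation(self):
        with pytest.raises(ValueError):
            ScoreModel(w_hbond=0.5)
        with pytest.raises(ValueError):
            ScoreModel(w_rot=-0.1)
        with pytest.raises(ValueError):
            ScoreModel(dR_tol=0.7, dR_max=0.6)
        with pytest.raises(ValueError):
            ScoreModel(temperature=0.0)
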