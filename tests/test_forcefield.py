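"""Energy engine: dielectric behavior, pair terms, oracle equivalence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seedgrow.forcefield import (COULOMB_CONSTANT, DielectricParams, dielectric,
                                 interaction_energy, pair_energy,
                                 per_residue_profile)
from seedgrow.structio import Atom, Structure

from conftest import brute_force_energy, random_parameterized_structure

P = DielectricParams()


def _atom(coord, q=0.0, r=1.9, eps=0.1, res=1):
    return Atom(serial=1, name="X", element="C", coord=np.array(coord, float),
                charge=q, vdw_radius=r, well_depth=eps, residue_index=res)


class TestDielectric:
    def test_limits(self):
        assert dielectric(1e6) == pytest.approx(P.eps0_water, abs=1e-6)
        assert dielectric(0.0) == pytest.approx(P.A + P.B / (1 + P.k), abs=1e-12)

    def test_monotonically_increasing(self):
        r = np.linspace(0, 50, 400)
        eps = dielectric(r)
        assert np.all(np.diff(eps) > 0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            dielectric(-0.1)

    @given(st.floats(min_value=0, max_value=1e5))
    @settings(max_examples=50, derandomize=True)
    def test_bounded(self, r):
        # mathematically eps_r < eps0_water, but the sigmoid saturates to the
        # bound within double precision a few tens of Angstrom out
        eps = dielectric(r)
        assert P.A + P.B / (1 + P.k) <= eps <= P.eps0_water


class TestPairEnergy:
    def test_lj_minimum_is_minus_well_depth(self):
        a = _atom([0, 0, 0], r=1.7, eps=0.21)
        b = _atom([1.7 + 1.9, 0, 0], r=1.9, eps=0.09)
        lj, _ = pair_energy(a, b)
        assert lj == pytest.approx(-math.sqrt(0.21 * 0.09), abs=1e-12)

    def test_zero_charge_gives_zero_coulomb(self):
        a = _atom([0, 0, 0], q=0.0)
        b = _atom([3, 0, 0], q=0.7)
        assert pair_energy(a, b)[1] == 0.0

    def test_coulomb_hand_calculation(self):
        # unit opposite charges at 3 A: E = -C / (eps_r(3) * 3), with eps_r
        # evaluated from the sigmoidal formula written out by hand
        a = _atom([0, 0, 0], q=1.0)
        b = _atom([3, 0, 0], q=-1.0)
        B = P.eps0_water - P.A
        eps3 = P.A + B / (1 + P.k * math.exp(-P.lam * B * 3.0))
        expected = -COULOMB_CONSTANT / (eps3 * 3.0)
        assert pair_energy(a, b)[1] == pytest.approx(expected, rel=1e-12)

    def test_overlapping_atoms_rejected(self):
        a = _atom([1, 2, 3])
        with pytest.raises(ValueError):
            pair_energy(a, _atom([1, 2, 3]))

    def test_lj_repulsive_wall_and_decay(self):
        a = _atom([0, 0, 0])
        near, _ = pair_energy(a, _atom([0.3, 0, 0]))
        far, _ = pair_energy(a, _atom([60.0, 0, 0]))
        assert near > 1e3
        assert far == pytest.approx(0.0, abs=1e-6) and far < 0


class TestInteractionEnergy:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        lig = random_parameterized_structure(rng, 50, n_residues=5)
        tgt = random_parameterized_structure(rng, 100, chain_id="B")
        rep = interaction_energy(lig, tgt)
        lj, coul, _ = brute_force_energy(lig, tgt)
        assert rep.total[0] == pytest.approx(lj, rel=1e-9)
        assert rep.total[1] == pytest.approx(coul, rel=1e-9)
        assert rep.total[2] == pytest.approx(lj + coul, rel=1e-9)

    def test_per_residue_sums_to_total(self):
        rng = np.random.default_rng(7)
        lig = random_parameterized_structure(rng, 30, n_residues=6)
        tgt = random_parameterized_structure(rng, 40, chain_id="B")
        rep = interaction_energy(lig, tgt)
        assert sum(v[2] for v in rep.per_residue.values()) == pytest.approx(
            rep.total[2], rel=1e-9)
        assert all(v[2] == pytest.approx(v[0] + v[1], rel=1e-12)
                   for v in rep.per_residue.values())

    def test_total_symmetric_under_role_swap(self):
        rng = np.random.default_rng(3)
        a = random_parameterized_structure(rng, 20, n_residues=4)
        b = random_parameterized_structure(rng, 25, n_residues=5, chain_id="B")
        assert interaction_energy(a, b).total[2] == pytest.approx(
            interaction_energy(b, a).total[2], rel=1e-9)

    def test_distant_neutral_ligand_is_zero(self):
        lig = Structure([_atom([1e4, 0, 0], q=0.0)])
        rng = np.random.default_rng(0)
        tgt = random_parameterized_structure(rng, 30, chain_id="B")
        assert abs(interaction_energy(lig, tgt).total[2]) < 1e-10

    def test_first_n_total_covers_leading_residues(self):
        rng = np.random.default_rng(5)
        lig = random_parameterized_structure(rng, 40, n_residues=8)
        tgt = random_parameterized_structure(rng, 30, chain_id="B")
        rep = interaction_energy(lig, tgt, first_n=5)
        manual = sum(v[2] for k, v in rep.per_residue.items() if k <= 5)
        assert rep.first_n_total == pytest.approx(manual, rel=1e-12)

    def test_unparameterized_atom_rejected(self):
        lig = Structure([Atom(serial=1, name="X", element="C",
                              coord=np.zeros(3))])
        tgt = Structure([_atom([3, 0, 0])])
        with pytest.raises(Exception):
            interaction_energy(lig, tgt)


class TestPerResidueProfile:
    def test_single_complex_has_zero_sd_and_count_one(self):
        rng = np.random.default_rng(1)
        lig = random_parameterized_structure(rng, 20, n_residues=4)
        tgt = random_parameterized_structure(rng, 20, chain_id="B")
        prof = per_residue_profile([(lig, tgt)])
        assert all(sd == 0.0 and n == 1 for _, sd, n in prof.values())

    def test_counts_follow_ligand_lengths(self):
        rng = np.random.default_rng(2)
        tgt = random_parameterized_structure(rng, 20, chain_id="B")
        lig5 = random_parameterized_structure(rng, 20, n_residues=5)
        lig8 = random_parameterized_structure(rng, 24, n_residues=8)
        prof = per_residue_profile([(lig5, tgt), (lig8, tgt)])
        assert all(prof[i][2] == 2 for i in range(1, 6))
        assert all(prof[i][2] == 1 for i in range(6, 9))

    def test_planted_contact_dominates(self, planted):
        prof = per_residue_profile([(planted.peptide, planted.target)])
        best = min(prof, key=lambda k: prof[k][0])
        assert best in (1, 2)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            per_residue_profile([])
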