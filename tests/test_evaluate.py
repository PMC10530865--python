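"""Superposition, ligand RMSD, benchmark statistics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from seedgrow import benchmark_stats, ligand_rmsd, superpose_targets
from seedgrow.errors import StructureError
from seedgrow.evaluate import RMSDResult, evaluate_mode
from seedgrow.geometry import apply_rigid
from seedgrow.structio import Atom, Structure


def _ca_chain(coords, chain="T"):
    return Structure([
        Atom(serial=i + 1, name="CA", element="C", coord=np.asarray(c, float),
             residue_index=i + 1, residue_name="GLY", chain_id=chain)
        for i, c in enumerate(coords)])


def _ligand(coords, res_indices, chain="P"):
    return Structure([
        Atom(serial=i + 1, name=f"C{i}", element="C",
             coord=np.asarray(c, float), residue_index=r,
             residue_name="ALA", chain_id=chain)
        for i, (c, r) in enumerate(zip(coords, res_indices))])


@pytest.fixture
def ref_target():
    rng = np.random.default_rng(0)
    return _ca_chain(rng.uniform(-10, 10, (8, 3)))


class TestSuperposeTargets:
    def test_identity_for_identical_targets(self, ref_target):
        R, t = superpose_targets(ref_target, ref_target)
        assert np.allclose(R, np.eye(3), atol=1e-8)
        assert np.allclose(t, 0.0, atol=1e-8)

    def test_inverts_quarter_turn(self, ref_target):
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = ref_target.copy()
        moved.set_coords(moved.coords() @ Rz.T)
        R, t = superpose_targets(moved, ref_target)
        assert np.allclose(R @ Rz, np.eye(3), atol=1e-6)

    def test_recovers_random_rigid_transform(self, ref_target):
        rng = np.random.default_rng(5)
        Rr = Rotation.random(random_state=7).as_matrix()
        tr = rng.uniform(-20, 20, 3)
        moved = ref_target.copy()
        moved.set_coords(apply_rigid(moved.coords(), Rr, tr))
        R, t = superpose_targets(moved, ref_target)
        back = apply_rigid(moved.coords(), R, t)
        rmsd = np.sqrt(((back - ref_target.coords()) ** 2).sum(1).mean())
        assert rmsd < 1e-6

    def test_too_few_common_atoms_rejected(self):
        a = _ca_chain([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(StructureError):
            superpose_targets(a, a)


class TestLigandRmsd:
    def test_identical_ligands_give_zero(self):
        lig = _ligand([[0, 0, 0], [1, 1, 1], [2, 0, 1]], [1, 2, 3])
        assert ligand_rmsd(lig, lig) == 0.0

    @pytest.mark.parametrize("d", [0.5, 2.0, 7.3])
    def test_single_displaced_atom_closed_form(self, d):
        n = 6
        coords = np.arange(n * 3, dtype=float).reshape(n, 3)
        ref = _ligand(coords, [1] * n)
        moved_coords = coords.copy()
        moved_coords[2, 0] += d
        mod = _ligand(moved_coords, [1] * n)
        assert ligand_rmsd(mod, ref) == pytest.approx(d / np.sqrt(n), rel=1e-12)

    def test_matches_direct_formula_on_random_pair(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(-5, 5, (12, 3))
        b = rng.uniform(-5, 5, (12, 3))
        res = [1 + i // 3 for i in range(12)]
        expected = float(np.sqrt(((a - b) ** 2).sum(1).mean()))
        assert ligand_rmsd(_ligand(a, res), _ligand(b, res)) == pytest.approx(
            expected, rel=1e-10)

    def test_first_n_subset_uses_residues_one_to_five(self):
        coords = np.zeros((7, 3))
        coords[:, 0] = np.arange(7)
        ref = _ligand(coords, [1, 2, 3, 4, 5, 6, 7])
        moved = coords.copy()
        moved[6, 1] += 100.0  # residue 7: must not affect the first-5 subset
        mod = _ligand(moved, [1, 2, 3, 4, 5, 6, 7])
        assert ligand_rmsd(mod, ref, "first_n") == 0.0
        assert ligand_rmsd(mod, ref, "full") > 10.0

    def test_hydrogens_excluded(self):
        ref = _ligand([[0, 0, 0]], [1])
        mod = _ligand([[0, 0, 0]], [1])
        for s in (ref, mod):
            s.atoms.append(Atom(serial=9, name="H", element="H",
                                coord=np.array([9.0 if s is mod else 0, 0, 0]),
                                residue_index=1, residue_name="ALA",
                                chain_id="P"))
        assert ligand_rmsd(mod, ref) == 0.0

    def test_correspondence_mismatch_rejected(self):
        a = _ligand([[0, 0, 0], [1, 0, 0]], [1, 2])
        b = _ligand([[0, 0, 0]], [1])
        with pytest.raises(StructureError):
            ligand_rmsd(a, b)

    def test_invariance_under_joint_rigid_transform(self, ref_target):
        rng = np.random.default_rng(13)
        lig_a = _ligand(rng.uniform(-4, 4, (9, 3)), [1, 1, 1, 2, 2, 2, 3, 3, 3])
        lig_b = _ligand(rng.uniform(-4, 4, (9, 3)), [1, 1, 1, 2, 2, 2, 3, 3, 3])
        base = evaluate_mode(ref_target, lig_a, ref_target, lig_b)
        R = Rotation.random(random_state=3).as_matrix()
        t = rng.uniform(-30, 30, 3)
        moved_t = ref_target.copy()
        moved_t.set_coords(apply_rigid(moved_t.coords(), R, t))
        moved_l = lig_a.copy()
        moved_l.set_coords(apply_rigid(moved_l.coords(), R, t))
        moved = evaluate_mode(moved_t, moved_l, ref_target, lig_b)
        assert moved.rmsd_full == pytest.approx(base.rmsd_full, abs=1e-8)


class TestBenchmarkStats:
    def _mode(self, full, first5, score):
        return RMSDResult(rmsd_full=full, rmsd_first5=first5,
                          n_atoms_full=10, n_atoms_first5=5, score=score)

    def test_single_mode_forces_top_equals_best(self):
        stats = benchmark_stats({"sys1": [self._mode(3.0, 2.0, -5.0)]})
        s = stats["systems"]["sys1"]
        assert s.rmsd_top_full == s.rmsd_best_full == 3.0

    def test_perfect_scoring_means_top_equals_best(self):
        # scores ordered exactly like RMSD: the best-scored mode is the best
        modes = [self._mode(5.0, 4.0, -1.0), self._mode(2.0, 1.5, -9.0),
                 self._mode(3.0, 2.5, -4.0)]
        stats = benchmark_stats({"s": modes})
        s = stats["systems"]["s"]
        assert s.rmsd_top_full == s.rmsd_best_full == 2.0

    def test_top_never_below_best(self):
        rng = np.random.default_rng(21)
        systems = {}
        for i in range(6):
            systems[f"s{i}"] = [
                self._mode(float(rng.uniform(1, 9)), float(rng.uniform(1, 9)),
                           float(rng.normal())) for _ in range(5)]
        stats = benchmark_stats(systems)
        for s in stats["systems"].values():
            assert s.rmsd_top_full >= s.rmsd_best_full
            assert s.rmsd_top_first5 >= s.rmsd_best_first5

    def test_summary_matches_hand_computation(self):
        systems = {
            "a": [self._mode(2.0, 1.0, -3.0), self._mode(4.0, 3.0, -1.0)],
            "b": [self._mode(6.0, 5.0, -2.0)],
            "c": [self._mode(3.0, 2.0, -7.0), self._mode(1.0, 0.5, -4.0)],
        }
        stats = benchmark_stats(systems)
        # RMSD_best_full: a->2, b->6, c->1; RMSD_top_full: a->2, b->6, c->3
        best = np.array([2.0, 6.0, 1.0])
        top = np.array([2.0, 6.0, 3.0])
        assert stats["summary"]["rmsd_best_full"] == pytest.approx(
            (best.mean(), best.std()))
        assert stats["summary"]["rmsd_top_full"] == pytest.approx(
            (top.mean(), top.std()))

    def test_empty_system_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            stats = benchmark_stats({"ok": [self._mode(1, 1, -1)], "bad": []})
        assert list(stats["systems"]) == ["ok"]
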