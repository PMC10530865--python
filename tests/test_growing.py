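"""Growing engine contracts: geometry, anchoring, clash-freedom, chirality."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from seedgrow import (GrowthConfig, Pose, assign_parameters, build_fragment,
                      grow_from_all_ranks, grow_peptide)
from seedgrow.fragments import FragmentSpec
from seedgrow.geometry import dihedral

CFG = GrowthConfig(n_models=12, rng_seed=9, protonated_nterm=True)


@pytest.fixture(scope="module")
def true_seed(planted):
    """The planted dipeptide pose, as a docked-seed stand-in."""
    frag = assign_parameters(
        build_fragment(planted.seed_window, planted.sequence,
                       protonated_nterm=True))
    return Pose(structure=frag, score=-1.0, cluster_rank=1)


@pytest.fixture(scope="module")
def models(planted, true_seed):
    return grow_peptide(planted.target, true_seed, planted.sequence,
                        planted.seed_window, CFG)


class TestGrowPeptide:
    def test_full_length_and_bond_geometry(self, models, planted):
        n = len(planted.sequence)
        for m in models:
            assert len(m.residues) == n
            co = {(a.residue_index, a.name): a.coord for a in m.atoms}
            for i in range(1, n):
                d = np.linalg.norm(co[(i, "C")] - co[(i + 1, "N")])
                assert d == pytest.approx(1.33, abs=0.05)

    def test_seed_backbone_anchored(self, models, true_seed):
        ref = {(a.residue_index, a.name): a.coord
               for a in true_seed.structure.atoms
               if a.residue_name not in ("ACE", "NME")
               and a.name in ("N", "CA", "C", "O")}
        for m in models:
            co = {(a.residue_index, a.name): a.coord for a in m.atoms}
            dev = max(np.linalg.norm(co[k] - v) for k, v in ref.items())
            assert dev <= 0.3

    def test_clash_free_against_target(self, models, planted):
        tgt = planted.target
        tc = tgt.coords()[tgt.heavy_mask()]
        tr = tgt.vdw_radii()[tgt.heavy_mask()]
        for m in models:
            hm = m.heavy_mask()
            d = cdist(m.coords()[hm], tc)
            rsum = m.vdw_radii()[hm][:, None] + tr[None, :]
            assert (d >= CFG.clash_factor * rsum).all()

    def test_l_chirality_everywhere(self, models):
        for m in models:
            by_res = {}
            for a in m.atoms:
                by_res.setdefault(a.residue_index, {})[a.name] = a.coord
            for co in by_res.values():
                if "CB" not in co:
                    continue  # glycine
                imp = dihedral(co["N"], co["C"], co["CA"], co["CB"])
                assert -150 < imp < -90  # L-configuration

    def test_deterministic_per_seed(self, planted, true_seed):
        a = grow_peptide(planted.target, true_seed, planted.sequence,
                         planted.seed_window, CFG)
        b = grow_peptide(planted.target, true_seed, planted.sequence,
                         planted.seed_window, CFG)
        assert len(a) == len(b)
        for ma, mb in zip(a, b):
            assert np.array_equal(ma.coords(), mb.coords())

    def test_single_model_boundary(self, planted, true_seed):
        out = grow_peptide(planted.target, true_seed, planted.sequence,
                           planted.seed_window,
                           GrowthConfig(n_models=1, rng_seed=2,
                                        protonated_nterm=True))
        assert len(out) == 1

    def test_models_parameterized(self, models):
        assert all(m.is_parameterized() for m in models)

    def test_internal_seed_grows_both_directions(self, planted):
        seq = planted.sequence
        spec = FragmentSpec(start=4, residues=seq.residues[3:5],
                            n_cap="acetyl")
        frag = assign_parameters(build_fragment(spec, seq))
        # place the capped fragment far from the receptor: free-space growth
        s = frag.copy()
        s.set_coords(s.coords() + np.array([0.0, 0.0, 60.0]))
        pose = Pose(structure=s, score=0.0, cluster_rank=1)
        out = grow_peptide(planted.target, pose, seq, spec,
                           GrowthConfig(n_models=3, rng_seed=1))
        for m in out:
            assert [r[1] for r in m.residues] == list(range(1, len(seq) + 1))
            names = {(a.residue_index, a.name) for a in m.atoms}
            assert (1, "H2") in names  # free N-terminal amine regrown

    def test_rng_seed_robustness_of_pool_energy(self, planted, true_seed):
        from seedgrow import interaction_energy
        med = []
        for seed in (1, 2):
            ms = grow_peptide(planted.target, true_seed, planted.sequence,
                              planted.seed_window,
                              GrowthConfig(n_models=15, rng_seed=seed,
                                           protonated_nterm=True))
            es = [interaction_energy(m, planted.target).total[2] for m in ms]
            med.append(np.median(es))
        assert abs(med[0] - med[1]) < 0.1 * abs(np.mean(med))


class TestGrowFromAllRanks:
    def test_pool_tagging_and_size(self, planted, true_seed):
        import dataclasses
        reps = [true_seed,
                dataclasses.replace(true_seed, cluster_rank=2)]
        pool = grow_from_all_ranks(planted.target, reps, planted.sequence,
                                   planted.seed_window,
                                   GrowthConfig(n_models=5, rng_seed=3,
                                                protonated_nterm=True))
        assert len(pool) <= 10
        assert {gm.seed_rank for gm in pool} <= {1, 2}
        assert [gm.model_id for gm in pool] == list(range(1, len(pool) + 1))

    def test_failing_rank_demoted_to_warning(self, planted, true_seed):
        import dataclasses
        # a rank buried inside the receptor cannot grow anything
        buried = true_seed.structure.copy()
        center = planted.target.coords().mean(axis=0)
        buried.set_coords(buried.coords() - buried.coords().mean(axis=0)
                          + center)
        bad = Pose(structure=buried, score=0.0, cluster_rank=2)
        reps = [true_seed, bad]
        with pytest.warns(UserWarning):
            pool = grow_from_all_ranks(
                planted.target, reps, planted.sequence, planted.seed_window,
                GrowthConfig(n_models=4, rng_seed=3, max_retries=3,
                             restart_factor=2, protonated_nterm=True))
        assert pool and {gm.seed_rank for gm in pool} == {1}

    def test_pool_deterministic(self, planted, true_seed):
        cfg = GrowthConfig(n_models=4, rng_seed=8, protonated_nterm=True)
        a = grow_from_all_ranks(planted.target, [true_seed], planted.sequence,
                                planted.seed_window, cfg)
        b = grow_from_all_ranks(planted.target, [true_seed], planted.sequence,
                                planted.seed_window, cfg)
        for ga, gb in zip(a, b):
            assert np.array_equal(ga.structure.coords(), gb.structure.coords())
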