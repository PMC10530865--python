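import numpy as np
import pytest

from seedgrow import (DielectricParams, FragmentSpec, PeptideSequence,
                      assign_parameters, build_fragment, make_planted_complex)
from seedgrow.structio import Atom, Structure


@pytest.fixture(scope="session")
def planted():
    """One shared planted complex (8 residues, seed 1)."""
    return make_planted_complex(8, rng_seed=1)


@pytest.fixture(scope="session")
def h3_seq():
    return PeptideSequence("ARTKQTARKSTGGKA")


@pytest.fixture(scope="session")
def capped_ar_fragment(h3_seq):
    """Double-capped AR dipeptide (window 7), parameterized."""
    spec = FragmentSpec(start=7, residues="AR", n_cap="acetyl")
    return assign_parameters(build_fragment(spec, h3_seq))


def random_parameterized_structure(rng, n_atoms, n_residues=1, spread=10.0,
                                   chain_id="A"):
    """Random atom cloud with plausible parameters, for energy oracles."""
    atoms = []
    for i in range(n_atoms):
        atoms.append(Atom(
            serial=i + 1, name=f"X{i}", element="C",
            coord=rng.uniform(-spread, spread, 3),
            charge=float(rng.uniform(-0.5, 0.5)),
            vdw_radius=float(rng.uniform(1.2, 2.0)),
            well_depth=float(rng.uniform(0.02, 0.3)),
            residue_index=1 + i % n_residues,
            residue_name="UNK", chain_id=chain_id))
    return Structure(atoms)


def brute_force_energy(ligand, target, p=DielectricParams()):
    """Independent double-loop oracle for the pairwise interaction energy."""
    lj_total, coul_total = 0.0, 0.0
    per_res = {}
    for a in ligand.atoms:
        for b in target.atoms:
            r = float(np.linalg.norm(np.asarray(a.coord) - np.asarray(b.coord)))
            rij = a.vdw_radius + b.vdw_radius
            eij = (a.well_depth * b.well_depth) ** 0.5
            lj = eij * ((rij / r) ** 12 - 2 * (rij / r) ** 6)
            eps = p.A + (p.eps0_water - p.A) / (
                1 + p.k * np.exp(-p.lam * (p.eps0_water - p.A) * r))
            coul = 332.0637 * a.charge * b.charge / (eps * r)
            lj_total += lj
            coul_total += coul
            ent = per_res.setdefault(a.residue_index, [0.0, 0.0])
            ent[0] += lj
            ent[1] += coul
    return lj_total, coul_total, per_res
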