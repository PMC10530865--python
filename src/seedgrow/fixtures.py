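"""Synthetic receptor-peptide complexes with planted ground truth.

The generator builds a peptide (histone-tail prefix, extended conformation)
and then constructs a toy receptor *around* its first two residues: a groove
of carbonyl-like carbon/oxygen probe pairs lining the lower hemisphere of
the N-terminal segment at van der Waals contact distance, plus a few buried
"C-alpha" marker atoms that give the evaluation stage something to superpose
on.  By construction the first two peptide residues make the dominant
(most negative) per-residue interaction energy and the planted pose is
clash-free, which mirrors the binding pattern of histone tails on reader
domains: the N-terminal anchor binds, the C-terminal end floats in bulk.

Fixtures exercise the mechanics of the pipeline; they are not a substitute
for validation against experimental complexes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.distance import cdist

from .builder import CHI1_ATOM, set_chi1
from .fragments import FragmentSpec, PeptideSequence, H3_SEQUENCE
from .geometry import rotate_about_axis
from .seeding import SearchBox
from .structio import Atom, Structure, assign_parameters
from .builder import build_chain

_PROBE_DISTANCE = 3.5    # polar probe offset from peptide heavy atoms (A)
_BACKING_DISTANCE = 6.9  # outer wall offset: blocks back-side docking
_MIN_ANCHOR_DIST = 3.0   # probe clearance from anchor-residue heavy atoms
_MIN_TAIL_DIST = 4.0     # wider clearance along the tail: growth corridor
_MIN_PROBE_DIST = 2.8    # probe-probe clearance


@dataclasses.dataclass
class PlantedComplex:
    """A toy complex whose true bound peptide conformation is known."""

    target: Structure
    peptide: Structure
    seed_window: FragmentSpec
    sequence: PeptideSequence
    rng_seed: int
    protonated_nterm: bool = True

    @property
    def box(self) -> SearchBox:
        """Default search box centered on the planted peptide centroid."""
        center = self.peptide.coords().mean(axis=0)
        return SearchBox(center=tuple(float(x) for x in center))


def make_planted_complex(n_res: int = 8, rng_seed: int = 0,
                         anchor_residues: int = 2) -> PlantedComplex:
    """Build a planted complex of `n_res` peptide residues (5..15).

    The groove encloses heavy atoms of the first `anchor_residues` residues.
    Deterministic for a fixed `rng_seed`.
    """
    if not 5 <= n_res <= 15:
        raise ValueError("n_res must be in 5..15")
    rng = np.random.default_rng(rng_seed)
    seq = PeptideSequence(H3_SEQUENCE[:n_res])
    # protonated N-terminal ammonium: the physiological state, and the specific
    # anchor that reader-domain pockets recognize
    peptide = build_chain([seq.residue_name(i + 1) for i in range(n_res)],
                          chain_id="P", protonated_nterm=True)
    peptide = assign_parameters(peptide)

    anchor = [a for a in peptide.atoms
              if not a.is_hydrogen and a.residue_index <= anchor_residues]
    pep_heavy = np.array([a.coord for a in peptide.atoms if not a.is_hydrogen])
    # clearance radius per peptide heavy atom: tight around the anchor, wide
    # along the tail so the pocket mouth leaves a growth corridor
    clearance = np.array([
        _MIN_ANCHOR_DIST if a.residue_index <= anchor_residues else _MIN_TAIL_DIST
        for a in peptide.atoms if not a.is_hydrogen])

    # half-open groove: probe sites below and beside the anchor segment
    directions = []
    for theta in (95.0, 120.0, 150.0, 180.0):  # polar angle from +z, degrees
        for phi_d in (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0):
            th, ph = np.radians(theta), np.radians(phi_d)
            directions.append(np.array([np.sin(th) * np.cos(ph),
                                        np.sin(th) * np.sin(ph), np.cos(th)]))
    probes: list[np.ndarray] = []
    backing: list[np.ndarray] = []
    for a in anchor:
        for d in directions:
            pos = a.coord + _PROBE_DISTANCE * d + rng.normal(scale=0.05, size=3)
            if (cdist(pos[None], pep_heavy)[0] < clearance).any():
                continue
            if probes and cdist(pos[None], np.array(probes)).min() < _MIN_PROBE_DIST:
                continue
            probes.append(pos)
    # outer wall one contact-shell further out: makes the groove a concave
    # pocket rather than a free-floating shell of probes
    for a in anchor:
        for d in directions:
            pos = a.coord + _BACKING_DISTANCE * d + rng.normal(scale=0.05, size=3)
            if (cdist(pos[None], pep_heavy)[0] < clearance).any():
                continue
            others = probes + backing
            if others and cdist(pos[None], np.array(others)).min() < _MIN_PROBE_DIST:
                continue
            backing.append(pos)

    atoms: list[Atom] = []
    # buried superposition markers, well below the groove
    lo = pep_heavy[:, 2].min() - 10.0
    span = pep_heavy[:, 0].max() - pep_heavy[:, 0].min()
    for i, (fx, fy) in enumerate(((0.15, 0.0), (0.45, 2.0), (0.75, -2.0),
                                  (0.95, 0.5))):
        pos = np.array([pep_heavy[:, 0].min() + fx * span, fy, lo])
        atoms.append(Atom(serial=len(atoms) + 1, name="CA", element="C",
                          coord=pos, residue_index=len(atoms) + 1,
                          residue_name="GLY", chain_id="T"))
    # probe identity complements the local peptide charge: oxygen (negative)
    # probes face positive peptide groups and carbon (positive) probes face
    # negative ones, so the planted orientation is the electrostatic optimum
    pep_all = peptide.coords()
    pep_q = np.array([0.0 if a.charge is None else a.charge
                      for a in peptide.atoms])
    for pos in probes:
        d = cdist(pos[None], pep_all)[0]
        local_q = float((pep_q / np.maximum(d, 1.0) ** 2).sum())
        name = "O" if local_q > 0 else "C"
        atoms.append(Atom(serial=len(atoms) + 1, name=name,
                          element=name, coord=pos,
                          residue_index=len(atoms) + 1,
                          residue_name="GLY", chain_id="T"))
    for i, pos in enumerate(backing):
        name = "C" if i % 2 == 0 else "O"  # wall: alternating, net-neutral
        atoms.append(Atom(serial=len(atoms) + 1, name=name,
                          element=name, coord=pos,
                          residue_index=len(atoms) + 1,
                          residue_name="GLY", chain_id="T"))
    target = assign_parameters(Structure(atoms))

    planted = PlantedComplex(
        target=target, peptide=peptide,
        seed_window=FragmentSpec(start=1, residues=seq.residues[:2], n_cap=None),
        sequence=seq, rng_seed=rng_seed)
    _assert_clash_free(planted)
    return planted


def _assert_clash_free(pc: PlantedComplex, clash_factor: float = 0.7) -> None:
    pep = pc.peptide
    tgt = pc.target
    hp = pep.heavy_mask()
    ht = tgt.heavy_mask()
    d = cdist(pep.coords()[hp], tgt.coords()[ht])
    rsum = pep.vdw_radii()[hp][:, None] + tgt.vdw_radii()[ht][None, :]
    if (d < clash_factor * rsum).any():
        raise AssertionError("planted peptide clashes with generated receptor")


def perturb_pose(s: Structure, magnitude: float, rng_seed: int = 0) -> Structure:
    """Random rigid displacement plus per-dihedral (chi1) noise.

    `magnitude` (A) scales both the translation (normal, sd = magnitude) and
    the rotation/torsion angles (sd = 10 deg per unit magnitude); the RMSD to
    the input grows with magnitude in expectation.  Deterministic per seed.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    out = s.copy()
    if magnitude == 0:
        return out
    rng = np.random.default_rng(rng_seed)
    coords = out.coords()
    centroid = coords.mean(axis=0)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.normal(scale=10.0 * magnitude)
    coords = rotate_about_axis(coords, centroid, axis, angle)
    coords = coords + rng.normal(scale=magnitude, size=3)
    out.set_coords(coords)
    # chi1 torsion noise, residue by residue
    by_res: dict[int, list[int]] = {}
    for i, a in enumerate(out.atoms):
        by_res.setdefault(a.residue_index, []).append(i)
    coords = out.coords()
    for ri, idxs in by_res.items():
        resname = out.atoms[idxs[0]].residue_name
        if resname not in CHI1_ATOM or resname == "PRO":
            continue
        names = {out.atoms[i].name: coords[i] for i in idxs}
        if "CB" not in names or CHI1_ATOM[resname] not in names:
            continue
        from .geometry import dihedral
        cur = dihedral(names["N"], names["CA"], names["CB"],
                       names[CHI1_ATOM[resname]])
        rotated = set_chi1(resname, names, cur + rng.normal(scale=10.0 * magnitude))
        for i in idxs:
            coords[i] = rotated[out.atoms[i].name]
    out.set_coords(coords)
    return out
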