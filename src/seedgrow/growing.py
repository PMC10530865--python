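"""In-situ growing of the full peptide from a docked dipeptide seed.

The docked seed's two residues stay fixed (their backbone is the anchor the
growing never moves); the caps are removed and their heavy atoms pin the
backbone torsions across the seed boundary, so the seed geometry is
preserved exactly.  The chain is then extended one residue at a time,
N-ward from the seed down to residue 1 first, then C-ward to the terminus.
Each extension draws backbone torsions from weighted Ramachandran basins
(alpha / beta / polyproline-II) and a chi1 rotamer, builds the residue with
ideal internal coordinates, rejects placements whose heavy atoms approach
target or already-built ligand heavy atoms closer than
``clash_factor x (R_i + R_j)``, and keeps the surviving draw with the best
incremental interaction energy against the target.  A model that cannot
place some residue within the retry budget is discarded and regrown.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy.spatial.distance import cdist

from . import params
from .builder import (CHI1_ATOM, CHI1_ROTAMERS, OMEGA, BOND_CA_C, BOND_N_CA,
                      ANGLE_CA_C_N, ANGLE_C_N_CA, ANGLE_N_CA_C,
                      assemble_structure, place_amide_h, place_carbonyl_o,
                      place_terminal_amine_h, residue_from_anchors)
from .errors import GrowthError, StructureError
from .forcefield import DielectricParams, energy_components
from .fragments import FragmentSpec, PeptideSequence
from .geometry import nerf_place
from .seeding import Pose
from .structio import Structure, assign_parameters

log = logging.getLogger(__name__)

#: (phi range, psi range, weight) Ramachandran basins: alpha, beta, PPII
DEFAULT_BASINS: tuple[tuple[tuple[float, float], tuple[float, float], float], ...] = (
    ((-80.0, -55.0), (-50.0, -25.0), 0.35),   # alpha helix
    ((-150.0, -110.0), (110.0, 150.0), 0.45),  # beta strand
    ((-80.0, -60.0), (135.0, 165.0), 0.20),    # polyproline II
)


@dataclasses.dataclass(frozen=True)
class GrowthConfig:
    n_models: int = 100
    candidates_per_residue: int = 8
    clash_factor: float = 0.7
    max_retries: int = 50
    rng_seed: int = 0
    ramachandran_basins: tuple = DEFAULT_BASINS
    restart_factor: int = 4  # growth attempts allowed per requested model
    protonated_nterm: bool = False  # charge state given to a grown N-terminus

    def __post_init__(self):
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if not 0.0 < self.clash_factor < 1.0:
            raise ValueError("clash_factor must be in (0, 1)")
        w = sum(b[2] for b in self.ramachandran_basins)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("basin weights must sum to 1")


@dataclasses.dataclass
class GrownModel:
    """One full-length peptide model with its provenance."""

    model_id: int
    seed_rank: int
    structure: Structure


def _element_of(name: str) -> str:
    if name.startswith("H"):
        return "H"
    if name.startswith("S"):
        return "S"
    return name[0]


def _draw_phipsi(rng: np.random.Generator, basins) -> tuple[float, float]:
    weights = np.array([b[2] for b in basins])
    i = int(rng.choice(len(basins), p=weights / weights.sum()))
    (plo, phi_), (slo, shi), _ = basins[i]
    return float(rng.uniform(plo, phi_)), float(rng.uniform(slo, shi))


class _TargetArrays:
    def __init__(self, target: Structure):
        self.coords = target.coords()
        self.q = target.charges()
        self.r = target.vdw_radii()
        self.e = target.well_depths()
        heavy = target.heavy_mask()
        self.heavy_coords = self.coords[heavy]
        self.heavy_r = self.r[heavy]


def _residue_arrays(resname: str, atoms: dict[str, np.ndarray]):
    names = list(atoms)
    coords = np.array([atoms[n] for n in names])
    qmap = params.residue_charges(resname, names)
    q = np.array([qmap[n] for n in names])
    rad = np.empty(len(names))
    eps = np.empty(len(names))
    heavy = np.empty(len(names), dtype=bool)
    for i, n in enumerate(names):
        el = _element_of(n)
        rad[i], eps[i] = params.vdw_params(resname, n, el)
        heavy[i] = el != "H"
    return names, coords, q, rad, eps, heavy


class _Grower:
    def __init__(self, target: Structure, seed: Pose, full_seq: PeptideSequence,
                 spec: FragmentSpec, cfg: GrowthConfig,
                 p: DielectricParams):
        self.t = _TargetArrays(target)
        self.seq = full_seq
        self.spec = spec
        self.cfg = cfg
        self.p = p
        self.seed_res: dict[int, tuple[str, dict[str, np.ndarray]]] = {}
        self.ace_c: np.ndarray | None = None
        self.nme_n: np.ndarray | None = None
        for a in seed.structure.atoms:
            if a.residue_name == "ACE":
                if a.name == "C":
                    self.ace_c = np.array(a.coord, float)
                continue
            if a.residue_name == "NME":
                if a.name == "N":
                    self.nme_n = np.array(a.coord, float)
                continue
            name_map = self.seed_res.setdefault(
                a.residue_index, (a.residue_name, {}))[1]
            name_map[a.name] = np.array(a.coord, float)
        if self.nme_n is None:
            raise StructureError("seed pose lacks its C-terminal cap nitrogen")
        if spec.start > 1 and self.ace_c is None:
            raise StructureError("internal seed pose lacks its acetyl cap carbon")

    # --- clash and scoring helpers ---
    def _clashes(self, cand_coords, cand_r, cand_heavy,
                 state: dict[int, tuple[str, dict[str, np.ndarray]]],
                 exclude: set[int]) -> bool:
        cc = cand_coords[cand_heavy]
        cr = cand_r[cand_heavy]
        d = cdist(cc, self.t.heavy_coords)
        if (d < self.cfg.clash_factor * (cr[:, None] + self.t.heavy_r[None, :])).any():
            return True
        for ri, (resname, atoms) in state.items():
            if ri in exclude:
                continue
            names = [n for n in atoms if _element_of(n) != "H"]
            if not names:
                continue
            oc = np.array([atoms[n] for n in names])
            orad = np.array([params.vdw_params(resname, n, _element_of(n))[0]
                             for n in names])
            d = cdist(cc, oc)
            if (d < self.cfg.clash_factor * (cr[:, None] + orad[None, :])).any():
                return True
        return False

    def _incremental_energy(self, coords, q, rad, eps) -> float:
        lj, coul = energy_components(coords, q, rad, eps, self.t.coords,
                                     self.t.q, self.t.r, self.t.e, self.p)
        return float(lj.sum() + coul.sum())

    # --- one growth attempt ---
    def grow_once(self, rng: np.random.Generator) -> Structure | None:
        state = {ri: (rn, dict(atoms)) for ri, (rn, atoms) in self.seed_res.items()}
        s = self.spec.start
        n_res = len(self.seq)
        # N-ward: s-1 ... 1, then C-ward: s+2 ... n_res
        for pos in list(range(s - 1, 0, -1)) + list(range(s + 2, n_res + 1)):
            if not self._place_residue(pos, state, rng):
                return None
        self._finalize_termini(state, rng)
        entries = [(ri, state[ri][0], state[ri][1]) for ri in sorted(state)]
        model = assemble_structure(entries, chain_id="P")
        return assign_parameters(model)

    def _place_residue(self, pos: int, state, rng) -> bool:
        nward = pos < self.spec.start
        anchor_pos = pos + 1 if nward else pos - 1
        resname = self.seq.residue_name(pos)
        _, anchor = state[anchor_pos]
        for _attempt in range(self.cfg.max_retries):
            best: tuple[float, dict[str, np.ndarray]] | None = None
            for _ in range(self.cfg.candidates_per_residue):
                atoms = self._build_candidate(pos, resname, state, rng)
                if atoms is None:
                    continue
                names, coords, q, rad, eps, heavy = _residue_arrays(resname, atoms)
                if self._clashes(coords, rad, heavy, state, {anchor_pos, pos}):
                    continue
                if not self._neighbor_o_admissible(pos, atoms, state):
                    continue
                e = self._incremental_energy(coords, q, rad, eps)
                if best is None or e < best[0]:
                    best = (e, atoms)
            if best is not None:
                state[pos] = (resname, best[1])
                self._update_neighbors(pos, state)
                return True
        return False

    def _neighbor_o_admissible(self, pos, atoms, state) -> bool:
        """Accepting this candidate re-points the previous residue's carbonyl O
        at its new N (C-ward growth); that moved O must stay clash-free."""
        s = self.spec.start
        if pos <= s + 1 or pos - 1 == s + 1:
            return True  # N-ward growth or seed boundary: no O moves
        _, dn = state[pos - 1]
        new_o = place_carbonyl_o(dn["N"], dn["CA"], dn["C"], atoms["N"])
        o_rad = params.vdw_params("GLY", "O", "O")[0]
        d = cdist(new_o[None], self.t.heavy_coords)[0]
        if (d < self.cfg.clash_factor * (o_rad + self.t.heavy_r)).any():
            return False
        for ri, (resname, ratoms) in state.items():
            if ri in (pos - 2, pos - 1, pos):
                continue
            for n, c in ratoms.items():
                if _element_of(n) == "H":
                    continue
                rj = params.vdw_params(resname, n, _element_of(n))[0]
                if np.linalg.norm(new_o - c) < self.cfg.clash_factor * (o_rad + rj):
                    return False
        return True

    def _build_candidate(self, pos, resname, state, rng):
        phi, psi = _draw_phipsi(rng, self.cfg.ramachandran_basins)
        chi1 = (float(rng.choice(CHI1_ROTAMERS))
                if resname in CHI1_ATOM and resname != "PRO" else None)
        if resname == "PRO":
            phi = -65.0
        s = self.spec.start
        if pos < s:  # N-ward
            _, nxt = state[pos + 1]
            n1, ca1 = nxt["N"], nxt["CA"]
            if pos == s - 1:
                c0 = self.ace_c  # pinned by the removed acetyl cap
            else:
                c0 = nerf_place(nxt["C"], ca1, n1, 1.335, ANGLE_C_N_CA, phi)
            ca0 = nerf_place(ca1, n1, c0, BOND_CA_C, ANGLE_CA_C_N, OMEGA)
            n0 = nerf_place(n1, c0, ca0, BOND_N_CA, ANGLE_N_CA_C, psi)
            atoms = residue_from_anchors(resname, n0, ca0, c0, chi1=chi1)
            atoms["O"] = place_carbonyl_o(n0, ca0, c0, n1)
            return atoms
        # C-ward
        _, prev = state[pos - 1]
        n1, ca1, c1 = prev["N"], prev["CA"], prev["C"]
        if pos == s + 2:
            n2 = self.nme_n  # pinned by the removed N-methyl cap
        else:
            psi_prev = _draw_phipsi(rng, self.cfg.ramachandran_basins)[1]
            n2 = nerf_place(n1, ca1, c1, 1.335, ANGLE_CA_C_N, psi_prev)
        ca2 = nerf_place(ca1, c1, n2, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c2 = nerf_place(c1, n2, ca2, BOND_CA_C, ANGLE_N_CA_C, phi)
        atoms = residue_from_anchors(resname, n2, ca2, c2, chi1=chi1)
        # provisional carbonyl O from this draw's psi; re-placed on extension
        atoms["O"] = place_carbonyl_o(
            n2, ca2, c2, nerf_place(n2, ca2, c2, 1.335, ANGLE_CA_C_N, psi))
        if resname != "PRO":
            atoms["H"] = place_amide_h(n2, ca2, c1)
        return atoms

    def _update_neighbors(self, pos, state):
        """Re-place neighbor atoms that depend on the new residue."""
        s = self.spec.start
        if pos < s:
            # the residue above now has a preceding carbonyl: place its amide H
            up_name, up = state[pos + 1]
            if up_name != "PRO" and pos + 1 != s:
                up["H"] = place_amide_h(up["N"], up["CA"], state[pos][1]["C"])
        else:
            # previous residue's carbonyl O now points anti to the new N
            dn_name, dn = state[pos - 1]
            if pos - 1 != s + 1:
                dn["O"] = place_carbonyl_o(dn["N"], dn["CA"], dn["C"],
                                           state[pos][1]["N"])

    def _finalize_termini(self, state, rng):
        if self.spec.start > 1:
            rn1, r1 = state[1]
            if rn1 != "PRO":
                r1.pop("H", None)
                r1.update(place_terminal_amine_h(
                    r1["N"], r1["CA"], r1["C"],
                    protonated=self.cfg.protonated_nterm))


def grow_peptide(target: Structure, seed: Pose, full_seq: PeptideSequence,
                 spec: FragmentSpec, cfg: GrowthConfig = GrowthConfig(),
                 p: DielectricParams = DielectricParams()) -> list[Structure]:
    """Grow up to `cfg.n_models` full-length peptide models from one seed pose.

    Deterministic for a fixed `cfg.rng_seed`.  Raises GrowthError if not a
    single model can be grown within the retry budget.
    """
    if not target.is_parameterized():
        raise StructureError("target must be parameterized")
    grower = _Grower(target, seed, full_seq, spec, cfg, p)
    rng = np.random.default_rng(cfg.rng_seed)
    models: list[Structure] = []
    attempts = 0
    budget = cfg.n_models * cfg.restart_factor
    while len(models) < cfg.n_models and attempts < budget:
        attempts += 1
        m = grower.grow_once(rng)
        if m is not None:
            models.append(m)
    if not models:
        raise GrowthError(
            "no model could be grown; consider loosening clash_factor")
    if len(models) < cfg.n_models:
        warnings.warn(f"grew only {len(models)}/{cfg.n_models} models")
    return models


def grow_from_all_ranks(target: Structure, representatives: list[Pose],
                        full_seq: PeptideSequence, spec: FragmentSpec,
                        cfg: GrowthConfig = GrowthConfig(),
                        p: DielectricParams = DielectricParams()
                        ) -> list[GrownModel]:
    """Model pool: union of `grow_peptide` over all seed representatives.

    Each representative uses an independent RNG stream derived from
    (cfg.rng_seed, rank); per-rank failures are demoted to warnings.
    """
    if not representatives:
        raise ValueError("no seed representatives")
    pool: list[GrownModel] = []
    for pose in representatives:
        rank = pose.cluster_rank if pose.cluster_rank is not None else 1
        sub = dataclasses.replace(
            cfg, rng_seed=int(np.random.SeedSequence(
                entropy=cfg.rng_seed, spawn_key=(rank,)).generate_state(1)[0]
                % (2**31)))
        try:
            models = grow_peptide(target, pose, full_seq, spec, sub, p)
        except GrowthError as exc:
            warnings.warn(f"seed rank {rank}: {exc}")
            log.warning("seed rank %s failed: %s", rank, exc)
            continue
        for m in models:
            pool.append(GrownModel(model_id=len(pool) + 1, seed_rank=rank,
                                   structure=m))
    return pool
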