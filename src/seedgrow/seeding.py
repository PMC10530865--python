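"""Seed docking: place the capped dipeptide in the target's binding region.

The docker is a deterministic, seeded rigid-body search: fragment conformers
(side-chain rotamer spins) x uniformly sampled orientations x a translation
grid inside the search box, scored with the intermolecular energy, with the
best placements refined by greedy rigid-body coordinate descent.  Several
independent replicates (fresh orientation draws) are merged, mirroring the
convention of running a stochastic docking engine several times.  Poses are
then grouped by greedy leader clustering on heavy-atom RMSD (no
superposition: poses share the target frame) and one representative per
cluster rank proceeds to the growing stage.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .builder import CHI1_ATOM, CHI1_ROTAMERS, set_chi1
from .errors import StructureError
from .forcefield import (COULOMB_CONSTANT, DielectricParams, energy_components,
                         interaction_energy)
from .structio import Structure, read_structure

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class SearchBox:
    """Axis-aligned search region: grid-point counts x spacing, as in grid-based
    docking (default 60 x 60 x 60 points at 0.375 A)."""

    center: tuple[float, float, float]
    n_points: tuple[int, int, int] = (60, 60, 60)
    spacing: float = 0.375

    @property
    def extent(self) -> np.ndarray:
        return (np.asarray(self.n_points) - 1) * self.spacing

    def contains(self, coords: np.ndarray) -> np.ndarray:
        half = self.extent / 2.0
        d = np.abs(np.asarray(coords) - np.asarray(self.center))
        return np.all(d <= half + 1e-9, axis=-1)


@dataclasses.dataclass
class Pose:
    """A placed fragment conformation with its score (kcal/mol)."""

    structure: Structure
    score: float
    cluster_rank: int | None = None
    source: str = "internal"


@dataclasses.dataclass(frozen=True)
class DockConfig:
    n_runs: int = 10                  # independent search replicates
    orientations_per_run: int = 64
    translation_stride: float = 1.0   # A, coarse placement grid
    contact_range: tuple[float, float] = (2.5, 7.0)  # centroid-to-target shell
    n_refine: int = 48                # placements taken into local refinement
    n_poses: int = 50                 # poses returned
    clash_factor: float = 0.55        # fraction of R_i+R_j tolerated pre-refinement
    rng_seed: int = 0


def _arrays(s: Structure):
    return (s.coords(), s.charges(), s.vdw_radii(), s.well_depths())


def _fragment_conformers(fragment: Structure, rng: np.random.Generator,
                         n: int) -> list[np.ndarray]:
    """Conformer coordinate sets from random chi1 rotamer assignments."""
    base = {a.name: i for i, a in enumerate(fragment.atoms)}
    by_res: dict[int, list[int]] = {}
    for i, a in enumerate(fragment.atoms):
        by_res.setdefault(a.residue_index, []).append(i)
    coords0 = fragment.coords()
    confs = [coords0]
    for _ in range(n - 1):
        coords = coords0.copy()
        for ri, idxs in by_res.items():
            resname = fragment.atoms[idxs[0]].residue_name
            if resname not in CHI1_ATOM or resname == "PRO":
                continue
            names = {fragment.atoms[i].name: coords[i] for i in idxs}
            if CHI1_ATOM[resname] not in names or "CB" not in names:
                continue
            rotated = set_chi1(resname, names, float(rng.choice(CHI1_ROTAMERS)))
            for i in idxs:
                coords[i] = rotated[fragment.atoms[i].name]
        confs.append(coords)
    return confs


def _translation_grid(box: SearchBox, target_heavy: np.ndarray,
                      stride: float, contact_range: tuple[float, float]):
    half = box.extent / 2.0
    axes = [np.arange(-half[i], half[i] + 1e-9, stride) for i in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    pts = pts + np.asarray(box.center)
    d = cdist(pts, target_heavy).min(axis=1)
    lo, hi = contact_range
    return pts[(d >= lo) & (d <= hi)]


def dock_seed(fragment: Structure, target: Structure, box: SearchBox,
              cfg: DockConfig = DockConfig(),
              p: DielectricParams = DielectricParams()) -> list[Pose]:
    """Ranked (best-first) clash-screened seed poses inside the box.

    Deterministic for a fixed `cfg.rng_seed`.  Returns an empty list with a
    warning if no clash-free placement exists.
    """
    if not fragment.is_parameterized() or not target.is_parameterized():
        raise StructureError("fragment and target must be parameterized")
    tc, tq, tr, te = _arrays(target)
    heavy_t = target.heavy_mask()
    if not np.any(box.contains(tc)):
        warnings.warn("search box does not overlap the target")
    fc0, fq, fr, fe = _arrays(fragment)
    heavy_f = fragment.heavy_mask()

    grid = _translation_grid(box, tc[heavy_t], cfg.translation_stride,
                             cfg.contact_range)
    if grid.size == 0:
        warnings.warn("no translation grid points near the target inside the box")
        return []

    rng = np.random.default_rng(cfg.rng_seed)
    candidates: list[tuple[float, np.ndarray]] = []
    for _run in range(cfg.n_runs):
        rots = Rotation.random(cfg.orientations_per_run,
                               random_state=int(rng.integers(2**31)))
        confs = _fragment_conformers(fragment, rng, 4)
        for rot in rots:
            conf = confs[int(rng.integers(len(confs)))]
            oriented = (conf - conf.mean(axis=0)) @ rot.as_matrix().T
            scores = _score_translations(oriented, fq, fr, fe, heavy_f,
                                         tc, tq, tr, te, heavy_t, grid, p,
                                         cfg.clash_factor)
            k = min(3, len(grid))
            for j in np.argpartition(scores, k - 1)[:k]:
                if np.isfinite(scores[j]):
                    candidates.append((float(scores[j]), oriented + grid[j]))
    if not candidates:
        warnings.warn("no clash-free pose found")
        return []
    candidates.sort(key=lambda c: c[0])

    poses: list[Pose] = []
    for score, coords in candidates[:cfg.n_refine]:
        coords, score = _refine_rigid(coords, fq, fr, fe, heavy_f,
                                      tc, tq, tr, te, heavy_t, p,
                                      cfg.clash_factor)
        if _has_clash(coords, heavy_f, tc, heavy_t, fr, tr, cfg.clash_factor):
            continue
        if not np.all(box.contains(coords[heavy_f])):
            continue
        s = fragment.copy()
        s.set_coords(coords)
        poses.append(Pose(structure=s, score=score))
    poses.sort(key=lambda po: po.score)
    return poses[:cfg.n_poses]


def _score_translations(oriented, fq, fr, fe, heavy_f, tc, tq, tr, te, heavy_t,
                        grid, p, clash_factor, chunk: int = 256):
    """Energy of `oriented + grid[k]` for every translation; clashes score +inf."""
    na = len(oriented)
    out = np.empty(len(grid))
    rsum = fr[heavy_f][:, None] + tr[heavy_t][None, :]
    for lo in range(0, len(grid), chunk):
        g = grid[lo:lo + chunk]
        stacked = (oriented[None, :, :] + g[:, None, :]).reshape(-1, 3)
        d = cdist(stacked, tc).reshape(len(g), na, -1)
        np.maximum(d, 0.05, out=d)  # keep r^-12 finite at heavy overlap
        rij = fr[:, None] + tr[None, :]
        eij = np.sqrt(fe[:, None] * te[None, :])
        s6 = (rij[None] / d) ** 6
        lj = (eij[None] * s6 * (s6 - 2.0)).sum(axis=(1, 2))
        eps = p.A + p.B / (1.0 + p.k * np.exp(-p.lam * p.B * d))
        coul = (COULOMB_CONSTANT * (fq[:, None] * tq[None, :])[None]
                / (eps * d)).sum(axis=(1, 2))
        e = lj + coul
        hard = (d[:, heavy_f][:, :, heavy_t] < clash_factor * rsum[None]
                ).any(axis=(1, 2))
        # hard overlaps stay in the pool (descent can rescue near-misses) but
        # never outrank genuinely favorable placements
        e[hard] = np.maximum(e[hard], 1e3)
        out[lo:lo + chunk] = e
    return out


def _pose_energy(coords, fq, fr, fe, tc, tq, tr, te, p):
    lj, coul = energy_components(coords, fq, fr, fe, tc, tq, tr, te, p)
    return float(lj.sum() + coul.sum())


def _has_clash(coords, heavy_f, tc, heavy_t, fr, tr, clash_factor):
    d = cdist(coords[heavy_f], tc[heavy_t])
    rsum = fr[heavy_f][:, None] + tr[heavy_t][None, :]
    return bool((d < clash_factor * rsum).any())


def _refine_rigid(coords, fq, fr, fe, heavy_f, tc, tq, tr, te, heavy_t, p,
                  clash_factor):
    """Greedy rigid-body coordinate descent: axis translations and rotations
    about the centroid, with shrinking step sizes."""
    best = coords
    best_e = _pose_energy(best, fq, fr, fe, tc, tq, tr, te, p)
    steps = [(1.0, 20.0), (0.5, 10.0), (0.25, 5.0), (0.1, 2.0)]
    axes = np.eye(3)
    for tstep, astep in steps:
        improved = True
        sweeps = 0
        while improved and sweeps < 12:
            improved = False
            sweeps += 1
            centroid = best.mean(axis=0)
            moves = [best + sign * tstep * ax for ax in axes for sign in (1, -1)]
            for ax in axes:
                for sign in (1, -1):
                    R = Rotation.from_rotvec(np.radians(sign * astep) * ax)
                    moves.append((best - centroid) @ R.as_matrix().T + centroid)
            for cand in moves:
                # no clash gate here: the r^-12 repulsion steers descent away
                # from overlap on its own
                e = _pose_energy(cand, fq, fr, fe, tc, tq, tr, te, p)
                if e < best_e - 1e-9:
                    best, best_e = cand, e
                    improved = True
    return best, best_e


def import_poses(paths, fragment_template: Structure, target: Structure,
                 p: DielectricParams = DielectricParams()) -> list[Pose]:
    """Load externally docked poses (PDB/mol2) and score them on import.

    Each file's atoms must match the template's (residue, atom-name)
    composition; missing template charges/vdW parameters are copied over.
    """
    poses = []
    tpl_key = [(a.residue_index, a.name) for a in fragment_template.atoms]
    for path in paths:
        s = read_structure(path)
        key = [(a.residue_index, a.name) for a in s.atoms]
        if sorted(key) != sorted(tpl_key):
            missing = set(tpl_key) - set(key)
            extra = set(key) - set(tpl_key)
            raise StructureError(
                f"{path}: atom composition mismatch with template "
                f"(missing {sorted(missing)}, unexpected {sorted(extra)})")
        # reorder to template order and inherit parameters
        lookup = {(a.residue_index, a.name): a for a in s.atoms}
        pose_struct = fragment_template.copy()
        pose_struct.set_coords(np.array([lookup[k].coord for k in tpl_key]))
        for a, k in zip(pose_struct.atoms, tpl_key):
            imported = lookup[k]
            if imported.charge is not None:
                a.charge = imported.charge
        rep = interaction_energy(pose_struct, target, p)
        poses.append(Pose(structure=pose_struct, score=rep.total[2],
                          source="imported"))
    return poses


def cluster_and_rank(poses: list[Pose], tol: float = 2.0) -> list[Pose]:
    """Greedy leader clustering on in-frame heavy-atom RMSD.

    Poses are visited best-score-first; each joins the first cluster whose
    leader lies within `tol`, else founds a new cluster.  Returns one
    representative (the best-scoring member, i.e. the leader) per cluster,
    with `cluster_rank` 1, 2, ... in order of best member score.
    """
    if not poses:
        raise ValueError("no poses to cluster")
    order = sorted(poses, key=lambda po: po.score)
    heavy = order[0].structure.heavy_mask()
    leaders: list[Pose] = []
    leader_coords: list[np.ndarray] = []
    for pose in order:
        c = pose.structure.coords()[heavy]
        joined = False
        for lc in leader_coords:
            if np.sqrt(((c - lc) ** 2).sum(axis=1).mean()) <= tol:
                joined = True
                break
        if not joined:
            rep = dataclasses.replace(pose, cluster_rank=len(leaders) + 1)
            leaders.append(rep)
            leader_coords.append(c)
    return leaders
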