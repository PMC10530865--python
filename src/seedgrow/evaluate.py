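"""Accuracy evaluation: target superposition, ligand RMSD, benchmark summaries.

A model complex is compared to a reference complex by first least-squares
superposing the *target* parts on shared C-alpha atoms (the peptide plays no
part in the fit) and then measuring the heavy-atom RMSD of the peptide
ligand, both over the full chain and over the five N-terminal residues.
``RMSD_best`` is the minimum over all binding modes of a system;
``RMSD_top`` is the RMSD of the mode the scoring function ranks first.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .errors import StructureError
from .geometry import apply_rigid, kabsch
from .structio import Structure


@dataclasses.dataclass
class RMSDResult:
    rmsd_full: float
    rmsd_first5: float
    n_atoms_full: int
    n_atoms_first5: int
    rotation: np.ndarray | None = None
    translation: np.ndarray | None = None
    score: float | None = None  # ranking score of the mode, if any


def superpose_targets(model_target: Structure, reference_target: Structure
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Kabsch fit of the model target onto the reference target C-alpha atoms.

    Atoms correspond by (residue_index); at least 3 shared CA are required.
    Returns (R, t) to be applied to the whole model complex.
    """
    mod_ca = {a.residue_index: a.coord for a in model_target.atoms
              if a.name == "CA"}
    ref_ca = {a.residue_index: a.coord for a in reference_target.atoms
              if a.name == "CA"}
    common = sorted(set(mod_ca) & set(ref_ca))
    if len(common) < 3:
        raise StructureError(
            f"only {len(common)} shared C-alpha atoms; need at least 3")
    P = np.array([mod_ca[i] for i in common])
    Q = np.array([ref_ca[i] for i in common])
    return kabsch(P, Q)


def ligand_rmsd(model_ligand: Structure, reference_ligand: Structure,
                subset: str = "full", first_n: int = 5) -> float:
    """Heavy-atom RMSD between matched ligand conformations (no fitting here;
    superposition of the targets must already have been applied).

    Atoms are matched by (residue_index, atom name); `subset` is "full" or
    "first_n" (residues 1..first_n).  Side-chain heavy atoms are included.
    """
    mod = {(a.residue_index, a.name): a.coord for a in model_ligand.atoms
           if not a.is_hydrogen}
    ref = {(a.residue_index, a.name): a.coord for a in reference_ligand.atoms
           if not a.is_hydrogen}
    if subset == "first_n":
        mod = {k: v for k, v in mod.items() if k[0] <= first_n}
        ref = {k: v for k, v in ref.items() if k[0] <= first_n}
    elif subset != "full":
        raise ValueError(f"unknown subset {subset!r}")
    unmatched = set(mod) ^ set(ref)
    if unmatched:
        raise StructureError(
            f"atom correspondence mismatch: {sorted(unmatched)[:10]}"
            + ("..." if len(unmatched) > 10 else ""))
    keys = sorted(mod)
    P = np.array([mod[k] for k in keys])
    E = np.array([ref[k] for k in keys])
    return float(np.sqrt(((P - E) ** 2).sum(axis=1).mean()))


def evaluate_mode(model_target: Structure, model_ligand: Structure,
                  reference_target: Structure, reference_ligand: Structure,
                  first_n: int = 5, score: float | None = None) -> RMSDResult:
    """Superpose targets, transform the model ligand, and compute both RMSDs."""
    R, t = superpose_targets(model_target, reference_target)
    moved = model_ligand.copy()
    moved.set_coords(apply_rigid(moved.coords(), R, t))
    full = ligand_rmsd(moved, reference_ligand, "full")
    first = ligand_rmsd(moved, reference_ligand, "first_n", first_n=first_n)
    nh = int(moved.heavy_mask().sum())
    nh5 = sum(1 for a in moved.atoms
              if not a.is_hydrogen and a.residue_index <= first_n)
    return RMSDResult(rmsd_full=full, rmsd_first5=first,
                      n_atoms_full=nh, n_atoms_first5=nh5,
                      rotation=R, translation=t, score=score)


@dataclasses.dataclass
class SystemStats:
    rmsd_best_full: float
    rmsd_best_first5: float
    rmsd_top_full: float
    rmsd_top_first5: float
    n_modes: int


def benchmark_stats(per_system_results: dict[str, list[RMSDResult]]) -> dict:
    """Per-system RMSD_best / RMSD_top and cross-system mean +/- SD.

    Each system's modes must carry ranking scores (`RMSDResult.score`,
    lower = better); systems with no modes are excluded with a warning.
    Returns {"systems": {name: SystemStats}, "summary": {...}} where summary
    holds mean/sd over systems for best/top x full/first5.
    """
    systems: dict[str, SystemStats] = {}
    for name, modes in per_system_results.items():
        if not modes:
            warnings.warn(f"system {name!r} has no modes; excluded")
            continue
        best_full = min(m.rmsd_full for m in modes)
        best_first = min(m.rmsd_first5 for m in modes)
        if any(m.score is None for m in modes):
            top = modes[0]
        else:
            top = min(modes, key=lambda m: m.score)
        systems[name] = SystemStats(
            rmsd_best_full=best_full, rmsd_best_first5=best_first,
            rmsd_top_full=top.rmsd_full, rmsd_top_first5=top.rmsd_first5,
            n_modes=len(modes))
    if not systems:
        raise ValueError("no evaluable systems")
    summary = {}
    for field in ("rmsd_best_full", "rmsd_best_first5",
                  "rmsd_top_full", "rmsd_top_first5"):
        vals = np.array([getattr(s, field) for s in systems.values()])
        summary[field] = (float(vals.mean()), float(vals.std()))
    return {"systems": systems, "summary": summary}
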