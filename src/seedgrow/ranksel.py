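"""Scoring and ranking of the grown model pool, and representative selection.

Models are ranked by the interaction energy of the five N-terminal residues
(the anchor region that carries nearly all of the binding), most negative
first.  The solution returned to the user is not the single best-scoring
model but the member of the top fraction (default 1%) closest to that
subset's mean coordinates -- an ensemble-aware choice that is robust to
individual outliers with spuriously good energies.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

from .errors import StructureError
from .forcefield import DielectricParams, interaction_energy
from .growing import GrownModel
from .structio import Structure


@dataclasses.dataclass
class ScoredModel:
    model_id: int
    seed_rank: int
    structure: Structure
    e_lj: float
    e_coulomb: float
    e_inter_full: float
    e_inter_first5: float


@dataclasses.dataclass
class RankedPool:
    """A scored pool with its top-fraction subset and selected representative."""

    models: list[ScoredModel]
    top_fraction: float = 0.01
    first_n: int = 5
    top_set: list[int] = dataclasses.field(default_factory=list)
    representative: int | None = None

    def by_id(self, model_id: int) -> ScoredModel:
        for m in self.models:
            if m.model_id == model_id:
                return m
        raise KeyError(model_id)

    @property
    def top_size(self) -> int:
        return max(1, math.ceil(self.top_fraction * len(self.models)))


def score_pool(pool: list[GrownModel], target: Structure,
               p: DielectricParams = DielectricParams(),
               top_fraction: float = 0.01, first_n: int = 5) -> RankedPool:
    """Score every model (full-ligand and first-`first_n` E_inter) and sort the
    pool by the first-`first_n` energy ascending.  Unparameterized models are
    skipped with a warning."""
    if not pool:
        raise ValueError("empty model pool")
    scored: list[ScoredModel] = []
    for gm in pool:
        if not gm.structure.is_parameterized():
            warnings.warn(f"model {gm.model_id} is unparameterized; skipped")
            continue
        rep = interaction_energy(gm.structure, target, p, first_n=first_n)
        scored.append(ScoredModel(
            model_id=gm.model_id, seed_rank=gm.seed_rank, structure=gm.structure,
            e_lj=rep.total[0], e_coulomb=rep.total[1],
            e_inter_full=rep.total[2], e_inter_first5=rep.first_n_total))
    if not scored:
        raise StructureError("no scorable models in pool")
    scored.sort(key=lambda m: (m.e_inter_first5, m.model_id))
    return RankedPool(models=scored, top_fraction=top_fraction, first_n=first_n)


def select_representative(rp: RankedPool) -> int:
    """Pick the solution model: the member of the top-fraction set with the
    lowest heavy-atom RMSD to the set's atom-wise mean coordinates.

    Fills `rp.top_set` and `rp.representative` and returns the model id.
    No superposition is applied: all models share the target frame.  Ties
    break to the lowest model id.
    """
    if not rp.models:
        raise ValueError("empty pool")
    k = rp.top_size
    top = rp.models[:k]
    rp.top_set = [m.model_id for m in top]
    heavy = top[0].structure.heavy_mask()
    coords = np.array([m.structure.coords()[heavy] for m in top])
    mean = coords.mean(axis=0)
    rmsds = np.sqrt(((coords - mean[None]) ** 2).sum(axis=2).mean(axis=1))
    order = sorted(range(k), key=lambda i: (rmsds[i], top[i].model_id))
    rp.representative = top[order[0]].model_id
    return rp.representative


def ranking_ablation(rp: RankedPool, key: str = "E_inter") -> list[int]:
    """Model ids re-ranked under one scoring component.

    `key` is one of "E_inter" (default ranking, first-5 E_inter), "LJ_only",
    "Coulomb_only" (full-ligand components), for score-ablation comparisons.
    """
    keyfun = {
        "E_inter": lambda m: m.e_inter_first5,
        "LJ_only": lambda m: m.e_lj,
        "Coulomb_only": lambda m: m.e_coulomb,
    }.get(key)
    if keyfun is None:
        raise ValueError(f"unknown ranking key {key!r}")
    return [m.model_id
            for m in sorted(rp.models, key=lambda m: (keyfun(m), m.model_id))]
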