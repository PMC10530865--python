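"""End-to-end pipeline: fragment build -> seed dock -> cluster/rank ->
grow from all ranks -> score pool -> representative selection -> evaluation.

`run_pipeline_for_seed` is the in-memory engine; `run_pipeline` wraps it
with file I/O, output tables and a reproducibility manifest for the CLI.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from .errors import SeedgrowError, StructureError
from .evaluate import evaluate_mode
from .forcefield import DielectricParams, interaction_energy
from .fragments import FragmentSpec, PeptideSequence, build_fragment
from .growing import GrowthConfig, grow_from_all_ranks
from .ranksel import RankedPool, score_pool, select_representative
from .seeding import (DockConfig, Pose, SearchBox, cluster_and_rank, dock_seed,
                      import_poses)
from .structio import (Structure, assign_parameters, prepare_target,
                       read_structure, write_structure, write_multi_model_pdb)

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Everything one run needs.  Paths are optional: the in-memory entry
    point takes structures directly; the CLI fills the paths in."""

    sequence: PeptideSequence
    seed_spec: FragmentSpec | None = None        # None: window 1 of the sequence
    box: SearchBox | None = None                 # None: center on reference ligand
    dock: DockConfig = dataclasses.field(default_factory=DockConfig)
    growth: GrowthConfig = dataclasses.field(default_factory=GrowthConfig)
    dielectric: DielectricParams = dataclasses.field(default_factory=DielectricParams)
    top_fraction: float = 0.01
    first_n: int = 5
    cluster_tol: float = 2.0
    max_seed_ranks: int = 5
    protonated_nterm: bool = False  # charge state of the peptide N-terminus
    rng_seed: int = 0
    # file-driven mode
    target_path: str | None = None
    reference_path: str | None = None
    imported_pose_paths: tuple[str, ...] = ()
    out_dir: str | None = None


@dataclasses.dataclass
class PipelineResult:
    representative_id: int
    representative: Structure
    pool: RankedPool
    seed_poses: list[Pose]
    seed_representatives: list[Pose]
    counts: dict
    rmsd_top_full: float | None = None
    rmsd_top_first5: float | None = None
    rmsd_best_full: float | None = None
    rmsd_best_first5: float | None = None


def run_pipeline_for_seed(target: Structure, spec: FragmentSpec,
                          cfg: PipelineConfig,
                          reference_ligand: Structure | None = None,
                          reference_target: Structure | None = None,
                          imported: list[Pose] | None = None) -> PipelineResult:
    """Run the full protocol for one seed window against a prepared target."""
    seq = cfg.sequence
    p = cfg.dielectric

    if imported is not None:
        poses = imported
        log.info("stage seed: %d imported poses", len(poses))
    else:
        fragment = assign_parameters(
            build_fragment(spec, seq, protonated_nterm=cfg.protonated_nterm))
        box = cfg.box
        if box is None:
            if reference_ligand is None:
                raise StructureError(
                    "no search box and no reference ligand to center one on")
            c = reference_ligand.coords().mean(axis=0)
            box = SearchBox(center=tuple(float(x) for x in c))
        dock_cfg = dataclasses.replace(cfg.dock, rng_seed=cfg.rng_seed)
        poses = dock_seed(fragment, target, box, dock_cfg, p)
        log.info("stage seed-dock: %d poses", len(poses))
    if not poses:
        raise SeedgrowError("seed docking produced no poses")

    reps = cluster_and_rank(poses, tol=cfg.cluster_tol)[:cfg.max_seed_ranks]
    log.info("stage cluster: %d representatives", len(reps))

    growth_cfg = dataclasses.replace(cfg.growth, rng_seed=cfg.rng_seed,
                                     protonated_nterm=cfg.protonated_nterm)
    pool = grow_from_all_ranks(target, reps, seq, spec, growth_cfg, p)
    log.info("stage grow: %d models", len(pool))

    rp = score_pool(pool, target, p, top_fraction=cfg.top_fraction,
                    first_n=cfg.first_n)
    rep_id = select_representative(rp)
    rep_model = rp.by_id(rep_id).structure
    log.info("stage select: top set %d, representative %d",
             len(rp.top_set), rep_id)

    result = PipelineResult(
        representative_id=rep_id, representative=rep_model, pool=rp,
        seed_poses=poses, seed_representatives=reps,
        counts={"poses": len(poses), "seed_ranks": len(reps),
                "models": len(pool), "top_set": len(rp.top_set)})

    if reference_ligand is not None:
        ref_target = reference_target if reference_target is not None else target
        modes = []
        for m in rp.models:
            r = evaluate_mode(target, m.structure, ref_target, reference_ligand,
                              first_n=cfg.first_n, score=m.e_inter_first5)
            modes.append(r)
        rep_eval = modes[[m.model_id for m in rp.models].index(rep_id)]
        result.rmsd_top_full = rep_eval.rmsd_full
        result.rmsd_top_first5 = rep_eval.rmsd_first5
        result.rmsd_best_full = min(m.rmsd_full for m in modes)
        result.rmsd_best_first5 = min(m.rmsd_first5 for m in modes)
    return result


def _config_digest(cfg: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)
    blob = json.dumps(dataclasses.asdict(cfg), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _split_reference(ref: Structure) -> tuple[Structure, Structure]:
    """Split a reference complex into (target part, ligand part).

    The ligand is taken to be the shortest chain of standard residues
    (peptides are short); everything else is the target.
    """
    chains: dict[str, int] = {}
    for c, _i, _n in ref.residues:
        chains[c] = chains.get(c, 0) + 1
    if len(chains) < 2:
        raise StructureError(
            "reference must contain target and ligand chains")
    lig_chain = min(chains, key=lambda c: (chains[c], c))
    lig_mask = [a.chain_id == lig_chain for a in ref.atoms]
    return ref.subset([not m for m in lig_mask]), ref.subset(lig_mask)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """File-driven pipeline run: validates paths, loads and prepares inputs,
    runs the protocol, writes outputs and a manifest under `cfg.out_dir`."""
    if cfg.target_path is None:
        raise ValueError("target_path is required")
    for path in filter(None, [cfg.target_path, cfg.reference_path,
                              *cfg.imported_pose_paths]):
        if not Path(path).exists():
            raise FileNotFoundError(path)

    target = prepare_target(read_structure(cfg.target_path))
    ref_target = ref_ligand = None
    if cfg.reference_path:
        ref = read_structure(cfg.reference_path)
        ref_target, ref_ligand = _split_reference(ref)
        ref_ligand = assign_parameters(ref_ligand)

    spec = cfg.seed_spec or FragmentSpec(
        start=1, residues=cfg.sequence.residues[:2], n_cap=None)

    imported = None
    if cfg.imported_pose_paths:
        fragment = assign_parameters(build_fragment(spec, cfg.sequence))
        imported = import_poses(list(cfg.imported_pose_paths), fragment,
                                target, cfg.dielectric)

    result = run_pipeline_for_seed(target, spec, cfg,
                                   reference_ligand=ref_ligand,
                                   reference_target=ref_target,
                                   imported=imported)

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_structure(result.representative, out / "solution.pdb")
        write_multi_model_pdb([po.structure for po in result.seed_representatives],
                              out / "seed_representatives.pdb")
        rows = [{
            "model_id": m.model_id, "rank": i + 1, "seed_rank": m.seed_rank,
            "E_LJ": m.e_lj, "E_Coulomb": m.e_coulomb,
            "E_inter_full": m.e_inter_full, "E_inter_first5": m.e_inter_first5,
            "in_top_set": m.model_id in result.pool.top_set,
            "representative": m.model_id == result.representative_id,
        } for i, m in enumerate(result.pool.models)]
        pd.DataFrame(rows).to_csv(out / "ranking.tsv", sep="\t", index=False,
                                  float_format="%.4f")
        rep = interaction_energy(result.representative, target, cfg.dielectric,
                                 first_n=cfg.first_n)
        pd.DataFrame(
            [{"residue": k, "E_LJ": v[0], "E_Coulomb": v[1], "E_inter": v[2]}
             for k, v in rep.per_residue.items()]
        ).to_csv(out / "per_residue_energy.tsv", sep="\t", index=False,
                 float_format="%.4f")
        manifest = {
            "config_sha256": _config_digest(cfg),
            "rng_seed": cfg.rng_seed,
            "counts": result.counts,
            "representative_id": result.representative_id,
        }
        if result.rmsd_top_full is not None:
            manifest["rmsd"] = {
                "top_full": result.rmsd_top_full,
                "top_first5": result.rmsd_top_first5,
                "best_full": result.rmsd_best_full,
                "best_first5": result.rmsd_best_first5,
            }
            pd.DataFrame([manifest["rmsd"]]).to_csv(
                out / "rmsd_report.tsv", sep="\t", index=False,
                float_format="%.3f")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
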