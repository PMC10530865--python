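"""Dipeptide fragment enumeration, construction, and seed selection.

A peptide ligand is cut into overlapping dipeptide windows at the amide C-N
bonds.  Cut ends are blocked with acetyl (Ac-) and N-methyl amide (-NHMe)
groups; the window starting at residue 1 keeps its genuine free N-terminus
and is therefore only C-capped.  One window is chosen as the *seed*: the
dipeptide that carries the strongest interaction with the target, either
read off a per-residue energy profile of a known complex, or measured by
running the whole pipeline per candidate and comparing RMSD_top.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

from . import params
from .builder import build_chain
from .errors import StructureError
from .forcefield import DielectricParams, interaction_energy
from .structio import Structure

log = logging.getLogger(__name__)

#: histone H3 N-terminal tail (first 15 residues)
H3_SEQUENCE = "ARTKQTARKSTGGKA"


@dataclasses.dataclass(frozen=True)
class PeptideSequence:
    """One-letter peptide sequence with optional per-position modification tags."""

    residues: str
    modifications: dict[int, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if len(self.residues) < 2:
            raise ValueError("peptide must have at least 2 residues")
        for pos in self.modifications:
            if not 1 <= pos <= len(self.residues):
                raise ValueError(f"modification position {pos} out of range")
        for ch in self.residues:
            if ch not in params.ONE_TO_THREE:
                raise ValueError(f"unknown residue code {ch!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def residue_name(self, pos: int) -> str:
        """Three-letter residue name at 1-based position, modification applied."""
        tag = self.modifications.get(pos)
        if tag is not None:
            if tag.lower() in ("me3", "kme3", "m3l", "trimethyl-k"):
                if self.residues[pos - 1] != "K":
                    raise ValueError(f"trimethylation tag on non-lysine at {pos}")
                return "M3L"
            raise ValueError(f"unsupported modification tag {tag!r}")
        return params.ONE_TO_THREE[self.residues[pos - 1]]


@dataclasses.dataclass(frozen=True)
class FragmentSpec:
    """A dipeptide window at 1-based position `start`, with capping state."""

    start: int
    residues: str  # the two one-letter codes
    n_cap: str | None  # None or "acetyl"
    c_cap: str = "N-methyl-amide"

    def __post_init__(self):
        if (self.n_cap is None) != (self.start == 1):
            raise ValueError("n_cap is absent if and only if start == 1")

    @property
    def label(self) -> str:
        return f"{self.start}:{self.residues}"


def enumerate_dipeptides(seq: PeptideSequence,
                         window_count: int = 9) -> list[FragmentSpec]:
    """All dipeptide windows at starts 1..window_count.

    Window n covers positions (n, n+1); consecutive windows overlap by one
    residue.  Window 1 keeps the free N-terminus (no acetyl); all windows are
    C-capped because the cut there is never the true C-terminus.
    """
    if len(seq) < window_count + 1:
        raise ValueError(
            f"sequence of length {len(seq)} too short for {window_count} windows")
    return [
        FragmentSpec(start=n, residues=seq.residues[n - 1:n + 1],
                     n_cap=None if n == 1 else "acetyl")
        for n in range(1, window_count + 1)
    ]


def build_fragment(spec: FragmentSpec, seq: PeptideSequence | None = None,
                   protonated_nterm: bool = False) -> Structure:
    """3D structure of a capped dipeptide in the extended conformation.

    Ideal bond lengths/angles, polar hydrogens only; `seq` supplies
    modification tags (e.g. trimethyl-lysine) for the window's positions.
    """
    if seq is not None:
        resnames = [seq.residue_name(spec.start), seq.residue_name(spec.start + 1)]
    else:
        resnames = [params.ONE_TO_THREE[c] for c in spec.residues]
    for rn in resnames:
        if rn not in params.KNOWN_RESIDUES:
            raise StructureError(f"unsupported residue {rn!r}")
    return build_chain(
        resnames, start_index=spec.start,
        n_cap="ACE" if spec.n_cap == "acetyl" else None,
        c_cap="NME",
        protonated_nterm=protonated_nterm,
    )


def select_seed_by_energy(ligand: Structure, target: Structure,
                          p: DielectricParams = DielectricParams(),
                          window_count: int | None = None) -> FragmentSpec:
    """Pick the seed window from a bound (holo) full-peptide complex.

    Computes the per-residue E_inter profile of the bound peptide and returns
    the dipeptide window with the most negative summed contribution; ties go
    to the smallest start.
    """
    rep = interaction_energy(ligand, target, p)
    positions = sorted(k for k in rep.per_residue if k >= 1)
    seq_letters = {}
    for a in ligand.atoms:
        seq_letters.setdefault(a.residue_index,
                               params.THREE_TO_ONE.get(a.residue_name, "K"))
    n_pos = max(positions)
    if window_count is None:
        window_count = min(9, n_pos - 1)
    best_start, best_e = 1, float("inf")
    for n in range(1, window_count + 1):
        e = rep.per_residue.get(n, (0, 0, 0))[2] + \
            rep.per_residue.get(n + 1, (0, 0, 0))[2]
        if e < best_e - 1e-12:
            best_start, best_e = n, e
    letters = seq_letters.get(best_start, "A") + seq_letters.get(best_start + 1, "A")
    return FragmentSpec(start=best_start, residues=letters,
                        n_cap=None if best_start == 1 else "acetyl")


def select_seed_by_rmsd(holo_target: Structure, reference_ligand: Structure,
                        candidates: list[FragmentSpec], cfg) -> FragmentSpec:
    """Pick the seed by running the full pipeline once per candidate window on
    the holo target and comparing the RMSD_top of the solutions.

    `cfg` is a PipelineConfig-like object accepted by `pipeline.run_pipeline`;
    candidates whose runs fail are skipped with a warning.
    """
    from .pipeline import run_pipeline_for_seed  # deferred: avoids import cycle

    if not candidates:
        raise ValueError("no candidate fragments")
    best: tuple[float, FragmentSpec] | None = None
    for cand in candidates:
        try:
            result = run_pipeline_for_seed(holo_target, cand, cfg,
                                           reference_ligand=reference_ligand)
            rmsd_top = result.rmsd_top_full
        except Exception as exc:  # noqa: BLE001 - candidate isolation
            warnings.warn(f"candidate {cand.label} failed: {exc}")
            log.warning("candidate %s failed: %s", cand.label, exc)
            continue
        log.info("candidate %s: RMSD_top %.2f A", cand.label, rmsd_top)
        if best is None or rmsd_top < best[0]:
            best = (rmsd_top, cand)
    if best is None:
        raise StructureError("all candidate seeds failed")
    return best[1]
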