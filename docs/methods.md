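# Methods

`seedgrow` builds atomic models of protein–peptide complexes for flexible
linear peptides (the motivating case is histone-tail recognition by reader
domains, where only the first few N-terminal residues bind specifically and
the rest of the peptide floats in solvent). The protocol: cut the peptide
into capped dipeptide windows, dock the strongest window (the *seed*) as a
rigid-ish small ligand, grow the remaining residues in situ in the pocket,
score the resulting model pool with a physical interaction energy, and
return a representative of the top-scoring ensemble.

## Interaction energy

All scoring uses the intermolecular energy between ligand atoms *i* and
target atoms *j*:

    E_inter = Σ_ij [ A_ij r_ij^-12 − B_ij r_ij^-6 ] + Σ_ij C q_i q_j / (ε_r(r_ij) r_ij)

with `A_ij = ε_ij R_ij^12`, `B_ij = 2 ε_ij R_ij^6`, `R_ij = R_i + R_j`,
`ε_ij = √(ε_i ε_j)`, so the Lennard-Jones minimum lies at the sum of the
Rmin/2 radii with depth −ε_ij. `C = 332.0637 kcal·Å·mol⁻¹·e⁻²` converts
charges in elementary units and distances in Å to kcal/mol. The Coulomb
term is screened by the sigmoidal distance-dependent dielectric of Mehler
and Solmajer,

    ε_r(r) = A + B / (1 + k·e^(−λBr)),   B = ε₀ − A

with the published constants A = −8.5525, λ = 0.003627 Å⁻¹, k = 7.7839 and
ε₀ = 78.4 (water, 25 °C), all exposed in `DielectricParams`. No pair is
excluded (the two molecules share no bonds) and no distance cutoff is
applied by default; an optional cutoff exists purely for speed. Pair terms
are attributed to the ligand atom's residue, giving the per-residue
decomposition used for seed selection and for the first-five ranking key.

## Atom model and parameters

Structures carry polar hydrogens only (hydrogens on N/O/S), the standard
preparation for grid-docking energy models; carbon parameters therefore act
as united atoms for their implicit hydrogens. Van der Waals parameters are
an Amber-style table (Rmin/2, ε) keyed by a deterministic element/atom-name
typing map (`params.py`). Charges come from a fixed per-(residue,
atom-name) template designed to be *group-neutral*: every chemical group
(backbone amide, hydroxyl, carboxylate, guanidinium, ammonium, …) sums
exactly to its formal charge, so any assembled peptide nets an integer
total without iterative charge equilibration. Imported mol2 charges always
take precedence over the template. Histidine is modeled as the neutral
NE2-protonated tautomer; aspartate/glutamate are deprotonated; lysine and
arginine carry +1. Trimethyl-lysine is supported as residue `M3L` with the
+1 spread over the quaternary ammonium group (parameters approximate).

The peptide N-terminus defaults to neutral NH₂; a `protonated_nterm` switch
builds the physiological NH₃⁺ ammonium instead. The synthetic fixture uses
the protonated form, because the charged α-amine is precisely the anchor
that real reader pockets recognize.

## Geometry engine

Residue geometry comes from the chemical component dictionary's ideal
coordinates (via biotite's bundled copy). Chains are assembled by natural
extension (NeRF) of the N/CA/C anchors with ideal bond lengths and angles
(C–N 1.335 Å, N–CA 1.458 Å, CA–C 1.525 Å, ω = 180°); each residue's
remaining atoms ride on a rigid three-point fit of the template to its
anchors, the carbonyl O is re-placed anti to the next backbone nitrogen,
and the amide H sits on the bisector of the peptide plane. χ1 is set by
rotating the side chain about CA–CB; the rotamer set is the three staggered
values (−60°, 180°, +60°). Fragments are built extended (φ = −120°,
ψ = +120°); proline's φ is pinned at −65°. No force-field minimization is
performed anywhere — downstream stages tolerate ideal geometry by design.

## Seed docking

The seed docker is a deterministic, seeded global search (it deliberately
replaces stochastic genetic-algorithm docking while keeping the same
contract): fragment conformers (random χ1 assignments) × uniformly random
orientations × a translation grid inside the search box (default 60×60×60
points at 0.375 Å spacing, 1.0 Å placement stride, centered on the known
ligand region), scored with E_inter. Ten independent replicates of 64
orientations each mirror the convention of running a stochastic docker ten
times. The best-scoring placements (48 by default) are refined by greedy
rigid-body coordinate descent with shrinking steps (1.0→0.1 Å,
20°→2°); hard steric overlaps are not pruned during descent — the r⁻¹²
repulsion steers the search out of overlap on its own — but final poses
must be clash-free at 0.55 of summed vdW radii and inside the box. Poses
are grouped by greedy leader clustering on in-frame heavy-atom RMSD
(tolerance 2.0 Å, the conventional value); cluster ranks are ordered by
best member score. The search is exactly reproducible for a fixed seed;
it is invariant under joint *translation* of target and box, but not under
joint rotation, because the orientation set and translation grid are laid
out in the global frame of the axis-aligned box.

## Growing

Growth starts from a docked seed whose two residues never move: the
removed caps pin the backbone torsions across the seed boundary (the
acetyl carbon fixes φ of the first seed residue; the N-methyl nitrogen
fixes ψ of the second), so the anchoring error of seed-internal atoms is
exactly zero. Extension is N-ward to residue 1 first, then C-ward to the
terminus, one residue at a time. Each step draws (φ, ψ) from weighted
Ramachandran basins — α (0.35), β (0.45), polyproline II (0.20), sampled
uniformly within each basin — plus a χ1 rotamer, builds the residue with
ideal geometry, and rejects it if any heavy atom comes closer than
`clash_factor × (R_i + R_j)` (default 0.7) to the target or to previously
built, non-adjacent ligand residues; the carbonyl oxygen of the preceding
residue, which is re-pointed at the new nitrogen, is held to the same
test. Among up to 8 surviving draws the one with the best incremental
E_inter against the target is kept. A model that cannot place a residue
within 50 re-draw rounds is discarded and regrown; a growth attempt budget
of 4× the requested pool bounds the total work. 100 models are grown per
seed rank, and all clustering ranks (default: the top 5) contribute to the
pool.

## Ranking and representative selection

Every pool model is scored with E_inter over the full ligand and over
ligand residues 1–5; the ranking key is the first-five energy (most
negative first), because the N-terminal anchor carries nearly all of the
specific binding while the C-terminal tail's energy is noise. The
solution is not the single best-scoring model: the top `ceil(0.01·n)`
models (floor of one) form the top set, their heavy-atom coordinates are
averaged atom-wise in the common target frame, and the member closest to
that mean (heavy-atom RMSD, ties to the lowest model id) is returned.
Component-only rankings (LJ-only, Coulomb-only) are available for ablation
comparisons.

## Evaluation

Model and reference complexes are compared after least-squares (Kabsch)
superposition of the *target* Cα atoms matched by residue index; the
transform is then applied to the whole model complex. Ligand RMSD is the
plain heavy-atom root-mean-square deviation over atoms matched by
(residue index, atom name) — side chains included, no re-fitting — over
the full peptide and over residues 1–5. For a pool, `RMSD_best` is the
minimum over all modes and `RMSD_top` the RMSD of the mode ranked first by
the score; `RMSD_top ≥ RMSD_best` always, with equality under perfect
ranking. Cross-system summaries report mean ± population SD.

## Synthetic planted fixture

`make_planted_complex` builds a ground-truth complex entirely in silico:
an 8-residue (configurable 5–15) histone-tail prefix in the extended
conformation with a protonated N-terminus, and a toy receptor constructed
around its first two residues. The receptor is a half-open groove of
single-atom carbonyl-like probes at 3.5 Å from the anchor atoms, with an
outer neutral wall one contact shell further out (so the groove is a
concave pocket, not a free-floating shell), plus four buried Cα marker
atoms for the superposition stage. Probe identity is chosen to complement
the local peptide charge — oxygen probes face positive groups (the
ammonium, the guanidinium), carbon probes face negative ones — which makes
the planted orientation the electrostatic optimum, as in a real reader
pocket. Probe placement keeps 3.0 Å clearance from anchor-residue heavy
atoms and 4.0 Å from the rest of the peptide, leaving a corridor through
which the growing stage can thread the tail. By construction the planted
pose is clash-free at factor 0.7 and the seed window carries the most
negative per-residue energies.

The fixture tests mechanics, not biology: it has a single rigid pocket,
no solvent, no target flexibility, pseudo-atoms instead of real residues,
and its energy surface is far smoother than a protein's. Passing the
planted-recovery tests demonstrates that docking, growing, scoring and
selection interlock correctly — not that the method attains any particular
accuracy on experimental complexes.

## Problem sizes and numerical choices

Default desk-scale sizes: ~60–70 receptor atoms in fixtures, 8-residue
peptides, 640 docking orientations, 100 models per seed rank (≤500-model
pools). A full fixture pipeline runs in a few minutes on one core. Ties
in seed-window selection break to the smallest start; representative ties
break to the lowest model id; greedy clustering visits poses best-first.
Energies are computed in float64 with no cutoff; the vectorized engine is
verified against a brute-force double loop at 1e-9 relative tolerance.

## Known limitations

- No intramolecular ligand energy, solvation, or explicit water; the score
  is purely intermolecular.
- The target is rigid throughout; alternate side-chain conformations of
  the receptor are not sampled.
- χ2+ side-chain torsions keep their ideal-template values (only χ1 is
  sampled), which limits side-chain packing accuracy.
- The seed docker's orientation coverage is stochastic; very enclosed
  pockets may need more orientations per run than the default.
- The fixed charge template is a deliberate simplification; it reproduces
  formal charges and group polarity, not ab-initio partial charges.
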