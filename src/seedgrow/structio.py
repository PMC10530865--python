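"""Molecular structure container, PDB/mol2 I/O, and target preparation.

Coordinates are Angstrom, charges elementary charge units, van der Waals
parameters Amber-style (Rmin/2 in Angstrom, well depth in kcal/mol).

PDB files are read and written through gemmi.  mol2 support is a minimal
TRIPOS reader/writer covering the MOLECULE and ATOM sections, which is all
the pipeline exchanges (the charge column is the reason mol2 exists here:
imported charges always take precedence over the template).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import gemmi
import numpy as np

from . import params
from .ccd import chain_atom_names, get_template
from .errors import ParseError, StructureError, TypingError
from .geometry import kabsch, apply_rigid


@dataclasses.dataclass
class Atom:
    """One atom record; `charge`/`vdw_radius`/`well_depth` are None until assigned."""

    serial: int
    name: str
    element: str
    coord: np.ndarray
    charge: float | None = None
    vdw_radius: float | None = None
    well_depth: float | None = None
    residue_index: int = 1
    residue_name: str = ""
    chain_id: str = "A"

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"

    def copy(self) -> "Atom":
        return dataclasses.replace(self, coord=np.array(self.coord, dtype=float))


class Structure:
    """An ordered collection of atoms with residue bookkeeping."""

    def __init__(self, atoms: list[Atom]):
        self.atoms = atoms

    # --- bookkeeping ---
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residues(self) -> list[tuple[str, int, str]]:
        seen: dict[tuple[str, int], str] = {}
        for a in self.atoms:
            key = (a.chain_id, a.residue_index)
            if key not in seen:
                seen[key] = a.residue_name
        return [(c, i, n) for (c, i), n in seen.items()]

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        for a, c in zip(self.atoms, coords):
            a.coord = np.array(c, dtype=float)

    def charges(self) -> np.ndarray:
        return np.array([np.nan if a.charge is None else a.charge for a in self.atoms])

    def vdw_radii(self) -> np.ndarray:
        return np.array([np.nan if a.vdw_radius is None else a.vdw_radius
                         for a in self.atoms])

    def well_depths(self) -> np.ndarray:
        return np.array([np.nan if a.well_depth is None else a.well_depth
                         for a in self.atoms])

    def residue_indices(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.atoms], dtype=int)

    def heavy_mask(self) -> np.ndarray:
        return np.array([not a.is_hydrogen for a in self.atoms], dtype=bool)

    def copy(self) -> "Structure":
        return Structure([a.copy() for a in self.atoms])

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "Structure":
        s = self.copy()
        s.set_coords(apply_rigid(s.coords(), R, t))
        return s

    def subset(self, mask) -> "Structure":
        mask = np.asarray(mask, dtype=bool)
        return Structure([a.copy() for a, m in zip(self.atoms, mask) if m])

    def residue_atoms(self, chain_id: str, residue_index: int) -> list[Atom]:
        return [a for a in self.atoms
                if a.chain_id == chain_id and a.residue_index == residue_index]

    def net_charge(self) -> float:
        q = self.charges()
        return float(np.nansum(q))

    def is_parameterized(self) -> bool:
        return all(a.charge is not None and a.vdw_radius is not None
                   and a.well_depth is not None for a in self.atoms)


# --- reading --------------------------------------------------------------

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


def read_structure(path, fmt: str | None = None) -> Structure:
    """Read a PDB or mol2 file into a Structure (file atom order preserved).

    mol2 partial charges populate Atom.charge; PDB leaves charges unset.
    The format is inferred from the suffix unless `fmt` is given.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mol2" if path.suffix.lower() == ".mol2" else "pdb"
    if fmt == "pdb":
        return _read_pdb(path)
    if fmt == "mol2":
        return _read_mol2(path)
    raise ValueError(f"unknown format {fmt!r}")


def _read_pdb(path: Path) -> Structure:
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no models found")
    atoms: list[Atom] = []
    model = st[0]
    for chain in model:
        for res in chain:
            for at in res:
                if at.altloc not in ("", "A", "\x00"):
                    continue  # keep altloc A or blank
                el = at.element.name
                if not el:
                    raise ParseError(
                        f"{path}: unknown element for atom {at.name} "
                        f"in residue {res.name} {res.seqid.num}")
                atoms.append(Atom(
                    serial=at.serial,
                    name=at.name,
                    element=el,
                    coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    residue_index=res.seqid.num,
                    residue_name=res.name,
                    chain_id=chain.name,
                ))
    return Structure(atoms)


def _read_mol2(path: Path) -> Structure:
    atoms: list[Atom] = []
    section = None
    n_expected = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("@<TRIPOS>"):
                section = line[9:].strip().upper()
                mol_header = 0
                continue
            if section == "MOLECULE":
                mol_header += 1
                if mol_header == 2:  # counts line
                    try:
                        n_expected = int(line.split()[0])
                    except (ValueError, IndexError):
                        raise ParseError(f"{path}:{lineno}: bad counts line {line!r}")
                continue
            if section != "ATOM":
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: short ATOM record {line!r}")
            try:
                serial = int(parts[0])
                name = parts[1]
                xyz = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
                sybyl = parts[5]
                subst_id = int(parts[6]) if len(parts) > 6 else 1
                subst_name = parts[7] if len(parts) > 7 else "UNK"
                charge = float(parts[8]) if len(parts) > 8 else None
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            element = sybyl.split(".")[0].capitalize()
            if element not in ("H", "C", "N", "O", "S", "P"):
                raise TypingError(
                    f"{path}:{lineno}: unsupported element {element!r}")
            resname = subst_name.rstrip("0123456789")
            atoms.append(Atom(
                serial=serial, name=name, element=element, coord=xyz,
                charge=charge, residue_index=subst_id,
                residue_name=resname or subst_name, chain_id="A",
            ))
    if n_expected is not None and n_expected != len(atoms):
        raise ParseError(
            f"{path}: MOLECULE header promises {n_expected} atoms, found {len(atoms)}")
    return Structure(atoms)


# --- writing --------------------------------------------------------------

def write_structure(s: Structure, path, fmt: str | None = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "mol2" if path.suffix.lower() == ".mol2" else "pdb"
    if fmt == "pdb":
        path.write_text(pdb_string(s))
    elif fmt == "mol2":
        path.write_text(_mol2_string(s, path.stem))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def pdb_string(s: Structure, model_number: int | None = None) -> str:
    lines = []
    if model_number is not None:
        lines.append(f"MODEL {model_number:>8d}")
    for i, a in enumerate(s.atoms, 1):
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        lines.append(
            f"ATOM  {i:>5d} {name:<4.4s} {a.residue_name:<3.3s} "
            f"{a.chain_id[:1]:1s}{a.residue_index:>4d}    "
            f"{a.coord[0]:8.3f}{a.coord[1]:8.3f}{a.coord[2]:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {a.element:>2.2s}"
        )
    lines.append("ENDMDL" if model_number is not None else "END")
    return "\n".join(lines) + "\n"


def write_multi_model_pdb(structures: list[Structure], path) -> None:
    """Pose ensembles / model pools as a multi-model PDB file."""
    text = "".join(pdb_string(s, model_number=i)
                   for i, s in enumerate(structures, 1))
    Path(path).write_text(text + "END\n")


def read_multi_model_pdb(path) -> list[Structure]:
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    out = []
    for model in st:
        atoms = []
        for chain in model:
            for res in chain:
                for at in res:
                    atoms.append(Atom(
                        serial=at.serial, name=at.name, element=at.element.name,
                        coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        residue_index=res.seqid.num, residue_name=res.name,
                        chain_id=chain.name))
        out.append(Structure(atoms))
    return out


def _mol2_string(s: Structure, name: str) -> str:
    lines = [
        "@<TRIPOS>MOLECULE",
        name,
        f"{s.n_atoms} 0 {len(s.residues)} 0 0",
        "SMALL",
        "USER_CHARGES",
        "@<TRIPOS>ATOM",
    ]
    for i, a in enumerate(s.atoms, 1):
        q = 0.0 if a.charge is None else a.charge
        lines.append(
            f"{i:>6d} {a.name:<6s} {a.coord[0]:>10.4f} {a.coord[1]:>10.4f} "
            f"{a.coord[2]:>10.4f} {a.element:<5s} {a.residue_index:>4d} "
            f"{a.residue_name}{a.residue_index} {q:>9.4f}"
        )
    return "\n".join(lines) + "\n"


# --- preparation ----------------------------------------------------------

def prepare_target(s: Structure, protonated_nterm: bool = False) -> Structure:
    """Prepare a PDB-derived target for docking and scoring.

    Removes waters/heteroatoms, keeps the first chain containing standard
    amino acids, renumbers its residues 1..n, strips any hydrogens present and
    adds polar hydrogens (N/O/S donors) at ideal-geometry positions, then
    assigns charges and van der Waals parameters.  Idempotent.
    """
    chain_order: list[str] = []
    for a in s.atoms:
        if a.chain_id not in chain_order:
            chain_order.append(a.chain_id)
    protein_chain = None
    for cid in chain_order:
        resnames = {a.residue_name for a in s.atoms if a.chain_id == cid}
        if resnames & (params.STANDARD_RESIDUES | params.MODIFIED_RESIDUES):
            protein_chain = cid
            break
    if protein_chain is None:
        raise StructureError("no protein chain found in structure")

    kept = [a for a in s.atoms
            if a.chain_id == protein_chain
            and a.residue_name in (params.STANDARD_RESIDUES | params.MODIFIED_RESIDUES)
            and not a.is_hydrogen]
    if not kept:
        raise StructureError("protein chain contains no standard residues")

    # renumber retained residues 1..n in file order
    order: list[int] = []
    for a in kept:
        if a.residue_index not in order:
            order.append(a.residue_index)
    remap = {old: i + 1 for i, old in enumerate(order)}
    atoms = []
    for a in kept:
        b = a.copy()
        b.residue_index = remap[a.residue_index]
        atoms.append(b)

    prepared = _add_polar_hydrogens(Structure(atoms), protonated_nterm)
    return assign_parameters(prepared)


def _add_polar_hydrogens(s: Structure, protonated_nterm: bool) -> Structure:
    """Place polar hydrogens by local superposition of ideal residue templates.

    For each hydrogen, the template frame is its bonded heavy atom plus that
    atom's heavy neighbors (and second neighbors if needed); backbone amide H
    is placed analytically in the peptide plane from the preceding carbonyl.
    """
    by_res: dict[tuple[str, int], list[Atom]] = {}
    for a in s.atoms:
        by_res.setdefault((a.chain_id, a.residue_index), []).append(a)
    res_keys = sorted(by_res, key=lambda k: k[1])
    out_atoms: list[Atom] = []
    prev_c: np.ndarray | None = None
    for ri, key in enumerate(res_keys):
        res = by_res[key]
        resname = res[0].residue_name
        names = {a.name: a for a in res}
        is_nterm = ri == 0
        tpl = get_template(resname)
        wanted = chain_atom_names(resname, nterm=is_nterm, cterm="OXT" in names,
                                  protonated_nterm=protonated_nterm)
        h_names = [n for n in wanted if tpl.has(n) and tpl.element(n) == "H"]
        for a in res:
            out_atoms.append(a.copy())
        for hn in h_names:
            coord = None
            if hn == "H" and not is_nterm and prev_c is not None and "N" in names \
                    and "CA" in names:
                npos = names["N"].coord
                u1 = prev_c - npos
                u2 = names["CA"].coord - npos
                u1 = u1 / np.linalg.norm(u1)
                u2 = u2 / np.linalg.norm(u2)
                d = -(u1 + u2)
                coord = npos + 1.01 * d / np.linalg.norm(d)
            else:
                frame = _hydrogen_frame(tpl, hn)
                present = [n for n in frame if n in names]
                if len(present) < 3:
                    continue  # cannot anchor; skip with incomplete residue
                mob = np.array([tpl.coord(n) for n in present[:4]])
                ref = np.array([names[n].coord for n in present[:4]])
                R, t = kabsch(mob, ref)
                coord = apply_rigid(tpl.coord(hn)[None, :], R, t)[0]
            out_atoms.append(Atom(
                serial=0, name=hn, element="H", coord=coord,
                residue_index=res[0].residue_index, residue_name=resname,
                chain_id=res[0].chain_id))
        if "C" in names:
            prev_c = names["C"].coord
    for i, a in enumerate(out_atoms, 1):
        a.serial = i
    return Structure(out_atoms)


def _hydrogen_frame(tpl, h_name: str) -> list[str]:
    """Heavy-atom frame anchoring one template hydrogen: bonded atom, its heavy
    neighbors, then second shell."""
    heavy = [n for n in tpl.neighbors[h_name] if tpl.element(n) != "H"]
    if not heavy:
        return []
    x = heavy[0]
    frame = [x]
    shell1 = [n for n in tpl.neighbors[x] if tpl.element(n) != "H" and n != h_name]
    frame.extend(shell1)
    if len(frame) < 3:
        for y in shell1:
            for z in tpl.neighbors[y]:
                if tpl.element(z) != "H" and z not in frame:
                    frame.append(z)
    return frame


def assign_parameters(s: Structure) -> Structure:
    """Assign vdW parameters to every atom and template charges to atoms that
    lack one (imported mol2 charges are left untouched)."""
    out = s.copy()
    by_res: dict[tuple[str, int], list[Atom]] = {}
    for a in out.atoms:
        by_res.setdefault((a.chain_id, a.residue_index), []).append(a)
    for key, res in by_res.items():
        resname = res[0].residue_name
        try:
            qmap = params.residue_charges(resname, [a.name for a in res])
        except TypingError as exc:
            raise TypingError(f"residue {resname} {key[1]} (chain {key[0]}): {exc}")
        for a in res:
            if a.charge is None:
                a.charge = qmap[a.name]
            try:
                r, eps = params.vdw_params(resname, a.name, a.element)
            except TypingError as exc:
                raise TypingError(
                    f"atom {a.name} of residue {resname} {key[1]}: {exc}")
            a.vdw_radius = r
            a.well_depth = eps
    return out
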