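"""Ideal-geometry peptide construction.

Backbone anchors (N, CA, C) are placed by internal coordinates (NeRF) from
ideal bond lengths and angles; the remaining atoms of each residue are
carried along by a rigid fit of the ideal residue template onto the anchors,
with the carbonyl oxygen and amide hydrogen re-placed analytically in the
peptide plane and chi1 set by rotating the side chain about CA-CB.

Works in the polar-hydrogen-only representation throughout.
"""

from __future__ import annotations

import numpy as np

from .ccd import chain_atom_names, get_template
from .errors import StructureError
from .geometry import apply_rigid, dihedral, kabsch, nerf_place, rotate_about_axis
from .structio import Atom, Structure

# ideal backbone internal coordinates (A / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.335
BOND_C_O = 1.231
BOND_N_H = 1.010
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
OMEGA = 180.0

# extended-conformation defaults
PHI_EXTENDED = -120.0
PSI_EXTENDED = 120.0

# first side-chain atom defining chi1, per residue type
CHI1_ATOM = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "CYS": "SG", "GLN": "CG",
    "GLU": "CG", "HIS": "CG", "ILE": "CG1", "LEU": "CG", "LYS": "CG",
    "MET": "CG", "PHE": "CG", "SER": "OG", "THR": "OG1", "TRP": "CG",
    "TYR": "CG", "VAL": "CG1", "M3L": "CG",
}
#: common chi1 rotamer values (gauche-, trans, gauche+)
CHI1_ROTAMERS = (-60.0, 180.0, 60.0)


def first_anchors() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical pose for the first residue: N at origin, CA on +x."""
    n = np.zeros(3)
    ca = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - ANGLE_N_CA_C)
    c = ca + BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    return n, ca, c


def next_anchors_cward(n, ca, c, psi: float, phi_next: float):
    """Anchors of residue i+1 from residue i and (psi_i, phi_{i+1})."""
    n2 = nerf_place(n, ca, c, BOND_C_N, ANGLE_CA_C_N, psi)
    ca2 = nerf_place(ca, c, n2, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
    c2 = nerf_place(c, n2, ca2, BOND_CA_C, ANGLE_N_CA_C, phi_next)
    return n2, ca2, c2


def next_anchors_nward(n, ca, c, phi: float, psi_prev: float):
    """Anchors of residue i-1 from residue i and (phi_i, psi_{i-1})."""
    c0 = nerf_place(c, ca, n, BOND_C_N, ANGLE_C_N_CA, phi)
    ca0 = nerf_place(ca, n, c0, BOND_CA_C, ANGLE_CA_C_N, OMEGA)
    n0 = nerf_place(n, c0, ca0, BOND_N_CA, ANGLE_N_CA_C, psi_prev)
    return n0, ca0, c0


def residue_from_anchors(resname: str, n, ca, c, chi1: float | None = None,
                         nterm: bool = False, cterm: bool = False,
                         protonated_nterm: bool = False) -> dict[str, np.ndarray]:
    """All non-(O, amide-H, terminal-H) atoms of a residue, fitted to anchors.

    Returns a name -> coordinate dict; O/H/H2/H3/OXT placement is deferred to
    the chain-level functions because it depends on the neighboring residue.
    """
    tpl = get_template(resname)
    roster = chain_atom_names(resname, nterm=nterm, cterm=cterm,
                              protonated_nterm=protonated_nterm)
    mob = np.array([tpl.coord(a) for a in ("N", "CA", "C")])
    R, t = kabsch(mob, np.array([n, ca, c]))
    out: dict[str, np.ndarray] = {}
    for a in roster:
        if a in ("O", "H", "H2", "H3", "OXT"):
            continue
        out[a] = apply_rigid(tpl.coord(a)[None, :], R, t)[0]
    out["N"], out["CA"], out["C"] = (np.array(n, float), np.array(ca, float),
                                     np.array(c, float))
    if chi1 is not None and resname in CHI1_ATOM and resname != "PRO":
        out = set_chi1(resname, out, chi1)
    return out


def set_chi1(resname: str, atoms: dict[str, np.ndarray], chi1: float):
    """Rotate the side chain distal to CB about the CA-CB axis to the target chi1."""
    ref = CHI1_ATOM.get(resname)
    if ref is None or ref not in atoms or "CB" not in atoms:
        return atoms
    current = dihedral(atoms["N"], atoms["CA"], atoms["CB"], atoms[ref])
    delta = chi1 - current
    backbone = {"N", "CA", "C", "O", "CB", "H", "H2", "H3", "OXT"}
    distal = [a for a in atoms if a not in backbone]
    if not distal:
        return atoms
    coords = np.array([atoms[a] for a in distal])
    rotated = rotate_about_axis(coords, atoms["CA"],
                                atoms["CB"] - atoms["CA"], delta)
    out = dict(atoms)
    for a, c in zip(distal, rotated):
        out[a] = c
    return out


def place_carbonyl_o(n, ca, c, next_n) -> np.ndarray:
    """Carbonyl O in the amide plane, anti to the next backbone nitrogen."""
    psi = dihedral(n, ca, c, next_n)
    return nerf_place(n, ca, c, BOND_C_O, ANGLE_CA_C_O, psi + 180.0)


def place_terminal_o(n, ca, c, psi: float) -> tuple[np.ndarray, np.ndarray]:
    """(O, OXT) of a free carboxylate given the notional psi."""
    o = nerf_place(n, ca, c, BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
    oxt = nerf_place(n, ca, c, BOND_C_O, ANGLE_CA_C_O, psi)
    return o, oxt


def place_amide_h(n, ca, prev_c) -> np.ndarray:
    """Amide H opposite the bisector of N->C(prev) and N->CA."""
    u1 = prev_c - n
    u2 = ca - n
    u1 = u1 / np.linalg.norm(u1)
    u2 = u2 / np.linalg.norm(u2)
    d = -(u1 + u2)
    return n + BOND_N_H * d / np.linalg.norm(d)


def place_terminal_amine_h(n, ca, c, protonated: bool) -> dict[str, np.ndarray]:
    """Free N-terminal amine hydrogens (NH2 neutral, NH3+ protonated)."""
    torsions = (60.0, 180.0, -60.0) if protonated else (120.0, -120.0)
    names = ("H", "H2", "H3") if protonated else ("H", "H2")
    out = {}
    for name, tor in zip(names, torsions):
        out[name] = nerf_place(c, ca, n, BOND_N_H, 109.5, tor)
    return out


def ace_cap_atoms(n1, ca1, c1, phi1: float) -> dict[str, np.ndarray]:
    """Acetyl cap (CH3-C=O) bonded to the first residue's nitrogen."""
    c = nerf_place(c1, ca1, n1, BOND_C_N, ANGLE_C_N_CA, phi1)
    ch3 = nerf_place(ca1, n1, c, 1.510, ANGLE_CA_C_N, OMEGA)
    o = nerf_place(ca1, n1, c, BOND_C_O, 122.9, 0.0)
    return {"CH3": ch3, "C": c, "O": o}


def nme_cap_atoms(n_last, ca_last, c_last, psi_last: float) -> dict[str, np.ndarray]:
    """N-methyl amide cap (-NH-CH3) bonded to the last residue's carbonyl."""
    n = nerf_place(n_last, ca_last, c_last, BOND_C_N, ANGLE_CA_C_N, psi_last)
    ch3 = nerf_place(ca_last, c_last, n, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
    h = place_amide_h(n, ch3, c_last)
    return {"N": n, "H": h, "CH3": ch3}


_ACE_ORDER = ("CH3", "C", "O")
_NME_ORDER = ("N", "H", "CH3")


def assemble_structure(residues: list[tuple[int, str, dict[str, np.ndarray]]],
                       chain_id: str = "P") -> Structure:
    """Turn (index, resname, atom dict) triples into an ordered Structure.

    Atoms follow the template roster order per residue (caps use their own
    fixed order); residues follow the order given.
    """
    atoms: list[Atom] = []
    for idx, resname, coords in residues:
        if resname == "ACE":
            order = [a for a in _ACE_ORDER if a in coords]
        elif resname == "NME":
            order = [a for a in _NME_ORDER if a in coords]
        else:
            tpl = get_template(resname)
            order = [a for a in tpl.names if a in coords]
            order += [a for a in coords if a not in order]
        for name in order:
            tplel = ("H" if name.startswith("H")
                     else ("S" if name.startswith("S") else name[0]))
            atoms.append(Atom(
                serial=len(atoms) + 1, name=name, element=tplel,
                coord=np.array(coords[name], dtype=float),
                residue_index=idx, residue_name=resname, chain_id=chain_id))
    return Structure(atoms)


def build_chain(resnames: list[str], start_index: int = 1,
                phi: list[float] | None = None, psi: list[float] | None = None,
                chi1: list[float | None] | None = None,
                n_cap: str | None = None, c_cap: str | None = None,
                protonated_nterm: bool = False,
                free_cterm_carboxylate: bool = False,
                chain_id: str = "P") -> Structure:
    """Build a peptide chain in one shot.

    phi/psi default to the extended conformation (-120, +120); proline's phi
    is pinned near -65 regardless.  `n_cap`/`c_cap` accept "ACE"/"NME".
    """
    n_res = len(resnames)
    if n_res < 1:
        raise StructureError("empty sequence")
    phi = list(phi) if phi is not None else [PHI_EXTENDED] * n_res
    psi = list(psi) if psi is not None else [PSI_EXTENDED] * n_res
    chi1 = list(chi1) if chi1 is not None else [None] * n_res
    for i, rn in enumerate(resnames):
        if rn == "PRO":
            phi[i] = -65.0

    anchors = [first_anchors()]
    for i in range(1, n_res):
        anchors.append(next_anchors_cward(*anchors[i - 1], psi[i - 1], phi[i]))

    entries: list[tuple[int, str, dict[str, np.ndarray]]] = []
    if n_cap == "ACE":
        entries.append((start_index - 1, "ACE",
                        ace_cap_atoms(*anchors[0], phi[0])))
    for i, rn in enumerate(resnames):
        nterm = i == 0 and n_cap is None
        cterm = (i == n_res - 1 and c_cap is None and free_cterm_carboxylate)
        res = residue_from_anchors(rn, *anchors[i], chi1=chi1[i],
                                   nterm=nterm, cterm=cterm,
                                   protonated_nterm=protonated_nterm)
        n_i, ca_i, c_i = anchors[i]
        if i + 1 < n_res:
            res["O"] = place_carbonyl_o(n_i, ca_i, c_i, anchors[i + 1][0])
        elif c_cap == "NME":
            cap = nme_cap_atoms(n_i, ca_i, c_i, psi[i])
            res["O"] = place_carbonyl_o(n_i, ca_i, c_i, cap["N"])
        elif cterm:
            res["O"], res["OXT"] = place_terminal_o(n_i, ca_i, c_i, psi[i])
        else:
            res["O"] = nerf_place(n_i, ca_i, c_i, BOND_C_O, ANGLE_CA_C_O,
                                  psi[i] + 180.0)
        if i == 0:
            if n_cap == "ACE":
                res["H"] = place_amide_h(n_i, ca_i, entries[0][2]["C"])
            elif rn != "PRO":
                res.update(place_terminal_amine_h(n_i, ca_i, c_i,
                                                  protonated_nterm))
        elif rn != "PRO":
            res["H"] = place_amide_h(n_i, ca_i, anchors[i - 1][2])
        entries.append((start_index + i, rn, res))
    if c_cap == "NME":
        entries.append((start_index + n_res, "NME",
                        nme_cap_atoms(*anchors[-1], psi[-1])))
    return assemble_structure(entries, chain_id=chain_id)
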