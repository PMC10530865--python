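"""Per-atom force-field parameters: van der Waals table, atom typing, charge template.

The van der Waals table follows the Amber convention in which ``R_i`` is the
Rmin/2 radius in Angstrom and ``eps_i`` the well depth in kcal/mol, so that the
pair minimum sits at ``R_ij = R_i + R_j`` with depth ``eps_ij = sqrt(eps_i eps_j)``.
Structures carry polar hydrogens only (AutoDock-style preparation), so the
carbon rows double as united-atom carriers of their implicit hydrogens.

Charges come from a fixed per-(residue, atom-name) template rather than an
iterative partial-equalization scheme.  The template is *group-neutral*: the
atoms of every chemical group (backbone amide, hydroxyl, guanidinium, ...)
sum exactly to the group's formal charge, so any peptide built from the
template has an integer net charge by construction.
"""

from __future__ import annotations

from .errors import TypingError

# --- van der Waals classes: class -> (Rmin/2 [A], well depth [kcal/mol]) ---
VDW_CLASSES: dict[str, tuple[float, float]] = {
    "C": (1.9080, 0.0860),   # sp2 carbon (carbonyl, aromatic, guanidinium)
    "CT": (1.9080, 0.1094),  # sp3 carbon
    "N": (1.8240, 0.1700),   # any nitrogen
    "O": (1.6612, 0.2100),   # carbonyl oxygen
    "O2": (1.6612, 0.2100),  # carboxylate oxygen
    "OH": (1.7210, 0.2104),  # hydroxyl oxygen
    "S": (2.0000, 0.2500),   # sulfur
    "H": (0.6000, 0.0157),   # polar hydrogen (on N/O/S)
}

# sp2 carbons per residue (side chains); backbone C and the acetyl cap C are
# always sp2, every other carbon defaults to sp3.
_SP2_SIDE = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "CD2", "CE1"},
    "ARG": {"CZ"},
    "ASP": {"CG"},
    "GLU": {"CD"},
    "ASN": {"CG"},
    "GLN": {"CD"},
}

_CARBONYL_O = {"O", "OD1", "OE1"}
_CARBOXYL_O = {"OD2", "OE2", "OXT"}
_HYDROXYL_O = {"OG", "OG1", "OH"}

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
MODIFIED_RESIDUES = {"M3L"}  # N-zeta-trimethyl-lysine
CAP_RESIDUES = {"ACE", "NME"}
KNOWN_RESIDUES = STANDARD_RESIDUES | MODIFIED_RESIDUES | CAP_RESIDUES

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}


def vdw_class(residue_name: str, atom_name: str, element: str) -> str:
    """Map an atom to its van der Waals class."""
    el = element.upper()
    if el == "H":
        return "H"
    if el == "N":
        return "N"
    if el == "S":
        return "S"
    if el == "O":
        if atom_name in _CARBONYL_O:
            return "O"
        if atom_name in _CARBOXYL_O:
            return "O2"
        if atom_name in _HYDROXYL_O:
            return "OH"
        return "O"
    if el == "C":
        if atom_name == "C":
            return "C"
        if atom_name in _SP2_SIDE.get(residue_name, ()):
            return "C"
        return "CT"
    raise TypingError(
        f"no van der Waals class for element {element!r} "
        f"(residue {residue_name}, atom {atom_name})"
    )


def vdw_params(residue_name: str, atom_name: str, element: str) -> tuple[float, float]:
    """(Rmin/2, well depth) for one atom."""
    return VDW_CLASSES[vdw_class(residue_name, atom_name, element)]


# --- charge template ------------------------------------------------------

_BACKBONE_Q = {"N": -0.52, "H": 0.31, "CA": 0.21, "C": 0.53, "O": -0.53}
_PRO_BACKBONE_Q = {"N": -0.26, "CA": 0.26, "C": 0.53, "O": -0.53}

# polar side-chain atoms; unlisted side-chain atoms carry 0.
_SIDE_Q: dict[str, dict[str, float]] = {
    "SER": {"CB": 0.10, "OG": -0.42, "HG": 0.32},
    "THR": {"CB": 0.10, "OG1": -0.42, "HG1": 0.32},
    "TYR": {"CZ": 0.10, "OH": -0.42, "HH": 0.32},
    "CYS": {"CB": 0.10, "SG": -0.32, "HG": 0.22},
    "MET": {"CG": 0.05, "SD": -0.10, "CE": 0.05},
    "TRP": {"NE1": -0.34, "HE1": 0.34},
    "ASN": {"CG": 0.55, "OD1": -0.55, "ND2": -0.62, "HD21": 0.31, "HD22": 0.31},
    "GLN": {"CD": 0.55, "OE1": -0.55, "NE2": -0.62, "HE21": 0.31, "HE22": 0.31},
    "ASP": {"CG": 0.34, "OD1": -0.67, "OD2": -0.67},
    "GLU": {"CD": 0.34, "OE1": -0.67, "OE2": -0.67},
    "LYS": {"CE": 0.20, "NZ": -0.19, "HZ1": 0.33, "HZ2": 0.33, "HZ3": 0.33},
    "ARG": {
        "CD": 0.10, "NE": -0.49, "HE": 0.31, "CZ": 0.64,
        "NH1": -0.62, "NH2": -0.62,
        "HH11": 0.42, "HH12": 0.42, "HH21": 0.42, "HH22": 0.42,
    },
    # neutral His, NE2-protonated tautomer
    "HIS": {"CG": 0.30, "ND1": -0.56, "CE1": 0.26, "NE2": -0.34, "HE2": 0.34},
    # trimethyl-lysine: +1 spread over the quaternary ammonium group
    "M3L": {"CE": 0.30, "NZ": 0.10, "CM1": 0.20, "CM2": 0.20, "CM3": 0.20},
}

_CAP_Q = {
    "ACE": {"CH3": 0.0, "C": 0.53, "O": -0.53},
    "NME": {"N": -0.52, "H": 0.31, "CH3": 0.21},
}

# terminal-group overrides, applied when the residue carries the marker atoms
_NTERM_NEUTRAL_Q = {"N": -0.83, "H": 0.31, "H2": 0.31, "CA": 0.21}
_NTERM_CHARGED_Q = {"N": -0.14, "H": 0.33, "H2": 0.33, "H3": 0.33, "CA": 0.15}
_CTERM_Q = {"C": 0.34, "O": -0.67, "OXT": -0.67}


def residue_charges(residue_name: str, atom_names: list[str]) -> dict[str, float]:
    """Template charges for one residue, given its actual atom roster.

    Terminal variants are detected from marker atoms: ``H2`` (free amine),
    ``H3`` (protonated amine), ``OXT`` (free carboxylate).
    """
    if residue_name in _CAP_Q:
        table = _CAP_Q[residue_name]
        return {a: table.get(a, 0.0) for a in atom_names}
    if residue_name not in KNOWN_RESIDUES:
        raise TypingError(f"no charge template for residue {residue_name!r}")
    base = dict(_PRO_BACKBONE_Q if residue_name == "PRO" else _BACKBONE_Q)
    base.update(_SIDE_Q.get(residue_name, {}))
    names = set(atom_names)
    if "H3" in names:
        base.update(_NTERM_CHARGED_Q)
    elif "H2" in names:
        base.update(_NTERM_NEUTRAL_Q)
    if "OXT" in names:
        base.update(_CTERM_Q)
    return {a: base.get(a, 0.0) for a in atom_names}
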