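"""Ideal residue geometry from the chemical component dictionary.

Templates (heavy atoms, hydrogens, connectivity, ideal coordinates) are pulled
from biotite's bundled component dictionary and cached.  The package works in
a polar-hydrogen-only representation, so helpers here also classify which
template hydrogens are polar (bonded to N, O or S).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import biotite.structure.info as strucinfo


class ResidueTemplate:
    """Ideal geometry of one residue type.

    Attributes
    ----------
    names, elements : list[str]
        Atom names / element symbols, template order.
    coords : (n, 3) ndarray
        Ideal coordinates in Angstrom.
    neighbors : dict[str, list[str]]
        Bonded-atom adjacency by atom name.
    """

    def __init__(self, name: str, atoms: list[str], elements: list[str],
                 coords: np.ndarray, neighbors: dict[str, list[str]]):
        self.name = name
        self.names = atoms
        self.elements = elements
        self.coords = coords
        self.neighbors = neighbors
        self._index = {a: i for i, a in enumerate(atoms)}

    def coord(self, atom_name: str) -> np.ndarray:
        return self.coords[self._index[atom_name]]

    def has(self, atom_name: str) -> bool:
        return atom_name in self._index

    def element(self, atom_name: str) -> str:
        return self.elements[self._index[atom_name]]

    def polar_hydrogens(self) -> list[str]:
        """Hydrogens bonded to N, O or S."""
        out = []
        for a, el in zip(self.names, self.elements):
            if el != "H":
                continue
            heavy = [b for b in self.neighbors[a] if self.element(b) != "H"]
            if heavy and self.element(heavy[0]) in ("N", "O", "S"):
                out.append(a)
        return out

    def heavy_names(self) -> list[str]:
        return [a for a, el in zip(self.names, self.elements) if el != "H"]


@lru_cache(maxsize=None)
def get_template(residue_name: str) -> ResidueTemplate:
    arr = strucinfo.residue(residue_name)
    if arr is None:
        raise KeyError(f"residue {residue_name!r} not in component dictionary")
    names = [str(n) for n in arr.atom_name]
    elements = [str(e).capitalize() for e in arr.element]
    coords = np.asarray(arr.coord, dtype=float)
    neighbors: dict[str, list[str]] = {n: [] for n in names}
    bond_array = arr.bonds.as_array()
    for i, j, _ in bond_array:
        neighbors[names[i]].append(names[j])
        neighbors[names[j]].append(names[i])
    return ResidueTemplate(residue_name, names, elements, coords, neighbors)


# hydrogens that belong to monomer-edge variants, not to a chain-internal residue
_VARIANT_ATOMS = {"OXT", "HXT", "H2", "H3", "HN2"}
# acidic protons dropped to keep Asp/Glu deprotonated and His in one tautomer
_DROPPED_PROTONS = {
    "ASP": {"HD2"},
    "GLU": {"HE2"},
    "HIS": {"HD1"},
}


def chain_atom_names(residue_name: str, nterm: bool = False, cterm: bool = False,
                     protonated_nterm: bool = False) -> list[str]:
    """Atom roster for a chain-internal (or terminal) residue in the
    polar-hydrogen-only representation, in template order.

    N-terminal residues keep the free-amine hydrogens (H + H2, plus H3 when
    `protonated_nterm`); C-terminal residues keep OXT.
    """
    tpl = get_template(residue_name)
    keep = set(tpl.heavy_names()) | set(tpl.polar_hydrogens())
    keep -= _VARIANT_ATOMS
    keep -= _DROPPED_PROTONS.get(residue_name, set())
    if nterm and residue_name != "PRO":
        keep.add("H2")
        if protonated_nterm:
            keep.add("H3")
    if cterm:
        keep.add("OXT")
    out = [a for a in tpl.names if a in keep]
    if nterm and protonated_nterm and not tpl.has("H3"):
        out.append("H3")  # placed geometrically by the builder
    return out
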