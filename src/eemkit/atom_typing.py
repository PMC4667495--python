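"""Atom typing: element symbol plus maximal incident bond order.

The atom type is the unit of EEM parameterization. A carbon whose highest
incident bond order is 2 (including aromatic-normalized ring bonds) is
"C2"; a nitrile carbon is "C3". Isolated atoms, having no multiple bond,
are assigned order 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable

if TYPE_CHECKING:  # pragma: no cover
    from .mol_model import Molecule


@dataclass(frozen=True, order=True)
class AtomType:
    element: str
    max_order: int

    def __post_init__(self) -> None:
        if self.max_order not in (1, 2, 3):
            raise ValueError(f"max_order {self.max_order} outside {{1,2,3}}")

    @property
    def key(self) -> str:
        """Compact key, e.g. ``"C2"`` or ``"Br1"``."""
        return f"{self.element}{self.max_order}"

    def __str__(self) -> str:  # pragma: no cover
        return self.key


def assign_atom_types(m: "Molecule") -> list[AtomType]:
    """One :class:`AtomType` per atom, in atom order."""
    max_order = [1] * m.n_atoms
    for bond in m.bonds:
        for idx in (bond.a, bond.b):
            if bond.order > max_order[idx]:
                max_order[idx] = bond.order
    return [AtomType(atom.element, order)
            for atom, order in zip(m.atoms, max_order)]


def type_histogram(molecules: Iterable["Molecule"]
                   ) -> dict[AtomType, tuple[int, int]]:
    """Occurrence counts per atom type over a molecule collection.

    Returns ``{type: (atom_count, molecule_count)}`` where ``atom_count``
    is the total number of atoms of that type and ``molecule_count`` the
    number of molecules containing at least one such atom. Atom counts sum
    to the total number of atoms seen.
    """
    atoms: dict[AtomType, int] = {}
    mols: dict[AtomType, int] = {}
    for m in molecules:
        types = assign_atom_types(m)
        for t in types:
            atoms[t] = atoms.get(t, 0) + 1
        for t in set(types):
            mols[t] = mols.get(t, 0) + 1
    return {t: (atoms[t], mols[t]) for t in sorted(atoms)}


def histogram_tsv(hist: dict[AtomType, tuple[int, int]], sink) -> None:
    """Export a histogram as TSV: type_key, atom_count, molecule_count."""
    sink.write("type_key\tatom_count\tmolecule_count\n")
    for t in sorted(hist):
        a, m = hist[t]
        sink.write(f"{t.key}\t{a}\t{m}\n")
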