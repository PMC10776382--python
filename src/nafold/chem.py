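"""Chemical component knowledge: residue templates, bond graphs, polar atoms.

Backed by the PDB chemical component dictionary bundled with biotite, which
supplies idealized coordinates, element symbols, bonded pairs and hydrogen
placement for every standard monomer.  Results are cached per component.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .alphabet import MolType

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

STANDARD_PROTEIN = frozenset(THREE_TO_ONE)
STANDARD_DNA = frozenset({"DA", "DC", "DG", "DT"})
STANDARD_RNA = frozenset({"A", "C", "G", "U"})

PROTEIN_BACKBONE = ("N", "CA", "C")
#: Backbone atoms required of every nucleotide monomer (unknown types carry
#: these only).  Primed names follow PDB v3 conventions.
NA_BACKBONE = ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'")

#: Nucleobase heavy atoms per standard nucleotide (everything that is not
#: sugar or phosphate); used by the base-specific contact rule.
_SUGAR_PHOSPHATE = frozenset(
    {"P", "OP1", "OP2", "OP3", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'",
     "C2'", "O2'", "C1'"}
)

PURINES = frozenset({"DA", "DG", "A", "G"})
GLYCOSIDIC_N = {name: ("N9" if name in PURINES else "N1")
                for name in STANDARD_DNA | STANDARD_RNA}

WC_COMPLEMENT = {"DA": "DT", "DT": "DA", "DG": "DC", "DC": "DG",
                 "A": "U", "U": "A", "G": "C", "C": "G"}

#: Watson-Crick hydrogen-bond heavy-atom partners, keyed by the purine of the
#: pair, listed as (purine atom, pyrimidine atom).
WC_HBOND_ATOMS = {
    "G": (("O6", "N4"), ("N1", "N3"), ("N2", "O2")),
    "A": (("N6", "O4"), ("N1", "N3")),
}


def moltype_of_residue(name: str) -> MolType | None:
    """Polymer type implied by a residue name; None if unrecognized.

    Unrecognized names are resolved by the caller from chain context (a
    modified base in a DNA chain stays DNA, as a backbone-only unknown).
    """
    name = name.strip().upper()
    if name in STANDARD_PROTEIN:
        return MolType.PROTEIN
    if name in STANDARD_DNA:
        return MolType.DNA
    if name in STANDARD_RNA:
        return MolType.RNA
    return None


@dataclass(frozen=True)
class ComponentTemplate:
    """Idealized template for one chemical component.

    ``coords`` covers heavy atoms only (terminal OP3/OXT excluded, since
    they exist only on free termini); ``h_coords`` maps each heavy donor
    candidate to the template positions of its bound hydrogens.
    """

    name: str
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    coords: np.ndarray                      # (n_heavy, 3)
    bonds: frozenset[tuple[str, str]]       # heavy-heavy, name-sorted pairs
    h_count: dict[str, int]                 # heavy atom -> bound hydrogens
    h_coords: dict[str, np.ndarray]

    def xyz(self, atom: str) -> np.ndarray:
        return self.coords[self.atom_names.index(atom)]

    def bonded(self, a: str, b: str) -> bool:
        return (a, b) in self.bonds or (b, a) in self.bonds

    def neighbors(self, atom: str) -> list[str]:
        out = [b if a == atom else a for a, b in self.bonds if atom in (a, b)]
        return sorted(out)

    @property
    def heavy_atom_count(self) -> int:
        return len(self.atom_names)


_TERMINAL_ONLY = {"OP3", "OXT"}
# Hydrogens that exist only on free (non-polymer) termini.  "H2" is terminal
# only when riding the backbone nitrogen (free amine); on adenine C2 it is a
# genuine base hydrogen.
_TERMINAL_H = {"HOP3", "HXT", "HO3'", "HO5'"}


@lru_cache(maxsize=None)
def component(name: str) -> ComponentTemplate:
    """Load one component from the bundled chemical component dictionary."""
    import biotite.structure.info as info

    arr = info.residue(name.strip().upper())
    if arr is None:
        raise KeyError(f"unknown chemical component {name!r}")
    keep = ~np.isin(arr.atom_name, list(_TERMINAL_ONLY))
    arr = arr[keep]
    heavy = arr.element != "H"
    names = tuple(arr.atom_name[heavy])
    elements = tuple(arr.element[heavy])
    coords = np.asarray(arr.coord[heavy], dtype=float)

    name_of = list(arr.atom_name)
    pair_set: set[tuple[str, str]] = set()
    h_count: dict[str, int] = {n: 0 for n in names}
    h_coords: dict[str, list[np.ndarray]] = {}
    for i, j, _ in arr.bonds.as_array():
        ai, aj = name_of[i], name_of[j]
        ei, ej = arr.element[i], arr.element[j]
        if ei != "H" and ej != "H":
            pair_set.add(tuple(sorted((ai, aj))))
            continue
        if ei == "H":
            hname, heavy_name, hidx = ai, aj, i
        else:
            hname, heavy_name, hidx = aj, ai, j
        if hname in _TERMINAL_H or (hname == "H2" and heavy_name == "N"):
            continue
        h_count[heavy_name] = h_count.get(heavy_name, 0) + 1
        h_coords.setdefault(heavy_name, []).append(np.asarray(arr.coord[hidx], float))
    return ComponentTemplate(
        name=name.strip().upper(),
        atom_names=names,
        elements=elements,
        coords=coords,
        bonds=frozenset(pair_set),
        h_count=h_count,
        h_coords={k: np.asarray(v) for k, v in h_coords.items()},
    )


def base_atoms(residue: str) -> tuple[str, ...]:
    """Nucleobase heavy atoms of a standard nucleotide."""
    comp = component(residue)
    return tuple(n for n in comp.atom_names if n not in _SUGAR_PHOSPHATE)


@lru_cache(maxsize=None)
def donor_acceptor_atoms(residue: str) -> tuple[frozenset[str], frozenset[str]]:
    """(donors, acceptors) heavy-atom names for one component.

    A donor is an N/O carrying at least one hydrogen in the template; an
    acceptor is an O, or an N with fewer than three heavy/hydrogen bonds
    (a lone-pair-bearing sp2 nitrogen such as purine N1/N3/N7).
    """
    comp = component(residue)
    donors, acceptors = set(), set()
    for atom, elem in zip(comp.atom_names, comp.elements):
        if elem not in ("N", "O"):
            continue
        n_heavy = len(comp.neighbors(atom))
        n_h = comp.h_count.get(atom, 0)
        if n_h > 0:
            donors.add(atom)
        if elem == "O" and n_heavy + n_h <= 2:
            acceptors.add(atom)
        if elem == "N" and n_heavy + n_h <= 2:
            acceptors.add(atom)
    return frozenset(donors), frozenset(acceptors)
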