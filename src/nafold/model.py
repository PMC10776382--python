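"""Hierarchical structure model: Assembly -> Chain -> Monomer -> Atom.

Internal indexing is 0-based throughout; file I/O converts to the 1-based
PDB convention on output.  Monomers carry a ``loss_excluded`` flag used by
the curation operators to mark padding positions that must not contribute
to training losses (they are still written to structure files as ordinary
residues).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .alphabet import INDEX, TOKENS, MolType, token_for_monomer
from .chem import (NA_BACKBONE, PROTEIN_BACKBONE, STANDARD_DNA, STANDARD_PROTEIN,
                   STANDARD_RNA, ONE_TO_THREE)


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")


@dataclass
class Monomer:
    """One residue or nucleotide.

    ``identity`` is a token index into the 32-token alphabet; ``name`` keeps
    the residue name used in structure files (standard monomers) or "UNK"
    style placeholders for backbone-only unknowns.
    """

    identity: int
    name: str
    moltype: MolType
    atoms: list[Atom] = field(default_factory=list)
    seq_index: int = 0
    loss_excluded: bool = False

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def xyz(self, name: str) -> np.ndarray | None:
        a = self.atom(name)
        return None if a is None else a.xyz

    def has_atoms(self, names) -> bool:
        present = {a.name for a in self.atoms}
        return all(n in present for n in names)

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element != "H"]

    @property
    def token(self) -> str:
        return TOKENS[self.identity]

    @property
    def is_standard(self) -> bool:
        if self.moltype is MolType.PROTEIN:
            return self.name in STANDARD_PROTEIN
        if self.moltype is MolType.DNA:
            return self.name in STANDARD_DNA
        return self.name in STANDARD_RNA

    def coords(self, heavy_only: bool = True) -> np.ndarray:
        atoms = self.heavy_atoms if heavy_only else self.atoms
        return np.array([a.xyz for a in atoms], dtype=float).reshape(-1, 3)


@dataclass
class Chain:
    id: str
    moltype: MolType
    monomers: list[Monomer] = field(default_factory=list)

    def __post_init__(self):
        self._validate()

    def _validate(self):
        idx = [m.seq_index for m in self.monomers]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"chain {self.id}: seq_index must be strictly increasing")
        if any(m.moltype is not self.moltype for m in self.monomers):
            raise ValueError(f"chain {self.id}: mixed polymer types")

    def __len__(self) -> int:
        return len(self.monomers)

    def __iter__(self):
        return iter(self.monomers)

    @property
    def sequence(self) -> str:
        out = []
        for m in self.monomers:
            tok = m.token
            out.append(tok if len(tok) == 1 else ("X" if tok.endswith("X") or tok == "<mask>" else tok[-1]))
        return "".join(out)

    def renumber(self):
        for i, m in enumerate(self.monomers):
            m.seq_index = i


@dataclass
class Assembly:
    chains: list[Chain] = field(default_factory=list)
    source: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [c.id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError("chain ids must be unique")

    def __iter__(self):
        return iter(self.chains)

    def chain(self, cid: str) -> Chain:
        for c in self.chains:
            if c.id == cid:
                return c
        raise KeyError(cid)

    @property
    def n_monomers(self) -> int:
        return sum(len(c) for c in self.chains)

    @property
    def n_atoms(self) -> int:
        return sum(len(m.atoms) for c in self.chains for m in c)

    def monomers(self):
        """Iterate (chain, monomer) over the whole assembly in order."""
        for c in self.chains:
            for m in c:
                yield c, m

    def coords(self, heavy_only: bool = True) -> np.ndarray:
        rows = []
        for c in self.chains:
            for m in c:
                atoms = m.heavy_atoms if heavy_only else m.atoms
                rows.extend(a.xyz for a in atoms)
        return np.array(rows, dtype=float).reshape(-1, 3)

    def copy(self) -> "Assembly":
        return copy.deepcopy(self)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Assembly":
        """Rigidly transformed copy: x -> R x + t."""
        out = self.copy()
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        for _, m in out.monomers():
            for a in m.atoms:
                a.xyz = R @ a.xyz + t
        return out


def make_monomer(residue_name: str, moltype: MolType, atoms: list[Atom],
                 seq_index: int, loss_excluded: bool = False) -> Monomer:
    """Monomer from a residue name, resolving the token index."""
    return Monomer(
        identity=token_for_monomer(residue_name, moltype),
        name=residue_name.strip().upper(),
        moltype=moltype,
        atoms=atoms,
        seq_index=seq_index,
        loss_excluded=loss_excluded,
    )


def required_backbone(moltype: MolType) -> tuple[str, ...]:
    return PROTEIN_BACKBONE if moltype is MolType.PROTEIN else NA_BACKBONE
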