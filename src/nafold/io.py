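"""Structure file I/O (PDB / mmCIF via gemmi) and FASTA helpers.

Reading maps files onto the package's Assembly model: chains are typed
from their residue names, alternate locations are resolved to the highest
occupancy (ties: first encountered), hydrogens are retained when present,
and non-standard monomers become backbone-only "unknown" tokens.  Writing
emits standard-conformant files with 1-based residue numbering.
"""

from __future__ import annotations

import os
from collections import Counter
from pathlib import Path

import gemmi

from .alphabet import MolType
from .chem import (NA_BACKBONE, PROTEIN_BACKBONE, moltype_of_residue)
from .model import Assembly, Atom, Chain, Monomer, make_monomer


class StructureFormatError(ValueError):
    """Unparseable or empty structure file."""


class StructureValidationError(ValueError):
    """Parsed but chemically inconsistent content (e.g. mixed-type chain)."""


_SKIP_RESIDUES = {"HOH", "DOD", "WAT"}


def _coor_format(fmt: str) -> gemmi.CoorFormat:
    fmt = fmt.lower()
    if fmt == "pdb":
        return gemmi.CoorFormat.Pdb
    if fmt in ("mmcif", "cif"):
        return gemmi.CoorFormat.Mmcif
    raise ValueError(f"unknown structure format {fmt!r}")


def _dedup_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Highest-occupancy conformer per atom name; ties keep the first."""
    best: dict[str, gemmi.Atom] = {}
    for at in residue:
        prev = best.get(at.name)
        if prev is None or at.occ > prev.occ + 1e-9:
            best[at.name] = at
    # preserve file order
    seen = set()
    out = []
    for at in residue:
        if at.name not in seen and best[at.name] is at:
            seen.add(at.name)
            out.append(at)
        elif at.name not in seen and best[at.name] is not at:
            seen.add(at.name)
            out.append(best[at.name])
    return out


def read_structure(path, format: str = "pdb") -> Assembly:
    """Read a PDB or mmCIF file into an Assembly.

    Chains are typed by MolType from residue names; a chain mixing polymer
    types raises StructureValidationError.  Monomers with unrecognized
    residue names are kept as backbone-only unknown tokens of the chain's
    polymer type (modified bases/amino acids).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=_coor_format(format))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0 or all(len(ch) == 0 for ch in st[0]):
        raise StructureFormatError(f"{path} contains no atoms")
    model = st[0]

    chains: list[Chain] = []
    for gch in model:
        residues = [r for r in gch if r.name.strip().upper() not in _SKIP_RESIDUES]
        if not residues:
            continue
        types = [moltype_of_residue(r.name) for r in residues]
        recognized = [t for t in types if t is not None]
        if not recognized:
            continue                      # ligand-only chain
        counts = Counter(recognized)
        if len(counts) > 1:
            raise StructureValidationError(
                f"chain {gch.name} mixes polymer types {sorted(c.value for c in counts)}")
        moltype = recognized[0]
        backbone = PROTEIN_BACKBONE if moltype is MolType.PROTEIN else NA_BACKBONE
        monomers = []
        for i, (res, rtype) in enumerate(zip(residues, types)):
            atoms = []
            for at in _dedup_altlocs(res):
                name = at.name
                if rtype is None and name not in backbone and at.element.name != "H":
                    continue              # nonstandard monomer: backbone only
                atoms.append(Atom(name, at.element.name,
                                  (at.pos.x, at.pos.y, at.pos.z)))
            monomers.append(make_monomer(res.name, moltype, atoms, i))
        chains.append(Chain(gch.name, moltype, monomers))
    if not chains:
        raise StructureFormatError(f"{path} contains no polymer chains")
    return Assembly(chains, source={"path": str(path), "format": format})


def write_structure(assembly: Assembly, path, format: str = "pdb") -> None:
    """Write an Assembly as PDB or mmCIF with 1-based residue numbering.

    loss-excluded padding positions are written as ordinary residues; the
    flag is internal bookkeeping only.
    """
    if assembly.n_monomers == 0:
        raise ValueError("assembly is empty")
    fmt = format.lower()
    if fmt == "pdb" and assembly.n_atoms > 99_999:
        raise OverflowError("more than 99,999 atoms cannot be written as PDB")
    st = gemmi.Structure()
    st.name = assembly.source.get("name", "nafold")
    model = gemmi.Model("1")
    for ch in assembly:
        gch = gemmi.Chain(ch.id)
        for i, mon in enumerate(ch):
            res = gemmi.Residue()
            res.name = mon.name
            res.seqid = gemmi.SeqId(i + 1, " ")
            res.het_flag = "A"
            for a in mon.atoms:
                at = gemmi.Atom()
                at.name = a.name
                at.element = gemmi.Element(a.element)
                at.pos = gemmi.Position(*a.xyz)
                at.occ = 1.0
                res.add_atom(at)
            gch.add_residue(res)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    path = str(path)
    if fmt == "pdb":
        st.write_pdb(path)
    else:
        st.make_mmcif_document().write_file(path)


def read_fasta(path) -> list[tuple[str, str]]:
    """(label, sequence) records from a FASTA file."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for label, seq in records:
            fh.write(f">{label}\n{seq}\n")
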