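"""Token alphabet shared by every module.

The sequence representation extends the classic 22-token protein scheme
(20 amino acids, an unknown/gap token, a mask token used for sequence
recovery training) with 10 nucleic-acid tokens: the four DNA nucleotides,
the four RNA nucleotides, and per-polymer unknown tokens.  Protein token
indices are unchanged relative to the 22-token parent scheme; the nucleic
acid tokens are appended, so indices are stable across the package.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class MolType(enum.Enum):
    """Polymer type of a chain.  Every chain carries exactly one."""

    PROTEIN = "protein"
    DNA = "dna"
    RNA = "rna"

    @property
    def is_nucleic(self) -> bool:
        return self in (MolType.DNA, MolType.RNA)


#: 20 amino acids in the conventional one-letter order used by the parent
#: 22-token scheme, followed by unknown/gap ("X") and the protein-only
#: mask token.
AMINO_ACIDS = tuple("ARNDCQEGHILKMFPSTWYV")
UNKNOWN_AA = "X"
MASK = "<mask>"

DNA_TOKENS = ("DA", "DC", "DG", "DT")
RNA_TOKENS = ("RA", "RC", "RG", "RU")
UNKNOWN_DNA = "DX"
UNKNOWN_RNA = "RX"

TOKENS: tuple[str, ...] = (
    AMINO_ACIDS
    + (UNKNOWN_AA, MASK)
    + DNA_TOKENS
    + RNA_TOKENS
    + (UNKNOWN_DNA, UNKNOWN_RNA)
)

assert len(TOKENS) == 32

INDEX: dict[str, int] = {tok: i for i, tok in enumerate(TOKENS)}

MASK_INDEX = INDEX[MASK]
UNKNOWN_AA_INDEX = INDEX[UNKNOWN_AA]
UNKNOWN_DNA_INDEX = INDEX[UNKNOWN_DNA]
UNKNOWN_RNA_INDEX = INDEX[UNKNOWN_RNA]

N_TOKENS = len(TOKENS)

# Single-character spellings accepted in sequence strings, per polymer type.
_DNA_CHAR = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}
_RNA_CHAR = {"A": "RA", "C": "RC", "G": "RG", "U": "RU"}


@dataclass(frozen=True)
class Alphabet:
    """The frozen 32-token alphabet.

    Exists as a type mostly so callers can pass the token table around
    explicitly; all instances are identical.
    """

    tokens: tuple[str, ...] = TOKENS

    @property
    def index(self) -> dict[str, int]:
        return INDEX

    def __len__(self) -> int:
        return len(self.tokens)


def tokenize(sequence: str, moltype: MolType) -> list[int]:
    """Map a one-letter sequence to token indices for the given polymer type.

    Unknown characters map to the polymer's unknown token; for proteins the
    unknown token doubles as the gap token, mirroring the parent scheme.
    """
    if not isinstance(moltype, MolType):
        raise ValueError(f"moltype must be a MolType, got {moltype!r}")
    out: list[int] = []
    seq = sequence.upper()
    if moltype is MolType.PROTEIN:
        for ch in seq:
            out.append(INDEX[ch] if ch in AMINO_ACIDS else UNKNOWN_AA_INDEX)
    elif moltype is MolType.DNA:
        for ch in seq:
            out.append(INDEX[_DNA_CHAR[ch]] if ch in _DNA_CHAR else UNKNOWN_DNA_INDEX)
    else:
        for ch in seq:
            out.append(INDEX[_RNA_CHAR[ch]] if ch in _RNA_CHAR else UNKNOWN_RNA_INDEX)
    return out


def detokenize(indices: list[int], moltype: MolType) -> str:
    """Inverse of :func:`tokenize` on valid sequences."""
    chars = []
    for i in indices:
        tok = TOKENS[i]
        if moltype is MolType.PROTEIN:
            chars.append(tok if tok in AMINO_ACIDS else "X")
        elif tok in (UNKNOWN_DNA, UNKNOWN_RNA):
            chars.append("X" if moltype is MolType.DNA else "X")
        else:
            chars.append(tok[-1])
    return "".join(chars)


def token_for_monomer(one_or_three: str, moltype: MolType) -> int:
    """Token index for a residue name as found in structure files."""
    name = one_or_three.strip().upper()
    if moltype is MolType.PROTEIN:
        from .chem import THREE_TO_ONE

        one = THREE_TO_ONE.get(name)
        return INDEX[one] if one is not None else UNKNOWN_AA_INDEX
    if moltype is MolType.DNA:
        return INDEX["D" + name[-1]] if name in ("DA", "DC", "DG", "DT") else UNKNOWN_DNA_INDEX
    return INDEX["R" + name] if name in ("A", "C", "G", "U") else UNKNOWN_RNA_INDEX
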