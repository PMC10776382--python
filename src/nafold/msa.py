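"""Multiple sequence alignments: A3M / Stockholm readers and depth filtering.

Only alignment bookkeeping lives here — database searching is out of
scope.  The filtering rule mirrors standard MSA-depth accounting for
structure prediction: rows are kept when they cover more than a minimum
fraction of the query's (non-gap) columns, and depth is counted in unique
retained sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alphabet import MolType


class MSAError(ValueError):
    pass


@dataclass
class MSA:
    """Aligned rows over a query; first row is the query itself."""

    moltype: MolType
    rows: list[str]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.rows:
            raise MSAError("empty MSA")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise MSAError("aligned rows differ in length")
        if not self.labels:
            self.labels = [f"seq{i}" for i in range(len(self.rows))]
        if len(self.labels) != len(self.rows):
            raise MSAError("labels/rows length mismatch")

    @property
    def query(self) -> str:
        return self.rows[0]

    @property
    def depth(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0])


def read_a3m(path, moltype: MolType) -> MSA:
    """Read an A3M alignment; lowercase insertion states (columns absent
    from the query) are dropped so all rows share the query's length."""
    labels, rows = [], []
    label, parts = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                if label is not None:
                    rows.append("".join(parts))
                    labels.append(label)
                label = line[1:].split()[0] or f"seq{len(labels)}"
                parts = []
            else:
                parts.append("".join(ch for ch in line if not ch.islower()))
        if label is not None:
            rows.append("".join(parts))
            labels.append(label)
    if not rows:
        raise MSAError(f"no sequences in {path}")
    return MSA(moltype, rows, labels)


def read_stockholm(path, moltype: MolType) -> MSA:
    from Bio import AlignIO

    aln = AlignIO.read(str(path), "stockholm")
    rows = [str(rec.seq).upper().replace(".", "-") for rec in aln]
    labels = [rec.id for rec in aln]
    if not rows:
        raise MSAError(f"no sequences in {path}")
    return MSA(moltype, rows, labels)


def coverage(row: str, query: str) -> float:
    """Fraction of the query's non-gap columns covered by ``row``."""
    qcols = [i for i, q in enumerate(query) if q not in "-."]
    if not qcols:
        return 0.0
    return sum(row[i] not in "-." for i in qcols) / len(qcols)


def filter_msa(msa: MSA, min_coverage: float = 0.5) -> tuple[MSA, int]:
    """Retain rows with coverage strictly greater than ``min_coverage``.

    Returns the filtered MSA (query always kept) and the number of unique
    retained sequences, the depth statistic used when deciding whether an
    alignment is deep enough (the canonical stopping rule looks for more
    than 10,000 unique sequences with >50% coverage).
    """
    if msa.depth == 0:
        raise MSAError("empty MSA")
    keep_rows, keep_labels = [msa.rows[0]], [msa.labels[0]]
    for row, label in zip(msa.rows[1:], msa.labels[1:]):
        if coverage(row, msa.query) > min_coverage:
            keep_rows.append(row)
            keep_labels.append(label)
    unique = len({r.upper() for r in keep_rows
                  if coverage(r, msa.query) > min_coverage})
    return MSA(msa.moltype, keep_rows, keep_labels), unique
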