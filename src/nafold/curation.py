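"""Training-set curation operators for protein-nucleic-acid complexes.

Implements the dataset-construction rules used when harvesting complexes
for structure-prediction training:

* duplexes are chain pairs making at least 10 base-base hydrogen bonds;
* a protein and an NA unit interact when their Calpha-to-heavy-atom
  contact count at 7 A exceeds 16;
* base-specific contacts are protein-atom/nucleobase-atom pairs within
  3.4 A, and three of them make a DNA complex eligible for end padding
  (0-6 random base pairs per end, excluded from losses) and for negative
  generation (contacted bases mutated, Watson-Crick pairing maintained);
* spatial cropping runs a minimum-weight traversal over a graph whose
  sequential edges weigh 1 and whose Watson-Crick and protein-NA
  proximity edges weigh 0.

The hydrogen-bond rule used here is purely geometric (donor-acceptor
distance <= 3.5 A with a donor angle >= 120 deg over ideally placed
hydrogens), deliberately independent of the energy module's parameters.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .alphabet import INDEX, MolType
from .chem import WC_COMPLEMENT, base_atoms, donor_acceptor_atoms
from .energies import _hydrogen_names, add_polar_hydrogens
from .geometry import bond_angle
from .model import Assembly, Chain, Monomer

HBOND_DA_MAX = 3.5              # Angstrom, donor-acceptor heavy distance
HBOND_MIN_ANGLE = math.radians(120.0)
DUPLEX_MIN_HBONDS = 10
CONTACT_RADIUS = 7.0            # Angstrom, Calpha to NA heavy atom
MIN_CONTACTS = 16               # strictly more than this to interact
BASE_CONTACT_CUTOFF = 3.4       # Angstrom, base-specific contacts
MIN_BASE_CONTACTS = 3
CROP_PROXIMITY = 12.0           # Angstrom, Calpha to P for weight-0 edges
MAX_PAD = 6


@dataclass(frozen=True)
class BasePair:
    chain_a: str
    index_a: int
    chain_b: str
    index_b: int
    watson_crick: bool
    n_hbonds: int


@dataclass
class ComplexRecord:
    """One curated complex: the assembly plus its curation annotations."""

    assembly: Assembly
    interacting: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)
    duplexes: list[tuple[str, str]] = field(default_factory=list)
    base_contacts: list[dict] = field(default_factory=list)
    is_negative: bool = False

    @classmethod
    def from_assembly(cls, assembly: Assembly) -> "ComplexRecord":
        rec = cls(assembly=assembly)
        rec.duplexes = find_duplexes(assembly)
        rec.interacting = find_interacting_pairs(assembly)
        rec.base_contacts = base_specific_contacts(assembly)
        return rec


# ---------------------------------------------------------------------------
# Hydrogen bonds and base pairing
# ---------------------------------------------------------------------------

def _with_hydrogens(assembly: Assembly) -> Assembly:
    # idempotent: existing hydrogens are preserved, missing ones placed
    return add_polar_hydrogens(assembly)


def _base_hbond_count(mon_a: Monomer, mon_b: Monomer) -> int:
    """Distinct base-base hydrogen bonds between two nucleotides.

    Geometric rule: donor-acceptor heavy distance <= 3.5 A with a
    donor-angle (D-H...A) >= 120 deg over ideally placed hydrogens, and
    each hydrogen donating to at most one acceptor — the one it points at
    best — so a single amide proton cannot be counted twice.
    """
    count = 0
    for d_mon, a_mon in ((mon_a, mon_b), (mon_b, mon_a)):
        if not (d_mon.is_standard and a_mon.is_standard):
            continue
        d_bases = set(base_atoms(d_mon.name))
        a_bases = set(base_atoms(a_mon.name))
        donors, _ = donor_acceptor_atoms(d_mon.name)
        _, acceptors = donor_acceptor_atoms(a_mon.name)
        bonds = set()
        for dname in donors & d_bases:
            dx = d_mon.xyz(dname)
            if dx is None:
                continue
            for h in _hydrogen_names(d_mon.name, dname):
                hx = d_mon.xyz(h)
                if hx is None:
                    continue
                best = None
                for aname in acceptors & a_bases:
                    ax = a_mon.xyz(aname)
                    if ax is None or np.linalg.norm(ax - dx) > HBOND_DA_MAX:
                        continue
                    ang = bond_angle(dx, hx, ax)
                    if ang >= HBOND_MIN_ANGLE and (best is None or ang > best[0]):
                        best = (ang, aname)
                if best is not None:
                    bonds.add((dname, best[1]))
        count += len(bonds)
    return count


def _antiparallel(mon_a: Monomer, mon_b: Monomer) -> bool:
    """Locally antiparallel backbones: the chains run through the pair
    plane in opposite directions.  Projecting each strand's local 5'->3'
    vector onto the pair normal is robust to the strong backbone
    inclination of A-form helices."""
    va = _backbone_direction(mon_a)
    vb = _backbone_direction(mon_b)
    n = _base_normal(mon_a) if mon_a.is_standard else None
    if va is None or vb is None:
        return True                      # undecidable: do not veto
    if n is None:
        return float(va @ vb) < 0.0
    return float(va @ n) * float(vb @ n) < 0.0


def _base_normal(mon: Monomer):
    names = [n for n in base_atoms(mon.name) if mon.xyz(n) is not None]
    if len(names) < 3:
        return None
    pts = np.array([mon.xyz(n) for n in names])
    _, _, vt = np.linalg.svd(pts - pts.mean(axis=0))
    return vt[2]


def _backbone_direction(mon: Monomer):
    a, b = mon.xyz("P"), mon.xyz("O3'")
    if a is None or b is None:
        return None
    v = b - a
    n = np.linalg.norm(v)
    return None if n < 1e-6 else v / n


def detect_wc_pairs(assembly: Assembly) -> list[BasePair]:
    """Watson-Crick base pairs: complementary identities, >= 2 base-base
    hydrogen bonds, and locally antiparallel backbones."""
    ass = _with_hydrogens(assembly)
    nts = [(ch, i, mon) for ch in ass.chains if ch.moltype.is_nucleic
           for i, mon in enumerate(ch.monomers)]
    pts = []
    for ch, i, mon in nts:
        c1 = mon.xyz("C1'")
        pts.append(c1 if c1 is not None else np.full(3, 1e6))
    if not nts:
        return []
    tree = cKDTree(np.asarray(pts))
    pairs = []
    seen = set()
    for ia, ib in tree.query_pairs(11.0):
        ch_a, i_a, mon_a = nts[ia]
        ch_b, i_b, mon_b = nts[ib]
        if ch_a.id == ch_b.id and abs(i_a - i_b) <= 2:
            continue
        if WC_COMPLEMENT.get(mon_a.name) != mon_b.name:
            continue
        if not _antiparallel(mon_a, mon_b):
            continue
        n_hb = _base_hbond_count(mon_a, mon_b)
        if n_hb >= 2:
            key = tuple(sorted([(ch_a.id, i_a), (ch_b.id, i_b)]))
            if key not in seen:
                seen.add(key)
                pairs.append(BasePair(ch_a.id, i_a, ch_b.id, i_b, True, n_hb))
    return sorted(pairs, key=lambda p: (p.chain_a, p.index_a))


def count_interchain_hbonds(assembly: Assembly, chain_a: str, chain_b: str) -> int:
    """Base-base hydrogen bonds between two chains (geometric rule)."""
    ass = _with_hydrogens(assembly)
    ca, cb = ass.chain(chain_a), ass.chain(chain_b)
    pts_a = [m.xyz("C1'") for m in ca]
    pts_b = [m.xyz("C1'") for m in cb]
    total = 0
    for i, mon_a in enumerate(ca.monomers):
        if pts_a[i] is None:
            continue
        for j, mon_b in enumerate(cb.monomers):
            if pts_b[j] is None or np.linalg.norm(pts_a[i] - pts_b[j]) > 12.0:
                continue
            total += _base_hbond_count(mon_a, mon_b)
    return total


def find_duplexes(assembly: Assembly) -> list[tuple[str, str]]:
    """Chain pairs forming a nucleic acid duplex: at least 10 inter-chain
    base-base hydrogen bonds."""
    na_ids = [c.id for c in assembly.chains if c.moltype.is_nucleic]
    out = []
    for k, a in enumerate(na_ids):
        for b in na_ids[k + 1:]:
            if count_interchain_hbonds(assembly, a, b) >= DUPLEX_MIN_HBONDS:
                out.append(tuple(sorted((a, b)))) # symmetric in chain order
    return sorted(out)


# ---------------------------------------------------------------------------
# Interaction rules
# ---------------------------------------------------------------------------

def na_units(assembly: Assembly,
             duplexes: list[tuple[str, str]] | None = None
             ) -> list[tuple[str, ...]]:
    """NA units: detected duplexes count as one unit; remaining nucleic
    chains stand alone."""
    duplexes = find_duplexes(assembly) if duplexes is None else duplexes
    in_duplex = {c for pair in duplexes for c in pair}
    units: list[tuple[str, ...]] = [tuple(sorted(p)) for p in duplexes]
    for c in assembly.chains:
        if c.moltype.is_nucleic and c.id not in in_duplex:
            units.append((c.id,))
    return units


def count_ca_contacts(assembly: Assembly, protein_chain: str,
                      unit: tuple[str, ...],
                      radius: float = CONTACT_RADIUS) -> int:
    """Number of (Calpha, NA heavy atom) pairs within ``radius``."""
    prot = assembly.chain(protein_chain)
    cas = np.array([m.xyz("CA") for m in prot if m.xyz("CA") is not None])
    na_xyz = []
    for cid in unit:
        for m in assembly.chain(cid):
            na_xyz.extend(a.xyz for a in m.heavy_atoms)
    if len(cas) == 0 or not na_xyz:
        return 0
    tree = cKDTree(np.asarray(na_xyz))
    return int(sum(len(tree.query_ball_point(ca, radius)) for ca in cas))


def find_interacting_pairs(assembly: Assembly) -> list[tuple[str, tuple[str, ...]]]:
    """(protein chain, NA unit) pairs with strictly more than 16 contacts
    at 7 A between protein Calphas and any non-hydrogen NA atom."""
    out = []
    units = na_units(assembly)
    for c in assembly.chains:
        if c.moltype is not MolType.PROTEIN:
            continue
        for unit in units:
            if count_ca_contacts(assembly, c.id, unit) > MIN_CONTACTS:
                out.append((c.id, unit))
    return out


def base_specific_contacts(assembly: Assembly,
                           cutoff: float = BASE_CONTACT_CUTOFF) -> list[dict]:
    """Protein-atom / nucleobase-atom pairs within ``cutoff`` (heavy atoms;
    sugar and phosphate atoms do not count as base-specific)."""
    prot_atoms, base_atoms_list = [], []
    for ch in assembly.chains:
        for i, mon in enumerate(ch.monomers):
            if ch.moltype is MolType.PROTEIN:
                for a in mon.heavy_atoms:
                    prot_atoms.append((ch.id, i, a.name, a.xyz))
            elif mon.is_standard:
                bset = set(base_atoms(mon.name))
                for a in mon.heavy_atoms:
                    if a.name in bset:
                        base_atoms_list.append((ch.id, i, a.name, a.xyz))
    if not prot_atoms or not base_atoms_list:
        return []
    tree = cKDTree(np.array([x[3] for x in base_atoms_list]))
    out = []
    for pc, pi, pn, px in prot_atoms:
        for k in tree.query_ball_point(px, cutoff):
            bc, bi, bn, bx = base_atoms_list[k]
            out.append({"protein_chain": pc, "residue": pi, "protein_atom": pn,
                        "na_chain": bc, "nucleotide": bi, "base_atom": bn,
                        "distance": float(np.linalg.norm(px - bx))})
    return out


# ---------------------------------------------------------------------------
# Padding and negatives
# ---------------------------------------------------------------------------

def _eligible(record: ComplexRecord) -> bool:
    has_ds_dna = any(
        all(record.assembly.chain(c).moltype is MolType.DNA for c in pair)
        for pair in record.duplexes)
    contacted = {(c["na_chain"], c["nucleotide"]) for c in record.base_contacts}
    return has_ds_dna and len(record.base_contacts) >= MIN_BASE_CONTACTS \
        and len(contacted) >= 1


def draw_pad_lengths(rng: np.random.Generator) -> tuple[int, int]:
    """Independent uniform draws on {0..6} for the two duplex ends."""
    return int(rng.integers(0, MAX_PAD + 1)), int(rng.integers(0, MAX_PAD + 1))


def pad_dna_ends(record: ComplexRecord, rng: np.random.Generator) -> ComplexRecord:
    """Extend both ends of each DNA duplex by 0-6 ideal B-form base pairs
    with random complementary sequence; added positions are flagged
    loss_excluded (present in structures, absent from losses).

    Ineligible complexes (no double-stranded DNA or fewer than three
    base-specific contacts) are returned unchanged with a notice.
    """
    if not _eligible(record):
        warnings.warn("complex not eligible for padding; returning unchanged")
        return record
    from .fixtures import extend_duplex

    assembly = record.assembly.copy()
    for pair in record.duplexes:
        if not all(assembly.chain(c).moltype is MolType.DNA for c in pair):
            continue
        n_end5, n_end3 = draw_pad_lengths(rng)
        assembly = extend_duplex(assembly, pair, n_end5, n_end3, rng)
    out = ComplexRecord.from_assembly(assembly)
    out.is_negative = record.is_negative
    return out


def mutate_nucleotide(mon: Monomer, new_name: str) -> None:
    """Replace a nucleotide's base in place, keeping sugar/phosphate atoms.

    The new base is placed with the monomer's own frame and torsions, so an
    ideal-geometry nucleotide gets an ideal-geometry replacement base and a
    distorted one keeps its backbone exactly.
    """
    from .geometry import build_all_atom, phosphate_frame, torsions_from_coords
    from .model import Atom

    coords = {a.name: a.xyz for a in mon.atoms}
    frame, _ = phosphate_frame(mon)
    tors = torsions_from_coords(coords, mon.name)
    new_atoms = build_all_atom(frame, tors, new_name, include_virtual=False)
    new_base = set(base_atoms(new_name))
    keep = [a for a in mon.atoms
            if a.name not in set(base_atoms(mon.name)) and a.element != "H"]
    mon.atoms = keep + [a for a in new_atoms if a.name in new_base]
    mon.name = new_name
    mon.identity = INDEX["D" + new_name[-1]] if new_name.startswith("D") \
        else INDEX["R" + new_name]


def make_negative(record: ComplexRecord, rng: np.random.Generator) -> ComplexRecord:
    """Negative example: every base making a base-specific contact to the
    protein is mutated to a uniformly chosen different base, and its
    Watson-Crick partner is updated to the complement."""
    if not _eligible(record):
        raise ValueError("complex not eligible for negative generation "
                         "(needs dsDNA and >= 3 base-specific contacts)")
    assembly = record.assembly.copy()
    wc = {}
    for bp in detect_wc_pairs(assembly):
        wc[(bp.chain_a, bp.index_a)] = (bp.chain_b, bp.index_b)
        wc[(bp.chain_b, bp.index_b)] = (bp.chain_a, bp.index_a)
    targets = sorted({(c["na_chain"], c["nucleotide"])
                      for c in record.base_contacts})
    mutated: set[tuple[str, int]] = set()
    for cid, idx in targets:
        if (cid, idx) in mutated:
            continue
        mon = assembly.chain(cid).monomers[idx]
        if not mon.is_standard:
            continue
        others = [n for n in ("DA", "DC", "DG", "DT") if n != mon.name] \
            if mon.moltype is MolType.DNA else \
            [n for n in ("A", "C", "G", "U") if n != mon.name]
        new_name = others[int(rng.integers(0, len(others)))]
        mutate_nucleotide(mon, new_name)
        mutated.add((cid, idx))
        partner = wc.get((cid, idx))
        if partner is not None:
            pmon = assembly.chain(partner[0]).monomers[partner[1]]
            mutate_nucleotide(pmon, WC_COMPLEMENT[new_name])
            mutated.add(partner)
    out = ComplexRecord.from_assembly(assembly)
    out.is_negative = True
    return out


# ---------------------------------------------------------------------------
# Sequence clustering
# ---------------------------------------------------------------------------

def sequence_identity(a: str, b: str) -> float:
    """Global-alignment identity over the shorter sequence's length."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -0.5
    aligner.extend_gap_score = -0.1
    aln = aligner.align(a.upper(), b.upper())[0]
    matches = sum(
        1
        for (s1, e1), (s2, e2) in zip(*aln.aligned)
        for x, y in zip(a.upper()[s1:e1], b.upper()[s2:e2])
        if x == y
    )
    return matches / min(len(a), len(b))


def cluster_by_identity(sequences: list[str], threshold: float = 0.80) -> list[int]:
    """Greedy length-sorted clustering at a sequence-identity threshold
    (the redundancy-reduction rule: 80% identity for RNA).

    Each sequence joins the first existing cluster whose representative
    shares >= threshold identity over the shorter length; otherwise it
    founds a new cluster.  Transitivity is not guaranteed (greedy).
    Returns one cluster id per input sequence.
    """
    if not sequences:
        raise ValueError("no sequences to cluster")
    order = sorted(range(len(sequences)), key=lambda i: -len(sequences[i]))
    reps: list[tuple[int, str]] = []     # (cluster id, representative)
    assign = [-1] * len(sequences)
    for i in order:
        seq = sequences[i]
        for cid, rep in reps:
            if sequence_identity(seq, rep) >= threshold:
                assign[i] = cid
                break
        else:
            cid = len(reps)
            reps.append((cid, seq))
            assign[i] = cid
    return assign


# ---------------------------------------------------------------------------
# Crop graph
# ---------------------------------------------------------------------------

@dataclass
class CropGraph:
    """Weighted monomer graph for spatial cropping.

    Nodes are global monomer indices in assembly order; ``meta`` maps a
    node to (chain position, seq index) for the deterministic tie-break.
    """

    n_nodes: int
    edges: list[tuple[int, int, float]]
    meta: list[tuple[int, int]]
    seed_edge: tuple[int, int] | None = None
    seed_node: int | None = None

    def adjacency(self) -> dict[int, list[tuple[int, float]]]:
        adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(self.n_nodes)}
        for a, b, w in self.edges:
            adj[a].append((b, w))
            adj[b].append((a, w))
        return adj


def _global_index(assembly: Assembly) -> dict[tuple[str, int], int]:
    out = {}
    k = 0
    for ch in assembly.chains:
        for i, _ in enumerate(ch.monomers):
            out[(ch.id, i)] = k
            k += 1
    return out


def build_crop_graph(record: ComplexRecord, rng: np.random.Generator) -> CropGraph:
    """Crop graph: sequential edges weight 1; Watson-Crick and protein-NA
    proximity (Calpha-P < 12 A) edges weight 0.  For negatives a single
    random protein-NA edge gets weight 0 instead of the proximity rule.
    The seed is a random protein-NA weight-0 edge, or a random nucleotide
    node when no such edge exists (NA-only complexes)."""
    ass = record.assembly
    gidx = _global_index(ass)
    meta = []
    for ci, ch in enumerate(ass.chains):
        for i, m in enumerate(ch.monomers):
            meta.append((ci, i))
    edges: list[tuple[int, int, float]] = []
    for ch in ass.chains:
        for i in range(len(ch.monomers) - 1):
            edges.append((gidx[(ch.id, i)], gidx[(ch.id, i + 1)], 1.0))
    for bp in detect_wc_pairs(ass):
        edges.append((gidx[(bp.chain_a, bp.index_a)],
                      gidx[(bp.chain_b, bp.index_b)], 0.0))

    prot_nodes = [gidx[(ch.id, i)] for ch in ass.chains
                  if ch.moltype is MolType.PROTEIN
                  for i in range(len(ch.monomers))]
    na_nodes = [gidx[(ch.id, i)] for ch in ass.chains
                if ch.moltype.is_nucleic for i in range(len(ch.monomers))]
    cross: list[tuple[int, int]] = []
    if record.is_negative:
        if prot_nodes and na_nodes:
            a = prot_nodes[int(rng.integers(0, len(prot_nodes)))]
            b = na_nodes[int(rng.integers(0, len(na_nodes)))]
            edges.append((a, b, 0.0))
            cross.append((a, b))
    else:
        cas, ca_nodes = [], []
        for ch in ass.chains:
            if ch.moltype is MolType.PROTEIN:
                for i, m in enumerate(ch.monomers):
                    ca = m.xyz("CA")
                    if ca is not None:
                        cas.append(ca)
                        ca_nodes.append(gidx[(ch.id, i)])
        ps, p_nodes = [], []
        for ch in ass.chains:
            if ch.moltype.is_nucleic:
                for i, m in enumerate(ch.monomers):
                    p = m.xyz("P")
                    if p is None:        # 5' terminus: nearest phosphate-
                        p = m.xyz("O5'")  # group atom stands in, flagged
                    if p is not None:
                        ps.append(p)
                        p_nodes.append(gidx[(ch.id, i)])
        if cas and ps:
            tree = cKDTree(np.asarray(ps))
            for ca, anode in zip(cas, ca_nodes):
                for k in tree.query_ball_point(ca, CROP_PROXIMITY):
                    edges.append((anode, p_nodes[k], 0.0))
                    cross.append((anode, p_nodes[k]))

    graph = CropGraph(n_nodes=len(meta), edges=edges, meta=meta)
    if cross:
        graph.seed_edge = cross[int(rng.integers(0, len(cross)))]
    elif na_nodes:
        warnings.warn("no protein-NA edge; seeding from a random nucleotide")
        graph.seed_node = na_nodes[int(rng.integers(0, len(na_nodes)))]
    else:
        graph.seed_node = int(rng.integers(0, len(meta)))
    return graph


def crop(graph: CropGraph, size: int = 256,
         rng: np.random.Generator | None = None) -> list[int]:
    """Minimum-weight traversal crop: the ``size`` nodes with smallest
    shortest-path cost from the seed (Dijkstra), ties broken by chain
    order then sequence index.  Both seed-edge endpoints are included."""
    if graph.n_nodes <= size:
        return list(range(graph.n_nodes))
    sources = list(graph.seed_edge) if graph.seed_edge is not None \
        else [graph.seed_node]
    adj = graph.adjacency()
    dist = {s: 0.0 for s in sources}
    heap = [(0.0, s) for s in sources]
    heapq.heapify(heap)
    done = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        for v, w in adj[u]:
            nd = d + w
            if nd < dist.get(v, float("inf")):
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    order = sorted(dist, key=lambda n: (dist[n], graph.meta[n][0], graph.meta[n][1]))
    return sorted(order[:size])
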