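"""Physics terms used at fine-tuning: Lennard-Jones, hydrogen bonds, and
the flat-bottomed linkage-geometry penalty.

These are behaviour-contracted reimplementations in package-defined units:
tests pin the shape of each term (minimum location and depth, cutoffs,
monotonic angular falloff, flat-bottom edges), not an external energy
scale.  Parameters live in a reduced per-element table rather than a full
molecular-mechanics atom typing.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .alphabet import MolType
from .chem import component, donor_acceptor_atoms
from .geometry import (ANG_C3_O3_P, ANG_O3_P_O5, P_O3_BOND, bond_angle)
from .model import Assembly, Atom

logger = logging.getLogger(__name__)

# Peptide linkage ideals (standard backbone restraints, Angstrom / radians).
C_N_BOND = 1.329
ANG_CA_C_N = math.radians(116.2)
ANG_C_N_CA = math.radians(121.7)

LJ_CUTOFF = 6.0              # Angstrom, with switching to zero
LJ_SWITCH_START = 5.0
LJ_RAMP_FRACTION = 0.6       # linearized below this fraction of rmin
HB_EPSILON = 1.0             # well depth of an ideal hydrogen bond (package units)
HB_DIST_OPT = 1.9            # H...A optimum, Angstrom
HB_DIST_MAX = 3.0            # H...A beyond which the bond scores zero


@lru_cache(maxsize=1)
def lj_params() -> dict[str, dict[str, float]]:
    """Per-element LJ parameters (rmin/2 and well depth) from the frozen
    data table."""
    with resources.files("nafold.data").joinpath("lj_params.json").open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class AtomTypeParams:
    """LJ parameters of one atom type."""

    rmin_half: float
    epsilon: float
    donor: bool = False
    acceptor: bool = False

    def __post_init__(self):
        if not (0.9 <= self.rmin_half * 2 <= 5.0) or self.epsilon <= 0:
            raise ValueError("implausible LJ parameters")


@dataclass(frozen=True)
class LinkageIdeal:
    """Ideal inter-monomer linkage geometry with flat-bottom tolerances.

    ``angles`` entries are (((atom, side), ...), ideal_radians) with side
    "prev"/"next" naming the monomer each atom belongs to.
    """

    bond: float
    bond_atoms: tuple[str, str]          # (prev-side atom, next-side atom)
    angles: tuple
    tol_bond: float = 0.02               # Angstrom
    tol_angle: float = math.radians(3.0)


PHOSPHODIESTER = LinkageIdeal(
    bond=P_O3_BOND,
    bond_atoms=("O3'", "P"),
    angles=(
        ((("C3'", "prev"), ("O3'", "prev"), ("P", "next")), ANG_C3_O3_P),
        ((("O3'", "prev"), ("P", "next"), ("O5'", "next")), ANG_O3_P_O5),
    ),
)
PEPTIDE = LinkageIdeal(
    bond=C_N_BOND,
    bond_atoms=("C", "N"),
    angles=(
        ((("CA", "prev"), ("C", "prev"), ("N", "next")), ANG_CA_C_N),
        ((("C", "prev"), ("N", "next"), ("CA", "next")), ANG_C_N_CA),
    ),
)


def _kabsch(moving: np.ndarray, target: np.ndarray):
    """Rigid transform (R, t) minimizing |R m + t - target|."""
    mc, tc = moving.mean(0), target.mean(0)
    H = (moving - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, tc - R @ mc


def add_polar_hydrogens(assembly: Assembly) -> Assembly:
    """Deterministically place polar hydrogens at ideal template geometry.

    For each N/O donor lacking its template hydrogens, the template's local
    heavy-atom neighbourhood is superposed onto the monomer and the
    template hydrogen positions carried along.  Existing hydrogens are
    preserved; a second call adds nothing.  Donors whose reference atoms
    are missing are skipped and logged.
    """
    out = assembly.copy()
    for _, mon in out.monomers():
        if not mon.is_standard:
            continue
        tpl = component(mon.name)
        present = {a.name for a in mon.atoms}
        for heavy, h_xyz in tpl.h_coords.items():
            if tpl.elements[tpl.atom_names.index(heavy)] not in ("N", "O"):
                continue
            h_names = _hydrogen_names(mon.name, heavy)
            if all(h in present for h in h_names):
                continue
            refs = _reference_atoms(tpl, heavy)
            if any(r not in present for r in refs):
                logger.info("skipping donor %s/%s: reference atoms missing",
                            mon.name, heavy)
                continue
            tgt = np.array([mon.xyz(r) for r in refs])
            mov = np.array([tpl.xyz(r) for r in refs])
            R, t = _kabsch(mov, tgt)
            for h_name, hx in zip(h_names, h_xyz):
                if h_name in present:
                    continue
                mon.atoms.append(Atom(h_name, "H", R @ hx + t))
                present.add(h_name)
    return out


@lru_cache(maxsize=None)
def _hydrogen_names(residue: str, heavy: str) -> tuple[str, ...]:
    """Template hydrogen names attached to one heavy atom, in file order."""
    import biotite.structure.info as info

    arr = info.residue(residue)
    names = []
    name_of = list(arr.atom_name)
    for i, j, _ in arr.bonds.as_array():
        if arr.element[i] == "H" and name_of[j] == heavy:
            names.append(name_of[i])
        elif arr.element[j] == "H" and name_of[i] == heavy:
            names.append(name_of[j])
    tpl = component(residue)
    want = len(tpl.h_coords.get(heavy, ()))
    keep = [n for n in names if not (n in ("HOP3", "HXT", "HO3'", "HO5'")
                                     or (n == "H2" and heavy == "N"))]
    return tuple(keep[:want])


def _reference_atoms(tpl, heavy: str) -> list[str]:
    """Up to four heavy atoms anchoring a donor's local frame."""
    refs = [heavy]
    for nb in tpl.neighbors(heavy):
        if nb not in refs:
            refs.append(nb)
    for nb in list(refs[1:]):
        for nb2 in tpl.neighbors(nb):
            if nb2 not in refs:
                refs.append(nb2)
    return refs[:4]


# ---------------------------------------------------------------------------
# Lennard-Jones
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _bond_distances_to(residue: str, anchor: str) -> dict[str, int]:
    """Bond-graph distance from every heavy atom to ``anchor``."""
    import networkx as nx

    tpl = component(residue)
    G = nx.Graph(list(tpl.bonds))
    if anchor not in G:
        return {}
    return nx.single_source_shortest_path_length(G, anchor)


def _flat_atoms(assembly: Assembly, heavy_only: bool = True):
    """(xyz array, element list, monomer ids, names, link distances)."""
    xyz, elem, mon_id, names = [], [], [], []
    link_prev, link_next = [], []        # bond distance to linkage atoms
    mid = 0
    for chain in assembly.chains:
        is_prot = chain.moltype is MolType.PROTEIN
        head, tail = ("N", "C") if is_prot else ("P", "O3'")
        for mon in chain.monomers:
            d_head = _bond_distances_to(mon.name, head) if mon.is_standard else {}
            d_tail = _bond_distances_to(mon.name, tail) if mon.is_standard else {}
            for a in mon.atoms:
                if heavy_only and a.element == "H":
                    continue
                xyz.append(a.xyz)
                elem.append(a.element)
                names.append(a.name)
                mon_id.append(mid)
                link_prev.append(d_head.get(a.name, 99))
                link_next.append(d_tail.get(a.name, 99))
            mid += 1
    return (np.asarray(xyz, float).reshape(-1, 3), elem,
            np.asarray(mon_id), names, np.asarray(link_prev),
            np.asarray(link_next))


def _lj_pair_energy(r: np.ndarray, rmin: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """12-6 energy with short-range linear ramp and switched cutoff."""
    r = np.asarray(r, float)
    ramp_at = LJ_RAMP_FRACTION * rmin
    rr = np.maximum(r, 1e-6)
    x = (rmin / rr) ** 6
    e = eps * (x * x - 2.0 * x)
    # linearization below the ramp point (clash tolerance)
    x0 = (1.0 / LJ_RAMP_FRACTION) ** 6
    e0 = eps * (x0 * x0 - 2.0 * x0)
    slope = eps * (-12.0 * (x0 * x0 - x0) / ramp_at)
    e_lin = e0 + slope * (rr - ramp_at)
    e = np.where(rr < ramp_at, e_lin, e)
    # cubic switch to zero between LJ_SWITCH_START and LJ_CUTOFF
    s = np.clip((LJ_CUTOFF - rr) / (LJ_CUTOFF - LJ_SWITCH_START), 0.0, 1.0)
    sw = s * s * (3.0 - 2.0 * s)
    return np.where(rr >= LJ_CUTOFF, 0.0, e * np.where(rr > LJ_SWITCH_START, sw, 1.0))


def lj_pair(r: float, elem_a: str, elem_b: str) -> float:
    """Energy of one atom pair at separation r (package units)."""
    p = lj_params()
    pa, pb = p.get(elem_a, p["C"]), p.get(elem_b, p["C"])
    rmin = pa["rmin_half"] + pb["rmin_half"]
    eps = math.sqrt(pa["epsilon"] * pb["epsilon"])
    return float(_lj_pair_energy(np.array([r]), np.array([rmin]),
                                 np.array([eps]))[0])


def _excluded(mon_i, mon_j, link_next_i, link_prev_j) -> np.ndarray:
    same = mon_i == mon_j
    adjacent = np.abs(mon_i - mon_j) == 1
    lo = np.where(mon_i < mon_j, link_next_i, link_prev_j)
    hi = np.where(mon_i < mon_j, link_prev_j, link_next_i)
    near_link = adjacent & (lo + 1 + hi <= 3)
    return same | near_link


def lj_energy(assembly: Assembly) -> float:
    """Total pairwise Lennard-Jones energy divided by the atom count.

    Pairs within the same monomer or within three bonds across a linkage
    are excluded (their geometry is covered by the kinematic build and the
    linkage term, not nonbonded physics).
    """
    if assembly.n_atoms == 0:
        raise ValueError("empty assembly")
    xyz, elem, mon_id, _names, link_prev, link_next = _flat_atoms(assembly)
    if len(xyz) < 2:
        return 0.0
    p = lj_params()
    rmin_half = np.array([p.get(e, p["C"])["rmin_half"] for e in elem])
    eps_i = np.array([p.get(e, p["C"])["epsilon"] for e in elem])
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(LJ_CUTOFF, output_type="ndarray")
    if len(pairs) == 0:
        return 0.0
    i, j = pairs[:, 0], pairs[:, 1]
    mask = ~_excluded(mon_id[i], mon_id[j], link_next[i], link_prev[j])
    i, j = i[mask], j[mask]
    r = np.linalg.norm(xyz[i] - xyz[j], axis=1)
    e = _lj_pair_energy(r, rmin_half[i] + rmin_half[j],
                        np.sqrt(eps_i[i] * eps_i[j]))
    return float(e.sum() / len(xyz))


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def _distance_factor(d_ha: np.ndarray) -> np.ndarray:
    """Polynomial falloff in [0, 1], peaked at the optimal H...A distance."""
    x = (d_ha - HB_DIST_OPT) / (HB_DIST_MAX - HB_DIST_OPT)
    return np.clip(1.0 - x * x, 0.0, 1.0)


def _angle_factor(cos_theta: np.ndarray) -> np.ndarray:
    """Quadratic in [0, 1]: 1 at linear D-H...A, 0 at 90 degrees or less."""
    c = np.clip(-cos_theta, 0.0, None)   # -cos(theta): 1 at 180 deg
    return c * c


def hbond_pairs(assembly: Assembly):
    """Enumerate (donor heavy, hydrogen, acceptor) geometry candidates.

    Returns dicts with monomer ids, atom names and the geometric
    quantities.  Donor and acceptor within the same monomer are excluded.
    """
    ass = assembly
    donors = []      # (mon id, D xyz, H xyz)
    acceptors = []   # (mon id, A xyz, base-of-acceptor xyz)
    mid = 0
    mons = []
    for chain in ass.chains:
        for mon in chain.monomers:
            mons.append(mon)
            if mon.is_standard:
                dset, aset = donor_acceptor_atoms(mon.name)
                tpl = component(mon.name)
                present = {a.name: a.xyz for a in mon.atoms}
                for d in dset:
                    if d not in present:
                        continue
                    for h in _hydrogen_names(mon.name, d):
                        if h in present:
                            donors.append((mid, d, h, present[d], present[h]))
                for acc in aset:
                    if acc not in present:
                        continue
                    bases = [present[n] for n in tpl.neighbors(acc)
                             if n in present]
                    if bases:
                        acceptors.append((mid, acc, present[acc],
                                          np.mean(bases, axis=0)))
            mid += 1
    out = []
    for dm, dname, hname, dx, hx in donors:
        for am, aname, ax, abase in acceptors:
            if am == dm:
                continue
            d_da = float(np.linalg.norm(ax - dx))
            if d_da > 4.0:
                continue
            d_ha = float(np.linalg.norm(ax - hx))
            cos_dha = float((dx - hx) @ (ax - hx)
                            / (np.linalg.norm(dx - hx) * max(d_ha, 1e-9)))
            theta_base = bond_angle(abase, ax, hx)
            out.append({"donor_mon": dm, "acceptor_mon": am,
                        "donor": dname, "hydrogen": hname, "acceptor": aname,
                        "d_ha": d_ha, "d_da": d_da, "cos_dha": cos_dha,
                        "theta_base": theta_base})
    return out


def hbond_energy(assembly: Assembly) -> float:
    """Hydrogen-bond energy (negative is favourable) per atom.

    E = -eps * F_dist(H...A) * F_ang(D-H...A) * F_ang(base-A...H), the
    product of a polynomial distance falloff and two angular factors in
    [0, 1].  Requires polar hydrogens (see add_polar_hydrogens).
    """
    if assembly.n_atoms == 0:
        raise ValueError("empty assembly")
    cands = hbond_pairs(assembly)
    if not cands:
        warnings.warn("no donor/acceptor pairs; hydrogen-bond energy is 0")
        return 0.0
    total = 0.0
    for c in cands:
        fd = float(_distance_factor(np.array(c["d_ha"])))
        fa = float(_angle_factor(np.array(c["cos_dha"])))
        fb = _base_angle_factor(c["theta_base"])
        total += -HB_EPSILON * fd * fa * fb
    return total / assembly.n_atoms


def _base_angle_factor(theta_base: float) -> float:
    """Quadratic ramp in [0, 1] on the (acceptor-substituent, A, H) angle:
    zero when the hydrogen approaches along the acceptor's bonds (90 deg or
    less), saturating at 130 deg — an open lone-pair approach."""
    c = math.cos(theta_base)
    x = (0.0 - c) / (0.0 - math.cos(math.radians(130.0)))
    return min(max(x, 0.0), 1.0) ** 2


# ---------------------------------------------------------------------------
# Linkage geometry
# ---------------------------------------------------------------------------

def linkage_geom_penalty(assembly: Assembly,
                         na_ideal: LinkageIdeal = PHOSPHODIESTER,
                         peptide_ideal: LinkageIdeal = PEPTIDE) -> float:
    """Flat-bottomed linear penalty on inter-monomer linkage geometry.

    Inside the tolerance window (0.02 A on the linkage bond, 3 deg on its
    flanking angles) the penalty is exactly zero; outside it grows with
    unit slope per Angstrom of bond excess and per degree of angle excess.
    Linkages stretched beyond twice the ideal bond length are treated as
    chain breaks: skipped and logged.
    """
    total = 0.0
    for chain in assembly.chains:
        ideal = peptide_ideal if chain.moltype is MolType.PROTEIN else na_ideal
        a_name, b_name = ideal.bond_atoms
        for prev, nxt in zip(chain.monomers, chain.monomers[1:]):
            pa, pb = prev.xyz(a_name), nxt.xyz(b_name)
            if pa is None or pb is None:
                continue
            blen = float(np.linalg.norm(pb - pa))
            if blen > 2.0 * ideal.bond:
                logger.info("chain %s: break between %d and %d (%.2f A)",
                            chain.id, prev.seq_index, nxt.seq_index, blen)
                continue
            excess = abs(blen - ideal.bond) - ideal.tol_bond
            if excess > 0:
                total += excess           # unit slope per Angstrom
            for triple, ang_ideal in ideal.angles:
                pts = [(prev if side == "prev" else nxt).xyz(nm)
                       for nm, side in triple]
                if any(p is None for p in pts):
                    continue
                ang = bond_angle(*pts)
                a_excess = abs(ang - ang_ideal) - ideal.tol_angle
                if a_excess > 0:
                    total += math.degrees(a_excess)  # unit slope per degree
    return total
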