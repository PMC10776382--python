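"""Nucleotide rigid frames and the 10-torsion all-atom parameterization.

Each nucleotide is represented by a rigid frame anchored on the phosphate
group (P at the origin, orientation from OP1/P/OP2) plus ten torsion angles:
six backbone (alpha..zeta), three ribose-ring (nu0..nu2) and the glycosidic
chi.  All-atom coordinates are produced by kinematically folding outward
from the phosphate along the bonded tree (NeRF-style internal-coordinate
construction), and recovered torsions/frames round-trip exactly.

Conventions
-----------
* Dihedral sign: IUPAC right-handed, eclipsed (cis) = 0, range (-pi, pi].
* Frame from three atoms (a, b, c): translation b; x-axis along c - b;
  y-axis the component of a - b orthogonal to x; z = x cross y.
  For nucleotides (a, b, c) = (OP1, P, OP2); for amino acids (N, CA, C).
* Inter-residue torsions: alpha(i) uses O3'(i-1); epsilon/zeta(i) place the
  next residue's phosphate.  An isolated build emits virtual neighbour
  atoms ("O3'-", "P+", "O5'+", "OP1+", "OP2+") at ideal phosphodiester
  geometry so that all ten torsions are measurable on a single nucleotide.
* The five-membered ribose ring has two torsional degrees of freedom once
  bond lengths/angles are fixed, but the parameterization exposes three
  ring torsions.  The ring is entered through O4' and C1', whose two
  orientation dihedrals are solved numerically so the measured nu1 and nu2
  equal the request; C2' is then placed directly by nu0.  The C2'-C3'
  ring-closure deviation absorbs any inconsistency among the three and is
  never hidden: see :func:`ring_closure_deviation`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from functools import lru_cache

import numpy as np
from scipy import optimize

from .alphabet import MolType, TOKENS
from .chem import (GLYCOSIDIC_N, NA_BACKBONE, PURINES, STANDARD_DNA,
                   STANDARD_RNA, base_atoms, component)
from .model import Atom, Chain, Monomer

TORSION_NAMES = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta",
                 "nu0", "nu1", "nu2", "chi")

# Phosphate / phosphodiester ideals (standard crystallographic restraint
# values).  The phosphate group is chemically identical across nucleotides,
# so one canonical geometry is shared; the component-dictionary templates
# carry free-acid phosphates with inconsistent protonation and are not used
# for this group.  The remaining bonded geometry does come from the
# component dictionary.
P_O3_BOND = 1.607          # Angstrom
P_O5_BOND = 1.593
P_OP_BOND = 1.485
ANG_C3_O3_P = math.radians(119.7)
ANG_O3_P_O5 = math.radians(104.0)
ANG_OP_P_OP = math.radians(119.6)
ANG_O5_P_OP = math.radians(108.1)

_EPS = 1e-10


def wrap_angle(x):
    """Wrap angle(s) to (-pi, pi]."""
    x = np.asarray(x, dtype=float)
    out = -((-x + np.pi) % (2.0 * np.pi) - np.pi)
    return out if out.ndim else float(out)


def _normalize(v):
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / n


def dihedral(a, b, c, d) -> float:
    """Signed dihedral angle a-b-c-d in (-pi, pi] (IUPAC convention).
    Broadcasts over leading dimensions."""
    b1 = np.asarray(b, float) - np.asarray(a, float)
    b2 = np.asarray(c, float) - np.asarray(b, float)
    b3 = np.asarray(d, float) - np.asarray(c, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2u = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    m1 = np.cross(n1, b2u)
    x = (n1 * n2).sum(axis=-1)
    y = (m1 * n2).sum(axis=-1)
    ang = np.arctan2(-y, x)
    return float(ang) if np.ndim(ang) == 0 else ang


def bond_angle(a, b, c) -> float:
    """Angle a-b-c in radians."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    cosang = (u * v).sum(axis=-1) / (
        np.linalg.norm(u, axis=-1) * np.linalg.norm(v, axis=-1))
    ang = np.arccos(np.clip(cosang, -1.0, 1.0))
    return float(ang) if np.ndim(ang) == 0 else ang


def nerf_place(p, g, gg, bond: float, angle: float, dih):
    """Place atom(s) x with |x-p| = bond, angle(x, p, g) = angle and
    dihedral(gg, g, p, x) = dih.  Broadcasts over leading dimensions of
    ``p``/``g``/``gg`` (rows of points) and/or ``dih`` (array of angles)."""
    p = np.asarray(p, float)
    g = np.asarray(g, float)
    gg = np.asarray(gg, float)
    dih = np.asarray(dih, float)
    u = g - p
    nu = np.linalg.norm(u, axis=-1, keepdims=True)
    if np.any(nu < _EPS):
        raise DegenerateGeometryError("coincident reference atoms")
    u = u / nu
    w = gg - g
    w_perp = w - (w * u).sum(axis=-1, keepdims=True) * u
    nw = np.linalg.norm(w_perp, axis=-1, keepdims=True)
    if np.any(nw < _EPS):
        raise DegenerateGeometryError("gg collinear with g-p")
    w1 = w_perp / nw                            # cis (dih = 0) direction
    w2 = np.cross(w1, u)
    cd = np.cos(dih)[..., None] if dih.ndim else math.cos(float(dih))
    sd = np.sin(dih)[..., None] if dih.ndim else math.sin(float(dih))
    d = math.cos(angle) * u + math.sin(angle) * (cd * w1 + sd * w2)
    return p + bond * d


def _sdihedral(a, b, c, d):
    """Scalar dihedral on 3-tuples; fast path for iterative solvers."""
    b1 = (b[0] - a[0], b[1] - a[1], b[2] - a[2])
    b2 = (c[0] - b[0], c[1] - b[1], c[2] - b[2])
    b3 = (d[0] - c[0], d[1] - c[1], d[2] - c[2])
    n1 = (b1[1] * b2[2] - b1[2] * b2[1], b1[2] * b2[0] - b1[0] * b2[2],
          b1[0] * b2[1] - b1[1] * b2[0])
    n2 = (b2[1] * b3[2] - b2[2] * b3[1], b2[2] * b3[0] - b2[0] * b3[2],
          b2[0] * b3[1] - b2[1] * b3[0])
    nb2 = math.sqrt(b2[0] ** 2 + b2[1] ** 2 + b2[2] ** 2)
    m1 = (n1[1] * b2[2] - n1[2] * b2[1], n1[2] * b2[0] - n1[0] * b2[2],
          n1[0] * b2[1] - n1[1] * b2[0])
    x = n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]
    y = (m1[0] * n2[0] + m1[1] * n2[1] + m1[2] * n2[2]) / nb2
    return math.atan2(-y, x)


def _snerf(p, g, gg, bond, angle, dih):
    """Scalar NeRF placement on 3-tuples; fast path for iterative solvers."""
    ux, uy, uz = g[0] - p[0], g[1] - p[1], g[2] - p[2]
    nu = math.sqrt(ux * ux + uy * uy + uz * uz)
    ux, uy, uz = ux / nu, uy / nu, uz / nu
    wx, wy, wz = gg[0] - g[0], gg[1] - g[1], gg[2] - g[2]
    dot = wx * ux + wy * uy + wz * uz
    wx, wy, wz = wx - dot * ux, wy - dot * uy, wz - dot * uz
    nw = math.sqrt(wx * wx + wy * wy + wz * wz)
    wx, wy, wz = wx / nw, wy / nw, wz / nw
    vx = wy * uz - wz * uy
    vy = wz * ux - wx * uz
    vz = wx * uy - wy * ux
    ca, sa = math.cos(angle), math.sin(angle)
    cd, sd = math.cos(dih), math.sin(dih)
    dx = ca * ux + sa * (cd * wx + sd * vx)
    dy = ca * uy + sa * (cd * wy + sd * vy)
    dz = ca * uz + sa * (cd * wz + sd * vz)
    return (p[0] + bond * dx, p[1] + bond * dy, p[2] + bond * dz)


class DegenerateGeometryError(ValueError):
    pass


class BuildError(ValueError):
    pass


@dataclass(frozen=True)
class RigidFrame:
    """Rotation (3x3, right-handed orthonormal) + translation (Angstrom)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, float)
        t = np.asarray(self.translation, float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-6 or np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper orthonormal")

    @classmethod
    def identity(cls) -> "RigidFrame":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_three_atoms(cls, a, b, c) -> "RigidFrame":
        """Gram-Schmidt frame: origin b, x along c-b, y from a-b."""
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        c = np.asarray(c, float)
        x = c - b
        nx = np.linalg.norm(x)
        if nx < 1e-6:
            raise DegenerateGeometryError("b and c coincide")
        x = x / nx
        y = (a - b) - ((a - b) @ x) * x
        ny = np.linalg.norm(y)
        if ny < 1e-6:
            raise DegenerateGeometryError("a, b, c are collinear")
        y = y / ny
        z = np.cross(x, y)
        return cls(np.stack([x, y, z], axis=1), b)

    def apply(self, points):
        """Map local coordinates into the global frame: R x + t."""
        pts = np.asarray(points, float)
        return pts @ self.rotation.T + self.translation

    def apply_inverse(self, points):
        pts = np.asarray(points, float)
        return (pts - self.translation) @ self.rotation

    def compose(self, other: "RigidFrame") -> "RigidFrame":
        """self o other (apply ``other`` first)."""
        return RigidFrame(self.rotation @ other.rotation,
                          self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidFrame":
        return RigidFrame(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass(frozen=True)
class TorsionSet:
    """The ten nucleotide torsions, radians in (-pi, pi]; None = absent."""

    alpha: float | None = None
    beta: float | None = None
    gamma: float | None = None
    delta: float | None = None
    epsilon: float | None = None
    zeta: float | None = None
    nu0: float | None = None
    nu1: float | None = None
    nu2: float | None = None
    chi: float | None = None

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if v is not None:
                object.__setattr__(self, f.name, float(wrap_angle(v)))

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in TORSION_NAMES}

    def get(self, name: str) -> float | None:
        return getattr(self, name)

    def replace(self, **kw) -> "TorsionSet":
        return replace(self, **kw)

    @property
    def present(self) -> tuple[str, ...]:
        return tuple(n for n in TORSION_NAMES if getattr(self, n) is not None)


def pucker_to_nu(phase: float, amplitude: float) -> tuple[float, float, float]:
    """(nu0, nu1, nu2) from pseudorotation phase/amplitude (radians)."""
    step = math.radians(144.0)
    return (amplitude * math.cos(phase + 2 * step),
            amplitude * math.cos(phase - step),
            amplitude * math.cos(phase))


def pseudorotation_phase(nu0: float, nu1: float, nu2: float) -> tuple[float, float]:
    """(phase, amplitude) recovered from nu0..nu2 by least squares on
    nu_j = tau_m cos(phase + delta_j)."""
    step = math.radians(144.0)
    deltas = np.array([2 * step, -step, 0.0])
    A = np.stack([np.cos(deltas), -np.sin(deltas)], axis=1)
    sol, *_ = np.linalg.lstsq(A, np.array([nu0, nu1, nu2]), rcond=None)
    c, s = sol
    return math.atan2(s, c), math.hypot(c, s)


# ---------------------------------------------------------------------------
# Kinematic trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    """One NeRF placement: dihedral = offset (+ torsion value if named).
    ``ring_station`` marks the two ring-entry atoms whose dihedrals are
    solved jointly so that nu1/nu2 are realized exactly."""

    name: str
    p: str
    g: str
    gg: str
    bond: float
    angle: float
    offset: float
    torsion: str | None = None
    virtual: bool = False
    ring_station: str | None = None     # "O4" or "C1"


@dataclass(frozen=True)
class KinematicTree:
    """Rooted placement tree over one nucleotide's heavy atoms."""

    residue: str
    records: tuple[AtomRecord, ...]

    @property
    def torsion_atoms(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {t: [] for t in TORSION_NAMES}
        for r in self.records:
            if r.torsion is not None:
                out[r.torsion].append(r.name)
            elif r.ring_station == "O4":
                out["nu1"].append(r.name)
            elif r.ring_station == "C1":
                out["nu2"].append(r.name)
        return out


class IdealGeometryTable:
    """Bonded geometry (lengths/angles) per monomer type, measured from the
    idealized chemical-component templates plus the phosphodiester-linkage
    constants above."""

    def __init__(self):
        self._cache: dict[str, dict] = {}

    def _tpl(self, residue: str):
        return component(residue)

    def bond_length(self, residue: str, a: str, b: str) -> float:
        tpl = self._tpl(residue)
        return float(np.linalg.norm(tpl.xyz(a) - tpl.xyz(b)))

    def bond_angle(self, residue: str, a: str, b: str, c: str) -> float:
        tpl = self._tpl(residue)
        return bond_angle(tpl.xyz(a), tpl.xyz(b), tpl.xyz(c))

    def template_dihedral(self, residue: str, a: str, b: str, c: str, d: str) -> float:
        tpl = self._tpl(residue)
        return dihedral(tpl.xyz(a), tpl.xyz(b), tpl.xyz(c), tpl.xyz(d))


IDEAL_GEOMETRY = IdealGeometryTable()


def _axial_angle(axis_from, axis_to, d_ref, d_new) -> float:
    """Signed angle from d_ref to d_new about the axis_from -> axis_to
    axis, in the same sign convention as differences of :func:`dihedral`
    values sharing that central bond."""
    u = _normalize(np.asarray(axis_to, float) - np.asarray(axis_from, float))
    a = np.asarray(d_ref, float) - np.asarray(axis_to, float)
    b = np.asarray(d_new, float) - np.asarray(axis_to, float)
    a = a - (a @ u) * u
    b = b - (b @ u) * u
    return math.atan2(np.cross(a, b) @ u, a @ b)


@lru_cache(maxsize=1)
def _canonical_phosphate() -> dict[str, np.ndarray]:
    """The one idealized phosphate group, in frame coordinates, with the
    virtual previous-residue O3' ("O3'-") placed at ideal linkage geometry.

    O5' sits symmetrically with respect to the two nonbridging oxygens;
    the mirror ambiguities (which side of the OP1/P/OP2 plane O5' and the
    bridging O3' occupy) are resolved against the component-dictionary
    template, whose OP3 marks the chemically correct bridging position of
    the previous residue's O3'.
    """
    import biotite.structure.info as info

    raw = info.residue("DA")
    traw = {n: np.asarray(raw.coord[list(raw.atom_name).index(n)], float)
            for n in ("P", "OP1", "OP2", "OP3", "O5'")}
    sign_o5 = math.copysign(1.0, dihedral(traw["OP1"], traw["OP2"],
                                          traw["P"], traw["O5'"]))
    d3_tpl = dihedral(traw["OP2"], traw["O5'"], traw["P"], traw["OP3"])

    P = np.zeros(3)
    OP2 = np.array([P_OP_BOND, 0.0, 0.0])
    OP1 = P_OP_BOND * np.array([math.cos(ANG_OP_P_OP), math.sin(ANG_OP_P_OP), 0.0])
    # O5' equidistant in angle from OP1 and OP2, on the template's side
    grid = sign_o5 * np.linspace(0.0, math.pi, 3601)
    cand = nerf_place(P, OP2, OP1, P_O5_BOND, ANG_O5_P_OP, grid)
    a1 = bond_angle(cand, P[None, :], OP1[None, :])
    O5 = cand[int(np.argmin(np.abs(a1 - ANG_O5_P_OP)))]
    # bridging O3'- at ideal linkage geometry on the template's OP3 side
    O3m = nerf_place(P, O5, OP2, P_O3_BOND, ANG_O3_P_O5, d3_tpl)
    dih_o5 = dihedral(OP1, OP2, P, O5)
    ang_o5 = bond_angle(O5, P, OP2)
    return {"P": P, "OP1": OP1, "OP2": OP2, "O5'": O5, "O3'-": O3m,
            "_consts": np.array([P_OP_BOND, P_OP_BOND, ANG_OP_P_OP,
                                 P_O5_BOND, ang_o5, dih_o5])}


@lru_cache(maxsize=None)
def kinematic_tree(residue: str) -> KinematicTree:
    """Kinematic tree for a standard nucleotide, derived from the component
    dictionary template plus phosphodiester-linkage ideals."""
    residue = residue.strip().upper()
    if residue not in STANDARD_DNA | STANDARD_RNA:
        raise BuildError(f"no kinematic tree for {residue!r}")
    tpl = component(residue)
    ph = _canonical_phosphate()
    T = IDEAL_GEOMETRY
    # Sugar/backbone geometry is shared within a polymer family (one ideal
    # deoxyribose, one ideal ribose) so that chain propagation is exactly
    # residue-independent; base geometry is residue-specific.
    sugar_ref = "DA" if residue in STANDARD_DNA else "A"

    def tb(a, b, own=False):
        return T.bond_length(residue if own else sugar_ref, a, b)

    def ta(a, b, c, own=False):
        return T.bond_angle(residue if own else sugar_ref, a, b, c)

    def td(a, b, c, d, own=False):
        return T.template_dihedral(residue if own else sugar_ref, a, b, c, d)

    recs: list[AtomRecord] = []
    b_op1, b_op2, ang_11, b_o5, ang_o5, dih_o5 = ph["_consts"]

    # Phosphate handled directly from the frame (see build_all_atom); the
    # records start with O5' and the virtual previous O3'.
    recs.append(AtomRecord("O5'", "P", "OP2", "OP1", float(b_o5), float(ang_o5),
                           float(dih_o5)))
    d_o3m = dihedral(ph["OP2"], ph["O5'"], ph["P"], ph["O3'-"])
    recs.append(AtomRecord("O3'-", "P", "O5'", "OP2", P_O3_BOND, ANG_O3_P_O5,
                           float(d_o3m), virtual=True))
    recs.append(AtomRecord("C5'", "O5'", "P", "O3'-", tb("C5'", "O5'"),
                           ta("C5'", "O5'", "P"), 0.0, torsion="alpha"))
    recs.append(AtomRecord("C4'", "C5'", "O5'", "P", tb("C4'", "C5'"),
                           ta("C4'", "C5'", "O5'"), 0.0, torsion="beta"))
    recs.append(AtomRecord("C3'", "C4'", "C5'", "O5'", tb("C3'", "C4'"),
                           ta("C3'", "C4'", "C5'"), 0.0, torsion="gamma"))
    recs.append(AtomRecord("O3'", "C3'", "C4'", "C5'", tb("O3'", "C3'"),
                           ta("O3'", "C3'", "C4'"), 0.0, torsion="delta"))
    # Ring entry: the O4' and C1' orientation dihedrals are solved at build
    # time (offsets store the template values as the starting guess) so the
    # measured nu1/nu2 equal the request; C2' is then placed directly by
    # nu0 and the C2'-C3' closure bond absorbs any residual inconsistency.
    recs.append(AtomRecord("O4'", "C4'", "C5'", "O5'", tb("O4'", "C4'"),
                           ta("O4'", "C4'", "C5'"),
                           td("O5'", "C5'", "C4'", "O4'"), ring_station="O4"))
    recs.append(AtomRecord("C1'", "O4'", "C4'", "C5'", tb("C1'", "O4'"),
                           ta("C1'", "O4'", "C4'"),
                           td("C5'", "C4'", "O4'", "C1'"), ring_station="C1"))
    recs.append(AtomRecord("C2'", "C1'", "O4'", "C4'", tb("C2'", "C1'"),
                           ta("C2'", "C1'", "O4'"), 0.0, torsion="nu0"))
    if residue in STANDARD_RNA:
        recs.append(AtomRecord("O2'", "C2'", "C1'", "O4'", tb("O2'", "C2'"),
                               ta("O2'", "C2'", "C1'"),
                               td("O4'", "C1'", "C2'", "O2'")))
    root = GLYCOSIDIC_N[residue]
    recs.append(AtomRecord(root, "C1'", "C2'", "C3'", tb(root, "C1'", own=True),
                           ta(root, "C1'", "C2'", own=True),
                           td("C3'", "C2'", "C1'", root, own=True)))
    chi_atom = "C4" if residue in PURINES else "C2"
    other_atom = "C8" if residue in PURINES else "C6"
    recs.append(AtomRecord(chi_atom, root, "C1'", "O4'",
                           tb(chi_atom, root, own=True),
                           ta(chi_atom, root, "C1'", own=True), 0.0,
                           torsion="chi"))
    chi_t = td("O4'", "C1'", root, chi_atom, own=True)
    recs.append(AtomRecord(other_atom, root, "C1'", "O4'",
                           tb(other_atom, root, own=True),
                           ta(other_atom, root, "C1'", own=True),
                           float(wrap_angle(td("O4'", "C1'", root, other_atom,
                                               own=True) - chi_t)),
                           torsion="chi"))
    # Remaining base atoms: breadth-first over the base bond graph; all
    # internal coordinates are template values, so the base is rigid.
    batoms = set(base_atoms(residue))
    pred: dict[str, str] = {root: "C1'", "C1'": "C2'", chi_atom: root,
                            other_atom: root}
    placed = {root, chi_atom, other_atom}
    queue = [chi_atom, other_atom]
    while queue:
        p = queue.pop(0)
        for x in component(residue).neighbors(p):
            if x not in batoms or x in placed:
                continue
            g = pred[p]
            gg = pred[g]
            recs.append(AtomRecord(x, p, g, gg, tb(x, p, own=True),
                                   ta(x, p, g, own=True),
                                   td(gg, g, p, x, own=True)))
            pred[x] = p
            placed.add(x)
            queue.append(x)
    missing = batoms - placed
    if missing:
        raise BuildError(f"{residue}: unplaced base atoms {missing}")

    # Next-residue phosphate (virtual): epsilon/zeta plus rigid offsets for
    # the nonbridging oxygens, mirrored from the canonical phosphate.
    recs.append(AtomRecord("P+", "O3'", "C3'", "C4'", P_O3_BOND, ANG_C3_O3_P,
                           0.0, torsion="epsilon", virtual=True))
    recs.append(AtomRecord("O5'+", "P+", "O3'", "C3'", float(b_o5), ANG_O3_P_O5,
                           0.0, torsion="zeta", virtual=True))
    for opname, bl in (("OP1+", float(b_op1)), ("OP2+", float(b_op2))):
        src = opname[:-1]
        ang = bond_angle(ph[src], ph["P"], ph["O3'-"])
        off = _axial_angle(ph["O3'-"], ph["P"], ph["O5'"], ph[src])
        recs.append(AtomRecord(opname, "P+", "O3'", "C3'", bl, ang, off,
                               torsion="zeta", virtual=True))
    tree = KinematicTree(residue, tuple(recs))
    for t in TORSION_NAMES:
        if not tree.torsion_atoms[t]:
            raise BuildError(f"{residue}: torsion {t} controls no atom")
    return tree


# ---------------------------------------------------------------------------
# Build: (frame, torsions) -> atoms
# ---------------------------------------------------------------------------

_DEFAULT_TORSIONS = TorsionSet(
    alpha=math.radians(-60), beta=math.radians(180), gamma=math.radians(60),
    delta=math.radians(130), epsilon=math.radians(180),
    zeta=math.radians(-90), chi=math.radians(-110),
    **dict(zip(("nu0", "nu1", "nu2"),
               pucker_to_nu(math.radians(162), math.radians(36)))))

_RING_CACHE: dict[tuple, tuple[float, float, float, float, float]] = {}


def _ring_key(residue, nu0, nu1, nu2, gamma):
    return (residue, round(nu0, 10), round(nu1, 10), round(nu2, 10),
            round(gamma, 10))


def _solve_ring(residue: str, nu0: float, nu1: float, nu2: float,
                gamma: float) -> tuple[float, float, float, float, float]:
    """Orientation dihedrals of the ring-entry atoms O4' and C1'.

    Returns (t_O4, t_C1, nu1_achieved, nu2_achieved, max_residual).  nu0 is
    realized exactly by the C2' placement; the two entry dihedrals are
    solved so the measured nu1/nu2 equal the request.  With rigid template
    bond angles not every (nu0, nu1, nu2) triple is geometrically
    consistent; infeasible requests return the closest achievable point
    (real ribose rings flex their bond angles slightly with pucker).
    Solved in a canonical local frame — the answer is placement-invariant.
    """
    key = _ring_key(residue, nu0, nu1, nu2, gamma)
    hit = _RING_CACHE.get(key)
    if hit is not None:
        return hit

    rec = {r.name: r for r in kinematic_tree(residue).records}
    o4, c1, c2, c3 = rec["O4'"], rec["C1'"], rec["C2'"], rec["C3'"]
    O5 = np.zeros(3)
    C5 = np.array([rec["C5'"].bond, 0.0, 0.0])
    C4 = nerf_place(C5, O5, np.array([0.0, 1.0, 0.0]), rec["C4'"].bond,
                    rec["C4'"].angle, 0.0)
    C3 = nerf_place(C4, C5, O5, c3.bond, c3.angle, gamma)
    tC4, tC5, tO5, tC3 = map(tuple, (C4, C5, O5, C3))

    def measure(t0, t1):
        O4 = _snerf(tC4, tC5, tO5, o4.bond, o4.angle, t0)
        C1 = _snerf(O4, tC4, tC5, c1.bond, c1.angle, t1)
        C2 = _snerf(C1, O4, tC4, c2.bond, c2.angle, nu0)
        return (_sdihedral(O4, C1, C2, tC3), _sdihedral(C1, C2, tC3, tC4))

    def resid(t):
        m1, m2 = measure(t[0], t[1])
        return np.array([wrap_angle(m1 - nu1), wrap_angle(m2 - nu2)])

    def attempt(x0):
        sol = optimize.root(resid, x0, method="hybr", options={"xtol": 1e-13})
        return float(np.abs(resid(sol.x)).max()), sol.x

    tmpl = np.array([o4.offset, c1.offset])
    best = attempt(tmpl)
    far = np.abs(wrap_angle(best[1] - tmpl)).max() > 1.0
    if best[0] > 1e-10 or far:
        # No root from the template start.  Minimize the nu residual with a
        # weak prior toward the template ring (keeps the geometry physical
        # when the requested triple is inconsistent), then try to polish
        # the result into an exact root.
        def resid_prior(t):
            r = resid(t)
            return np.array([r[0], r[1],
                             0.05 * wrap_angle(t[0] - tmpl[0]),
                             0.05 * wrap_angle(t[1] - tmpl[1])])

        ls = optimize.least_squares(resid_prior, tmpl, xtol=1e-15,
                                    ftol=1e-15, gtol=1e-15)
        cand = attempt(ls.x)
        if cand[0] > 1e-10:
            ls_err = float(np.abs(resid(ls.x)).max())
            cand = (ls_err, ls.x) if ls_err < cand[0] else cand
        cand_far = np.abs(wrap_angle(cand[1] - tmpl)).max() > 1.0
        if cand[0] < best[0] or (far and not cand_far and cand[0] < 1e-10):
            best = cand
    t0, t1 = float(wrap_angle(best[1][0])), float(wrap_angle(best[1][1]))
    m1, m2 = measure(t0, t1)
    out = (t0, t1, float(m1), float(m2), best[0])
    _RING_CACHE[key] = out
    # The achieved values solve their own request exactly with the same
    # geometry; share the solution so build/extract cycles are idempotent.
    _RING_CACHE.setdefault(_ring_key(residue, nu0, m1, m2, gamma),
                           (t0, t1, float(m1), float(m2), 0.0))
    return out


def closed_ring_torsions(residue: str, nu0: float, nu1: float, nu2: float,
                         gamma: float) -> tuple[float, float, float]:
    """Project a ring-torsion triple onto the closed-ring manifold.

    Finds the ring conformation with ideal template bond angles whose
    C2'-C3' closure bond stays at its ideal length while approaching the
    requested (nu0, nu1, nu2) as nearly as possible, and returns the
    measured triple.  Used to sample physically closed rings; the returned
    triple round-trips exactly through build/extract.
    """
    residue = str(residue).strip().upper()
    rec = {r.name: r for r in kinematic_tree(residue).records}
    o4, c1, c2, c3 = rec["O4'"], rec["C1'"], rec["C2'"], rec["C3'"]
    b_close = IDEAL_GEOMETRY.bond_length(residue, "C2'", "C3'")
    O5 = np.zeros(3)
    C5 = np.array([rec["C5'"].bond, 0.0, 0.0])
    C4 = nerf_place(C5, O5, np.array([0.0, 1.0, 0.0]), rec["C4'"].bond,
                    rec["C4'"].angle, 0.0)
    C3 = nerf_place(C4, C5, O5, c3.bond, c3.angle, gamma)
    tC4, tC5, tO5, tC3 = map(tuple, (C4, C5, O5, C3))

    def build(t):
        O4 = _snerf(tC4, tC5, tO5, o4.bond, o4.angle, t[0])
        C1 = _snerf(O4, tC4, tC5, c1.bond, c1.angle, t[1])
        C2 = _snerf(C1, O4, tC4, c2.bond, c2.angle, t[2])
        return O4, C1, C2

    def resid(t):
        O4, C1, C2 = build(t)
        close = math.dist(C2, tC3) - b_close
        return np.array([
            wrap_angle(_sdihedral(tC4, O4, C1, C2) - nu0),
            wrap_angle(_sdihedral(O4, C1, C2, tC3) - nu1),
            wrap_angle(_sdihedral(C1, C2, tC3, tC4) - nu2),
            8.0 * close,
        ])

    x0 = np.array([o4.offset, c1.offset, nu0])
    ls = optimize.least_squares(resid, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    O4, C1, C2 = build(ls.x)
    m0 = _sdihedral(tC4, O4, C1, C2)
    m1 = _sdihedral(O4, C1, C2, tC3)
    m2 = _sdihedral(C1, C2, tC3, tC4)
    # Share the solution with the build-time solver so the sampled triple
    # reproduces this exact closed ring.
    _RING_CACHE.setdefault(
        _ring_key(residue, float(m0), float(m1), float(m2), gamma),
        (float(wrap_angle(ls.x[0])), float(wrap_angle(ls.x[1])),
         float(m1), float(m2), 0.0))
    return float(m0), float(m1), float(m2)


def realizable_torsions(torsions: TorsionSet, residue: str) -> TorsionSet:
    """Project a torsion set onto the geometrically realizable manifold.

    Backbone torsions and chi are free; with rigid template bond angles the
    ring triple has two degrees of freedom, so nu1/nu2 are replaced by the
    values actually achieved by the kinematic build (nu0 is always exact).
    A realizable set round-trips through build/extract exactly.
    """
    tv = {n: torsions.get(n) for n in TORSION_NAMES}
    for n, v in tv.items():
        if v is None:
            tv[n] = _DEFAULT_TORSIONS.get(n)
    *_, m1, m2, _err = _solve_ring(str(residue).strip().upper(), tv["nu0"],
                                   tv["nu1"], tv["nu2"], tv["gamma"])
    return torsions.replace(nu1=m1, nu2=m2)


def random_torsion_set(rng: np.random.Generator, residue: str) -> TorsionSet:
    """Random realizable torsion set: backbone/chi uniform on (-pi, pi],
    ring from a uniform pseudorotation phase and a fiber-like amplitude,
    projected onto the ideal-geometry ring manifold."""
    names = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi")
    tv = {n: float(rng.uniform(-math.pi, math.pi)) for n in names}
    phase = float(rng.uniform(0.0, 2.0 * math.pi))
    amp = float(rng.uniform(math.radians(25.0), math.radians(45.0)))
    nu0, nu1, nu2 = pucker_to_nu(phase, amp)
    m0, m1, m2 = closed_ring_torsions(residue, nu0, nu1, nu2, tv["gamma"])
    return TorsionSet(nu0=m0, nu1=m1, nu2=m2, **tv)


def build_all_atom(frame: RigidFrame, torsions: TorsionSet, identity,
                   table: IdealGeometryTable | None = None,
                   tree: KinematicTree | None = None,
                   prev_o3: np.ndarray | None = None,
                   include_virtual: bool = True,
                   backbone_only: bool = False) -> list[Atom]:
    """All heavy atoms of one nucleotide from its frame and torsions.

    ``identity`` is a residue name ("DA", "G", ...) or a token index.
    Virtual neighbour atoms (trailing "+"/"-") are included by default so
    that all ten torsions are measurable on the result; pass
    ``include_virtual=False`` for the residue's own atoms only.
    ``prev_o3`` supplies the real previous O3' as the alpha reference when
    building chains.
    """
    if isinstance(identity, (int, np.integer)):
        tok = TOKENS[int(identity)]
        name_map = {"DA": "DA", "DC": "DC", "DG": "DG", "DT": "DT",
                    "RA": "A", "RC": "C", "RG": "G", "RU": "U"}
        if tok not in name_map:
            if backbone_only:
                identity = "DA" if tok == "DX" else "A"
            else:
                raise BuildError(f"cannot build all atoms for token {tok!r}; "
                                 "request backbone_only for a stub")
        else:
            identity = name_map[tok]
    residue = str(identity).strip().upper()
    tree = tree or kinematic_tree(residue)
    tpl = component(residue)
    ph = _canonical_phosphate()

    tvals = {n: torsions.get(n) for n in TORSION_NAMES}
    for n, v in tvals.items():
        if v is None:
            tvals[n] = _DEFAULT_TORSIONS.get(n)

    coords: dict[str, np.ndarray] = {
        "P": frame.apply(ph["P"]),
        "OP1": frame.apply(ph["OP1"]),
        "OP2": frame.apply(ph["OP2"]),
    }
    ring_t: tuple[float, float] | None = None
    for rec in tree.records:
        if rec.name == "O3'-" and prev_o3 is not None:
            coords["O3'-"] = np.asarray(prev_o3, float)
            continue
        if backbone_only and rec.name not in NA_BACKBONE and not rec.virtual:
            continue
        if rec.ring_station is not None:
            if ring_t is None:
                ring_t = _solve_ring(residue, tvals["nu0"], tvals["nu1"],
                                     tvals["nu2"], tvals["gamma"])[:2]
            dih = ring_t[0] if rec.ring_station == "O4" else ring_t[1]
        elif rec.torsion is not None:
            dih = wrap_angle(tvals[rec.torsion] + rec.offset)
        else:
            dih = rec.offset
        coords[rec.name] = nerf_place(coords[rec.p], coords[rec.g],
                                      coords[rec.gg], rec.bond, rec.angle, dih)

    elements = dict(zip(tpl.atom_names, tpl.elements))
    atoms: list[Atom] = []
    for name, xyz in coords.items():
        if name.endswith(("+", "-")):
            if include_virtual:
                atoms.append(Atom(name, name.rstrip("+-")[0], xyz))
            continue
        atoms.append(Atom(name, elements.get(name, name[0]), xyz))
    return atoms


def ring_closure_deviation(atom_xyz: dict[str, np.ndarray], residue: str) -> float:
    """Deviation (Angstrom) of the C2'-C3' closure bond from its template
    length; the honest report of how consistent (nu0, nu1, nu2) were."""
    d = float(np.linalg.norm(atom_xyz["C2'"] - atom_xyz["C3'"]))
    return d - IDEAL_GEOMETRY.bond_length(residue, "C2'", "C3'")


# ---------------------------------------------------------------------------
# Extract: atoms -> (frame, torsions)
# ---------------------------------------------------------------------------

_TORSION_QUADS = {
    "alpha": (("-", "O3'"), ("", "P"), ("", "O5'"), ("", "C5'")),
    "beta": (("", "P"), ("", "O5'"), ("", "C5'"), ("", "C4'")),
    "gamma": (("", "O5'"), ("", "C5'"), ("", "C4'"), ("", "C3'")),
    "delta": (("", "C5'"), ("", "C4'"), ("", "C3'"), ("", "O3'")),
    "epsilon": (("", "C4'"), ("", "C3'"), ("", "O3'"), ("+", "P")),
    "zeta": (("", "C3'"), ("", "O3'"), ("+", "P"), ("+", "O5'")),
    "nu0": (("", "C4'"), ("", "O4'"), ("", "C1'"), ("", "C2'")),
    "nu1": (("", "O4'"), ("", "C1'"), ("", "C2'"), ("", "C3'")),
    "nu2": (("", "C1'"), ("", "C2'"), ("", "C3'"), ("", "C4'")),
}


def chi_quad(residue: str) -> tuple[str, str, str, str]:
    if residue in PURINES:
        return ("O4'", "C1'", "N9", "C4")
    return ("O4'", "C1'", "N1", "C2")


def torsions_from_coords(coords: dict[str, np.ndarray], residue: str,
                         prev_coords: dict[str, np.ndarray] | None = None,
                         next_coords: dict[str, np.ndarray] | None = None
                         ) -> TorsionSet:
    """Measure the ten torsions from named coordinates.

    Neighbour atoms come from ``prev_coords``/``next_coords`` when given;
    otherwise virtual atoms ("O3'-", "P+", "O5'+") present in ``coords``
    are used, and a torsion whose atoms are absent is None.
    """

    def lookup(tag: str, name: str):
        if tag == "-":
            if prev_coords is not None:
                return prev_coords.get(name)
            return coords.get(name + "-")
        if tag == "+":
            if next_coords is not None:
                return next_coords.get(name)
            return coords.get(name + "+")
        return coords.get(name)

    vals: dict[str, float | None] = {}
    for tname, quad in _TORSION_QUADS.items():
        pts = [lookup(tag, name) for tag, name in quad]
        vals[tname] = None if any(p is None for p in pts) else float(dihedral(*pts))
    quad = chi_quad(residue)
    pts = [coords.get(n) for n in quad]
    vals["chi"] = None if any(p is None for p in pts) else float(dihedral(*pts))
    return TorsionSet(**vals)


def _coord_map(monomer: Monomer) -> dict[str, np.ndarray]:
    return {a.name: a.xyz for a in monomer.atoms}


def phosphate_frame(monomer: Monomer) -> tuple[RigidFrame | None, bool]:
    """(frame, imputed) for one nucleotide.

    Uses (OP1, P, OP2) when present.  At 5' termini lacking nonbridging
    oxygens (or P itself) the phosphate is imputed at ideal geometry from
    the O5'/C5'/C4' backbone and flagged.
    """
    c = _coord_map(monomer)
    if all(n in c for n in ("OP1", "P", "OP2")):
        return RigidFrame.from_three_atoms(c["OP1"], c["P"], c["OP2"]), False
    residue = monomer.name if monomer.is_standard else ("DA" if monomer.moltype is MolType.DNA else "A")
    ph = _canonical_phosphate()
    if not all(n in c for n in ("O5'", "C5'", "C4'")):
        return None, True
    if "P" not in c:
        c = dict(c)
        c["P"] = nerf_place(c["O5'"], c["C5'"], c["C4'"],
                            float(ph["_consts"][3]), math.radians(120.9),
                            math.radians(-60.0))
    # Rebuild nonbridging oxygens at canonical geometry about the P-O5'
    # axis.  The azimuth about that axis is unconstrained without the real
    # oxygens, so OP1 is anchored to the C5' half-plane (deterministic) and
    # OP2 placed at the canonical OP1->OP2 axial offset.
    rel = _axial_angle(ph["O5'"], ph["P"], ph["OP1"], ph["OP2"])
    op = {}
    for name, off in (("OP1", math.radians(60.0)),
                      ("OP2", math.radians(60.0) + rel)):
        ang = bond_angle(ph[name], ph["P"], ph["O5'"])
        bl = float(np.linalg.norm(ph[name]))
        op[name] = nerf_place(c["P"], c["O5'"], c["C5'"], bl, ang, off)
    return RigidFrame.from_three_atoms(op["OP1"], c["P"], op["OP2"]), True


def extract_frames_and_torsions(chain: Chain) -> list[tuple[RigidFrame | None, TorsionSet]]:
    """Per-nucleotide (frame, torsions) for a nucleic acid chain.

    Torsions whose defining atoms are missing (chain termini, incomplete
    residues) are None in the returned TorsionSet.
    """
    if chain.moltype is MolType.PROTEIN:
        raise TypeError("extract_frames_and_torsions expects a nucleic acid chain")
    out = []
    mons = chain.monomers
    for i, m in enumerate(mons):
        c = _coord_map(m)
        prev_c = _coord_map(mons[i - 1]) if i > 0 else {}
        next_c = _coord_map(mons[i + 1]) if i + 1 < len(mons) else {}
        residue = m.name if m.is_standard else "DA"
        tors = torsions_from_coords(c, residue, prev_coords=prev_c,
                                    next_coords=next_c)
        if not m.is_standard:
            tors = tors.replace(chi=None, nu0=None, nu1=None, nu2=None)
        try:
            frame, _ = phosphate_frame(m)
        except DegenerateGeometryError:
            frame = None
        out.append((frame, tors))
    return out


def protein_frames(chain: Chain) -> list[RigidFrame | None]:
    """Backbone frame per residue from (N, CA, C), CA at the origin.
    Residues missing a backbone atom yield None."""
    if chain.moltype is not MolType.PROTEIN:
        raise TypeError("protein_frames expects a protein chain")
    out = []
    for m in chain:
        n, ca, c = m.xyz("N"), m.xyz("CA"), m.xyz("C")
        if n is None or ca is None or c is None:
            out.append(None)
            continue
        try:
            out.append(RigidFrame.from_three_atoms(n, ca, c))
        except DegenerateGeometryError:
            out.append(None)
    return out


def next_frame_from_atoms(atoms: list[Atom]) -> RigidFrame:
    """Frame of the following residue from a build's virtual phosphate."""
    c = {a.name: a.xyz for a in atoms}
    return RigidFrame.from_three_atoms(c["OP1+"], c["P+"], c["OP2+"])


def build_nucleotide_chain(residues: list[str], torsions: list[TorsionSet],
                           initial_frame: RigidFrame | None = None
                           ) -> list[list[Atom]]:
    """Kinematically build a connected chain, 5' to 3'.

    Each residue is built from the frame propagated through the previous
    residue's virtual phosphate (which the epsilon/zeta torsions place), so
    inter-residue linkage geometry is ideal by construction.  Returns per-
    residue real atoms (virtuals stripped).
    """
    if len(residues) != len(torsions):
        raise ValueError("residues and torsions must have equal length")
    frame = initial_frame or RigidFrame.identity()
    out: list[list[Atom]] = []
    prev_o3 = None
    for res, ts in zip(residues, torsions):
        atoms = build_all_atom(frame, ts, res, prev_o3=prev_o3,
                               include_virtual=True)
        frame = next_frame_from_atoms(atoms)
        byname = {a.name: a.xyz for a in atoms}
        prev_o3 = byname["O3'"]
        out.append([a for a in atoms if not a.name.endswith(("+", "-"))])
    return out
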