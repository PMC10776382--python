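"""Deterministic synthetic-structure generators.

Every operation in the package is testable without downloads: ideal B-form
DNA duplexes, A-form RNA duplexes and hairpins, toy alpha-helical proteins,
and posed protein-NA complexes with controlled contact counts.

Helix construction
------------------
A chain built from one repeated torsion set is an exact helix: successive
residues are related by a constant screw S.  Per-family backbone torsions
were refined once (frozen in data/helix_params.json) so that the screw's
twist/rise match fiber-diffraction values (36 deg / 3.38 A for B-DNA,
32.7 deg / 2.81 A for A-RNA) and the complementary strand - placed by the
duplex dyad, a two-fold rotation about an axis perpendicular to and
intersecting the helix axis - forms Watson-Crick hydrogen bonds.  Because
the dyad conjugates S into its inverse exactly, both strands are uniform
ideal-geometry chains and every base pair is related by the same rule.
"""

from __future__ import annotations

import json
import math
from functools import lru_cache
from importlib import resources

import numpy as np
from scipy import optimize
from scipy.spatial import cKDTree

from .alphabet import MolType
from .chem import WC_COMPLEMENT
from .energies import (ANG_C_N_CA, ANG_CA_C_N, C_N_BOND)
from .geometry import (RigidFrame, TorsionSet, build_all_atom, nerf_place,
                       next_frame_from_atoms, wrap_angle)
from .model import Assembly, Atom, Chain, make_monomer

_DNA_NAME = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}
_RNA_NAME = {"A": "A", "C": "C", "G": "G", "U": "U"}


@lru_cache(maxsize=1)
def helix_params() -> dict:
    """Frozen per-family helix parameters: refined torsions, dyad placement
    and the target twist/rise they reproduce."""
    with resources.files("nafold.data").joinpath("helix_params.json").open() as fh:
        return json.load(fh)


def family_torsions(family: str) -> TorsionSet:
    p = helix_params()[family]
    return TorsionSet(**{k: math.radians(v) for k, v in p["torsions_deg"].items()})


# ---------------------------------------------------------------------------
# Screw / helix frame machinery
# ---------------------------------------------------------------------------

def screw_parameters(S: RigidFrame) -> tuple[float, np.ndarray, float, np.ndarray]:
    """(twist, axis, rise, axis_point) of a screw transform.

    The axis is oriented so the rise is positive; the twist is the signed
    right-handed rotation about it.
    """
    R, t = S.rotation, S.translation
    v = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    s = np.linalg.norm(v) / 2.0
    c = (np.trace(R) - 1.0) / 2.0
    omega = math.atan2(s, c)
    if s < 1e-12:
        raise ValueError("degenerate screw (no rotation)")
    u = v / (2.0 * s)
    if t @ u < 0:
        u, omega = -u, -omega
    rise = float(t @ u)
    # point on axis: (I - R) p = t_perp
    t_perp = t - rise * u
    p0, *_ = np.linalg.lstsq(np.eye(3) - R, t_perp, rcond=None)
    p0 = p0 - (p0 @ u) * u
    return float(omega), u, rise, p0


def helix_frame(S: RigidFrame, anchor: np.ndarray) -> RigidFrame:
    """Frame with the screw axis as z, origin on the axis, and x pointing
    towards the (projected) anchor point - a deterministic convention."""
    _, u, _, p0 = screw_parameters(S)
    r = anchor - p0
    x = r - (r @ u) * u
    n = np.linalg.norm(x)
    if n < 1e-6:
        x = np.array([1.0, 0.0, 0.0]) - u[0] * u
        n = np.linalg.norm(x)
    x = x / n
    y = np.cross(u, x)
    return RigidFrame(np.stack([x, y, u], axis=1), p0)


def duplex_dyad(S: RigidFrame, anchor: np.ndarray, phi: float, z: float) -> RigidFrame:
    """The duplex two-fold axis as a rigid transform: rotation by pi about
    the in-plane direction phi at height z of the helix frame."""
    H = helix_frame(S, anchor)
    d = np.array([math.cos(phi), math.sin(phi), 0.0])
    Rd = 2.0 * np.outer(d, d) - np.eye(3)       # rotation by pi about d
    local = RigidFrame(Rd, np.array([0.0, 0.0, z]) - Rd @ np.array([0.0, 0.0, z]))
    return H.compose(local).compose(H.inverse())


def family_screw(family: str) -> tuple[RigidFrame, RigidFrame]:
    """(screw S, dyad D) of a helix family, from the frozen parameters."""
    p = helix_params()[family]
    theta = family_torsions(family)
    ref = p["reference_residue"]
    atoms = build_all_atom(RigidFrame.identity(), theta, ref)
    S = next_frame_from_atoms(atoms)
    c1 = next(a.xyz for a in atoms if a.name == "C1'")
    D = duplex_dyad(S, c1, math.radians(p["dyad_phi_deg"]), p["dyad_z"])
    return S, D


def _power(S: RigidFrame, k: int) -> RigidFrame:
    out = RigidFrame.identity()
    step = S if k >= 0 else S.inverse()
    for _ in range(abs(k)):
        out = step.compose(out)
    return out


def _strand_frames(S: RigidFrame, n: int) -> list[RigidFrame]:
    frames = [RigidFrame.identity()]
    for _ in range(n - 1):
        frames.append(S.compose(frames[-1]))
    return frames


def _build_strand(residues: list[str], frames: list[RigidFrame],
                  theta: TorsionSet, chain_id: str, moltype: MolType) -> Chain:
    monomers = []
    prev_o3 = None
    for i, (res, fr) in enumerate(zip(residues, frames)):
        atoms = build_all_atom(fr, theta, res, prev_o3=prev_o3,
                               include_virtual=False)
        byname = {a.name: a.xyz for a in atoms}
        prev_o3 = byname["O3'"]
        monomers.append(make_monomer(res, moltype, atoms, i))
    return Chain(chain_id, moltype, monomers)


def _revcomp(residues: list[str]) -> list[str]:
    return [WC_COMPLEMENT[r] for r in reversed(residues)]


def _gen_duplex(residues: list[str], family: str, moltype: MolType,
                chain_ids: tuple[str, str] = ("A", "B")) -> Assembly:
    if not residues:
        raise ValueError("empty sequence")
    theta = family_torsions(family)
    S, D = family_screw(family)
    n = len(residues)
    f1 = _strand_frames(S, n)
    chain_a = _build_strand(residues, f1, theta, chain_ids[0], moltype)
    # strand 2: dyad images, 5'->3' antiparallel
    f2 = [_power(S, n - 1 - j).compose(D) for j in range(n)]
    chain_b = _build_strand(_revcomp(residues), f2, theta, chain_ids[1], moltype)
    return Assembly([chain_a, chain_b], source={"family": family})


def gen_bform_dna(sequence: str) -> Assembly:
    """Ideal B-form DNA duplex; the complementary strand is generated
    antiparallel and every position forms a detectable WC pair."""
    try:
        residues = [_DNA_NAME[c] for c in sequence.upper()]
    except KeyError as exc:
        raise ValueError(f"invalid DNA base {exc}") from exc
    return _gen_duplex(residues, "B", MolType.DNA)


def gen_aform_rna(sequence: str) -> Assembly:
    """Ideal A-form RNA duplex."""
    try:
        residues = [_RNA_NAME[c] for c in sequence.upper().replace("T", "U")]
    except KeyError as exc:
        raise ValueError(f"invalid RNA base {exc}") from exc
    return _gen_duplex(residues, "A", MolType.RNA)


# ---------------------------------------------------------------------------
# RNA hairpin
# ---------------------------------------------------------------------------

_LOOP_CACHE: dict[tuple, list[TorsionSet]] = {}


def _loop_torsions(stem_len: int, loop_len: int, family: str = "A"
                   ) -> list[TorsionSet]:
    """Backbone torsions closing a loop from the end of stem arm 1 onto
    the start of the dyad-placed arm 2 (least-squares chain closure on the
    next-phosphate frame)."""
    key = (stem_len, loop_len, family)
    if key in _LOOP_CACHE:
        return _LOOP_CACHE[key]
    theta = family_torsions(family)
    S, D = family_screw(family)
    start = _power(S, stem_len)                   # frame after arm-1 end
    target = _power(S, stem_len - 1).compose(D)   # arm-2 first residue frame
    ref = helix_params()[family]["reference_residue"]
    probe = np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [0.0, 1.5, 0.0],
                      [0.0, 0.0, 1.5]])
    target_pts = target.apply(probe)
    free = ("alpha", "beta", "gamma", "epsilon", "zeta")
    x0 = np.tile([theta.get(n) for n in free], loop_len)

    def chain_end(x):
        fr = start
        for k in range(loop_len):
            tv = dict(zip(free, x[5 * k:5 * k + 5]))
            ts = theta.replace(**tv)
            atoms = build_all_atom(fr, ts, ref, backbone_only=True)
            fr = next_frame_from_atoms(atoms)
        return fr

    def resid(x):
        fr = chain_end(x)
        geo = (fr.apply(probe) - target_pts).ravel()
        return np.concatenate([geo, 0.05 * (x - x0)])

    sol = optimize.least_squares(resid, x0, xtol=1e-12, ftol=1e-12)
    out = []
    for k in range(loop_len):
        tv = dict(zip(free, sol.x[5 * k:5 * k + 5]))
        out.append(theta.replace(**{n: float(wrap_angle(v))
                                    for n, v in tv.items()}))
    _LOOP_CACHE[key] = out
    return out


def gen_hairpin_rna(stem: str, loop: str | int) -> Assembly:
    """RNA stem-loop: ``stem`` is the 5' arm sequence (the 3' arm is its
    reverse complement), ``loop`` a sequence or a length (poly-U)."""
    if isinstance(loop, int):
        loop_seq = "U" * loop
    else:
        loop_seq = loop.upper().replace("T", "U")
    stem_res = [_RNA_NAME[c] for c in stem.upper().replace("T", "U")]
    loop_res = [_RNA_NAME[c] for c in loop_seq]
    if not stem_res or not loop_res:
        raise ValueError("stem and loop must be non-empty")
    n, m = len(stem_res), len(loop_res)
    theta = family_torsions("A")
    S, D = family_screw("A")
    frames = _strand_frames(S, n)
    loop_ts = _loop_torsions(n, m)
    # chain the loop to recover its frames
    fr = _power(S, n)
    loop_frames = []
    for ts in loop_ts:
        loop_frames.append(fr)
        atoms = build_all_atom(fr, ts, "U", backbone_only=True)
        fr = next_frame_from_atoms(atoms)
    arm2 = [_power(S, n - 1 - j).compose(D) for j in range(n)]
    residues = stem_res + loop_res + _revcomp(stem_res)
    all_frames = frames + loop_frames + arm2
    all_tors = [theta] * n + loop_ts + [theta] * n
    monomers = []
    prev_o3 = None
    for i, (res, f, ts) in enumerate(zip(residues, all_frames, all_tors)):
        atoms = build_all_atom(f, ts, res, prev_o3=prev_o3,
                               include_virtual=False)
        prev_o3 = next(a.xyz for a in atoms if a.name == "O3'")
        monomers.append(make_monomer(res, MolType.RNA, atoms, i))
    return Assembly([Chain("A", MolType.RNA, monomers)],
                    source={"family": "A", "hairpin": True})


# ---------------------------------------------------------------------------
# Toy protein
# ---------------------------------------------------------------------------

_PHI = math.radians(-57.0)
_PSI = math.radians(-47.0)
_OMEGA = math.pi
N_CA_BOND, CA_C_BOND, C_O_BOND, CA_CB_BOND = 1.458, 1.525, 1.231, 1.530
ANG_N_CA_C = math.radians(111.2)
ANG_CA_C_O = math.radians(120.1)
ANG_N_CA_CB = math.radians(110.5)
DIH_C_N_CA_CB = math.radians(-122.6)   # improper placing CB


def gen_toy_protein(sequence: str, chain_id: str = "P") -> Assembly:
    """Ideal alpha-helical backbone (phi -57, psi -47, omega 180) with
    carbonyl O and CB stubs (glycine gets none)."""
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    from .chem import ONE_TO_THREE

    # seed backbone
    N0 = np.zeros(3)
    CA0 = np.array([N_CA_BOND, 0.0, 0.0])
    C0 = nerf_place(CA0, N0, np.array([0.0, 1.0, 0.0]), CA_C_BOND,
                    math.pi - ANG_N_CA_C, 0.0)
    backbone = [(N0, CA0, C0)]
    for _ in range(1, len(seq)):
        Np, CAp, Cp = backbone[-1]
        N = nerf_place(Cp, CAp, Np, C_N_BOND, ANG_CA_C_N, _PSI)
        CA = nerf_place(N, Cp, CAp, N_CA_BOND, ANG_C_N_CA, _OMEGA)
        C = nerf_place(CA, N, Cp, CA_C_BOND, ANG_N_CA_C, _PHI)
        backbone.append((N, CA, C))
    monomers = []
    for i, ch in enumerate(seq):
        N, CA, C = backbone[i]
        atoms = [Atom("N", "N", N), Atom("CA", "C", CA), Atom("C", "C", C)]
        # carbonyl O: anti to the next N (psi + pi about CA-C)
        o_dih = float(wrap_angle(_PSI + math.pi))
        atoms.append(Atom("O", "O", nerf_place(C, CA, N, C_O_BOND,
                                               ANG_CA_C_O, o_dih)))
        name = ONE_TO_THREE.get(ch, "ALA")
        if name != "GLY":
            atoms.append(Atom("CB", "C", nerf_place(CA, N, C, CA_CB_BOND,
                                                    ANG_N_CA_CB,
                                                    DIH_C_N_CA_CB)))
        monomers.append(make_monomer(name, MolType.PROTEIN, atoms, i))
    return Assembly([Chain(chain_id, MolType.PROTEIN, monomers)])


# ---------------------------------------------------------------------------
# Posed complexes
# ---------------------------------------------------------------------------

def random_rotation(rng: np.random.Generator) -> np.ndarray:
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    return Q * np.sign(np.linalg.det(Q))


def _count_ca_contacts_brute(cas: np.ndarray, na_xyz: np.ndarray,
                             radius: float = 7.0) -> int:
    tree = cKDTree(na_xyz)
    return int(sum(len(tree.query_ball_point(ca, radius)) for ca in cas))


def gen_toy_complex(n_contacts_target: int, rng: np.random.Generator,
                    protein_len: int = 30, dna_len: int = 12,
                    max_trials: int = 60):
    """Toy protein posed against a generated B-DNA duplex so that the
    Calpha-to-NA-heavy-atom 7 A contact count equals the target exactly
    (verified internally by brute force).  Returns a ComplexRecord."""
    from .curation import ComplexRecord

    if n_contacts_target < 0:
        raise ValueError("n_contacts_target must be >= 0")
    seq = "".join(rng.choice(list("ACGT"), size=dna_len))
    duplex = gen_bform_dna(seq)
    protein = gen_toy_protein("A" * protein_len)
    na_xyz = duplex.coords()
    na_center = na_xyz.mean(axis=0)

    if n_contacts_target == 0:
        placed = protein.transformed(np.eye(3), na_center + np.array([80.0, 0, 0]))
        assembly = Assembly(duplex.chains + placed.chains)
        return ComplexRecord.from_assembly(assembly)

    tree = cKDTree(na_xyz)
    for _ in range(max_trials):
        R = random_rotation(rng)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        prot = protein.transformed(R, np.zeros(3))
        cas0 = np.array([m.xyz("CA") for _, m in prot.monomers()])
        cas0 = cas0 - cas0.mean(axis=0)

        def count_at(t):
            pts = cas0 + na_center + t * direction
            return int(sum(len(tree.query_ball_point(p, 7.0)) for p in pts))

        lo, hi = None, None
        for t in np.arange(60.0, 2.0, -1.0):
            c = count_at(t)
            if c == n_contacts_target:
                lo = t
                break
            if c > n_contacts_target:
                hi = t
                break
        if lo is None and hi is not None:
            for t in np.arange(hi + 1.0, hi, -0.004):
                if count_at(t) == n_contacts_target:
                    lo = t
                    break
        if lo is not None:
            placed = protein.transformed(R, np.zeros(3))
            cas_now = np.array([m.xyz("CA") for _, m in placed.monomers()])
            delta = (na_center + lo * direction) - cas_now.mean(axis=0)
            placed = placed.transformed(np.eye(3), delta)
            assembly = Assembly(duplex.chains + placed.chains)
            cas = np.array([m.xyz("CA") for _, m in placed.monomers()])
            assert _count_ca_contacts_brute(cas, na_xyz) == n_contacts_target
            return ComplexRecord.from_assembly(assembly)
    raise ValueError(f"could not achieve exactly {n_contacts_target} contacts")


def gen_basecontact_complex(rng: np.random.Generator, n_targets: int = 3,
                            dna_len: int = 12, protein_len: int = 12):
    """Protein-DNA complex engineered to make base-specific contacts:
    protein atoms are posed within hydrogen-bonding distance (~2.9 A) of
    major-groove base atoms, gating padding/negative eligibility."""
    from .curation import ComplexRecord, base_specific_contacts
    from .energies import _kabsch

    seq = "GC" + "".join(rng.choice(list("ACGT"), size=dna_len - 4)) + "GC"
    duplex = gen_bform_dna(seq)
    chain_a = duplex.chains[0]
    mid = len(chain_a) // 2
    groove_pref = ("N7", "O6", "N6", "N4", "O4", "C5", "C6")
    targets = []
    axis_pts = duplex.coords().mean(axis=0)
    for k in range(n_targets):
        mon = chain_a.monomers[mid - 1 + k]
        from .chem import base_atoms as _ba

        names = [n for n in groove_pref if n in _ba(mon.name)]
        atom = mon.xyz(names[0])
        out_dir = atom - axis_pts
        out_dir = out_dir / np.linalg.norm(out_dir)
        targets.append(atom + 2.9 * out_dir)
    protein = gen_toy_protein("N" * protein_len)
    cbs = [m.xyz("CB") for _, m in protein.monomers()]
    step = max(1, protein_len // (n_targets + 1))
    moving = np.array([cbs[step * (k + 1) - 1] for k in range(n_targets)])
    R, t = _kabsch(moving, np.array(targets))
    placed = protein.transformed(R, t)
    assembly = Assembly(duplex.chains + placed.chains)
    # nudge towards the duplex until enough contacts register
    contacts = base_specific_contacts(assembly)
    center_dir = duplex.coords().mean(axis=0) - placed.coords().mean(axis=0)
    center_dir /= np.linalg.norm(center_dir)
    nudges = 0
    while len({(c["na_chain"], c["nucleotide"]) for c in contacts}) < n_targets \
            and nudges < 20:
        placed = placed.transformed(np.eye(3), 0.1 * center_dir)
        assembly = Assembly(duplex.chains + placed.chains)
        contacts = base_specific_contacts(assembly)
        nudges += 1
    return ComplexRecord.from_assembly(assembly)


def perturb(assembly: Assembly, mode: str, rng: np.random.Generator,
            sigma: float = 0.5, shift: float = 2.0) -> Assembly:
    """Deterministic (seeded) perturbations for metric sensitivity tests.

    gaussian: independent N(0, sigma) displacement of every atom.
    rigid: one random rotation + translation of the whole assembly.
    interface_shift: translate only the nucleic acid chains by ``shift``
    Angstrom along a random direction.
    """
    if mode == "gaussian":
        out = assembly.copy()
        for _, m in out.monomers():
            for a in m.atoms:
                a.xyz = a.xyz + rng.normal(scale=sigma, size=3)
        return out
    if mode == "rigid":
        return assembly.transformed(random_rotation(rng),
                                    rng.normal(scale=10.0, size=3))
    if mode == "interface_shift":
        out = assembly.copy()
        d = rng.normal(size=3)
        d = shift * d / np.linalg.norm(d)
        for ch in out.chains:
            if ch.moltype.is_nucleic:
                for m in ch:
                    for a in m.atoms:
                        a.xyz = a.xyz + d
        return out
    raise ValueError(f"unknown perturbation mode {mode!r}")


# ---------------------------------------------------------------------------
# Duplex extension (used by curation.pad_dna_ends)
# ---------------------------------------------------------------------------

def extend_duplex(assembly: Assembly, pair: tuple[str, str],
                  n_end5: int, n_end3: int,
                  rng: np.random.Generator) -> Assembly:
    """Extend a duplex with ideal B-form base pairs of random complementary
    sequence: ``n_end5`` pairs before chain A's 5' end and ``n_end3`` after
    its 3' end.  Added monomers are flagged loss_excluded."""
    from .energies import _kabsch

    out = assembly.copy()
    ca = out.chain(pair[0])
    cb = out.chain(pair[1])
    alphabet = "ACGT" if ca.moltype is MolType.DNA else "ACGU"
    gen = gen_bform_dna if ca.moltype is MolType.DNA else gen_aform_rna

    def strand_seq(ch):
        return "".join(m.name[-1] for m in ch.monomers)

    def backbone_pts(mons):
        names = ("P", "O5'", "C5'", "C4'", "C3'", "O3'", "C1'")
        return np.array([m.xyz(nm) for m in mons for nm in names
                         if m.xyz(nm) is not None])

    def make_pad(overlap_res, pad_seq, at_five_prime: bool):
        """Ideal duplex covering pad + 2 overlap bp, superposed on the
        overlap; returns (new A monomers, new B monomers)."""
        if at_five_prime:
            seq = pad_seq + "".join(m.name[-1] for m in overlap_res)
            guide_idx = [len(pad_seq), len(pad_seq) + 1]
        else:
            seq = "".join(m.name[-1] for m in overlap_res) + pad_seq
            guide_idx = [0, 1]
        g = gen(seq)
        gA, gB = g.chains[0], g.chains[1]
        moving = backbone_pts([gA.monomers[i] for i in guide_idx])
        targetp = backbone_pts(overlap_res)
        R, t = _kabsch(moving, targetp)
        for ch in (gA, gB):
            for m in ch.monomers:
                for a in m.atoms:
                    a.xyz = R @ a.xyz + t
                m.loss_excluded = True
        N = len(seq)
        # gA[i] pairs gB[N-1-i]; both generated chains run 5'->3'.
        if at_five_prime:
            padA = gA.monomers[:len(pad_seq)]
            padB = gB.monomers[N - len(pad_seq):]   # appended at B's 3' end
        else:
            padA = gA.monomers[2:]
            padB = gB.monomers[:len(pad_seq)]       # prepended at B's 5' end
        return padA, padB

    if n_end5 > 0:
        pad_seq = "".join(rng.choice(list(alphabet), size=n_end5))
        padA, padB = make_pad(ca.monomers[:2], pad_seq, at_five_prime=True)
        ca.monomers = padA + ca.monomers
        cb.monomers = cb.monomers + list(padB)
    if n_end3 > 0:
        pad_seq = "".join(rng.choice(list(alphabet), size=n_end3))
        padA, padB = make_pad(ca.monomers[-2:], pad_seq, at_five_prime=False)
        ca.monomers = ca.monomers + list(padA)
        cb.monomers = list(padB) + cb.monomers
    ca.renumber()
    cb.renumber()
    return out
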