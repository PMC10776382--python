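"""Nucleotide frame/torsion kinematics: round trips, conventions, oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nafold.alphabet import MolType
from nafold.chem import component
from nafold.geometry import (DegenerateGeometryError, BuildError, RigidFrame,
                             TORSION_NAMES, TorsionSet, build_all_atom,
                             build_nucleotide_chain, dihedral,
                             extract_frames_and_torsions, nerf_place,
                             protein_frames, pseudorotation_phase,
                             pucker_to_nu, random_torsion_set,
                             ring_closure_deviation, torsions_from_coords,
                             wrap_angle)
from nafold.model import Chain, make_monomer

from conftest import random_rigid

NUCLEOTIDES = ("DA", "DC", "DG", "DT", "A", "C", "G", "U")


def angdiff(a, b):
    return abs(float(wrap_angle(a - b)))


# ---------------------------------------------------------------------------
# Frames
# ---------------------------------------------------------------------------

def test_frame_from_three_atoms_convention():
    fr = RigidFrame.from_three_atoms((1, 0, 0), (0, 0, 0), (0, 1, 0))
    assert np.allclose(fr.translation, 0)
    # x-axis along c - b
    assert np.allclose(fr.rotation @ [1, 0, 0], [0, 1, 0])
    # z = x cross y
    x, y = fr.rotation[:, 0], fr.rotation[:, 1]
    assert np.allclose(fr.rotation[:, 2], np.cross(x, y))


def test_frame_gram_schmidt_matches_independent_oracle(rng):
    def oracle(a, b, c):
        # second, independently written Gram-Schmidt
        a, b, c = map(np.asarray, (a, b, c))
        e1 = (c - b) / np.linalg.norm(c - b)
        v = (a - b) - np.dot(a - b, e1) * e1
        e2 = v / np.linalg.norm(v)
        e3 = np.cross(e1, e2)
        return np.column_stack([e1, e2, e3]), b

    tpl = component("DA")
    pts = [tpl.xyz("OP1"), tpl.xyz("P"), tpl.xyz("OP2")]
    fr = RigidFrame.from_three_atoms(*pts)
    R, t = oracle(*pts)
    assert np.abs(fr.rotation - R).max() < 1e-10
    assert np.abs(fr.translation - t).max() < 1e-10


def test_frame_equivariance_under_rigid_motion(rng):
    a, b, c = rng.normal(size=(3, 3))
    R, t = random_rigid(rng)
    fr = RigidFrame.from_three_atoms(a, b, c)
    fr2 = RigidFrame.from_three_atoms(R @ a + t, R @ b + t, R @ c + t)
    assert np.abs(fr2.rotation - R @ fr.rotation).max() < 1e-10
    assert np.abs(fr2.translation - (R @ fr.translation + t)).max() < 1e-10


def test_frame_degenerate_inputs_raise():
    with pytest.raises(DegenerateGeometryError):
        RigidFrame.from_three_atoms((1, 0, 0), (0, 0, 0), (2, 0, 0))
    with pytest.raises(DegenerateGeometryError):
        RigidFrame.from_three_atoms((0, 0, 0), (0, 0, 0), (1, 0, 0))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_frame_compose_inverse_identity(seed):
    r = np.random.default_rng(seed)
    R, t = random_rigid(r)
    fr = RigidFrame(R, t)
    ident = fr.compose(fr.inverse())
    assert np.abs(ident.rotation - np.eye(3)).max() < 1e-12
    assert np.abs(ident.translation).max() < 1e-12


# ---------------------------------------------------------------------------
# Dihedrals / NeRF
# ---------------------------------------------------------------------------

def test_dihedral_matches_biotite_convention(rng):
    import biotite.structure as struc

    for _ in range(20):
        pts = rng.normal(size=(4, 3)) * 3
        assert angdiff(dihedral(*pts), float(struc.dihedral(*pts))) < 1e-6


def test_nerf_realizes_requested_internal_coordinates(rng):
    from nafold.geometry import bond_angle

    for _ in range(20):
        gg, g, p = rng.normal(size=(3, 3)) * 3
        bond, angle, dih = 1.5, 1.9, float(rng.uniform(-np.pi, np.pi))
        x = nerf_place(p, g, gg, bond, angle, dih)
        assert abs(np.linalg.norm(x - p) - bond) < 1e-10
        assert abs(bond_angle(x, p, g) - angle) < 1e-10
        assert angdiff(dihedral(gg, g, p, x), dih) < 1e-10


# ---------------------------------------------------------------------------
# Build / extract round trips
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("res", NUCLEOTIDES)
def test_build_extract_roundtrip_all_nucleotides(res, rng):
    for _ in range(12):
        ts = random_torsion_set(rng, res)
        R, t = random_rigid(rng)
        frame = RigidFrame(R, t)
        atoms = build_all_atom(frame, ts, res)
        coords = {a.name: a.xyz for a in atoms}
        back = torsions_from_coords(coords, res)
        for name in TORSION_NAMES:
            assert angdiff(back.get(name), ts.get(name)) < 1e-6, name
        fr2 = RigidFrame.from_three_atoms(coords["OP1"], coords["P"],
                                          coords["OP2"])
        assert np.abs(fr2.rotation - R).max() < 1e-9
        assert np.abs(fr2.translation - t).max() < 1e-9
        # sampled ring conformations close properly
        assert abs(ring_closure_deviation(coords, res)) < 0.01


def test_chi_locality_base_moves_backbone_fixed(rng):
    ts = random_torsion_set(rng, "DG")
    a1 = {a.name: a.xyz for a in build_all_atom(RigidFrame.identity(), ts, "DG")}
    ts2 = ts.replace(chi=wrap_angle(ts.chi + math.pi))
    a2 = {a.name: a.xyz for a in build_all_atom(RigidFrame.identity(), ts2, "DG")}
    from nafold.chem import base_atoms

    base = set(base_atoms("DG")) - {"N9"}      # N9 sits on the chi axis
    for name in a1:
        if name in base:
            continue
        assert np.abs(a1[name] - a2[name]).max() < 1e-8, name
    moved = [n for n in base if np.abs(a1[n] - a2[n]).max() > 0.5]
    assert moved, "chi rotation must move base atoms"


def test_guanine_build_has_component_dictionary_heavy_atom_count(rng):
    ts = random_torsion_set(rng, "G")
    atoms = [a for a in build_all_atom(RigidFrame.identity(), ts, "G",
                                       include_virtual=False)]
    # CCD heavy atoms for G minus the terminal-only OP3
    assert len(atoms) == component("G").heavy_atom_count


def test_unknown_token_build_errors_and_backbone_stub():
    from nafold.alphabet import INDEX

    with pytest.raises(BuildError):
        build_all_atom(RigidFrame.identity(), TorsionSet(), INDEX["DX"])
    stub = build_all_atom(RigidFrame.identity(), TorsionSet(), INDEX["DX"],
                          backbone_only=True, include_virtual=False)
    names = {a.name for a in stub}
    assert names == {"P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'"}


# ---------------------------------------------------------------------------
# Chain extraction
# ---------------------------------------------------------------------------

def _chain_from(residues, torsions, moltype=MolType.DNA):
    atoms = build_nucleotide_chain(residues, torsions)
    mons = [make_monomer(r, moltype, a, i)
            for i, (r, a) in enumerate(zip(residues, atoms))]
    return Chain("A", moltype, mons)


def test_chain_extraction_recovers_torsions_and_terminal_bookkeeping(rng):
    residues = ["DA", "DG", "DC", "DT"]
    tors = [random_torsion_set(rng, r) for r in residues]
    chain = _chain_from(residues, tors)
    out = extract_frames_and_torsions(chain)
    assert out[0][1].alpha is None          # 5' terminus lacks O3'(i-1)
    assert out[-1][1].epsilon is None and out[-1][1].zeta is None
    for i, (frame, ts) in enumerate(out):
        assert frame is not None
        for name in TORSION_NAMES:
            got = ts.get(name)
            if got is None:
                continue
            assert angdiff(got, tors[i].get(name)) < 1e-6, (i, name)


def test_chain_rigid_motion_rotates_frames_not_torsions(rng):
    residues = ["A", "G", "U"]
    tors = [random_torsion_set(rng, r) for r in residues]
    chain = _chain_from(residues, tors, MolType.RNA)
    R, t = random_rigid(rng)
    moved = Chain("A", MolType.RNA, [
        make_monomer(m.name, MolType.RNA,
                     [type(a)(a.name, a.element, R @ a.xyz + t) for a in m.atoms],
                     m.seq_index)
        for m in chain.monomers])
    base = extract_frames_and_torsions(chain)
    rot = extract_frames_and_torsions(moved)
    for (f1, t1), (f2, t2) in zip(base, rot):
        for name in TORSION_NAMES:
            a, b = t1.get(name), t2.get(name)
            assert (a is None) == (b is None)
            if a is not None:
                assert angdiff(a, b) < 1e-8
        assert np.abs(f2.rotation - R @ f1.rotation).max() < 1e-8


def test_chi_quadruples_follow_purine_pyrimidine_convention(rng):
    # chi measured over O4'-C1'-N9-C4 (purine) / O4'-C1'-N1-C2 (pyrimidine)
    for res, quad in (("DA", ("O4'", "C1'", "N9", "C4")),
                      ("DC", ("O4'", "C1'", "N1", "C2"))):
        ts = random_torsion_set(rng, res)
        c = {a.name: a.xyz for a in build_all_atom(RigidFrame.identity(), ts, res)}
        direct = dihedral(*[c[n] for n in quad])
        assert angdiff(direct, ts.chi) < 1e-8
        assert -math.pi < direct <= math.pi


def test_non_nucleic_chain_rejected(toy_helix):
    with pytest.raises(TypeError):
        extract_frames_and_torsions(toy_helix.chains[0])


# ---------------------------------------------------------------------------
# Protein frames
# ---------------------------------------------------------------------------

def test_protein_frames_one_per_residue(toy_helix):
    frames = protein_frames(toy_helix.chains[0])
    assert len(frames) == 20
    assert all(f is not None for f in frames)
    # CA is the origin
    for f, mon in zip(frames, toy_helix.chains[0].monomers):
        assert np.abs(f.translation - mon.xyz("CA")).max() < 1e-12


def test_protein_frames_glycine_and_equivariance(rng):
    from nafold.fixtures import gen_toy_protein

    prot = gen_toy_protein("GGG")
    frames = protein_frames(prot.chains[0])
    assert all(f is not None for f in frames)
    R, t = random_rigid(rng)
    moved = prot.transformed(R, t)
    frames2 = protein_frames(moved.chains[0])
    for f1, f2 in zip(frames, frames2):
        assert np.abs(f2.rotation - R @ f1.rotation).max() < 1e-9


# ---------------------------------------------------------------------------
# Pseudorotation
# ---------------------------------------------------------------------------

@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.floats(0.0, 2 * math.pi), st.floats(0.45, 0.8))
def test_pseudorotation_phase_recovers_inputs(phase, amp):
    nus = pucker_to_nu(phase, amp)
    p, a = pseudorotation_phase(*nus)
    assert angdiff(p, phase) < 1e-9
    assert abs(a - amp) < 1e-9


def test_built_pucker_reproduces_stated_phase(rng):
    # build with a stated pucker; recover the phase from the as-built
    # nu angles via the standard pseudorotation relation (direct formula)
    phase, amp = math.radians(162.0), math.radians(36.0)
    nus = pucker_to_nu(phase, amp)
    ts = random_torsion_set(rng, "DA").replace(nu0=nus[0], nu1=nus[1], nu2=nus[2])
    from nafold.geometry import realizable_torsions

    ts = realizable_torsions(ts, "DA")
    c = {a.name: a.xyz for a in build_all_atom(RigidFrame.identity(), ts, "DA")}
    back = torsions_from_coords(c, "DA")
    p, a = pseudorotation_phase(back.nu0, back.nu1, back.nu2)
    assert angdiff(p, phase) < math.radians(8.0)
    assert abs(a - amp) < math.radians(6.0)
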