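"""Training-loss terms: oracles, invariances, weighted aggregation."""

import math

import numpy as np
import pytest

from nafold.alphabet import MolType, N_TOKENS
from nafold.geometry import (RigidFrame, TORSION_NAMES, TorsionSet,
                             build_all_atom, random_torsion_set)
from nafold.losses import (BASE_COMPONENTS, FINETUNE_COMPONENTS,
                           DistogramSpec, FrameSet, LossWeights,
                           allatom_fape, allatom_frames, backbone_fape,
                           backbone_frames, combine_losses, distogram_loss,
                           fape, masked_seq_loss, pair_error_loss,
                           plddt_error_loss, torsion_frames,
                           torsion_frame_triples, torsion_loss,
                           _matched_coords)
from nafold.model import Assembly, Atom, Chain, Monomer, make_monomer

from conftest import random_rigid


def brute_force_fape(pf, ppts, tf, tpts, clamp=10.0):
    """Independent double loop over frames x points."""
    total, count = 0.0, 0
    for fp, ft in zip(pf.frames, tf.frames):
        for xp, xt in zip(ppts, tpts):
            lp = fp.rotation.T @ (np.asarray(xp) - fp.translation)
            lt = ft.rotation.T @ (np.asarray(xt) - ft.translation)
            total += min(float(np.linalg.norm(lp - lt)), clamp)
            count += 1
    return total / count / clamp


def _tiny_complex(rng, n_nt=3):
    """Small NA chain + 2-residue protein with slight prediction noise."""
    from nafold.fixtures import gen_bform_dna, gen_toy_protein, perturb

    duplex = gen_bform_dna("ACG"[:n_nt])
    prot = gen_toy_protein("AK")
    prot = prot.transformed(np.eye(3), np.array([15.0, 0, 0]))
    ref = Assembly(duplex.chains + prot.chains)
    pred = perturb(ref, "gaussian", rng, sigma=0.3)
    return pred, ref


def test_backbone_fape_zero_on_identity(gc_duplex):
    assert backbone_fape(gc_duplex, gc_duplex) == pytest.approx(0.0, abs=1e-12)


def test_backbone_fape_invariant_under_rigid_motion(rng, mixed_duplex):
    R, t = random_rigid(rng)
    moved = mixed_duplex.transformed(R, t)
    assert backbone_fape(moved, mixed_duplex) == pytest.approx(0.0, abs=1e-8)
    pred = mixed_duplex.copy()
    pred.chains[0].monomers[0].atoms[0].xyz = \
        pred.chains[0].monomers[0].atoms[0].xyz + 1.0
    v1 = backbone_fape(pred, mixed_duplex)
    v2 = backbone_fape(pred.transformed(R, t), mixed_duplex)
    assert v1 == pytest.approx(v2, abs=1e-8)
    assert v1 > 0


def test_backbone_fape_matches_brute_force_oracle(rng):
    pred, ref = _tiny_complex(rng)
    got = backbone_fape(pred, ref)
    pf, tf = backbone_frames(pred), backbone_frames(ref)
    ppts, tpts = _matched_coords(pred, ref)
    want = brute_force_fape(pf, ppts, tf, tpts)
    assert got == pytest.approx(want, abs=1e-10)


def test_single_displaced_point_toy_fape(rng):
    # 2-residue toy, one point displaced 1 A, clamp 10
    ref_pts = np.array([[0.0, 0, 0], [3.0, 0, 0]])
    frames = FrameSet([RigidFrame.identity(),
                       RigidFrame(np.eye(3), np.array([3.0, 0, 0]))], [0, 1])
    pred_pts = ref_pts.copy()
    pred_pts[1, 1] += 1.0
    got = fape(frames, pred_pts, frames, ref_pts)
    want = brute_force_fape(frames, pred_pts, frames, ref_pts)
    assert got == pytest.approx(want, abs=1e-12)
    # both frames see the same 1 A displacement on one of two points
    assert got == pytest.approx(0.5 / 10.0, abs=1e-12)


def test_torsion_frames_ten_nondegenerate_bonded(rng):
    from nafold.chem import component

    ts = random_torsion_set(rng, "G")
    atoms = build_all_atom(RigidFrame.identity(), ts, "G")
    mon = make_monomer("G", MolType.RNA,
                       [Atom(a.name, a.element, a.xyz) for a in atoms], 0)
    frames = torsion_frames(mon)
    assert set(frames) == set(TORSION_NAMES)
    assert all(f is not None for f in frames.values())
    comp = component("G")
    for tname, (a, b, c) in torsion_frame_triples("G").items():
        # the two atoms defining the torsion's rotatable bond are bonded
        if not (b.endswith("+") or c.endswith("+")):
            assert comp.bonded(b, c), (tname, b, c)
        if not (a.endswith("+") or b.endswith("+")):
            assert comp.bonded(a, b), (tname, a, b)


def test_torsion_frames_equivariance(rng):
    ts = random_torsion_set(rng, "DA")
    atoms = build_all_atom(RigidFrame.identity(), ts, "DA")
    mon = make_monomer("DA", MolType.DNA, atoms, 0)
    f1 = torsion_frames(mon)
    R, t = random_rigid(rng)
    mon2 = make_monomer("DA", MolType.DNA,
                        [Atom(a.name, a.element, R @ a.xyz + t) for a in atoms], 0)
    f2 = torsion_frames(mon2)
    for name in TORSION_NAMES:
        assert np.abs(f2[name].rotation - R @ f1[name].rotation).max() < 1e-9


def test_allatom_fape_single_nucleotide_brute_force(rng):
    from nafold.fixtures import perturb

    ts = random_torsion_set(rng, "DG")
    atoms = build_all_atom(RigidFrame.identity(), ts, "DG",
                           include_virtual=False)
    mon = make_monomer("DG", MolType.DNA, atoms, 0)
    ref = Assembly([Chain("A", MolType.DNA, [mon])])
    pred = perturb(ref, "gaussian", rng, sigma=0.2)
    got = allatom_fape(pred, ref)
    pf, tf = allatom_frames(pred), allatom_frames(ref)
    ppts, tpts = _matched_coords(pred, ref)
    want = brute_force_fape(pf, ppts, tf, tpts)
    assert got == pytest.approx(want, abs=1e-10)
    assert allatom_fape(ref, ref) == pytest.approx(0.0, abs=1e-12)


def test_loss_excluded_positions_contribute_nothing(rng):
    pred, ref = _tiny_complex(rng)
    base = backbone_fape(pred, ref)
    pred2, ref2 = pred.copy(), ref.copy()
    # corrupt an excluded position: the loss must not change
    for asm in (pred2, ref2):
        asm.chains[0].monomers[0].loss_excluded = True
    pred2.chains[0].monomers[0].atoms[0].xyz = \
        pred2.chains[0].monomers[0].atoms[0].xyz + 50.0
    with_flag = backbone_fape(pred2, ref2)
    pred3, ref3 = pred.copy(), ref.copy()
    for asm in (pred3, ref3):
        asm.chains[0].monomers[0].loss_excluded = True
    assert with_flag == pytest.approx(backbone_fape(pred3, ref3), abs=1e-12)
    assert with_flag != pytest.approx(base, abs=1e-12)


# ---------------------------------------------------------------------------
# Scalar losses
# ---------------------------------------------------------------------------

def test_torsion_loss_zero_and_periodic(rng):
    ts = random_torsion_set(rng, "DA")
    assert torsion_loss([ts], [ts]) == 0.0
    shifted = TorsionSet(**{n: ts.get(n) + 2 * math.pi for n in TORSION_NAMES})
    assert torsion_loss([shifted], [ts]) == pytest.approx(0.0, abs=1e-12)


def test_torsion_loss_half_turn_hand_value(rng):
    n = 3
    true = [random_torsion_set(rng, "DA") for _ in range(n)]
    pred = [t for t in true]
    pred[0] = true[0].replace(alpha=true[0].alpha + math.pi)
    # (2 sin)^2 + (2 cos)^2 = 4 on one slot out of 10 n
    assert torsion_loss(pred, true) == pytest.approx(4.0 / (10 * n), abs=1e-12)


def test_masked_seq_loss_examples():
    n = 4
    tokens = np.array([0, 5, 22, 23])
    moltypes = [MolType.PROTEIN, MolType.PROTEIN, MolType.DNA, MolType.DNA]
    onehot = np.full((n, N_TOKENS), -1e9)
    onehot[np.arange(n), tokens] = 10.0
    mask = np.array([True, True, False, False])
    assert masked_seq_loss(onehot, tokens, mask, moltypes) == pytest.approx(0.0, abs=1e-6)
    uniform = np.zeros((n, N_TOKENS))
    assert masked_seq_loss(uniform, tokens, mask, moltypes) == \
        pytest.approx(math.log(32), abs=1e-12)
    assert masked_seq_loss(uniform, tokens, np.zeros(n, bool), moltypes) == 0.0
    with pytest.raises(ValueError):
        masked_seq_loss(uniform, tokens, np.array([False, False, True, False]),
                        moltypes)


def test_distogram_loss_examples(rng):
    spec = DistogramSpec.default()
    assert spec.n_bins == 37
    n = 4
    dist = rng.uniform(3.0, 25.0, size=(n, n))
    dist = (dist + dist.T) / 2
    # one-hot on the true bin -> 0
    probs = np.zeros((n, n, spec.n_bins))
    for i in range(n):
        for j in range(n):
            probs[i, j, spec.bin_of(dist[i, j])] = 1.0
    assert distogram_loss(probs, dist, spec) == pytest.approx(0.0, abs=1e-9)
    uniform = np.full((n, n, spec.n_bins), 1.0 / spec.n_bins)
    assert distogram_loss(uniform, dist, spec) == \
        pytest.approx(math.log(spec.n_bins), abs=1e-12)
    # negative example: all mass in the final catch-all bin -> 0
    neg = np.zeros((n, n, spec.n_bins))
    neg[:, :, -1] = 1.0
    assert distogram_loss(neg, dist, spec, is_negative=True) == \
        pytest.approx(0.0, abs=1e-9)
    bad = uniform * 0.9
    with pytest.raises(ValueError):
        distogram_loss(bad, dist, spec)


def test_plddt_error_loss_examples():
    a = np.array([0.5, 0.7, 0.9])
    assert plddt_error_loss(a, a) == 0.0
    assert plddt_error_loss(a, a - 0.1) == pytest.approx(0.01, abs=1e-12)
    with pytest.raises(ValueError):
        plddt_error_loss(np.array([]), np.array([]))
    with pytest.raises(ValueError):
        plddt_error_loss(np.array([1.2]), np.array([0.5]))


def test_pair_error_loss_examples():
    p = np.array([[0.0, 2.0], [2.0, 0.0]])
    assert pair_error_loss(p, p) == 0.0
    a = np.array([[0.0, 4.0], [1.0, 0.0]])
    want = ((0 - 0) ** 2 + (2 - 4) ** 2 + (2 - 1) ** 2 + 0) / 4
    assert pair_error_loss(p, a) == pytest.approx(want, abs=1e-12)
    # symmetric under transposing both inputs
    assert pair_error_loss(p.T, a.T) == pytest.approx(pair_error_loss(p, a))
    # actual errors are clamped at the FAPE clamp
    huge = np.array([[0.0, 50.0], [50.0, 0.0]])
    assert pair_error_loss(p, huge) == pytest.approx(((2 - 10) ** 2) * 2 / 4)
    with pytest.raises(ValueError):
        pair_error_loss(p, np.zeros((3, 3)))


def test_combine_losses_printed_weight_sums():
    ones = {k: 1.0 for k in FINETUNE_COMPONENTS}
    assert combine_losses(ones, finetune=False) == pytest.approx(24.1, abs=1e-12)
    assert combine_losses(ones, finetune=True) == pytest.approx(24.37, abs=1e-12)
    zero = LossWeights(0, 0, 0, 0, 0, 0, 0, 0, 0)
    assert combine_losses(ones, zero, finetune=True) == 0.0


def test_combine_losses_linearity_and_missing_component(rng):
    vals = {k: float(rng.uniform(0, 2)) for k in BASE_COMPONENTS}
    base = combine_losses(vals)
    bumped = dict(vals)
    bumped["str"] += 1.0
    assert combine_losses(bumped) - base == pytest.approx(10.0, abs=1e-9)
    with pytest.raises(ValueError, match="tors"):
        combine_losses({k: 1.0 for k in BASE_COMPONENTS if k != "tors"})
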