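"""Training-loss terms for protein-nucleic-acid structure prediction.

The total loss is a weighted sum

    loss = w_seq*seq + w_6d*6D + w_str*str + w_tors*tors + w_err*err

with a fine-tuning phase that adds physics and pair-error terms

    loss_ft = loss + w_LJ*LJ + w_hbond*hbond + w_geom*geom + w_pairerr*pairerr

The structure term is Frame Aligned Point Error (FAPE): every atom is
expressed in every local rigid frame of both prediction and truth, and the
clamped distance between the two local positions is averaged.  For
nucleotides the backbone frame is the phosphate group; the all-atom variant
adds ten frames per nucleotide, one per rotatable torsion, each built from
the two bonded atoms defining the torsion plus a third bonded atom closer
to the phosphate in the bond graph.

Default weights (w_seq 3.0, w_6d 1.0, w_str 10.0, w_tors 10.0, w_err 0.1;
fine-tune w_geom 0.1, w_LJ 0.02, w_hbond 0.05, w_pairerr 0.1) are frozen in
LossWeights.  Positions flagged loss_excluded contribute nothing to the
structure and torsion terms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields

import numpy as np

from .alphabet import MolType, N_TOKENS
from .chem import GLYCOSIDIC_N, PURINES, component
from .geometry import (RigidFrame, TORSION_NAMES, TorsionSet,
                       DegenerateGeometryError)
from .model import Assembly, Chain, Monomer

DEFAULT_CLAMP = 10.0  # Angstrom; also the FAPE normalization scale


@dataclass(frozen=True)
class LossWeights:
    """Weighted-sum coefficients; defaults are the training values."""

    w_seq: float = 3.0
    w_6d: float = 1.0
    w_str: float = 10.0
    w_tors: float = 10.0
    w_err: float = 0.1
    w_geom: float = 0.1
    w_lj: float = 0.02
    w_hbond: float = 0.05
    w_pairerr: float = 0.1

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")


BASE_COMPONENTS = ("seq", "six_d", "str", "tors", "err")
FINETUNE_COMPONENTS = BASE_COMPONENTS + ("lj", "hbond", "geom", "pairerr")
_WEIGHT_OF = {"seq": "w_seq", "six_d": "w_6d", "str": "w_str",
              "tors": "w_tors", "err": "w_err", "geom": "w_geom",
              "lj": "w_lj", "hbond": "w_hbond", "pairerr": "w_pairerr"}


@dataclass(frozen=True)
class DistogramSpec:
    """Distance binning; the final bin is the catch-all "no contact" bin."""

    edges: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.edges, float)
        object.__setattr__(self, "edges", e)
        if e.ndim != 1 or len(e) < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("edges must be strictly increasing, length >= 2")

    @classmethod
    def default(cls) -> "DistogramSpec":
        # 36 bins spanning 2-20 A plus the final catch-all: 37 bins total.
        return cls(np.linspace(2.0, 20.0, 37))

    @property
    def n_bins(self) -> int:
        return len(self.edges)            # len-1 in-range bins + catch-all

    def bin_of(self, distance: float) -> int:
        e = self.edges
        if distance < e[0] or distance >= e[-1]:
            return self.n_bins - 1
        return int(np.searchsorted(e, distance, side="right") - 1)


@dataclass
class FrameSet:
    """Rigid frames with the indices of the monomers that own them."""

    frames: list[RigidFrame]
    owners: list[int]

    def __post_init__(self):
        if len(self.frames) != len(self.owners):
            raise ValueError("frames/owners length mismatch")


def _local(frames: FrameSet, points: np.ndarray) -> np.ndarray:
    """(n_frames, n_points, 3) array of points expressed in each frame."""
    R = np.stack([f.rotation for f in frames.frames])          # (F,3,3)
    t = np.stack([f.translation for f in frames.frames])       # (F,3)
    # local = R^T (x - t):  out[f,p,j] = sum_i R[f,i,j] (x - t)[f,p,i]
    return np.einsum("fij,fpi->fpj", R, points[None, :, :] - t[:, None, :])


def fape(pred_frames: FrameSet, pred_points: np.ndarray,
         true_frames: FrameSet, true_points: np.ndarray,
         clamp: float = DEFAULT_CLAMP) -> float:
    """Clamped frame-aligned point error, normalized by the clamp."""
    pred_points = np.asarray(pred_points, float)
    true_points = np.asarray(true_points, float)
    if len(pred_frames.frames) != len(true_frames.frames):
        raise ValueError("prediction and truth have different frame counts")
    if pred_points.shape != true_points.shape:
        raise ValueError("prediction and truth have different point counts")
    if len(pred_frames.frames) == 0 or len(pred_points) == 0:
        raise ValueError("empty frame or point set")
    d = np.linalg.norm(_local(pred_frames, pred_points)
                       - _local(true_frames, true_points), axis=-1)
    return float(np.minimum(d, clamp).mean() / clamp)


def _backbone_frame(mon: Monomer) -> RigidFrame | None:
    from .geometry import phosphate_frame

    if mon.moltype is MolType.PROTEIN:
        n, ca, c = mon.xyz("N"), mon.xyz("CA"), mon.xyz("C")
        if n is None or ca is None or c is None:
            return None
        try:
            return RigidFrame.from_three_atoms(n, ca, c)
        except DegenerateGeometryError:
            return None
    try:
        frame, _ = phosphate_frame(mon)
    except DegenerateGeometryError:
        return None
    return frame


def backbone_frames(assembly: Assembly, include_excluded: bool = False) -> FrameSet:
    """One frame per monomer: N-CA-C for protein, OP1-P-OP2 for nucleic."""
    frames, owners = [], []
    idx = 0
    for _, mon in assembly.monomers():
        if include_excluded or not mon.loss_excluded:
            f = _backbone_frame(mon)
            if f is not None:
                frames.append(f)
                owners.append(idx)
        idx += 1
    return FrameSet(frames, owners)


def _matched_coords(pred: Assembly, true: Assembly,
                    skip_excluded: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Heavy-atom coordinates matched by (chain, monomer, atom name)."""
    ppts, tpts = [], []
    pch = {c.id: c for c in pred.chains}
    for tc in true.chains:
        if tc.id not in pch:
            raise ValueError(f"chain {tc.id} missing from prediction")
        pc = pch[tc.id]
        if len(pc) != len(tc):
            raise ValueError(f"chain {tc.id}: monomer count mismatch")
        for pm, tm in zip(pc, tc):
            if skip_excluded and (pm.loss_excluded or tm.loss_excluded):
                continue
            pmap = {a.name: a.xyz for a in pm.heavy_atoms}
            for a in tm.heavy_atoms:
                if a.name in pmap:
                    ppts.append(pmap[a.name])
                    tpts.append(a.xyz)
    return (np.asarray(ppts, float).reshape(-1, 3),
            np.asarray(tpts, float).reshape(-1, 3))


def backbone_fape(pred: Assembly, true: Assembly,
                  clamp: float = DEFAULT_CLAMP) -> float:
    """FAPE over backbone frames crossed with all matched heavy atoms."""
    pf = backbone_frames(pred)
    tf = backbone_frames(true)
    keep = sorted(set(pf.owners) & set(tf.owners))
    pf = FrameSet([f for f, o in zip(pf.frames, pf.owners) if o in keep],
                  [o for o in pf.owners if o in keep])
    tf = FrameSet([f for f, o in zip(tf.frames, tf.owners) if o in keep],
                  [o for o in tf.owners if o in keep])
    ppts, tpts = _matched_coords(pred, true)
    return fape(pf, ppts, tf, tpts, clamp)


# --- torsion frames -------------------------------------------------------

#: For each named torsion, the frame triple (a, b, c): b and c are the two
#: bonded atoms defining the torsion's rotatable bond and a is a bonded
#: atom closer to the phosphate in the bond graph.  The frame is built by
#: frame_from_three_atoms(a, b, c).  chi entries depend on the base type
#: and are resolved per monomer.  "+" names refer to the next residue.
_TRIPLES = {
    "alpha": ("P", "O5'", "C5'"),
    "beta": ("O5'", "C5'", "C4'"),
    "gamma": ("C5'", "C4'", "C3'"),
    "delta": ("C4'", "C3'", "O3'"),
    "epsilon": ("C3'", "O3'", "P+"),
    "zeta": ("O3'", "P+", "O5'+"),
    "nu0": ("O4'", "C1'", "C2'"),
    "nu1": ("C1'", "C2'", "C3'"),
    "nu2": ("C2'", "C3'", "C4'"),
}


def torsion_frame_triples(residue: str) -> dict[str, tuple[str, str, str]]:
    """Atom triples defining the ten per-torsion frames of one nucleotide."""
    out = dict(_TRIPLES)
    root = GLYCOSIDIC_N[residue]
    out["chi"] = ("C1'", root, "C4" if residue in PURINES else "C2")
    return out


def torsion_frames(mon: Monomer) -> dict[str, RigidFrame | None]:
    """The ten torsion frames of a nucleotide; missing atoms give None.

    Inter-residue atoms (the next residue's phosphate for epsilon/zeta) are
    taken from virtual atoms when present; callers working on chains can
    splice the real neighbour coordinates in as "P+"/"O5'+" entries.
    """
    if not mon.moltype.is_nucleic:
        raise TypeError("torsion_frames expects a nucleotide")
    coords = {a.name: a.xyz for a in mon.atoms}
    residue = mon.name if mon.is_standard else "DA"
    frames: dict[str, RigidFrame | None] = {}
    for tname, (a, b, c) in torsion_frame_triples(residue).items():
        pa, pb, pc = coords.get(a), coords.get(b), coords.get(c)
        if pa is None or pb is None or pc is None:
            frames[tname] = None
            continue
        try:
            frames[tname] = RigidFrame.from_three_atoms(pa, pb, pc)
        except DegenerateGeometryError:
            frames[tname] = None
    return frames


def allatom_frames(assembly: Assembly) -> FrameSet:
    """Union of per-torsion nucleotide frames and protein backbone frames,
    skipping loss-excluded monomers."""
    frames, owners = [], []
    idx = 0
    for chain in assembly.chains:
        for i, mon in enumerate(chain.monomers):
            if not mon.loss_excluded:
                if mon.moltype.is_nucleic:
                    coords = {a.name: a.xyz for a in mon.atoms}
                    if i + 1 < len(chain.monomers):
                        nxt = chain.monomers[i + 1]
                        if nxt.xyz("P") is not None:
                            coords["P+"] = nxt.xyz("P")
                        if nxt.xyz("O5'") is not None:
                            coords["O5'+"] = nxt.xyz("O5'")
                    tmp = Monomer(mon.identity, mon.name, mon.moltype,
                                  [_atom(k, v) for k, v in coords.items()],
                                  mon.seq_index)
                    for f in torsion_frames(tmp).values():
                        if f is not None:
                            frames.append(f)
                            owners.append(idx)
                else:
                    f = _backbone_frame(mon)
                    if f is not None:
                        frames.append(f)
                        owners.append(idx)
            idx += 1
    return FrameSet(frames, owners)


def _atom(name, xyz):
    from .model import Atom

    element = name.rstrip("+'").rstrip("0123456789'")
    return Atom(name, (element[:1] or name[:1]), xyz)


def allatom_fape(pred: Assembly, true: Assembly,
                 clamp: float = DEFAULT_CLAMP, clamped: bool = True) -> float:
    """FAPE over the all-atom frame scheme crossed with all heavy atoms."""
    pf = allatom_frames(pred)
    tf = allatom_frames(true)
    if len(pf.frames) != len(tf.frames):
        raise ValueError("prediction/truth frame sets differ; check that "
                         "the same atoms are present in both")
    ppts, tpts = _matched_coords(pred, true)
    eff_clamp = clamp if clamped else float("inf")
    d = np.linalg.norm(_local(pf, ppts) - _local(tf, tpts), axis=-1)
    return float(np.minimum(d, eff_clamp).mean() / clamp)


# --- scalar losses --------------------------------------------------------

def torsion_loss(pred: list[TorsionSet], true: list[TorsionSet]) -> float:
    """Mean squared error on (sin, cos) pairs over present torsions.

    Periodic by construction: theta and theta + 2*pi are identical, and a
    half-turn error contributes (2 sin)^2 + (2 cos)^2 = 4 for that slot.
    Slots where either side is absent are masked out.
    """
    if len(pred) != len(true):
        raise ValueError("torsion lists differ in length")
    total, count = 0.0, 0
    for p, t in zip(pred, true):
        for name in TORSION_NAMES:
            pv, tv = p.get(name), t.get(name)
            count += 1
            if pv is None or tv is None:
                continue
            total += (math.sin(pv) - math.sin(tv)) ** 2 \
                + (math.cos(pv) - math.cos(tv)) ** 2
    if count == 0:
        warnings.warn("all torsions masked; torsion loss defined as 0")
        return 0.0
    return total / count


def masked_seq_loss(logits: np.ndarray, true_tokens: np.ndarray,
                    mask: np.ndarray, moltypes: list[MolType]) -> float:
    """Cross-entropy of the 32-way token prediction over masked positions.

    Masking is a protein-only training operation; a mask covering a
    nucleotide position is a caller error.
    """
    logits = np.asarray(logits, float)
    true_tokens = np.asarray(true_tokens, int)
    mask = np.asarray(mask, bool)
    if logits.shape != (len(true_tokens), N_TOKENS):
        raise ValueError(f"logits must be (n, {N_TOKENS})")
    for i, m in enumerate(mask):
        if m and moltypes[i] is not MolType.PROTEIN:
            raise ValueError(f"mask covers non-protein position {i}")
    if not mask.any():
        return 0.0
    z = logits[mask]
    z = z - z.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return float(-logp[np.arange(mask.sum()), true_tokens[mask]].mean())


def distogram_loss(pred_probs: np.ndarray, true_dist: np.ndarray,
                   spec: DistogramSpec | None = None,
                   is_negative: bool = False,
                   cross_mask: np.ndarray | None = None) -> float:
    """Cross-entropy of binned pair distances.

    ``pred_probs``: (n, n, B) normalized per pair.  ``true_dist``: (n, n)
    distances.  For negative (non-binding) examples the target for
    cross-complex pairs (``cross_mask``, default all off-diagonal pairs)
    is the final catch-all bin: the model is taught to place all its
    probability mass there.
    """
    spec = spec or DistogramSpec.default()
    pred_probs = np.asarray(pred_probs, float)
    true_dist = np.asarray(true_dist, float)
    n = true_dist.shape[0]
    if pred_probs.shape != (n, n, spec.n_bins):
        raise ValueError("pred_probs shape mismatch")
    sums = pred_probs.sum(axis=-1)
    if np.abs(sums - 1.0).max() > 1e-6:
        raise ValueError("pred_probs rows are not normalized")
    target = np.vectorize(spec.bin_of)(true_dist)
    if is_negative:
        cm = (np.ones((n, n), bool) & ~np.eye(n, dtype=bool)
              if cross_mask is None else np.asarray(cross_mask, bool))
        target = np.where(cm, spec.n_bins - 1, target)
    iu = np.triu_indices(n, k=1)
    p = pred_probs[iu[0], iu[1], target[iu]]
    return float(-np.log(np.clip(p, 1e-30, None)).mean())


def plddt_error_loss(predicted: np.ndarray, actual: np.ndarray) -> float:
    """MSE between predicted and actual per-monomer lDDT, both in [0, 1]."""
    p = np.asarray(predicted, float)
    a = np.asarray(actual, float)
    if p.size == 0:
        raise ValueError("empty lDDT vectors")
    if p.shape != a.shape:
        raise ValueError("shape mismatch")
    if np.any((p < 0) | (p > 1)) or np.any((a < 0) | (a > 1)):
        raise ValueError("lDDT values must lie in [0, 1]")
    return float(((p - a) ** 2).mean())


def pair_error_loss(predicted: np.ndarray, actual: np.ndarray,
                    clamp: float = DEFAULT_CLAMP) -> float:
    """MSE between the predicted pair-error matrix and the clamped actual
    pair errors (clamp shared with FAPE)."""
    p = np.asarray(predicted, float)
    a = np.asarray(actual, float)
    if p.ndim != 2 or p.shape[0] != p.shape[1] or p.shape != a.shape:
        raise ValueError("pair error matrices must be square and matched")
    return float(((p - np.minimum(a, clamp)) ** 2).mean())


def average_over_layers(values: list[float]) -> float:
    """Average of a per-layer loss series (e.g. backbone FAPE over all
    structure layers); inputs are caller-supplied scalars."""
    if not values:
        raise ValueError("no layer values")
    return float(np.mean(values))


def combine_losses(components: dict[str, float],
                   weights: LossWeights | None = None,
                   finetune: bool = False) -> float:
    """Exact weighted sum of loss components.

    Base phase requires seq, six_d, str, tors, err; fine-tuning adds lj,
    hbond, geom, pairerr.  A missing component is an error naming it.
    """
    weights = weights or LossWeights()
    needed = FINETUNE_COMPONENTS if finetune else BASE_COMPONENTS
    missing = [k for k in needed if k not in components]
    if missing:
        raise ValueError(f"missing loss components: {', '.join(missing)}")
    return float(sum(getattr(weights, _WEIGHT_OF[k]) * components[k]
                     for k in needed))
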