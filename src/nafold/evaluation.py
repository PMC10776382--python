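"""Structure and interface accuracy metrics with confidence gating.

Implements the assessment toolbox for predicted protein-nucleic-acid
complexes: superposition-free lDDT, fraction of native contacts (FNAT),
CAPRI interface classification (protein-protein thresholds with the
nucleic acid treated as the ligand), mean interface predicted aligned
error (PAE), and the confidence gates used to select trustworthy models
(mean interface PAE < 10 A; predicted lDDT > 0.9, both strict).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.spatial import cKDTree

from .alphabet import MolType
from .model import Assembly

LDDT_RADIUS = 15.0
LDDT_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)
FNAT_CUTOFF = 5.0
PAE_CONFIDENT = 10.0
PLDDT_CONFIDENT = 0.9


class CapriClass(str, Enum):
    INCORRECT = "incorrect"
    ACCEPTABLE = "acceptable"
    MEDIUM = "medium"
    HIGH = "high"


@dataclass
class PAEMatrix:
    """Predicted aligned errors (Angstrom): entry [i, j] is the expected
    error of monomer j when aligned on monomer i's frame."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("PAE matrix must be square")
        if np.any(v < 0):
            raise ValueError("PAE entries must be non-negative")
        self.values = v

    @classmethod
    def from_json(cls, path) -> "PAEMatrix":
        """Read the documented JSON schema: {"pae": [[...], ...]} or a bare
        nested list."""
        with open(path) as fh:
            obj = json.load(fh)
        if isinstance(obj, dict):
            obj = obj.get("pae", obj.get("predicted_aligned_error"))
        return cls(np.asarray(obj, float))

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class EvalReport:
    lddt: float | None = None
    fnat: float | None = None
    capri_class: CapriClass | None = None
    mean_interface_pae: float | None = None
    plddt: float | None = None
    confident_pae: bool | None = None
    confident_plddt: bool | None = None

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        if self.capri_class is not None:
            d["capri_class"] = self.capri_class.value
        return d


# ---------------------------------------------------------------------------
# lDDT
# ---------------------------------------------------------------------------

def _atom_table(assembly: Assembly):
    xyz, mon_of = [], []
    idx = 0
    for ch in assembly.chains:
        for mon in ch.monomers:
            for a in mon.heavy_atoms:
                xyz.append(a.xyz)
                mon_of.append(idx)
            idx += 1
    return np.asarray(xyz, float).reshape(-1, 3), np.asarray(mon_of)


def lddt(pred: Assembly, ref: Assembly, radius: float = LDDT_RADIUS,
         thresholds=LDDT_THRESHOLDS) -> tuple[float | None, np.ndarray]:
    """Local Distance Difference Test in [0, 1] plus per-monomer values.

    Superposition-free: all heavy-atom pairs of different monomers within
    ``radius`` in the reference are scored by the fraction of the four
    distance thresholds under which the predicted distance error falls.
    Monomers with no reference pairs get NaN; an empty pair set overall
    returns (None, empty).
    """
    pxyz, pmon = _matched_atoms(pred, ref)
    rxyz = pxyz[1]
    pxyz = pxyz[0]
    tree = cKDTree(rxyz)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    pairs = pairs[pmon[pairs[:, 0]] != pmon[pairs[:, 1]]]
    if len(pairs) == 0:
        return None, np.full(int(pmon.max()) + 1 if len(pmon) else 0, np.nan)
    dr = np.linalg.norm(rxyz[pairs[:, 0]] - rxyz[pairs[:, 1]], axis=1)
    dp = np.linalg.norm(pxyz[pairs[:, 0]] - pxyz[pairs[:, 1]], axis=1)
    err = np.abs(dr - dp)
    frac = np.zeros(len(err))
    for t in thresholds:
        frac += (err < t)
    frac /= len(thresholds)
    n_mon = int(pmon.max()) + 1
    per = np.full(n_mon, np.nan)
    num = np.zeros(n_mon)
    den = np.zeros(n_mon)
    for side in (0, 1):
        np.add.at(num, pmon[pairs[:, side]], frac)
        np.add.at(den, pmon[pairs[:, side]], 1.0)
    mask = den > 0
    per[mask] = num[mask] / den[mask]
    return float(frac.mean()), per


def _matched_atoms(pred: Assembly, ref: Assembly):
    """Heavy atoms matched by (chain, monomer index, atom name); returns
    ((pred_xyz, ref_xyz), monomer index array)."""
    p_xyz, r_xyz, mon_of = [], [], []
    pch = {c.id: c for c in pred.chains}
    idx = 0
    for rc in ref.chains:
        if rc.id not in pch:
            raise ValueError(f"chain {rc.id} missing from prediction")
        pc = pch[rc.id]
        if len(pc) != len(rc):
            raise ValueError(f"chain {rc.id}: length mismatch")
        for pm, rm in zip(pc, rc):
            pmap = {a.name: a.xyz for a in pm.heavy_atoms}
            for a in rm.heavy_atoms:
                if a.name in pmap:
                    p_xyz.append(pmap[a.name])
                    r_xyz.append(a.xyz)
                    mon_of.append(idx)
            idx += 1
    return ((np.asarray(p_xyz, float).reshape(-1, 3),
             np.asarray(r_xyz, float).reshape(-1, 3)), np.asarray(mon_of))


# ---------------------------------------------------------------------------
# Interface contacts / FNAT / CAPRI
# ---------------------------------------------------------------------------

def _interface_contacts(assembly: Assembly, cutoff: float = FNAT_CUTOFF) -> set:
    """Residue-nucleotide contact set across the protein-NA interface: any
    heavy-atom pair within ``cutoff``."""
    prot, na = [], []
    for ch in assembly.chains:
        bucket = prot if ch.moltype is MolType.PROTEIN else na
        for i, mon in enumerate(ch.monomers):
            for a in mon.heavy_atoms:
                bucket.append((ch.id, i, a.xyz))
    if not prot or not na:
        return set()
    na_xyz = np.array([x[2] for x in na])
    tree = cKDTree(na_xyz)
    out = set()
    for cid, i, xyz in prot:
        for k in tree.query_ball_point(xyz, cutoff):
            out.add(((cid, i), (na[k][0], na[k][1])))
    return out


def fnat(pred: Assembly, ref: Assembly, cutoff: float = FNAT_CUTOFF) -> float | None:
    """Fraction of the reference's cross-interface residue contacts that
    the prediction reproduces; None when the reference has no contacts."""
    ref_contacts = _interface_contacts(ref, cutoff)
    if not ref_contacts:
        return None
    pred_contacts = _interface_contacts(pred, cutoff)
    return len(ref_contacts & pred_contacts) / len(ref_contacts)


def _kabsch_rmsd(moving: np.ndarray, target: np.ndarray,
                 apply_to: np.ndarray | None = None):
    mc, tc = moving.mean(0), target.mean(0)
    H = (moving - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    apply_to = moving if apply_to is None else apply_to
    moved = (apply_to - mc) @ R.T + tc
    return moved


def _backbone_xyz(assembly: Assembly, chain_ids) -> np.ndarray:
    names_prot = ("N", "CA", "C")
    names_na = ("P", "O5'", "C4'", "C1'", "O3'")
    out = []
    for cid in chain_ids:
        ch = assembly.chain(cid)
        names = names_prot if ch.moltype is MolType.PROTEIN else names_na
        for mon in ch.monomers:
            for n in names:
                x = mon.xyz(n)
                if x is not None:
                    out.append((cid, mon.seq_index, n, x))
    return out


def _paired_backbone(pred, ref, chain_ids):
    rp = {(c, i, n): x for c, i, n, x in _backbone_xyz(ref, chain_ids)}
    pp = {(c, i, n): x for c, i, n, x in _backbone_xyz(pred, chain_ids)}
    keys = [k for k in rp if k in pp]
    return (np.array([pp[k] for k in keys]).reshape(-1, 3),
            np.array([rp[k] for k in keys]).reshape(-1, 3))


def ligand_rmsd(pred: Assembly, ref: Assembly) -> float | None:
    """RMSD of the NA (ligand) backbone after superposing on the protein
    (receptor) backbone."""
    prot = [c.id for c in ref.chains if c.moltype is MolType.PROTEIN]
    na = [c.id for c in ref.chains if c.moltype.is_nucleic]
    if not prot or not na:
        return None
    p_rec, r_rec = _paired_backbone(pred, ref, prot)
    p_lig, r_lig = _paired_backbone(pred, ref, na)
    if len(p_rec) < 3 or len(p_lig) == 0:
        return None
    moved_lig = _kabsch_rmsd(p_rec, r_rec, apply_to=p_lig)
    return float(np.sqrt(((moved_lig - r_lig) ** 2).sum(axis=1).mean()))


def interface_rmsd(pred: Assembly, ref: Assembly, radius: float = 10.0) -> float | None:
    """Backbone RMSD over interface monomers (within ``radius`` of the
    other molecule type in the reference), superposed on themselves."""
    contacts = _interface_contacts(ref, radius)
    if not contacts:
        return None
    iface = {m for pair in contacts for m in pair}
    rp, pp = [], []
    for cid, i in sorted(iface):
        ch_r = ref.chain(cid)
        ch_p = pred.chain(cid)
        names = ("N", "CA", "C") if ch_r.moltype is MolType.PROTEIN \
            else ("P", "O5'", "C4'", "C1'", "O3'")
        for n in names:
            xr = ch_r.monomers[i].xyz(n)
            xp = ch_p.monomers[i].xyz(n)
            if xr is not None and xp is not None:
                rp.append(xr)
                pp.append(xp)
    if len(rp) < 3:
        return None
    rp, pp = np.array(rp), np.array(pp)
    moved = _kabsch_rmsd(pp, rp)
    return float(np.sqrt(((moved - rp) ** 2).sum(axis=1).mean()))


def capri_class_from_metrics(fnat_value: float, lrms: float | None,
                             irms: float | None) -> CapriClass:
    """The standard CAPRI threshold table (protein-protein criteria, the
    nucleic acid treated as the ligand)."""
    lrms = math.inf if lrms is None else lrms
    irms = math.inf if irms is None else irms
    if fnat_value >= 0.5 and (lrms <= 1.0 or irms <= 1.0):
        return CapriClass.HIGH
    if fnat_value >= 0.3 and (lrms <= 5.0 or irms <= 2.0):
        return CapriClass.MEDIUM
    if fnat_value >= 0.1 and (lrms <= 10.0 or irms <= 4.0):
        return CapriClass.ACCEPTABLE
    return CapriClass.INCORRECT


def capri_rank(pred: Assembly, ref: Assembly,
               fnat_value: float | None = None) -> CapriClass:
    """CAPRI quality class of a predicted complex against its reference."""
    f = fnat(pred, ref) if fnat_value is None else fnat_value
    if f is None:
        raise ValueError("reference has no interface contacts")
    return capri_class_from_metrics(f, ligand_rmsd(pred, ref),
                                    interface_rmsd(pred, ref))


# ---------------------------------------------------------------------------
# PAE / confidence
# ---------------------------------------------------------------------------

def mean_interface_pae(pae: PAEMatrix, assembly: Assembly,
                       symmetric: bool = True) -> float | None:
    """Mean PAE over protein<->NA monomer pairs, averaged over both
    orientations (i on j and j on i); None when there is no interface."""
    if len(pae) != assembly.n_monomers:
        raise ValueError("PAE size does not match assembly")
    kinds = []
    for ch in assembly.chains:
        kinds.extend([ch.moltype.is_nucleic] * len(ch.monomers))
    kinds = np.asarray(kinds)
    prot = np.where(~kinds)[0]
    na = np.where(kinds)[0]
    if len(prot) == 0 or len(na) == 0:
        return None
    v = pae.values
    cross = v[np.ix_(prot, na)]
    if symmetric:
        cross = np.concatenate([cross.ravel(), v[np.ix_(na, prot)].ravel()])
    return float(np.mean(cross))


def confidence_flags(mean_pae: float | None = None,
                     plddt: float | None = None) -> dict[str, bool | None]:
    """Strict confidence gates: PAE < 10 A; plDDT > 0.9."""
    return {
        "confident_pae": None if mean_pae is None else bool(mean_pae < PAE_CONFIDENT),
        "confident_plddt": None if plddt is None else bool(plddt > PLDDT_CONFIDENT),
    }


def evaluate_complex(pred: Assembly, ref: Assembly,
                     pae: PAEMatrix | None = None,
                     plddt: float | None = None) -> EvalReport:
    """Full report for one predicted-vs-reference complex."""
    global_lddt, _ = lddt(pred, ref)
    f = fnat(pred, ref)
    rep = EvalReport(lddt=global_lddt, fnat=f, plddt=plddt)
    if f is not None:
        rep.capri_class = capri_rank(pred, ref, fnat_value=f)
    if pae is not None:
        rep.mean_interface_pae = mean_interface_pae(pae, pred)
    flags = confidence_flags(rep.mean_interface_pae, plddt)
    rep.confident_pae = flags["confident_pae"]
    rep.confident_plddt = flags["confident_plddt"]
    return rep


# ---------------------------------------------------------------------------
# Binding specificity
# ---------------------------------------------------------------------------

def specificity_compare(binding_scores, nonbinding_scores) -> dict:
    """Separation between interface-PAE scores of binding and nonbinding
    DNA sequences for one protein.

    Lower PAE = more confident binding, so a discriminating model scores
    binding sequences below nonbinding ones.  The rank statistic is the
    fraction of (binding, nonbinding) pairs with binding < nonbinding
    (ties count half) — the Mann-Whitney U statistic normalized to [0, 1].
    """
    b = np.asarray(list(binding_scores), float)
    n = np.asarray(list(nonbinding_scores), float)
    if b.size == 0 or n.size == 0:
        raise ValueError("both score lists must be non-empty")
    wins = sum((bi < ni) + 0.5 * (bi == ni) for bi in b for ni in n)
    auc = float(wins / (b.size * n.size))
    return {
        "mean_difference": float(n.mean() - b.mean()),
        "rank_separation": auc,
        "discriminates": bool(b.mean() < n.mean()),
    }


def batch_evaluate(pairs, pae_paths=None) -> "object":
    """Evaluate a list of (pred, ref) assemblies; returns a DataFrame with
    one row per complex (lddt, fnat, capri, pae, flags)."""
    import pandas as pd

    rows = []
    pae_paths = pae_paths or [None] * len(pairs)
    for (pred, ref), pae_path in zip(pairs, pae_paths):
        pae = PAEMatrix.from_json(pae_path) if pae_path else None
        rep = evaluate_complex(pred, ref, pae=pae)
        rows.append(rep.as_dict())
    return pd.DataFrame(rows)
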