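# Methods

This note records the model, the parameter choices, and the scope of
the synthetic data used throughout the package. Every quantitative
statement here is either a definition or a quantity computed by the
test suite or by `scripts/acceptance.py`.

## 1. Frames and torsions

**Rigid frames.** A frame is built from three atoms (a, b, c) by
Gram–Schmidt: the origin is b, the x axis points from b toward c, the
y axis is the component of a − b orthogonal to x, and z = x × y.
Nucleotide frames use (OP1, P, OP2); protein frames use (N, CA, C).
Frames compose and invert exactly; `RigidFrame.from_three_atoms` on
rebuilt coordinates recovers the generating frame to ~1e-15 (see
`geometry_roundtrip_max_frame_error` in the acceptance output).

**Torsion set.** Each nucleotide carries ten named torsions:
α (O3′⁻–P–O5′–C5′), β, γ, δ along the backbone, ε and ζ which place
the *next* phosphate, the sugar ring angles ν0, ν1, ν2, and the
glycosidic χ. Dihedrals follow the IUPAC sign convention (verified
against an independent library implementation). α of residue i needs
O3′ of residue i − 1; ε/ζ of residue i place virtual atoms
(P⁺, O5′⁺, OP1⁺, OP2⁺) that become the next residue's phosphate
group, so a chain is built 5′→3′ by handing each frame to its
successor.

**All-atom reconstruction.** Atoms are placed by internal-coordinate
(NeRF) chaining from the frame atoms using ideal bond lengths and
angles taken from chemical-component templates. Sugar and backbone
geometry is taken from one reference residue per family (DA for DNA,
A for RNA) so that chain propagation under uniform torsions is exactly
residue-independent; base geometry is per-residue.

**Ring closure.** With bond lengths and angles held rigid, the
five-membered furanose ring has only two internal torsional degrees of
freedom, so the triple (ν0, ν1, ν2) is in general not exactly
realizable. The ring is entered through O4′ and C1′, whose two
placement dihedrals are solved (analytically where a root exists, by
prior-weighted least squares otherwise); C2′ is then placed directly
by ν0 and the residual C2′–C3′ bond-closure deviation is reported
(`ring_closure_deviation`). `closed_ring_torsions` projects an
arbitrary (ν0, ν1, ν2) onto the realizable manifold, and
`random_torsion_set` samples from it, which is why build → measure
round trips close to machine precision (worst torsion error ~4e-15
rad over 400 random sets per acceptance run) with closure deviations
below 4e-4 Å.

**Canonical phosphate.** The (P, OP1, OP2, O5′, O3′⁻) group placed by
the frame uses a single canonical geometry (P–O3′ 1.607 Å, P–O5′
1.593 Å, P–OP 1.485 Å; O3′–P–O5′ 104.0°, OP–P–OP 119.6°, C3′–O3′–P
119.7°), with chirality anchored to the DA component template. The
free-acid phosphates in component templates are mutually inconsistent
(one is mirrored), so a shared canonical group is used for all eight
standard nucleotides.

**Sugar pucker.** `pucker_to_nu` / `pseudorotation_phase` convert
between (ν0, ν1, ν2) and the pseudorotation phase/amplitude
description (C2′-endo ≈ 155–160° for B-DNA, C3′-endo ≈ 15–20° for
A-RNA).

## 2. Synthetic structures

**Ideal helices.** A duplex strand is generated by applying powers of
a single screw motion S to a reference-residue frame; the second
strand is placed by a dyad D (a two-fold rotation about an axis
perpendicular to and intersecting the helix axis) chosen so that
D S D⁻¹ = S⁻¹, which makes the two strands exactly antiparallel
copies. The free parameters — seven backbone/glycosidic torsions,
three ring torsions, and the dyad's phase and axial offset — are
refined once per family (`scripts/refine_helix_params.py`) by
multi-start least squares against: fiber twist and rise (B: 36.0°,
3.38 Å; A: 32.7°, 2.81 Å), the five canonical Watson–Crick
donor–acceptor distances (G:C — O6–N4 2.91, N1–N3 2.95, N2–O2 2.86 Å;
A:T/U — N6–O4 2.95, N1–N3 2.82 Å), C1′–C1′ span 10.44 Å, λ angles
54.5°, base-pair coplanarity, donor-hydrogen alignment (the ideal N–H
direction must point at the acceptor), ring closure, and — for B-form
only — a flat-bottomed pull keeping the pair centroid within 0.5 Å of
the helix axis. The refined values are frozen in
`src/nafold/data/helix_params.json` (B: twist 36.001°, rise 3.3954 Å;
A: 32.700°, 2.8099 Å) and the generators read them; regenerating is
deterministic given the seed.

**Other generators.** `gen_hairpin_rna` closes a single-stranded loop
over an A-form stem by least-squares loop closure on backbone-only
builds. `gen_toy_protein` builds an ideal α-helix (φ = −57°,
ψ = −47°, ω = 180°) with N, CA, C, O, CB. `gen_toy_complex` poses a
toy protein against a duplex so that the number of Cα/NA-heavy-atom
contacts at 7 Å is *exactly* a requested target (verified brute-force
at construction). `gen_basecontact_complex` poses residues against
major-groove base atoms to create base-specific contacts at 3.4 Å.
`perturb` supplies Gaussian-noise, rigid-motion, and interface-shift
decoys; `extend_duplex` grows a duplex by superposing ideal padding
onto the terminal step.

These ideal structures are the study conditions: all thresholds are
exercised at their stated values on geometry that either satisfies
them exactly or misses them decisively. No experimental structures
are included.

## 3. Losses

**FAPE.** For frame set {F_i} and matched atom sets {x_j},
FAPE = mean_{i,j} min(‖F_i⁻¹ x_j^pred − F_i⁻¹ x_j^true‖, 10 Å) / 10 Å.
The backbone variant uses one frame per monomer (phosphate or N-CA-C);
the all-atom variant adds per-torsion frames (one rigid frame per
torsion-defined atom group). Both match a double-loop reference
implementation to ~1e-15 and are invariant to rigid motion of either
argument (acceptance: `backbone_fape_vs_oracle_max_abs_diff`).

**Other terms.** Torsion loss is the mean squared error of (sin, cos)
pairs over predicted torsion slots. Masked-sequence loss is a
cross-entropy over a 32-token alphabet (20 amino acids + X + mask +
4 DNA + 4 RNA + 2 unknown-nucleotide tokens), masked to protein
positions. The distogram uses 37 bins from 2 to 20 Å plus a catch-all
final bin; in negative examples the nucleic contacts are pushed to the
final bin. Error-prediction losses (per-residue and pairwise) are MSE
against actual errors clamped at 10 Å.

**Aggregation.** Weights are seq 3.0, 2D-distribution 1.0, structure
(FAPE) 10.0, torsion 10.0, error 0.1; fine-tuning adds LJ 0.1, H-bond
0.02, linkage geometry 0.05, pairwise error 0.1. Unit components
therefore sum to 24.1 (base) and 24.37 (fine-tune), which
`combine_losses` reproduces exactly.

## 4. Physics terms

**Lennard-Jones.** 12-6 with per-element parameters (rmin/2, ε in
kcal/mol: C 1.90/0.08, N 1.80/0.17, O 1.70/0.16, P 2.10/0.40,
S 2.00/0.45, H 0.90/0.02), a linear ramp below 0.6·rmin to keep
gradients bounded, a cubic switch from 5.0 to 6.0 Å, and exclusions
for atom pairs within the same monomer or separated by ≤ 3 bonds
across a linkage. The pair minimum is exactly −ε at rmin.

**Hydrogen bonds.** Polar hydrogens are placed by superposing the
component-template neighborhood of each donor (Kabsch). The energy
is −ε_hb · F_dist(d_HA) · F_ang(cos θ_DHA)² · F_base, with the
distance factor optimal at 1.9 Å and vanishing at 3.0 Å, the angular
factor favouring linear D–H···A, and a ramp on the base angle.

**Linkage geometry.** Flat-bottomed penalties on the phosphodiester
connection (O3′–P bond 1.607 Å; angles C3′–O3′–P 119.7°, O3′–P–O5′
104.0°) and the peptide bond (C–N 1.329 Å; CA–C–N 116.2°, C–N–CA
121.7°): zero within ±0.02 Å / ±3°, then linear with unit slope per Å
and per degree. Connections stretched beyond twice the ideal bond
length are treated as chain breaks and skipped. Generated ideal
structures score exactly zero.

## 5. Curation rules

**Hydrogen-bond counting.** A donor–acceptor pair counts if the
heavy-atom distance is ≤ 3.5 Å and the D–H···A angle over ideally
placed hydrogens is ≥ 120°, with each hydrogen donating to at most
one acceptor (the best-angle one). This last rule prevents one amide
hydrogen from being counted toward two nearby acceptors; without it an
ideal 10-bp G:C duplex counts 40 "bonds" instead of the canonical 30.

**Watson–Crick pairs** require complementary identities, ≥ 2 hydrogen
bonds under the rule above, and antiparallel backbone directions as
projected onto the base-pair normal (a projection-free test fails for
inclined A-form backbones). Same-chain pairs are accepted when
separated by more than two positions (hairpin stems).

**Thresholds.** A duplex requires ≥ 10 inter-strand hydrogen bonds. A
protein chain interacts with a nucleic-acid unit when strictly more
than 16 Cα-to-heavy-atom contacts exist at 7 Å. Base-specific
contacts are protein-heavy-atom-to-nucleobase contacts at 3.4 Å, with
≥ 3 required for padding/negative eligibility.

**Padding** draws two independent lengths uniformly from {0, …, 6}
and extends bound double-stranded DNA with ideal, loss-excluded base
pairs. **Negatives** mutate every base-specifically contacted
nucleotide to a uniformly random different base, mutating Watson–Crick
partners to maintain complementarity. **Clustering** is greedy on
pairwise sequence identity (matches / shorter length) at 80%.

**Cropping.** Monomers are nodes; edges are sequential neighbours
(weight 1), Watson–Crick pairs (weight 0), and — for positives —
Cα–P pairs under 12 Å (weight 0). A random interface edge seeds a
multi-source Dijkstra; the 256 lowest-cost nodes are kept, ties broken
by (cost, chain id, sequence index). The acceptance script checks
agreement with an independent `scipy` Dijkstra implementation on
complexes of 300–600 monomers.

## 6. Evaluation

lDDT uses a 15 Å inclusion radius and thresholds {0.5, 1, 2, 4} Å and
is superposition-free. FNAT counts preserved residue-level interface
contacts at 5 Å over heavy atoms. CAPRI classes follow the standard
FNAT / ligand-RMSD / interface-RMSD table; RMSDs superpose on the
protein (Kabsch) and measure the nucleic backbone. Mean interface PAE
symmetrizes the off-diagonal inter-molecule blocks. Confidence gates
are strict: mean interface PAE < 10 Å, plDDT > 0.9.

## 7. Numerical choices and limitations

- All dihedral/placement math is float64; scalar fast paths mirror the
  vectorized routines exactly.
- Ring solving caches solutions keyed by torsion values rounded to
  10 decimals and pre-seeds the achieved values, so build → extract →
  rebuild cycles are idempotent.
- Determinism: all stochastic operators take an explicit
  `numpy.random.Generator`; no global seeding.
- The package contains no neural network, no MSA search, and no folding
  engine; it is the deterministic substrate such a system would train
  and evaluate against.
- Synthetic structures are ideal by construction. Thresholded rules
  are validated at exact boundary cases (16 vs 17 contacts, 8 vs 30
  hydrogen bonds), not on experimental distributions.
- The DT component template's free-acid phosphate is mirrored relative
  to the other templates; the shared canonical phosphate sidesteps
  this, at the cost of not reproducing each template's own phosphate
  verbatim (backbone rebuild fidelity is asserted through the torsion
  round trip instead).
- Problem sizes: geometry round trips run 400–500 random torsion sets
  across all 8 nucleotides; crops are validated on 50 complexes of
  300–600 monomers in the tests and 10 in the acceptance script;
  padding uniformity uses 10,000 draws.
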