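"""Physics scoring terms: Lennard-Jones, hydrogen bonds, linkage geometry.

The LJ pair term has its minimum of -epsilon at the sum of half-radii
and is switched off smoothly before the cutoff. The H-bond term scores
ideal Watson-Crick donor-acceptor pairs favourably. The linkage term is
a flat-bottomed penalty on backbone-connection bonds and angles.
"""

from nafold.energies import (add_polar_hydrogens, hbond_energy, hbond_pairs,
                             linkage_geom_penalty, lj_pair, lj_params)
from nafold.fixtures import gen_bform_dna

p = lj_params()["C"]
rmin = 2 * p["rmin_half"]
print(f"LJ C-C at rmin={rmin:.2f} A: {lj_pair(rmin, 'C', 'C'):+.3f} "
      f"(epsilon = {p['epsilon']})")
print(f"LJ C-C at 7.0 A (past cutoff): {lj_pair(7.0, 'C', 'C'):+.3f}")

gc = add_polar_hydrogens(gen_bform_dna("GC"))
print(f"H-bond energy of a G:C dimer duplex: {hbond_energy(gc):+.4f}")
wc = {(c['donor'], c['acceptor'], round(c['d_ha'], 2))
      for c in hbond_pairs(gc)
      if (c['donor'], c['acceptor']) in
      {("N1", "N3"), ("N2", "O2"), ("N4", "O6")} and c['d_ha'] < 2.6}
for d, a, dist in sorted(wc):
    print(f"  WC donor {d} -> acceptor {a}: H...A {dist:.2f} A")

print(f"linkage penalty, ideal duplex: "
      f"{linkage_geom_penalty(gen_bform_dna('GCGC')):.1f}")
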