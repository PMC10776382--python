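"""Generate ideal nucleic-acid duplexes and check their geometry.

Duplexes are built as exact helices (every inter-residue step is the
same screw motion); the second strand is placed by a dyad so the two
strands are related by a two-fold rotation, as in fiber-diffraction
models. The curation detectors then recover the expected base pairing.
"""

import numpy as np

from nafold.curation import count_interchain_hbonds, detect_wc_pairs, find_duplexes
from nafold.energies import linkage_geom_penalty
from nafold.fixtures import (family_screw, gen_aform_rna, gen_bform_dna,
                             gen_hairpin_rna, screw_parameters)

for fam, asm, n in (("B", gen_bform_dna("GCGCGCGCGC"), 10),
                    ("A", gen_aform_rna("GGCCAAUU"), 8)):
    S, _ = family_screw(fam)
    twist, _, rise, _ = screw_parameters(S)
    pairs = detect_wc_pairs(asm)
    hb = count_interchain_hbonds(asm, "A", "B")
    print(f"{fam}-form {n}-mer: twist {np.degrees(twist):.2f} deg, "
          f"rise {rise:.3f} A, {len(pairs)} WC pairs, {hb} H-bonds, "
          f"duplex={find_duplexes(asm)}, "
          f"linkage penalty {linkage_geom_penalty(asm):.1f}")

h = gen_hairpin_rna("GGCGGC", 4)
print(f"hairpin (stem 6 + loop 4): {len(detect_wc_pairs(h))} stem pairs, "
      f"linkage penalty {linkage_geom_penalty(h):.1e}")
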