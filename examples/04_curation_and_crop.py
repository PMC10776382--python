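"""Dataset-curation operators: interaction rules, negatives, cropping.

A protein chain "interacts" with a nucleic-acid unit when strictly more
than 16 C-alpha/heavy-atom contacts exist at 7 A. Negatives mutate every
base-specifically contacted nucleotide (and its Watson-Crick partner).
Crops grow outward from a random interface edge by graph distance.
"""

import numpy as np

from nafold.curation import (build_crop_graph, count_ca_contacts, crop,
                             find_interacting_pairs, make_negative)
from nafold.fixtures import gen_basecontact_complex, gen_toy_complex

rng = np.random.default_rng(4)
for target in (16, 17):
    rec = gen_toy_complex(target, rng)
    n = count_ca_contacts(rec.assembly, "P", ("A", "B"))
    print(f"complex with {n} contacts -> interacting: "
          f"{bool(find_interacting_pairs(rec.assembly))}")

rec = gen_basecontact_complex(np.random.default_rng(31))
neg = make_negative(rec, rng)
changed = sum(a.name != b.name
              for ca, cb in zip(rec.assembly.chains, neg.assembly.chains)
              for a, b in zip(ca.monomers, cb.monomers))
contacted = {(c["na_chain"], c["nucleotide"]) for c in rec.base_contacts}
print(f"negative example: {len(contacted)} contacted bases, "
      f"{changed} nucleotides mutated (contacts + WC partners)")

big = gen_toy_complex(20, rng, protein_len=250, dna_len=100)
graph = build_crop_graph(big, rng)
sel = crop(graph, 256, rng)
print(f"crop: {big.assembly.n_monomers} monomers -> {len(sel)} kept, "
      f"seed edge {graph.seed_edge} included: "
      f"{set(graph.seed_edge) <= set(sel)}")
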