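"""Dataset-curation operators: pairing, thresholds, padding, negatives,
clustering and the crop graph."""

import numpy as np
import pytest
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from nafold.alphabet import MolType
from nafold.chem import WC_COMPLEMENT
from nafold.curation import (ComplexRecord, build_crop_graph,
                             base_specific_contacts, cluster_by_identity,
                             count_ca_contacts, count_interchain_hbonds,
                             crop, detect_wc_pairs, draw_pad_lengths,
                             find_duplexes, find_interacting_pairs,
                             make_negative, pad_dna_ends, sequence_identity)
from nafold.fixtures import gen_bform_dna, gen_toy_complex, gen_toy_protein
from nafold.model import Assembly


# ---------------------------------------------------------------------------
# Watson-Crick pairs and duplexes
# ---------------------------------------------------------------------------

def test_ideal_duplex_all_positions_pair(gc_duplex):
    pairs = detect_wc_pairs(gc_duplex)
    assert len(pairs) == 10
    assert all(p.watson_crick for p in pairs)
    # G:C pairs carry three hydrogen bonds each
    assert all(p.n_hbonds == 3 for p in pairs)


def test_single_strand_has_no_pairs(gc_duplex):
    single = Assembly([gc_duplex.copy().chains[0]])
    assert detect_wc_pairs(single) == []


def test_mismatched_position_drops_one_pair():
    from nafold.curation import mutate_nucleotide

    asm = gen_bform_dna("GCGCGCGCGC")
    # engineer a mismatch: G -> A against C (not complementary)
    mutate_nucleotide(asm.chains[0].monomers[4], "DA")
    assert len(detect_wc_pairs(asm)) == 9


def test_duplex_rule_hydrogen_bond_threshold(gc_duplex):
    # 10 GC pairs -> 30 hydrogen bonds: a duplex
    assert count_interchain_hbonds(gc_duplex, "A", "B") == 30
    assert find_duplexes(gc_duplex) == [("A", "B")]
    # 4 AT pairs -> 8 bonds < 10: not a duplex
    at = gen_bform_dna("ATAT")
    assert count_interchain_hbonds(at, "A", "B") == 8
    assert find_duplexes(at) == []


def test_far_apart_strands_are_not_a_duplex(gc_duplex):
    moved = gc_duplex.copy()
    for m in moved.chains[1]:
        for a in m.atoms:
            a.xyz = a.xyz + 100.0
    assert find_duplexes(moved) == []


def test_duplex_detection_symmetric_in_chain_order(gc_duplex):
    flipped = Assembly([gc_duplex.copy().chains[1], gc_duplex.copy().chains[0]])
    assert find_duplexes(flipped) == [("A", "B")]


# ---------------------------------------------------------------------------
# Interaction rule (7 A / >16 contacts)
# ---------------------------------------------------------------------------

def brute_force_ca_contacts(assembly, protein_chain, na_chains, radius=7.0):
    count = 0
    prot = assembly.chain(protein_chain)
    for mon in prot:
        ca = mon.xyz("CA")
        if ca is None:
            continue
        for cid in na_chains:
            for nm in assembly.chain(cid):
                for a in nm.heavy_atoms:
                    if np.linalg.norm(a.xyz - ca) <= radius:
                        count += 1
    return count


@pytest.mark.parametrize("target,expect_interacting", [(17, True), (16, False)])
def test_contact_threshold_is_strictly_more_than_16(target, expect_interacting):
    rec = gen_toy_complex(target, np.random.default_rng(100 + target))
    unit = ("A", "B")
    got = count_ca_contacts(rec.assembly, "P", unit)
    brute = brute_force_ca_contacts(rec.assembly, "P", unit)
    assert got == brute == target
    assert bool(rec.interacting) is expect_interacting


def test_far_protein_not_interacting():
    rec = gen_toy_complex(0, np.random.default_rng(3))
    assert rec.interacting == []
    assert find_interacting_pairs(rec.assembly) == []


# ---------------------------------------------------------------------------
# Base-specific contacts
# ---------------------------------------------------------------------------

def test_engineered_base_contacts_detected(basecontact_record):
    contacts = basecontact_record.base_contacts
    assert len({(c["na_chain"], c["nucleotide"]) for c in contacts}) >= 3
    assert all(c["distance"] <= 3.4 for c in contacts)


def test_backbone_only_approach_gives_no_base_contacts(gc_duplex):
    # protein posed against the phosphate backbone from outside the helix:
    # near the phosphates but > 3.4 A from every base atom
    from nafold.chem import base_atoms

    prot = gen_toy_protein("A")
    p_xyz = gc_duplex.chains[0].monomers[5].xyz("P")
    center = gc_duplex.coords().mean(axis=0)
    outward = (p_xyz - center) / np.linalg.norm(p_xyz - center)
    target = p_xyz + 3.0 * outward
    delta = target - prot.chains[0].monomers[0].xyz("CB")
    prot = prot.transformed(np.eye(3), delta)
    # precondition: the pose really is backbone-only
    base_xyz = np.array([m.xyz(n) for c in gc_duplex.chains for m in c
                         for n in base_atoms(m.name)])
    prot_xyz = prot.coords()
    dmin = np.sqrt(((prot_xyz[:, None, :] - base_xyz[None, :, :]) ** 2
                    ).sum(-1)).min()
    assert dmin > 3.4
    asm = Assembly(gc_duplex.copy().chains + prot.chains)
    assert base_specific_contacts(asm) == []


# ---------------------------------------------------------------------------
# Padding
# ---------------------------------------------------------------------------

def test_pad_lengths_uniform_on_0_to_6():
    from scipy.stats import chisquare

    rng = np.random.default_rng(42)
    draws = [d for _ in range(5000) for d in draw_pad_lengths(rng)]
    counts = np.bincount(draws, minlength=7)
    assert len(counts) == 7
    _, p = chisquare(counts)
    assert p > 0.001


def test_pad_zero_draw_leaves_structure_unchanged(basecontact_record):
    class ZeroRng:
        def integers(self, lo, hi):
            return 0

        def choice(self, seq, size=None):
            return np.array(list(seq))[:size]

    out = pad_dna_ends(basecontact_record, ZeroRng())
    assert out.assembly.n_monomers == basecontact_record.assembly.n_monomers


def test_pad_adds_excluded_ideal_pairs(basecontact_record):
    rng = np.random.default_rng(8)
    out = pad_dna_ends(basecontact_record, rng)
    added = out.assembly.n_monomers - basecontact_record.assembly.n_monomers
    assert added % 2 == 0
    excluded = [m for _, m in out.assembly.monomers() if m.loss_excluded]
    assert len(excluded) == added
    if added:
        # padding extends the duplex with detectable WC pairs
        before = len(detect_wc_pairs(basecontact_record.assembly))
        after = len(detect_wc_pairs(out.assembly))
        assert after == before + added // 2


def test_pad_ineligible_complex_is_noop():
    rec = gen_toy_complex(0, np.random.default_rng(5))
    with pytest.warns(UserWarning):
        out = pad_dna_ends(rec, np.random.default_rng(1))
    assert out.assembly.n_monomers == rec.assembly.n_monomers


# ---------------------------------------------------------------------------
# Negatives
# ---------------------------------------------------------------------------

def _names(assembly):
    return {(c.id, i): m.name for c in assembly.chains
            for i, m in enumerate(c.monomers)}


def test_make_negative_contract(basecontact_record):
    rec = basecontact_record
    rng = np.random.default_rng(9)
    neg = make_negative(rec, rng)
    assert neg.is_negative
    before, after = _names(rec.assembly), _names(neg.assembly)
    contacted = {(c["na_chain"], c["nucleotide"]) for c in rec.base_contacts}
    wc_before = {}
    for bp in detect_wc_pairs(rec.assembly):
        wc_before[(bp.chain_a, bp.index_a)] = (bp.chain_b, bp.index_b)
        wc_before[(bp.chain_b, bp.index_b)] = (bp.chain_a, bp.index_a)
    changed = {k for k in before if before[k] != after[k]}
    # every contacted base changed identity
    assert contacted <= changed
    # originally-WC pairs remain complementary after mutation
    for k, partner in wc_before.items():
        assert WC_COMPLEMENT[after[k]] == after[partner]
    # nothing outside contacted bases and their partners changed
    allowed = contacted | {wc_before[k] for k in contacted if k in wc_before}
    assert changed <= allowed


def test_repeated_negatives_always_mutate_away_from_current(basecontact_record):
    # mutation excludes the current identity, so each application changes
    # every contacted base relative to its immediate predecessor
    rec = basecontact_record
    neg1 = make_negative(rec, np.random.default_rng(10))
    neg2 = make_negative(neg1, np.random.default_rng(11))
    before = _names(rec.assembly)
    mid = _names(neg1.assembly)
    after = _names(neg2.assembly)
    for c in rec.base_contacts:
        k = (c["na_chain"], c["nucleotide"])
        assert mid[k] != before[k]
    for c in neg1.base_contacts:
        k = (c["na_chain"], c["nucleotide"])
        assert after[k] != mid[k]


def test_make_negative_requires_eligibility():
    rec = gen_toy_complex(0, np.random.default_rng(6))
    with pytest.raises(ValueError):
        make_negative(rec, np.random.default_rng(1))


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def test_identical_sequences_one_cluster():
    assign = cluster_by_identity(["ACGUACGU"] * 4)
    assert len(set(assign)) == 1


def test_random_sequences_split_at_80_percent(rng):
    a = "".join(rng.choice(list("ACGU"), size=100))
    b = "".join(rng.choice(list("ACGU"), size=100))
    ident = sequence_identity(a, b)
    assert ident < 0.8                    # random identity ~ 25-40%
    assert len(set(cluster_by_identity([a, b]))) == 2


def test_greedy_clustering_is_not_transitive():
    # A ~ B and B ~ C at 80% but A !~ C: with B as the representative all
    # three join one cluster even though A vs C alone would split.
    b = "ACGUAGCUAGGCAUCGAUGC"             # longest: becomes representative
    a = b[:16]                             # identity 1.0 over the shorter
    c = b[4:]                              # identity 1.0 over the shorter
    assert sequence_identity(a, b) >= 0.8
    assert sequence_identity(c, b) >= 0.8
    assert sequence_identity(a, c) < 0.8
    assign = cluster_by_identity([a, b, c])
    assert assign[0] == assign[1] == assign[2]


# ---------------------------------------------------------------------------
# Crop graph
# ---------------------------------------------------------------------------

def brute_force_crop(graph, size):
    """Independent Dijkstra (scipy csgraph) + the documented tie rule."""
    n = graph.n_nodes
    rows, cols, vals = [], [], []
    for a, b, w in graph.edges:
        rows += [a, b]
        cols += [b, a]
        vals += [w + 1e-12, w + 1e-12]     # csgraph drops explicit zeros
    mat = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    sources = list(graph.seed_edge) if graph.seed_edge is not None \
        else [graph.seed_node]
    dist = dijkstra(mat, directed=False, indices=sources).min(axis=0)
    eps = 1e-6
    order = sorted(range(n), key=lambda i: (round(dist[i] / eps) * eps
                                            if np.isfinite(dist[i]) else np.inf,
                                            graph.meta[i][0], graph.meta[i][1]))
    order = [i for i in order if np.isfinite(dist[i])]
    return sorted(order[:size])


def test_crop_graph_edge_weight_audit(basecontact_record):
    rng = np.random.default_rng(12)
    graph = build_crop_graph(basecontact_record, rng)
    ass = basecontact_record.assembly
    gidx = {}
    k = 0
    for ch in ass.chains:
        for i in range(len(ch.monomers)):
            gidx[(ch.id, i)] = k
            k += 1
    weights = {}
    for a, b, w in graph.edges:
        weights[frozenset((a, b))] = min(w, weights.get(frozenset((a, b)), 1))
    # sequential edges weight 1
    for ch in ass.chains:
        for i in range(len(ch.monomers) - 1):
            key = frozenset((gidx[(ch.id, i)], gidx[(ch.id, i + 1)]))
            assert weights[key] == 1.0
    # WC edges weight 0
    for bp in detect_wc_pairs(ass):
        key = frozenset((gidx[(bp.chain_a, bp.index_a)],
                         gidx[(bp.chain_b, bp.index_b)]))
        assert weights[key] == 0.0
    # Calpha-P proximity edges weight 0 (brute-force scan)
    for ch in ass.chains:
        if ch.moltype is not MolType.PROTEIN:
            continue
        for i, m in enumerate(ch.monomers):
            ca = m.xyz("CA")
            for nch in ass.chains:
                if not nch.moltype.is_nucleic:
                    continue
                for j, nm in enumerate(nch.monomers):
                    p = nm.xyz("P")
                    if p is not None and np.linalg.norm(ca - p) < 12.0:
                        key = frozenset((gidx[(ch.id, i)], gidx[(nch.id, j)]))
                        assert weights.get(key) == 0.0


def test_negative_complex_gets_single_random_cross_edge(basecontact_record):
    neg = make_negative(basecontact_record, np.random.default_rng(13))
    graph = build_crop_graph(neg, np.random.default_rng(14))
    ass = neg.assembly
    kinds = []
    for ch in ass.chains:
        kinds.extend([ch.moltype] * len(ch.monomers))
    cross = [(a, b) for a, b, w in graph.edges if w == 0.0
             and {kinds[a].is_nucleic, kinds[b].is_nucleic} == {True, False}]
    assert len(cross) == 1
    assert graph.seed_edge == cross[0]


def test_rna_only_complex_seeds_from_a_node():
    from nafold.fixtures import gen_aform_rna

    rec = ComplexRecord.from_assembly(gen_aform_rna("GGCC"))
    with pytest.warns(UserWarning):
        graph = build_crop_graph(rec, np.random.default_rng(15))
    assert graph.seed_edge is None
    assert graph.seed_node is not None


def test_crop_small_complex_keeps_everything(basecontact_record):
    rng = np.random.default_rng(16)
    graph = build_crop_graph(basecontact_record, rng)
    sel = crop(graph, 256, rng)
    assert len(sel) == basecontact_record.assembly.n_monomers


def test_crop_matches_brute_force_dijkstra_oracle():
    rng = np.random.default_rng(17)
    rec = gen_toy_complex(20, rng, protein_len=180, dna_len=70)
    graph = build_crop_graph(rec, rng)
    sel = crop(graph, 256, rng)
    assert len(sel) == 256
    assert set(graph.seed_edge) <= set(sel)
    assert sel == brute_force_crop(graph, 256)
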