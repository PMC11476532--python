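"""Tandem arrays, alignment statistics, segmental pairs, collinear blocks,
reciprocal best hits and ortholog intersections."""

import itertools

import networkx as nx
import numpy as np
import pytest

from lacfam import (
    Anchor,
    GeneModel,
    SimilarityHit,
    classify_segmental,
    classify_tandem,
    detect_collinear_blocks,
    global_align_stats,
    ortholog_intersections,
    reciprocal_best_hits,
)


def gm(gid, start, chrom="chr1", length=1000, strand="+"):
    return GeneModel(gid, chrom, start, start + length - 1, strand)


class TestTandem:
    def test_adjacent_members_10kb_apart_share_array(self):
        genes = [gm("a", 1000), gm("b", 11_000)]
        t = classify_tandem({"a", "b"}, genes)
        assert t["a"] == t["b"] == "TA1"

    def test_window_violation_is_not_tandem(self):
        genes = [gm("a", 1000), gm("b", 151_000)]
        assert classify_tandem({"a", "b"}, genes) == {}

    def test_six_intervening_genes_break_the_link(self):
        fillers = [gm(f"f{i}", 3000 + i * 1000, length=500) for i in range(6)]
        genes = [gm("a", 1000), *fillers, gm("b", 15_000)]
        assert classify_tandem({"a", "b"}, genes) == {}
        # with five intervening the pair links
        assert classify_tandem({"a", "b"}, genes[:6] + [genes[-1]]) != {}

    def test_member_missing_from_annotation_raises(self):
        with pytest.raises(ValueError, match="zz"):
            classify_tandem({"zz"}, [gm("a", 1000)])

    def test_matches_bruteforce_pair_oracle(self, rng):
        starts = np.sort(rng.choice(np.arange(1, 2_000_000, 2000), 60, replace=False))
        genes = [gm(f"g{i}", int(s)) for i, s in enumerate(starts)]
        members = {f"g{i}" for i in rng.choice(60, 25, replace=False)}
        got = classify_tandem(members, genes)

        order = sorted(genes, key=lambda g: (g.start, g.end, g.gene_id))
        rank = {g.gene_id: i for i, g in enumerate(order)}
        pos = {g.gene_id: (g.start, g.end) for g in genes}
        G = nx.Graph()
        G.add_nodes_from(members)
        for a, b in itertools.combinations(sorted(members), 2):
            if abs(rank[a] - rank[b]) - 1 <= 5:
                lo = min(pos[a][0], pos[b][0])
                hi = max(pos[a][1], pos[b][1])
                if hi - lo + 1 <= 100_000:
                    G.add_edge(a, b)
        comps = [sorted(c) for c in nx.connected_components(G) if len(c) >= 2]
        assert {frozenset(c) for c in comps} == {
            frozenset(g for g, a in got.items() if a == aid)
            for aid in set(got.values())
        }


class TestAlignStats:
    def test_identical_sequences(self):
        assert global_align_stats("MKVLITGAGSGLG", "MKVLITGAGSGLG") == (1.0, 1.0)

    def test_coverage_reflects_length_ratio(self):
        a = "MKVLITGAGSGLGREMAKQ"
        cov, sim = global_align_stats(a, a + "W" * 10)
        assert cov == pytest.approx(len(a) / (len(a) + 10))
        assert sim == 1.0

    def test_symmetric_in_arguments(self):
        a, b = "MKVLITGAGSGLG", "MKVLITHAGSGWG"
        assert global_align_stats(a, b) == global_align_stats(b, a)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align_stats("", "MK")


class TestSegmental:
    def test_planted_mutated_copy_is_segmental(self, small_fixture):
        fix = small_fixture
        tandem = classify_tandem(set(fix.truth.family_genes), fix.models)
        seg = classify_segmental(
            set(fix.truth.family_genes), fix.representative_seqs, tandem
        )
        assert {p.key for p in seg} == fix.truth.segmental_pairs
        for p in seg:
            assert p.coverage > 0.75 and p.similarity > 0.75

    def test_similarity_exactly_75_percent_is_not_segmental(self, rng):
        # 100 residues, exactly 25 substitutions, no indels: similarity 0.75
        aas = "ACDEFGHIKLMNPQRSTVWY"
        a = "".join(rng.choice(list(aas), 100))
        b = list(a)
        for i in rng.choice(100, 25, replace=False):
            b[i] = aas[(aas.index(b[i]) + 1) % 20]
        b = "".join(b)
        cov, sim = global_align_stats(a, b)
        assert sim == pytest.approx(0.75)
        seg = classify_segmental({"x", "y"}, {"x": a, "y": b}, {})
        assert seg == set()

    def test_raising_similarity_threshold_never_adds_pairs(self, small_fixture):
        fix = small_fixture
        seqs = fix.representative_seqs
        members = set(fix.truth.family_genes)
        loose = classify_segmental(members, seqs, {}, min_similarity=0.5)
        tight = classify_segmental(members, seqs, {}, min_similarity=0.9)
        assert {p.key for p in tight} <= {p.key for p in loose}

    def test_tandem_pairs_excluded(self):
        seqs = {"a": "MKVLITGAGS" * 10, "b": "MKVLITGAGS" * 10}
        tandem = {"a": "TA1", "b": "TA1"}
        assert classify_segmental({"a", "b"}, seqs, tandem) == set()


def _chain_oracle(anchors, min_anchors, max_gap):
    """Exhaustive search over all monotone chains (DFS), greedy extraction
    with the same best-chain criterion as the implementation."""

    def best_chain(remaining):
        order = sorted(range(len(remaining)),
                       key=lambda i: (remaining[i].pos_a, remaining[i].pos_b,
                                      remaining[i].gene_a, remaining[i].gene_b))
        best = {+1: None, -1: None}
        for sign in (+1, -1):
            chains = [(idx,) for idx in range(len(order))]
            all_chains = list(chains)
            while chains:
                new = []
                for ch in chains:
                    last = remaining[order[ch[-1]]]
                    for idx in range(ch[-1] + 1, len(order)):
                        nxt = remaining[order[idx]]
                        if not (last.pos_a < nxt.pos_a and sign * last.pos_b < sign * nxt.pos_b):
                            continue
                        if (nxt.pos_a - last.pos_a - 1 > max_gap
                                or abs(nxt.pos_b - last.pos_b) - 1 > max_gap):
                            continue
                        new.append(ch + (idx,))
                all_chains.extend(new)
                chains = new
            length = max(len(c) for c in all_chains)
            best[sign] = min(c for c in all_chains if len(c) == length)
        cands = sorted(
            ((len(best[s]), s, best[s]) for s in (+1, -1)),
            key=lambda t: (-t[0], -t[1]),
        )
        length, sign, chain = cands[0]
        return length, sign, [order[k] for k in chain]

    remaining = list(anchors)
    blocks = []
    while remaining:
        length, sign, idxs = best_chain(remaining)
        if length < min_anchors:
            break
        blocks.append(tuple((remaining[i].gene_a, remaining[i].gene_b) for i in idxs))
        used = set(idxs)
        remaining = [a for i, a in enumerate(remaining) if i not in used]
    return blocks


class TestCollinearBlocks:
    def test_six_collinear_anchors_form_one_block(self):
        anchors = [Anchor(f"a{i}", f"b{i}", "cA", i, "cB", i) for i in range(6)]
        blocks = detect_collinear_blocks(anchors, min_anchors=5)
        assert len(blocks) == 1
        assert blocks[0].score == 6
        assert blocks[0].orientation == 1

    def test_inverted_block_detected_descending(self):
        anchors = [Anchor(f"a{i}", f"b{i}", "cA", i, "cB", 5 - i) for i in range(6)]
        blocks = detect_collinear_blocks(anchors, min_anchors=5)
        assert len(blocks) == 1 and blocks[0].orientation == -1

    def test_short_chains_discarded(self):
        anchors = [Anchor(f"a{i}", f"b{i}", "cA", i, "cB", i) for i in range(4)]
        assert detect_collinear_blocks(anchors, min_anchors=5) == []

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_exhaustive_chain_search(self, trial):
        rng = np.random.default_rng(500 + trial)
        n = int(rng.integers(5, 13))
        pa = rng.choice(40, n, replace=False)
        pb = rng.choice(40, n, replace=False)
        anchors = [
            Anchor(f"a{i}", f"b{i}", "cA", int(pa[i]), "cB", int(pb[i]))
            for i in range(n)
        ]
        got = detect_collinear_blocks(anchors, min_anchors=3, max_gap_genes=10)
        oracle = _chain_oracle(anchors, min_anchors=3, max_gap=10)
        assert [b.anchors for b in got] == oracle


class TestOrthologs:
    def test_symmetric_one_to_one_tables_all_kept(self):
        ab = [SimilarityHit(f"a{i}", f"b{i}", 1e-20, 0.9, 100, 0.9) for i in range(4)]
        ba = [SimilarityHit(f"b{i}", f"a{i}", 1e-20, 0.9, 100, 0.9) for i in range(4)]
        assert reciprocal_best_hits(ab, ba) == {(f"a{i}", f"b{i}") for i in range(4)}

    def test_asymmetric_best_hit_rejected(self):
        ab = [SimilarityHit("a", "b", 1e-20, 0.9, 100, 0.9)]
        ba = [SimilarityHit("b", "c", 1e-30, 0.9, 100, 0.9),
              SimilarityHit("b", "a", 1e-10, 0.9, 100, 0.9)]
        assert reciprocal_best_hits(ab, ba) == set()

    def test_matches_double_argmin_oracle(self, rng):
        qa = [f"a{i}" for i in range(6)]
        qb = [f"b{i}" for i in range(6)]
        ab = [SimilarityHit(q, s, float(10 ** rng.uniform(-30, 0)),
                            float(rng.uniform(0.3, 1)), 100, 0.9)
              for q in qa for s in rng.choice(qb, 3, replace=False)]
        ba = [SimilarityHit(q, s, float(10 ** rng.uniform(-30, 0)),
                            float(rng.uniform(0.3, 1)), 100, 0.9)
              for q in qb for s in rng.choice(qa, 3, replace=False)]
        cut = 1e-5

        def best(hits, q):
            cand = [h for h in hits if h.query_id == q and h.evalue <= cut]
            if not cand:
                return None
            return min(cand, key=lambda h: (h.evalue, -h.identity, h.subject_id)).subject_id

        oracle = {
            (a, best(ab, a))
            for a in qa
            if best(ab, a) is not None and best(ba, best(ab, a)) == a
        }
        assert reciprocal_best_hits(ab, ba, cut) == oracle

    def test_core_and_exclusive_counts(self):
        tables = {
            "dicot1": {"g1", "g2"}, "dicot2": {"g1", "g2"}, "monocot": {"g1"},
        }
        counts = ortholog_intersections(tables)
        assert counts[("dicot1", "dicot2", "monocot")] == 1  # core: g1
        assert counts[("dicot1", "dicot2")] == 1  # g2 absent from the monocot

    def test_identical_sets_core_equals_size(self):
        tables = {f"s{i}": {"g1", "g2", "g3"} for i in range(6)}
        counts = ortholog_intersections(tables)
        assert counts[tuple(sorted(tables))] == 3

    def test_matches_powerset_oracle(self, rng):
        genes = [f"g{i}" for i in range(10)]
        tables = {
            f"s{i}": {g for g in genes if rng.random() < 0.5} for i in range(4)
        }
        counts = ortholog_intersections(tables)
        species = sorted(tables)
        for subset, n in counts.items():
            inside = set.intersection(*(tables[s] for s in subset))
            outside = set().union(
                *(tables[s] for s in species if s not in subset), set()
            )
            assert n == len(inside - outside)
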