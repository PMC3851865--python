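"""Similarity filtering, paralogy-set construction and weakest-edge trimming."""

import itertools

import pandas as pd
import pytest

from aliquote.model import ParalogPair
from aliquote.preprocessing import (
    assign_multicopy_ranks,
    build_paralogy_sets,
    filter_similarity,
    preprocess,
    trim_to_k,
)
from aliquote.model import Parameters

from conftest import pairs_from_frame


def P(a, b, s):
    return ParalogPair(*sorted((a, b)), s)


class TestFilterSimilarity:
    def test_lower_cutoff_is_closed(self):
        """A cutoff removing pairs below 72 keeps similarity exactly 72."""
        pairs = [
            P("a", "b", 60.0),
            P("c", "d", 71.9),
            P("e", "f", 72.0),
            P("g", "h", 85.0),
        ]
        kept = filter_similarity(pairs, sim_min=72.0)
        assert [p.similarity for p in kept] == [72.0, 85.0]

    def test_unbounded_band_is_identity(self):
        pairs = [P("a", "b", 1.0), P("c", "d", 99.0)]
        assert filter_similarity(pairs) == pairs

    def test_band_separates_polyploidy_events(self, noisy_sim_small):
        """With the old event planted near 60 and the target near 80, the
        72 cutoff keeps the target pairs and removes the old ones -
        checked against the simulator's per-pair origin labels."""
        sim = noisy_sim_small
        origin = {
            (r.gene_a, r.gene_b): r.origin
            for r in sim.truth.pair_origins.itertuples()
        }
        pairs = pairs_from_frame(sim.pairs)
        kept = filter_similarity(pairs, sim_min=72.0)
        kept_keys = {p.key for p in kept}
        for p in pairs:
            if origin[p.key] == "target_wgd":
                assert (p.key in kept_keys) == (p.similarity >= 72.0)
        # planted 5 similarity units below the cutoff: essentially nothing
        # from the old event survives, essentially everything target does
        n_target = sum(1 for k in origin.values() if k == "target_wgd")
        n_old_kept = sum(1 for k in kept_keys if origin[k] == "old_wgd")
        assert n_old_kept <= 0.02 * len(kept_keys)
        assert len(kept_keys) - n_old_kept >= 0.95 * n_target


class TestBuildSets:
    def test_transitive_connectivity(self):
        sets, dropped = build_paralogy_sets(
            [P("a", "b", 80), P("b", "c", 81)], k=3
        )
        assert len(sets) == 1 and not dropped
        assert sets[0].genes == {"a", "b", "c"}

    def test_disjoint_components_stay_apart(self):
        sets, _ = build_paralogy_sets([P("a", "b", 80), P("c", "d", 81)], k=3)
        assert sorted(tuple(sorted(s.genes)) for s in sets.values()) == [
            ("a", "b"),
            ("c", "d"),
        ]

    def test_component_count_matches_surviving_families(self, noisy_sim_small):
        """Without contamination, each family with >= 2 surviving copies is
        one connected component."""
        sim = noisy_sim_small
        origin = {
            (r.gene_a, r.gene_b): r.origin
            for r in sim.truth.pair_origins.itertuples()
        }
        target_only = [
            p
            for p in pairs_from_frame(sim.pairs)
            if origin[p.key] == "target_wgd"
        ]
        sets, dropped = build_paralogy_sets(target_only, k=3)
        n_multi_families = (
            sim.truth.genes.groupby("family")["gene"].count() >= 2
        ).sum()
        assert len(sets) == n_multi_families
        assert not dropped


class TestTrimToK:
    def build(self, edges):
        import networkx as nx

        g = nx.Graph()
        for a, b, s in edges:
            g.add_edge(a, b, similarity=s)
        return g

    def test_small_component_untouched(self):
        g = self.build([("a", "b", 90), ("b", "c", 80)])
        [out] = trim_to_k(g, k=3)
        assert set(out.nodes) == {"a", "b", "c"}
        assert out.number_of_edges() == 2

    def test_path_splits_at_weakest_edge(self):
        # brute-force check by hand: deleting the 50-edge splits a-b | c-d
        g = self.build([("a", "b", 90), ("b", "c", 50), ("c", "d", 88)])
        parts = sorted(tuple(sorted(s.nodes)) for s in trim_to_k(g, k=3))
        assert parts == [("a", "b"), ("c", "d")]

    def test_two_triangles_recovered_from_weak_clique(self):
        """A 6-clique whose strong edges form two triangles decomposes into
        those triangles once all weaker edges are deleted (weakest-first
        deletion enumerated by hand)."""
        strong = [("a", "b", 85), ("b", "c", 85), ("a", "c", 85),
                  ("x", "y", 85), ("y", "z", 85), ("x", "z", 85)]
        weak = [
            (u, v, 60.0)
            for u, v in itertools.product("abc", "xyz")
        ]
        g = self.build(strong + weak)
        parts = sorted(tuple(sorted(s.nodes)) for s in trim_to_k(g, k=3))
        assert parts == [("a", "b", "c"), ("x", "y", "z")]

    def test_tie_break_is_canonical_pair_order(self):
        # all weights equal: deletion order falls back to lexicographic
        # canonical pair ids, so ('a','b') goes first, then ('b','c')
        g = self.build([("a", "b", 70), ("b", "c", 70), ("c", "d", 70),
                       ("d", "e", 70)])
        parts = sorted(tuple(sorted(s.nodes)) for s in trim_to_k(g, k=3))
        assert parts == [("a",), ("b",), ("c", "d", "e")]

    def test_singleton_remnants_dropped(self):
        g = self.build(
            [("a", "b", 90), ("b", "c", 89), ("c", "d", 88), ("d", "e", 50)]
        )
        sets, dropped = build_paralogy_sets(
            [P(a, b, s) for a, b, s in
             [("a", "b", 90), ("b", "c", 89), ("c", "d", 88), ("d", "e", 50)]],
            k=4,
        )
        assert dropped == ["e"]
        assert {tuple(sorted(s.genes)) for s in sets.values()} == {
            ("a", "b", "c", "d")
        }


class TestRanks:
    def make_table(self):
        rows = [
            ("g1", "c1", 100), ("s1", "c1", 150), ("g2", "c1", 200),
            ("s2", "c1", 250), ("g3", "c1", 300), ("g4", "c2", 10),
        ]
        df = pd.DataFrame(rows, columns=["gene", "chromosome", "position"])
        df["order_index"] = df.groupby("chromosome").cumcount()
        return df

    def test_single_copy_genes_do_not_perturb_ranks(self):
        sets = {}
        from aliquote.model import ParalogySet

        sets[0] = ParalogySet(
            0, frozenset({"g1", "g2", "g3"}),
            (P("g1", "g2", 80), P("g2", "g3", 80)),
        )
        out = assign_multicopy_ranks(self.make_table(), sets)
        ranks = out.set_index("gene")["multicopy_rank"]
        assert list(ranks[["g1", "g2", "g3"]]) == [0, 1, 2]
        assert ranks[["s1", "s2", "g4"]].isna().all()
        assert (out.set_index("gene")["copy_class"][["s1", "s2"]] == "single").all()

    def test_all_genes_units_use_order_index(self):
        from aliquote.model import ParalogySet

        sets = {
            0: ParalogySet(
                0, frozenset({"g1", "g2", "g3"}),
                (P("g1", "g2", 80), P("g2", "g3", 80)),
            )
        }
        out = assign_multicopy_ranks(
            self.make_table(), sets, gap_units="all-genes"
        )
        ranks = out.set_index("gene")["multicopy_rank"]
        assert list(ranks[["g1", "g2", "g3"]]) == [0, 2, 4]

    def test_total_ranked_equals_sum_of_set_sizes(self, noisy_sim_small):
        sim = noisy_sim_small
        params = Parameters(sim_min=72.0)
        sets, table, index = preprocess(
            pairs_from_frame(sim.pairs),
            sim.genes[["gene", "chromosome", "position", "order_index"]],
            params,
        )
        assert index.n_multicopy == sum(len(s.genes) for s in sets.values())
        assert (table["multicopy_rank"].notna()).sum() == index.n_multicopy


def test_preprocessing_is_idempotent(noisy_sim_small):
    """Re-running filter -> build -> trim on its own retained edges changes
    nothing."""
    params = Parameters(sim_min=72.0)
    sets1, _, _ = preprocess(
        pairs_from_frame(noisy_sim_small.pairs),
        noisy_sim_small.genes[["gene", "chromosome", "position", "order_index"]],
        params,
    )
    retained = [e for s in sets1.values() for e in s.edges]
    sets2, _, _ = preprocess(
        retained,
        noisy_sim_small.genes[["gene", "chromosome", "position", "order_index"]],
        params,
    )
    assert {frozenset(s.genes) for s in sets1.values()} == {
        frozenset(s.genes) for s in sets2.values()
    }
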