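"""Merge-score law: analytic cases and oracle equivalence.

The score of merging two k-tuples is, over matched region pairs,
``sum [gap_component - j*chi(jump)] - h*d*chi(d>0)`` with
``gap_component = r`` when the part reduces gapped genes, ``max(0, r - x)``
otherwise, and no gap reward for parts whose regions share no chromosome.
"""

import numpy as np
import pytest

from aliquote.core import cross_edges, execute_merge, score_merge
from aliquote.model import Parameters
from aliquote.simulate import SimConfig, simulate
from aliquote.preprocessing import preprocess

from _oracles import build_index, make_sets, make_tuple, oracle_score
from conftest import pairs_from_frame


@pytest.fixture
def params():
    return Parameters(k=3, r=40.0, j=15.0, h=10.0)


def three_chrom_layout(n=60):
    return build_index(
        {
            "X": [f"x{i}" for i in range(n)],
            "Y": [f"y{i}" for i in range(n)],
            "Z": [f"z{i}" for i in range(n)],
        }
    )


def singleton_tuples(index, params, offsets):
    """Two tuples of three single-gene regions each, the second shifted by
    the given per-chromosome offsets."""
    sets = make_sets(
        [
            [("x0", "y0", 80), ("y0", "z0", 80)],
            [
                (f"x{offsets[0]}", f"y{offsets[1]}", 80),
                (f"y{offsets[1]}", f"z{offsets[2]}", 80),
            ],
        ]
    )
    t1 = make_tuple(0, index, [["x0"], ["y0"], ["z0"]], [0])
    t2 = make_tuple(
        1,
        index,
        [[f"x{offsets[0]}"], [f"y{offsets[1]}"], [f"z{offsets[2]}"]],
        [1],
    )
    return sets, t1, t2


class TestAnalyticCases:
    def test_three_adjacent_parts_score_k_times_r(self, params):
        """All matched genes adjacent on their chromosomes: S = 3r = 120."""
        index = three_chrom_layout()
        sets, t1, t2 = singleton_tuples(index, params, (1, 1, 1))
        ms = score_merge(t1, t2, params, sets, index)
        assert ms.S == 3 * params.r == 120.0
        assert ms.matching == ((0, 0), (1, 1), (2, 2))
        assert all(p.x == 0 and not p.jump_flag for p in ms.per_part)

    def test_gap_beyond_r_contributes_zero(self, params):
        """One part with x = 55 > r contributes max(0, 40-55) = 0:
        S = 0 + 40 + 40 = 80."""
        index = three_chrom_layout()
        sets, t1, t2 = singleton_tuples(index, params, (56, 1, 1))
        ms = score_merge(t1, t2, params, sets, index)
        assert ms.S == 80.0
        xs = sorted(p.x for p in ms.per_part)
        assert xs == [0, 0, 55]

    def test_partial_gap_penalty_linear_in_x(self, params):
        """x = 10 on one part: S = (40-10) + 40 + 40 = 110."""
        index = three_chrom_layout()
        sets, t1, t2 = singleton_tuples(index, params, (11, 1, 1))
        assert score_merge(t1, t2, params, sets, index).S == 110.0

    def test_gap_reduction_earns_full_reward(self, params):
        """A part whose merge fills part of a gap (x < 0) earns exactly r,
        not r - x."""
        index = three_chrom_layout()
        sets = make_sets(
            [
                [("x0", "x20", 80)],  # region with a 19-gene gap
                [("x10", "y0", 80)],
            ]
        )
        t1 = make_tuple(0, index, [["x0", "x20"]], [0])
        t2 = make_tuple(1, index, [["x10"]], [1])
        ms = score_merge(t1, t2, params, sets, index)
        assert ms.per_part[0].x == -1
        assert ms.S == params.r

    def test_jump_penalty_per_introduced_chromosome_jump(self, params):
        """Two regions meeting on X, each bringing a chromosome the other
        lacks: the merged region spans a new chromosome, so the part takes
        the adjacency reward minus the jump penalty: S = 40 - 15."""
        index = build_index(
            {
                "X": [f"x{i}" for i in range(10)],
                "W": ["w0"],
                "V": ["v0"],
            }
        )
        sets = make_sets([[("w0", "x5", 80)], [("v0", "x6", 80)]])
        t1 = make_tuple(0, index, [["x5", "w0"]], [0])
        t2 = make_tuple(1, index, [["x6", "v0"]], [1])
        ms = score_merge(t1, t2, params, sets, index)
        assert ms.S == 40.0 - 15.0
        assert ms.per_part[0].jump_flag is True
        assert ms.per_part[0].shared_chromosome is True

    def test_pure_cross_chromosome_part_gets_no_gap_reward(self, params):
        """Regions sharing no chromosome: the part is a pure jump worth -j;
        merging two full tuples on disjoint chromosome triples can never be
        profitable."""
        index = three_chrom_layout()
        sets = make_sets(
            [
                [("x0", "y0", 80), ("y0", "z0", 80)],
                [("x30", "y30", 80), ("y30", "z30", 80)],
            ]
        )
        t1 = make_tuple(0, index, [["x0"], ["y0"], ["z0"]], [0])
        t2 = make_tuple(1, index, [["y30"], ["z30"], ["x30"]], [1])
        # identity matching: same-chromosome hulls 30 apart -> x=29 -> 11 each
        # cross matchings would pay -j per part; best is the aligned one
        ms = score_merge(t1, t2, params, sets, index)
        assert ms.S == 3 * (40 - 29)
        assert ms.matching == ((0, 2), (1, 0), (2, 1))  # aligns X-X, Y-Y, Z-Z

    def test_defect_penalty_h_times_d(self):
        """A merge placing both genes of a retained pair in one region pays
        h*d on top of the gap component."""
        index = three_chrom_layout()
        sets = make_sets([[("x0", "x5", 80)]])
        t1 = make_tuple(0, index, [["x0"]], [0])
        t2 = make_tuple(1, index, [["x5"]], [0])
        for h in (20.0, 40.0, 400.0):
            params = Parameters(k=3, r=40.0, j=15.0, h=h)
            ms = score_merge(t1, t2, params, sets, index)
            assert ms.d == 1
            assert ms.S == (40.0 - 4.0) - h
        assert cross_edges(t1, t2, sets, index) == {(0, 0): 1}

    def test_defect_free_reading_when_genes_in_distinct_regions(self, params):
        index = three_chrom_layout()
        sets, t1, t2 = singleton_tuples(index, params, (1, 1, 1))
        ms = score_merge(t1, t2, params, sets, index)
        assert ms.d == 0

    def test_per_tuple_jump_rule_charges_once(self):
        """Two matched parts that each introduce a new chromosome: per-part
        charges 2j, per-tuple charges j once."""
        index = build_index(
            {
                "X": [f"x{i}" for i in range(4)],
                "Y": [f"y{i}" for i in range(4)],
                "W": ["w0"],
                "V": ["v0"],
                "U": ["u0"],
                "Q": ["q0"],
            }
        )
        sets = make_sets(
            [
                [("w0", "x0", 80), ("v0", "y0", 80), ("x0", "y0", 80)],
                [("u0", "x1", 80), ("q0", "y1", 80), ("x1", "y1", 80)],
            ]
        )
        t1 = make_tuple(0, index, [["x0", "w0"], ["y0", "v0"]], [0])
        t2 = make_tuple(1, index, [["x1", "u0"], ["y1", "q0"]], [1])
        per_part = Parameters(k=3, r=40.0, j=15.0, jump_rule="per-part")
        per_tuple = Parameters(k=3, r=40.0, j=15.0, jump_rule="per-tuple")
        s_part = score_merge(t1, t2, per_part, sets, index).S
        s_tuple = score_merge(t1, t2, per_tuple, sets, index).S
        assert s_part == 80.0 - 2 * 15.0
        assert s_tuple == 80.0 - 15.0


class TestMatching:
    def test_region_budget_forces_full_matching(self, params):
        """3-region x 3-region at k=3 admits only full matchings."""
        index = three_chrom_layout()
        sets, t1, t2 = singleton_tuples(index, params, (1, 1, 1))
        ms = score_merge(t1, t2, params, sets, index)
        merged = execute_merge(t1, t2, ms, 99)
        assert len(merged.regions) == 3

    def test_partial_matching_carries_unmatched_regions(self, params):
        index = three_chrom_layout()
        sets = make_sets([[("x0", "y0", 80)], [("x1", "z0", 80)]])
        t1 = make_tuple(0, index, [["x0"], ["y0"]], [0])
        t2 = make_tuple(1, index, [["x1"], ["z0"]], [1])
        ms = score_merge(t1, t2, params, sets, index)
        # best: match only the X pair (+40); matching Y-Z would cost -j
        assert ms.S == 40.0
        assert ms.matching == ((0, 0),)
        merged = execute_merge(t1, t2, ms, 99)
        assert len(merged.regions) == 3
        assert merged.n_genes == 4

    def test_tie_break_prefers_lexicographically_smallest(self, params):
        """Two symmetric matchings with equal S: the smaller one wins."""
        index = three_chrom_layout()
        sets = make_sets(
            [[("x0", "x10", 80)], [("x4", "x6", 80)]]
        )
        t1 = make_tuple(0, index, [["x0"], ["x10"]], [0])
        t2 = make_tuple(1, index, [["x4"], ["x6"]], [1])
        ms = score_merge(t1, t2, params, sets, index)
        equal = oracle_score(t1, t2, params, sets, index)
        assert ms.S == equal[0]
        assert ms.matching == equal[1]

    def test_self_merge_rejected(self, params):
        index = three_chrom_layout()
        sets, t1, _ = singleton_tuples(index, params, (1, 1, 1))
        with pytest.raises(ValueError):
            score_merge(t1, t1, params, sets, index)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_random_tuple_pairs_match_bruteforce(self, seed):
        """On random small genomes, the library score (fragment-list path,
        cached cross-edges) equals an independent gene-set enumeration."""
        rng = np.random.default_rng(seed)
        sim = simulate(
            SimConfig(
                C=1,
                genes_per_chromosome=8,
                inversions=int(rng.integers(0, 3)),
                translocations=0,
                fusions=0,
                fissions=0,
                retention=(0.9, 0.7, 0.6),
                old_wgd_fraction=0.2,
                old_sim_mean=70.0,
                seed=int(rng.integers(1, 10_000)),
            )
        )
        params = Parameters(
            k=3,
            r=float(rng.integers(2, 12)),
            j=float(rng.integers(1, 10)),
            h=float(rng.integers(1, 50)),
        )
        sets, _, index = preprocess(
            pairs_from_frame(sim.pairs),
            sim.genes[["gene", "chromosome", "position", "order_index"]],
            params,
        )
        from aliquote.core import initial_tuples

        tuples = list(initial_tuples(sets, index).values())
        import itertools

        for t1, t2 in itertools.combinations(tuples, 2):
            ms = score_merge(t1, t2, params, sets, index)
            s_oracle, matching_oracle = oracle_score(t1, t2, params, sets, index)
            assert ms.S == pytest.approx(s_oracle)
            if ms.S == s_oracle:
                assert ms.matching == matching_oracle
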