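"""Shared fixture builders and independent oracles for the test suite.

The oracles recompute merge scores and clustering outcomes through a
different path than the library (gene sets and hull arithmetic instead of
fragment-list merging; full enumeration instead of incremental caches), so
agreement is a meaningful check.
"""

from __future__ import annotations

import itertools

from aliquote.core import initial_tuples
from aliquote.model import (
    GenomeIndex,
    KTuple,
    ParalogPair,
    ParalogySet,
    Parameters,
    Region,
)


def build_index(layout: dict[str, list[str]]) -> GenomeIndex:
    """layout: chromosome -> gene ids in rank order ('' marks a hole)."""
    return GenomeIndex(
        {
            g: (c, i)
            for c, genes in layout.items()
            for i, g in enumerate(genes)
            if g
        }
    )


def make_sets(
    groups: list[list[tuple[str, str, float]]]
) -> dict[int, ParalogySet]:
    """One ParalogySet per group of (gene_a, gene_b, similarity) edges."""
    sets = {}
    for sid, edges in enumerate(groups):
        canon = tuple(
            ParalogPair(*((a, b) if a < b else (b, a)), s) for a, b, s in edges
        )
        genes = frozenset(g for e in canon for g in (e.gene_a, e.gene_b))
        sets[sid] = ParalogySet(sid, genes, canon)
    return sets


def make_tuple(
    tid: int,
    index: GenomeIndex,
    region_genes: list[list[str]],
    set_ids: list[int],
    defects: int = 0,
) -> KTuple:
    regions = [
        Region.from_positions([index.rank_of[g] for g in genes])
        for genes in region_genes
    ]
    return KTuple(tid, regions, list(set_ids), defects)


# ---------------------------------------------------------------------------
# oracle: merge scoring from gene sets


def _region_gene_sets(t: KTuple, index: GenomeIndex) -> list[set[str]]:
    return [set(index.genes_in(r)) for r in t.regions]


def _gapped_of(genes: set[str], index: GenomeIndex) -> int:
    """Gapped genes = uncovered ranks inside each chromosome hull."""
    by: dict[str, list[int]] = {}
    for g in genes:
        c, rk = index.rank_of[g]
        by.setdefault(c, []).append(rk)
    total = 0
    for ranks in by.values():
        total += max(ranks) - min(ranks) + 1 - len(ranks)
    return total


def _chroms_of(genes: set[str], index: GenomeIndex) -> set[str]:
    return {index.rank_of[g][0] for g in genes}


def _defects_of(
    region_sets: list[set[str]], sets: dict[int, ParalogySet]
) -> int:
    count = 0
    for s in sets.values():
        for e in s.edges:
            for rs in region_sets:
                if e.gene_a in rs and e.gene_b in rs:
                    count += 1
    return count


def oracle_score(
    t1: KTuple,
    t2: KTuple,
    params: Parameters,
    sets: dict[int, ParalogySet],
    index: GenomeIndex,
) -> tuple[float, tuple[tuple[int, int], ...]]:
    """Best merge score and matching, recomputed from gene sets by full
    enumeration.  Ties resolved to the lexicographically smallest matching."""
    g1 = _region_gene_sets(t1, index)
    g2 = _region_gene_sets(t2, index)
    a, b = len(g1), len(g2)
    m_min = max(1, a + b - params.k)
    base_defects = _defects_of(g1, sets) + _defects_of(g2, sets)
    best: tuple[float, tuple] | None = None
    for m in range(m_min, min(a, b) + 1):
        for a_idx in itertools.combinations(range(a), m):
            for b_idx in itertools.permutations(range(b), m):
                matching = tuple(zip(a_idx, b_idx))
                merged_sets = []
                used2 = set(b_idx)
                for i1, i2 in matching:
                    merged_sets.append(g1[i1] | g2[i2])
                for i1 in range(a):
                    if i1 not in dict(matching):
                        merged_sets.append(g1[i1])
                for i2 in range(b):
                    if i2 not in used2:
                        merged_sets.append(g2[i2])
                s = 0.0
                n_jumps = 0
                for i1, i2 in matching:
                    u = g1[i1] | g2[i2]
                    x = (
                        _gapped_of(u, index)
                        - _gapped_of(g1[i1], index)
                        - _gapped_of(g2[i2], index)
                    )
                    c1 = _chroms_of(g1[i1], index)
                    c2 = _chroms_of(g2[i2], index)
                    jump = len(c1 | c2) > max(len(c1), len(c2))
                    n_jumps += jump
                    if c1 & c2:
                        s += params.r if x < 0 else max(0.0, params.r - x)
                    if jump and params.jump_rule == "per-part":
                        s -= params.j
                if params.jump_rule == "per-tuple" and n_jumps:
                    s -= params.j
                d = _defects_of(merged_sets, sets) - base_defects
                if d > 0:
                    s -= params.effective_h * d
                key = (s, matching)
                if best is None or s > best[0] or (s == best[0] and matching < best[1]):
                    best = key
    assert best is not None
    return best


def oracle_execute(
    t1: KTuple,
    t2: KTuple,
    matching: tuple[tuple[int, int], ...],
    index: GenomeIndex,
    new_id: int,
) -> KTuple:
    g1 = _region_gene_sets(t1, index)
    g2 = _region_gene_sets(t2, index)
    m1 = dict(matching)
    used2 = {i2 for _, i2 in matching}
    region_genes = []
    for i1 in range(len(g1)):
        region_genes.append(g1[i1] | g2[m1[i1]] if i1 in m1 else g1[i1])
    for i2 in range(len(g2)):
        if i2 not in used2:
            region_genes.append(g2[i2])
    regions = [
        Region.from_positions(sorted(index.rank_of[g] for g in genes))
        for genes in region_genes
    ]
    return KTuple(new_id, regions, t1.set_ids + t2.set_ids)


def canonical_partition(tuples, index: GenomeIndex) -> frozenset:
    return frozenset(
        frozenset(
            frozenset(index.genes_in(r)) for r in t.regions
        )
        for t in tuples
    )


def exhaustive_clusterings(
    sets: dict[int, ParalogySet],
    index: GenomeIndex,
    params: Parameters,
    max_states: int = 20000,
) -> set[frozenset]:
    """All terminal partitions reachable by any sequence of positive-score
    merges, by depth-first search over merge orders (small instances only)."""
    start = list(initial_tuples(sets, index).values())
    terminals: set[frozenset] = set()
    seen: set[frozenset] = set()
    stack = [start]
    n_states = 0
    while stack:
        tuples = stack.pop()
        state = canonical_partition(tuples, index)
        if state in seen:
            continue
        seen.add(state)
        n_states += 1
        if n_states > max_states:
            raise RuntimeError("state space too large for exhaustive search")
        positive = []
        for ia, ib in itertools.combinations(range(len(tuples)), 2):
            s, matching = oracle_score(
                tuples[ia], tuples[ib], params, sets, index
            )
            if s > 0:
                positive.append((ia, ib, matching))
        if not positive:
            terminals.add(state)
            continue
        for ia, ib, matching in positive:
            merged = oracle_execute(
                tuples[ia], tuples[ib], matching, index, 10_000 + n_states
            )
            rest = [t for i, t in enumerate(tuples) if i not in (ia, ib)]
            stack.append(rest + [merged])
    return terminals
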