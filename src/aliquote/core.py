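"""Greedy agglomerative aliquoting of k-tuples of regions.

The clustering score for merging two k-tuples sums, over matched region
pairs, a gap component and a chromosome-jump component, and subtracts a
penalty for newly created aliquoting defects::

    S = sum over matched parts [ gap_component - j * chi(jump) ] - h * d * chi(d > 0)

with, for a matched part whose regions meet on at least one shared
chromosome,

* ``gap_component = r``                if the part reduces the total number
  of gapped genes (x < 0), and
* ``gap_component = max(0, r - x)``    otherwise,

where ``x`` is the change in gapped genes (merged minus both inputs) and the
jump indicator fires when the merged region spans more chromosomes than
either input alone.  A matched part whose regions share *no* chromosome is a
pure chromosome jump: it earns no gap reward and contributes ``-j``.  (Gaps
are a same-chromosome notion, so ``x = 0`` for such parts; awarding them the
full ``r`` would make every cross-chromosome merge profitable whenever
``r > j`` and collapse the whole genome into one cluster, which is neither
the intent of the while-S>0 loop nor compatible with solutions in which
distinct clusters share a fused chromosome.)

``d`` counts paralog pairs that the merge newly places inside a single
region.  The region-to-region assignment between the two tuples is chosen by
exhaustive enumeration of injective partial matchings (cheap for the k <= 5
this method targets), keeping the score-maximal, lexicographically smallest
matching; matchings leaving the merged tuple with more than ``k`` regions
are inadmissible.

The greedy loop merges the S-maximal pair while any pair scores S > 0, with
ties broken by the smallest (tuple_id, tuple_id) pair, which makes runs
bit-reproducible.  Initialization scores all candidate pairs (quadratic);
after a merge only scores involving the new cluster are computed.  Pairs of
tuples with no shared chromosome whose fragment hulls come within ``r + 1``
ranks of each other cannot score positively and are skipped; tests assert
this pruning is equivalent to unpruned scoring.
"""

from __future__ import annotations

import heapq
import itertools
import logging
import math
from dataclasses import dataclass

from .model import (
    GenomeIndex,
    KTuple,
    Parameters,
    ParalogySet,
    Region,
    Solution,
    merge_regions,
)

logger = logging.getLogger(__name__)

NEG_INF = -math.inf


@dataclass(frozen=True)
class PartScore:
    """One matched region pair inside a candidate merge."""

    x: int
    gap_component: float
    jump_flag: bool
    shared_chromosome: bool


@dataclass(frozen=True)
class MergeScore:
    """The best-scoring way to merge two k-tuples.

    ``matching`` maps region indices of the first tuple to region indices of
    the second, as a tuple of (i1, i2) pairs sorted by i1.  ``d`` is the
    increase in aliquoting defects under that matching.
    """

    S: float
    matching: tuple[tuple[int, int], ...]
    per_part: tuple[PartScore, ...]
    d: int
    merged_regions: tuple[Region, ...] = ()

    @property
    def admissible(self) -> bool:
        return self.S != NEG_INF


def _part_info(a: Region, b: Region, params: Parameters) -> tuple:
    merged, x, jump, shared = merge_regions(a, b)
    if shared:
        gap = params.r if x < 0 else max(0.0, params.r - x)
    else:
        gap = 0.0
    return merged, PartScore(x, gap, jump, shared)


def cross_edges(
    t1: KTuple,
    t2: KTuple,
    sets: dict[int, ParalogySet],
    index: GenomeIndex,
    scan: str = "both",
) -> dict[tuple[int, int], int]:
    """Count retained paralog edges running between a region of ``t1`` and a
    region of ``t2``, keyed by (region index in t1, region index in t2).

    These are the only edges whose same-region status a merge can change:
    matching part (i1, i2) turns every such edge into a new defect.

    ``scan="small"`` scans only the member sets of the tuple with fewer of
    them.  That is exact whenever every paralogy set's genes lie wholly
    within the tuple that absorbed it - which greedy clustering maintains by
    construction (tuples merge whole sets) - and is what the clustering hot
    path uses; the default scans both tuples' sets and is correct for
    arbitrarily constructed tuples.  Audit mode cross-checks the two.
    """
    if scan == "small":
        src_sets = (
            t1.set_ids if len(t1.set_ids) <= len(t2.set_ids) else t2.set_ids
        )
    else:
        src_sets = t1.set_ids + t2.set_ids
    out: dict[tuple[int, int], int] = {}
    seen: set[tuple[str, str]] = set()
    for sid in src_sets:
        for e in sets[sid].edges:
            if e.key in seen:
                continue
            seen.add(e.key)
            pa = index.rank_of.get(e.gene_a)
            pb = index.rank_of.get(e.gene_b)
            if pa is None or pb is None:
                continue
            i1 = t1.region_of(*pa)
            if i1 is not None:
                i2 = t2.region_of(*pb)
            else:
                i2 = t2.region_of(*pa)
                i1 = t1.region_of(*pb) if i2 is not None else None
            if i1 is None or i2 is None:
                continue
            out[(i1, i2)] = out.get((i1, i2), 0) + 1
    return out


def _matchings(a: int, b: int, m_min: int):
    """Yield injective partial matchings between range(a) and range(b) with
    at least ``m_min`` matched pairs, in lexicographic order."""
    for m in range(m_min, min(a, b) + 1):
        for a_idx in itertools.combinations(range(a), m):
            for b_idx in itertools.permutations(range(b), m):
                yield tuple(zip(a_idx, b_idx))


def score_merge(
    t1: KTuple,
    t2: KTuple,
    params: Parameters,
    sets: dict[int, ParalogySet],
    index: GenomeIndex,
    scan: str = "both",
) -> MergeScore:
    """Evaluate the best admissible merge of two k-tuples.

    Returns the score-maximal, lexicographically smallest matching.  The
    sentinel ``S = -inf`` marks an inadmissible merge (cannot arise for
    tuples respecting the <= k regions invariant, but kept for safety).
    """
    if t1 is t2:
        raise ValueError("cannot merge a tuple with itself")
    a, b = len(t1.regions), len(t2.regions)
    m_min = max(1, a + b - params.k)
    if m_min > min(a, b):
        return MergeScore(NEG_INF, (), (), 0)

    parts: dict[tuple[int, int], tuple[Region, PartScore]] = {}
    for i1 in range(a):
        for i2 in range(b):
            parts[(i1, i2)] = _part_info(t1.regions[i1], t2.regions[i2], params)

    cross = cross_edges(t1, t2, sets, index, scan=scan)
    h = params.effective_h

    best: MergeScore | None = None
    for matching in _matchings(a, b, m_min):
        gap_sum = 0.0
        n_jumps = 0
        d = 0
        for i1, i2 in matching:
            ps = parts[(i1, i2)][1]
            gap_sum += ps.gap_component
            n_jumps += ps.jump_flag
            d += cross.get((i1, i2), 0)
        if params.jump_rule == "per-tuple":
            jump_pen = params.j if n_jumps else 0.0
        else:
            jump_pen = params.j * n_jumps
        s = gap_sum - jump_pen - (h * d if d > 0 else 0.0)
        if best is None or s > best.S or (s == best.S and matching < best.matching):
            best = MergeScore(
                s,
                matching,
                tuple(parts[m][1] for m in matching),
                d,
                tuple(parts[m][0] for m in matching),
            )
    assert best is not None
    return best


def execute_merge(
    t1: KTuple, t2: KTuple, ms: MergeScore, new_id: int
) -> KTuple:
    """Build the merged k-tuple for an evaluated merge: matched region pairs
    are replaced by their merged regions (in t1's region order), unmatched
    regions of both tuples carry over unchanged."""
    if not ms.admissible:
        raise ValueError("inadmissible merge")
    matched1 = {i1: pos for pos, (i1, _) in enumerate(ms.matching)}
    matched2 = {i2 for _, i2 in ms.matching}
    regions: list[Region] = []
    for i1, reg in enumerate(t1.regions):
        if i1 in matched1:
            regions.append(ms.merged_regions[matched1[i1]])
        else:
            regions.append(reg)
    for i2, reg in enumerate(t2.regions):
        if i2 not in matched2:
            regions.append(reg)
    return KTuple(
        new_id,
        regions,
        t1.set_ids + t2.set_ids,
        t1.defects + t2.defects + ms.d,
    )


def initial_tuples(
    sets: dict[int, ParalogySet], index: GenomeIndex
) -> dict[int, KTuple]:
    """One k-tuple per paralogy set, each gene its own single-fragment
    region; regions ordered by (chromosome, rank) for determinism."""
    tuples: dict[int, KTuple] = {}
    for tid, sid in enumerate(sorted(sets)):
        positions = sorted(index.rank_of[g] for g in sets[sid].genes)
        regions = [Region.from_gene(c, rk) for c, rk in positions]
        tuples[tid] = KTuple(tid, regions, [sid])
    return tuples


class _HullIndex:
    """Per-chromosome fragment hulls of the live tuples, used to enumerate
    pairs that could possibly score S > 0."""

    def __init__(self, margin: int):
        self.margin = margin
        self.by_chrom: dict[str, dict[int, tuple[int, int]]] = {}
        self.of_tuple: dict[int, dict[str, tuple[int, int]]] = {}

    def add(self, t: KTuple) -> None:
        hulls: dict[str, tuple[int, int]] = {}
        for reg in t.regions:
            for c in reg.frags:
                lo, hi = reg.hull(c)  # type: ignore[misc]
                if c in hulls:
                    hulls[c] = (min(hulls[c][0], lo), max(hulls[c][1], hi))
                else:
                    hulls[c] = (lo, hi)
        self.of_tuple[t.tuple_id] = hulls
        for c, hull in hulls.items():
            self.by_chrom.setdefault(c, {})[t.tuple_id] = hull

    def remove(self, tid: int) -> None:
        for c in self.of_tuple.pop(tid):
            del self.by_chrom[c][tid]

    def candidates(self, tid: int) -> list[int]:
        out: set[int] = set()
        for c, (lo, hi) in self.of_tuple[tid].items():
            lo -= self.margin
            hi += self.margin
            for tid2, (lo2, hi2) in self.by_chrom.get(c, {}).items():
                if tid2 != tid and lo2 <= hi and lo <= hi2:
                    out.add(tid2)
        return sorted(out)

    def all_pairs(self) -> list[tuple[int, int]]:
        pairs: set[tuple[int, int]] = set()
        for tid in self.of_tuple:
            for tid2 in self.candidates(tid):
                pairs.add((tid, tid2) if tid < tid2 else (tid2, tid))
        return sorted(pairs)


def greedy_cluster(
    sets: dict[int, ParalogySet],
    index: GenomeIndex,
    params: Parameters,
    audit: bool = False,
    prune: bool = True,
) -> Solution:
    """Agglomerate paralogy sets into k-tuples of regions.

    While any pair of live k-tuples has merge score S > 0, the maximal pair
    (ties: smallest ids) is merged; scores involving dead tuples are
    discarded lazily from the priority queue.  With ``audit=True`` every
    executed merge is checked against a full unpruned re-scan of all live
    pairs and all cached defect counts are recounted from scratch (slow;
    meant for tests on small instances).
    """
    if not sets:
        raise ValueError("no paralogy sets to cluster")
    tuples = initial_tuples(sets, index)
    hulls = _HullIndex(margin=int(math.ceil(params.r)) + 1)
    for t in tuples.values():
        hulls.add(t)

    def pairs_for(tid: int) -> list[int]:
        if prune:
            return hulls.candidates(tid)
        return [t2 for t2 in tuples if t2 != tid]

    heap: list[tuple[float, int, int]] = []
    for t1_id, t2_id in (
        hulls.all_pairs()
        if prune
        else itertools.combinations(sorted(tuples), 2)
    ):
        ms = score_merge(
            tuples[t1_id], tuples[t2_id], params, sets, index, scan="small"
        )
        if ms.S > 0:
            heap.append((-ms.S, t1_id, t2_id))
    heapq.heapify(heap)
    logger.info(
        "greedy init: %d tuples, %d positive candidate pairs",
        len(tuples),
        len(heap),
    )

    next_id = len(tuples)
    n_merges = 0
    while heap:
        neg_s, t1_id, t2_id = heapq.heappop(heap)
        if t1_id not in tuples or t2_id not in tuples:
            continue
        t1, t2 = tuples[t1_id], tuples[t2_id]
        ms = score_merge(t1, t2, params, sets, index, scan="small")
        assert ms.S == -neg_s, "cached score differs from recomputation"
        if ms.S <= 0:  # defensive; only positive scores are pushed
            continue
        if audit:
            _audit_max(tuples, params, sets, index, ms.S, (t1_id, t2_id))
        merged = execute_merge(t1, t2, ms, next_id)
        del tuples[t1_id], tuples[t2_id]
        hulls.remove(t1_id)
        hulls.remove(t2_id)
        tuples[next_id] = merged
        hulls.add(merged)
        for other in pairs_for(next_id):
            ms2 = score_merge(
                tuples[next_id], tuples[other], params, sets, index,
                scan="small",
            )
            if ms2.S > 0:
                lo, hi = min(next_id, other), max(next_id, other)
                heapq.heappush(heap, (-ms2.S, lo, hi))
        next_id += 1
        n_merges += 1
        if audit:
            _audit_defects(tuples, sets, index)

    solution = Solution(
        ktuples=[tuples[tid] for tid in sorted(tuples)],
        sets=sets,
        index=index,
        params=params,
        n_input_sets=len(sets),
        n_input_chromosomes=len(index.gene_at),
        n_merges=n_merges,
    )
    if audit:
        solution.validate()
    logger.info(
        "greedy done: %d merges, %d tuples", n_merges, len(solution.ktuples)
    )
    return solution


def _audit_max(tuples, params, sets, index, chosen_s, chosen_pair) -> None:
    for ta, tb in itertools.combinations(sorted(tuples), 2):
        ms = score_merge(tuples[ta], tuples[tb], params, sets, index)
        if ms.S > chosen_s:
            raise AssertionError(
                f"merge {chosen_pair} (S={chosen_s}) is not maximal: "
                f"({ta},{tb}) scores {ms.S}"
            )


def _audit_defects(tuples, sets, index) -> None:
    assign: dict[str, tuple[int, int]] = {}
    for t in tuples.values():
        for ri, reg in enumerate(t.regions):
            for g in index.genes_in(reg):
                assign[g] = (t.tuple_id, ri)
    recount = {tid: 0 for tid in tuples}
    for s in sets.values():
        for e in s.edges:
            pa, pb = assign.get(e.gene_a), assign.get(e.gene_b)
            if pa is not None and pa == pb:
                recount[pa[0]] += 1
    for tid, t in tuples.items():
        if t.defects != recount[tid]:
            raise AssertionError(
                f"tuple {tid}: cached defects {t.defects} != {recount[tid]}"
            )


# ---------------------------------------------------------------------------
# post-processing: fill short gaps by relocating genes


def _region_without(reg: Region, chrom: str, rank: int) -> Region | None:
    """Return ``reg`` minus the gene at (chrom, rank), or None if emptied."""
    frags = {c: list(fl) for c, fl in reg.frags.items()}
    fl = frags[chrom]
    for i, (s, e) in enumerate(fl):
        if s <= rank <= e:
            repl = []
            if s < rank:
                repl.append((s, rank - 1))
            if rank < e:
                repl.append((rank + 1, e))
            fl[i : i + 1] = repl
            break
    else:
        raise ValueError(f"rank {rank} not in region on {chrom}")
    if not fl:
        del frags[chrom]
    if not frags:
        return None
    return Region(frags)


def postprocess_fill_gaps(
    solution: Solution,
    t: int | None = None,
    max_new_defects_per_move: int | None = None,
) -> Solution:
    """Fill same-chromosome gaps of fewer than ``t`` multi-copy genes by
    moving the gap's genes out of their current regions into the gapped
    region, when the move creates at most ``max_new_defects_per_move`` new
    aliquoting defects.

    Moves are scanned in deterministic order (tuple id, region, fragment
    order); each gene moves at most once per pass, and a gap containing an
    already-moved gene is left alone, so the pass terminates.  Regions (and
    tuples) emptied by moves are deleted.  Moved genes that end up violating
    the k-partition - a retained paralog in the same region, or in a
    different k-tuple - are counted as inconsistent.
    """
    params = solution.params
    t = params.t if t is None else t
    max_new = (
        params.max_move_defects
        if max_new_defects_per_move is None
        else max_new_defects_per_move
    )
    index = solution.index

    # working copies keyed by stable region ids
    regions: dict[int, Region] = {}
    region_tuple: dict[int, int] = {}
    tuple_rids: dict[int, list[int]] = {}
    rid = 0
    for kt in solution.ktuples:
        tuple_rids[kt.tuple_id] = []
        for reg in kt.regions:
            regions[rid] = reg
            region_tuple[rid] = kt.tuple_id
            tuple_rids[kt.tuple_id].append(rid)
            rid += 1
    pos_region: dict[tuple[str, int], int] = {}
    for r, reg in regions.items():
        for p in reg.iter_positions():
            pos_region[p] = r

    # paralog adjacency over retained edges
    partners: dict[str, list[str]] = {}
    for s in solution.sets.values():
        for e in s.edges:
            partners.setdefault(e.gene_a, []).append(e.gene_b)
            partners.setdefault(e.gene_b, []).append(e.gene_a)

    moved: set[str] = set()
    n_moves = 0
    for tid in sorted(tuple_rids):
        for target_rid in list(tuple_rids[tid]):
            blocked: set[tuple[str, int, int]] = set()
            progress = True
            while progress:
                progress = False
                reg = regions.get(target_rid)
                if reg is None:
                    break
                for c in sorted(reg.frags):
                    fl = reg.frags[c]
                    for (s1, e1), (s2, _) in zip(fl, fl[1:]):
                        gap = s2 - e1 - 1
                        if not (0 < gap < t) or (c, e1, s2) in blocked:
                            continue
                        gap_positions = [
                            (c, rk)
                            for rk in range(e1 + 1, s2)
                            if index.gene_at[c][rk]  # skip single-copy holes
                        ]
                        gap_genes = [index.gene_at[c][rk] for _, rk in gap_positions]
                        if (
                            not gap_genes
                            or any(g in moved for g in gap_genes)
                            or any(p not in pos_region for p in gap_positions)
                        ):
                            blocked.add((c, e1, s2))
                            continue
                        created, destroyed = _move_defect_delta(
                            gap_genes, target_rid, pos_region, index, partners
                        )
                        if created > max_new:
                            blocked.add((c, e1, s2))
                            continue
                        # execute the move
                        for (pc, prk), g in zip(gap_positions, gap_genes):
                            src = pos_region[(pc, prk)]
                            if src == target_rid:  # pragma: no cover - impossible
                                continue
                            new_src = _region_without(regions[src], pc, prk)
                            if new_src is None:
                                src_tid = region_tuple.pop(src)
                                tuple_rids[src_tid].remove(src)
                                del regions[src]
                            else:
                                regions[src] = new_src
                            pos_region[(pc, prk)] = target_rid
                            moved.add(g)
                        merged, _, _, _ = merge_regions(
                            regions[target_rid],
                            Region.from_positions(gap_positions),
                        )
                        regions[target_rid] = merged
                        n_moves += 1
                        progress = True
                        break
                    if progress:
                        break

    # rebuild tuples, recount defects from scratch
    set_ids_of = {kt.tuple_id: kt.set_ids for kt in solution.ktuples}
    new_tuples: list[KTuple] = []
    assign: dict[str, tuple[int, int]] = {}
    for tid in sorted(tuple_rids):
        rids = tuple_rids[tid]
        if not rids:
            continue
        regs = [regions[r] for r in rids]
        kt = KTuple(tid, regs, set_ids_of[tid])
        new_tuples.append(kt)
        for ri, reg in enumerate(regs):
            for g in index.genes_in(reg):
                assign[g] = (tid, ri)
    defect_count: dict[int, int] = {kt.tuple_id: 0 for kt in new_tuples}
    for s in solution.sets.values():
        for e in s.edges:
            pa, pb = assign.get(e.gene_a), assign.get(e.gene_b)
            if pa is not None and pa == pb:
                defect_count[pa[0]] += 1
    for kt in new_tuples:
        kt.defects = defect_count[kt.tuple_id]

    inconsistent = 0
    for g in sorted(moved):
        bad = False
        for p in partners.get(g, []):
            pg, pp = assign.get(g), assign.get(p)
            if pp is None:
                continue
            if pg == pp or pg[0] != pp[0]:  # same region, or split tuples
                bad = True
                break
        inconsistent += bad

    logger.info(
        "post-processing: %d moves, %d genes moved, %d inconsistent",
        n_moves,
        len(moved),
        inconsistent,
    )
    return Solution(
        ktuples=new_tuples,
        sets=solution.sets,
        index=index,
        params=params,
        n_input_sets=solution.n_input_sets,
        n_input_chromosomes=solution.n_input_chromosomes,
        n_merges=solution.n_merges,
        moved_genes=sorted(moved),
        inconsistent_genes=inconsistent,
    )


def _move_defect_delta(
    gap_genes: list[str],
    target_rid: int,
    pos_region: dict[tuple[str, int], int],
    index: GenomeIndex,
    partners: dict[str, list[str]],
) -> tuple[int, int]:
    """Defects created/destroyed by moving ``gap_genes`` into region
    ``target_rid`` (each edge counted once)."""
    moving = set(gap_genes)

    def region_after(g: str) -> int | None:
        if g in moving:
            return target_rid
        p = index.rank_of.get(g)
        return None if p is None else pos_region.get(p)

    def region_before(g: str) -> int | None:
        p = index.rank_of.get(g)
        return None if p is None else pos_region.get(p)

    created = destroyed = 0
    seen: set[tuple[str, str]] = set()
    for g in gap_genes:
        for p in partners.get(g, []):
            key = (g, p) if g < p else (p, g)
            if key in seen:
                continue
            seen.add(key)
            before = region_before(g) == region_before(p) != None
            after_g, after_p = region_after(g), region_after(p)
            after = after_g is not None and after_g == after_p
            created += after and not before
            destroyed += before and not after
    return created, destroyed


# ---------------------------------------------------------------------------
# solution characteristics

RANK_CLASS_NAMES = ("largest", "middle", "smallest")


def region_rank_classes(kt: KTuple) -> list[str]:
    """Assign each region of a tuple to a size-rank class by gene count:
    the gene-richest region is "largest", the poorest "smallest" (when the
    tuple has >= 2 regions), everything in between "middle".  Ties break by
    region order, keeping the assignment deterministic."""
    order = sorted(
        range(len(kt.regions)), key=lambda i: (-kt.regions[i].n_genes, i)
    )
    classes = [""] * len(kt.regions)
    for pos, i in enumerate(order):
        if pos == 0:
            classes[i] = "largest"
        elif pos == len(order) - 1:
            classes[i] = "smallest"
        else:
            classes[i] = "middle"
    return classes


def summarize(solution: Solution) -> dict:
    """Solution characteristics: genes included (count and proportion of
    multi-copy genes), fragment count, C'' (number of k-tuples), inconsistent
    genes, and per size-rank-class region statistics (gene counts and mean
    chromosomes per region)."""
    included = solution.included_tuples()
    genes_included = sum(t.n_genes for t in included)
    n_multi = solution.index.n_multicopy
    class_stats: dict[str, dict[str, float]] = {}
    for name in RANK_CLASS_NAMES:
        class_stats[name] = {"n_regions": 0, "genes": 0, "chromosomes": 0}
    for t in included:
        for reg, cls in zip(t.regions, region_rank_classes(t)):
            st = class_stats[cls]
            st["n_regions"] += 1
            st["genes"] += reg.n_genes
            st["chromosomes"] += len(reg.chromosomes)
    for st in class_stats.values():
        n = st["n_regions"]
        st["mean_genes"] = st["genes"] / n if n else float("nan")
        st["mean_chromosomes"] = st["chromosomes"] / n if n else float("nan")
    return {
        "n_tuples": solution.C_doubleprime,
        "n_included_tuples": len(included),
        "n_fragments": solution.n_fragments,
        "n_multicopy_genes": n_multi,
        "genes_included": genes_included,
        "genes_included_proportion": (
            genes_included / n_multi if n_multi else float("nan")
        ),
        "inconsistent_genes": solution.inconsistent_genes,
        "n_merges": solution.n_merges,
        "n_input_sets": solution.n_input_sets,
        "n_input_chromosomes": solution.n_input_chromosomes,
        "defects_total": sum(t.defects for t in solution.ktuples),
        "gapped_genes_total": sum(
            r.gapped_genes for t in solution.ktuples for r in t.regions
        ),
        "jumps_total": sum(
            r.jumps for t in solution.ktuples for r in t.regions
        ),
        "rank_classes": class_stats,
    }


def compute_spans_and_coverage(solution: Solution, gene_table) -> dict:
    """Region spans in all-gene order units, and single-copy gene coverage.

    The span of a region on a chromosome runs from its first to its last
    gene there (inclusive, ``order_index`` units).  Reports, for every
    single-copy gene, whether it falls inside any span; spans of different
    tuples may overlap (reported, not forbidden).
    """
    order_of = {
        row.gene: (row.chromosome, int(row.order_index))
        for row in gene_table.itertuples()
    }
    spans: list[dict] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for t in solution.included_tuples():
        for ri, reg in enumerate(t.regions):
            per_chrom: dict[str, tuple[int, int]] = {}
            for g in solution.index.genes_in(reg):
                c, o = order_of[g]
                if c in per_chrom:
                    lo, hi = per_chrom[c]
                    per_chrom[c] = (min(lo, o), max(hi, o))
                else:
                    per_chrom[c] = (o, o)
            for c, (lo, hi) in sorted(per_chrom.items()):
                spans.append(
                    {
                        "tuple_id": t.tuple_id,
                        "region_index": ri,
                        "chromosome": c,
                        "start_order": lo,
                        "end_order": hi,
                        "length_genes": hi - lo + 1,
                    }
                )
                by_chrom.setdefault(c, []).append((lo, hi))

    singles = gene_table[gene_table["copy_class"] == "single"]
    spanned = outside = 0
    for row in singles.itertuples():
        o = int(row.order_index)
        if any(lo <= o <= hi for lo, hi in by_chrom.get(row.chromosome, [])):
            spanned += 1
        else:
            outside += 1

    overlapping_pairs = 0
    for c, ivs in by_chrom.items():
        ivs = sorted(ivs)
        for (lo1, hi1), (lo2, _) in zip(ivs, ivs[1:]):
            overlapping_pairs += lo2 <= hi1
    return {
        "spans": spans,
        "single_copy_spanned": spanned,
        "single_copy_outside": outside,
        "overlapping_span_pairs": overlapping_pairs,
    }
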