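"""Domain types for subgenome aliquoting.

The objects here mirror the structural vocabulary of ancient-polyploid
analysis: a genome is a set of chromosomes carrying an ordered sequence of
genes; retained duplicate ("multi-copy") genes group into *paralogy sets* of
at most ``k`` members; runs of contiguous multi-copy genes assigned to one
putative subgenome piece are *fragments*; an ordered collection of fragments
separated by gaps or chromosome jumps is a *region*; and up to ``k``
putatively homeologous regions form a *k-tuple*, the unit the clustering
algorithm agglomerates.

Gene coordinates come in two flavours:

``order_index``
    0-based rank of a gene along its chromosome among *all* annotated genes.
``multicopy_rank``
    0-based rank among retained multi-copy genes only.  Gap and fragment
    arithmetic uses this scale by default, because single-copy genes are
    removed from consideration before clustering.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "ParalogPair",
    "ParalogySet",
    "Parameters",
    "Fragment",
    "Region",
    "KTuple",
    "GenomeIndex",
    "Solution",
    "canonical_pair",
    "merge_fragment_lists",
]


def canonical_pair(gene_a: str, gene_b: str) -> tuple[str, str]:
    """Return the unordered pair in canonical (lexicographic) storage order."""
    return (gene_a, gene_b) if gene_a < gene_b else (gene_b, gene_a)


@dataclass(frozen=True)
class ParalogPair:
    """An unordered pair of paralogous genes with a similarity score.

    ``gene_a < gene_b`` lexicographically (canonical storage).  The similarity
    is on whatever scale the comparison tool reports (e.g. a 0-100 percent
    identity); the algorithm only requires that larger means more similar.
    """

    gene_a: str
    gene_b: str
    similarity: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair not allowed: {self.gene_a}")
        if self.gene_a > self.gene_b:
            raise ValueError(
                f"pair not canonical: {self.gene_a!r} > {self.gene_b!r}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass(frozen=True)
class ParalogySet:
    """A connected component of the (trimmed) paralogy graph: 2..k genes.

    ``edges`` are the similarity edges that survived trimming; they form a
    connected graph on ``genes`` and are the edges counted when looking for
    aliquoting defects.
    """

    set_id: int
    genes: frozenset[str]
    edges: tuple[ParalogPair, ...]

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError(f"paralogy set {self.set_id} has < 2 genes")
        for e in self.edges:
            if e.gene_a not in self.genes or e.gene_b not in self.genes:
                raise ValueError(
                    f"edge {e.key} leaves paralogy set {self.set_id}"
                )


@dataclass(frozen=True)
class Parameters:
    """Run parameters for the aliquoting pipeline.

    k : hypothesized ploidy (>= 3), the maximum paralogy-set size and the
        maximum number of regions per tuple.
    r : short-gap reward (> 0), in gap-units of genes.  A merge part closing
        or nearly closing a gap earns up to ``r``.
    j : chromosome-jump penalty magnitude (> 0); subtracted once per matched
        part that brings a new chromosome into the merged region.
    h : aliquoting-defect penalty per new defect; ``None`` means "equal to r"
        (one new defect cancels one perfect-gap reward).
    t : post-processing gap threshold (>= 0); same-chromosome gaps of fewer
        than ``t`` multi-copy genes are filled by relocating genes.
    sim_min, sim_max : similarity band retained by preprocessing (closed).
    jump_rule : "per-part" charges j inside the per-region sum (default);
        "per-tuple" charges j once per merge if any part introduces a jump.
    max_move_defects : maximum number of new defects a single gap-filling
        move may create (0 = only defect-free moves).
    gap_units : "multicopy" counts gaps in multicopy_rank units (default);
        "all-genes" counts every annotated gene lying in the gap.
    """

    k: int = 3
    r: float = 40.0
    j: float = 15.0
    h: float | None = None
    t: int = 3
    sim_min: float = -math.inf
    sim_max: float = math.inf
    jump_rule: str = "per-part"
    max_move_defects: int = 0
    gap_units: str = "multicopy"

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ValueError("k must be >= 3")
        if self.r <= 0:
            raise ValueError("r must be > 0")
        if self.j <= 0:
            raise ValueError("j must be > 0 (stored as a magnitude)")
        if self.h is not None and self.h <= 0:
            raise ValueError("h must be > 0")
        if self.t < 0:
            raise ValueError("t must be >= 0")
        if self.sim_min > self.sim_max:
            raise ValueError("sim_min > sim_max")
        if self.jump_rule not in ("per-part", "per-tuple"):
            raise ValueError(f"unknown jump_rule {self.jump_rule!r}")
        if self.max_move_defects < 0:
            raise ValueError("max_move_defects must be >= 0")
        if self.gap_units not in ("multicopy", "all-genes"):
            raise ValueError(f"unknown gap_units {self.gap_units!r}")

    @property
    def effective_h(self) -> float:
        return self.r if self.h is None else self.h

    def to_dict(self) -> dict:
        """JSON-safe mapping (infinite band bounds become None)."""
        out = {}
        for k, v in vars(self).items():
            out[k] = None if isinstance(v, float) and math.isinf(v) else v
        return out


@dataclass(frozen=True)
class Fragment:
    """A maximal run of contiguous multi-copy genes on one chromosome."""

    chromosome: str
    start_rank: int
    end_rank: int

    def __post_init__(self) -> None:
        if self.start_rank > self.end_rank:
            raise ValueError("start_rank > end_rank")

    def __len__(self) -> int:
        return self.end_rank - self.start_rank + 1


def merge_fragment_lists(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Merge two sorted fragment lists on one chromosome, coalescing
    touching or interleaving runs into maximal fragments.

    Inputs come from gene-disjoint regions, so intervals never share a rank,
    but they may interleave; a run is coalesced whenever the next fragment
    starts at or before ``current_end + 1``.
    """
    out: list[tuple[int, int]] = []
    ia = ib = 0
    na, nb = len(a), len(b)
    while ia < na or ib < nb:
        if ib >= nb or (ia < na and a[ia][0] <= b[ib][0]):
            s, e = a[ia]
            ia += 1
        else:
            s, e = b[ib]
            ib += 1
        if out and s <= out[-1][1] + 1:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def _gapped(frags: Sequence[tuple[int, int]]) -> int:
    return sum(frags[i + 1][0] - frags[i][1] - 1 for i in range(len(frags) - 1))


class Region:
    """A set of fragments across one or more chromosomes.

    Internally a mapping ``chromosome -> sorted list of (start, end) rank
    intervals`` (maximal, coalesced).  Gap counts (``gapped_genes``) and
    chromosome jumps are derived from the fragment structure; fragments are
    reported sorted by (chromosome, start_rank), under which ordering the
    number of jumps is ``len(chromosomes) - 1``.
    """

    __slots__ = ("frags", "gapped_genes", "n_genes")

    def __init__(self, frags: Mapping[str, Sequence[tuple[int, int]]]):
        self.frags: dict[str, list[tuple[int, int]]] = {
            c: list(fl) for c, fl in frags.items() if fl
        }
        self.gapped_genes = sum(_gapped(fl) for fl in self.frags.values())
        self.n_genes = sum(
            e - s + 1 for fl in self.frags.values() for s, e in fl
        )

    @classmethod
    def from_gene(cls, chromosome: str, rank: int) -> "Region":
        return cls({chromosome: [(rank, rank)]})

    @classmethod
    def from_positions(cls, positions: Iterable[tuple[str, int]]) -> "Region":
        """Build a region from (chromosome, rank) gene positions."""
        by_chrom: dict[str, list[int]] = {}
        for c, rk in positions:
            by_chrom.setdefault(c, []).append(rk)
        frags: dict[str, list[tuple[int, int]]] = {}
        for c, ranks in by_chrom.items():
            ranks.sort()
            fl: list[tuple[int, int]] = []
            for rk in ranks:
                if fl and rk == fl[-1][1] + 1:
                    fl[-1] = (fl[-1][0], rk)
                elif fl and rk <= fl[-1][1]:
                    raise ValueError(f"duplicate rank {rk} on {c}")
                else:
                    fl.append((rk, rk))
            frags[c] = fl
        return cls(frags)

    @property
    def chromosomes(self) -> set[str]:
        return set(self.frags)

    @property
    def jumps(self) -> int:
        return max(0, len(self.frags) - 1)

    @property
    def n_fragments(self) -> int:
        return sum(len(fl) for fl in self.frags.values())

    def fragments(self) -> list[Fragment]:
        return [
            Fragment(c, s, e)
            for c in sorted(self.frags)
            for s, e in self.frags[c]
        ]

    def hull(self, chromosome: str) -> tuple[int, int] | None:
        fl = self.frags.get(chromosome)
        if not fl:
            return None
        return (fl[0][0], fl[-1][1])

    def contains(self, chromosome: str, rank: int) -> bool:
        fl = self.frags.get(chromosome)
        if not fl:
            return False
        i = bisect.bisect_right(fl, (rank, math.inf)) - 1
        return i >= 0 and fl[i][0] <= rank <= fl[i][1]

    def iter_positions(self) -> Iterator[tuple[str, int]]:
        for c in sorted(self.frags):
            for s, e in self.frags[c]:
                for rk in range(s, e + 1):
                    yield (c, rk)

    def __len__(self) -> int:
        return self.n_genes

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        parts = [
            f"{c}:{s}-{e}" for c in sorted(self.frags) for s, e in self.frags[c]
        ]
        return f"Region({', '.join(parts)})"


def merge_regions(a: Region, b: Region) -> tuple[Region, int, bool, bool]:
    """Merge two gene-disjoint regions.

    Returns ``(merged, x, jump_flag, shares_chromosome)`` where ``x`` is the
    change in gapped genes (merged minus the two inputs) and ``jump_flag`` is
    true iff the merged region spans more chromosomes than either input alone,
    i.e. the merge introduces a new chromosome jump.
    """
    frags: dict[str, list[tuple[int, int]]] = dict(a.frags)
    shared = False
    for c, fl in b.frags.items():
        if c in frags:
            shared = True
            frags[c] = merge_fragment_lists(frags[c], fl)
        else:
            frags[c] = list(fl)
    merged = Region.__new__(Region)
    merged.frags = frags
    merged.gapped_genes = sum(_gapped(fl) for fl in frags.values())
    merged.n_genes = a.n_genes + b.n_genes
    if merged.n_genes != sum(e - s + 1 for fl in frags.values() for s, e in fl):
        raise ValueError("regions share a gene (overlapping ranks)")
    x = merged.gapped_genes - a.gapped_genes - b.gapped_genes
    jump_flag = len(frags) > max(len(a.frags), len(b.frags))
    return merged, x, jump_flag, shared


class KTuple:
    """A cluster of up to ``k`` putatively homeologous regions.

    ``set_ids`` records the paralogy sets absorbed; ``defects`` caches the
    number of retained paralog pairs whose two genes lie in one region
    (recomputable from scratch, asserted in audit mode).
    """

    __slots__ = ("tuple_id", "regions", "set_ids", "defects")

    def __init__(
        self,
        tuple_id: int,
        regions: list[Region],
        set_ids: list[int],
        defects: int = 0,
    ):
        if not 1 <= len(regions):
            raise ValueError("a k-tuple needs at least one region")
        self.tuple_id = tuple_id
        self.regions = regions
        self.set_ids = set_ids
        self.defects = defects

    @property
    def n_genes(self) -> int:
        return sum(r.n_genes for r in self.regions)

    @property
    def chromosomes(self) -> set[str]:
        out: set[str] = set()
        for r in self.regions:
            out |= r.chromosomes
        return out

    def region_of(self, chromosome: str, rank: int) -> int | None:
        for i, r in enumerate(self.regions):
            if r.contains(chromosome, rank):
                return i
        return None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"KTuple({self.tuple_id}, {len(self.regions)} regions, "
            f"{self.n_genes} genes, {self.defects} defects)"
        )


class GenomeIndex:
    """Bidirectional map between genes and (chromosome, rank).

    Built from a gene table once multi-copy ranks are assigned; the clustering
    core works purely in rank space and uses this index to translate back to
    gene identifiers.  Under the default gap units the rank scale is the
    dense multi-copy rank; under all-genes units it is ``order_index``, in
    which case the rank axis has holes at single-copy genes (empty slots).
    """

    def __init__(self, rank_of: Mapping[str, tuple[str, int]]):
        self.rank_of: dict[str, tuple[str, int]] = dict(rank_of)
        self.gene_at: dict[str, list[str]] = {}
        for g, (c, rk) in self.rank_of.items():
            lst = self.gene_at.setdefault(c, [])
            if rk >= len(lst):
                lst.extend([""] * (rk + 1 - len(lst)))
            if lst[rk]:
                raise ValueError(f"rank collision at {c}:{rk}")
            lst[rk] = g

    @classmethod
    def from_gene_table(cls, genes) -> "GenomeIndex":
        """Build from a gene table DataFrame with a ``multicopy_rank`` column."""
        multi = genes[genes["multicopy_rank"].notna()]
        return cls(
            {
                row.gene: (row.chromosome, int(row.multicopy_rank))
                for row in multi.itertuples()
            }
        )

    @property
    def n_multicopy(self) -> int:
        return len(self.rank_of)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.gene_at)

    def genes_in(self, region: Region) -> list[str]:
        out = []
        for c, rk in region.iter_positions():
            g = self.gene_at[c][rk]
            if g:  # skip single-copy holes (all-genes rank units)
                out.append(g)
        return out


@dataclass
class Solution:
    """The output of aliquoting: the final k-tuples plus bookkeeping.

    ``ktuples`` keep their creation-order ids from the clustering run;
    serialization renumbers tuples and regions sequentially.
    """

    ktuples: list[KTuple]
    sets: dict[int, ParalogySet]
    index: GenomeIndex
    params: Parameters
    n_input_sets: int = 0
    n_input_chromosomes: int = 0
    n_merges: int = 0
    moved_genes: list[str] = field(default_factory=list)
    inconsistent_genes: int = 0

    @property
    def C_doubleprime(self) -> int:
        return len(self.ktuples)

    @property
    def n_fragments(self) -> int:
        return sum(r.n_fragments for t in self.ktuples for r in t.regions)

    def included_tuples(self) -> list[KTuple]:
        """K-tuples built from at least two paralogy sets: the detected
        homeologous structures (a never-merged set is not a detection)."""
        return [t for t in self.ktuples if len(t.set_ids) >= 2]

    def assignments(self) -> dict[str, tuple[int, int]]:
        """gene -> (tuple creation id, region index within tuple)."""
        out: dict[str, tuple[int, int]] = {}
        for t in self.ktuples:
            for ri, reg in enumerate(t.regions):
                for g in self.index.genes_in(reg):
                    out[g] = (t.tuple_id, ri)
        return out

    def validate(self) -> None:
        """Check conservation and recomputability invariants; raise on
        violation.  Used by tests and audit mode."""
        seen: set[str] = set()
        for t in self.ktuples:
            if not 1 <= len(t.regions) <= self.params.k:
                raise AssertionError(
                    f"tuple {t.tuple_id} has {len(t.regions)} regions"
                )
            for reg in t.regions:
                for c, fl in reg.frags.items():
                    for i in range(1, len(fl)):
                        if fl[i][0] <= fl[i - 1][1] + 1:
                            raise AssertionError("fragments not maximal")
                genes = self.index.genes_in(reg)
                dup = seen.intersection(genes)
                if dup:
                    raise AssertionError(f"genes in two regions: {sorted(dup)[:3]}")
                seen.update(genes)
                if reg.gapped_genes != sum(
                    _gapped(fl) for fl in reg.frags.values()
                ):
                    raise AssertionError("stale gapped_genes cache")
        # every recorded defect count must equal a from-scratch recount:
        # a defect is a retained paralog pair whose two genes share a region,
        # attributed to the tuple owning that region
        assign = self.assignments()
        recount: dict[int, int] = {t.tuple_id: 0 for t in self.ktuples}
        for s in self.sets.values():
            for e in s.edges:
                pa = assign.get(e.gene_a)
                pb = assign.get(e.gene_b)
                if pa is not None and pa == pb:
                    recount[pa[0]] += 1
        for t in self.ktuples:
            if recount[t.tuple_id] != t.defects:
                raise AssertionError(
                    f"tuple {t.tuple_id}: defects {t.defects} != "
                    f"recount {recount[t.tuple_id]}"
                )
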