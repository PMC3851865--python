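"""From raw paralog pairs to <= k-member paralogy sets on a multi-copy order.

Steps, in pipeline order:

1. ``filter_similarity`` keeps pairs inside the similarity band
   [sim_min, sim_max] (closed on both ends; a lower cutoff of 72 removes
   pairs with similarity *below* 72).  The band is how contamination from an
   older or younger polyploidy event is controlled.
2. ``build_paralogy_sets`` takes connected components of the filtered
   paralogy graph; genes touching no retained pair are single-copy and carry
   no aliquoting information.
3. ``trim_to_k`` deletes the weakest similarity edges of any component with
   more than k genes until every component has at most k, re-computing
   connectivity after each deletion.  Components reduced to one gene revert
   to single-copy status.
4. ``assign_multicopy_ranks`` numbers the surviving multi-copy genes 0..m-1
   along each chromosome; all gap arithmetic downstream runs on this scale.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .model import GenomeIndex, ParalogPair, ParalogySet, Parameters

logger = logging.getLogger(__name__)

TANDEM_WARN_RANKS = 5


def filter_similarity(
    pairs: Sequence[ParalogPair],
    sim_min: float = float("-inf"),
    sim_max: float = float("inf"),
) -> list[ParalogPair]:
    """Keep pairs with sim_min <= similarity <= sim_max, preserving order."""
    if sim_min > sim_max:
        raise ValueError("sim_min > sim_max")
    kept = [p for p in pairs if sim_min <= p.similarity <= sim_max]
    logger.info(
        "similarity filter [%s, %s]: kept %d of %d pairs",
        sim_min,
        sim_max,
        len(kept),
        len(pairs),
    )
    if pairs and not kept:
        logger.warning("similarity band removed every pair")
    return kept


def build_paralogy_graph(pairs: Iterable[ParalogPair]) -> nx.Graph:
    g = nx.Graph()
    for p in pairs:
        # parallel pairs were already deduplicated to max similarity on read
        g.add_edge(p.gene_a, p.gene_b, similarity=p.similarity)
    return g


def trim_to_k(component: nx.Graph, k: int) -> list[nx.Graph]:
    """Split an oversized connected component by deleting its weakest edges.

    While the component holds more than k genes, remove the globally weakest
    remaining edge (ties broken by canonical pair id) and recompute
    connectivity; recurse into the resulting components.  Returns connected
    subgraphs of size <= k (including size-1 remnants; the caller discards
    those to single-copy status).
    """
    if component.number_of_nodes() <= k:
        return [component]
    g = component.copy()
    u, v = min(
        g.edges,
        key=lambda e: (
            g.edges[e]["similarity"],
            *(e if e[0] < e[1] else (e[1], e[0])),
        ),
    )
    g.remove_edge(u, v)
    out: list[nx.Graph] = []
    for nodes in nx.connected_components(g):
        out.extend(trim_to_k(g.subgraph(nodes).copy(), k))
    return out


def build_paralogy_sets(
    pairs: Sequence[ParalogPair], k: int
) -> tuple[dict[int, ParalogySet], list[str]]:
    """Partition genes incident to pairs into paralogy sets of 2..k genes.

    Returns ``(sets keyed by set_id, genes dropped back to single-copy)``.
    Set ids are assigned in order of each set's lexicographically smallest
    gene, making the output deterministic for a given input.
    """
    graph = build_paralogy_graph(pairs)
    final: list[nx.Graph] = []
    dropped: list[str] = []
    n_oversized = 0
    for nodes in nx.connected_components(graph):
        comp = graph.subgraph(nodes).copy()
        if comp.number_of_nodes() > k:
            n_oversized += 1
        for sub in trim_to_k(comp, k):
            if sub.number_of_nodes() < 2:
                dropped.extend(sub.nodes)
            else:
                final.append(sub)
    final.sort(key=lambda g: min(g.nodes))
    sets: dict[int, ParalogySet] = {}
    for sid, sub in enumerate(final):
        edges = tuple(
            sorted(
                (
                    ParalogPair(
                        *((u, v) if u < v else (v, u)),
                        sub.edges[u, v]["similarity"],
                    )
                    for u, v in sub.edges
                ),
                key=lambda e: e.key,
            )
        )
        sets[sid] = ParalogySet(sid, frozenset(sub.nodes), edges)
    logger.info(
        "paralogy sets: %d sets from %d pairs (%d oversized components "
        "trimmed, %d genes dropped to single-copy)",
        len(sets),
        len(pairs),
        n_oversized,
        len(dropped),
    )
    return sets, sorted(dropped)


def assign_multicopy_ranks(
    gene_table: pd.DataFrame,
    sets: dict[int, ParalogySet],
    gap_units: str = "multicopy",
) -> pd.DataFrame:
    """Mark copy classes and assign per-chromosome multi-copy ranks.

    Multi-copy genes are exactly the members of the final paralogy sets;
    under the default ``gap_units="multicopy"`` they are numbered 0..m-1
    along each chromosome in ``order_index`` order, so downstream gap
    counts ignore single-copy genes.  Under ``"all-genes"`` the rank *is*
    the order_index, so gaps count every annotated gene they skip.
    Returns a new gene table with ``copy_class`` and ``multicopy_rank``
    columns; single-copy genes get a missing rank.
    """
    multi = set()
    for s in sets.values():
        multi |= s.genes
    missing = multi.difference(gene_table["gene"])
    if missing:
        raise ValueError(
            f"{len(missing)} paralogy-set genes absent from the gene table, "
            f"e.g. {sorted(missing)[:3]}"
        )
    out = gene_table.sort_values(
        ["chromosome", "order_index"], kind="mergesort"
    ).copy()
    out["copy_class"] = [
        "multi" if g in multi else "single" for g in out["gene"]
    ]
    is_multi = out["copy_class"] == "multi"
    if gap_units == "all-genes":
        out["multicopy_rank"] = out["order_index"].where(is_multi).astype("Int64")
    else:
        out["multicopy_rank"] = (
            out[is_multi].groupby("chromosome").cumcount().reindex(out.index)
        ).astype("Int64")
    return out.reset_index(drop=True)


def warn_tandem_like(
    sets: dict[int, ParalogySet], index: GenomeIndex
) -> list[tuple[str, str]]:
    """Flag retained pairs whose genes sit within a few ranks on one
    chromosome - candidate tandem duplicates, which the polyploidy model does
    not expect.  They are kept, only logged."""
    suspicious: list[tuple[str, str]] = []
    for s in sets.values():
        for e in s.edges:
            ca, ra = index.rank_of[e.gene_a]
            cb, rb = index.rank_of[e.gene_b]
            if ca == cb and abs(ra - rb) <= TANDEM_WARN_RANKS:
                suspicious.append(e.key)
    if suspicious:
        logger.warning(
            "%d retained pairs look tandem-like (within %d ranks), e.g. %s",
            len(suspicious),
            TANDEM_WARN_RANKS,
            suspicious[:3],
        )
    return suspicious


def preprocess(
    pairs: Sequence[ParalogPair],
    gene_table: pd.DataFrame,
    params: Parameters,
) -> tuple[dict[int, ParalogySet], pd.DataFrame, GenomeIndex]:
    """Similarity filter -> components -> trim -> ranks, in one call.

    Returns the final paralogy sets, the annotated gene table and the
    rank index the clustering core consumes.
    """
    kept = filter_similarity(pairs, params.sim_min, params.sim_max)
    sets, _ = build_paralogy_sets(kept, params.k)
    table = assign_multicopy_ranks(gene_table, sets, params.gap_units)
    index = GenomeIndex.from_gene_table(table)
    warn_tandem_like(sets, index)
    return sets, table, index
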