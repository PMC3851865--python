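"""Validation metrics against planted simulation truth.

A correct aliquoting groups the descendants of each ancestral chromosome
into one k-tuple, with each region drawn from a single subgenome.  The
metrics quantify this:

* adjusted Rand index (ARI) between inferred tuple membership and planted
  ancestral-chromosome membership, over placed genes;
* per-region subgenome purity (fraction of a region's genes from its modal
  planted subgenome);
* the fate of retained paralog pairs: across distinct regions of one tuple
  (the ideal), within one region (aliquoting defects), or across tuples
  (splits);
* the dominance direction: the planted subgenome behind the gene-richest
  region of each tuple.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .core import region_rank_classes
from .model import Solution
from .simulate import Truth


@dataclass(frozen=True)
class RecoveryMetrics:
    ari: float
    mean_region_purity: float
    pair_ideal_fraction: float
    pair_defect_fraction: float
    pair_split_fraction: float
    dominant_subgenome: int | None
    largest_class_modal_subgenomes: tuple[int, ...]
    n_placed: int


def recovery_metrics(solution: Solution, truth: Truth) -> RecoveryMetrics:
    """Compare a solution with the planted truth of the simulation that
    produced its input.  Genes in k-tuples of >= 2 member sets count as
    placed; raises if the solution contains genes the truth does not."""
    tg = truth.genes.set_index("gene")
    anc = tg["ancestral_chromosome"].to_dict()
    sub = tg["subgenome"].to_dict()

    placed_genes: list[str] = []
    placed_labels: list[int] = []
    purities: list[float] = []
    largest_modal: list[int] = []
    included = solution.included_tuples()
    for t in included:
        classes = region_rank_classes(t)
        for reg, cls in zip(t.regions, classes):
            genes = solution.index.genes_in(reg)
            unknown = [g for g in genes if g not in anc]
            if unknown:
                raise ValueError(
                    f"solution gene absent from truth: {unknown[0]!r}"
                )
            subs = np.array([sub[g] for g in genes])
            modal = int(np.bincount(subs).argmax())
            purities.append(float((subs == modal).mean()))
            if cls == "largest":
                largest_modal.append(modal)
            placed_genes.extend(genes)
            placed_labels.extend(anc[g] for g in genes)

    assign = solution.assignments()
    tuple_of = {g: assign[g][0] for g in placed_genes}
    ari = (
        float(
            adjusted_rand_score(
                placed_labels, [tuple_of[g] for g in placed_genes]
            )
        )
        if placed_genes
        else float("nan")
    )

    ideal = defect = split = 0
    for s in solution.sets.values():
        for e in s.edges:
            pa = assign.get(e.gene_a)
            pb = assign.get(e.gene_b)
            if pa is None or pb is None:
                continue
            if pa == pb:
                defect += 1
            elif pa[0] == pb[0]:
                ideal += 1
            else:
                split += 1
    n_pairs = ideal + defect + split

    dominant = (
        int(np.bincount(largest_modal).argmax()) if largest_modal else None
    )
    return RecoveryMetrics(
        ari=ari,
        mean_region_purity=float(np.mean(purities)) if purities else float("nan"),
        pair_ideal_fraction=ideal / n_pairs if n_pairs else float("nan"),
        pair_defect_fraction=defect / n_pairs if n_pairs else float("nan"),
        pair_split_fraction=split / n_pairs if n_pairs else float("nan"),
        dominant_subgenome=dominant,
        largest_class_modal_subgenomes=tuple(largest_modal),
        n_placed=len(placed_genes),
    )
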