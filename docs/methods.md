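# Methods

## Model and assumptions

The package assumes the genome under study descends from a single
2k-ploidization with known k > 2 (k is not inferred). Genes matter only
through (a) their position in the gene order of a chromosome and (b) the
paralogy set they belong to; strand and sequence are ignored. Paralogy
assignments are taken from the input pair table and treated as essentially
correct once the similarity band has removed contamination from other
polyploidy events. All gene-order arithmetic runs, by default, on the
*multi-copy rank* scale: single-copy genes are removed before clustering
and do not count toward gaps (`gap_units="all-genes"` switches gaps to the
full annotated order; the gap reward `r` is then in all-gene units).

## Preprocessing

* **Similarity band** `[sim_min, sim_max]`, closed on both ends: a cutoff
  of 72 keeps pairs with similarity ≥ 72. The upper bound defaults to +∞;
  it exists to exclude very recent duplicates if needed.
* **Components and trimming.** Connected components of the filtered
  paralogy graph become paralogy sets. A component with more than k genes
  loses its globally weakest edge (ties: lexicographic canonical pair id)
  repeatedly, with connectivity recomputed after every deletion, until all
  pieces have ≤ k genes. Pieces reduced to one gene revert to single-copy
  status. Edges are trimmed, not vertices, because weak edges are the
  likely contaminants (e.g. from an older event bridging two families).
* **Tandem-like pairs** (both genes within 5 ranks on one chromosome) are
  kept but logged; the model does not expect them.

## The merge score

Merging two k-tuples requires an injective partial matching between their
regions (a region may also carry over unmatched); the merged tuple may not
exceed k regions. For k ≤ 5 all admissible matchings are enumerated
(≤ 5! per pair) and the score-maximal one is kept, ties broken by the
lexicographically smallest matching. Each matched part contributes

* `r` if the part reduces the total number of gapped genes (x < 0) — any
  fill of an existing gap earns the full reward;
* `max(0, r − x)` otherwise, where x is the change in gapped genes;
* minus `j` if the merged region spans more chromosomes than either input
  region alone (the part introduces a chromosome jump);
* and a part whose two regions share **no** chromosome earns no gap
  component at all, only −j.

The last rule is a deliberate design decision. Gaps are a same-chromosome
notion, so a chromosome-disjoint part always has x = 0; awarding it
`max(0, r − 0) = r` would make *every* cross-chromosome merge profitable
whenever r > j, and the greedy loop would collapse the genome into a
single k-tuple — incompatible both with meaningful output (separate
clusters can share a fused chromosome) and with the while-S > 0
termination semantics. Restricting the reward to the gap channel is the
minimal consistent reading. Finally, if the matching newly places d > 0
retained paralog pairs inside one region (aliquoting defects), `h·d` is
subtracted once for the merge. With pipeline-built tuples d is
structurally 0 during clustering (tuples absorb whole paralogy sets, and
matchings never merge two regions of the same tuple), so the defect term
guards post-processing and externally constructed tuples; it is exercised
directly in tests.

`--jump-rule per-tuple` charges j once per merge instead of once per
jumping part; the default `per-part` follows the placement of the jump
indicator inside the per-region sum.

## Parameters

| name | meaning | default | units |
|------|---------|---------|-------|
| k | hypothesized ploidy | 3 | – |
| r | short-gap reward | 40 | genes (multi-copy ranks) |
| j | chromosome-jump penalty | 15 | score units |
| h | defect penalty | = r | score units per defect |
| t | post-processing gap threshold | 3 | genes |
| sim_min/sim_max | similarity band | −∞/+∞ | score scale of the input |

Defaults for r, j, t follow established practice for hexaploid plant
genomes at this gene density. **Guidance on j:** at ploidy k, a merge
supported by a single shared-chromosome adjacency plus k−1 jumping parts
scores r − (k−1)j, while the legitimate re-join of a translocated segment
supported by k−1 shared chromosomes scores (k−1)r − j. Choosing j in
[r/(k−1), (k−1)r) blocks the former; choosing j in [r, (k−1)r)
additionally blocks single-part "bridge" merges between 2-region tuples
(r − j ≤ 0). The validation studies therefore run with j = 40 (= r) at
r = 40, k = 3. The spurious merges that remain are those supported by two
or more independent shared-chromosome adjacencies — see Limitations.

## Greedy agglomeration

Initialization makes one k-tuple per paralogy set (one single-gene region
per member) and scores all candidate pairs (quadratic); a lazy max-heap
drives the iteration, and after each merge only pairs involving the new
tuple are rescored (linear update). Candidate generation prunes pairs
whose per-chromosome fragment hulls, expanded by r + 1 ranks, are disjoint
on every shared chromosome: such pairs cannot reach a positive score
(every shared-chromosome part then has x > r and no fill is possible).
Ties on the maximal S break on the smallest (tuple_id, tuple_id), making
runs bit-reproducible; the core is fully deterministic, all randomness
lives in the simulator. An `audit=True` mode re-scans all live pairs
un-pruned at every step, asserts the executed merge is maximal, and
recounts every cached gap/jump/defect figure from scratch; tests run it on
small instances, and separately assert pruned and un-pruned runs coincide.

## Post-processing

For every same-chromosome gap of fewer than t multi-copy genes between
consecutive fragments of a region, the gap's genes are pulled out of their
current regions into the gapped region, provided the move creates at most
`max_move_defects` new defects (default 0). Gaps are scanned in
deterministic order (tuple id, region, fragment order); a gap is moved
atomically (all its genes or none); each gene relocates at most once per
pass and a gap containing an already-moved gene is left alone, so the pass
terminates and cannot oscillate. Regions and tuples emptied by moves are
deleted. A moved gene left with a retained paralog in the same region, or
in a different tuple, is counted *inconsistent*. Raising t recruits more
genes into dense regions at the price of inconsistent genes; t = 0
disables the step. The `sweep` subcommand tabulates this trade-off; the
choice remains instance-specific and is not automated.

## Solution characteristics

C″ counts all final k-tuples (with zero merges, C″ = n). A k-tuple built
from at least two paralogy sets counts as *detected*; `genes_included` is
the number (and proportion) of multi-copy genes in detected tuples — a
never-merged singleton set is not a detected homeologous structure.
Within each detected tuple, regions are ranked by gene count into
largest / middle / smallest classes; the summary reports mean gene counts
and mean chromosomes-per-region per class, which is how subgenome
dominance (unequal retention) shows up. Region *spans* (first to last gene
in all-gene order units, per chromosome) and the counts of single-copy
genes inside/outside all spans quantify how much of the genome the
solution organizes.

## The simulator

`SimConfig` defaults define the validation conditions: k = 3, C = 7
ancestral chromosomes × 300 families, 30 inversions (tract length uniform
in [2, 50] genes — inversion tracts are short relative to chromosomes, and
unbounded tracts would turn every junction-crossing inversion into a
junction multiplier, conflating inversion and translocation counts), 5
reciprocal translocations (uniform suffix swaps), 2 fusions, 2 fissions,
retention (0.8, 0.5, 0.4) modelling subgenome dominance, target-event
similarities N(80, 4²) clipped to (0, 100], and 30 % contamination pairs
between random non-family genes at N(60, 4²) mimicking an older event.
Fractionation is per-copy independent Bernoulli, redrawn when a family
would lose all copies (the single-copy floor); a geometric run-length
deletion mode exists for robustness checks. Families reduced to one copy
are emitted as single-copy genes without pairs.

What the generator does **not** emulate: molecular-clock sequence
evolution (similarities are exchangeable noise, only the overlap of the
two similarity modes matters), tandem duplication, gene conversion,
positionally correlated fractionation between subgenomes, or an explicit
two-round nested polyploidy (contamination pairs approximate the older
event's effect on the pair table). Passing the validation studies
therefore demonstrates correct reconstruction under rearrangement,
dominance-biased loss and band-filterable contamination — not robustness
to paralogy-assignment error or assembly artifacts in real data.

## Validation studies and problem sizes

* *Clean recovery*: the default genome with zero events and full
  retention (6,300 genes, 2,100 sets) must yield exactly 7 k-tuples of
  three gapless, jumpless, defect-free regions, 100 % inclusion, ARI 1.0.
* *Noisy recovery*: ten replicates at the default noisy conditions
  (~1,300 sets each); metrics are the ARI between tuple membership and
  planted ancestral chromosome over included genes, and whether the
  modal subgenome of the gene-richest region class is the 0.8-retention
  one. These sizes keep the full suite within a few minutes on one CPU.
* *Oracle equivalence*: on instances of ≤ 7 sets, every executed merge is
  verified maximal by full re-scan, and greedy output equals exhaustive
  search over merge orders on fixtures with a unique positive merge
  available at each step.

## Known limitations

* **Two-link ambiguity.** Two ancestral chromosomes connected by two
  independent rearrangement links with distinct subgenome coordinates on
  both sides are *score-indistinguishable* from one ancestral chromosome
  split by a translocation: both present two shared-chromosome adjacencies
  plus one jump part, S = (k−1)r − j. No parameter setting can reject the
  former while keeping the latter, so such pairs fuse into one k-tuple.
  Under the default noisy conditions this affects roughly a third to a
  half of replicates (one fusion costs ≈ 0.15 ARI); it is a property of
  the objective, not of the search. Any claim of ancestral-chromosome
  recovery should be read per-tuple (purity stays high) rather than
  genome-wide.
* The greedy search carries no optimality guarantee beyond the audited
  max-S property at each step.
* k and the similarity band are user inputs; the package neither dates
  polyploidy events nor infers ploidy.
* Post-processing outcomes depend on scan order (deterministically so).
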