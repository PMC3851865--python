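"""Seeded simulator of post-polyploidization genome evolution.

The model: an ancestor of ``C`` chromosomes, each carrying
``genes_per_chromosome`` gene families in order, undergoes 2k-ploidization
(every chromosome and gene replicated into k subgenomes), then evolves by

* inversions (reverse a random interval of one chromosome),
* reciprocal translocations (swap the suffixes of two chromosomes),
* fusions (concatenate two chromosomes) and fissions (split one),

followed by *fractionation*: each family member is retained independently
with its subgenome's retention probability (unequal probabilities model
subgenome dominance); if every copy of a family would be lost the draw is
resampled, honouring the rule that at least one copy per family survives.
Families reduced to a single copy become single-copy genes - present in the
gene table, absent from the pair table.

The emitted paralog-pair table contains all within-family pairs among
survivors, with similarities drawn from a Gaussian clipped to (0, 100]
(the polyploidy event of interest), plus contamination pairs between random
genes of different families at a lower similarity mode, mimicking an older
event whose paralog similarities overlap the band filter.

Everything is deterministic given the seed.  Planted truth (family,
ancestral chromosome, subgenome of every gene; event of origin of every
pair) is returned alongside for validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import canonical_pair

logger = logging.getLogger(__name__)

SUBGENOME_LETTERS = "abcdefgh"


@dataclass(frozen=True)
class SimConfig:
    """Simulation scenario.

    Defaults are the moderate-rearrangement, dominance-biased scenario used
    throughout validation: a paleohexaploid (k=3) of 7 ancestral
    chromosomes, 300 families each, 30 inversions, 5 reciprocal
    translocations, 2 fusions, 2 fissions, retention (0.8, 0.5, 0.4), and
    30% old-event contamination centred at similarity 60 against a target
    event centred at 80.
    """

    k: int = 3
    C: int = 7
    genes_per_chromosome: int = 300
    inversions: int = 30
    inversion_max_len: int | None = 50
    translocations: int = 5
    fusions: int = 2
    fissions: int = 2
    retention: tuple[float, ...] = (0.8, 0.5, 0.4)
    target_sim_mean: float = 80.0
    target_sim_sd: float = 4.0
    old_wgd_fraction: float = 0.3
    old_sim_mean: float = 60.0
    old_sim_sd: float = 4.0
    run_deletion: bool = False
    run_length_mean: float = 3.0
    seed: int = 17

    def __post_init__(self) -> None:
        if self.k < 2 or self.k > len(SUBGENOME_LETTERS):
            raise ValueError("k out of range")
        if len(self.retention) != self.k:
            raise ValueError("retention must list one probability per subgenome")
        if not all(0.0 <= p <= 1.0 for p in self.retention):
            raise ValueError("retention probabilities must be in [0, 1]")
        if any(p == 0.0 for p in self.retention) and all(
            p == 0.0 for p in self.retention
        ):
            raise ValueError("at least one subgenome must retain genes")
        for name in ("inversions", "translocations", "fusions", "fissions"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.old_wgd_fraction:
            raise ValueError("old_wgd_fraction must be >= 0")
        if self.C < 1 or self.genes_per_chromosome < 1:
            raise ValueError("need at least one chromosome and one family")


@dataclass
class Truth:
    """Planted ground truth: per-gene origin and per-pair event labels."""

    genes: pd.DataFrame  # gene, family, ancestral_chromosome, subgenome, n_copies
    pair_origins: pd.DataFrame  # gene_a, gene_b, origin in {target_wgd, old_wgd}

    def family_sizes(self) -> pd.Series:
        return self.genes.groupby("family")["gene"].count()


@dataclass
class SimResult:
    config: SimConfig
    genes: pd.DataFrame  # gene, chromosome, position, order_index, copy_class
    pairs: pd.DataFrame  # geneA..similarity, 7 plain-TSV columns
    truth: Truth


def _gene_id(family: int, subgenome: int) -> str:
    return f"F{family:05d}{SUBGENOME_LETTERS[subgenome]}"


def _apply_rearrangements(
    chroms: list[list[str]], cfg: SimConfig, rng: np.random.Generator
) -> list[list[str]]:
    events = (
        ["inv"] * cfg.inversions
        + ["tra"] * cfg.translocations
        + ["fus"] * cfg.fusions
        + ["fis"] * cfg.fissions
    )
    order = rng.permutation(len(events))
    for ev in (events[i] for i in order):
        if ev == "inv":
            ci = int(rng.integers(len(chroms)))
            n = len(chroms[ci])
            if n < 2:
                continue
            if cfg.inversion_max_len is None:
                i, j = sorted(int(v) for v in rng.integers(0, n, size=2))
            else:
                # inversion tracts are short relative to the chromosome:
                # uniform length in [2, inversion_max_len]
                length = int(
                    rng.integers(2, min(cfg.inversion_max_len, n) + 1)
                )
                i = int(rng.integers(0, n - length + 1))
                j = i + length - 1
            chroms[ci][i : j + 1] = chroms[ci][i : j + 1][::-1]
        elif ev == "tra":
            if len(chroms) < 2:
                continue
            ci, cj = (int(v) for v in rng.choice(len(chroms), 2, replace=False))
            if len(chroms[ci]) < 2 or len(chroms[cj]) < 2:
                continue
            cut_i = int(rng.integers(1, len(chroms[ci])))
            cut_j = int(rng.integers(1, len(chroms[cj])))
            tail_i, tail_j = chroms[ci][cut_i:], chroms[cj][cut_j:]
            chroms[ci] = chroms[ci][:cut_i] + tail_j
            chroms[cj] = chroms[cj][:cut_j] + tail_i
        elif ev == "fus":
            if len(chroms) < 2:
                continue
            ci, cj = sorted(
                int(v) for v in rng.choice(len(chroms), 2, replace=False)
            )
            chroms[ci] = chroms[ci] + chroms[cj]
            del chroms[cj]
        else:  # fission
            big = [i for i, c in enumerate(chroms) if len(c) >= 2]
            if not big:
                raise ValueError("fission impossible: no chromosome has >= 2 genes")
            ci = int(rng.choice(big))
            cut = int(rng.integers(1, len(chroms[ci])))
            chroms.append(chroms[ci][cut:])
            chroms[ci] = chroms[ci][:cut]
    return chroms


def _fractionate(
    n_families: int, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Boolean (n_families, k) retention mask with at least one survivor
    per family (all-lost draws are redrawn)."""
    p = np.asarray(cfg.retention)
    if cfg.run_deletion:
        # geometric run-length deletion along each pristine subgenome copy
        keep = np.ones((n_families, cfg.k), dtype=bool)
        for s in range(cfg.k):
            del_frac = 1.0 - p[s]
            if del_frac <= 0:
                continue
            # alternate kept/deleted runs; deleted runs geometric with the
            # configured mean, kept runs sized to hit the retention rate
            mean_del = cfg.run_length_mean
            mean_keep = mean_del * p[s] / del_frac if del_frac < 1 else 0.01
            i = 0
            deleting = rng.random() < del_frac
            while i < n_families:
                mean = mean_del if deleting else max(mean_keep, 0.01)
                run = 1 + int(rng.geometric(1.0 / (1.0 + mean)) - 1)
                if deleting:
                    keep[i : i + run, s] = False
                i += run
                deleting = not deleting
        lost = ~keep.any(axis=1)
        for fam in np.nonzero(lost)[0]:
            keep[fam, int(rng.integers(cfg.k))] = True
        return keep
    keep = rng.random((n_families, cfg.k)) < p
    bad = np.nonzero(~keep.any(axis=1))[0]
    while bad.size:
        keep[bad] = rng.random((bad.size, cfg.k)) < p
        bad = bad[~keep[bad].any(axis=1)]
    return keep


def simulate(config: SimConfig) -> SimResult:
    """Run the generator; see the module docstring for the model."""
    rng = np.random.default_rng(config.seed)
    n_families = config.C * config.genes_per_chromosome

    # ancestor, replicated k-fold
    chroms: list[list[str]] = []
    for s in range(config.k):
        for c in range(config.C):
            fams = range(
                c * config.genes_per_chromosome,
                (c + 1) * config.genes_per_chromosome,
            )
            chroms.append([_gene_id(f, s) for f in fams])

    chroms = _apply_rearrangements(chroms, config, rng)

    keep = _fractionate(n_families, config, rng)
    surviving = {
        _gene_id(f, s)
        for f in range(n_families)
        for s in range(config.k)
        if keep[f, s]
    }
    family_size = keep.sum(axis=1)

    gene_rows = []
    for ci, genes in enumerate(c for c in chroms if c):
        label = f"chr{ci + 1:02d}"
        order = 0
        for g in genes:
            if g not in surviving:
                continue
            fam = int(g[1:-1])
            gene_rows.append(
                (
                    g,
                    label,
                    float((order + 1) * 1000),  # synthetic bp coordinate
                    order,
                    "multi" if family_size[fam] >= 2 else "single",
                )
            )
            order += 1
    gene_table = pd.DataFrame(
        gene_rows,
        columns=["gene", "chromosome", "position", "order_index", "copy_class"],
    )
    loc = {
        row.gene: (row.chromosome, row.position)
        for row in gene_table.itertuples()
    }

    # within-family pairs among survivors: the target polyploidy event
    pair_rows = []
    origin_rows = []
    for fam in range(n_families):
        members = [
            _gene_id(fam, s) for s in range(config.k) if keep[fam, s]
        ]
        for i in range(len(members)):
            for jj in range(i + 1, len(members)):
                ga, gb = canonical_pair(members[i], members[jj])
                sim = float(
                    np.clip(
                        rng.normal(config.target_sim_mean, config.target_sim_sd),
                        1e-6,
                        100.0,
                    )
                )
                pair_rows.append((ga, gb, sim))
                origin_rows.append((ga, gb, "target_wgd"))

    # contamination: random cross-family pairs at the old event's similarity
    n_old = int(round(config.old_wgd_fraction * len(pair_rows)))
    all_genes = gene_table["gene"].to_numpy()
    fam_of = {g: int(g[1:-1]) for g in all_genes}
    existing = {canonical_pair(a, b) for a, b, _ in pair_rows}
    made = 0
    while made < n_old:
        ga, gb = (str(g) for g in rng.choice(all_genes, 2, replace=False))
        if fam_of[ga] == fam_of[gb]:
            continue
        key = canonical_pair(ga, gb)
        if key in existing:
            continue
        existing.add(key)
        sim = float(
            np.clip(
                rng.normal(config.old_sim_mean, config.old_sim_sd), 1e-6, 100.0
            )
        )
        pair_rows.append((*key, sim))
        origin_rows.append((*key, "old_wgd"))
        made += 1

    pairs = pd.DataFrame(
        [
            (
                ga,
                loc[ga][0],
                loc[ga][1],
                gb,
                loc[gb][0],
                loc[gb][1],
                sim,
            )
            for ga, gb, sim in pair_rows
        ],
        columns=[
            "gene_a",
            "chr_a",
            "pos_a",
            "gene_b",
            "chr_b",
            "pos_b",
            "similarity",
        ],
    )

    truth_genes = pd.DataFrame(
        [
            (
                row.gene,
                fam_of[row.gene],
                fam_of[row.gene] // config.genes_per_chromosome,
                SUBGENOME_LETTERS.index(row.gene[-1]),
                int(family_size[fam_of[row.gene]]),
            )
            for row in gene_table.itertuples()
        ],
        columns=["gene", "family", "ancestral_chromosome", "subgenome", "n_copies"],
    )
    truth = Truth(
        genes=truth_genes,
        pair_origins=pd.DataFrame(
            origin_rows, columns=["gene_a", "gene_b", "origin"]
        ),
    )
    logger.info(
        "simulated %d genes (%d multi-copy) on %d chromosomes, %d pairs "
        "(%d contamination)",
        len(gene_table),
        int((gene_table["copy_class"] == "multi").sum()),
        gene_table["chromosome"].nunique(),
        len(pairs),
        n_old,
    )
    return SimResult(config=config, genes=gene_table, pairs=pairs, truth=truth)


def write_sim(result: SimResult, out_dir: str) -> dict[str, str]:
    """Write the plain-TSV pair table, the gene table and the truth tables."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "pairs": os.path.join(out_dir, "pairs.tsv"),
        "genes": os.path.join(out_dir, "genes.tsv"),
        "truth_genes": os.path.join(out_dir, "truth_genes.tsv"),
        "truth_pairs": os.path.join(out_dir, "truth_pairs.tsv"),
    }
    result.pairs.to_csv(paths["pairs"], sep="\t", index=False, header=False)
    result.genes[["gene", "chromosome", "position"]].to_csv(
        paths["genes"], sep="\t", index=False, header=False
    )
    result.truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    result.truth.pair_origins.to_csv(paths["truth_pairs"], sep="\t", index=False)
    return paths
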