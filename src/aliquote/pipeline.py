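"""End-to-end orchestration: preprocessing -> clustering -> post-processing
-> reports, plus the parameter sweep over (r, t) grids."""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Sequence

import pandas as pd

from . import core, io, preprocessing
from .model import ParalogPair, Parameters, Solution

logger = logging.getLogger(__name__)


def run_pipeline(
    pairs: Sequence[ParalogPair],
    gene_table: pd.DataFrame,
    params: Parameters,
    out_dir: str | None = None,
    audit: bool = False,
) -> tuple[Solution, dict]:
    """Run the full aliquoting pipeline on an in-memory pair table.

    ``gene_table`` must cover at least every gene in ``pairs``; extra
    (single-copy) genes improve the span/coverage report.  Returns the
    post-processed solution and its summary; writes artifacts when
    ``out_dir`` is given.  Deterministic for fixed inputs and parameters.
    """
    sets, table, index = preprocessing.preprocess(pairs, gene_table, params)
    if not sets:
        raise io.InputError(
            "no paralogy sets survive preprocessing; check the similarity band"
        )
    solution = core.greedy_cluster(sets, index, params, audit=audit)
    solution = core.postprocess_fill_gaps(solution)
    if audit:
        solution.validate()
    summary = core.summarize(solution)
    summary["params"] = params.to_dict()
    coverage = core.compute_spans_and_coverage(solution, table)
    summary["single_copy_spanned"] = coverage["single_copy_spanned"]
    summary["single_copy_outside"] = coverage["single_copy_outside"]
    if out_dir is not None:
        io.write_solution(
            solution,
            out_dir,
            gene_table=table,
            summary_extra={
                "single_copy_spanned": coverage["single_copy_spanned"],
                "single_copy_outside": coverage["single_copy_outside"],
            },
        )
    return solution, summary


def run_pipeline_from_files(
    pairs_path: str,
    params: Parameters,
    dialect: str = "plain_tsv",
    genes_path: str | None = None,
    gff_path: str | None = None,
    out_dir: str | None = None,
) -> tuple[Solution, dict]:
    """File-based front end for :func:`run_pipeline`."""
    pairs, pair_genes = io.read_paralog_pairs(pairs_path, dialect=dialect)
    if gff_path is not None:
        gene_table = io.read_gff3(gff_path)
    elif genes_path is not None:
        gene_table = io.read_gene_table(genes_path)
    else:
        gene_table = pair_genes
        logger.info(
            "no gene table given; using the %d genes present in the pair "
            "table (single-copy genes unknown)",
            len(gene_table),
        )
    return run_pipeline(pairs, gene_table, params, out_dir=out_dir)


SWEEP_COLUMNS = [
    "r",
    "t",
    "genes_included_proportion",
    "n_fragments",
    "n_tuples",
    "inconsistent_genes",
]


def sweep_parameters(
    pairs: Sequence[ParalogPair],
    gene_table: pd.DataFrame,
    base_params: Parameters,
    r_values: Sequence[float],
    t_values: Sequence[int],
) -> pd.DataFrame:
    """Solution characteristics over an (r, t) grid, other parameters fixed.

    One row per grid point: proportion of multi-copy genes included, number
    of fragments, C'' and the number of inconsistent genes - the
    characteristics by which solutions are compared when choosing
    parameters.
    """
    rows = []
    for r in r_values:
        for t in t_values:
            params = replace(base_params, r=float(r), t=int(t))
            _, summary = run_pipeline(pairs, gene_table, params)
            rows.append(
                {
                    "r": r,
                    "t": t,
                    "genes_included_proportion": summary[
                        "genes_included_proportion"
                    ],
                    "n_fragments": summary["n_fragments"],
                    "n_tuples": summary["n_tuples"],
                    "inconsistent_genes": summary["inconsistent_genes"],
                }
            )
            logger.info("sweep r=%s t=%s: %s", r, t, rows[-1])
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)
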