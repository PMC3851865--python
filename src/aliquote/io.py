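"""Readers and writers for the external formats.

Input is a self-comparison paralog-pair table in one of two dialects:

``plain_tsv``
    Seven tab-separated columns: geneA, chrA, posA, geneB, chrB, posB,
    similarity.  Lines starting with ``#`` are comments.

``synmap_dagchainer``
    The collinearity-block output of a SynMap-style self comparison.  Rows
    are tab-separated; the two gene fields are ``||``-delimited annotation
    bundles (``chromosome||start||stop||name||...``) and the final numeric
    column is taken as the similarity score of the pair.  ``#`` lines
    (block headers) are skipped.  Which score column a comparison tool
    emits (percent identity or another monotone similarity) is left to the
    user; any monotone similarity works.

An optional GFF3 supplies the full gene order (including single-copy
genes), which the span/coverage report needs.  Output is a directory of
TSV/JSON files plus an optional BED of fragment spans when base-pair
coordinates are known.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Iterable

import pandas as pd

from .model import ParalogPair, Solution, canonical_pair

logger = logging.getLogger(__name__)

__all__ = [
    "InputError",
    "read_paralog_pairs",
    "read_gene_table",
    "read_gff3",
    "build_gene_table",
    "write_solution",
    "read_regions_table",
]


class InputError(ValueError):
    """Malformed or inconsistent input data."""


def _parse_synmap_gene(field: str, lineno: int) -> tuple[str, str, float]:
    parts = field.split("||")
    if len(parts) < 4:
        raise InputError(
            f"line {lineno}: expected chrom||start||stop||name..., got {field!r}"
        )
    chrom, start, _stop, name = parts[0], parts[1], parts[2], parts[3]
    try:
        pos = float(start)
    except ValueError as exc:
        raise InputError(f"line {lineno}: bad start coordinate {start!r}") from exc
    return name, chrom, pos


def _iter_rows(path: str) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_paralog_pairs(
    path: str, dialect: str = "plain_tsv"
) -> tuple[list[ParalogPair], pd.DataFrame]:
    """Read a paralog-pair table; return canonical deduplicated pairs and a
    gene table with one row per distinct gene.

    Self-pairs (the comparison diagonal) are dropped with a warning.  A pair
    seen several times (e.g. in overlapping collinear blocks) keeps its
    maximum similarity.  A gene reported with two conflicting positions is
    an error.
    """
    if dialect not in ("plain_tsv", "synmap_dagchainer"):
        raise InputError(f"unknown dialect {dialect!r}")
    best: dict[tuple[str, str], float] = {}
    gene_pos: dict[str, tuple[str, float]] = {}
    n_rows = n_self = 0
    for lineno, fields in _iter_rows(path):
        if dialect == "plain_tsv":
            if len(fields) < 7:
                raise InputError(
                    f"line {lineno}: expected 7 columns, got {len(fields)}"
                )
            ga, ca, pa_, gb, cb, pb_, sim_ = fields[:7]
            try:
                pa, pb, sim = float(pa_), float(pb_), float(sim_)
            except ValueError as exc:
                raise InputError(f"line {lineno}: non-numeric field") from exc
            recs = [(ga, ca, pa), (gb, cb, pb)]
        else:
            bundles = [f for f in fields if "||" in f]
            if len(bundles) != 2:
                raise InputError(
                    f"line {lineno}: expected two gene annotation fields, "
                    f"found {len(bundles)}"
                )
            recs = [_parse_synmap_gene(b, lineno) for b in bundles]
            try:
                sim = float(fields[-1])
            except ValueError as exc:
                raise InputError(
                    f"line {lineno}: last column is not a numeric score"
                ) from exc
        n_rows += 1
        (ga, ca, pa), (gb, cb, pb) = recs
        for g, c, p in recs:
            if g in gene_pos and gene_pos[g] != (c, p):
                raise InputError(
                    f"line {lineno}: gene {g!r} at {c}:{p} conflicts with "
                    f"earlier position {gene_pos[g][0]}:{gene_pos[g][1]}"
                )
            gene_pos[g] = (c, p)
        if ga == gb:
            n_self += 1
            continue
        key = canonical_pair(ga, gb)
        if key not in best or sim > best[key]:
            best[key] = sim
    if n_self:
        logger.warning("dropped %d self-pairs (comparison diagonal)", n_self)
    pairs = [ParalogPair(a, b, s) for (a, b), s in sorted(best.items())]
    genes = build_gene_table(
        pd.DataFrame(
            [(g, c, p) for g, (c, p) in sorted(gene_pos.items())],
            columns=["gene", "chromosome", "position"],
        )
    )
    logger.info(
        "read %d rows -> %d unique pairs over %d genes", n_rows, len(pairs), len(genes)
    )
    return pairs, genes


def build_gene_table(df: pd.DataFrame) -> pd.DataFrame:
    """Derive 0-based ``order_index`` per chromosome by sorting on position,
    ties broken by gene id."""
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise InputError(f"duplicate gene id {dup!r} in gene table")
    out = df.sort_values(
        ["chromosome", "position", "gene"], kind="mergesort"
    ).reset_index(drop=True)
    out["order_index"] = out.groupby("chromosome").cumcount()
    return out


def read_gene_table(path: str) -> pd.DataFrame:
    """Plain TSV gene table: gene, chromosome, position (bp or any
    monotone coordinate); '#' comments allowed."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["gene", "chromosome", "position"],
        dtype={"gene": str, "chromosome": str},
    )
    if df.isna().any().any():
        raise InputError(f"{path}: missing fields in gene table")
    return build_gene_table(df)


def read_gff3(path: str, feature_type: str = "gene") -> pd.DataFrame:
    """Gene order from a GFF3: one row per ``feature_type`` feature, using
    the ID attribute as the gene id and the start coordinate as position."""
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for feat in db.features_of_type(feature_type):
        fid = feat.attributes.get("ID", [feat.id])[0]
        rows.append((fid, feat.seqid, float(feat.start)))
    if not rows:
        raise InputError(f"{path}: no {feature_type!r} features")
    return build_gene_table(
        pd.DataFrame(rows, columns=["gene", "chromosome", "position"])
    )


# ---------------------------------------------------------------------------
# solution output


def _final_ids(solution: Solution) -> dict[int, int]:
    """Renumber surviving tuples 0..C''-1 in creation order."""
    return {
        t.tuple_id: i
        for i, t in enumerate(
            sorted(solution.ktuples, key=lambda t: t.tuple_id)
        )
    }


def write_solution(
    solution: Solution,
    out_dir: str,
    gene_table: pd.DataFrame | None = None,
    summary_extra: dict | None = None,
) -> dict[str, str]:
    """Write the solution as TSV/JSON artifacts; returns {name: path}.

    Files: ``assignments.tsv`` (gene -> tuple/region), ``regions.tsv``
    (fragment structure per region, with base-pair spans when the gene
    table carries positions), ``chords.tsv`` (one row per retained paralog
    pair with both placements - the data behind a circle plot), and
    ``summary.json``.  ``spans.bed`` is added when base-pair positions are
    available.
    """
    from .core import summarize

    if not solution.ktuples:
        raise ValueError("refusing to write a solution with no k-tuples")
    os.makedirs(out_dir, exist_ok=True)
    ids = _final_ids(solution)
    index = solution.index

    pos_of: dict[str, float] = {}
    if gene_table is not None and "position" in gene_table.columns:
        pos_of = dict(zip(gene_table["gene"], gene_table["position"]))

    paths: dict[str, str] = {}

    region_rows = []
    assign_rows = []
    region_ids: dict[tuple[int, int], int] = {}
    rid = 0
    for t in sorted(solution.ktuples, key=lambda t: t.tuple_id):
        for ri, reg in enumerate(t.regions):
            region_ids[(t.tuple_id, ri)] = rid
            frag_strs = []
            bp_strs = []
            for f in reg.fragments():
                frag_strs.append(f"{f.chromosome}:{f.start_rank}-{f.end_rank}")
                if pos_of:
                    genes = [
                        index.gene_at[f.chromosome][k]
                        for k in range(f.start_rank, f.end_rank + 1)
                    ]
                    bps = [pos_of[g] for g in genes if g in pos_of]
                    if bps:
                        bp_strs.append(
                            f"{f.chromosome}:{min(bps):.0f}-{max(bps):.0f}"
                        )
            region_rows.append(
                {
                    "tuple_id": ids[t.tuple_id],
                    "region_id": rid,
                    "n_genes": reg.n_genes,
                    "gapped_genes": reg.gapped_genes,
                    "jumps": reg.jumps,
                    "chromosomes": ",".join(sorted(reg.chromosomes)),
                    "fragments": ";".join(frag_strs),
                    "fragments_bp": ";".join(bp_strs),
                }
            )
            for g in index.genes_in(reg):
                assign_rows.append(
                    {"gene": g, "tuple_id": ids[t.tuple_id], "region_id": rid}
                )
            rid += 1

    paths["regions"] = os.path.join(out_dir, "regions.tsv")
    pd.DataFrame(region_rows).to_csv(paths["regions"], sep="\t", index=False)
    paths["assignments"] = os.path.join(out_dir, "assignments.tsv")
    pd.DataFrame(assign_rows).to_csv(paths["assignments"], sep="\t", index=False)

    assign = solution.assignments()
    chord_rows = []
    for s in sorted(solution.sets):
        for e in solution.sets[s].edges:
            pa = assign.get(e.gene_a)
            pb = assign.get(e.gene_b)
            chord_rows.append(
                {
                    "gene_a": e.gene_a,
                    "gene_b": e.gene_b,
                    "similarity": e.similarity,
                    "tuple_a": ids[pa[0]] if pa else "",
                    "region_a": region_ids.get(pa, "") if pa else "",
                    "tuple_b": ids[pb[0]] if pb else "",
                    "region_b": region_ids.get(pb, "") if pb else "",
                }
            )
    paths["chords"] = os.path.join(out_dir, "chords.tsv")
    pd.DataFrame(chord_rows).to_csv(paths["chords"], sep="\t", index=False)

    summary = summarize(solution)
    summary["params"] = solution.params.to_dict()
    if summary_extra:
        summary.update(summary_extra)
    paths["summary"] = os.path.join(out_dir, "summary.json")
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    if pos_of:
        bed_rows = []
        for t in sorted(solution.ktuples, key=lambda t: t.tuple_id):
            for ri, reg in enumerate(t.regions):
                for f in reg.fragments():
                    genes = [
                        index.gene_at[f.chromosome][k]
                        for k in range(f.start_rank, f.end_rank + 1)
                    ]
                    bps = [pos_of[g] for g in genes if g in pos_of]
                    if not bps:
                        continue
                    bed_rows.append(
                        (
                            f.chromosome,
                            int(min(bps)),  # 0-based half-open
                            int(max(bps)) + 1,
                            f"tuple{ids[t.tuple_id]}_region"
                            f"{region_ids[(t.tuple_id, ri)]}",
                        )
                    )
        paths["bed"] = os.path.join(out_dir, "spans.bed")
        with open(paths["bed"], "w") as fh:
            for row in bed_rows:
                fh.write("\t".join(str(x) for x in row) + "\n")
    return paths


def read_regions_table(path: str) -> pd.DataFrame:
    """Read back ``regions.tsv``; fragment bounds round-trip bit-exactly."""
    df = pd.read_csv(path, sep="\t", dtype={"fragments": str})
    frags = []
    for s in df["fragments"]:
        parsed = []
        for part in str(s).split(";"):
            chrom, bounds = part.rsplit(":", 1)
            lo, hi = bounds.split("-")
            parsed.append((chrom, int(lo), int(hi)))
        frags.append(tuple(parsed))
    df["fragment_tuples"] = frags
    return df
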