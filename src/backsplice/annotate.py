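"""Categorize final candidates against a gene model and write reports.

A circle end is exonic when it lies inside any annotated exon, intronic when
inside a gene span but no exon, intergenic otherwise.  The candidate takes
the lowest-precedence call of its two ends: any intergenic end makes it
intergenic; otherwise any intronic end makes it intronic; otherwise exonic.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .model import CircCandidate, GeneModel

REPORT_COLUMNS = [
    "circRNA_id",
    "chrom",
    "start",
    "end",
    "strand",
    "junction_reads",
    "distinct_signal_layouts",
    "non_junction_reads",
    "rel_exp",
    "category",
    "gene_ids",
    "signal_types",
    "filterlog",
]


@dataclass(frozen=True, slots=True)
class CircAnnotation:
    category: str  # exon | intron | intergenic
    gene_ids: tuple[str, ...]
    end_calls: tuple[str, str]


def _end_call(model: GeneModel, chrom: str, pos: int) -> str:
    if model.exons_at(chrom, pos):
        return "exon"
    if model.genes_at(chrom, pos):
        return "intron"
    return "intergenic"


def categorize(cand: CircCandidate, model: Optional[GeneModel]) -> CircAnnotation:
    """Assign exon/intron/intergenic category and overlapping gene ids.

    Without an annotation every candidate is labelled "unannotated".  An end
    exactly on a gene-span edge counts as inside the gene; when one end is
    intronic and the other intergenic, intergenic wins.
    """
    if model is None:
        return CircAnnotation("unannotated", (), ("unannotated", "unannotated"))
    calls = (
        _end_call(model, cand.chrom, cand.start),
        _end_call(model, cand.chrom, cand.end),
    )
    if "intergenic" in calls:
        category = "intergenic"
    elif "intron" in calls:
        category = "intron"
    else:
        category = "exon"
    gene_ids = tuple(
        sorted(
            model.genes_at(cand.chrom, cand.start)
            | model.genes_at(cand.chrom, cand.end)
        )
    )
    return CircAnnotation(category, gene_ids, calls)


def annotate_candidates(
    cands: list[CircCandidate], model: Optional[GeneModel]
) -> None:
    for c in cands:
        ann = categorize(c, model)
        c.category = ann.category
        c.gene_ids = ann.gene_ids


def write_report(cands: list[CircCandidate], path) -> None:
    """Write the candidate table as a TSV (deterministic byte-for-byte)."""
    rows = []
    for c in sorted(cands, key=lambda c: (c.chrom, c.start, c.end)):
        rows.append(
            "\t".join(
                [
                    c.circ_id,
                    c.chrom,
                    str(c.start),
                    str(c.end),
                    c.strand,
                    str(c.junction_reads),
                    str(c.distinct_signal_layouts),
                    str(c.non_junction_reads),
                    f"{c.rel_exp:.4f}" if c.rel_exp is not None else "n/a",
                    c.category,
                    ",".join(c.gene_ids) if c.gene_ids else "n/a",
                    ",".join(c.signal_types),
                    ";".join(f"{name}:{status}" for name, status in c.filter_log),
                ]
            )
        )
    Path(path).write_text("\t".join(REPORT_COLUMNS) + "\n" + "".join(r + "\n" for r in rows))


def read_report(path) -> pd.DataFrame:
    """Parse a report TSV back into a DataFrame (round-trip of write_report)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(REPORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"report {path} missing columns: {sorted(missing)}")
    return df


def write_bed(cands: list[CircCandidate], path) -> None:
    """BED6 export of junction intervals (score = junction read count)."""
    lines = []
    for c in sorted(cands, key=lambda c: (c.chrom, c.start, c.end)):
        score = min(1000, c.junction_reads)
        strand = c.strand if c.strand in "+-" else "."
        lines.append(
            f"{c.chrom}\t{c.start - 1}\t{c.end}\t{c.circ_id}\t{score}\t{strand}"
        )
    Path(path).write_text("".join(l + "\n" for l in lines))
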