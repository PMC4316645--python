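"""Readers and writers for SAM, FASTA and GTF/GFF.

SAM records are parsed with pysam and grouped per query/mate end; secondary
and unmapped records are dropped.  Hard-clipped supplementary records inherit
the full query sequence from the primary record of the same read end (the
second-scan aligner needs bases).
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterator, Optional

import pysam

from .model import (
    AlignmentSegment,
    Gene,
    GeneModel,
    ReferenceGenome,
    Transcript,
    revcomp,
)

_CIGAR_OPS = "MIDNSHP=XB"


class SamParseError(ValueError):
    pass


def _segment_from_pysam(r: "pysam.AlignedSegment") -> AlignmentSegment:
    cigar = tuple((_CIGAR_OPS[op], n) for op, n in (r.cigartuples or ()))
    return AlignmentSegment(
        read_id=r.query_name,
        ref=r.reference_name,
        pos=r.reference_start + 1,
        strand="-" if r.is_reverse else "+",
        cigar=cigar,
        mapq=r.mapping_quality,
        is_paired=r.is_paired,
        mate_ref=r.next_reference_name if r.next_reference_id >= 0 else None,
        mate_pos=(r.next_reference_start + 1) if r.next_reference_id >= 0 else None,
        seq=r.query_sequence,
        is_supplementary=r.is_supplementary,
        is_secondary=r.is_secondary,
        mate_index=2 if (r.is_paired and r.is_read2) else 1,
    )


def iter_sam_records(path) -> Iterator[AlignmentSegment]:
    """Stream mapped primary + supplementary segments from a SAM file."""
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        n = 0
        it = fh.fetch(until_eof=True)
        while True:
            try:
                r = next(it)
            except StopIteration:
                break
            except (ValueError, OSError) as exc:  # pragma: no cover - defensive
                raise SamParseError(f"malformed SAM record #{n + 1}: {exc}") from exc
            n += 1
            if r.is_unmapped or r.is_secondary:
                continue
            yield _segment_from_pysam(r)


def _inherit_full_seq(group: list[AlignmentSegment]) -> None:
    """Attach the full query sequence to every segment of one read end."""
    primary = next(
        (s for s in group if not s.is_supplementary and s.seq is not None), None
    )
    if primary is None:
        return
    for seg in group:
        if seg.seq is not None and len(seg.seq) == primary.query_len:
            seg.full_seq = seg.seq
        elif seg.strand == primary.strand:
            seg.full_seq = primary.seq
        else:
            seg.full_seq = revcomp(primary.seq)


def read_sam_grouped(
    path,
) -> Iterator[tuple[tuple[str, int], list[AlignmentSegment]]]:
    """Group mapped SAM records by (query name, mate index).

    Records of one query may be interleaved anywhere in the file; groups are
    yielded in first-appearance order, so the grouping is a deterministic
    partition of the mapped primary/supplementary records.
    """
    groups: dict[tuple[str, int], list[AlignmentSegment]] = {}
    for seg in iter_sam_records(path):
        groups.setdefault((seg.read_id, seg.mate_index), []).append(seg)
    for key, group in groups.items():
        _inherit_full_seq(group)
        yield key, group


def sam_reference_names(path) -> list[str]:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        return list(fh.references)


def load_fasta(path) -> ReferenceGenome:
    """Load a (possibly .fai-indexed) FASTA into memory, uppercased."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
    seqs = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    if not seqs:
        raise ValueError(f"empty FASTA: {path}")
    return ReferenceGenome(seqs)


def write_fasta(genome: ReferenceGenome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chroms:
            fh.write(f">{chrom}\n")
            seq = genome.sequence(chrom)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_gtf(path) -> GeneModel:
    """Build a GeneModel from GTF2.2 or GFF3 exon features.

    Both attribute dialects (``key "value";`` and ``key=value``) are accepted;
    attributes beyond gene_id/transcript_id are ignored.  Exons lacking a
    transcript_id are skipped with a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    # (gene_id, transcript_id) -> [(chrom, strand, start, end), ...]
    by_tx: dict[tuple[str, str], list] = {}
    n_exons = 0
    for feat in db.features_of_type("exon"):
        n_exons += 1
        tx = feat.attributes.get("transcript_id") or feat.attributes.get("Parent")
        if not tx:
            warnings.warn(f"exon at {feat.seqid}:{feat.start} lacks transcript_id; skipped")
            continue
        gene = feat.attributes.get("gene_id") or feat.attributes.get("gene")
        gene_id = gene[0] if gene else tx[0]
        by_tx.setdefault((gene_id, tx[0]), []).append(
            (feat.seqid, feat.strand, feat.start, feat.end)
        )
    if n_exons == 0:
        raise ValueError(f"no exon features in annotation: {path}")
    genes: dict[str, dict] = {}
    for (gene_id, tx_id), exons in by_tx.items():
        chrom, strand = exons[0][0], exons[0][1]
        ivals = tuple(sorted((s, e) for _, _, s, e in exons))
        rec = genes.setdefault(gene_id, {"chrom": chrom, "strand": strand, "tx": []})
        rec["tx"].append(Transcript(tx_id, ivals))
    return GeneModel(
        Gene(gid, rec["chrom"], rec["strand"], tuple(sorted(rec["tx"], key=lambda t: t.transcript_id)))
        for gid, rec in genes.items()
    )


def write_gtf(model: GeneModel, path, dialect: str = "gtf") -> None:
    """Serialize a GeneModel as GTF2.2 or GFF3 exon/transcript/gene lines."""
    lines = []
    if dialect == "gff3":
        lines.append("##gff-version 3")
    for g in model.genes:
        gs, ge = g.span
        if dialect == "gtf":
            attrs = f'gene_id "{g.gene_id}";'
            lines.append(
                f"{g.chrom}\tsynth\tgene\t{gs}\t{ge}\t.\t{g.strand}\t.\t{attrs}"
            )
        else:
            lines.append(
                f"{g.chrom}\tsynth\tgene\t{gs}\t{ge}\t.\t{g.strand}\t.\tID={g.gene_id}"
            )
        for t in g.transcripts:
            ts, te = t.span
            if dialect == "gtf":
                attrs = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
                lines.append(
                    f"{g.chrom}\tsynth\ttranscript\t{ts}\t{te}\t.\t{g.strand}\t.\t{attrs}"
                )
            else:
                lines.append(
                    f"{g.chrom}\tsynth\ttranscript\t{ts}\t{te}\t.\t{g.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={g.gene_id}"
                )
            for k, (es, ee) in enumerate(t.exons, 1):
                if dialect == "gtf":
                    attrs = (
                        f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}"; '
                        f'exon_number "{k}";'
                    )
                    lines.append(
                        f"{g.chrom}\tsynth\texon\t{es}\t{ee}\t.\t{g.strand}\t.\t{attrs}"
                    )
                else:
                    lines.append(
                        f"{g.chrom}\tsynth\texon\t{es}\t{ee}\t.\t{g.strand}\t.\t"
                        f"ID={t.transcript_id}.exon{k};Parent={t.transcript_id};"
                        f"gene_id={g.gene_id};transcript_id={t.transcript_id}"
                    )
    Path(path).write_text("\n".join(lines) + "\n")


def sam_header(genome: ReferenceGenome) -> "pysam.AlignmentHeader":
    return pysam.AlignmentHeader.from_references(
        genome.chroms, [genome.length(c) for c in genome.chroms]
    )
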