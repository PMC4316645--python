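"""Core domain types shared by the detector, simulator and reporters.

Coordinates are 1-based inclusive throughout (SAM/GTF native).  A back-splice
junction is written ``chrom:start|end`` where ``start`` is the splice acceptor
(5' end of the circle on the plus strand) and ``end`` the donor.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

# CIGAR operation groups (SAM spec semantics)
QUERY_OPS = frozenset("MIS=X")
REF_OPS = frozenset("MDN=X")
CLIP_OPS = frozenset("SH")
VALID_OPS = frozenset("MIDNSHP=X")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def parse_cigar(text: str) -> tuple[tuple[str, int], ...]:
    """Parse a CIGAR string into ``((op, length), ...)`` tokens.

    Raises ``ValueError`` for empty/malformed strings or zero-length tokens.
    """
    if not text or text == "*":
        raise ValueError("empty CIGAR")
    out: list[tuple[str, int]] = []
    num = ""
    for ch in text:
        if ch.isdigit():
            num += ch
        elif ch in VALID_OPS:
            if not num:
                raise ValueError(f"malformed CIGAR {text!r}")
            n = int(num)
            if n < 1:
                raise ValueError(f"zero-length CIGAR token in {text!r}")
            out.append((ch, n))
            num = ""
        else:
            raise ValueError(f"invalid CIGAR op {ch!r} in {text!r}")
    if num:
        raise ValueError(f"malformed CIGAR {text!r}")
    return tuple(out)


def cigar_to_string(cigar: Iterable[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


@dataclass(slots=True)
class AlignmentSegment:
    """One mapped SAM record (primary or supplementary)."""

    read_id: str
    ref: str
    pos: int  # 1-based leftmost mapped reference coordinate
    strand: str  # '+' or '-'
    cigar: tuple[tuple[str, int], ...]
    mapq: int
    is_paired: bool = False
    mate_ref: Optional[str] = None
    mate_pos: Optional[int] = None
    seq: Optional[str] = None
    is_supplementary: bool = False
    is_secondary: bool = False
    mate_index: int = 1  # 1 for read1/single-end, 2 for read2
    full_seq: Optional[str] = None  # full query in this record's orientation

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for op, n in self.cigar:
            if op not in VALID_OPS or n < 1:
                raise ValueError(f"bad CIGAR token ({op}, {n})")
        if self.seq is not None:
            soft = sum(n for op, n in self.cigar if op in QUERY_OPS)
            if soft != len(self.seq):
                raise ValueError(
                    f"CIGAR query length {soft} != SEQ length {len(self.seq)} "
                    f"for read {self.read_id}"
                )

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in REF_OPS)

    @property
    def end(self) -> int:
        """1-based inclusive rightmost mapped reference coordinate."""
        return self.pos + self.ref_span - 1

    @property
    def query_len(self) -> int:
        """Full query length including hard-clipped bases."""
        return sum(n for op, n in self.cigar if op in QUERY_OPS or op == "H")

    @property
    def cigar_string(self) -> str:
        return cigar_to_string(self.cigar)


class ClipForm(enum.Enum):
    NONE = "NONE"
    LEFT_CLIP = "LEFT_CLIP"  # xS/H yM
    RIGHT_CLIP = "RIGHT_CLIP"  # xM yS/H
    BOTH_CLIP = "BOTH_CLIP"  # xS/H yM zS/H


@dataclass(frozen=True, slots=True)
class ClipSignature:
    """Clip/match decomposition of one record's CIGAR.

    ``x``/``y``/``z`` follow the field convention of the split-read patterns:
    LEFT_CLIP x = leading clip, y = match; RIGHT_CLIP x = match, y = trailing
    clip; BOTH_CLIP x = leading clip, y = match, z = trailing clip.  The match
    block length is its query span; ``ref_span`` carries its reference span
    (differs when internal I/D/N ops occur, flagged by ``has_internal_indel``).
    """

    form: ClipForm
    leading: int
    match: int
    trailing: int
    read_len: int
    ref_span: int
    has_internal_indel: bool = False

    @property
    def x(self) -> int:
        if self.form is ClipForm.RIGHT_CLIP:
            return self.match
        if self.form is ClipForm.NONE:
            return 0
        return self.leading

    @property
    def y(self) -> int:
        if self.form is ClipForm.RIGHT_CLIP:
            return self.trailing
        return self.match

    @property
    def z(self) -> int:
        return self.trailing if self.form is ClipForm.BOTH_CLIP else 0


def classify_signature(seg: AlignmentSegment) -> ClipSignature:
    """Decompose a segment's CIGAR into terminal clips and a match block.

    S and H clips are treated identically.  Internal I/D/N ops are absorbed
    into the match block (query span for the block length, reference span kept
    separately) and flagged.  Total function: unclipped records yield NONE.
    """
    toks = seg.cigar
    i, j = 0, len(toks)
    lead = trail = 0
    while i < j and toks[i][0] in CLIP_OPS:
        lead += toks[i][1]
        i += 1
    while j > i and toks[j - 1][0] in CLIP_OPS:
        trail += toks[j - 1][1]
        j -= 1
    mid = toks[i:j]
    match_q = sum(n for op, n in mid if op in QUERY_OPS)
    ref_span = sum(n for op, n in mid if op in REF_OPS)
    indel = any(op in "IDN" for op, _ in mid)
    read_len = lead + trail + match_q
    if lead and trail:
        form = ClipForm.BOTH_CLIP
    elif lead:
        form = ClipForm.LEFT_CLIP
    elif trail:
        form = ClipForm.RIGHT_CLIP
    else:
        form = ClipForm.NONE
    return ClipSignature(form, lead, match_q, trail, read_len, ref_span, indel)


class ReferenceGenome:
    """In-memory reference: chromosome name -> uppercase sequence."""

    def __init__(self, sequences: dict[str, str]):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}
        bad: set[str] = set()
        for s in self._seqs.values():
            bad |= set(s)
        bad -= set("ACGTN")
        if bad:
            raise ValueError(f"non-nucleotide characters in reference: {bad}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Subsequence by 1-based inclusive interval; out-of-range is an error."""
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self._seqs[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise IndexError(
                f"interval {chrom}:{start}-{end} outside chromosome (len {len(seq)})"
            )
        return seq[start - 1 : end]

    def try_fetch(self, chrom: str, start: int, end: int) -> Optional[str]:
        """Like :meth:`fetch` but returns None when off the chromosome."""
        try:
            return self.fetch(chrom, start, end)
        except (KeyError, IndexError):
            return None


@dataclass(frozen=True, slots=True)
class Transcript:
    transcript_id: str
    exons: tuple[tuple[int, int], ...]  # sorted, non-overlapping, 1-based incl.

    def __post_init__(self) -> None:
        prev_end = 0
        for s, e in self.exons:
            if s > e or s <= prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons must be sorted, "
                    f"non-overlapping 1-based intervals"
                )
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass(frozen=True, slots=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[Transcript, ...]

    @property
    def span(self) -> tuple[int, int]:
        starts = [t.span[0] for t in self.transcripts]
        ends = [t.span[1] for t in self.transcripts]
        return min(starts), max(ends)


class GeneModel:
    """Gene/transcript/exon annotation with derived per-chromosome indexes."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes: list[Gene] = sorted(
            genes, key=lambda g: (g.chrom, g.span[0], g.span[1], g.gene_id)
        )
        self._exon_starts: dict[str, set[int]] = {}
        self._exon_ends: dict[str, set[int]] = {}
        self._exon_tree = None
        self._gene_tree = None
        for g in self.genes:
            ss = self._exon_starts.setdefault(g.chrom, set())
            es = self._exon_ends.setdefault(g.chrom, set())
            for t in g.transcripts:
                for s, e in t.exons:
                    ss.add(s)
                    es.add(e)

    def __len__(self) -> int:
        return len(self.genes)

    def exon_starts(self, chrom: str) -> set[int]:
        return self._exon_starts.get(chrom, set())

    def exon_ends(self, chrom: str) -> set[int]:
        return self._exon_ends.get(chrom, set())

    def _build_trees(self):
        from intervaltree import IntervalTree

        exon_tree: dict[str, IntervalTree] = {}
        gene_tree: dict[str, IntervalTree] = {}
        for g in self.genes:
            gt = gene_tree.setdefault(g.chrom, IntervalTree())
            s, e = g.span
            gt.addi(s, e + 1, g.gene_id)
            et = exon_tree.setdefault(g.chrom, IntervalTree())
            for t in g.transcripts:
                for es, ee in t.exons:
                    et.addi(es, ee + 1, g.gene_id)
        self._exon_tree, self._gene_tree = exon_tree, gene_tree

    def exons_at(self, chrom: str, pos: int) -> set[str]:
        """Gene ids whose exons contain ``pos``."""
        if self._exon_tree is None:
            self._build_trees()
        tree = self._exon_tree.get(chrom)
        return {iv.data for iv in tree[pos]} if tree is not None else set()

    def genes_at(self, chrom: str, pos: int) -> set[str]:
        """Gene ids whose spans contain ``pos`` (span edges count as inside)."""
        if self._gene_tree is None:
            self._build_trees()
        tree = self._gene_tree.get(chrom)
        return {iv.data for iv in tree[pos]} if tree is not None else set()


class SignalType(enum.Enum):
    TWO_SEG = "TWO_SEG"
    SHORT_EXON_3SEG = "SHORT_EXON_3SEG"
    SMALL_CIRCLE_3SEG = "SMALL_CIRCLE_3SEG"


@dataclass(slots=True)
class JunctionReadEvidence:
    """One read end supporting a putative back-splice junction."""

    read_id: str
    mate_index: int
    signal_type: SignalType
    chrom: str
    start: int
    end: int
    split_point: int  # query coordinate of the junction within the read
    segment_mapqs: tuple[int, ...]
    strand: str = "?"
    offset_applied: int = 0
    clip_asymmetry: int = 0  # downstream match minus upstream clip length
    max_segment_match: int = 0
    filter_log: list = field(default_factory=list)

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def key(self) -> tuple[str, int]:
        return (self.read_id, self.mate_index)


@dataclass(slots=True)
class CircCandidate:
    """A clustered junction with its supporting evidence and filter history."""

    chrom: str
    start: int
    end: int
    strand: str
    evidence: list[JunctionReadEvidence]
    recovered_reads: int = 0
    non_junction_reads: int = 0
    rel_exp: Optional[float] = None
    category: str = "unannotated"
    gene_ids: tuple[str, ...] = ()
    filter_log: list = field(default_factory=list)

    @property
    def circ_id(self) -> str:
        return f"{self.chrom}:{self.start}|{self.end}"

    @property
    def junction_reads(self) -> int:
        return len(self.evidence) + self.recovered_reads

    @property
    def distinct_signal_layouts(self) -> int:
        return len({(ev.split_point, ev.signal_type) for ev in self.evidence})

    @property
    def signal_types(self) -> list[str]:
        return sorted({ev.signal_type.value for ev in self.evidence})

    @property
    def longest_junction_segment(self) -> int:
        vals = [ev.max_segment_match for ev in self.evidence]
        return max(vals) if vals else 0


@dataclass
class DPParams:
    """Scoring for the fit (semi-global) alignment used by the second scan."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -3
    gap_extend: int = -1
    min_identity: float = 0.90
    min_overhang: int = 8
    score_margin: int = 2

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if not (self.gap_open < 0 and self.gap_extend < 0):
            raise ValueError("gap penalties must be negative")


@dataclass
class DetectorConfig:
    """Detection parameters (mirrors the tool's command-line surface)."""

    pe_mode: bool = True
    min_segment: int = 19
    max_span: int = 200_000
    mapq_per_segment: int = 0  # -u; 3 recommended for single-end libraries
    mapq_total: int = 0  # -b; 13 recommended for single-end libraries
    stringency: str = "high"  # high: >=2 distinct PCC layouts; low: keep all
    boundary_tolerance: int = 5
    exon_boundary_mode: str = "off"  # off | complement | alternative
    identical_seq_filter: bool = False
    min_rel_exp: Optional[float] = None
    dp: DPParams = field(default_factory=DPParams)
    read_len: Optional[int] = None  # inferred from the SAM when unset
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_segment < 1 or self.max_span < 1:
            raise ValueError("min_segment and max_span must be >= 1")
        if self.min_rel_exp is not None and not 0 <= self.min_rel_exp <= 1:
            raise ValueError("min_rel_exp must be in [0, 1]")
        if self.stringency not in ("high", "low"):
            raise ValueError("stringency must be 'high' or 'low'")
        if self.exon_boundary_mode not in ("off", "complement", "alternative"):
            raise ValueError("exon_boundary_mode must be off|complement|alternative")
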