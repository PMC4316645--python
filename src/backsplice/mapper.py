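"""Deterministic k-mer seed-and-extend split mapper for fixture data.

Emits BWA-MEM-style SAM records: a soft-clipped primary per read end,
hard-clipped supplementary records for the other split parts, MAPQ 60 for
unique placements and 0 for multireads.  Split parts shorter than the
emission floor (19 bp by default, matching BWA-MEM's minimum seed/output
length) are not reported - reproducing the unbalanced-junction-read
phenomenon the detector's second scan recovers.

Intended for low-error simulated reads (substitutions only, no indels):
each candidate placement is an ungapped diagonal, scored +1/-4 and trimmed
to its best-scoring run.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pysam

from .model import ReferenceGenome, revcomp

_LUT = np.zeros(128, np.uint8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i

MATCH_SCORE = 1
MISMATCH_SCORE = -4


def _codes(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.upper().encode(), np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    n = codes.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, np.int64)
    c = np.zeros(n, np.int64)
    for j in range(k):
        c = (c << 2) | codes[j : j + n]
    return c


class GenomeIndex:
    """Exact k-mer index over the concatenated reference."""

    def __init__(self, genome: ReferenceGenome, k: int = 19, max_hits: int = 25):
        self.k = k
        self.max_hits = max_hits
        self.names = genome.chroms
        self.lengths = [genome.length(c) for c in self.names]
        self.offsets = np.concatenate([[0], np.cumsum(self.lengths)])
        self.codes = np.concatenate(
            [_codes(genome.sequence(c)) for c in self.names]
        )
        index: dict[int, object] = {}
        for i, code in enumerate(_kmer_codes(self.codes, k).tolist()):
            cur = index.get(code)
            if cur is None:
                index[code] = i
            elif isinstance(cur, int):
                index[code] = [cur, i]
            elif len(cur) <= max_hits:
                cur.append(i)
        self.index = index

    def chrom_of(self, gpos: int) -> int:
        return int(np.searchsorted(self.offsets, gpos, side="right")) - 1


@dataclass(slots=True)
class _Segment:
    orient: str  # '+' maps the read, '-' maps its reverse complement
    qs: int  # 0-based query interval in the oriented frame
    qe: int
    gstart: int  # concatenated 0-based genome start of the aligned block
    score: int
    chrom_idx: int
    mapq: int = 60

    def orig_interval(self, n: int) -> tuple[int, int]:
        return (self.qs, self.qe) if self.orient == "+" else (n - self.qe, n - self.qs)


def _best_run(mism: np.ndarray) -> tuple[int, int, int]:
    """Best-scoring contiguous run under +1/-4 scoring (leftmost on ties)."""
    best = (-1, 0, 0)  # score, start, end(excl)
    cur = 0
    cur_start = 0
    for i, bad in enumerate(mism):
        if cur <= 0:
            cur = 0
            cur_start = i
        cur += MISMATCH_SCORE if bad else MATCH_SCORE
        if cur > best[0]:
            best = (cur, cur_start, i + 1)
    return best


def _map_oriented(
    idx: GenomeIndex, codes: np.ndarray, kcodes: list, orient: str, min_segment: int
) -> list[_Segment]:
    n = codes.shape[0]
    diags: dict[int, int] = {}
    get = idx.index.get
    for qi, code in enumerate(kcodes):
        hits = get(code)
        if hits is None:
            continue
        if isinstance(hits, int):
            hits = (hits,)
        elif len(hits) > idx.max_hits:
            continue
        for g in hits:
            d = g - qi
            diags[d] = diags.get(d, 0) + 1
    total = idx.codes.shape[0]
    segs: list[_Segment] = []
    for d in sorted(diags):
        qlo = max(0, -d)
        qhi = min(n, total - d)
        if qhi - qlo < min_segment:
            continue
        # clamp to the chromosome containing the diagonal body
        cidx = idx.chrom_of(d + qlo)
        clo, chi = int(idx.offsets[cidx]), int(idx.offsets[cidx + 1])
        qlo = max(qlo, clo - d)
        qhi = min(qhi, chi - d)
        if qhi - qlo < min_segment:
            continue
        mism = idx.codes[d + qlo : d + qhi] != codes[qlo:qhi]
        score, s, e = _best_run(mism)
        s += qlo
        e += qlo
        if e - s >= min_segment:
            segs.append(_Segment(orient, s, e, d + s, score, cidx))
    return segs


def map_read(
    idx: GenomeIndex, seq: str, min_segment: int = 19
) -> list[_Segment]:
    """Map one read; returns kept split segments, best first (primary)."""
    n = len(seq)
    if n < idx.k:
        return []
    fwd = _codes(seq)
    rev = _codes(revcomp(seq))
    cands: list[_Segment] = []
    for orient, codes in (("+", fwd), ("-", rev)):
        kcodes = _kmer_codes(codes, idx.k).tolist()
        cands.extend(_map_oriented(idx, codes, kcodes, orient, min_segment))
    if not cands:
        return []
    cands.sort(key=lambda s: (-s.score, s.gstart, s.orient))
    kept: list[_Segment] = []
    for s in cands:
        a, b = s.orig_interval(n)
        ok = True
        for t in kept:
            ta, tb = t.orig_interval(n)
            if min(b, tb) - max(a, ta) > 8:
                ok = False
                break
        if ok:
            kept.append(s)
        if len(kept) >= 4:
            break
    # multi-mapping check against every candidate placement
    for s in kept:
        a, b = s.orig_interval(n)
        for t in cands:
            if t is s:
                continue
            ta, tb = t.orig_interval(n)
            ov = min(b, tb) - max(a, ta)
            if (
                ov >= 0.8 * min(b - a, tb - ta)
                and t.score >= s.score - 3
                and (t.gstart != s.gstart or t.orient != s.orient)
            ):
                s.mapq = 0
                break
    return kept


def _strip_mate_suffix(name: str) -> str:
    return name[:-2] if name.endswith(("/1", "/2")) else name


def _records_for_read(
    header: "pysam.AlignmentHeader",
    name: str,
    seq: str,
    segs: list[_Segment],
    mate_primary: Optional[_Segment],
    mate_len: int,
    is_read1: bool,
    paired: bool,
) -> list["pysam.AlignedSegment"]:
    n = len(seq)
    recs = []
    pair_flag = 0
    if paired:
        pair_flag |= 0x1 | (0x40 if is_read1 else 0x80)
        if mate_primary is None:
            pair_flag |= 0x8
        elif mate_primary.orient == "-":
            pair_flag |= 0x20
    if not segs:
        a = pysam.AlignedSegment(header)
        a.query_name = name
        a.flag = 0x4 | pair_flag
        a.query_sequence = seq
        a.query_qualities = pysam.qualitystring_to_array("I" * n)
        if mate_primary is not None:
            a.next_reference_id = mate_primary.chrom_idx
            a.next_reference_start = mate_primary.gstart - _offset(
                header, mate_primary.chrom_idx, segs
            )
        return [a]
    offsets = None
    for i, s in enumerate(segs):
        a = pysam.AlignedSegment(header)
        a.query_name = name
        flag = pair_flag
        if s.orient == "-":
            flag |= 0x10
        if i > 0:
            flag |= 0x800
        a.flag = flag
        a.reference_id = s.chrom_idx
        a.reference_start = s.gstart - _offset(header, s.chrom_idx, segs)
        a.mapping_quality = s.mapq
        oriented = seq if s.orient == "+" else revcomp(seq)
        lead, m, trail = s.qs, s.qe - s.qs, n - s.qe
        if i == 0:
            cig = []
            if lead:
                cig.append((4, lead))
            cig.append((0, m))
            if trail:
                cig.append((4, trail))
            a.cigartuples = cig
            a.query_sequence = oriented
            a.query_qualities = pysam.qualitystring_to_array("I" * n)
        else:
            cig = []
            if lead:
                cig.append((5, lead))
            cig.append((0, m))
            if trail:
                cig.append((5, trail))
            a.cigartuples = cig
            a.query_sequence = oriented[s.qs : s.qe]
            a.query_qualities = pysam.qualitystring_to_array("I" * m)
        if paired and mate_primary is not None:
            a.next_reference_id = mate_primary.chrom_idx
            a.next_reference_start = mate_primary.gstart - _offset(
                header, mate_primary.chrom_idx, segs
            )
            if mate_primary.chrom_idx == segs[0].chrom_idx:
                a.flag = a.flag | 0x2
        recs.append(a)
    return recs


_OFFSETS_CACHE: dict[int, np.ndarray] = {}


def _offset(header, chrom_idx, _segs) -> int:
    key = id(header)
    offs = _OFFSETS_CACHE.get(key)
    if offs is None:
        lengths = [header.get_reference_length(name) for name in header.references]
        offs = np.concatenate([[0], np.cumsum(lengths)])
        _OFFSETS_CACHE[key] = offs
    return int(offs[chrom_idx])


def fixture_map(
    fq1,
    fq2,
    genome: ReferenceGenome,
    out_sam,
    k: int = 19,
    min_segment: int = 19,
    max_hits: int = 25,
) -> GenomeIndex:
    """Map a (pair of) FASTQ file(s) against ``genome`` into a SAM file.

    ``fq2=None`` maps a single-end library.  Output order follows input
    order, so repeated runs are byte-identical.
    """
    idx = GenomeIndex(genome, k=k, max_hits=max_hits)
    header = pysam.AlignmentHeader.from_references(idx.names, idx.lengths)
    reads1 = pysam.FastxFile(str(fq1))
    reads2 = pysam.FastxFile(str(fq2)) if fq2 is not None else None
    with pysam.AlignmentFile(str(out_sam), "w", header=header) as out:
        for r1 in reads1:
            name = _strip_mate_suffix(r1.name)
            segs1 = map_read(idx, r1.sequence, min_segment)
            if reads2 is not None:
                r2 = next(reads2)
                segs2 = map_read(idx, r2.sequence, min_segment)
                p1 = segs1[0] if segs1 else None
                p2 = segs2[0] if segs2 else None
                for rec in _records_for_read(
                    header, name, r1.sequence, segs1, p2, len(r2.sequence), True, True
                ):
                    out.write(rec)
                for rec in _records_for_read(
                    header, name, r2.sequence, segs2, p1, len(r1.sequence), False, True
                ):
                    out.write(rec)
            else:
                for rec in _records_for_read(
                    header, name, r1.sequence, segs1, None, 0, True, False
                ):
                    out.write(rec)
    reads1.close()
    if reads2 is not None:
        reads2.close()
    return idx
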