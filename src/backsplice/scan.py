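"""First scan: paired chiastic clipping (PCC) signal detection and the
preliminary junction-read filters.

A back-splice junction read maps in a chiastic order: its 5' part aligns
downstream (record ``xM yS/H``) and its 3' part upstream (record
``xS/H yM``).  Circles shorter than the read, and junctions flanked by exons
shorter than the read, instead produce three-segment layouts around a
doubly-clipped middle record (``xS/H yM zS/H``).
"""
from __future__ import annotations

from typing import Iterable, Optional

from .model import (
    AlignmentSegment,
    CircCandidate,
    ClipForm,
    DetectorConfig,
    GeneModel,
    JunctionReadEvidence,
    ReferenceGenome,
    SignalType,
    classify_signature,
)


def _mapq_ok(mapqs: Iterable[int], cfg: DetectorConfig) -> bool:
    mq = list(mapqs)
    return all(q >= cfg.mapq_per_segment for q in mq) and sum(mq) >= cfg.mapq_total


def pair_chiastic(
    group: list[AlignmentSegment], cfg: DetectorConfig
) -> list[JunctionReadEvidence]:
    """Detect two-segment PCC signals within the records of one read end.

    A LEFT_CLIP record A (``xS yM``) and a RIGHT_CLIP record B (``xM yS``)
    on the same reference and strand form a signal when their clip/match
    decompositions correspond (|A.x - B.x| and |A.y - B.y| within the
    boundary tolerance) and A maps upstream of B.  The tentative circle is
    then [A.pos, B.pos + B.match_span - 1].
    """
    tol = cfg.boundary_tolerance
    sigs = [(seg, classify_signature(seg)) for seg in group]
    lefts = [(s, c) for s, c in sigs if c.form is ClipForm.LEFT_CLIP]
    rights = [(s, c) for s, c in sigs if c.form is ClipForm.RIGHT_CLIP]
    out: list[JunctionReadEvidence] = []
    seen: set[tuple[int, int]] = set()
    for a, ca in lefts:
        for b, cb in rights:
            if a.ref != b.ref or a.strand != b.strand:
                continue
            if abs(ca.x - cb.x) > tol or abs(ca.y - cb.y) > tol:
                continue
            if a.pos > b.pos:
                continue  # not chiastic: would be a forward (linear) splice
            start, end = a.pos, b.pos + cb.ref_span - 1
            if end < start or end - start + 1 > cfg.max_span:
                continue
            if not _mapq_ok((a.mapq, b.mapq), cfg):
                continue
            if (start, end) in seen:
                continue
            seen.add((start, end))
            out.append(
                JunctionReadEvidence(
                    read_id=a.read_id,
                    mate_index=a.mate_index,
                    signal_type=SignalType.TWO_SEG,
                    chrom=a.ref,
                    start=start,
                    end=end,
                    split_point=ca.x,
                    segment_mapqs=(a.mapq, b.mapq),
                    clip_asymmetry=cb.x - ca.x,
                    max_segment_match=max(ca.match, cb.match),
                )
            )
    return out


def detect_three_segment(
    group: list[AlignmentSegment], cfg: DetectorConfig
) -> list[JunctionReadEvidence]:
    """Detect three-segment PCC signals (short-exon and small-circle layouts).

    A doubly-clipped middle record M (``xS yM zS``) is combined with terminal
    records of form ``(x+y)S zM`` or ``xM (y+z)S``.  Terminal match blocks
    falling inside M's reference interval (and abutting its termini) indicate
    a circle shorter than the read; blocks outside indicate a short
    junction-flanking exon, with the circle bounded by the chiastic outer
    coordinates.
    """
    tol = cfg.boundary_tolerance
    sigs = [(seg, classify_signature(seg)) for seg in group]
    mids = [(s, c) for s, c in sigs if c.form is ClipForm.BOTH_CLIP]
    terms = [
        (s, c)
        for s, c in sigs
        if c.form in (ClipForm.LEFT_CLIP, ClipForm.RIGHT_CLIP)
    ]
    out: list[JunctionReadEvidence] = []
    seen: set[tuple[int, int, SignalType]] = set()
    for m, cm in mids:
        m_start, m_end = m.pos, m.pos + cm.ref_span - 1
        small_ok: list[tuple[AlignmentSegment, int]] = []
        small_reject = False
        for t, ct in terms:
            if t.ref != m.ref or t.strand != m.strand:
                continue
            t_start, t_end = t.pos, t.pos + ct.ref_span - 1
            overlaps = t_start <= m_end and t_end >= m_start
            if ct.form is ClipForm.RIGHT_CLIP:
                # terminal xM (y+z)S: read prefix
                if abs(ct.x - cm.x) > tol or abs(ct.y - (cm.y + cm.z)) > tol:
                    continue
                if overlaps:
                    if abs(t_end - m_end) <= tol:
                        small_ok.append((t, ct.match))
                    else:
                        small_reject = True
                elif t_start > m_end:
                    start, end = m_start, t_end
                    ev = _three_seg_evidence(
                        m, cm, t, start, end, SignalType.SHORT_EXON_3SEG,
                        split_point=cm.x, cfg=cfg,
                        max_match=max(cm.match, ct.match),
                        asym=ct.x - cm.x,
                    )
                    if ev and (start, end, ev.signal_type) not in seen:
                        seen.add((start, end, ev.signal_type))
                        out.append(ev)
            else:
                # terminal (x+y)S zM: read suffix
                if abs(ct.x - (cm.x + cm.y)) > tol or abs(ct.y - cm.z) > tol:
                    continue
                if overlaps:
                    if abs(t_start - m_start) <= tol:
                        small_ok.append((t, ct.match))
                    else:
                        small_reject = True
                elif t_end < m_start:
                    start, end = t_start, m_end
                    ev = _three_seg_evidence(
                        m, cm, t, start, end, SignalType.SHORT_EXON_3SEG,
                        split_point=cm.x + cm.y, cfg=cfg,
                        max_match=max(cm.match, ct.match),
                        asym=0,
                    )
                    if ev and (start, end, ev.signal_type) not in seen:
                        seen.add((start, end, ev.signal_type))
                        out.append(ev)
        if small_ok and not small_reject:
            mapqs = (m.mapq,) + tuple(t.mapq for t, _ in small_ok)
            if m_end - m_start + 1 <= cfg.max_span and _mapq_ok(mapqs, cfg):
                key = (m_start, m_end, SignalType.SMALL_CIRCLE_3SEG)
                if key not in seen:
                    seen.add(key)
                    out.append(
                        JunctionReadEvidence(
                            read_id=m.read_id,
                            mate_index=m.mate_index,
                            signal_type=SignalType.SMALL_CIRCLE_3SEG,
                            chrom=m.ref,
                            start=m_start,
                            end=m_end,
                            split_point=cm.x,
                            segment_mapqs=mapqs,
                            max_segment_match=max(
                                [cm.match] + [n for _, n in small_ok]
                            ),
                        )
                    )
    return out


def _three_seg_evidence(
    m, cm, t, start, end, signal_type, split_point, cfg, max_match, asym
) -> Optional[JunctionReadEvidence]:
    if end < start or end - start + 1 > cfg.max_span:
        return None
    if not _mapq_ok((m.mapq, t.mapq), cfg):
        return None
    return JunctionReadEvidence(
        read_id=m.read_id,
        mate_index=m.mate_index,
        signal_type=signal_type,
        chrom=m.ref,
        start=start,
        end=end,
        split_point=split_point,
        segment_mapqs=(m.mapq, t.mapq),
        clip_asymmetry=asym,
        max_segment_match=max_match,
    )


def detect_evidence(
    group: list[AlignmentSegment], cfg: DetectorConfig
) -> list[JunctionReadEvidence]:
    """All PCC evidence (two- and three-segment) from one read end."""
    evs = pair_chiastic(group, cfg) + detect_three_segment(group, cfg)
    seen: set[tuple[int, int, SignalType]] = set()
    uniq = []
    for ev in evs:
        key = (ev.start, ev.end, ev.signal_type)
        if key not in seen:
            seen.add(key)
            uniq.append(ev)
    return uniq


def pem_filter(
    ev: JunctionReadEvidence,
    mate: Optional[list[AlignmentSegment]],
    cfg: DetectorConfig,
) -> tuple[bool, str]:
    """Paired-end mapping filter: the mate must align within the putative
    circle.  Skipped (recorded as omitted) for single-end libraries.

    A small slack of ``boundary_tolerance`` is allowed at each end because a
    mate abutting a circle boundary may over-extend by a few fortuitously
    matching bases.
    """
    if not cfg.pe_mode:
        return True, "omitted"
    if not mate:
        return False, "mate_unmapped"
    tol = cfg.boundary_tolerance
    for seg in mate:
        if (
            seg.ref == ev.chrom
            and seg.pos >= ev.start - tol
            and seg.end <= ev.end + tol
        ):
            return True, "pass"
    return False, "fail"


def _shift_order(tol: int):
    yield 0
    for d in range(1, tol + 1):
        yield d
        yield -d


def splice_signal_filter(
    ev: JunctionReadEvidence, genome: ReferenceGenome, cfg: DetectorConfig
) -> tuple[bool, int, int, str, str]:
    """GT-AG splice-signal filter with common-shift boundary correction.

    Acceptance on the plus strand requires AG immediately upstream of the
    corrected start and GT immediately downstream of the corrected end
    (AC/CT for the minus strand).  Shifts are searched smallest first
    (0, +1, -1, ...).  When the two split records disagree on the split
    point by ``ev.clip_asymmetry`` = delta (chance extension past the
    junction), the end shift is constrained to d_end = d_start - delta; for
    delta = 0 this is exactly the same-direction/same-distance rule.

    Returns (pass, corrected_start, corrected_end, strand, flag).
    """
    tol = cfg.boundary_tolerance
    delta = ev.clip_asymmetry
    edge = False
    for ds in _shift_order(tol):
        de = ds - delta
        if abs(de) > tol:
            continue
        s, e = ev.start + ds, ev.end + de
        if s > e:
            continue
        left = genome.try_fetch(ev.chrom, s - 2, s - 1)
        right = genome.try_fetch(ev.chrom, e + 1, e + 2)
        if left is None or right is None:
            edge = True
            continue
        if left == "AG" and right == "GT":
            return True, s, e, "+", "pass"
        if left == "AC" and right == "CT":
            return True, s, e, "-", "pass"
    return False, ev.start, ev.end, "?", ("edge" if edge else "fail")


def exon_boundary_filter(
    ev: JunctionReadEvidence, model: GeneModel, cfg: DetectorConfig
) -> tuple[bool, int, int]:
    """Annotated-exon-boundary filter with the same common-shift correction.

    Passes when some annotated exon start equals the corrected circle start
    and some annotated exon end equals the corrected end, under a common
    shift d (constrained by the clip asymmetry like the splice filter).
    """
    tol = cfg.boundary_tolerance
    delta = ev.clip_asymmetry
    starts = model.exon_starts(ev.chrom)
    ends = model.exon_ends(ev.chrom)
    for ds in _shift_order(tol):
        de = ds - delta
        if abs(de) > tol:
            continue
        s, e = ev.start + ds, ev.end + de
        if s <= e and s in starts and e in ends:
            return True, s, e
    return False, ev.start, ev.end


def identical_sequence_filter(
    ev: JunctionReadEvidence, genome: ReferenceGenome, cfg: DetectorConfig
) -> bool:
    """Fail candidates whose junction-spanning sequence occurs collinearly
    elsewhere near the locus (such a copy explains the read without a circle).

    The probe is the concatenation of the ``w = min_segment`` bases inside
    the end boundary and the ``w`` bases inside the start boundary - the
    sequence a junction read crosses - searched exactly within ``max_span``
    of either boundary.
    """
    w = cfg.min_segment
    left = genome.try_fetch(ev.chrom, ev.end - w + 1, ev.end)
    right = genome.try_fetch(ev.chrom, ev.start, ev.start + w - 1)
    if left is None or right is None:
        return True
    probe = left + right
    lo = max(1, ev.start - cfg.max_span)
    hi = min(genome.length(ev.chrom), ev.end + cfg.max_span)
    region = genome.fetch(ev.chrom, lo, hi)
    return probe not in region


def cluster_junctions(
    evidence: list[JunctionReadEvidence],
) -> list[CircCandidate]:
    """Merge boundary-corrected evidence sharing (chrom, start, end)."""
    by_locus: dict[tuple[str, int, int], list[JunctionReadEvidence]] = {}
    for ev in evidence:
        by_locus.setdefault((ev.chrom, ev.start, ev.end), []).append(ev)
    out = []
    for (chrom, start, end), evs in sorted(by_locus.items()):
        strand = next((e.strand for e in evs if e.strand in "+-"), ".")
        out.append(CircCandidate(chrom, start, end, strand, evs))
    return out
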