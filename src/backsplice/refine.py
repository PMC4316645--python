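"""Second scan: recover unbalanced junction reads by DP alignment, remove
homology/repeat false positives, count non-junction reads and compute
relative expression.

An unbalanced junction read has one split part shorter than the aligner's
emission floor (19 bp by default), so only one of its records appears in the
SAM.  Aligning the full read against a junction construct - the genomic
flanks stitched across the back-splice seam - decides whether it supports
the circle or the corresponding linear transcript.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

from .align import FitAlignment, dp_fit_align
from .model import (
    AlignmentSegment,
    CircCandidate,
    ClipForm,
    DetectorConfig,
    DPParams,
    ReferenceGenome,
    classify_signature,
    revcomp,
)


@dataclass(slots=True)
class JunctionConstruct:
    """Reference sequence stitched across a candidate's back-splice seam.

    For a circle at [start, end] and read length L the construct is
    ``genome[end-a+1..end] + genome[start..start+a-1]`` with
    ``a = L - min_segment``; the seam sits at 0-based offset ``a``.  Circles
    shorter than ``a`` are tiled (rolling-circle constructs), producing one
    seam per copy boundary.
    """

    seq: str
    seams: tuple[int, ...]

    @classmethod
    def build(
        cls, cand: CircCandidate, genome: ReferenceGenome, read_len: int, min_segment: int
    ) -> "JunctionConstruct":
        a = read_len - min_segment
        if a < 1:
            raise ValueError("read length must exceed min_segment")
        span = cand.end - cand.start + 1
        if span >= a:
            left = genome.fetch(cand.chrom, cand.end - a + 1, cand.end)
            right = genome.fetch(cand.chrom, cand.start, cand.start + a - 1)
            return cls(left + right, (a,))
        circ = genome.fetch(cand.chrom, cand.start, cand.end)
        reps = math.ceil(2 * a / span) + 1
        seq = circ * reps
        seams = tuple(span * k for k in range(1, reps))
        return cls(seq, seams)


class ReadSupport(enum.Enum):
    JUNCTION = "JUNCTION"
    LINEAR = "LINEAR"
    AMBIGUOUS = "AMBIGUOUS"
    NEITHER = "NEITHER"


def _linear_window(
    genome: ReferenceGenome, chrom: str, boundary: int, read_len: int, pad: int
) -> tuple[str, int]:
    lo = max(1, boundary - read_len - pad)
    hi = min(genome.length(chrom), boundary + read_len + pad)
    return genome.fetch(chrom, lo, hi), lo


def classify_read_support(
    seg: AlignmentSegment,
    cand: CircCandidate,
    construct: JunctionConstruct,
    genome: ReferenceGenome,
    params: DPParams,
    read_len: int,
    tol: int = 5,
) -> ReadSupport:
    """Decide whether one read supports the back-splice junction, the linear
    transcript across a boundary, both equally (AMBIGUOUS), or neither.

    JUNCTION: the fit alignment to the junction construct reaches the
    identity floor, crosses a seam with ``min_overhang`` bases on both sides
    and out-scores the best linear-context alignment by ``score_margin``.
    LINEAR: the read aligns contiguously across start-1/start or end/end+1
    and out-scores the construct by the margin.
    """
    seq = seg.full_seq or seg.seq
    if not seq:
        return ReadSupport.NEITHER
    jfit = dp_fit_align(seq, construct.seq, params)
    junction_ok = jfit.identity >= params.min_identity and any(
        jfit.crosses(s, params.min_overhang) for s in construct.seams
    )
    lin_best: Optional[FitAlignment] = None
    linear_ok = False
    for boundary, left_side in ((cand.start, False), (cand.end, True)):
        window, lo = _linear_window(genome, cand.chrom, boundary, read_len, tol)
        lfit = dp_fit_align(seq, window, params)
        if lin_best is None or lfit.score > lin_best.score:
            lin_best = lfit
        # seam index within the window: boundary between start-1/start is at
        # 0-based column (boundary - lo); between end/end+1 at (boundary-lo+1)
        seam = boundary - lo + (1 if left_side else 0)
        if lfit.identity >= params.min_identity and lfit.crosses(
            seam, params.min_overhang
        ):
            linear_ok = True
    lin_score = lin_best.score if lin_best is not None else -(10**6)
    if junction_ok and jfit.score >= lin_score + params.score_margin:
        return ReadSupport.JUNCTION
    if linear_ok and lin_score >= jfit.score + params.score_margin:
        return ReadSupport.LINEAR
    if (junction_ok or linear_ok) and abs(jfit.score - lin_score) < params.score_margin:
        return ReadSupport.AMBIGUOUS
    return ReadSupport.NEITHER


def homology_filter(
    cand: CircCandidate, lookalike_lengths: list[int], cfg: DetectorConfig
) -> bool:
    """Pass/fail a candidate against homologous-copy lookalike reads.

    ``lookalike_lengths`` are the mapped lengths of reads highly similar to
    the candidate's junction reads but mapping collinearly elsewhere (outside
    the candidate's max_span context).  The candidate fails when such reads
    that are at least as long as the longest junction-read segment outnumber
    the junction-supporting reads.
    """
    longest = cand.longest_junction_segment
    qualifying = [n for n in lookalike_lengths if n >= longest]
    return len(qualifying) <= cand.junction_reads


def relative_expression(cand: CircCandidate) -> float:
    """rel_exp = J / (J + N): junction reads over junction + boundary-spanning
    linear reads."""
    j = cand.junction_reads
    n = cand.non_junction_reads
    if j < 1:
        raise ValueError("candidate without junction reads")
    return j / (j + n)


def apply_stringency(
    cands: list[CircCandidate], cfg: DetectorConfig
) -> list[CircCandidate]:
    """High stringency keeps only candidates supported by >= 2 distinct PCC
    signal layouts (split point x signal type); low keeps every candidate."""
    if cfg.stringency == "low":
        return list(cands)
    return [c for c in cands if c.distinct_signal_layouts >= 2]


def _seam_probe(cand: CircCandidate, genome: ReferenceGenome, w: int) -> Optional[str]:
    left = genome.try_fetch(cand.chrom, cand.end - w + 1, cand.end)
    right = genome.try_fetch(cand.chrom, cand.start, cand.start + w - 1)
    if left is None or right is None:
        return None
    return left + right


def refine_candidates(
    sam_path,
    candidates: list[CircCandidate],
    genome: ReferenceGenome,
    cfg: DetectorConfig,
    read_len: int,
) -> list[CircCandidate]:
    """Run the second SAM scan over the given first-scan candidates.

    For every primary record near a candidate boundary the read is classified
    by DP alignment (recovering unbalanced junction reads and counting
    non-junction reads); reads carrying a candidate's seam sequence but
    mapping collinearly elsewhere feed the homology filter.
    """
    from intervaltree import IntervalTree

    from .io import iter_sam_records

    if not candidates:
        return []
    params = cfg.dp
    constructs = {
        id(c): JunctionConstruct.build(c, genome, read_len, cfg.min_segment)
        for c in candidates
    }
    trees: dict[str, IntervalTree] = {}
    probe_map: dict[str, list[CircCandidate]] = {}
    w = cfg.min_segment
    for c in candidates:
        tree = trees.setdefault(c.chrom, IntervalTree())
        for b in (c.start, c.end):
            tree.addi(max(1, b - read_len), b + read_len + 1, c)
        probe = _seam_probe(c, genome, w)
        if probe and len(probe) == 2 * w:
            probe_map.setdefault(probe, []).append(c)
    scan1_keys = {
        (ev.read_id, ev.mate_index): True
        for c in candidates
        for ev in c.evidence
    }
    recovered: dict[int, set] = {id(c): set() for c in candidates}
    n_counts: dict[int, int] = {id(c): 0 for c in candidates}
    lookalikes: dict[int, list[int]] = {id(c): [] for c in candidates}
    probe_len = 2 * w

    for seg in iter_sam_records(sam_path):
        if seg.is_supplementary:
            continue
        key = (seg.read_id, seg.mate_index)
        tree = trees.get(seg.ref)
        hits = tree.overlap(seg.pos, seg.end + 1) if tree is not None else ()
        cands_here = {id(iv.data): iv.data for iv in hits}
        for cid, cand in cands_here.items():
            if key in scan1_keys:
                continue
            support = classify_read_support(
                seg, cand, constructs[cid], genome, params, read_len,
                tol=cfg.boundary_tolerance,
            )
            if support is ReadSupport.JUNCTION:
                recovered[cid].add(key)
            elif support is ReadSupport.LINEAR:
                n_counts[cid] += 1
        # homology lookalikes: collinear full-block reads carrying a seam
        if probe_map and not cands_here and seg.seq:
            sig = classify_signature(seg)
            if sig.form is ClipForm.NONE:
                for s in (seg.seq, revcomp(seg.seq)):
                    for i in range(len(s) - probe_len + 1):
                        hit = probe_map.get(s[i : i + probe_len])
                        if hit:
                            for cand in hit:
                                if (
                                    seg.ref != cand.chrom
                                    or seg.end < cand.start - cfg.max_span
                                    or seg.pos > cand.end + cfg.max_span
                                ):
                                    lookalikes[id(cand)].append(sig.match)
    kept: list[CircCandidate] = []
    for c in candidates:
        c.recovered_reads = len(recovered[id(c)])
        c.non_junction_reads = n_counts[id(c)]
        hom_ok = homology_filter(c, lookalikes[id(c)], cfg)
        c.filter_log.append(("homology", "pass" if hom_ok else "fail"))
        if not hom_ok:
            continue
        c.rel_exp = relative_expression(c)
        if cfg.min_rel_exp is not None and c.rel_exp < cfg.min_rel_exp:
            c.filter_log.append(("rel_exp", "fail"))
            continue
        c.filter_log.append(("rel_exp", "pass"))
        kept.append(c)
    return kept
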