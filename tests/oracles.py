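"""Independent brute-force oracles used to cross-check the implementation.

These re-derive expected results directly from the geometric/scoring
definitions with plain enumeration, deliberately sharing no code with the
package internals they check.
"""
from __future__ import annotations

from backsplice.model import ClipForm, classify_signature


def brute_pcc(group, cfg):
    """Enumerate every segment pair/triple against the PCC geometry.

    Returns a set of (start, end, kind) with kind in
    {"TWO_SEG", "SHORT_EXON_3SEG", "SMALL_CIRCLE_3SEG"}.
    """
    tol = cfg.boundary_tolerance
    out = set()
    sigs = [(s, classify_signature(s)) for s in group]

    def mapq_ok(*segs):
        return all(s.mapq >= cfg.mapq_per_segment for s in segs) and sum(
            s.mapq for s in segs
        ) >= cfg.mapq_total

    # pairs: LEFT_CLIP a (xS yM) + RIGHT_CLIP b (xM yS)
    for a, ca in sigs:
        for b, cb in sigs:
            if a is b or ca.form is not ClipForm.LEFT_CLIP or cb.form is not ClipForm.RIGHT_CLIP:
                continue
            if a.ref != b.ref or a.strand != b.strand:
                continue
            if abs(ca.leading - cb.match) > tol:
                continue
            if abs(ca.match - cb.trailing) > tol:
                continue
            if a.pos > b.pos:
                continue
            start, end = a.pos, b.pos + cb.ref_span - 1
            if end < start or end - start + 1 > cfg.max_span:
                continue
            if mapq_ok(a, b):
                out.add((start, end, "TWO_SEG"))

    # triples around a BOTH_CLIP middle
    for m, cm in sigs:
        if cm.form is not ClipForm.BOTH_CLIP:
            continue
        m_start, m_end = m.pos, m.pos + cm.ref_span - 1
        abutting = []
        reject_small = False
        for t, ct in sigs:
            if t is m or t.ref != m.ref or t.strand != m.strand:
                continue
            if ct.form is ClipForm.RIGHT_CLIP:
                compatible = (
                    abs(ct.match - cm.leading) <= tol
                    and abs(ct.trailing - (cm.match + cm.trailing)) <= tol
                )
                if not compatible:
                    continue
                t_start, t_end = t.pos, t.pos + ct.ref_span - 1
                if t_start <= m_end and t_end >= m_start:
                    if abs(t_end - m_end) <= tol:
                        abutting.append(t)
                    else:
                        reject_small = True
                elif t_start > m_end:
                    start, end = m_start, t_end
                    if (
                        start <= end
                        and end - start + 1 <= cfg.max_span
                        and mapq_ok(m, t)
                    ):
                        out.add((start, end, "SHORT_EXON_3SEG"))
            elif ct.form is ClipForm.LEFT_CLIP:
                compatible = (
                    abs(ct.leading - (cm.leading + cm.match)) <= tol
                    and abs(ct.match - cm.trailing) <= tol
                )
                if not compatible:
                    continue
                t_start, t_end = t.pos, t.pos + ct.ref_span - 1
                if t_start <= m_end and t_end >= m_start:
                    if abs(t_start - m_start) <= tol:
                        abutting.append(t)
                    else:
                        reject_small = True
                elif t_end < m_start:
                    start, end = t_start, m_end
                    if (
                        start <= end
                        and end - start + 1 <= cfg.max_span
                        and mapq_ok(m, t)
                    ):
                        out.add((start, end, "SHORT_EXON_3SEG"))
        if abutting and not reject_small:
            if m_end - m_start + 1 <= cfg.max_span and mapq_ok(m, *abutting):
                out.add((m_start, m_end, "SMALL_CIRCLE_3SEG"))
    return out


def linear_fit_score(query: str, target: str, match=1, mismatch=-2, gap=-3):
    """Quadratic fit-alignment DP with a flat (non-affine) gap penalty."""
    m, n = len(query), len(target)
    prev = [0] * (n + 1)
    for i in range(1, m + 1):
        cur = [prev[0] + gap] + [0] * n
        qc = query[i - 1]
        for j in range(1, n + 1):
            s = match if qc == target[j - 1] else mismatch
            cur[j] = max(prev[j - 1] + s, prev[j] + gap, cur[j - 1] + gap)
        prev = cur
    return max(prev)


def max_gap_length(fit, query_len: int) -> int:
    """Longest gap (in query or target) of a FitAlignment's traceback path."""
    pq, pt = fit.pairs_q, fit.pairs_t
    if len(pq) == 0:
        return query_len
    worst = max(int(pq[0]), int(query_len - 1 - pq[-1]))
    for k in range(1, len(pq)):
        worst = max(worst, int(pq[k] - pq[k - 1] - 1), int(pt[k] - pt[k - 1] - 1))
    return worst


def brute_splice_scan(chrom_seq: str, start: int, end: int, delta: int, tol: int):
    """Exhaustive shift scan for GT-AG/AC-CT signals, smallest shift first.

    Returns (start, end, strand) of the first acceptance or None; the end
    shift is constrained to d_end = d_start - delta.
    """
    order = [0]
    for d in range(1, tol + 1):
        order += [d, -d]
    for ds in order:
        de = ds - delta
        if abs(de) > tol:
            continue
        s, e = start + ds, end + de
        if s > e or s - 2 < 1 or e + 2 > len(chrom_seq):
            continue
        left = chrom_seq[s - 3 : s - 1]
        right = chrom_seq[e : e + 2]
        if left == "AG" and right == "GT":
            return s, e, "+"
        if left == "AC" and right == "CT":
            return s, e, "-"
    return None
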