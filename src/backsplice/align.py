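"""Fit (semi-global) alignment with affine gaps for the second scan.

The full query is aligned against any substring of the target (free target
end gaps).  Inner loops are jit-compiled; traceback is deterministic:
diagonal is preferred over a gap in the target (up), which is preferred over
a gap in the query (left); gaps close as early as possible.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .model import DPParams

NEG = -(10**6)


@njit(cache=True)
def _fill(q, t, match, mismatch, go, ge):  # pragma: no cover - jit
    m, n = q.shape[0], t.shape[0]
    H = np.full((m + 1, n + 1), NEG, np.int32)
    E = np.full((m + 1, n + 1), NEG, np.int32)  # gap in query (left)
    F = np.full((m + 1, n + 1), NEG, np.int32)  # gap in target (up)
    for j in range(n + 1):
        H[0, j] = 0
    for i in range(1, m + 1):
        F[i, 0] = go + (i - 1) * ge
        H[i, 0] = F[i, 0]
        for j in range(1, n + 1):
            e = E[i, j - 1] + ge
            eo = H[i, j - 1] + go
            E[i, j] = e if e > eo else eo
            f = F[i - 1, j] + ge
            fo = H[i - 1, j] + go
            F[i, j] = f if f > fo else fo
            s = match if q[i - 1] == t[j - 1] else mismatch
            h = H[i - 1, j - 1] + s
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            H[i, j] = h
    return H, E, F


@njit(cache=True)
def _traceback(q, t, H, E, F, jend, match, mismatch, go, ge):  # pragma: no cover
    # returns (jstart, n_pairs, pairs_q, pairs_t, n_matches, n_cols)
    m = q.shape[0]
    cap = m + t.shape[0] + 2
    pq = np.empty(cap, np.int32)
    pt = np.empty(cap, np.int32)
    np_pairs = 0
    n_matches = 0
    n_cols = 0
    i, j = m, jend
    state = 0  # 0=H, 1=E, 2=F
    while i > 0:
        if state == 0:
            s = match if (j > 0 and q[i - 1] == t[j - 1]) else mismatch
            if j > 0 and H[i, j] == H[i - 1, j - 1] + s:
                pq[np_pairs] = i - 1
                pt[np_pairs] = j - 1
                np_pairs += 1
                if q[i - 1] == t[j - 1]:
                    n_matches += 1
                n_cols += 1
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = 2
            else:
                state = 1
        elif state == 2:  # gap in target: consume query
            n_cols += 1
            if H[i - 1, j] + go == F[i, j]:
                state = 0
            i -= 1
        else:  # gap in query: consume target
            n_cols += 1
            if H[i, j - 1] + go == E[i, j]:
                state = 0
            j -= 1
    return j, np_pairs, pq[:np_pairs], pt[:np_pairs], n_matches, n_cols


_BASE = np.zeros(128, np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE[ord(_b)] = _i
_BASE[ord("N")] = 4


def encode(seq: str) -> np.ndarray:
    return _BASE[np.frombuffer(seq.upper().encode(), np.uint8)]


@dataclass(slots=True)
class FitAlignment:
    """Result of aligning a full query against a target substring."""

    score: int
    target_start: int  # 1-based inclusive within the target
    target_end: int
    identity: float
    n_matches: int
    n_columns: int
    pairs_q: np.ndarray  # 0-based aligned (query, target) column indices
    pairs_t: np.ndarray

    def bases_left_of(self, seam: int) -> int:
        """Aligned query bases on target positions <= seam (0-based seam index:
        columns with target index < seam are 'left')."""
        return int(np.count_nonzero(self.pairs_t < seam))

    def bases_right_of(self, seam: int) -> int:
        return int(np.count_nonzero(self.pairs_t >= seam))

    def crosses(self, seam: int, min_overhang: int) -> bool:
        """True when >= min_overhang query bases align on each side of the
        boundary between target columns seam-1 and seam (0-based)."""
        return (
            self.bases_left_of(seam) >= min_overhang
            and self.bases_right_of(seam) >= min_overhang
        )


def dp_fit_align(query: str, target: str, params: DPParams | None = None) -> FitAlignment:
    """Align ``query`` end-to-end against the best-scoring substring of
    ``target`` with affine gap penalties.

    Ties on the alignment end are broken toward the leftmost target position;
    the traceback preference order is diagonal, up (gap in target), left
    (gap in query).
    """
    if not query or not target:
        raise ValueError("query and target must be non-empty")
    p = params or DPParams()
    q = encode(query)
    t = encode(target)
    H, E, F = _fill(q, t, p.match, p.mismatch, p.gap_open, p.gap_extend)
    last = H[len(q)]
    jend = int(np.argmax(last))
    score = int(last[jend])
    jstart, n_pairs, pq, pt, n_matches, n_cols = _traceback(
        q, t, H, E, F, jend, p.match, p.mismatch, p.gap_open, p.gap_extend
    )
    identity = n_matches / n_cols if n_cols else 0.0
    # reverse traceback order -> ascending
    return FitAlignment(
        score=score,
        target_start=jstart + 1,
        target_end=jend,
        identity=identity,
        n_matches=n_matches,
        n_columns=n_cols,
        pairs_q=pq[::-1].copy(),
        pairs_t=pt[::-1].copy(),
    )
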