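"""Fit-DP alignment, junction constructs, read-support classification,
homology filtering, relative expression and stringency."""
import numpy as np
import pytest

from backsplice.align import dp_fit_align
from backsplice.model import (
    CircCandidate,
    DetectorConfig,
    DPParams,
    JunctionReadEvidence,
    ReferenceGenome,
    SignalType,
    revcomp,
)
from backsplice.refine import (
    JunctionConstruct,
    ReadSupport,
    apply_stringency,
    classify_read_support,
    homology_filter,
    relative_expression,
)
from conftest import make_seg, random_genome
from oracles import linear_fit_score, max_gap_length


class TestDpFitAlign:
    def test_exact_substring(self, rng):
        t = random_genome(rng, 200)
        q = t[60:110]
        fit = dp_fit_align(q, t)
        assert fit.score == 50 and fit.identity == 1.0
        assert (fit.target_start, fit.target_end) == (61, 110)

    def test_single_mismatch_score(self, rng):
        t = random_genome(rng, 200)
        q = list(t[60:110])
        q[20] = {"A": "C", "C": "A", "G": "T", "T": "G"}[q[20]]
        fit = dp_fit_align("".join(q), t)
        assert fit.score == 49 * 1 - 2  # 47 under +1/-2 scoring
        assert fit.identity == pytest.approx(49 / 50)

    def test_agrees_with_quadratic_reference_dp(self):
        """Affine fit DP >= flat-gap quadratic oracle, with equality whenever
        the affine optimum uses no gap longer than one base (1000 pairs)."""
        rng = np.random.default_rng(3)
        n_equal = 0
        for _ in range(1000):
            t = random_genome(rng, int(rng.integers(60, 120)))
            if rng.random() < 0.5:  # mutated substring of the target
                a = int(rng.integers(0, len(t) - 40))
                q = list(t[a : a + int(rng.integers(20, 40))])
                for _k in range(int(rng.integers(0, 4))):
                    p = int(rng.integers(0, len(q)))
                    r = rng.random()
                    if r < 0.6:
                        q[p] = "ACGT"[rng.integers(0, 4)]
                    elif r < 0.8 and len(q) > 21:
                        del q[p]
                    else:
                        q.insert(p, "ACGT"[rng.integers(0, 4)])
                q = "".join(q)
            else:
                q = random_genome(rng, int(rng.integers(20, 40)))
            fit = dp_fit_align(q, t)
            ref = linear_fit_score(q, t)
            assert fit.score >= ref
            if max_gap_length(fit, len(q)) <= 1:
                assert fit.score == ref
                n_equal += 1
        assert n_equal > 500

    def test_empty_sequences_rejected(self):
        with pytest.raises(ValueError):
            dp_fit_align("", "ACGT")


class TestJunctionConstruct:
    def _cand(self, start, end):
        return CircCandidate("c", start, end, "+", [_ev(start, end)])

    def test_flank_construct_geometry(self, rng):
        g = ReferenceGenome({"c": random_genome(rng, 3000)})
        c = JunctionConstruct.build(self._cand(1000, 2000), g, read_len=100, min_segment=19)
        assert len(c.seq) == 2 * 81 and c.seams == (81,)
        assert c.seq[:81] == g.fetch("c", 1920, 2000)
        assert c.seq[81:] == g.fetch("c", 1000, 1080)

    def test_small_circle_construct_is_tiled(self, rng):
        g = ReferenceGenome({"c": random_genome(rng, 3000)})
        c = JunctionConstruct.build(self._cand(1000, 1059), g, read_len=100, min_segment=19)
        circ = g.fetch("c", 1000, 1059)
        assert c.seq == circ * (len(c.seq) // 60)
        assert len(c.seq) >= 2 * 81
        assert all(c.seq[s - 1] == circ[-1] and c.seq[s] == circ[0] for s in c.seams)


def _ev(start, end, rid="r", split=40, match=61):
    return JunctionReadEvidence(
        read_id=rid,
        mate_index=1,
        signal_type=SignalType.TWO_SEG,
        chrom="c",
        start=start,
        end=end,
        split_point=split,
        segment_mapqs=(60, 60),
        max_segment_match=match,
    )


class TestClassifyReadSupport:
    L = 100

    @pytest.fixture
    def setup(self, rng):
        g = ReferenceGenome({"c": random_genome(rng, 6000)})
        cand = CircCandidate("c", 2000, 3000, "+", [_ev(2000, 3000)])
        construct = JunctionConstruct.build(cand, g, self.L, 19)
        return g, cand, construct

    def test_unbalanced_junction_read_recovered(self, setup):
        """A junction read with a 12 bp overhang (below the 19 bp aligner
        emission floor) is classified as junction support."""
        g, cand, construct = setup
        read = g.fetch("c", 3000 - 87, 3000) + g.fetch("c", 2000, 2011)
        seg = make_seg("88M12S", pos=3000 - 87, ref="c", seq=read)
        assert (
            classify_read_support(seg, cand, construct, g, DPParams(), self.L)
            is ReadSupport.JUNCTION
        )

    def test_linear_read_across_boundary(self, setup):
        g, cand, construct = setup
        read = g.fetch("c", 2950, 3049)
        seg = make_seg("100M", pos=2950, ref="c", seq=read)
        assert (
            classify_read_support(seg, cand, construct, g, DPParams(), self.L)
            is ReadSupport.LINEAR
        )

    def test_equal_scores_are_ambiguous(self, rng):
        """If the sequence inside the start equals the sequence after the
        end (an exact repeat), boundary reads score equally against the
        junction construct and the linear context."""
        n = 6000
        seq = list(random_genome(rng, n))
        start, end = 2000, 3000
        seq[end : end + 120] = seq[start - 1 : start + 119]  # repeat after end
        g = ReferenceGenome({"c": "".join(seq)})
        cand = CircCandidate("c", start, end, "+", [_ev(start, end)])
        construct = JunctionConstruct.build(cand, g, self.L, 19)
        read = g.fetch("c", end - 49, end + 50)
        seg = make_seg("100M", pos=end - 49, ref="c", seq=read)
        assert (
            classify_read_support(seg, cand, construct, g, DPParams(), self.L)
            is ReadSupport.AMBIGUOUS
        )

    def test_sequence_unavailable_is_neither(self, setup):
        g, cand, construct = setup
        seg = make_seg("50H50M", pos=2950, ref="c", seq=None)
        assert (
            classify_read_support(seg, cand, construct, g, DPParams(), self.L)
            is ReadSupport.NEITHER
        )

    def test_linear_transcript_reads_never_classify_as_junction(self, rng):
        """Error-free reads drawn from the linear sequence around a circle's
        boundaries are never called junction support (10^4 reads)."""
        g = ReferenceGenome({"c": random_genome(rng, 8000)})
        cand = CircCandidate("c", 3000, 4000, "+", [_ev(3000, 4000)])
        construct = JunctionConstruct.build(cand, g, self.L, 19)
        params = DPParams()
        n_junction = 0
        for _ in range(10_000):
            b = 3000 if rng.random() < 0.5 else 4000
            s = int(rng.integers(b - self.L - 50, b + 51))
            read = g.fetch("c", s, s + self.L - 1)
            if rng.random() < 0.5:
                read = revcomp(read)
                seg = make_seg(f"{self.L}M", pos=s, ref="c", strand="-", seq=read)
            else:
                seg = make_seg(f"{self.L}M", pos=s, ref="c", seq=read)
            got = classify_read_support(seg, cand, construct, g, params, self.L)
            n_junction += got is ReadSupport.JUNCTION
        assert n_junction == 0


class TestHomologyFilter:
    def _cand(self, n_reads, longest=61):
        evs = [_ev(1000, 2000, rid=f"r{i}", match=longest) for i in range(n_reads)]
        return CircCandidate("c", 1000, 2000, "+", evs)

    def test_planted_paralog_copy_fails(self, cfg):
        """Few junction reads vs many full-length collinear copies at a
        paralogous locus - the classic tubulin-style false positive."""
        cand = self._cand(3)
        assert not homology_filter(cand, [100] * 50, cfg)

    def test_no_lookalikes_pass(self, cfg):
        assert homology_filter(self._cand(20), [], cfg)

    def test_short_partial_matches_ignored(self, cfg):
        cand = self._cand(5, longest=61)
        assert homology_filter(cand, [40, 35], cfg)

    def test_monotone_in_junction_reads(self, cfg):
        """Adding junction reads never flips the filter from pass to fail."""
        lengths = [100] * 10
        prev = False
        for j in range(1, 30):
            ok = homology_filter(self._cand(j), lengths, cfg)
            assert ok >= prev
            prev = ok
        assert prev  # eventually passes once J outnumbers the lookalikes


class TestRelativeExpressionAndStringency:
    def test_rel_exp_values(self):
        c = CircCandidate("c", 1, 10, "+", [_ev(1, 10, rid=f"r{i}") for i in range(10)])
        c.non_junction_reads = 30
        assert relative_expression(c) == pytest.approx(0.25)
        c2 = CircCandidate("c", 1, 10, "+", [_ev(1, 10, rid=f"r{i}") for i in range(4)])
        c2.non_junction_reads = 0
        assert relative_expression(c2) == 1.0

    def test_rel_exp_threshold_drops_candidate(self):
        cfg = DetectorConfig(min_rel_exp=0.1)
        c = CircCandidate("c", 1, 10, "+", [_ev(1, 10)])
        c.non_junction_reads = 19
        assert relative_expression(c) == 0.05 < cfg.min_rel_exp

    def test_stringency(self):
        dup = CircCandidate("c", 1, 10, "+", [_ev(1, 10, rid=f"r{i}") for i in range(5)])
        two = CircCandidate(
            "c", 20, 40, "+", [_ev(20, 40, rid="a", split=40), _ev(20, 40, rid="b", split=31)]
        )
        high = DetectorConfig(stringency="high")
        low = DetectorConfig(stringency="low")
        assert apply_stringency([dup, two], high) == [two]
        assert apply_stringency([dup, two], low) == [dup, two]
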