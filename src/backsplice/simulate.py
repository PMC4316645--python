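"""Read simulator and synthetic-genome generator.

The generator emulates the ingredients back-splice detection depends on: a
random genome carrying multi-exon genes whose introns are GT..AG bounded
(AC..CT on the plus strand for minus-strand genes), splice signals flanking
every exon, and optional GT-AG-bounded intronic/intergenic fragments (ICFs)
that can circularize on their own.  Linear transcripts are sequenced at
1-100x, circular transcripts at a fixed configurable coverage; fragments
from circles are drawn uniformly around the circle so junction-spanning and
rolling-circle reads arise naturally.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import Gene, GeneModel, ReferenceGenome, Transcript, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class GenomeOptions:
    """Layout parameters for the synthetic genome."""

    length: int = 500_000
    chrom: str = "chrS"
    gc: float = 0.42
    exon_count_range: tuple[int, int] = (3, 8)
    exon_len_range: tuple[int, int] = (80, 300)
    intron_len_range: tuple[int, int] = (80, 600)
    intergenic_gap_range: tuple[int, int] = (150, 800)
    short_exons: int = 0  # genes receiving one short internal exon
    short_exon_len_range: tuple[int, int] = (29, 70)
    n_intronic_icfs: int = 0
    n_intergenic_icfs: int = 0
    icf_len_range: tuple[int, int] = (60, 400)
    circle_loci_sizes: tuple[int, ...] = ()  # explicit intergenic circle loci
    alt_splice_prob: float = 0.6


@dataclass(frozen=True, slots=True)
class IcfRegion:
    """A GT-AG bounded non-exonic fragment able to act as a circle."""

    chrom: str
    start: int
    end: int
    strand: str
    kind: str  # intronic | intergenic | locus
    gene_id: Optional[str] = None


@dataclass
class SyntheticGenome:
    genome: ReferenceGenome
    model: GeneModel
    icfs: list[IcfRegion]


@dataclass
class SimParams:
    """Sequencing-simulation parameters."""

    read_len: int = 100
    insert_len: int = 350
    circ_coverage: float = 10.0
    linear_coverage_range: tuple[float, float] = (1.0, 100.0)
    error_rate: float = 0.005
    p_linear: float = 0.5
    p_circ: float = 0.5
    p_icf: Optional[float] = None  # defaults to p_circ
    rolling_circle: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_len > self.insert_len:
            raise ValueError("read_len must be <= insert_len")
        if self.circ_coverage <= 0 or self.linear_coverage_range[0] <= 0:
            raise ValueError("coverages must be > 0")
        if not 0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0, 0.1)")
        for p in (self.p_linear, self.p_circ, self.p_icf if self.p_icf is not None else 0):
            if not 0 <= p <= 1:
                raise ValueError("selection probabilities must be in [0, 1]")


@dataclass(frozen=True, slots=True)
class CircleSelection:
    chrom: str
    strand: str
    intervals: tuple[tuple[int, int], ...]
    coverage: float
    kind: str  # exonic | intronic | intergenic | locus

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)


@dataclass(frozen=True, slots=True)
class LinearSelection:
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    coverage: float


@dataclass
class SimSelection:
    linear: list[LinearSelection]
    circles: list[CircleSelection]


@dataclass(frozen=True, slots=True)
class SimTruthRecord:
    """One simulated circRNA, as written to the truth table."""

    circ_id: str
    chrom: str
    start: int
    end: int
    strand: str
    kind: str
    intervals: tuple[tuple[int, int], ...]
    length: int
    coverage: float
    expected_pairs: int


def _plant(arr: bytearray, start: int, end: int, strand: str) -> None:
    """Write splice signals around a 1-based inclusive feature interval."""
    before, after = (b"AG", b"GT") if strand == "+" else (b"AC", b"CT")
    arr[start - 3 : start - 1] = before
    arr[end : end + 2] = after


def generate_genome(
    n_genes: int = 50, seed: int = 0, opts: Optional[GenomeOptions] = None
) -> SyntheticGenome:
    """Build a seeded random genome with GT-AG gene models and planted ICFs.

    Raises ``ValueError`` when the requested features do not fit the genome.
    """
    opts = opts or GenomeOptions()
    rng = np.random.default_rng(seed)
    pg = opts.gc / 2
    pa = (1 - opts.gc) / 2
    arr = bytearray(
        _BASES[rng.choice(4, size=opts.length, p=[pa, pg, pg, pa])].tobytes()
    )
    genes: list[Gene] = []
    icfs: list[IcfRegion] = []
    free_gaps: list[list[int]] = []  # [start, end] 1-based usable gaps
    cursor = 10  # 1-based next free coordinate, small head margin
    short_quota = opts.short_exons
    for gi in range(n_genes):
        gap = int(rng.integers(*opts.intergenic_gap_range, endpoint=True))
        gap_start = cursor
        cursor += gap
        if gap >= 60:
            free_gaps.append([gap_start + 10, cursor - 10])
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(*opts.exon_count_range, endpoint=True))
        exon_lens = [
            int(rng.integers(*opts.exon_len_range, endpoint=True)) for _ in range(n_ex)
        ]
        if short_quota > 0 and n_ex >= 3:
            idx = int(rng.integers(1, n_ex - 1))
            exon_lens[idx] = int(
                rng.integers(*opts.short_exon_len_range, endpoint=True)
            )
            short_quota -= 1
        intron_lens = [
            int(rng.integers(*opts.intron_len_range, endpoint=True))
            for _ in range(n_ex - 1)
        ]
        span = sum(exon_lens) + sum(intron_lens)
        if cursor + span + 200 > opts.length:
            raise ValueError(
                f"genome of {opts.length} bp too small for {n_genes} genes "
                f"(placed {gi})"
            )
        exons = []
        pos = cursor
        for k in range(n_ex):
            s, e = pos, pos + exon_lens[k] - 1
            exons.append((s, e))
            _plant(arr, s, e, strand)
            pos = e + 1 + (intron_lens[k] if k < n_ex - 1 else 0)
        cursor = exons[-1][1] + 10
        gene_id = f"gene{gi:04d}"
        transcripts = [Transcript(f"{gene_id}.t1", tuple(exons))]
        if n_ex >= 4 and rng.random() < opts.alt_splice_prob:
            drop = int(rng.integers(1, n_ex - 1))
            alt = tuple(ex for k, ex in enumerate(exons) if k != drop)
            transcripts.append(Transcript(f"{gene_id}.t2", alt))
        genes.append(Gene(gene_id, opts.chrom, strand, tuple(transcripts)))
        # intronic ICF placement is deferred; remember introns via the gene
    tail_start = cursor + 10
    if tail_start + 60 < opts.length:
        free_gaps.append([tail_start, opts.length - 10])

    # intronic ICFs
    placed = 0
    tries = 0
    while placed < opts.n_intronic_icfs and tries < opts.n_intronic_icfs * 60:
        tries += 1
        g = genes[int(rng.integers(0, len(genes)))]
        t = g.transcripts[0]
        if len(t.exons) < 2:
            continue
        k = int(rng.integers(0, len(t.exons) - 1))
        ilo, ihi = t.exons[k][1] + 1, t.exons[k + 1][0] - 1
        size = int(rng.integers(*opts.icf_len_range, endpoint=True))
        if ihi - ilo + 1 < size + 24:
            continue
        s = int(rng.integers(ilo + 10, ihi - size - 10))
        e = s + size - 1
        if any(
            i.gene_id == g.gene_id and not (e < i.start - 12 or s > i.end + 12)
            for i in icfs
        ):
            continue
        _plant(arr, s, e, g.strand)
        icfs.append(IcfRegion(opts.chrom, s, e, g.strand, "intronic", g.gene_id))
        placed += 1
    if placed < opts.n_intronic_icfs:
        raise ValueError("could not place all requested intronic ICFs")

    # intergenic ICFs and explicit circle loci
    requests = [("intergenic", int(rng.integers(*opts.icf_len_range, endpoint=True)))
                for _ in range(opts.n_intergenic_icfs)]
    requests += [("locus", int(size)) for size in opts.circle_loci_sizes]
    for kind, size in requests:
        slot = next((gp for gp in free_gaps if gp[1] - gp[0] + 1 >= size + 10), None)
        if slot is None:
            raise ValueError("no intergenic room left for requested ICF/circle loci")
        s = slot[0] + 5
        e = s + size - 1
        slot[0] = e + 12
        _plant(arr, s, e, "+")
        icfs.append(IcfRegion(opts.chrom, s, e, "+", kind, None))

    genome = ReferenceGenome({opts.chrom: arr.decode()})
    return SyntheticGenome(genome, GeneModel(genes), icfs)


def select_transcripts(syn: SyntheticGenome, params: SimParams) -> SimSelection:
    """Draw the linear and circular transcript sets.

    Two independent uniform draws per transcript decide linear and circular
    selection (transcripts of one gene are independent, mimicking
    alternative splicing); a selected circular transcript contributes a
    random contiguous exon run.  ICFs circularize with probability ``p_icf``
    (explicit circle loci always).
    """
    rng = np.random.default_rng([params.seed, 11])
    lo, hi = params.linear_coverage_range
    linear: list[LinearSelection] = []
    circles: list[CircleSelection] = []
    for gene in syn.model.genes:
        for t in gene.transcripts:
            r_lin, r_circ = rng.random(2)
            if r_lin < params.p_linear:
                linear.append(
                    LinearSelection(
                        gene.gene_id, gene.chrom, gene.strand, t.exons,
                        float(rng.uniform(lo, hi)),
                    )
                )
            if r_circ < params.p_circ:
                n = len(t.exons)
                i = int(rng.integers(0, n))
                j = int(rng.integers(i, n))
                circles.append(
                    CircleSelection(
                        gene.chrom, gene.strand, t.exons[i : j + 1],
                        params.circ_coverage, "exonic",
                    )
                )
    p_icf = params.p_icf if params.p_icf is not None else params.p_circ
    for icf in syn.icfs:
        p = 1.0 if icf.kind == "locus" else p_icf
        if rng.random() < p:
            circles.append(
                CircleSelection(
                    icf.chrom, icf.strand, ((icf.start, icf.end),),
                    params.circ_coverage,
                    "intergenic" if icf.kind == "locus" else icf.kind,
                )
            )
    seen: set[tuple[str, int, int]] = set()
    uniq = []
    for c in circles:
        key = (c.chrom, c.start, c.end)
        if key not in seen:
            seen.add(key)
            uniq.append(c)
    return SimSelection(linear, uniq)


def _interval_seq(
    genome: ReferenceGenome, chrom: str, intervals: Sequence[tuple[int, int]], strand: str
) -> str:
    s = "".join(genome.fetch(chrom, a, b) for a, b in intervals)
    return revcomp(s) if strand == "-" else s


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), np.uint8).copy()
    mask = rng.random(arr.shape[0]) < rate
    n = int(mask.sum())
    if n == 0:
        return seq
    lut = np.zeros(128, np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    codes = lut[arr[mask]]
    codes = (codes + rng.integers(1, 4, size=n)) % 4
    arr[mask] = _BASES[codes]
    return arr.tobytes().decode()


def generate_reads(
    syn: SyntheticGenome,
    selection: SimSelection,
    params: SimParams,
    fq1_path,
    fq2_path,
    truth_path=None,
) -> list[SimTruthRecord]:
    """Write the paired FASTQ files and the circle truth table.

    Read-pair counts follow ``round(coverage x length / (2 x read_len))``;
    fragment starts are uniform along the molecule (uniform around the
    circle for circular molecules, with rolling-circle tiling when the
    circle is shorter than the insert).
    """
    rng = np.random.default_rng([params.seed, 23])
    L, ins = params.read_len, params.insert_len
    genome = syn.genome
    out1: list[str] = []
    out2: list[str] = []
    qual = "I" * L

    def emit(name: str, frag: str) -> None:
        r1 = _mutate(frag[:L], rng, params.error_rate)
        r2 = _mutate(revcomp(frag[-L:]), rng, params.error_rate)
        out1.append(f"@{name}/1\n{r1}\n+\n{qual}\n")
        out2.append(f"@{name}/2\n{r2}\n+\n{qual}\n")

    for k, lin in enumerate(selection.linear):
        seq = _interval_seq(genome, lin.chrom, lin.exons, lin.strand)
        if len(seq) < L:
            continue
        eff = max(min(ins, len(seq)), L)
        n_pairs = round(lin.coverage * len(seq) / (2 * L))
        starts = rng.integers(0, len(seq) - eff + 1, size=n_pairs)
        for i, s in enumerate(starts):
            emit(f"ln{k}_{i}", seq[s : s + eff])

    truth: list[SimTruthRecord] = []
    for k, circ in enumerate(selection.circles):
        seq = _interval_seq(genome, circ.chrom, circ.intervals, circ.strand)
        cl = len(seq)
        if cl < 2:
            warnings.warn(f"circle {k} shorter than 2 bp; skipped")
            continue
        if not params.rolling_circle and cl < L:
            warnings.warn(f"circle {k} shorter than the read; skipped (rolling off)")
            continue
        eff = ins if (params.rolling_circle or cl >= ins) else cl
        reps = min(math.ceil(eff / cl) + 1, math.ceil(ins / cl) + 1)
        tile = seq * max(reps, 1)
        n_pairs = round(circ.coverage * cl / (2 * L))
        starts = rng.integers(0, cl, size=n_pairs)
        for i, s in enumerate(starts):
            emit(f"cr{k}_{i}", tile[s : s + eff])
        truth.append(
            SimTruthRecord(
                circ_id=f"circ{k:04d}",
                chrom=circ.chrom,
                start=circ.start,
                end=circ.end,
                strand=circ.strand,
                kind=circ.kind,
                intervals=circ.intervals,
                length=cl,
                coverage=circ.coverage,
                expected_pairs=n_pairs,
            )
        )
    Path(fq1_path).write_text("".join(out1))
    Path(fq2_path).write_text("".join(out2))
    if truth_path is not None:
        write_truth(truth, truth_path)
    return truth


def write_truth(truth: list[SimTruthRecord], path) -> None:
    header = "circ_id\tchrom\tstart\tend\tstrand\tkind\tlength\tcoverage\tintervals\texpected_pairs\n"
    rows = [
        f"{t.circ_id}\t{t.chrom}\t{t.start}\t{t.end}\t{t.strand}\t{t.kind}\t"
        f"{t.length}\t{t.coverage:g}\t"
        + ",".join(f"{a}-{b}" for a, b in t.intervals)
        + f"\t{t.expected_pairs}\n"
        for t in truth
    ]
    Path(path).write_text(header + "".join(rows))


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


@dataclass
class EvalResult:
    sensitivity: float
    fdr: float
    n_truth: int
    n_predictions: int
    n_matched: int
    matched: list[tuple[str, str]] = field(default_factory=list)  # (circ_id, pred_id)
    matched_truth_ids: set = field(default_factory=set)


def evaluate(predictions, truth, tol: int = 0) -> EvalResult:
    """Match a prediction table against the simulated truth list.

    A prediction matches a truth circle when chrom agrees and both boundary
    deviations are within ``tol``; every truth record matches at most one
    prediction, extra predictions of the same junction count as false
    positives.  ``predictions``/``truth`` may be paths or DataFrames with
    chrom/start/end columns.
    """
    pred_df = predictions if isinstance(predictions, pd.DataFrame) else pd.read_csv(
        predictions, sep="\t", dtype={"chrom": str}
    )
    truth_df = truth if isinstance(truth, pd.DataFrame) else read_truth(truth)
    if len(truth_df) == 0:
        raise ValueError("empty truth list")
    unmatched: dict[str, dict[tuple[int, int], list]] = {}
    for _, row in truth_df.iterrows():
        unmatched.setdefault(str(row["chrom"]), {}).setdefault(
            (int(row["start"]), int(row["end"])), []
        ).append(str(row["circ_id"]) if "circ_id" in row else f"{row['start']}|{row['end']}")
    matched: list[tuple[str, str]] = []
    matched_truth: set = set()
    n_fp = 0
    for _, row in pred_df.iterrows():
        chrom = str(row["chrom"])
        s, e = int(row["start"]), int(row["end"])
        pred_id = str(row["circRNA_id"]) if "circRNA_id" in row else f"{chrom}:{s}|{e}"
        best = None
        for (ts, te), ids in unmatched.get(chrom, {}).items():
            if ids and abs(ts - s) <= tol and abs(te - e) <= tol:
                d = abs(ts - s) + abs(te - e)
                if best is None or d < best[0]:
                    best = (d, (ts, te))
        if best is None:
            n_fp += 1
        else:
            ids = unmatched[chrom][best[1]]
            tid = ids.pop(0)
            matched.append((tid, pred_id))
            matched_truth.add(tid)
    n_pred = len(pred_df)
    sens = len(matched_truth) / len(truth_df)
    fdr = n_fp / n_pred if n_pred else 0.0
    return EvalResult(
        sensitivity=sens,
        fdr=fdr,
        n_truth=len(truth_df),
        n_predictions=n_pred,
        n_matched=len(matched_truth),
        matched=matched,
        matched_truth_ids=matched_truth,
    )
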