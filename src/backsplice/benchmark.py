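"""Simulation studies: simulate -> map -> detect -> evaluate in one call.

Used by the test suite and the reproduction script; everything is seeded
and runs in a scratch directory.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import pandas as pd

from .annotate import read_report, write_report
from .mapper import fixture_map
from .model import DetectorConfig
from .pipeline import RunManifest, detect
from .simulate import (
    CircleSelection,
    EvalResult,
    GenomeOptions,
    SimParams,
    SimSelection,
    SyntheticGenome,
    evaluate,
    generate_genome,
    generate_reads,
    select_transcripts,
    write_truth,
)


@dataclass
class StudyResult:
    sensitivity: float
    fdr: float
    n_truth: int
    n_predictions: int
    truth: pd.DataFrame
    predictions: pd.DataFrame
    eval_result: EvalResult
    manifest: RunManifest
    workdir: Path


def run_study(
    workdir,
    seed: int = 0,
    n_genes: int = 50,
    genome_opts: Optional[GenomeOptions] = None,
    sim_params: Optional[SimParams] = None,
    cfg: Optional[DetectorConfig] = None,
    tol: int = 0,
    select_hook: Optional[Callable[[SyntheticGenome, SimSelection], SimSelection]] = None,
) -> StudyResult:
    """Run one full simulation study and score it against the truth list.

    ``select_hook`` may rewrite the transcript selection (e.g. to plant
    circles with prescribed structures) before reads are generated.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    sim_params = sim_params or SimParams(seed=seed)
    cfg = cfg or DetectorConfig()
    syn = generate_genome(n_genes=n_genes, seed=seed, opts=genome_opts)
    selection = select_transcripts(syn, sim_params)
    if select_hook is not None:
        selection = select_hook(syn, selection)
    fq1 = workdir / "reads_1.fastq"
    fq2 = workdir / "reads_2.fastq"
    truth_path = workdir / "truth.tsv"
    truth = generate_reads(syn, selection, sim_params, fq1, fq2, truth_path)
    sam = workdir / "mapped.sam"
    fixture_map(fq1, fq2, syn.genome, sam, min_segment=cfg.min_segment)
    cands, manifest = detect(sam, syn.genome, model=None, cfg=cfg)
    report = workdir / "report.tsv"
    write_report(cands, report)
    pred_df = read_report(report)
    truth_df = pd.read_csv(truth_path, sep="\t", dtype={"chrom": str})
    if len(truth_df):
        ev = evaluate(pred_df, truth_df, tol=tol)
        sens, fdr = ev.sensitivity, ev.fdr
    else:
        ev = EvalResult(0.0, 0.0, 0, len(pred_df), 0)
        sens, fdr = 0.0, 0.0
    return StudyResult(
        sensitivity=sens,
        fdr=fdr,
        n_truth=len(truth_df),
        n_predictions=len(pred_df),
        truth=truth_df,
        predictions=pred_df,
        eval_result=ev,
        manifest=manifest,
        workdir=workdir,
    )


def study_coverage(workdir, seed: int, circ_coverage: float = 10.0) -> StudyResult:
    """Reference simulation design: 500 kb genome, ~130 mixed circles
    (exonic runs, intronic and intergenic ICFs, short exons included),
    100 bp paired-end reads, linear background 1-100x, 0.5% error."""
    return run_study(
        workdir,
        seed=seed,
        n_genes=150,
        genome_opts=GenomeOptions(
            length=500_000,
            intron_len_range=(80, 500),
            intergenic_gap_range=(150, 600),
            n_intronic_icfs=20,
            n_intergenic_icfs=15,
            short_exons=8,
        ),
        sim_params=SimParams(seed=seed, circ_coverage=circ_coverage, error_rate=0.005),
        cfg=DetectorConfig(stringency="low"),
    )


def study_size_classes(workdir, seed: int, per_class: int = 30) -> StudyResult:
    """80 bp reads at 10x circular coverage over circles planted in four
    size classes relative to the read length (<=80/81-160/161-240/>240)."""
    import numpy as np

    rng = np.random.default_rng([seed, 3])
    sizes: list[int] = []
    for lo, hi in ((40, 80), (81, 160), (161, 240), (241, 400)):
        sizes += [int(x) for x in rng.integers(lo, hi, size=per_class, endpoint=True)]
    return run_study(
        workdir,
        seed=seed,
        n_genes=25,
        genome_opts=GenomeOptions(
            length=300_000,
            intron_len_range=(80, 500),
            intergenic_gap_range=(400, 1200),
            circle_loci_sizes=tuple(sizes),
        ),
        sim_params=SimParams(
            seed=seed, read_len=80, insert_len=200, circ_coverage=10.0,
            p_circ=0.0, p_icf=1.0, error_rate=0.005,
        ),
        cfg=DetectorConfig(stringency="low"),
    )


def study_linear_only(workdir, seed: int) -> StudyResult:
    """Background false-positive test: a linear-only library of >= 10^5
    read pairs; the detector should call (almost) nothing."""
    return run_study(
        workdir,
        seed=seed,
        n_genes=300,
        genome_opts=GenomeOptions(
            length=1_150_000,
            intron_len_range=(80, 500),
            intergenic_gap_range=(150, 600),
        ),
        sim_params=SimParams(seed=seed, p_circ=0.0, p_linear=1.0, error_rate=0.005),
        cfg=DetectorConfig(stringency="low"),
    )


def study_exact_recovery(workdir, seed: int) -> StudyResult:
    """Error-free simulation at default (high) stringency: every reported
    junction should match the truth at zero tolerance."""
    return run_study(
        workdir,
        seed=seed,
        n_genes=60,
        genome_opts=GenomeOptions(
            length=250_000,
            intron_len_range=(80, 500),
            n_intronic_icfs=8,
            n_intergenic_icfs=6,
            short_exons=4,
        ),
        sim_params=SimParams(seed=seed, error_rate=0.0),
        cfg=DetectorConfig(),
    )


def study_small_circles(workdir, seed: int, n_loci: int = 30) -> StudyResult:
    """Circles of 40-80 bp (shorter than the read) sequenced with
    rolling-circle fragments."""
    import numpy as np

    rng = np.random.default_rng([seed, 5])
    sizes = tuple(int(x) for x in rng.integers(40, 80, size=n_loci, endpoint=True))
    return run_study(
        workdir,
        seed=seed,
        n_genes=15,
        genome_opts=GenomeOptions(
            length=150_000,
            intron_len_range=(80, 400),
            circle_loci_sizes=sizes,
        ),
        sim_params=SimParams(seed=seed, p_circ=0.0, p_icf=1.0, error_rate=0.005),
        cfg=DetectorConfig(stringency="low"),
    )


def study_short_exon_circles(workdir, seed: int, n_genes: int = 35) -> StudyResult:
    """Circles whose junction-flanking first exon is 29-50 bp (much shorter
    than the read), exercising the three-segment signal path."""

    def hook(syn, sel):
        circles = []
        for g in syn.model.genes:
            t = g.transcripts[0]
            for i, (s, e) in enumerate(t.exons):
                if 29 <= e - s + 1 <= 50 and i + 1 < len(t.exons):
                    j = min(i + 2, len(t.exons) - 1)
                    circles.append(
                        CircleSelection(g.chrom, g.strand, t.exons[i : j + 1], 10.0, "exonic")
                    )
                    break
        sel.circles = circles
        return sel

    return run_study(
        workdir,
        seed=seed,
        n_genes=n_genes,
        genome_opts=GenomeOptions(
            length=300_000,
            intron_len_range=(80, 500),
            short_exons=n_genes,
            short_exon_len_range=(29, 50),
        ),
        sim_params=SimParams(seed=seed, p_circ=0.0, p_linear=0.3, error_rate=0.005),
        cfg=DetectorConfig(stringency="low"),
        select_hook=hook,
    )


def sensitivity_by_class(
    result: StudyResult, edges: tuple[int, ...] = (80, 160, 240)
) -> dict[str, tuple[float, int]]:
    """Per-size-class sensitivity, classes split at the given length edges.

    Returns {label: (sensitivity, n_truth_in_class)}.
    """
    truth = result.truth
    matched = result.eval_result.matched_truth_ids
    bounds = [0, *edges, float("inf")]
    out = {}
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        label = f"<={hi:g}" if lo == 0 else (f">{lo:g}" if hi == float("inf") else f"{lo + 1:g}-{hi:g}")
        sub = truth[(truth["length"] > lo) & (truth["length"] <= hi)]
        n = len(sub)
        hit = sum(1 for cid in sub["circ_id"] if cid in matched)
        out[label] = (hit / n if n else float("nan"), n)
    return out
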