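"""End-to-end detection pipeline: two SAM scans, filtering, annotation.

Stage order mirrors the detection workflow: PCC signal scan -> paired-end
mapping filter -> splice-signal / exon-boundary correction -> clustering ->
second-scan DP refinement and homology filtering -> stringency -> annotation
-> report.
"""
from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .annotate import annotate_candidates, write_report
from .io import load_fasta, load_gtf, read_sam_grouped, sam_reference_names
from .model import CircCandidate, DetectorConfig, GeneModel, ReferenceGenome
from .refine import apply_stringency, refine_candidates
from .scan import (
    cluster_junctions,
    detect_evidence,
    exon_boundary_filter,
    identical_sequence_filter,
    pem_filter,
    splice_signal_filter,
)


@dataclass
class RunManifest:
    """Provenance and per-stage survival counts for one detection run."""

    inputs: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    version: str = ""
    survival: list = field(default_factory=list)  # ordered (stage, count)
    wall_times: dict = field(default_factory=dict)

    def record(self, stage: str, count: int) -> None:
        self.survival.append((stage, count))

    def to_dict(self) -> dict:
        return {
            "inputs": self.inputs,
            "config": self.config,
            "version": self.version,
            "survival": self.survival,
            "wall_times": self.wall_times,
        }


def _file_md5(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def detect(
    sam_path,
    genome: ReferenceGenome,
    model: Optional[GeneModel] = None,
    cfg: Optional[DetectorConfig] = None,
    manifest: Optional[RunManifest] = None,
) -> tuple[list[CircCandidate], RunManifest]:
    """Run both scans over a SAM file and return final annotated candidates."""
    cfg = cfg or DetectorConfig()
    manifest = manifest or RunManifest()
    t0 = time.perf_counter()

    sam_refs = set(sam_reference_names(sam_path))
    missing = sorted(r for r in sam_refs if r not in genome)
    if missing:
        raise ValueError(
            f"SAM references absent from the FASTA: {', '.join(missing)}"
        )

    # scan 1: collect groups per read end, keyed also by query for PEM mates
    by_query: dict[str, dict[int, list]] = {}
    read_len = 0
    for (qname, mate), group in read_sam_grouped(sam_path):
        by_query.setdefault(qname, {})[mate] = group
        for seg in group:
            read_len = max(read_len, seg.query_len)
    if cfg.read_len:
        read_len = cfg.read_len
    manifest.record("read_ends_scanned", sum(len(v) for v in by_query.values()))

    raw = []
    for qname, mates in by_query.items():
        for mate_idx, group in mates.items():
            for ev in detect_evidence(group, cfg):
                raw.append((ev, mates.get(2 if mate_idx == 1 else 1)))
    manifest.record("pcc_evidence", len(raw))

    after_pem = []
    for ev, mate_group in raw:
        ok, label = pem_filter(ev, mate_group, cfg)
        ev.filter_log.append(("pem", label))
        if ok:
            after_pem.append(ev)
    manifest.record("after_pem", len(after_pem))

    corrected = []
    for ev in after_pem:
        ok = False
        if cfg.exon_boundary_mode != "alternative":
            ok, s, e, strand, label = splice_signal_filter(ev, genome, cfg)
            ev.filter_log.append(("splice_signal", label))
            if ok:
                ev.offset_applied = s - ev.start
                ev.start, ev.end, ev.strand = s, e, strand
        if not ok and cfg.exon_boundary_mode != "off" and model is not None:
            ok2, s, e = exon_boundary_filter(ev, model, cfg)
            ev.filter_log.append(("exon_boundary", "pass" if ok2 else "fail"))
            if ok2:
                ev.offset_applied = s - ev.start
                ev.start, ev.end = s, e
                ok = True
        if ok:
            corrected.append(ev)
    manifest.record("after_boundary_filters", len(corrected))

    if cfg.identical_seq_filter:
        kept = []
        for ev in corrected:
            ok = identical_sequence_filter(ev, genome, cfg)
            ev.filter_log.append(("identical_seq", "pass" if ok else "fail"))
            if ok:
                kept.append(ev)
        corrected = kept
    manifest.record("after_identical_seq", len(corrected))

    candidates = cluster_junctions(corrected)
    manifest.record("candidates_clustered", len(candidates))
    manifest.wall_times["scan1_s"] = round(time.perf_counter() - t0, 3)

    t1 = time.perf_counter()
    refined = refine_candidates(sam_path, candidates, genome, cfg, read_len)
    manifest.record("after_homology_rel_exp", len(refined))
    final = apply_stringency(refined, cfg)
    manifest.record("after_stringency", len(final))
    manifest.wall_times["scan2_s"] = round(time.perf_counter() - t1, 3)

    annotate_candidates(final, model)
    return final, manifest


def run_detect(
    sam_path,
    fasta_path,
    out_path,
    gtf_path=None,
    cfg: Optional[DetectorConfig] = None,
    bed_path=None,
) -> tuple[list[CircCandidate], RunManifest]:
    """File-level entry point used by the command line."""
    from . import __version__
    from .annotate import write_bed

    genome = load_fasta(fasta_path)
    model = load_gtf(gtf_path) if gtf_path else None
    cfg = cfg or DetectorConfig()
    manifest = RunManifest(
        inputs={
            "sam": str(sam_path),
            "sam_md5": _file_md5(sam_path),
            "fasta": str(fasta_path),
            "fasta_md5": _file_md5(fasta_path),
            "gtf": str(gtf_path) if gtf_path else None,
        },
        config={k: str(v) for k, v in vars(cfg).items()},
        version=__version__,
    )
    cands, manifest = detect(sam_path, genome, model, cfg, manifest)
    write_report(cands, out_path)
    if bed_path:
        write_bed(cands, bed_path)
    return cands, manifest
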