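# Methods

## Detection model

A back-splice junction joins a downstream splice donor (circle end) to an
upstream acceptor (circle start), so a read crossing it aligns in two parts
in reversed genomic order. The detector consumes the SAM records of a local
split aligner (BWA-MEM conventions: one soft-clipped primary plus
hard-clipped supplementary records per split read; secondary records are
ignored, since split parts are flagged supplementary) and performs two
passes.

**Scan 1 — PCC signals.** For each read end, every pair of records with
complementary clip/match decompositions (`xS yM` upstream vs `xM yS`
downstream, S and H equivalent) is tested for the chiastic geometry; clip
lengths must correspond within the boundary tolerance, the records must share
reference and strand, the upstream match must start at or before the
downstream record, and the implied span must not exceed `max_span`.
Three-segment variants handle (a) junction-flanking exons shorter than the
read (terminal blocks outside the doubly clipped middle record) and (b)
circles shorter than the read (terminal blocks inside the middle interval and
abutting its termini). MAPQ thresholds (`-u` per segment, `-b` summed) are
applied per emitted evidence.

**Filters.** In paired-end mode the mate must map within the putative circle
(single-end libraries skip this step, recorded as "omitted"). Splice-signal
filtering accepts a junction only when `AG`/`GT` (plus strand) or `AC`/`CT`
(minus strand) flank the corrected boundaries. Because clipped boundaries are
obscured when bases beyond the junction fortuitously match the reference,
shifts `d = 0, +1, −1, …` up to the tolerance are searched and applied to
*both* ends together. When the two split records themselves disagree on the
split point by `delta` (downstream match minus upstream clip — the signature
of independent chance extension at the two ends), the end shift is
constrained to `d_end = d_start − delta`; with agreeing records (`delta = 0`)
this reduces exactly to the same-direction/same-distance rule. Without this
resolution a large fraction of junction reads at low coverage would be
discarded for a 1–3 bp chance extension. Annotated exon boundaries can be
used as a complementary (OR) or alternative filter; an optional filter (`-E`)
removes junctions whose seam-spanning `2w`-mer (`w = min_segment`) occurs
collinearly within `max_span` of the locus.

**Scan 2 — DP refinement.** Accepted evidence is clustered by corrected
locus. For each candidate a junction construct stitches the `L − 19` bases
inside each boundary across the seam (`L` = read length; circles shorter than
the flank are tiled, giving one seam per copy). Every primary record
overlapping a boundary ± `L` window is fit-aligned (full query against any
target substring, affine gaps, deterministic traceback) against the construct
and against the linear context windows at both boundaries. A read supports
the junction when identity ≥ 0.90, it crosses a seam with ≥ 8 bases on both
sides and beats the best linear alignment by ≥ 2 score units; the symmetric
rule yields linear (non-junction) support, near-ties are ambiguous and
counted for neither. This recovers unbalanced junction reads whose short
split part (< 19 bp) the aligner never reported. Relative expression is
`J/(J+N)`. Reads containing a candidate's seam sequence but aligning
collinearly and full-length outside the candidate's `max_span` context are
homology lookalikes: a candidate fails when lookalikes at least as long as
its longest junction segment outnumber its junction reads (the
tubulin-paralog failure mode). High stringency finally requires two distinct
(split point, signal type) layouts; low stringency reports everything.

Candidates are categorized against an optional gene model: an end inside any
exon is exonic, inside a gene span but no exon intronic, otherwise
intergenic; the candidate takes intergenic over intron over exon precedence
across its two ends (documented choice: when one end is intronic and the
other intergenic, intergenic wins; gene-span edges count as inside).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_segment` | 19 bp | aligner emission floor; flank width of constructs/probes |
| `max_span` | 200 kb | maximum circle span considered |
| `boundary_tolerance` | 5 bp | clip-correspondence and shift-search window |
| `-u` / `-b` | 0 / 0 | MAPQ per segment / summed (3/13 advisable for single-end) |
| `stringency` | high | high: ≥ 2 distinct PCC layouts; low: report all |
| DP scoring | +1/−2, gap −3/−1 | fit alignment; identity ≥ 0.90, overhang ≥ 8, margin 2 |
| `min_rel_exp` | off | optional floor on `J/(J+N)` |

The DP scoring constants and the identity/overhang/margin thresholds are this
package's choices (the refinement step only prescribes *a* dynamic
programming alignment); all are exposed in `DPParams`. The paired-end mate
containment check allows `boundary_tolerance` slack at each end, since a mate
abutting a boundary routinely over-extends by a few chance-matching bases.

## Synthetic data

`generate_genome` draws a random sequence (default 500 kb, GC 0.42) and
plants multi-exon genes (3–8 exons of 80–300 bp, introns 80–600 bp by
default, 1–2 transcripts per gene with one exon skipped to mimic alternative
splicing) such that every exon is flanked by `AG…GT` (strand-appropriately),
hence every intron is GT…AG in transcription orientation. Optional planted
features: short internal exons (29–70 bp), GT-AG-bounded intronic and
intergenic fragments that can circularize on their own, and explicit circle
loci of prescribed sizes. `select_transcripts` draws two independent uniforms
per transcript (linear with `p_linear`, circular with `p_circ`, both 0.5 by
default since only the mechanism, not the rates, is prescribed); a circular
selection contributes a random contiguous exon run; linear coverage is
uniform on 1–100x, circular coverage fixed (10x default). Fragments are
placed uniformly (uniformly around the circle for circular molecules, tiled
rolling-circle when the circle is shorter than the insert; at most
`ceil(insert/circle)+1` copies), with pair counts
`round(cov·len/(2·read_len))`, fixed fragment length = insert (350 bp
default, 100 bp reads), and per-base substitution errors (0.5% default).
Duplicate circles arising from shared exon runs are de-duplicated by locus.

The fixture mapper indexes every genomic 19-mer and scores each read
diagonal ungapped at +1/−4, trimming to the best run; split parts shorter
than 19 bp are *not* emitted, reproducing the unbalanced-read phenomenon.
MAPQ is 60 for unique placements, 0 when an equivalent-scoring placement
overlaps ≥ 80% of the same read interval.

**What the simulation does not model:** indel sequencing errors, quality
score profiles, PCR duplicates, strand-specific protocols, GC/coverage bias,
repeat families beyond chance k-mer repeats, and multi-fragment non-exonic
circles (each planted fragment circularizes alone). Passing benchmarks
therefore demonstrates correctness of the geometric/filtering logic under
idealized substitution-only noise, not performance on real libraries mapped
with a production aligner.

## Benchmark designs (scripts/acceptance.py, tests/test_acceptance.py)

Problem sizes are chosen to keep each study in tens of seconds on one core:

- **coverage studies** — 500 kb genome, 150 genes, ~130 mixed circles
  (exonic runs, 20 intronic + 15 intergenic fragments, 8 short exons),
  100 bp PE reads, linear 1–100x, 0.5% error; circular coverage 10x and 3x;
  sensitivity at zero tolerance after splice correction, low stringency.
- **size classes** — 30 circle loci in each of ≤80/81–160/161–240/>240 bp,
  80 bp reads, insert 200, 10x; per-class sensitivity.
- **linear-only background** — 1.15 Mb, 300 genes, every transcript linear
  (≥ 10⁵ pairs), no circles; candidate count measured.
- **exact recovery** — error-free 250 kb design at default (high)
  stringency; every call must match truth exactly.
- **small circles / short exons** — 40–80 bp loci with rolling-circle
  fragments; circles whose first exon is 29–50 bp.

## Numerical and degenerate-case choices

Ties in the fit alignment resolve to the leftmost target end and a
diagonal-first (then gap-in-target, then gap-in-query) traceback; shift
search order is `0, +1, −1, …` (positive first). Clustering, reporting and
the mapper iterate in deterministic orders, so all outputs are byte-stable
under a fixed seed. Hard-clipped supplementary records inherit the full read
sequence from their primary (reverse-complemented across strands). Circles
shorter than 2 bp are skipped with a warning; reads without usable sequence
classify as neither junction nor linear. Empty candidate sets short-circuit
scan 2. Reference intervals are 1-based inclusive everywhere; junction ids
use `chrom:start|end`.

## Known limitations

- Junction constructs use genomic flanks; for multi-exon circles whose
  boundary exon is shorter than `L − 19`, the construct diverges beyond the
  exon and some unbalanced reads are not recovered (the balanced three-segment
  path still covers these junctions).
- The homology lookalike search requires an exact seam `2w`-mer within a
  read, so lookalikes carrying a sequencing error inside the seam are missed.
- Trans-chromosomal and strand-discordant chimeras are out of scope, as are
  BAM/CRAM input and isoform-structure inference within a circle.
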