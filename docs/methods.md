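# Methods

This note documents the models and procedures `retromap` implements, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions a maintainer would want to
know. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Junction model

A provirus integrated by its integrase carries intact long terminal
repeats whose outermost dinucleotides (5'-TG ... CA-3') end up immediately
adjacent to host DNA, usually with a short target-site duplication (TSD)
of the host sequence flanking the insert. Junctions created instead by
homologous recombination or non-homologous end joining typically erode one
or both termini and duplicate nothing. `retromap` therefore distinguishes
two junction classes:

* **integrase-catalyzed** — the complete library anchor (which ends with
  the LTR terminal dinucleotide in read orientation, for both library
  ends) is present and the host-flank alignment starts at the very next
  base;
* **process-unresolved** — anything else: a partial anchor (eroded
  terminus), or *microhomology*: a host flank that itself begins with the
  terminal dinucleotide, in which case the boundary cannot be assigned to
  either side. Microhomology is operationalized as the host flank opening
  with the 2-base terminus (`CA` in read orientation); longer overlaps
  imply that shorter one, and a 1-base test would reclassify a quarter of
  all genuine integrase junctions on base-composition grounds alone.

Calls are keyed by (chromosome, first host base, host-flank strand,
library end). TSDs are deliberately ignored in coordinates: the two
junctions of one event therefore land within `tsd` bases of each other in
host coordinates and are reconciled by clustering, not by arithmetic.

## 2. Amplicon (TraDIS-style) calling

Authenticity criteria, applied in order, with thresholds in
`FilterParams`:

| parameter | default | unit | rationale |
|---|---|---|---|
| `min_overlap_merge` | 10 | bp | minimum mate overlap to merge a pair |
| `min_host_match` | 30 | bp | minimum uniquely matched host flank |
| `min_mapq` | 30 | phred | "Q30" mapping-quality gate |
| `cluster_radius` | 250 | bp | neighboring unique positions count once |
| `anchor_mismatch_tolerance` | 0 | subst. | anchors are matched exactly |

Anchor detection accepts a *partial* anchor prefix down to
`MIN_ANCHOR_MATCH = 20` bases. This is what lets terminus-eroded junctions
be detected at all (they can never be called integrase-catalyzed); an
erosion deeper than `anchor length − 20` leaves too little anchor and the
end is invisible to its library, which mirrors the loss of the priming
region in a real library. A substitution within the first 20 bases defeats
detection entirely under the default zero tolerance.

"Immediately followed by splinkerette" is operationalized as the adapter
beginning within 5 bases of the anchor end; the window distinguishes empty
inserts from genuine host flanks, which must then survive the 30-bp
unique-match criterion anyway.

Deduplication collapses identical (chromosome, position, strand, end)
calls — the PCR-duplicate rule — taking the majority junction class with
ties resolved to unresolved. Clustering is transitive single linkage: a
new cluster starts when the gap to the previous sorted position exceeds
the radius, so a chain 0, 200, 400 is one cluster. Unique positions are
strand-aware; clusters are not (they group positions regardless of
strand). The 5'- and 3'-end libraries are never merged into joint events;
all tables report them separately.

## 3. Read mapping

The built-in aligner is a seed-and-extend *ungapped* mapper: exact 15-mer
seeds (sorted-array index, binary-search lookup, forward strand indexed,
reverse strand seeded from the reverse-complemented query), every seeded
diagonal evaluated by taking the maximum-scoring contiguous segment
(match +1 / mismatch −1, Kadane on the match profile). This yields
soft-clipped local alignments, which is exactly what junction-spanning
reads need; indels are not modeled because no junction criterion depends
on them, and alignments from an external gapped aligner can be supplied
via SAM instead. Host and provirus are indexed together so each read
competes across both references.

Mapping quality is `min(60, 2·(best − second-best score))`, and 0 whenever
the best score is tied (`n_cooptimal > 1`). The calibration is not meant
to reproduce any particular external aligner's mapq — only the semantics
of the Q30 gate (unique, high-confidence placements pass; ambiguous ones
do not). "Uniquely mapped" means a single best-scoring placement.

## 4. WGS burden estimator

Evidence categories: *partial* requires a split read with ≥ 20 aligned
bases on each reference and complementary query spans (≤ 12 bases of slop
at the boundary); *independent* requires one mate host-only and one
provirus-only; *virus-only* pairs carry no positional evidence. A
chimeric assignment is vetoed when a second host placement explains the
would-be provirus segment at least as well (endogenous look-alike guard).
Partial junctions are deduplicated at 100 bp; independent pairs within one
insert length (default 400 bp, the fragment maximum) of a counted partial
junction are treated as re-observations of it (disable with
`suppress=False` for purely additive counting), and remaining independents
are chained at the same radius.

The estimator treats each properly mapped pair as one sequenced
read-length segment of some nucleus' diploid genome:
`b̂ = x·S/R` with `S = 2·G/ℓ`, and the 95% CI is the Clopper–Pearson
interval for `x` successes in `R` trials scaled by `S`, computed from the
incomplete-beta inverse and reported at full precision (rounding happens
only in reports).

**Known approximation.** The segment-sampling model undercounts the true
per-pair detection zone: a full-length provirus exposes two junctions, and
each junction is detectable by either mate or by the inter-mate gap, so
the zone per event is several hundred bases rather than one read length.
At high per-event depth, deduplication saturates the count (every event is
seen, each counted once) and the estimator's bias is modest and upward; at
very low depth (the regime of a real library made from millions of
nuclei), read-level counting would overestimate in proportion to
`zone/ℓ`. The estimator is kept exactly as specified — its arithmetic on
the published tallies is a fixed reference point — and the synthetic
burden experiment (below) shows that its exact CI still covers the planted
burden at desk scale. The high-throughput path counts screened-out
(provirus-free) pairs as properly mapped without aligning them; they are
drawn as proper pairs by construction and at the default 0.1% error rate
essentially all of them would map.

Ancillary conversions: nuclei in a library = `mass_ng × 1000 / 0.79 pg`
(diploid genome mass); per-organism burden = per-nucleus × 1,000 nuclei.

## 5. Region annotation and bias test

Composition and site classification share one precedence rule: exon over
intron over intergenic, with "exon" meaning annotated exon bases (UTRs are
not modeled; the annotation schema is gene/mRNA/exon only). Sites are
classified by cluster representative, defined as the minimum member
position. The bias test is a single pre-registered comparison — observed
non-coding site count against the genome's non-coding base fraction, exact
binomial, upper tail — so no multiple-testing correction applies.

## 6. Synthetic-data generator

The generator's defaults are the study conditions the rest of the package
is tested under:

| parameter | default | emulates |
|---|---|---|
| region fractions | (0.04, 0.39, 0.57) | exon/intron/intergenic shares of the host assembly |
| amplicon fragments | 150–400 bp | 200–400 bp size selection, with the short-fragment tail that makes mate merging observable |
| read length | 100 | 100-cycle paired-end sequencing |
| WGS coverage | 48× | the study's sequencing depth |
| TSD length | 5 (0–10 allowed) | HIV-1 integrase's ~5-bp staggered cut |
| truncation spectrum | uniform 1–200 bp per terminus | terminus erosion of recombination-style events (sizes unreported; both termini erode) |
| integrase fraction | 1.0 | configurable per experiment |
| decoys / empty inserts | 10% / 5% of signal | filter rejection paths |
| provirus | 2 kb, 634-bp LTRs, authentic terminal 32/37 nt | miniature provirus preserving the junction structure |
| sequencing errors | 0.1% substitutions, flat Q37/Q10 | quality values feed no filter; only mapping quality matters |

Genes are tiled (gap, gene, gap, ...) with ±25% size jitter around means
chosen from the target fractions; each gene starts and ends with an exon.
Realized fractions land within ±2 percentage points of target on
megabase-scale chromosomes.

Proviruses are planted only at *junction-unambiguous* sites: a position
whose flank would extend the LTR terminal dinucleotide (host flank opening
`CA`, or closing `TG` before the insert; ~13% of random positions) is
redrawn, because such junctions are unclassifiable by definition (§1) and
would otherwise leak planted "integrase" truth into the unresolved class.
Events are spaced ≥ 1 kb apart so clusters correspond to events.

The WGS population mode (`simulate_wgs_study`) models `n_nuclei = 16`
genomes, each with its own independently placed integrations, sequenced
jointly to the target coverage. Sixteen nuclei keeps per-nucleus coverage
at 3× — every planted event is sampled by a handful of pairs, sites remain
(almost) private to their nucleus, and the whole experiment stays
desk-sized; a real library's millions of nuclei are out of computational
reach and unnecessary for exercising the estimator.

Not emulated: indel or quality-by-cycle error models, PCR duplicates
beyond identical fragment draws, chimeric library artifacts, repeat-driven
multi-mapping (host genomes are i.i.d. random and essentially
repeat-free). Passing tests therefore demonstrate correctness of the
pipeline's logic and statistics on clean, non-repetitive genomes — not
robustness to the repeat structure or artifact spectrum of real libraries.

## 7. Numerical and degenerate-input choices

* Merge resolution: among overlaps satisfying the 10% mismatch bound, the
  one with the most matching columns wins (longer on ties); disagreeing
  columns take the higher-quality base, quality ties take read 1.
* Alignment ties: results sorted by (score, reference, start, strand);
  co-optimal best scores force mapq 0.
* Clopper–Pearson at x = 0 (or x = n) pins the corresponding bound to 0
  (or 1) exactly.
* Empty inputs: empty FASTA → empty map; no calls → header-only BED and
  all-zero summary tables; an empty category list → x = 0.
* Coordinates are 0-based half-open internally everywhere; 1-based
  fully-closed only at the GFF3 boundary and in printed reports.
* Every stage derives its RNG stream from `SimConfig.seed` plus a fixed
  stage label, so studies are bit-reproducible and stages independent.

## 8. Problem sizes used by the tests and acceptance script

Amplicon recovery runs on 3 Mb annotated genomes with 20 planted events;
the truncation-mix experiment uses 200 events on 2 Mb with a 1–15 bp
erosion spectrum (within the detectable range of the 20-base minimum
anchor, so the planted class mix is observable); the WGS burden experiment
uses a 2 Mb genome, 16 nuclei × 2 integrations, 48× coverage (480,000
pairs), repeated over 20 seeds in the acceptance suite. These sizes were
chosen as the smallest at which each statistical claim is meaningfully
testable.

## 9. Known limitations

* The aligner is ungapped and k-mer seeded: junctions within ~15 bases of
  an indel-bearing or highly degenerate flank would be missed; real
  studies should feed SAM from a gapped aligner for such genomes.
* The burden estimator inherits the segment-sampling approximation
  discussed in §4; its CI is exact for the binomial model, not for the
  detection geometry.
* Cross-end reconciliation (pairing 5'- and 3'-junctions of one event) is
  intentionally not part of any count; per-end reporting matches the
  survey design the package reproduces.
* The GFF reader takes the first mRNA of each gene (the synthetic
  annotation is single-transcript); multi-isoform annotations collapse to
  one transcript's exon set.
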