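# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `hml2ltr`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and alignment

Internally all genomic intervals are 0-based half-open; the 1-based
inclusive browser style (`chr19:37,866,177-37,867,144`) is produced and
parsed only by the converters in `sequence_io`, so the off-by-one shift
exists in exactly one place.

Pairwise alignment is affine-gap global alignment (Needleman–Wunsch /
Gotoh) through Biopython's `PairwiseAligner` with defaults **match +2,
mismatch −1, gap open −4, gap extend −1** — standard nucleotide scoring;
identity statistics should always be reported together with the scoring
used, since no universal parameter set exists for LTR work. Ties between
co-optimal alignments are resolved by taking the aligner's first alignment
in its deterministic enumeration order, so all results are reproducible
run to run. The implementation is validated against an independent Gotoh
dynamic program exhaustively on all sequence pairs up to length 6.

*Gap-stripped identity* is percent matches over columns where neither row
is a gap; `N` aligns freely but never counts as a match (conservative).
The published panel similarity statistics were computed after a multiple
alignment whose settings are unpublished; this package strips gaps
per pair and flags that choice here — per-pair and MSA-wide stripping can
differ by a few tenths of a percent, which is why the similarity
acceptance band is ±0.5.

## Element discovery

The search mirrors the indexing scheme of BLAT: the genome is indexed with
k = 11 k-mers at stride 5 ("all overlapping 11-mers in steps of 5" is
internally contradictory; stride-5 indexing with a stride-1 query scan is
BLAT's actual scheme and maximizes sensitivity at that index density).
K-mers containing N are skipped and k-mers occurring more than 1,000 times
are dropped (repeat filter). Each consensus is scanned at stride 1 in both
orientations; seeds sharing a diagonal band (width = chain gap, default
100 nt) on one contig/strand are chained, and bands with ≥ 8 seeds become
candidates (a ~970-nt consensus yields ~960 query k-mers, so 8 seeds
tolerates heavy divergence while suppressing noise). Candidates are padded
by 50 nt, aligned to the consensus end-gap-free in the window, trimmed to
the outermost aligned consensus positions, and discarded below 60%
identity. Hits from different references with reciprocal overlap > 50% are
collapsed to the highest identity × coverage hit — necessary because the
three consensuses are similar enough that every real locus attracts all
three references.

This is deliberately not a full BLAT reimplementation, and raw genome-wide
hit counts from the original hg38 screens depend on BLAT's exact
heuristics and the assembly; the package's contract is instead exact
recall/precision on planted synthetic genomes, which the acceptance script
measures.

## Screening and classification

Elements are kept when their span is at least 60% of the full-length
consensus of their subtype (the screen is idempotent and order-preserving).
Subtype classification is the argmax of gap-stripped identity against the
subtype consensuses, ties broken by coverage then name order. This is a
deterministic surrogate for the original reference-plus-tree assignment;
on synthetic elements at ≤ 10% divergence it is ≥ 99% accurate (tested).

## Phylogeny

Distances are Kimura 2-parameter,
`d = −½·ln(1−2P−Q) − ¼·ln(1−2Q)`, with P/Q the transition/transversion
proportions over gap-free columns. Saturated pairs (non-positive log
arguments) are set to a ceiling of 5.0 substitutions/site and flagged.
Trees are built with canonical neighbor joining, lowest-Q pair first and
exact ties resolved by label order; negative branch lengths are clamped to
zero and flagged. Bootstrap support is the fraction of column-resampled
replicate NJ trees containing each original bipartition, reported in
[0, 1].

The original subtype analysis used maximum likelihood (K2+G with NNI
search); that is out of scope here by design. The gamma shape parameter
was never published, making K2+G unimplementable faithfully, and the
acceptance surface is clade structure — LTR5Hs cleanly separated, LTR5A
nested within LTR5B — which the K2P + NJ + bootstrap surrogate resolves
deterministically at desk scale. Pairwise distances come from pairwise
alignments (gap columns excluded per pair), not from an MSA.

## TSS-relative frame and motif statistics

Position +1 is the first base of R; U3 occupies −792..0. The four
canonical sections (−792..−553, −552..−264, −263..0, 1..177; inclusive
endpoints as printed) tile −792..177 exactly **only if coordinate 0 exists
and belongs to the upstream section** — that interpretation is adopted
here (sections of 240/289/264/177 nt). Elements are projected into the
frame by global alignment to the frame reference (anchoring fails below
60% identity); a section is usable when ≥ 80% of its frame positions map,
and excluded elements are enumerated in the extraction report rather than
silently dropped.

Motif matching is exact IUPAC-degenerate on the sense strand, all
overlapping matches reported; a PWM scanner is deliberately not used
because the biological contrast of interest is between discrete alleles
(`GGGCTGG` vs `TGGCTGG`), not graded binding scores. An element counts as
motif-positive when its extracted section has ≥ 1 match; percentages are
rounded half-up to two decimals. Frequencies within the −263..0 section
are the headline numbers; whole-LTR counts can be computed by passing a
wider section. Column conservation is `IC = 2 − H` bits per column over
non-gap, non-N observations, without small-sample correction.

## Regulatory domains

The GREAT basal+extension rule: basal = 5,000 bp upstream / 1,000 bp
downstream of the TSS (strand-aware); extension reaches the nearest
neighboring gene's basal boundary, at most 1 Mb beyond the own basal
boundary, clipped to the contig; the extended domain never shrinks below
the basal one (overlapping basal domains simply stop extension on that
side). Elements associate by interval midpoint (whole-interval overlap is
available as an option); element strand is ignored, matching the original
analysis configuration as far as it is stated. GREAT's curated regulatory
domains cannot be reproduced without its internal curation data and are
omitted. Published associated-gene counts depend on the annotation
snapshot GREAT used and are therefore not reproduction targets; the
package's contract is exact agreement with a brute-force implementation of
the stated rule, which is tested.

## Construct design

Chimeras replace the backbone subsequence homologous to a section (located
by frame anchoring) with the donor's homologous subsequence; flanks are
untouched. Every construct records an ordered edit list sufficient to
replay the final sequence byte-for-byte, with length bookkeeping
(`length_delta = Σ len(inserted) − len(removed)`). Site mutations refuse
ambiguous targets: if the mutation string occurs more than once, the
caller must name the occurrence — silent first-match edits are the classic
cloning-design bug. Because the published POU2F1 mutation replaces an
11-nt site with a 30-nt sequence, edits are ordered and coordinates are
re-derived after each edit. Printed genomic spans and printed lengths
disagree slightly for some loci (e.g. a span arithmetic of 968 vs a
printed 967 bp); the package treats supplied sequence as ground truth and
records, rather than resolves, such discrepancies.

## Assay quantification

Normalized fold change = mean(firefly/*Renilla* over the construct's wells
in a stimulus) / mean(firefly/*Renilla* over empty-vector wells **in plain
medium** — the denominator is always the medium condition). Replicates are
aggregated as the arithmetic mean of per-well ratios (the formula brackets
"average [firefly/Renilla]"). 2^−ΔΔCT uses per-sample mean CTs normalized
to the reference gene. The ChIP-qPCR quantification formula is not
published; the default here is ΔΔCT fold enrichment over the
negative-control probe, with percent-input available as an alternative,
since the probe layout implies an NC-normalized design. One-way ANOVA is
the classical fixed-effects F test (delegated to scipy, cross-checked
against explicit sums of squares); no multiple-testing correction is
applied, matching per-comparison reporting. Error bars in this package's
outputs are SEM of biological replicates; the original figures' "standard
errors" are interpreted the same way.

## Synthetic data generator

The generator's defaults are the study conditions, not tuning knobs:

- **Panels**: 43 LTR5A, 62 LTR5B, 194 LTR5Hs elements.
- **Consensus trio**: a synthetic 970-nt LTR5Hs frame (coords −792..177,
  human-like GC 0.41) carrying the wild-type motif alleles at fixed sites
  inside −263..0; LTR5B derived from it at 0.10 substitutions/site and
  LTR5A from LTR5B at 0.055. This reproduces the published divergence
  ordering (LTR5B oldest/most diverged, LTR5A intermediate and derived
  from LTR5B, LTR5Hs youngest and well separated). The real Dfam
  consensuses are not redistributed; every reference sequence is a
  labelled synthetic stand-in.
- **Element divergence**: per-site substitution with a 2:1
  transition:transversion ratio (consistent with the K2 model family),
  rates 0.058 / 0.088 / 0.0175 per subtype — calibrated so mean
  gap-stripped identity to the own consensus matches the published
  94.21% / 91.16% / 98.25% statistics (0.0175 → 98.25% is verified by a
  dedicated test). Indels, when enabled, initiate per site and have
  geometric lengths (p = 0.5, mean 2 nt); motif sites are protected so
  planting truth stays exact.
- **Motif planting**: each canonical site is set to the wild-type allele
  with the published per-subtype probability, else to the published LTR5B
  variant allele — mirroring the biological contrast actually measured
  (LTR5Hs-like vs LTR5B-like alleles) rather than random ablation.
  Planting is independent across motifs. Chance matches elsewhere in the
  sequence are scrubbed (one base toggled, never inside a planted site),
  so the truth table is an exact sufficient statistic for presence.
- **Genomes**: i.i.d. background at GC 0.41 with indel-free planted copies
  (coordinates exact by construction), ≥ 1 kb apart, reverse-complemented
  with probability ½.
- **Plates/CT tables**: per-well F/R = fold × baseline × lognormal(0, σ)
  with *Renilla* lognormal around a constant level; CT values are
  normal(σ_ct) around gene/sample baselines constructed to give exact
  target ΔΔCTs.

What the generator does **not** emulate: real repeat landscapes (no
Alu/LINE decoys), sequencing error, CpG-biased substitution, recombination
between subtypes, and alignment ambiguity from long indels. Passing tests
therefore demonstrate correctness of the algorithms under the stated
generative model, not sensitivity/specificity on real hg38 — raw
genome-wide hit counts, GREAT gene counts and experimental fold changes
are explicitly not reproduction targets.

### Noise floor of the plate estimator

With n = 3 wells per side and lognormal σ = 0.1 per well, the fold
estimator (ratio of two 3-well means) has log-SD ≈ σ·√(2/3) ≈ 0.082, so
roughly a quarter of plates necessarily fall outside ±10% of the true
fold. Recovery contracts are therefore stated in aggregate (median of 500
seeded plates within 5%, mean within 10%, spread matching the noise
model), which the acceptance suite verifies.

## Problem sizes

Defaults used by the tests and the acceptance script: panels at the study
sizes (43/62/194), raw screening panels at 704/828/256, discovery on a
120-kb synthetic contig with 6 planted elements, trees on 30 leaves
(10 per subtype) with 100 bootstrap replicates, and 500 simulated plates —
sizes chosen so the full pipeline re-runs from scratch in seconds to a
minute on a single CPU while keeping every statistical check at its stated
confidence level. The bootstrap convention (support in [0, 1]) follows the
original figures; 1,000 replicates remain the library default for
standalone use.
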