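# hml2ltr

Desk-scale analysis toolkit for the three long terminal repeat (LTR)
subtypes of the human endogenous retrovirus HERV-K (HML-2) clade —
**LTR5A**, **LTR5B** and **LTR5Hs** — aimed at researchers studying how
solo LTRs act as promoters/enhancers in the human genome.

An HML-2 LTR is a U3–R–U5 repeat whose U3 region carries the core
promoter and enhancer elements. The youngest subtype, LTR5Hs, carries a
distinctive set of transcription-factor binding sites in its −263..0
enhancer/core-promoter section (coordinates relative to the transcription
start site, +1 = first base of R): a TATA box (`TATAAA`), an NF-κB site
(`AGGGAAAAACCG`), two p53 half-sites (`GGGCTGG`, `GGGCAGC`) and a POU2F1
site (`TGTATGCATAT`). The package implements the full computational
workflow around that biology:

- **Element discovery** (`hml2ltr.discovery`) — BLAT-style k-mer seeding
  (genome indexed with overlapping 11-mers at stride 5, repeat-heavy
  k-mers dropped), diagonal chaining, and semi-global re-alignment of
  candidates against subtype consensus sequences, on both strands.
- **Screening & classification** (`hml2ltr.screening`) — the
  ≥60%-of-consensus-length filter and highest-identity subtype calls.
- **Phylogeny** (`hml2ltr.phylogeny`) — Kimura 2-parameter distances
  (d = −½ln(1−2P−Q) − ¼ln(1−2Q)), deterministic neighbor joining and
  column-resampling bootstrap supports.
- **Motif profiling** (`hml2ltr.frame`, `hml2ltr.motifs`) — alignment
  anchoring of elements into the TSS-relative frame, extraction of the
  four canonical sections (−792..−553, −552..−264, −263..0, 1..177), exact
  IUPAC consensus scanning, per-subtype frequency/co-occurrence tables and
  WebLogo-style column information content.
- **Regulatory domains** (`hml2ltr.domains`) — GREAT-style basal+extension
  gene association (5 kb up / 1 kb down, up to 1 Mb extension) and
  three-way Venn overlaps.
- **Construct design** (`hml2ltr.constructs`) — in-silico LTR5B→LTR5Hs
  section-replacement chimeras (5Hs1-5B … 5Hs4-5B), site-directed
  binding-site mutants with replayable edit audit trails, and
  reverse-orientation inserts.
- **Assay quantification** (`hml2ltr.assays`) — dual-luciferase normalized
  fold change (mean firefly/*Renilla* ratio over the empty vector in plain
  medium), 2^−ΔΔCT relative expression, ChIP-qPCR enrichment over a
  negative-control probe, one-way ANOVA.
- **Synthetic data** (`hml2ltr.synth`) — generators for every input with
  exact ground truth: diverged consensus trios, motif-planted element
  panels, genomes with planted solo-LTR copies, luciferase plates and CT
  tables. See `docs/methods.md` for the model details.

## Worked example

```python
from hml2ltr import synth, discovery

refs = synth.simulate_subtype_references(seed=0)
genome, truth = synth.simulate_genome(
    refs, {"LTR5A": 2, "LTR5B": 2, "LTR5Hs": 2}, seed=5)
for hit in discovery.discover_elements(genome, refs.refs()):
    print(hit.subtype, hit.interval.to_locus_string(),
          hit.interval.strand, round(hit.identity, 1))
```

prints (one line per recovered planted element; coordinates match the
truth table exactly):

```
LTR5A synthetic_chr1:18,914-19,902 - 93.0
LTR5A synthetic_chr1:22,825-23,813 - 93.5
LTR5B synthetic_chr1:28,657-29,645 + 90.2
LTR5B synthetic_chr1:43,381-44,369 - 90.8
LTR5Hs synthetic_chr1:53,056-54,025 + 98.6
LTR5Hs synthetic_chr1:56,653-57,622 - 96.8
```

Each line is a discovered locus: subtype call, 1-based inclusive
coordinates, strand of the copy, and percent identity to the consensus —
e.g. the LTR5Hs copies sit near 98% identity because LTR5Hs is the
youngest subtype and its copies have accumulated the fewest mutations.

The same pipeline is shell-runnable:

```sh
hml2ltr simulate --seed 3 --per-subtype 1 --out-prefix sim
hml2ltr discover sim.genome.fasta sim.refs.fasta \
    --out-bed hits.bed --out-tsv hits.tsv
hml2ltr quantify --plate plate.tsv --qpcr qpcr.tsv --out folds.json
```

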