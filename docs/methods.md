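# Methods

## Model and assumptions

The method treats alternative splicing as a *local* property of splice
junctions rather than of whole transcripts. Its unit of evidence is a gapped
read alignment; its unit of comparison is a single reference gene model per
locus. This avoids isoform-assembly ambiguity at the cost of never calling
events that only exist as combinations of distant junctions. Assumptions:

* Alignments are trustworthy once filtered (unique, ≤ 8 mismatches, ≥ 8 nt
  overhang on the shorter side of every junction, intron ≥ 25 nt). Gaps
  shorter than 25 nt are treated as alignment artifacts (deletions): the
  read is kept as unspliced evidence but contributes no junction.
* One reference splicing pattern per locus. Multi-isoform GFF3 genes are
  collapsed to the union of their exons; this is the least-assuming single
  model and makes "novel junction" well defined. Consequently an exon
  present in only some isoforms is part of the reference, and its absence is
  an event.
* Both forms must be transcribed: every event needs positive support for
  the alternative *and* the constitutive form. For intron retention this
  means complete per-base coverage of the intron *and* an observed excising
  junction — full coverage alone could be a mis-annotated exon.
* Events are identical across libraries only at exact coordinates
  (gene, type, alternative interval); no fuzzy matching, since junction
  positions are base-exact.

## Event definitions

Against a gene's annotated introns (gaps between union-model exons), a
novel junction is classified by its endpoint pattern, with the precedence
Antisense > ES > Alt‑5′/Alt‑3′ > IRc so each junction yields at most one
event:

* **Antisense** — splice-motif orientation (from the GT‑AG/GC‑AG/AT‑AC
  dinucleotide table and its reverse complements) opposes the gene strand.
  Constitutive support is the maximum annotated-junction support, as
  evidence of sense transcription.
* **ES** — start equals one annotated intron's start and end equals a
  *different* annotated intron's end, with ≥ 1 complete exon strictly
  inside; every flanking annotated intron must be supported. Multi-exon
  skips are allowed.
* **Alt‑5′ / Alt‑3′** — exactly one endpoint shared with a supported
  annotated intron. Whether the shifted endpoint is the donor or acceptor
  follows from the gene strand (intron start is the donor on +, the end on
  −). The shift distance is the displacement of the moved site; a shift
  divisible by 3 preserves the downstream reading frame.
* **IRc** — both endpoints strictly interior to a single annotated exon
  (a spliced-out segment where the annotation has none).
* **IR** — coverage-based and independent of the junction taxonomy: an
  annotated intron with every base at depth ≥ `min_ir_depth` whose excising
  junction is also observed.

A novel junction matching none of these patterns (e.g. both ends internal to
different exons) is counted as unclassified and excluded — the six-type
taxonomy has no bucket for it.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_intron` | 25 nt | smallest gap treated as an intron |
| `max_mismatches` | 8 | per-alignment mismatch cap (NM tag) |
| `min_overhang` | 8 nt | aligned length on the junction's shorter side |
| `require_unique` | true | NH == 1 when present, else MAPQ above the multi-mapping sentinel (3) |
| `min_samples` | 3 | libraries required for a conserved event |
| `min_ir_depth` | 1 | per-base floor for "complete" intron coverage |
| `aer_window` | 0.05 | AER histogram bin width |

The defaults are the method's standard operating point; `min_ir_depth` is
configurable because depth-1 retention calls are noise-prone at low
coverage. The mismatch cap is applied per alignment record (mates are
independent junction evidence; the method is junction-local, so no
fragment-level reconstruction is attempted).

## Quantification and statistics

The Alternative Event Ratio compares read evidence for the two forms, with
a per-type formula (IR: median intronic depth / junction support; ES: skip
support / summed flanking supports; ratio of supports otherwise). For IRc
no canonical formula exists; this package uses the plain ratio with the
constitutive side quantified as the median exonic depth over the spliced-out
interval — a deliberate, configurable design choice. The per-base median
(not a sliding-window median) is used for IR depth. Cross-sample events
carry the median of per-sample AERs (robust to one aberrant library).

The in-frame test is an exact two-sided binomial test (summing all outcomes
with point probability ≤ that of the observation) of the in-frame
proportion against p₀ = 1/3, applied within the AER strata < 0.1 and
[0.1, 1). Sidedness is configurable; two-sided is the default. The
implementation delegates to `scipy.stats.binomtest`, which the test suite
verifies against an independent exact rational-arithmetic summation to
1 × 10⁻¹² for every n ≤ 200.

Ties and degenerate inputs: the median of an even-length depth vector is
the mean of the two central values; empty AER strata return an undefined
test (n = 0, no p-value); zero-variance covariates yield flagged undefined
correlations; a junction contained in two genes goes to the one whose
annotated pattern it matches, then to the tighter locus, and is otherwise
flagged ambiguous and excluded — mirroring the single-gene TU rule, under
which TUs overlapping zero or ≥ 2 genes are dropped. TU–gene overlap means
≥ 1 shared base with the gene body (no flanking slop); TU extents include
intron-spanning reads, so one spliced read cannot belong to two TUs.

## What the simulator emulates — and what it does not

`splicevents.simulate` reproduces the structural features the detector
depends on: 85 bp reads, multi-exon genes on both strands with introns
≥ 25 nt, canonical splice motifs at the plant-genome mixture
94 % GT‑AG / 2.1 % GC‑AG / 0.7 % AT‑AC (remainder non-canonical), UTR and
CDS context, constitutive junctions at full coverage and alternative forms
at a planted fraction (default 0.2) in configurable library subsets.
Alternative read *counts* are planted deterministically
(`round(fraction × coverage)`); only placement within exons is random, and
depth-based expectations (IR, IRc) are computed from the actually planted
layout, so the truth table is exact per sample.

It does **not** model sequencing errors, mapping ambiguity, expression
heterogeneity across genes, fragment-size effects, or annotation errors.
Passing tests therefore demonstrate correctness of the junction arithmetic,
event logic, AER algebra and conservation filtering under clean alignments —
not robustness to noisy real libraries, where the quality filters carry the
load. Problem sizes used by the test suite and the acceptance script
(≈ 100–200 genes, 30× coverage, 3–10 libraries) were chosen as the smallest
studies in which every event type, conservation level and stratum is
populated.

## Known limitations

* Events spanning several junctions jointly (e.g. mutually exclusive exons)
  are out of scope, as is isoform-level quantification (FPKM/TPM).
* The union-exon reference can misclassify a junction that is constitutive
  for a minor isoform as novel.
* Antisense calls need a known motif orientation; junctions with
  non-canonical dinucleotides can never be called antisense.
* With `min_ir_depth = 1`, long introns at high expression are easier to
  call retained than short introns at low expression; compare AERs, not raw
  IR counts, across expression classes.
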