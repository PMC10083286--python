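# Methods

This note documents the models, conventions and numerical choices behind
`repeatspan`, the reasoning for the genuinely open design decisions, and
what the synthetic study design does and does not demonstrate.

## Locus model and coordinates

A locus is `left_flank + tract + right_flank`, where the tract is an
ordered list of motif tokens drawn from a catalog: one core unit (default
GGCCTG) plus variant interruption units (default GGCTG, GGCCCTG, GGCCG,
GGCCTTG — the interruptions reported in expanded SCA36 alleles; note every
one of them is a single insertion or deletion away from the core). All
coordinates are 0-based half-open, including the repeat interval, anchor
hits, and token intervals. Flanks must be at least one anchor long and
must not contain a run of two or more core units, otherwise the repeat
boundary would be ambiguous; `generate_locus` rejects such flanks.

## Synthetic read generator

The generator emulates single-pass CLR reads:

* **Allele draw.** `generate_allele(n_core_target, f, weights, seed)` emits
  `round(n_core_target/(1-f))` i.i.d. tokens: core with probability `1-f`,
  else a variant by weight. The realized core count is binomial around the
  target.
* **Somatic heterogeneity.** `simulate_sample` gives every sequenced
  molecule its own allele, with core count `Normal(mean_core, jitter_sd)`
  truncated below at 20 units. Jitter is an empirical device to reproduce
  the wide per-sample repeat-number spread seen in expansion carriers, not
  a mechanistic claim; technical spread is controlled independently by the
  error rate.
* **Fragments.** Read lengths follow a lognormal (default median 0.75 of
  the locus length, sigma 0.55) truncated to [500 bp, locus length];
  fragment start positions are uniform. Sampling continues until total
  bases reach `coverage x locus length`.
* **Errors.** Per-base i.i.d. with total rate `error_rate` split
  substitution/insertion/deletion = 0.25/0.45/0.30 (indel-dominant, the
  CLR character). Substitutions always change the base; insertions add one
  uniform random base. CLR single-pass error is quoted at 11–15%, so 0.12
  is the default.
* **Truth.** Span class, source allele and true core count are recorded
  from the fragment's placement *before* error injection. For reads the
  simulator reverse complements, the truth class is swapped
  (full-forward ↔ full-reverse, 5' ↔ 3' partial), because span classes are
  defined in read orientation.

Deliberately not modeled: homopolymer-context errors, chimeras, adapters,
quality-value realism (qualities are constant Phred 30 and never
consumed). Passing tests on this generator therefore demonstrate the
pipeline's logic and its behavior under *random* error, not performance on
real CLR data with systematic error structure.

### Truth classes are anchor-aware

Truth uses the same resolution as the classifier contract: an anchor
counts as present when the fragment covers it up to the classifier's edit
allowance `E = ceil(max_edit_fraction x K)`. A fragment whose end falls
`m <= E` bases inside an anchor still produces a legitimate infix hit at
edit distance `m`, so a purely geometric interval-overlap truth would
disagree with *any* finite-anchor classifier on boundary fragments even at
zero error. With the anchor-aware definition, error-free classification
agreement is exactly 100% by construction-independent measurement.

## Span classification

Anchors are the innermost `K = 30` bp of each flank, located by edlib
semi-global (infix) alignment against the read and its reverse complement
with acceptance threshold `ceil(0.25 x K) = 8` edits — loose enough to
tolerate 12–15% read error on a 30-mer, tight enough that a 30-mer
essentially never matches unrelated flank or repeat sequence. Per
(anchor, strand) only the minimum-distance hit is kept, ties broken by
leftmost start. Minus-strand hits are reported in coordinates of the
reverse-complemented read, so the repeat always lies right of a left-anchor
hit; extraction therefore yields tracts in the repeat's 5'→3' orientation
for both strands. Classification prefers the strand explaining more
anchors (then lower total edit distance); contradictory double hits are
logged and classed non-spanning. Partial classes require at least
`min_tract_bp = 1` base of overhang beyond the anchor — any read reaching
into the tract counts.

Reverse-strand full span (`full_dGGCCTGr`) is read as "both anchors found
on the reverse-complemented read"; this interpretation makes
reverse-complementing an input swap the two full classes and the two
partial classes exactly (the involution property the tests enforce).

## Tokenization and repeat counting

The tokenizer is a minimum-cost DP over tract positions. A step consumes
`u ∈ [4, 8]` bases at cost `edit_distance(segment, m)` for the best catalog
motif `m` (cost capped at 2), or one base at cost 1 labeled `other`. Ties
are broken by preferring the core label, then the longer step, then the
lexicographically smaller label; consecutive `other` steps merge into
runs. On exact catalog concatenations the DP returns cost 0 and recovers
the generating tokens whenever the parse is unambiguous; for short tracts
the suite checks the DP cost against an independently implemented
exhaustive-enumeration oracle.

One consequence of cost ties worth knowing: a base adjacent to an
unassigned run can be absorbed into a cost-capped 7–8 bp near-core token
(`GGCCTG + X` is always within edit distance 1 of the core), so the
residual unassigned run may be shorter than the inserted novel segment. De-novo
promotion therefore operates on the residual runs: identical unassigned
segments of length 4–8 recurring ≥3 times in a sample are added to the
catalog and the sample re-tokenized.

The repeat number of a tract is the count of core-labeled tokens
(`count_core_repeats`, DP mode). An `exact` mode (left-greedy
non-overlapping exact matches) exists for comparison but is far more
fragile under error: a single substitution destroys an exact unit, while
the DP keeps it as a cost-1 core token.

### Known bias of token-level counting under indel error

Because every catalog variant is a single-indel derivative of the core, a
single well-placed sequencing indel turns a true core unit into an *exact*
variant copy, which any cost-minimizing tokenizer must label as the
variant (cost 0 beats the core's cost 1). Under the default error mix
(45% insertions, 30% deletions) a few percent of core units per unit of
error rate are converted: measured by the acceptance report, the recovered mean repeat
number sits ~7–8% below truth at 5% error (and further below at the full
12%), while at 0% error recovery is exact per read. The bias is a property
of the counting contract, not of the implementation: distinguishing an
error-converted variant from a real interruption at the single-token level
is impossible without an error model, and an error-model-dependent counter
would no longer be exact on clean data. Sample-level comparisons (between
samples sequenced at the same error rate) are unaffected in ranking terms;
absolute repeat numbers at high error should be read with this bias in
mind. The pathogenic rule (>650) inherits it: near-threshold alleles are
conservatively undercalled at high error.

## Summary statistics and rounding

The per-sample row counts all spanning reads (full + partial, both
strands) as the subread number and as the denominator of the >650
percentage; the numerator likewise includes partial reads, since a partial
read showing >650 core units is direct evidence of a pathogenic allele.
(The printed report convention anchors the denominator to "total
subreads"; whether partial reads enter the numerator is a judgment call —
documented here, adjustable by filtering the per-read table.) Length and
repeat min/mean/max are restricted to full-length tracts, where the whole
allele is observed. Percentages are rounded half-up to 2 decimals
(9/76 → 11.84, 23/162 → 14.20, 20/96 → 20.83); means are printed as
integers (half-up). Forward and reverse full spans are pooled in the
"Full" column, with the reverse count kept in a debug column. A sample
with zero spanning reads yields an all-zero row, ratio 0.00, and a
warning.

## Motif ratios, ranking, rarity

A motif's percentage is `100 x nucleotides under that label / total
nucleotides` in scope; the pooled scope concatenates all full-length
tracts of a sample (default), the per-tract scope keeps each read
separate. Group tables (5/6/7-nt) drop `other` and renormalize within the
group. Rankings sort by percentage descending with lexicographic
tie-breaks; the rarity rule for waterfall blackout is strictly below 1%.
All-scope percentages sum to 100 up to floating-point.

## Figures

Waterfalls draw one fixed-size rectangle per token, row-major at
`row_width = 50` units per row (free parameter; no convention exists),
5' upper-left to 3' lower-right, colored by the catalog map (core blue;
de-novo motifs from a deterministic CRC-keyed palette; rare labels black).
The SVG is assembled by hand and is a pure function of its inputs;
matplotlib figures use a fixed hash salt and no date metadata so they are
reproducible byte-for-byte too.

## Determinism and problem sizes

Every stochastic stage takes an explicit seed derived from the single run
seed; re-running any configuration reproduces byte-identical FASTQ and TSV
outputs. The default study design — three samples with mean core counts
600/790/870 (bracketing the published per-sample means 598/787/868),
jitter SD 150, 2% interruption rate, 200 bp flanks, 60-fold coverage —
keeps a full pipeline run plus test suite in the tens of seconds while
leaving ≥20 full-length reads per sample, enough for stable summary rows.
The published cohort-scale inputs (100-fold whole-genome CLR, genome-scale
alignment to GRCh38/fake-GRCh38) are out of scope; the fake-reference
module reproduces the reference-construction contract, and anchor-based
classification reproduces the read-sorting semantics at desk scale.

## Known limitations

* Token-level repeat counts are downward-biased under heavy indel error
  (quantified above); no correction is applied.
* Flanks are synthetic stand-ins; real-locus use requires supplying the
  genomic flank sequences (or a reference FASTA + repeat BED) and assumes
  they are locally unique.
* No diploid deconvolution: a normal 3–14 unit allele contributes only
  non-spanning or short-tract reads and is not genotyped.
* Partial-read truth core counts count only tokens fully inside the
  fragment/tract overlap, so boundary tokens may be attributed to neither
  side.
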