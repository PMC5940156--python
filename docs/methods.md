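# Methods

This note documents the models, conventions and design choices behind
`aneupore`: what each stage computes, which parameters matter, what the
synthetic-data generator does and does not emulate, and where the genuinely
open design decisions were resolved.

## Overview

The pipeline mirrors the dry-lab analysis of an ultra-low-coverage,
barcode-multiplexed aneuploidy assay on nanopore short reads:

```
reads (FASTQ) → demultiplex → align → uniqueness filter → first-N counting
             → reference-normalized ratios → modified Z-score → karyotype
```

Aneuploidy is inferred purely from per-chromosome counts of uniquely
assigned (UA) reads; base-level content is never interpreted beyond
alignment.

## Demultiplexing

Barcodes are ligated at fragment ends, so matching is restricted to the two
terminal windows of each read, each `ceil(barcode_len × (1 + max_error_rate))`
bases long (29 nt for a 24-nt barcode at rate 0.20). Interior hits are
deliberately ignored.

**Matching semantics.** Within a window the matcher runs a semi-global
edit-distance search in which the barcode may start anywhere in the window
and may additionally be truncated at the read's *outer* boundary (a barcode
hanging off the end of the read). For every window end position it keeps the
minimum-error alignment, with span maximized among cost-optimal alignments.
A candidate qualifies when its matched span on the read is at least
`min_overlap` (default 20) and its error count is at most
`floor(max_error_rate × span)` — errors are unit-cost substitutions,
insertions and deletions, and the error-rate denominator is the matched span
on the read. The best match minimizes `errors/span`, with ties broken toward
more matched bases, then the leftmost position (window-local coordinates,
outer boundary first); across end/strand combinations ties resolve in the
fixed order 5′-forward, 5′-reverse-complement, 3′-forward,
3′-reverse-complement.

Both read ends and both barcode orientations are searched by default:
native barcoding ligates adapters on both sides, and single-strand reads
arrive in either orientation. Each search is flag-controllable.

**Assignment and trimming.** A read goes to the single barcode with the
lowest best error rate; an exact rate tie between different barcodes leaves
the read unassigned (conservative — no sample bleed-through). The winning
barcode's best qualifying match at each end is trimmed away; reads shorter
than `min_length` (default 50) after trimming are set aside as `too_short`.
Every input read lands in exactly one bin.

The production matcher is a numba-compiled batched dynamic program; the test
suite checks it against an independent plain-Python enumerator that tries
every anchored start and every outer truncation explicitly (1,000 random
instances plus constructed edge cases).

Because a candidate with error rate `q` becomes eligible exactly when
`max_error_rate ≥ q`, the assigned count is monotone non-decreasing in
`max_error_rate` and non-increasing in `min_overlap`; both properties are
tested.

## Alignment and counting

Alignment evidence can come from PSL (21-column, header optional), PAF
(≥ 12 columns, residue matches as score) or SAM/BAM (via pysam; POS converted
to the internal 0-based half-open convention; AS tag preferred as score,
falling back to aligned length minus NM). Reads appearing only as unmapped
records count as unaligned, not as errors.

**Toy aligner.** For self-contained operation the package carries a
seed-and-verify aligner: exact 15-mer seeding on both strands (2-bit packed
k-mers in a prefix-bucketed sorted index), clustering of seed hits by genomic
diagonal, and verification of each candidate locus by a gapped edit-distance
alignment (edlib, infix mode) against the local genomic window. The reported
score is `read_len − edit_distance`. An ungapped extension scheme was
rejected during design: at ~10% per-base error with ~5% indels an ungapped
segment breaks every ~20 bp and can never reach half the read length, so a
gapped verifier is the only way a toy aligner can emulate what pblat/minimap2
do on such reads. Candidate clusters need at least 2 supporting seeds
(capped by what a short read can give) — on a random genome an isolated
single-seed hit is almost always spurious, and random DNA sits near 50%
identity, exactly at the default score floor, so unverified single-seed loci
would otherwise inject junk records.

**Uniqueness.** "Aligned to a unique genomic location" is operationalized
as: the best record scores at least `min_score_fraction` (default 0.5) of the
read length, and either no other record exists or the best beats the
runner-up by at least `margin` score units (default 1). Ties are never UA.
This reproduces the intent — discard multi-mappers such as satellite/repeat
reads — with a rule that is testable and configurable.

**First-N stopping.** Counting consumes the arrival-ordered stream of UA
reads and truncates after `N = 9000` (the assay's design depth); if the
stream runs out first the tally is kept, flagged, and a warning logged. The
operation is a pure stream prefix: counting the first M arrivals, where M is
the index of the N-th UA read, gives the identical result. Per-chromosome
counts always sum to the number of UA reads used.

## Karyotype calling

With a normal-male reference (one X, one Y — enforced at configuration
time):

* `ratio_c = (sample_c / sample_total) / (reference_c / reference_total)`
* `z_c = (ratio_c − 1) / sd_normal` for autosomes; `sd_normal` defaults to
  0.0897, an empirical standard deviation of normal autosomal ratios
  (calibrated on 219 observations in the assay this default derives from).
  `recalibrate_sd` recomputes it from user-supplied normal samples but never
  changes the default silently.
* gain iff `z ≥ z_threshold`, loss iff `z ≤ −z_threshold`; the default
  threshold 3.5 is the conventional modified-Z cutoff.

The *closure effect* matters: a trisomy inflates the sample total, so its
expected ratio is `1.5 / (1 + w_c/2)` with `w_c` the chromosome's haploid
weight — below 1.5, but for every human-scale chromosome weight still far
beyond threshold (property-tested across all 22 autosomes of the default
genome, and symmetrically for monosomies).

**Sex chromosomes** are excluded from the Z machinery. chrY is declared
absent below a presence ratio of 0.3 (a normal male's chrY ratio is ~1 with
relative noise ~15% at design depth; a female's is ~0); present chromosomes
round to the nearest copy, with at least one. If neither X nor Y shows any
signal the caller raises — that pattern indicates upstream failure, not a
karyotype. An XO result is rendered `45,XO` (clinical shorthand, not ISCN
`45,X`). Autosomes with zero sample counts against a nonzero reference are
reported as losses but flagged prominently, again as likely upstream
failure.

**Reference.** Any counts table can serve as reference. For simulation
studies the package also provides the deterministic expected normal-male
profile (`expected_counts`) — the idealized limit of a deeply sequenced
normal male. Using it rather than a second same-depth simulated male halves
the ratio variance; at 9,000 reads a same-depth noisy reference would make
the smallest chromosomes' ratio noise (~12%) exceed what `sd_normal = 0.0897`
encodes, which is a statement about reference depth, not about the caller.

## Poisson design

At depth `n` a span covering fraction `f` of the mappable genome receives
`λ = n·f` UA reads in expectation. The two error rates use deliberately
simple boundary conventions, echoed in all JSON output:

* type-I (false gain of factor `F`): `P(X > ceil(F·λ))`, `X ~ Poisson(λ)`.
  At the assay's operating point — λ = 41, the expected chrY count of a
  normal male at 9,000 UA reads — and `F = 1.5`, the boundary is 62 and the
  probability 0.0008. The alternative reading `P(X ≥ 62) ≈ 0.0013` is not
  used; the strict upper tail is this package's documented convention.
* type-II (missing a true change of factor `F`): `P(X' < λ)`, i.e.
  `P(X' ≤ ceil(λ)−1)` with `X' ~ Poisson(F·λ)`; 0.035 (≈ 0.04) at λ = 41,
  `F = 1.3`.

Tails are computed with scipy's regularized incomplete-gamma implementation
and verified in the tests against term-by-term summation to 1e−12.
`min_reads_for_region` inverts the two bounds for a given region span by
exponential bracketing plus bisection; because Poisson boundaries are
integer-valued in λ, feasibility is not perfectly monotone in `n`, so the
result is post-verified (`n` feasible, `n−1` not). The default effective
genome span for depth planning is 3,100 Mb, a uniquely-alignable human-genome
proxy; it is configuration-exposed.

## Synthetic data

The generator emulates the features of real runs that the pipeline is
sensitive to, and nothing more.

* **Genome.** 24 chromosomes (`chr1..chr22, chrX, chrY`) of uniform-random
  sequence, 1.2 Mb total by default. Autosome weights follow a linear ramp,
  5.70% down to 2.86% of the haploid total — human-like ordering with the
  size range compressed, so that at the 9,000-read design depth every
  autosome receives ≳250 reads and per-chromosome multinomial noise stays
  inside the regime the empirical `sd_normal` encodes. chrX takes 5%; chrY
  is solved analytically so a normal male's diploid-weighted chrY share is
  exactly 41/9000, reproducing the assay's empirical anchor (E[chrY] = 41 at
  9,000 UA male reads). Mappable length defaults to sequence length and is
  the weighting used for read sourcing: reads are drawn with probability
  `copy_c × mappable_len_c / Σ(copy × mappable_len)`.
* **Reads.** Fragment lengths are log-normal (median 650, σ = 0.35) clipped
  to [400, 2000] — matching a "majority between 500 and 1000 bp" profile;
  only a range is knowable, so the law is declared, not inferred. Fragments
  are read from either strand. The barcode is prepended at 5′ and (by
  default, as native barcoding does) its reverse complement appended at 3′.
* **Errors.** Total per-base error 0.10 (mean Q ≈ 10), split
  substitution:insertion:deletion = 2:1:1. Quality strings are the constant
  Phred character of the configured rate — the generator does not model
  per-base quality variation, homopolymer-specific errors, chimeras, or
  basecaller artifacts. Passing tests therefore demonstrate correctness of
  the *pipeline logic* under a calibrated error load, not robustness to
  every real nanopore failure mode.
* **Multiplexing.** Samples are interleaved by a seeded random permutation;
  this arrival order is what the first-N rule consumes. Every stage is
  deterministic given its seed; identical config + seed reproduces
  byte-identical FASTQ and reports.
* **Barcodes.** Real native-barcode sequences are proprietary, so barcode
  sets are synthetic by construction: rejection-sampled 24-mers with
  pairwise edit distance ≥ 8 (verified exhaustively at build time). A
  user-supplied barcode FASTA overrides the synthetic set.

The simulated truth table (read id → sample, chromosome, 0-based start,
strand, fragment length) is exhaustive and is the oracle for the zero-noise
round-trip tests: with `per_base_error = 0`, demultiplex → align → count
recovers it exactly.

## Numerical and degenerate-input conventions

* All genomic intervals are 0-based half-open; SAM input is converted on
  read.
* Error-rate comparisons use integer cross-multiplication
  (`e1·w2 < e2·w1`), never float division, wherever ties must be exact.
* Empty reads, reads shorter than the seed length, and empty streams yield
  empty results, not exceptions; structurally invalid inputs (malformed PSL
  lines, missing SAM headers, zero reference counts, infeasible barcode-set
  requests) fail loudly with the offending record named.
* The stopping rule rejects `N ≤ 0`; the caller rejects `sd_normal ≤ 0` and
  non-male references.

## Problem sizes used in the test suite

Study-scale statistical checks run at the assay's design depth: the
karyotype-recovery test simulates 20 five-sample multiplexed runs (100
samples; 9,500 reads each at 10% error, first 9,000 UA counted) and demands
≥ 98/100 correct karyotype strings with zero gain/loss calls on disomic
autosomes. The zero-noise panel runs the five-karyotype sample set once at
the same depth. Unit and property tests use a two-chromosome 100 kb genome
with hundreds of reads, which is sufficient to pin down the deterministic
semantics they target.

## Known limitations

* Polyploidy with preserved proportions (69,XXX vs 46,XX) is undetectable by
  construction; satellite/heteromorphism expansions are excluded by the
  uniqueness filter. Neither is called, matching the method's scope.
* Mosaicism (non-integer copies) and sub-chromosomal CNV segmentation are
  out of scope; `expected_region_reads`/`min_reads_for_region` give
  order-of-magnitude depth guidance only, since they ignore GC/mappability
  bias and multiple testing.
* The toy aligner targets random toy genomes; it has no repeat-resolution
  heuristics beyond best-score-with-margin and is not a substitute for a
  production aligner on real genomes.
* Exact behavioral parity with any specific external demultiplexing tool is
  not claimed; the implemented semantics are the stated thresholds applied
  to semi-global matching, as documented above.
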