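# aneupore

Rapid aneuploidy screening from multiplexed nanopore short reads.

Whole-chromosome aneuploidies (trisomy 21, trisomy 18, monosomy X, ...) can be
detected from ultra-low-coverage whole-genome sequencing: at a few thousand
reads per sample, per-chromosome *read counts* — not base-level variants —
carry the signal. `aneupore` implements the complete dry-lab half of a
barcode-multiplexed nanopore short-read assay of this kind, for people who
want to analyze such runs, re-analyze exported alignments, or study the
statistical behavior of the method on simulated data:

* **demultiplexing** of barcoded reads under edit-distance tolerance
  (≥ 20 bp match to a barcode, error rate ≤ 0.20, reads ≥ 50 bp after
  trimming are kept), searching both read ends and both strands;
* **per-chromosome counting** of uniquely assigned (UA) reads from PSL
  (blat/pblat), PAF (minimap2) or SAM alignments — or from a built-in
  seed-and-verify toy aligner — with a *first-9,000-UA* stopping rule that
  mirrors real-time acquisition;
* **karyotype calling** by reference-normalized modified Z-score;
* **Poisson design calculations** for error rates and read-depth planning;
* a **synthetic-data module** that simulates multiplexed, error-bearing
  nanopore-style reads of known karyotype, so the entire pipeline is testable
  without any external data.

## The statistic at the core

For chromosome *c*, with a known normal male used as reference,

```
ratio_c = (sample_c / sample_total) / (reference_c / reference_total)
z_c     = (ratio_c − 1) / sd_normal,          sd_normal = 0.0897
```

A chromosome is called a **gain** at `z ≥ 3.5` and a **loss** at `z ≤ −3.5`.
A full trisomy pushes `ratio → ~1.5` (slightly less, because the extra
chromosome inflates the sample total — the closure effect), i.e.
`z ≈ 0.5/0.0897 ≈ 5.6`, comfortably beyond the threshold. Sex chromosomes are
converted to copy numbers by rounding their ratios against the single-X,
single-Y reference, and the result is rendered as a karyotype string
(`46,XX`, `45,XO`, `47,XY,+21`, ...).

Whether the counts are deep enough is a Poisson question. At 9,000 UA reads a
normal male yields ~41 chrY reads; with `X ~ Poisson(λ = 41)` the probability
of a normal chromosome's count exceeding the 50%-gain boundary
`ceil(1.5 λ) = 62` is

```
P(X > 62) = 0.0008        (per-chromosome type-I error)
```

and the probability of a true 30% change escaping below the normal
expectation is `P(X' < 41 | X' ~ Poisson(1.3·41)) = 0.04` (type-II). The
same tails drive `min_reads_for_region`, which answers "how many reads do I
need to see a CNV of this size?".

## Worked example

Simulate a two-sample multiplexed run (normal female + trisomy 21) at 10%
per-base read error, demultiplex, align, count the first 9,000 UA reads per
sample, and call:

```
$ aneupore simulate -k "46,XX" -k "47,XY,+21" --n-reads 10000 \
      --error-rate 0.1 --seed 9 --out demo
```

The report shows both karyotypes recovered:

```json
{ "sample_id": "S01", "karyotype": "46,XX",      "expected_karyotype": "46,XX",      "concordant": true,  "n_ua_used": 9000 }
{ "sample_id": "S02", "karyotype": "47,XY,+21",  "expected_karyotype": "47,XY,+21",  "concordant": true,  "n_ua_used": 9000 }
```

and `demo/S02.calls.tsv` holds the per-chromosome evidence. For the trisomic
sample, chr21 carries 387 of the 9,000 UA reads against an expected share of
~277, a ratio of 1.394 (closure keeps it below 1.5) and `z = 4.39` → gain;
chrY receives 45 reads (the ~41 expected for one Y copy):

```
chrom   ua_count  ratio   z      call
chr1    495       0.937   -0.70  normal
...
chr21   387       1.394    4.39  gain
chrX    217       0.937           sex
chrY    45        1.098           sex
```

The design numbers themselves:

```
$ aneupore power --lam 41 --factor 1.5
{"alpha": 0.0008488595852436996, "beta": 0.0022954722380758782,
 "effect_factor": 1.5, "lam": 41.0, "type1_boundary": 62, ...}
```

(`beta` here is the miss probability for a 50% change under the same
conventions; the 30%-change value comes from `--factor 1.3`.)

Each subcommand (`simulate`, `demux`, `count`, `call`, `power`, `run`) is a
thin wrapper over the library; `aneupore run --config run.yaml` drives a full
reproducible run from a YAML config with an explicit seed.

## Limitations

Polyploidies that preserve chromosome proportions (e.g. 69,XXX vs 46,XX) are
invisible to ratio-based counting, as are satellite-DNA/heteromorphism
expansions, whose reads are discarded by the uniqueness filter. Sub-chromosomal
CNV calling and mosaic fractions are out of scope; `docs/methods.md` details
the model, the simulator's fidelity envelope, and all numerical conventions.
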