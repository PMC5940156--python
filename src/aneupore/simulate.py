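"""Synthetic nanopore-style data: toy genomes, barcode sets, multiplexed reads.

This module stands in for the wet half of the assay so the whole dry-lab
pipeline can be exercised without any sequence download.  It emulates the
features of the real runs that matter downstream:

* multiplexed samples of known karyotype, each tagged with a ligated barcode
  (on the 5' end, or both ends as native barcoding does);
* reads of predominantly 500-1000 bp (log-normal, clipped to [400, 2000]);
* ~10% per-base error split 2:1:1 between substitutions, insertions and
  deletions (mean Q ~ 10), with quality strings emitted at the constant
  Phred of the configured rate;
* per-chromosome read counts proportional to copy number x mappable length,
  with the default genome's chrY weight calibrated so a normal male yields
  an expected 41 chrY reads out of 9,000 uniquely assigned ones.

It does not model raw signal, basecaller error profiles, or fragment-size
chemistry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .karyotype import CHROM_ORDER, Karyotype

_BASES = b"ACGT"
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase
_DECODE = np.frombuffer(_BASES, dtype=np.uint8)

#: Expected chrY share of a normal male's uniquely assigned reads (41 of 9,000).
CHRY_MALE_FRACTION = 41 / 9000


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _DECODE[rng.integers(0, 4, size=length)].tobytes().decode()


class SimRead(NamedTuple):
    read_id: str
    sequence: str
    quality: str


@dataclass
class ToyGenome:
    """An ordered set of named chromosome sequences with mappable lengths."""

    chromosomes: dict[str, str]
    mappable_len: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome has no chromosomes")
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name} has an empty sequence")
        if not self.mappable_len:
            self.mappable_len = {n: len(s) for n, s in self.chromosomes.items()}
        for name, m in self.mappable_len.items():
            if name not in self.chromosomes:
                raise ValueError(f"mappable_len names unknown chromosome {name}")
            if not (0 < m <= len(self.chromosomes[name])):
                raise ValueError(
                    f"mappable_len for {name} must be in (0, sequence length]"
                )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.chromosomes)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chromosomes.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    @classmethod
    def from_fasta(cls, path) -> "ToyGenome":
        from Bio import SeqIO

        chroms = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
        return cls(chromosomes=chroms)


def make_toy_genome(spec: dict[str, int], seed: int) -> ToyGenome:
    """Uniform-random genome with the given chromosome lengths, reproducible by seed."""
    for name, length in spec.items():
        if length < 1000:
            raise ValueError(
                f"chromosome {name}: length must be >= 1000, got {length}"
            )
    rng = np.random.default_rng(seed)
    chroms = {name: _random_seq(rng, length) for name, length in spec.items()}
    return ToyGenome(chromosomes=chroms)


def default_genome_spec(
    total_bp: int = 1_200_000, chry_male_fraction: float = CHRY_MALE_FRACTION
) -> dict[str, int]:
    """24-chromosome length table with a calibrated chrY share.

    Autosome weights follow a linear ramp (chr1 largest, chr22 smallest) over
    a compressed, human-like size range; chrX takes 5% of the haploid total;
    chrY is solved so that its share of a normal male's diploid-weighted
    genome equals ``chry_male_fraction`` -- the study-scale anchor of 41
    expected chrY reads among 9,000 uniquely assigned male reads.
    """
    auto = np.linspace(57.0, 28.6, 22)
    x = 50.0
    a = float(auto.sum())
    c = chry_male_fraction
    y = c * (2 * a + x) / (1 - c)
    weights = dict(zip(CHROM_ORDER, [*auto, x, y]))
    total_w = sum(weights.values())
    return {name: int(round(total_bp * w / total_w)) for name, w in weights.items()}


def default_toy_genome(seed: int = 7, total_bp: int = 1_200_000) -> ToyGenome:
    return make_toy_genome(default_genome_spec(total_bp), seed)


def diploid_weights(genome: ToyGenome, karyotype: Karyotype) -> dict[str, float]:
    """Per-chromosome sampling probabilities: copy x mappable length, normalized."""
    w = {
        name: karyotype.copy_of(name) * genome.mappable_len[name]
        for name in genome.names
    }
    total = sum(w.values())
    if total <= 0:
        raise ValueError("karyotype places zero copies on every genome chromosome")
    return {name: v / total for name, v in w.items()}


def expected_counts(
    genome: ToyGenome, karyotype: Karyotype, n_reads: int
) -> dict[str, float]:
    """Expected per-chromosome UA counts for ``n_reads`` draws (analytic profile)."""
    return {c: n_reads * p for c, p in diploid_weights(genome, karyotype).items()}


@dataclass
class BarcodeSet:
    """Ordered, uniquely named barcode sequences of equal length."""

    entries: list[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("barcode ids must be unique")
        lengths = {len(s) for _, s in self.entries}
        if len(lengths) > 1:
            raise ValueError("all barcodes must have the same length")

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, key: str) -> str:
        return dict(self.entries)[key]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(i for i, _ in self.entries)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for bc_id, seq in self.entries:
                fh.write(f">{bc_id}\n{seq}\n")

    @classmethod
    def from_fasta(cls, path) -> "BarcodeSet":
        from Bio import SeqIO

        return cls(
            entries=[(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
        )


def make_barcode_set(
    n: int, length: int = 24, min_dist: int = 8, seed: int = 0
) -> BarcodeSet:
    """Rejection-sample ``n`` barcodes with pairwise edit distance >= ``min_dist``.

    Every accepted candidate is checked exhaustively (edlib global distance)
    against all previously accepted barcodes.
    """
    import edlib

    if n < 1:
        raise ValueError(f"need at least one barcode, got n={n}")
    if min_dist > length:
        raise ValueError("min_dist cannot exceed barcode length")
    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    tries = 0
    max_tries = 500 * n
    while len(accepted) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not build {n} barcodes of length {length} with "
                f"min pairwise edit distance {min_dist} in {max_tries} tries"
            )
        cand = _random_seq(rng, length)
        if all(
            edlib.align(cand, prev, mode="NW")["editDistance"] >= min_dist
            for prev in accepted
        ):
            accepted.append(cand)
    return BarcodeSet(
        entries=[(f"BC{i + 1:02d}", seq) for i, seq in enumerate(accepted)]
    )


@dataclass
class ReadSimConfig:
    """Read-generation law for one sample.

    Lengths are log-normal with the given median and sigma, clipped to
    ``[length_min, length_max]``; the per-base error budget is split by
    ``error_weights`` into substitution:insertion:deletion.
    """

    n_reads: int = 10_000
    length_min: int = 400
    length_median: int = 650
    length_max: int = 2000
    length_sigma: float = 0.35
    per_base_error: float = 0.10
    error_weights: tuple[float, float, float] = (2.0, 1.0, 1.0)
    barcode_placement: str = "both_ends"  # or "five_prime_only"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if not (0 <= self.per_base_error < 0.5):
            raise ValueError("per_base_error must be in [0, 0.5)")
        if self.barcode_placement not in ("both_ends", "five_prime_only"):
            raise ValueError(
                f"unknown barcode_placement {self.barcode_placement!r}"
            )
        if not (self.length_min <= self.length_median <= self.length_max):
            raise ValueError("length law requires min <= median <= max")

    @property
    def quality_char(self) -> str:
        if self.per_base_error <= 0:
            q = 40
        else:
            q = min(40, int(round(-10 * math.log10(self.per_base_error))))
        return chr(33 + q)


def _apply_errors(
    seq: str, rate: float, weights: tuple[float, float, float], rng: np.random.Generator
) -> str:
    """Apply substitution/insertion/deletion noise at the given total rate."""
    if rate <= 0:
        return seq
    arr = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int64)
    n = arr.size
    wsum = sum(weights)
    p_sub = rate * weights[0] / wsum
    p_ins = rate * weights[1] / wsum
    p_del = rate * weights[2] / wsum
    u = rng.random(n)
    sub = u < p_sub
    dele = (u >= p_sub) & (u < p_sub + p_del)
    ins = (u >= p_sub + p_del) & (u < p_sub + p_del + p_ins)
    n_sub = int(sub.sum())
    if n_sub:
        arr[sub] = (arr[sub] + rng.integers(1, 4, size=n_sub)) % 4
    n_ins = int(ins.sum())
    kept_pos = np.nonzero(~dele)[0]
    ins_pos = np.nonzero(ins)[0]
    ins_bases = rng.integers(0, 4, size=n_ins)
    # riffle: an inserted base lands immediately before its anchor position
    keys = np.concatenate([2 * kept_pos + 1, 2 * ins_pos])
    vals = np.concatenate([arr[kept_pos], ins_bases])
    order = np.argsort(keys, kind="stable")
    return _DECODE[vals[order].astype(np.uint8)].tobytes().decode()


def simulate_sample(
    genome: ToyGenome,
    karyotype: Karyotype,
    barcode: tuple[str, str] | None,
    cfg: ReadSimConfig,
    sample_id: str = "sample",
) -> tuple[list[SimRead], pd.DataFrame]:
    """Simulate one barcoded sample; returns reads plus an exhaustive truth table.

    The truth table records, per read id, the source chromosome, the 0-based
    fragment start on that chromosome, and the strand the fragment was read
    from.  Unknown chromosomes in the karyotype (positive copies on a name
    the genome lacks) are rejected.
    """
    for chrom, copies in karyotype.autosome_copies.items():
        if copies > 0 and chrom not in genome.chromosomes:
            raise ValueError(f"karyotype references unknown chromosome {chrom}")
    probs = diploid_weights(genome, karyotype)
    names = list(probs)
    rng = np.random.default_rng(cfg.seed)
    chrom_idx = rng.choice(len(names), size=cfg.n_reads, p=[probs[n] for n in names])
    raw_len = rng.lognormal(math.log(cfg.length_median), cfg.length_sigma, cfg.n_reads)
    frag_len = np.clip(raw_len, cfg.length_min, cfg.length_max).astype(np.int64)
    strands = np.where(rng.random(cfg.n_reads) < 0.5, "+", "-")

    bc_seq = barcode[1] if barcode is not None else ""
    bc_rc = revcomp(bc_seq)
    reads: list[SimRead] = []
    rows = []
    qchar = cfg.quality_char
    for i in range(cfg.n_reads):
        chrom = names[chrom_idx[i]]
        seq = genome.chromosomes[chrom]
        flen = min(int(frag_len[i]), len(seq))
        start = int(rng.integers(0, len(seq) - flen + 1))
        frag = seq[start : start + flen]
        if strands[i] == "-":
            frag = revcomp(frag)
        molecule = bc_seq + frag
        if barcode is not None and cfg.barcode_placement == "both_ends":
            molecule += bc_rc
        read_seq = _apply_errors(molecule, cfg.per_base_error, cfg.error_weights, rng)
        read_id = f"{sample_id}-{i:06d}"
        reads.append(SimRead(read_id, read_seq, qchar * len(read_seq)))
        rows.append((read_id, sample_id, chrom, start, strands[i], flen))
    truth = pd.DataFrame(
        rows,
        columns=["read_id", "sample_id", "chromosome", "start", "strand", "length"],
    )
    return reads, truth


def multiplex(samples: Sequence[Sequence[SimRead]], seed: int = 0) -> list[SimRead]:
    """Deterministically interleave several samples' reads into one arrival order."""
    if not samples:
        raise ValueError("multiplex needs at least one sample")
    pooled = [read for sample in samples for read in sample]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pooled))
    return [pooled[i] for i in order]


def write_fastq(reads: Iterable[SimRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path) -> list[SimRead]:
    from Bio import SeqIO

    out = []
    parser = SeqIO.parse(str(path), "fastq")
    while True:
        try:
            rec = next(parser)
        except StopIteration:
            break
        except ValueError as err:
            raise ValueError(
                f"malformed FASTQ record at index {len(out)} in {path}: {err}"
            ) from err
        qual = "".join(
            chr(33 + q) for q in rec.letter_annotations["phred_quality"]
        )
        out.append(SimRead(rec.id, str(rec.seq).upper(), qual))
    return out
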