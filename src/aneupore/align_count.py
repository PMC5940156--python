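"""Alignment evidence -> per-chromosome unique-assignment counts.

The pipeline consumes alignment records from the standard short-read formats
(21-column PSL, PAF, SAM) or produces them with a built-in toy aligner, then

* keeps only *uniquely assigned* (UA) reads -- best score at least
  ``min_score_fraction`` of the read length and ahead of the runner-up by at
  least ``margin`` score units (multi-mappers, e.g. repeat-derived reads, are
  discarded);
* accumulates per-chromosome counts over the arrival-ordered stream, stopping
  after the first ``N`` UA reads (N = 9,000 at the assay's design depth).

All coordinates are 0-based half-open internally; SAM's 1-based POS is
converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .simulate import _ENCODE, SimRead, ToyGenome

logger = logging.getLogger(__name__)

DEFAULT_N_UA = 9000


class AlignmentRecord(NamedTuple):
    read_id: str
    chrom: str
    start: int  # 0-based half-open target interval
    end: int
    strand: str
    score: int  # matched-base count (aligner-dependent proxy)
    read_len: int


@dataclass(frozen=True)
class UAFilterConfig:
    min_score_fraction: float = 0.5
    margin: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.min_score_fraction <= 1):
            raise ValueError("min_score_fraction must be in (0, 1]")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")


@dataclass
class ChromCounts:
    """Per-chromosome UA tallies for one sample."""

    sample_id: str
    counts: dict[str, float]
    n_ua_used: int
    truncated_at_n: bool = False

    @property
    def total(self) -> float:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.sample_id, c, n) for c, n in self.counts.items()],
            columns=["sample_id", "chrom", "ua_count"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ChromCounts":
        df = pd.read_csv(path, sep="\t")
        sample_ids = df["sample_id"].unique()
        if len(sample_ids) != 1:
            raise ValueError(f"expected one sample in {path}, got {list(sample_ids)}")
        counts = dict(zip(df["chrom"], df["ua_count"]))
        total = sum(counts.values())
        n = int(round(total))
        return cls(sample_id=str(sample_ids[0]), counts=counts, n_ua_used=n)


# ---------------------------------------------------------------------------
# format readers / writers


def _parse_int(text: str, what: str, line_no: int, path) -> int:
    try:
        value = int(text)
    except ValueError as err:
        raise ValueError(f"{path} line {line_no}: bad {what} {text!r}") from err
    if value < 0:
        raise ValueError(f"{path} line {line_no}: negative {what} {value}")
    return value


def read_psl(path) -> Iterator[AlignmentRecord]:
    """Parse 21-column PSL (blat/pblat), with or without the 5-line header."""
    with open(path) as fh:
        lines = fh.readlines()
    start_idx = 0
    if lines and lines[0].startswith("psLayout"):
        for i, line in enumerate(lines[:10]):
            if set(line.strip()) <= {"-"} and line.strip():
                start_idx = i + 1
                break
        else:
            raise ValueError(f"{path}: psLayout header without separator line")
    for line_no, line in enumerate(lines[start_idx:], start=start_idx + 1):
        if not line.strip():
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) != 21:
            raise ValueError(
                f"{path} line {line_no}: expected 21 PSL columns, got {len(cols)}"
            )
        matches = _parse_int(cols[0], "matches", line_no, path)
        strand = cols[8]
        q_name = cols[9]
        q_size = _parse_int(cols[10], "qSize", line_no, path)
        t_name = cols[13]
        t_start = _parse_int(cols[15], "tStart", line_no, path)
        t_end = _parse_int(cols[16], "tEnd", line_no, path)
        if t_end <= t_start:
            raise ValueError(f"{path} line {line_no}: tEnd <= tStart")
        yield AlignmentRecord(
            q_name, t_name, t_start, t_end, strand[:1] or "+", matches, q_size
        )


def write_psl(records: Iterable[AlignmentRecord], path, chrom_sizes=None) -> None:
    chrom_sizes = chrom_sizes or {}
    with open(path, "w") as fh:
        for r in records:
            t_size = chrom_sizes.get(r.chrom, r.end)
            block = r.end - r.start
            cols = [
                r.score, 0, 0, 0, 0, 0, 0, 0, r.strand, r.read_id, r.read_len,
                0, r.read_len, r.chrom, t_size, r.start, r.end,
                1, f"{block},", "0,", f"{r.start},",
            ]
            fh.write("\t".join(str(c) for c in cols) + "\n")


def read_paf(path) -> Iterator[AlignmentRecord]:
    """Parse PAF (minimap2): >= 12 tab-separated columns, residue matches in col 10."""
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 12:
                raise ValueError(
                    f"{path} line {line_no}: expected >= 12 PAF columns, got {len(cols)}"
                )
            q_name = cols[0]
            q_len = _parse_int(cols[1], "qlen", line_no, path)
            strand = cols[4]
            t_name = cols[5]
            t_start = _parse_int(cols[7], "tstart", line_no, path)
            t_end = _parse_int(cols[8], "tend", line_no, path)
            n_match = _parse_int(cols[9], "residue matches", line_no, path)
            if t_end <= t_start:
                raise ValueError(f"{path} line {line_no}: tend <= tstart")
            yield AlignmentRecord(q_name, t_name, t_start, t_end, strand, n_match, q_len)


def write_paf(records: Iterable[AlignmentRecord], path, chrom_sizes=None) -> None:
    chrom_sizes = chrom_sizes or {}
    with open(path, "w") as fh:
        for r in records:
            t_size = chrom_sizes.get(r.chrom, r.end)
            block = r.end - r.start
            cols = [
                r.read_id, r.read_len, 0, r.read_len, r.strand,
                r.chrom, t_size, r.start, r.end, r.score, block, 60,
            ]
            fh.write("\t".join(str(c) for c in cols) + "\n")


def read_sam(path) -> Iterator[AlignmentRecord]:
    """Parse SAM/BAM via pysam; mapped records only (secondaries included).

    Reads that appear only as unmapped records yield nothing and are later
    treated as unaligned, not as errors.  POS is converted to 0-based
    half-open.  The matched-base score is taken from the AS tag when present,
    else approximated as aligned query length minus NM.
    """
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as fh:
        if not fh.header.get("SQ"):
            raise ValueError(f"{path}: SAM header with SQ lines required")
        for rec in fh:
            if rec.is_unmapped:
                continue
            if rec.has_tag("AS"):
                score = int(rec.get_tag("AS"))
            elif rec.has_tag("NM"):
                score = rec.query_alignment_length - int(rec.get_tag("NM"))
            else:
                score = rec.query_alignment_length
            read_len = rec.infer_read_length() or rec.query_length
            yield AlignmentRecord(
                rec.query_name,
                rec.reference_name,
                rec.reference_start,
                rec.reference_end,
                "-" if rec.is_reverse else "+",
                score,
                read_len,
            )


def write_sam(records: Sequence[AlignmentRecord], path, chrom_sizes=None) -> None:
    import pysam

    records = list(records)
    if chrom_sizes is None:
        chrom_sizes = {}
        for r in records:
            chrom_sizes[r.chrom] = max(chrom_sizes.get(r.chrom, 0), r.end)
    names = list(chrom_sizes)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": int(chrom_sizes[n])} for n in names],
    }
    seen: set[str] = set()
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for r in records:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = r.read_id
            a.flag = (16 if r.strand == "-" else 0) | (
                256 if r.read_id in seen else 0
            )
            seen.add(r.read_id)
            a.reference_id = names.index(r.chrom)
            a.reference_start = r.start
            a.mapping_quality = 60
            block = r.end - r.start
            soft = r.read_len - block
            cigar = [(0, block)]
            if soft > 0:
                cigar.append((4, soft))
            a.cigartuples = cigar
            a.set_tag("AS", int(r.score))
            fh.write(a)


# ---------------------------------------------------------------------------
# toy aligner


class GenomeIndex:
    """Exact k-mer index over a toy genome, both strands resolved at query time.

    k-mers are packed into 2-bit integer codes and stored sorted, with a
    prefix-bucket table over the top bits so a lookup touches only a handful
    of adjacent entries (the index is queried millions of times per run).
    """

    _PREFIX_BASES = 8

    def __init__(self, genome: ToyGenome, k: int = 15):
        if k < self._PREFIX_BASES or k > 15:
            raise ValueError(f"k must be in [{self._PREFIX_BASES}, 15]")
        self.genome = genome
        self.k = k
        self.names = list(genome.names)
        self.offsets = np.zeros(len(self.names) + 1, dtype=np.int64)
        codes_parts = []
        pos_parts = []
        weights = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
        offset = 0
        for i, name in enumerate(self.names):
            seq = genome.chromosomes[name]
            enc = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int64)
            self.offsets[i] = offset
            if len(seq) >= k:
                win = np.lib.stride_tricks.sliding_window_view(enc, k)
                codes = win @ weights
                codes_parts.append(codes)
                pos_parts.append(np.arange(len(codes), dtype=np.int64) + offset)
            offset += len(seq)
        self.offsets[-1] = offset
        all_codes = np.concatenate(codes_parts)
        all_pos = np.concatenate(pos_parts)
        order = np.argsort(all_codes, kind="stable")
        self.sorted_codes = all_codes[order].astype(np.int32)  # 4^15 = 2^30
        self.sorted_pos = all_pos[order].astype(np.int32)
        self._prefix_shift = 2 * (k - self._PREFIX_BASES)
        boundaries = np.arange(4**self._PREFIX_BASES + 1, dtype=np.int64)
        self.bucket_starts = np.searchsorted(
            self.sorted_codes, (boundaries << self._prefix_shift).astype(np.int64)
        ).astype(np.int64)
        self._weights = weights

    def seed_clusters(self, enc_read: np.ndarray, stride: int, band: int) -> np.ndarray:
        """Candidate loci from exact seed hits, clustered by genomic diagonal.

        Returns an array of (representative global diagonal, votes) rows
        sorted by descending votes.
        """
        if enc_read.size < self.k:
            return np.empty((0, 2), dtype=np.int64)
        return _seed_cluster_kernel(
            enc_read.astype(np.int64),
            self.k,
            stride,
            band,
            self.sorted_codes,
            self.sorted_pos,
            self.bucket_starts,
            self._prefix_shift,
        )

    def locate(self, gpos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self.offsets, gpos, side="right")) - 1
        return self.names[i], gpos - int(self.offsets[i])


@njit(cache=False)
def _seed_cluster_kernel(
    enc, k, stride, band, sorted_codes, sorted_pos, bucket_starts, prefix_shift
):  # pragma: no cover
    n_seed_pos = enc.shape[0] - k + 1
    # rolling 2-bit k-mer codes at stride positions
    n_hits = 0
    max_hits = 4 * (n_seed_pos // stride + 1) + 64
    diags = np.empty(max_hits, dtype=np.int64)
    for q_off in range(0, n_seed_pos, stride):
        code = np.int64(0)
        for t in range(k):
            code = code * 4 + enc[q_off + t]
        code32 = np.int32(code)
        bucket = code >> prefix_shift
        lo = bucket_starts[bucket]
        hi_b = bucket_starts[bucket + 1]
        # binary search inside the (small) prefix bucket
        a, b = lo, hi_b
        while a < b:
            mid = (a + b) // 2
            if sorted_codes[mid] < code32:
                a = mid + 1
            else:
                b = mid
        lo = a
        b = hi_b
        while a < b:
            mid = (a + b) // 2
            if sorted_codes[mid] <= code32:
                a = mid + 1
            else:
                b = mid
        hi = a
        for h in range(lo, hi):
            if n_hits >= max_hits:
                break
            diags[n_hits] = sorted_pos[h] - q_off
            n_hits += 1
    if n_hits == 0:
        return np.empty((0, 2), dtype=np.int64)
    ds = np.sort(diags[:n_hits])
    n_clusters = 1
    for i in range(1, n_hits):
        if ds[i] - ds[i - 1] > band:
            n_clusters += 1
    out = np.empty((n_clusters, 2), dtype=np.int64)
    c = 0
    start = 0
    for i in range(1, n_hits + 1):
        if i == n_hits or ds[i] - ds[i - 1] > band:
            out[c, 0] = ds[(start + i - 1) // 2]  # median-ish representative
            out[c, 1] = i - start
            c += 1
            start = i
    # sort clusters by descending votes (tiny arrays; selection sort is fine)
    for i in range(n_clusters):
        best = i
        for j in range(i + 1, n_clusters):
            if out[j, 1] > out[best, 1]:
                best = j
        if best != i:
            tmp0, tmp1 = out[i, 0], out[i, 1]
            out[i, 0], out[i, 1] = out[best, 0], out[best, 1]
            out[best, 0], out[best, 1] = tmp0, tmp1
    return out


def toy_align(
    read: SimRead | str,
    index: GenomeIndex | ToyGenome,
    min_score_fraction: float = 0.5,
    stride: int = 5,
    max_candidates: int = 8,
    min_votes: int = 2,
    read_id: str = "read",
) -> list[AlignmentRecord]:
    """Seed-and-verify alignment of one read against the toy genome.

    Exact k-mer seeds on both strands propose candidate loci (clustered by
    genomic diagonal, requiring ``min_votes`` supporting seeds -- isolated
    single-seed hits on a random genome are almost always spurious); each
    candidate is verified by a gapped edit-distance alignment (edlib, infix
    mode) of the read against the local genomic window.  The reported score
    is ``read_len - edit_distance``; all distinct loci scoring at least
    ``min_score_fraction * read_len`` are returned.
    """
    import edlib

    if isinstance(index, ToyGenome):
        index = GenomeIndex(index)
    if isinstance(read, SimRead):
        read_id, seq = read.read_id, read.sequence
    else:
        seq = read
    rlen = len(seq)
    if rlen < index.k:
        return []
    from .simulate import revcomp

    results: list[AlignmentRecord] = []
    band = max(40, rlen // 10)
    # short reads carry few seeds; never demand more votes than they can give
    min_votes = min(min_votes, max(1, (rlen - index.k) // stride))
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        enc = _ENCODE[np.frombuffer(oriented.encode(), dtype=np.uint8)]
        clusters = index.seed_clusters(enc, stride, band)
        for c in range(min(clusters.shape[0], max_candidates)):
            if clusters[c, 1] < min_votes:
                continue
            diag = int(clusters[c, 0])
            chrom, local = index.locate(max(diag, 0))
            chrom_seq = index.genome.chromosomes[chrom]
            w_start = max(0, local - band)
            w_end = min(len(chrom_seq), local + rlen + band)
            window = chrom_seq[w_start:w_end]
            if len(window) < index.k:
                continue
            # bounded distance check first; locations only for accepted loci.
            # Most true loci sit well under the score threshold's distance
            # budget, so probe with a tight bound before the full one.
            max_dist = rlen - int(np.ceil(min_score_fraction * rlen))
            tight = min(max_dist, int(0.3 * rlen) + 8)
            probe = edlib.align(oriented, window, mode="HW", task="distance",
                                k=tight)
            dist = probe["editDistance"]
            if dist < 0 and tight < max_dist:
                probe = edlib.align(oriented, window, mode="HW",
                                    task="distance", k=max_dist)
                dist = probe["editDistance"]
            if dist < 0:
                continue
            score = rlen - dist
            if score < min_score_fraction * rlen:
                continue
            aln = edlib.align(oriented, window, mode="HW", task="locations",
                              k=dist)
            loc = aln["locations"][0]
            start = w_start + loc[0]
            end = w_start + loc[1] + 1
            # overlapping loci are one locus: keep the best-scoring version
            replaced = False
            dominated = False
            for p, prev in enumerate(results):
                if prev.chrom == chrom and min(prev.end, end) - max(
                    prev.start, start
                ) > 0:
                    if score > prev.score:
                        results[p] = AlignmentRecord(
                            read_id, chrom, start, end, strand, score, rlen
                        )
                        replaced = True
                    else:
                        dominated = True
                    break
            if not replaced and not dominated:
                results.append(
                    AlignmentRecord(read_id, chrom, start, end, strand, score, rlen)
                )
    results.sort(key=lambda r: -r.score)
    return results


def align_reads(
    reads: Iterable[SimRead],
    index: GenomeIndex | ToyGenome,
    min_score_fraction: float = 0.5,
    stride: int = 5,
) -> Iterator[tuple[str, list[AlignmentRecord]]]:
    """toy_align over a stream, yielding (read_id, records) in arrival order."""
    if isinstance(index, ToyGenome):
        index = GenomeIndex(index)
    for read in reads:
        yield read.read_id, toy_align(
            read, index, min_score_fraction=min_score_fraction, stride=stride
        )


# ---------------------------------------------------------------------------
# uniqueness filter and first-N accumulation


def group_by_read(
    records: Iterable[AlignmentRecord],
) -> dict[str, list[AlignmentRecord]]:
    """Group alignment records per read, preserving first-appearance order."""
    grouped: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        grouped.setdefault(rec.read_id, []).append(rec)
    return grouped


def is_unique(records: Sequence[AlignmentRecord], cfg: UAFilterConfig) -> str | None:
    """Chromosome of the unique assignment, or None if the read is not UA."""
    if not records:
        return None
    ranked = sorted(records, key=lambda r: -r.score)
    best = ranked[0]
    if best.score < cfg.min_score_fraction * best.read_len:
        return None
    if len(ranked) > 1 and best.score - ranked[1].score < cfg.margin:
        return None
    return best.chrom


def unique_assignments(
    grouped: Mapping[str, Sequence[AlignmentRecord]],
    cfg: UAFilterConfig | None = None,
) -> dict[str, str]:
    """read_id -> chromosome for uniquely assigned reads only."""
    cfg = cfg or UAFilterConfig()
    out: dict[str, str] = {}
    for read_id, records in grouped.items():
        chrom = is_unique(records, cfg)
        if chrom is not None:
            out[read_id] = chrom
    return out


def first_n_ua(
    assignments: Iterable[tuple[str, str]],
    n: int = DEFAULT_N_UA,
    sample_id: str = "sample",
    chrom_order: Sequence[str] | None = None,
) -> ChromCounts:
    """Accumulate per-chromosome counts over the first ``n`` UA reads.

    ``assignments`` is the arrival-ordered stream of (read_id, chromosome)
    for UA reads.  Counting truncates once ``n`` UA reads are consumed; if
    the stream runs out first, all of it is used and a warning is logged.
    """
    if n <= 0:
        raise ValueError(f"N must be positive, got {n}")
    counts: dict[str, float] = {c: 0 for c in (chrom_order or [])}
    used = 0
    truncated = False
    for _read_id, chrom in assignments:
        counts[chrom] = counts.get(chrom, 0) + 1
        used += 1
        if used >= n:
            truncated = True
            break
    if not truncated:
        logger.warning(
            "sample %s: stream exhausted at %d UA reads (< N=%d)", sample_id, used, n
        )
    return ChromCounts(
        sample_id=sample_id, counts=counts, n_ua_used=used, truncated_at_n=truncated
    )
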