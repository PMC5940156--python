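"""Barcode demultiplexing under edit-distance tolerance.

A read is matched against each barcode inside its two terminal windows (a
window is ``ceil(barcode_len * (1 + max_error_rate))`` bases; barcodes are
ligated at fragment ends, so interior hits are ignored).  Matching is a
semi-global edit-distance search in which the barcode may sit anywhere in the
window and may additionally be truncated at the read's *outer* boundary (a
barcode hanging off the end of the read).  For every end position the search
keeps the minimum-error alignment (span maximized among cost-optimal paths);
a candidate qualifies when

* its matched span on the read is at least ``min_overlap`` bases, and
* its error count is at most ``floor(max_error_rate * span)``,

errors being unit-cost substitutions, insertions and deletions.  The best
match minimizes the error rate ``errors / span``, ties broken by more matched
bases, then by leftmost position on the read.  A read is assigned to the
single barcode with the lowest error rate; an exact rate tie between two
barcodes leaves the read unassigned (conservative: no sample bleed-through).
Assigned reads are trimmed through the matched terminal segments and kept
only if the trimmed sequence is at least ``min_length`` bases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .simulate import _ENCODE, BarcodeSet, SimRead, revcomp

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"
FORWARD = "forward"
REVCOMP = "reverse_complement"

ASSIGNED = "assigned"
UNASSIGNED = "unassigned"
TOO_SHORT = "too_short"


@dataclass(frozen=True)
class DemuxConfig:
    min_overlap: int = 20
    max_error_rate: float = 0.20
    min_length: int = 50
    search_both_ends: bool = True
    search_reverse_complement: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.max_error_rate < 1):
            raise ValueError("max_error_rate must be in (0, 1)")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")

    def window_len(self, barcode_len: int) -> int:
        return math.ceil(barcode_len * (1 + self.max_error_rate))


@dataclass(frozen=True)
class BarcodeMatch:
    barcode_id: str
    end: str  # five_prime | three_prime
    strand: str  # forward | reverse_complement
    start: int  # 0-based half-open span on the read
    stop: int
    errors: int

    @property
    def span(self) -> int:
        return self.stop - self.start

    @property
    def error_rate(self) -> float:
        return self.errors / self.span


@dataclass
class DemuxResult:
    read_id: str
    status: str  # assigned | unassigned | too_short
    barcode_id: str | None = None
    trimmed_sequence: str = ""
    trimmed_quality: str = ""


@njit(cache=False)
def _match_kernel(windows, wlens, queries, min_overlap, max_rate):  # pragma: no cover
    """Best qualifying (errors, start, end) per (window, query), or -1s.

    DP over query rows x window columns with two free entry families:
    row 0 free at every column (barcode starts anywhere in the window) and
    column 0 free at every row (barcode truncated at the outer boundary).
    Per end column the minimal-error, then maximal-span alignment is kept;
    the best candidate minimizes errors/span, ties to larger span, then
    smaller start.
    """
    n_win = windows.shape[0]
    n_q = queries.shape[0]
    m = queries.shape[1]
    out = np.full((n_win, n_q, 3), -1, dtype=np.int64)
    width = windows.shape[1] + 1
    d_prev = np.empty(width, dtype=np.int64)
    d_cur = np.empty(width, dtype=np.int64)
    s_prev = np.empty(width, dtype=np.int64)
    s_cur = np.empty(width, dtype=np.int64)
    for w_i in range(n_win):
        length = wlens[w_i]
        for q_i in range(n_q):
            for j in range(length + 1):
                d_prev[j] = 0
                s_prev[j] = j
            for i in range(1, m + 1):
                qc = queries[q_i, i - 1]
                d_cur[0] = 0
                s_cur[0] = 0
                for j in range(1, length + 1):
                    sub = 0 if windows[w_i, j - 1] == qc else 1
                    best = d_prev[j - 1] + sub
                    src = s_prev[j - 1]
                    alt = d_prev[j] + 1
                    if alt < best or (alt == best and s_prev[j] < src):
                        best = alt
                        src = s_prev[j]
                    alt = d_cur[j - 1] + 1
                    if alt < best or (alt == best and s_cur[j - 1] < src):
                        best = alt
                        src = s_cur[j - 1]
                    d_cur[j] = best
                    s_cur[j] = src
                for j in range(length + 1):
                    d_prev[j] = d_cur[j]
                    s_prev[j] = s_cur[j]
            be = -1
            bs = -1
            bj = -1
            for j in range(1, length + 1):
                e = d_prev[j]
                s = s_prev[j]
                span = j - s
                if span < min_overlap:
                    continue
                if e > int(max_rate * span + 1e-9):
                    continue
                if be < 0:
                    be, bs, bj = e, s, j
                    continue
                lhs = e * (bj - bs)
                rhs = be * span
                better = False
                if lhs < rhs:
                    better = True
                elif lhs == rhs:
                    if span > bj - bs:
                        better = True
                    elif span == bj - bs and s < bs:
                        better = True
                if better:
                    be, bs, bj = e, s, j
            out[w_i, q_i, 0] = be
            out[w_i, q_i, 1] = bs
            out[w_i, q_i, 2] = bj
    return out


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _build_windows(
    reads: Sequence[str], window: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Left windows as-is and right windows reversed (outer boundary at col 0)."""
    n = len(reads)
    left = np.full((n, window), 255, dtype=np.uint8)
    right = np.full((n, window), 255, dtype=np.uint8)
    lens = np.empty(n, dtype=np.int64)
    for i, seq in enumerate(reads):
        enc = _encode(seq)
        w = min(window, enc.size)
        lens[i] = w
        left[i, :w] = enc[:w]
        right[i, :w] = enc[enc.size - w :][::-1]
    return left, right, lens, lens.copy()


def _combo_queries(barcodes: BarcodeSet, cfg: DemuxConfig) -> tuple[np.ndarray, list]:
    """Stacked queries for the left/right kernels plus (end, strand) labels.

    Left-block queries are the barcode and its reverse complement; right-block
    queries are those reversed (the right window is fed in reversed).
    """
    seqs = [s for _, s in barcodes.entries]
    fwd = [_encode(s) for s in seqs]
    rc = [_encode(revcomp(s)) for s in seqs]
    queries = np.stack(fwd + rc)
    combos = [(FIVE_PRIME, FORWARD), (FIVE_PRIME, REVCOMP),
              (THREE_PRIME, FORWARD), (THREE_PRIME, REVCOMP)]
    return queries, combos


@njit(cache=False)
def _select_kernel(
    left, right, read_lens, window, n_bc, use_rc, use_right
):  # pragma: no cover
    """Per read: winning barcode, trim coordinates, and the winner's best rate.

    Returns (winner, trim5, trim3, best_e, best_w) per read; winner -1 means
    no qualifying match, -2 means an exact error-rate tie across barcodes.
    """
    n = left.shape[0]
    res = np.full((n, 5), -1, dtype=np.int64)
    for r in range(n):
        rlen = read_lens[r]
        off = rlen - window
        if off < 0:
            off = 0
        best_e = np.int64(-1)
        best_w = np.int64(0)
        best_start = np.int64(0)
        winner = np.int64(-1)
        tie = False
        for b in range(n_bc):
            bb_e = np.int64(-1)
            bb_w = np.int64(0)
            bb_start = np.int64(0)
            for c in range(4):
                if c >= 2 and not use_right:
                    continue
                if (c == 1 or c == 3) and not use_rc:
                    continue
                col = b if (c == 0 or c == 2) else n_bc + b
                if c < 2:
                    e = left[r, col, 0]
                    s = left[r, col, 1]
                    j = left[r, col, 2]
                    if e < 0:
                        continue
                    start = s
                    span = j - s
                else:
                    e = right[r, col, 0]
                    s = right[r, col, 1]
                    j = right[r, col, 2]
                    if e < 0:
                        continue
                    wl = rlen if rlen < window else window
                    start = off + (wl - j)
                    span = j - s
                if bb_e < 0:
                    bb_e, bb_w, bb_start = e, span, start
                    continue
                lhs = e * bb_w
                rhs = bb_e * span
                if lhs < rhs or (
                    lhs == rhs
                    and (span > bb_w or (span == bb_w and start < bb_start))
                ):
                    bb_e, bb_w, bb_start = e, span, start
            if bb_e < 0:
                continue
            if winner < 0:
                winner = b
                best_e, best_w, best_start = bb_e, bb_w, bb_start
                tie = False
                continue
            lhs = bb_e * best_w
            rhs = best_e * bb_w
            if lhs < rhs:
                winner = b
                best_e, best_w, best_start = bb_e, bb_w, bb_start
                tie = False
            elif lhs == rhs:
                tie = True
        if winner < 0:
            continue
        if tie:
            res[r, 0] = -2
            continue
        # trim through the winner's best qualifying match at each end
        trim5 = np.int64(0)
        trim3 = rlen
        t_e = np.int64(-1)
        t_w = np.int64(0)
        for c in range(2):
            if c == 1 and not use_rc:
                continue
            col = winner if c == 0 else n_bc + winner
            e = left[r, col, 0]
            if e < 0:
                continue
            s = left[r, col, 1]
            j = left[r, col, 2]
            span = j - s
            if t_e < 0 or e * t_w < t_e * span or (
                e * t_w == t_e * span and span > t_w
            ):
                t_e, t_w = e, span
                trim5 = j
        if use_right:
            t_e = np.int64(-1)
            t_w = np.int64(0)
            for c in range(2):
                if c == 1 and not use_rc:
                    continue
                col = winner if c == 0 else n_bc + winner
                e = right[r, col, 0]
                if e < 0:
                    continue
                s = right[r, col, 1]
                j = right[r, col, 2]
                span = j - s
                wl = rlen if rlen < window else window
                if t_e < 0 or e * t_w < t_e * span or (
                    e * t_w == t_e * span and span > t_w
                ):
                    t_e, t_w = e, span
                    trim3 = off + (wl - j)
        if trim3 < trim5:
            trim3 = trim5
        res[r, 0] = winner
        res[r, 1] = trim5
        res[r, 2] = trim3
        res[r, 3] = best_e
        res[r, 4] = best_w
    return res


def _kernel_outputs(
    seqs: Sequence[str], barcodes: BarcodeSet, cfg: DemuxConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    m = len(barcodes.entries[0][1])
    window = cfg.window_len(m)
    left_w, right_w, lens, _ = _build_windows(seqs, window)
    queries, _ = _combo_queries(barcodes, cfg)
    rev_queries = queries[:, ::-1].copy()
    left_out = _match_kernel(
        left_w, lens, queries, cfg.min_overlap, cfg.max_error_rate
    )
    right_out = _match_kernel(
        right_w, lens, rev_queries, cfg.min_overlap, cfg.max_error_rate
    )
    return left_out, right_out, lens, window


def find_barcode_match(
    read: str,
    barcode: str,
    cfg: DemuxConfig | None = None,
    barcode_id: str = "barcode",
) -> BarcodeMatch | None:
    """Best qualifying match of one barcode in one read, or None.

    Searches the 5' terminal window, and -- per the config flags -- the 3'
    window and the reverse complement of the barcode.  An empty or too-short
    read simply yields None.
    """
    cfg = cfg or DemuxConfig()
    if not read:
        return None
    bset = BarcodeSet(entries=[(barcode_id, barcode)])
    left_out, right_out, lens, window = _kernel_outputs([read], bset, cfg)
    rlen = len(read)
    off = max(0, rlen - window)
    wl = min(window, rlen)
    candidates: list[tuple[float, int, int, int, BarcodeMatch]] = []
    combo_defs = [
        (FIVE_PRIME, FORWARD, left_out[0, 0]),
        (FIVE_PRIME, REVCOMP, left_out[0, 1]),
        (THREE_PRIME, FORWARD, right_out[0, 0]),
        (THREE_PRIME, REVCOMP, right_out[0, 1]),
    ]
    for rank, (end, strand, cell) in enumerate(combo_defs):
        if end == THREE_PRIME and not cfg.search_both_ends:
            continue
        if strand == REVCOMP and not cfg.search_reverse_complement:
            continue
        e, s, j = int(cell[0]), int(cell[1]), int(cell[2])
        if e < 0:
            continue
        if end == FIVE_PRIME:
            start, stop = s, j
        else:
            start, stop = off + (wl - j), off + (wl - s)
        match = BarcodeMatch(barcode_id, end, strand, start, stop, e)
        candidates.append((match.error_rate, -match.span, start, rank, match))
    if not candidates:
        return None
    candidates.sort(key=lambda t: t[:4])
    return candidates[0][4]


def demultiplex_reads(
    reads: Sequence[SimRead], barcodes: BarcodeSet, cfg: DemuxConfig | None = None
) -> list[DemuxResult]:
    """Assign a batch of reads to barcodes; every read gets exactly one status."""
    cfg = cfg or DemuxConfig()
    if not barcodes.entries:
        raise ValueError("barcode set is empty")
    if not reads:
        return []
    seqs = [r.sequence for r in reads]
    left_out, right_out, lens, window = _kernel_outputs(seqs, barcodes, cfg)
    read_lens = np.array([len(s) for s in seqs], dtype=np.int64)
    sel = _select_kernel(
        left_out,
        right_out,
        read_lens,
        window,
        len(barcodes),
        cfg.search_reverse_complement,
        cfg.search_both_ends,
    )
    ids = barcodes.ids
    results: list[DemuxResult] = []
    for i, read in enumerate(reads):
        winner = int(sel[i, 0])
        if winner < 0:
            results.append(DemuxResult(read.read_id, UNASSIGNED))
            continue
        t5, t3 = int(sel[i, 1]), int(sel[i, 2])
        trimmed = read.sequence[t5:t3]
        if len(trimmed) < cfg.min_length:
            results.append(DemuxResult(read.read_id, TOO_SHORT, ids[winner]))
            continue
        results.append(
            DemuxResult(
                read.read_id,
                ASSIGNED,
                ids[winner],
                trimmed,
                read.quality[t5:t3],
            )
        )
    return results


def demultiplex_read(
    read: SimRead | str, barcodes: BarcodeSet, cfg: DemuxConfig | None = None
) -> DemuxResult:
    if isinstance(read, str):
        read = SimRead("read", read, "I" * len(read))
    return demultiplex_reads([read], barcodes, cfg)[0]


def summarize(results: Iterable[DemuxResult], barcodes: BarcodeSet) -> pd.DataFrame:
    """Per-bin read counts and fractions (barcodes plus unassigned/too_short)."""
    results = list(results)
    total = len(results)
    rows = []
    for bc_id in barcodes.ids:
        n = sum(1 for r in results if r.status == ASSIGNED and r.barcode_id == bc_id)
        rows.append((bc_id, n))
    rows.append((UNASSIGNED, sum(1 for r in results if r.status == UNASSIGNED)))
    rows.append((TOO_SHORT, sum(1 for r in results if r.status == TOO_SHORT)))
    df = pd.DataFrame(rows, columns=["bin", "n_reads"])
    df["fraction"] = df["n_reads"] / total if total else 0.0
    return df


def demultiplex_stream(
    reads: Iterable[SimRead],
    barcodes: BarcodeSet,
    cfg: DemuxConfig | None = None,
    out_dir=None,
    chunk_size: int = 20_000,
) -> tuple[dict[str, list[SimRead]], pd.DataFrame]:
    """Demultiplex an arrival-ordered stream into per-barcode bins.

    Returns the bins (barcode id -> reads, plus ``unassigned`` and
    ``too_short``) and a summary table.  When ``out_dir`` is given each bin is
    also written as ``<bin>.fastq``.  Arrival order is preserved within bins.
    """
    cfg = cfg or DemuxConfig()
    bins: dict[str, list[SimRead]] = {bc: [] for bc in barcodes.ids}
    bins[UNASSIGNED] = []
    bins[TOO_SHORT] = []
    all_results: list[DemuxResult] = []
    chunk: list[SimRead] = []

    def flush(chunk: list[SimRead]) -> None:
        for read, res in zip(chunk, demultiplex_reads(chunk, barcodes, cfg)):
            all_results.append(res)
            if res.status == ASSIGNED:
                bins[res.barcode_id].append(
                    SimRead(read.read_id, res.trimmed_sequence, res.trimmed_quality)
                )
            else:
                bins[res.status].append(read)

    for read in reads:
        chunk.append(read)
        if len(chunk) >= chunk_size:
            flush(chunk)
            chunk = []
    if chunk:
        flush(chunk)
    summary = summarize(all_results, barcodes)
    if out_dir is not None:
        from pathlib import Path

        from .simulate import write_fastq

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, rs in bins.items():
            write_fastq(rs, out / f"{name}.fastq")
        summary.to_csv(out / "demux_summary.tsv", sep="\t", index=False)
    return bins, summary
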