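"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written as plain-Python enumeration or
term-by-term summation, sharing no code path with the package internals it
checks.
"""

from __future__ import annotations

import math


def edit_distance(a: str, b: str) -> int:
    """Plain O(nm) Levenshtein distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = cur
    return prev[-1]


def poisson_tail_above(k: int, lam: float, terms: int = 4000) -> float:
    """P(X > k) by term-by-term pmf summation of the lower tail."""
    if k < 0:
        return 1.0
    term = math.exp(-lam)
    total = term
    for i in range(1, k + 1):
        term *= lam / i
        total += term
    return 1.0 - total


def poisson_tail_at_most(k: int, lam: float) -> float:
    return 1.0 - poisson_tail_above(k, lam)


def _final_row(query: str, window: str) -> list[int]:
    """Global-alignment DP final row: D[m][j] of query vs window[:j]."""
    m = len(query)
    prev = list(range(len(window) + 1))
    for i in range(1, m + 1):
        qc = query[i - 1]
        cur = [i]
        for j in range(1, len(window) + 1):
            cur.append(
                min(
                    prev[j] + 1,
                    cur[j - 1] + 1,
                    prev[j - 1] + (window[j - 1] != qc),
                )
            )
        prev = cur
    return prev


def oracle_window_best(
    query: str, window: str, min_overlap: int, max_rate: float
) -> tuple[int, int, int] | None:
    """Exhaustive semi-global search of one window: (errors, start, end) or None.

    Enumerates every alignment family explicitly: the full query starting at
    every window offset, plus every outer truncation of the query anchored at
    window position 0.  Per end position the minimum-error (then leftmost-
    start) alignment is kept; candidates must span >= min_overlap read bases
    with errors <= floor(max_rate * span); the best candidate minimizes the
    error rate, ties to larger span then leftmost start.
    """
    m, length = len(query), len(window)
    INF = 10**9
    best: list[tuple[int, int]] = [(INF, 0)] * (length + 1)  # (errors, start)/end j

    def consider(j: int, e: int, s: int) -> None:
        if (e, s) < best[j]:
            best[j] = (e, s)

    for s in range(length + 1):
        row = _final_row(query, window[s:])
        for dj, e in enumerate(row):
            consider(s + dj, e, s)
    for t in range(1, m):
        row = _final_row(query[t:], window)
        for j, e in enumerate(row):
            consider(j, e, 0)

    chosen: tuple[int, int, int] | None = None
    for j in range(1, length + 1):
        e, s = best[j]
        span = j - s
        if e >= INF or span < min_overlap:
            continue
        if e > int(max_rate * span + 1e-9):
            continue
        if chosen is None:
            chosen = (e, s, j)
            continue
        ce, cs, cj = chosen
        cspan = cj - cs
        if e * cspan < ce * span or (
            e * cspan == ce * span
            and (span > cspan or (span == cspan and s < cs))
        ):
            chosen = (e, s, j)
    return chosen


def oracle_find_match(
    read: str,
    barcode: str,
    min_overlap: int = 20,
    max_rate: float = 0.20,
    both_ends: bool = True,
    revcomp_search: bool = True,
):
    """Exhaustive counterpart of find_barcode_match.

    Returns (end, strand, start, stop, errors) of the best match or None.
    """
    comp = str.maketrans("ACGT", "TGCA")
    rc = barcode.translate(comp)[::-1]
    m = len(barcode)
    window_len = math.ceil(m * (1 + max_rate))
    wl = min(window_len, len(read))
    off = max(0, len(read) - window_len)
    left = read[:wl]
    right = read[len(read) - wl :][::-1]
    combos = [
        ("five_prime", "forward", left, barcode),
        ("five_prime", "reverse_complement", left, rc),
        ("three_prime", "forward", right, barcode[::-1]),
        ("three_prime", "reverse_complement", right, rc[::-1]),
    ]
    candidates = []
    for rank, (end, strand, window, query) in enumerate(combos):
        if end == "three_prime" and not both_ends:
            continue
        if strand == "reverse_complement" and not revcomp_search:
            continue
        hit = oracle_window_best(query, window, min_overlap, max_rate)
        if hit is None:
            continue
        e, s, j = hit
        if end == "five_prime":
            start, stop = s, j
        else:
            start, stop = off + (wl - j), off + (wl - s)
        span = stop - start
        candidates.append((e / span, -span, start, rank, (end, strand, start, stop, e)))
    if not candidates:
        return None
    candidates.sort(key=lambda t: t[:4])
    return candidates[0][4]
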