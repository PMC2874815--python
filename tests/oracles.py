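"""Independent brute-force oracles used by the test suite.

Each oracle re-derives the expected answer by exhaustive search or direct
per-element recounting, sharing no code with the implementation it checks.
"""

from __future__ import annotations

from collections import Counter

_ACGT = set("ACGT")


# ---------------------------------------------------------------- trimming

def _interval_ok(errors, windows, s, e, end_max=None) -> bool:
    length = e - s
    if length <= 0:
        return False
    if end_max is not None and (errors[s] > end_max or errors[e - 1] > end_max):
        return False
    for wlen, bound in windows:
        if length >= wlen:
            for i in range(s, e - wlen + 1):
                if sum(errors[i : i + wlen]) > bound * wlen:
                    return False
        else:
            if sum(errors[s:e]) > bound * length:
                return False
    return True


def oracle_longest_interval(errors, windows, end_max=None):
    """Longest (leftmost tie) interval valid under the window rules."""
    n = len(errors)
    for length in range(n, 0, -1):
        for s in range(0, n - length + 1):
            if _interval_ok(errors, windows, s, s + length, end_max):
                return (s, s + length)
    return (0, 0)


def oracle_trim(errors, bracket_max, windows):
    """Bracket scan followed by exhaustive constrained interval search."""
    n = len(errors)
    b0 = 0
    while b0 < n and errors[b0] > bracket_max:
        b0 += 1
    b1 = n
    while b1 > b0 and errors[b1 - 1] > bracket_max:
        b1 -= 1
    if b0 >= b1:
        return (0, 0)
    sub = errors[b0:b1]
    s, e = oracle_longest_interval(sub, windows, end_max=bracket_max)
    return (b0 + s, b0 + e) if e > s else (0, 0)


def oracle_best_run(quals, min_len, min_avg) -> bool:
    """Any contiguous run of >= min_len bases with mean quality >= min_avg."""
    n = len(quals)
    for s in range(n):
        for e in range(s + min_len, n + 1):
            if sum(quals[s:e]) / (e - s) >= min_avg:
                return True
    return False


# ---------------------------------------------------------------- SSR mining

def _periodic(s: str, start: int, end: int, u: int) -> bool:
    return all(s[i] == s[i + u] for i in range(start, end - u))


def oracle_find_ssrs(seq: str, min_unit=2, max_unit=4, min_len=24):
    """Maximal perfect tandem tracts by per-character extension.

    Returns (start, end, unit_size) tuples after smallest-unit reporting and
    longest/leftmost/smallest-unit overlap resolution.
    """
    s = seq.upper()
    n = len(s)
    cands = []
    for u in range(max(2, min_unit), max_unit + 1):
        for start in range(n - 2 * u + 1):
            if any(s[i] not in _ACGT for i in range(start, start + u)):
                continue
            # left-maximality
            if start > 0 and s[start - 1] in _ACGT and s[start - 1] == s[start - 1 + u]:
                continue
            end = start + u
            while end < n and s[end] in _ACGT and s[end] == s[end - u]:
                end += 1
            if end - start < max(min_len, 2 * u):
                continue
            tract = s[start:end]
            min_period = next(
                q for q in range(1, u + 1)
                if all(tract[i] == tract[i + q] for i in range(len(tract) - q))
            )
            if min_period < u:
                continue
            cands.append((start, end, u))
    cands = sorted(set(cands), key=lambda c: (-(c[1] - c[0]), c[0], c[2]))
    chosen = []
    for c in cands:
        if all(c[1] <= s0 or e0 <= c[0] for s0, e0, _ in chosen):
            chosen.append(c)
    return sorted(chosen)


# ---------------------------------------------------------------- SNP calling

def oracle_variant_columns(rows):
    """Per-column recount: {column: {base: count}} for polymorphic columns."""
    out = {}
    width = len(rows[0])
    for col in range(width):
        counts = Counter(
            row[col].upper() for row in rows if row[col].upper() in _ACGT
        )
        if len(counts) >= 2:
            out[col] = dict(counts)
    return out


def oracle_filter(counts: dict, min_count: int) -> bool:
    return sum(1 for v in counts.values() if v >= min_count) >= 2
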