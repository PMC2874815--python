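"""Lucy-style quality trimming of Sanger EST reads.

Trimming operates on per-base Phred qualities.  Two rules combine:

* a *bracket* rule that clips low-quality bases off both ends until the
  terminal bases have error probability at or below ``bracket_max_error``
  (Q30 = 0.001 by default), and
* a *window* rule that keeps the longest contiguous stretch in which every
  sliding window of the configured length has mean error probability at or
  below its bound (a single 10-base window at 0.063 by default).

A trimmed read then passes the survey's quality gate if some contiguous run
of at least ``pass_min_len`` kept bases has mean Phred quality of at least
``pass_min_avg_q`` (100 bases at Q20 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ReadRecord",
    "TrimPolicy",
    "phred_to_error",
    "bracket_trim",
    "window_trim",
    "trim_read",
    "passes_quality",
    "pass_rate",
    "pass_fraction",
]


@dataclass
class ReadRecord:
    """A read with per-base Phred qualities and a kept interval.

    ``kept`` is a 0-based half-open interval into ``bases``; it defaults to
    the whole read and may be empty after trimming (read discarded).
    """

    read_id: str
    bases: str
    quals: np.ndarray
    kept: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int64)
        if len(self.quals) != len(self.bases):
            raise ValueError(
                f"{self.read_id}: {len(self.quals)} qualities for "
                f"{len(self.bases)} bases"
            )
        if np.any(self.quals < 0):
            raise ValueError(f"{self.read_id}: negative Phred quality")
        if self.kept is None:
            self.kept = (0, len(self.bases))
        s, e = self.kept
        if not (0 <= s <= e <= len(self.bases)):
            raise ValueError(f"{self.read_id}: kept interval {self.kept} out of range")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def kept_bases(self) -> str:
        s, e = self.kept
        return self.bases[s:e]

    @property
    def kept_quals(self) -> np.ndarray:
        s, e = self.kept
        return self.quals[s:e]

    def as_kept(self) -> "ReadRecord":
        """Return a new record holding only the kept slice."""
        s, e = self.kept
        return ReadRecord(self.read_id, self.bases[s:e], self.quals[s:e])


@dataclass(frozen=True)
class TrimPolicy:
    """Trimming thresholds.

    ``windows`` is a sequence of (length, max mean error) pairs; an interval
    shorter than a window length must satisfy that bound over the whole
    interval instead.
    """

    bracket_max_error: float = 0.001
    windows: tuple[tuple[int, float], ...] = ((10, 0.063),)
    pass_min_len: int = 100
    pass_min_avg_q: float = 20.0

    def __post_init__(self) -> None:
        if not (0.0 < self.bracket_max_error <= 1.0):
            raise ValueError("bracket_max_error must be in (0, 1]")
        for length, bound in self.windows:
            if length < 1:
                raise ValueError("window lengths must be >= 1")
            if not (0.0 < bound <= 1.0):
                raise ValueError("window error bounds must be in (0, 1]")
        if self.pass_min_len < 1:
            raise ValueError("pass_min_len must be >= 1")


def phred_to_error(q):
    """Phred score -> error probability, e = 10**(-Q/10).

    Accepts scalars or arrays; rejects negative scores.
    """
    arr = np.asarray(q, dtype=float)
    if np.any(arr < 0):
        raise ValueError("Phred scores must be non-negative")
    out = 10.0 ** (-arr / 10.0)
    return float(out) if np.isscalar(q) or arr.ndim == 0 else out


def bracket_trim(errors: Sequence[float], max_error: float) -> tuple[int, int]:
    """Clip both ends so the outermost retained bases have error <= max_error.

    Only end bases are stripped; interior bases above the bound survive.
    Returns a (possibly empty) 0-based half-open interval.
    """
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("empty error sequence")
    good = np.flatnonzero(e <= max_error)
    if good.size == 0:
        return (0, 0)
    return (int(good[0]), int(good[-1]) + 1)


def _window_structures(e: np.ndarray, windows):
    """Per-window-spec prefix structures for O(1) interval checks.

    For each (L, bound) returns (L, bound, lastbad) where lastbad[j] is the
    largest window-start index <= j whose L-window mean exceeds bound, or -1.
    lastbad is None when no L-window fits the sequence.
    """
    n = e.size
    prefix = np.concatenate(([0.0], np.cumsum(e)))
    out = []
    for length, bound in windows:
        if length <= n:
            wsum = prefix[length:] - prefix[:-length]
            bad = wsum > bound * length
            lastbad = np.where(bad, np.arange(bad.size), -1)
            np.maximum.accumulate(lastbad, out=lastbad)
        else:
            lastbad = None
        out.append((length, bound, lastbad))
    return prefix, out


def _longest_valid_interval(
    e: np.ndarray,
    windows,
    end_max: float | None = None,
) -> tuple[int, int]:
    """Longest (leftmost on ties) interval satisfying every window rule.

    If ``end_max`` is given the interval's terminal bases must additionally
    have error <= end_max.  Windows of length L constrain every L-window
    inside the interval; intervals shorter than L must satisfy the mean
    bound over their whole extent.
    """
    n = e.size
    if n == 0:
        return (0, 0)
    prefix, specs = _window_structures(e, windows)
    endok = np.ones(n, dtype=bool) if end_max is None else (e <= end_max)
    # next_good[i] = smallest j >= i with endok[j], else n
    next_good = np.full(n + 1, n, dtype=np.int64)
    for i in range(n - 1, -1, -1):
        next_good[i] = i if endok[i] else next_good[i + 1]

    lmax = max(length for length, _ in windows)
    best = (0, 0)

    # Intervals long enough that every window spec applies via its windows.
    if lmax <= n:
        for epos in range(lmax, n + 1):
            if not endok[epos - 1]:
                continue
            smin = 0
            for length, _bound, lastbad in specs:
                smin = max(smin, int(lastbad[epos - length]) + 1)
            s = int(next_good[smin])
            if epos - s >= lmax and epos - s > best[1] - best[0]:
                best = (s, epos)

    # Shorter intervals: some specs switch to the whole-interval mean rule.
    cap = min(lmax - 1, n)
    for length_i in range(cap, best[1] - best[0], -1):
        for s in range(0, n - length_i + 1):
            epos = s + length_i
            if not (endok[s] and endok[epos - 1]):
                continue
            ok = True
            for wlen, bound, lastbad in specs:
                if length_i >= wlen:
                    ok = int(lastbad[epos - wlen]) < s
                else:
                    ok = (prefix[epos] - prefix[s]) <= bound * length_i
                if not ok:
                    break
            if ok:
                return (s, epos)  # lengths descend, starts ascend: first hit wins
    return best


def window_trim(
    errors: Sequence[float],
    windows: Iterable[tuple[int, float]] = ((10, 0.063),),
) -> tuple[int, int]:
    """Longest contiguous interval whose every window passes its error bound.

    Ties broken leftmost.  Returns a 0-based half-open interval, possibly
    empty.
    """
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("empty error sequence")
    return _longest_valid_interval(e, tuple(windows))


def trim_read(read: ReadRecord, policy: TrimPolicy = TrimPolicy()) -> ReadRecord:
    """Apply bracket and window rules; returns the read with ``kept`` set.

    The kept interval is the longest (leftmost on ties) stretch inside the
    bracket interval that satisfies every window rule and whose terminal
    bases meet the bracket bound — so trimming is idempotent.
    """
    e = phred_to_error(read.quals)
    b0, b1 = bracket_trim(e, policy.bracket_max_error)
    if b0 >= b1:
        return replace(read, kept=(0, 0))
    s, t = _longest_valid_interval(
        e[b0:b1], policy.windows, end_max=policy.bracket_max_error
    )
    kept = (b0 + s, b0 + t) if t > s else (0, 0)
    return replace(read, kept=kept)


def passes_quality(read: ReadRecord, policy: TrimPolicy = TrimPolicy()) -> bool:
    """True iff some run of >= pass_min_len kept bases has mean Phred >= threshold."""
    q = read.kept_quals.astype(float)
    k = policy.pass_min_len
    if q.size < k:
        return False
    t = q - policy.pass_min_avg_q
    prefix = np.concatenate(([0.0], np.cumsum(t)))
    run_min = np.minimum.accumulate(prefix[: q.size - k + 1])
    return bool(np.any(prefix[k:] - run_min >= -1e-9))


def pass_rate(
    reads: Iterable[ReadRecord], policy: TrimPolicy = TrimPolicy()
) -> float:
    """Fraction of reads passing the quality gate (reads must be trimmed)."""
    total = passed = 0
    for read in reads:
        total += 1
        passed += passes_quality(read, policy)
    if total == 0:
        raise ValueError("empty read collection")
    return passed / total


def pass_fraction(n_passed: int, n_total: int) -> float:
    """Passing fraction from already-tallied counts."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not (0 <= n_passed <= n_total):
        raise ValueError("n_passed must be in [0, n_total]")
    return n_passed / n_total
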