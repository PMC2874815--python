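"""Microsatellite (SSR) mining with Sputnik-style parameters.

Finds maximal perfect tandem repeats of 2-4 bp units at a minimum tract
length of 24 nucleotides, reports each tract at its smallest generating
unit, names motifs canonically (minimum over rotations and reverse-
complement rotations), and classifies tracts into 5'UTR / ORF / 3'UTR by
tract midpoint when CDS coordinates are available.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SsrRecord",
    "SsrSummary",
    "find_ssrs",
    "canonical_motif",
    "classify_region",
    "ssr_summary",
]

_COMP = str.maketrans("ACGT", "TGCA")
_ACGT = frozenset("ACGT")


@dataclass
class SsrRecord:
    """One microsatellite tract; coordinates 0-based half-open."""

    seq_id: str
    start: int
    end: int
    unit: str
    canonical_motif: str
    unit_length: int
    tract_length: int
    region: str | None = None

    def __post_init__(self) -> None:
        if self.tract_length != self.end - self.start:
            raise ValueError("tract_length must equal end - start")
        if self.tract_length < 2 * self.unit_length:
            raise ValueError("tract must contain at least two repeat units")


@dataclass(frozen=True)
class SsrSummary:
    by_unit_length: dict[int, int]
    by_motif: dict[str, int]
    total: int


def canonical_motif(unit: str) -> str:
    """Lexicographically smallest rotation of the unit or its reverse complement."""
    unit = unit.upper()
    if not (2 <= len(unit) <= 4) or set(unit) - _ACGT:
        raise ValueError(f"invalid repeat unit {unit!r}")
    rc = unit.translate(_COMP)[::-1]
    rotations = {u[i:] + u[:i] for u in (unit, rc) for i in range(len(u))}
    return min(rotations)


def _min_period(tract: str, upto: int) -> int:
    """Smallest q <= upto that is a period of the tract (tract[i]==tract[i+q])."""
    for q in range(1, upto + 1):
        if tract[:-q] == tract[q:]:
            return q
    return upto + 1  # unreachable when upto is itself a period


def find_ssrs(
    sequence: str,
    seq_id: str = "seq",
    min_unit: int = 2,
    max_unit: int = 4,
    min_len: int = 24,
) -> list[SsrRecord]:
    """All maximal perfect tandem tracts meeting the unit and length bounds.

    N (or any non-ACGT character) breaks tracts.  A tract is reported at its
    smallest generating unit; homopolymer runs are excluded.  Overlaps are
    resolved longest-first, then leftmost, then smallest unit.
    """
    if not (1 <= min_unit <= max_unit):
        raise ValueError("require 1 <= min_unit <= max_unit")
    s = sequence.upper()
    n = len(s)
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    ok = (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))

    candidates: list[tuple[int, int, int]] = []
    for u in range(max(2, min_unit), max_unit + 1):
        if n < 2 * u:
            continue
        eq = (arr[u:] == arr[: n - u]) & ok[u:] & ok[: n - u]
        edges = np.flatnonzero(np.diff(np.concatenate(
            ([0], eq.view(np.int8), [0]))))
        for a, b in zip(edges[::2], edges[1::2]):
            start, end = int(a), int(b) + u
            if end - start < max(min_len, 2 * u):
                continue
            if _min_period(s[start:end], u) < u:
                continue  # reported at the smaller unit instead
            candidates.append((start, end, u))

    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[2]))
    chosen: list[tuple[int, int, int]] = []
    for c in candidates:
        if all(c[1] <= s0 or e0 <= c[0] for s0, e0, _ in chosen):
            chosen.append(c)
    chosen.sort()

    records = []
    for start, end, u in chosen:
        unit = s[start : start + u]
        records.append(
            SsrRecord(seq_id, start, end, unit, canonical_motif(unit), u, end - start)
        )
    return records


def classify_region(
    record: SsrRecord, cds_start: int, cds_end: int, seq_length: int | None = None
) -> str:
    """Region of the tract midpoint relative to the CDS interval."""
    if not (0 <= cds_start < cds_end):
        raise ValueError("require 0 <= cds_start < cds_end")
    if seq_length is not None and cds_end > seq_length:
        raise ValueError("CDS extends beyond the sequence")
    mid = (record.start + record.end) / 2.0
    if mid < cds_start:
        return "5'UTR"
    if mid >= cds_end:
        return "3'UTR"
    return "ORF"


def ssr_summary(records: Iterable[SsrRecord]) -> SsrSummary:
    """Counts by unit length and by canonical motif."""
    records = list(records)
    by_unit = Counter(r.unit_length for r in records)
    by_motif = Counter(r.canonical_motif for r in records)
    return SsrSummary(dict(sorted(by_unit.items())),
                      dict(sorted(by_motif.items())), len(records))
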