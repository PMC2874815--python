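"""Cluster membership for EST reads and per-library cluster summaries.

Real surveys assemble reads with an external assembler and this module
consumes its output (ACE files or membership tables).  For synthetic data a
greedy single-linkage clusterer over shared canonical k-mers stands in for
the assembler: two reads are linked when they share at least ``min_shared``
distinct canonical (strand-collapsed) k-mers, and clusters are the
transitive closure of that relation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ClusterAssignment",
    "LibrarySummary",
    "cluster_reads",
    "summarize",
    "read_membership",
    "write_membership",
    "read_ace",
]

_COMP = str.maketrans("ACGT", "TGCA")


@dataclass
class ClusterAssignment:
    """read_id -> dense cluster id, with optional per-read round tags."""

    clusters: dict[str, int]
    rounds: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.clusters:
            raise ValueError("empty cluster assignment")

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for cid in self.clusters.values():
            out[cid] = out.get(cid, 0) + 1
        return out


@dataclass(frozen=True)
class LibrarySummary:
    """Per-library counts feeding the redundancy statistics.

    n: total reads; d: distinct clusters; n1: singleton clusters;
    contigs: clusters of size >= 2.  Invariant: d = n1 + contigs.
    """

    library: str
    n: int
    d: int
    n1: int
    contigs: int

    def __post_init__(self) -> None:
        if self.d != self.n1 + self.contigs:
            raise ValueError("d must equal n1 + contigs")
        if not (self.n >= self.d >= 1):
            raise ValueError("require n >= d >= 1")
        if self.n1 > self.n:
            raise ValueError("n1 cannot exceed n")


def _informative_starts(arr, k: int, max_period: int = 4):
    """Start positions of k-mers that are neither ambiguous nor repeat-like.

    A k-mer is repeat-like when, for some period q <= max_period, all but
    two of its (k - q) period-q base comparisons match.  Repeat-derived
    k-mers are shared between unrelated genes carrying the same
    microsatellite motif; excluding them plays the role repeat masking plays
    ahead of a real assembly.
    """
    import numpy as np

    n = arr.size
    valid = ((arr == 65) | (arr == 67) | (arr == 71) | (arr == 84)).astype(np.int64)
    vsum = np.concatenate(([0], np.cumsum(valid)))
    ok = (vsum[k:] - vsum[:-k]) == k  # every base A/C/G/T
    repeatlike = np.zeros(n - k + 1, dtype=bool)
    for q in range(1, max_period + 1):
        eq = (arr[q:] == arr[:-q]).astype(np.int64)
        esum = np.concatenate(([0], np.cumsum(eq)))
        w = k - q
        repeatlike |= (esum[w:] - esum[:-w])[: n - k + 1] >= w - 2
    return np.flatnonzero(ok & ~repeatlike)


def _canonical_kmers(seq: str, k: int) -> set[str]:
    import numpy as np

    s = seq.upper()
    n = len(s)
    if n < k:
        return set()
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    rc = s.translate(_COMP)[::-1]
    out: set[str] = set()
    for i in _informative_starts(arr, k):
        fwd = s[i : i + k]
        rev = rc[n - k - i : n - i]
        out.add(fwd if fwd <= rev else rev)
    return out


def _find(parent: list[int], x: int) -> int:
    root = x
    while parent[root] != root:
        root = parent[root]
    while parent[x] != root:
        parent[x], x = root, parent[x]
    return root


def cluster_reads(
    reads: Mapping[str, str] | Iterable,
    k: int = 16,
    min_shared: int = 3,
) -> ClusterAssignment:
    """Single-linkage clusters over the shared-canonical-k-mer relation.

    Two reads are related when they share at least ``min_shared`` distinct
    canonical k-mers (low-complexity k-mers excluded); clusters are the
    transitive closure.  ``reads`` maps read_id -> sequence (ReadRecord
    iterables are accepted; their kept slice is used).  Output is
    input-order independent; dense cluster ids are assigned in order of each
    cluster's smallest read_id.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    if not isinstance(reads, Mapping):
        reads = {r.read_id: r.kept_bases for r in reads}
    if not reads:
        raise ValueError("no reads to cluster")

    import numpy as np

    ids = sorted(reads)
    parent = list(range(len(ids)))
    buckets: dict[str, list[int]] = {}
    for idx, rid in enumerate(ids):
        kmers = _canonical_kmers(reads[rid], k)
        cand: list[int] = []
        for km in kmers:
            hit = buckets.get(km)
            if hit:
                cand.extend(hit)
        if cand:
            counts = np.bincount(np.asarray(cand, dtype=np.int64), minlength=idx)
            for mate in np.flatnonzero(counts >= min_shared):
                ra, rb = _find(parent, idx), _find(parent, int(mate))
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
        for km in kmers:
            buckets.setdefault(km, []).append(idx)

    roots: dict[int, list[str]] = {}
    for idx, rid in enumerate(ids):
        roots.setdefault(_find(parent, idx), []).append(rid)
    order = sorted(roots.values(), key=lambda members: members[0])
    clusters = {rid: cid for cid, members in enumerate(order) for rid in members}
    return ClusterAssignment(clusters)


def summarize(assignment: ClusterAssignment, library: str = "library") -> LibrarySummary:
    """Collapse an assignment to the (n, d, n1, contigs) counts."""
    sizes = assignment.sizes()
    n = sum(sizes.values())
    d = len(sizes)
    n1 = sum(1 for s in sizes.values() if s == 1)
    return LibrarySummary(library, n, d, n1, d - n1)


def _dense_ids(pairs: list[tuple[str, str]]) -> dict[str, int]:
    """Map raw cluster labels to dense ints ordered by smallest member read_id."""
    first: dict[str, str] = {}
    for rid, label in pairs:
        if label not in first or rid < first[label]:
            first[label] = rid
    order = {label: i for i, (_, label) in enumerate(
        sorted((m, lab) for lab, m in first.items()))}
    return {rid: order[label] for rid, label in pairs}


def read_membership(path: str | Path) -> ClusterAssignment:
    """Read a membership TSV: read_id <tab> cluster_id [<tab> round_id]."""
    pairs: list[tuple[str, str]] = []
    rounds: dict[str, str] = {}
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 columns, "
                                 f"got {len(fields)}")
            rid, label = fields[0], fields[1]
            if rid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate read_id {rid!r}")
            seen.add(rid)
            pairs.append((rid, label))
            if len(fields) == 3:
                rounds[rid] = fields[2]
    if not pairs:
        raise ValueError(f"{path}: empty membership file")
    return ClusterAssignment(_dense_ids(pairs), rounds or None)


def write_membership(assignment: ClusterAssignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# read_id\tcluster_id" +
                 ("\tround_id" if assignment.rounds else "") + "\n")
        for rid in sorted(assignment.clusters):
            row = f"{rid}\t{assignment.clusters[rid]}"
            if assignment.rounds:
                row += f"\t{assignment.rounds.get(rid, '')}"
            fh.write(row + "\n")


def read_ace(path: str | Path, read_list: Iterable[str] | None = None) -> ClusterAssignment:
    """Extract contig membership from an ACE assembly file (CO/AF records).

    Reads named in ``read_list`` but absent from every contig are treated as
    singletons, each in its own cluster.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[str] = set()
    contig = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("CO "):
                fields = line.split()
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: malformed CO record")
                contig = fields[1]
            elif line.startswith("AF "):
                fields = line.split()
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: malformed AF record")
                if contig is None:
                    raise ValueError(f"{path}:{lineno}: AF record before any CO")
                rid = fields[1]
                if rid in seen:
                    raise ValueError(f"{path}:{lineno}: duplicate read_id {rid!r}")
                seen.add(rid)
                pairs.append((rid, contig))
    if read_list is not None:
        for rid in read_list:
            if rid not in seen:
                pairs.append((rid, f"__singleton__{rid}"))
    if not pairs:
        raise ValueError(f"{path}: no contig membership found")
    return ClusterAssignment(_dense_ids(pairs))
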