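"""Completeness of ESTs/unigenes relative to matched protein entries.

A query is 5'-complete when its protein alignment starts within ``margin``
amino acids of the protein N-terminus (subject_start - 1 <= margin) and
3'-complete when it ends within ``margin`` of the C-terminus
(subject_length - subject_end <= margin).  Calls are tabulated by protein
length class as proportions within each class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ProteinHit",
    "CompletenessCall",
    "CLASSES",
    "LENGTH_BINS",
    "classify_completeness",
    "bin_by_length",
    "best_hit_per_query",
    "completeness_table",
    "read_tabular_hits",
    "write_completeness_table",
]

CLASSES = ("both", "five_only", "three_only", "incomplete")
LENGTH_BINS = ("<250aa", "251-500aa", "501-750aa", "751-1000aa", ">1000aa")
_BIN_UPPER = (250, 500, 750, 1000)


@dataclass(frozen=True)
class ProteinHit:
    """A query-to-protein alignment; subject coordinates are 1-based inclusive."""

    query_id: str
    subject_id: str
    subject_start: int
    subject_end: int
    subject_length: int
    evalue: float

    def __post_init__(self) -> None:
        if not (1 <= self.subject_start <= self.subject_end <= self.subject_length):
            raise ValueError(
                f"{self.query_id}->{self.subject_id}: invalid subject coordinates "
                f"[{self.subject_start}, {self.subject_end}] on length "
                f"{self.subject_length}"
            )
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")

    @property
    def subject_coverage(self) -> float:
        return (self.subject_end - self.subject_start + 1) / self.subject_length


@dataclass(frozen=True)
class CompletenessCall:
    query_id: str
    cls: str
    length_bin: str


def classify_completeness(hit: ProteinHit, margin: int = 10) -> str:
    """both / five_only / three_only / incomplete by terminus distance."""
    five = hit.subject_start - 1 <= margin
    three = hit.subject_length - hit.subject_end <= margin
    if five and three:
        return "both"
    if five:
        return "five_only"
    if three:
        return "three_only"
    return "incomplete"


def bin_by_length(subject_length: int) -> str:
    """Protein length class; boundaries at 250/500/750/1000 aa (inclusive below)."""
    if subject_length < 1:
        raise ValueError("subject_length must be >= 1")
    for upper, label in zip(_BIN_UPPER, LENGTH_BINS):
        if subject_length <= upper:
            return label
    return LENGTH_BINS[-1]


def best_hit_per_query(hits: Iterable[ProteinHit]) -> list[ProteinHit]:
    """Collapse to one hit per query: lowest e-value, then highest subject
    coverage, then lexicographic subject_id."""
    best: dict[str, ProteinHit] = {}
    for hit in hits:
        cur = best.get(hit.query_id)
        if cur is None or (
            (hit.evalue, -hit.subject_coverage, hit.subject_id)
            < (cur.evalue, -cur.subject_coverage, cur.subject_id)
        ):
            best[hit.query_id] = hit
    return [best[q] for q in sorted(best)]


def call_hits(
    hits: Iterable[ProteinHit], margin: int = 10, best_only: bool = True
) -> list[CompletenessCall]:
    """Classify hits (best hit per query by default) into completeness calls."""
    pool = best_hit_per_query(hits) if best_only else list(hits)
    return [
        CompletenessCall(h.query_id, classify_completeness(h, margin),
                         bin_by_length(h.subject_length))
        for h in pool
    ]


def completeness_table(
    calls: Iterable[CompletenessCall],
) -> tuple[pd.DataFrame, pd.Series, float]:
    """Proportions-by-length-class matrix, per-bin totals, and the overall
    fraction of queries complete on both ends."""
    calls = list(calls)
    if not calls:
        raise ValueError("no completeness calls")
    df = pd.DataFrame(
        [(c.cls, c.length_bin) for c in calls], columns=["cls", "bin"]
    )
    counts = pd.crosstab(df["cls"], df["bin"]).reindex(
        index=list(CLASSES), columns=list(LENGTH_BINS), fill_value=0
    )
    totals = counts.sum(axis=0)
    props = counts / totals.replace(0, pd.NA)
    both_fraction = (df["cls"] == "both").mean()
    return props, totals, float(both_fraction)


def read_tabular_hits(
    hits_path: str | Path, lengths: str | Path | Mapping[str, int]
) -> list[ProteinHit]:
    """Parse standard 12-column tabular hits plus a subject-length table.

    Reverse-frame hits (sstart > send) are skipped with a warning.  The
    length table is a TSV of (subject_id, length) or a mapping.
    """
    if not isinstance(lengths, Mapping):
        ldf = pd.read_csv(lengths, sep="\t", comment="#",
                          names=["subject_id", "length"], dtype={"subject_id": str})
        if str(ldf.iloc[0]["subject_id"]) == "subject_id":  # header present
            ldf = ldf.iloc[1:]
        lengths = {str(r.subject_id): int(r.length) for r in ldf.itertuples()}

    hits: list[ProteinHit] = []
    n_reverse = 0
    with open(hits_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{hits_path}:{lineno}: expected 12 columns, got {len(fields)}"
                )
            qid, sid = fields[0], fields[1]
            if qid == "qseqid":  # header row
                continue
            sstart, send = int(fields[8]), int(fields[9])
            if sstart > send:
                n_reverse += 1
                continue
            if sid not in lengths:
                raise ValueError(f"{hits_path}:{lineno}: no length for subject {sid!r}")
            hits.append(
                ProteinHit(qid, sid, sstart, send, lengths[sid], float(fields[10]))
            )
    if n_reverse:
        warnings.warn(f"{hits_path}: skipped {n_reverse} reverse-frame hits")
    return hits


def write_completeness_table(
    props: pd.DataFrame, totals: pd.Series, both_fraction: float, path
) -> None:
    with open(path, "w") as fh:
        fh.write("# completeness proportions by protein length class\n")
        fh.write(f"# overall fraction complete on both ends: {both_fraction:.4f}\n")
        out = props.round(4)
        out.loc["total"] = totals
        out.to_csv(fh, sep="\t")
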