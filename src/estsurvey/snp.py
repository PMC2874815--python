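"""Candidate SNP calling from per-cluster multiple alignments.

A candidate is any alignment column with at least two distinct A/C/G/T
bases (gaps and N never count as alleles).  The reliability filter keeps a
candidate when at least two bases are each observed at least ``min_count``
times; filtered biallelic candidates are classified as transitions
(A<->G, C<->T) or transversions, and columns with three or more passing
alleles are reported separately as multiallelic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SnpCandidate",
    "TsTvSummary",
    "call_variant_columns",
    "apply_min_count_filter",
    "classify_substitution",
    "tstv_summary",
    "write_snp_table",
    "write_vcf_like",
]

_ALLELES = "ACGT"
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}
_ALLOWED = frozenset("ACGTN-")


@dataclass
class SnpCandidate:
    """A polymorphic alignment column; ``column`` is 0-based."""

    contig_id: str
    column: int
    allele_counts: dict[str, int]
    passes_filter: bool = False
    substitution_class: str = "unset"

    def observed(self) -> list[str]:
        return [b for b in _ALLELES if self.allele_counts.get(b, 0) > 0]


@dataclass(frozen=True)
class TsTvSummary:
    n_transition: int
    n_transversion: int
    n_multiallelic: int
    fraction_transition: float | None


def call_variant_columns(
    alignment: Sequence[str], contig_id: str = "contig"
) -> list[SnpCandidate]:
    """One candidate per column carrying >= 2 distinct A/C/G/T bases.

    ``alignment`` is a list of equal-length rows over {A,C,G,T,N,-}
    (case-insensitive).  Ragged alignments and foreign characters are
    rejected.
    """
    rows = [r.upper() for r in alignment]
    if not rows:
        raise ValueError("empty alignment")
    width = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != width:
            raise ValueError(f"ragged alignment: row {i} has length {len(r)}, "
                             f"expected {width}")
        bad = set(r) - _ALLOWED
        if bad:
            raise ValueError(f"row {i}: invalid characters {sorted(bad)}")

    mat = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
    mat = mat.reshape(len(rows), width)
    counts = {b: (mat == ord(b)).sum(axis=0) for b in _ALLELES}
    stacked = np.stack([counts[b] for b in _ALLELES])
    poly = np.flatnonzero((stacked > 0).sum(axis=0) >= 2)

    out = []
    for col in poly:
        cc = {b: int(counts[b][col]) for b in _ALLELES if counts[b][col] > 0}
        out.append(SnpCandidate(contig_id, int(col), cc))
    return out


def apply_min_count_filter(
    candidates: Iterable[SnpCandidate], min_count: int = 2
) -> list[SnpCandidate]:
    """Keep candidates where >= 2 bases each occur >= min_count times.

    Kept candidates get ``passes_filter`` set and, when exactly two alleles
    pass, a transition/transversion class; columns with three or more
    passing alleles are flagged "multiallelic".
    """
    kept = []
    for cand in candidates:
        passing = [b for b in _ALLELES if cand.allele_counts.get(b, 0) >= min_count]
        if len(passing) < 2:
            continue
        cls = (
            classify_substitution(passing[0], passing[1])
            if len(passing) == 2
            else "multiallelic"
        )
        kept.append(
            SnpCandidate(cand.contig_id, cand.column, dict(cand.allele_counts),
                         passes_filter=True, substitution_class=cls)
        )
    return kept


def classify_substitution(base_a: str, base_b: str) -> str:
    """'transition' for A<->G / C<->T, 'transversion' otherwise; symmetric."""
    a, b = base_a.upper(), base_b.upper()
    if a not in _ALLELES or b not in _ALLELES:
        raise ValueError(f"invalid bases ({base_a!r}, {base_b!r})")
    if a == b:
        raise ValueError("bases must differ")
    return "transition" if frozenset((a, b)) in _TRANSITIONS else "transversion"


def tstv_summary(candidates: Iterable[SnpCandidate]) -> TsTvSummary:
    """Transition/transversion counts over filtered biallelic candidates."""
    ts = tv = multi = 0
    for cand in candidates:
        if cand.substitution_class == "transition":
            ts += 1
        elif cand.substitution_class == "transversion":
            tv += 1
        elif cand.substitution_class == "multiallelic":
            multi += 1
    frac = ts / (ts + tv) if ts + tv else None
    return TsTvSummary(ts, tv, multi, frac)


def _major_minor(cand: SnpCandidate) -> tuple[str, str]:
    ranked = sorted(cand.allele_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[0][0], ranked[1][0]


def write_snp_table(candidates: Iterable[SnpCandidate], path) -> None:
    with open(path, "w") as fh:
        fh.write("# columns are 0-based alignment coordinates\n")
        fh.write("contig_id\tcolumn\tref_allele\talt_allele\tcounts\t"
                 "passes_filter\tclass\n")
        for c in candidates:
            ref, alt = _major_minor(c)
            counts = ",".join(f"{b}:{c.allele_counts[b]}"
                              for b in _ALLELES if b in c.allele_counts)
            fh.write(f"{c.contig_id}\t{c.column}\t{ref}\t{alt}\t{counts}\t"
                     f"{int(c.passes_filter)}\t{c.substitution_class}\n")


def write_vcf_like(candidates: Iterable[SnpCandidate], path) -> None:
    """Minimal VCF-like export; POS is 1-based (shifted from internal columns)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2-minimal\n")
        fh.write("##INFO=positions are 1-based, shifted from 0-based columns\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\n")
        for c in candidates:
            ref, alt = _major_minor(c)
            fh.write(f"{c.contig_id}\t{c.column + 1}\t.\t{ref}\t{alt}\n")
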