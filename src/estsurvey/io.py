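"""File formats shared across the pipeline.

FASTQ (Phred+33), FASTA and FASTA+QUAL go through Biopython for parsing;
FASTQ writing is done directly so output is byte-identical for a given seed
and configuration.  Qualities above ``max_q`` (60 by default, the Sanger
contract) are rejected with the offending read and position.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml
from Bio import SeqIO
from Bio.SeqIO.QualityIO import PairedFastaQualIterator

from .trim import ReadRecord

__all__ = [
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "read_fasta_qual",
    "read_config",
    "write_manifest",
    "write_trim_report",
    "write_truth",
    "write_ssr_table",
]

MAX_QUALITY = 60


def _check_quals(read_id: str, quals, max_q: int) -> np.ndarray:
    q = np.asarray(quals, dtype=np.int64)
    bad = np.flatnonzero((q < 0) | (q > max_q))
    if bad.size:
        raise ValueError(
            f"{read_id}: quality {int(q[bad[0]])} at position {int(bad[0])} "
            f"outside [0, {max_q}]"
        )
    return q


def read_fastq(path: str | Path, max_q: int = MAX_QUALITY) -> list[ReadRecord]:
    """Parse Phred+33 FASTQ into ReadRecords (kept = full read)."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        q = _check_quals(rec.id, rec.letter_annotations["phred_quality"], max_q)
        out.append(ReadRecord(rec.id, str(rec.seq), q))
    return out


def write_fastq(records: Iterable[ReadRecord], path: str | Path,
                use_kept: bool = False) -> None:
    """Write Phred+33 FASTQ; with ``use_kept`` only the kept slice is emitted."""
    with open(path, "w") as fh:
        for r in records:
            s, e = r.kept if use_kept else (0, len(r.bases))
            if e <= s:
                continue
            qline = "".join(chr(int(q) + 33) for q in r.quals[s:e])
            fh.write(f"@{r.read_id}\n{r.bases[s:e]}\n+\n{qline}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta_qual(fasta_path: str | Path, qual_path: str | Path,
                    max_q: int = MAX_QUALITY) -> list[ReadRecord]:
    """Parse a FASTA + QUAL pair into ReadRecords."""
    out = []
    with open(fasta_path) as ffh, open(qual_path) as qfh:
        for rec in PairedFastaQualIterator(ffh, qfh):
            q = _check_quals(rec.id, rec.letter_annotations["phred_quality"], max_q)
            out.append(ReadRecord(rec.id, str(rec.seq), q))
    return out


def read_config(path: str | Path, known_keys: Iterable[str] | None = None) -> dict:
    """Load a key-value YAML config; unknown keys are rejected by name."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a key-value mapping")
    if known_keys is not None:
        unknown = sorted(set(cfg) - set(known_keys))
        if unknown:
            raise ValueError(f"{path}: unknown config keys: {', '.join(unknown)}")
    return cfg


def write_manifest(path: str | Path, config: Mapping) -> None:
    """Echo every resolved parameter into a JSON run manifest."""
    from . import __version__

    payload = {"artifact_version": __version__, "parameters": dict(config)}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def write_trim_report(reads: Iterable[ReadRecord], passed: Mapping[str, bool],
                      path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# kept coordinates are 0-based, half-open\n")
        fh.write("read_id\traw_len\tkept_start\tkept_end\tpassed\n")
        for r in reads:
            fh.write(f"{r.read_id}\t{len(r.bases)}\t{r.kept[0]}\t{r.kept[1]}\t"
                     f"{int(passed[r.read_id])}\n")


def write_truth(truth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# true_start/true_end and tx_start are 0-based, half-open\n")
        truth.to_csv(fh, sep="\t", index=False)


def write_ssr_table(records, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# start/end are 0-based, half-open\n")
        fh.write("seq_id\tstart\tend\tunit\tcanonical_motif\tunit_length\t"
                 "tract_length\tregion\n")
        for r in records:
            fh.write(f"{r.seq_id}\t{r.start}\t{r.end}\t{r.unit}\t"
                     f"{r.canonical_motif}\t{r.unit_length}\t{r.tract_length}\t"
                     f"{r.region if r.region is not None else 'NA'}\n")
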