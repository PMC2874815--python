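"""Synthetic EST survey generator.

Builds a transcriptome with skewed (lognormal) transcript abundances, two
haplotypes per gene carrying planted SNPs, embedded microsatellite tracts,
and per-gene CDS coordinates; models duplex-specific-nuclease (DSN) cDNA
normalization as ideal second-order reassociation kinetics; and samples
5'-anchored single-pass reads with position-dependent quality decay and
quality-consistent substitution errors.  Every downstream stage of the
package can therefore be exercised against known truth.

The DSN model: after denaturation and reassociation for a composite exposure
theta = k*C0*t, the single-stranded (surviving) fraction of a transcript with
abundance share p_i is 1/(1 + theta*p_i) — abundant species reassociate
first and are degraded.  The surviving shares are renormalized.  theta is
not measured; it is calibrated against an observed fold-reduction of a
dominant transcript (e.g. the 40-fold reduction of rhodopsin duplicates
observed on library filters).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .trim import ReadRecord, TrimPolicy, trim_read

__all__ = [
    "DsnParams",
    "ReadModel",
    "PlantedSsr",
    "PlantedSnp",
    "TranscriptomeModel",
    "sample_abundances",
    "dsn_normalize",
    "calibrate_theta",
    "build_transcriptome",
    "simulate_reads",
    "expected_distinct",
    "alignments_from_truth",
    "synthetic_protein_hits",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# primitive repeat units (minimal period == unit length), used for planting
_SSR_MOTIFS = {
    2: ("AC", "AG", "AT", "CG"),
    3: ("AAT", "AAG", "ACT", "AGG"),
    4: ("AAAT", "AAGT", "ACCT", "AGAT"),
}


@dataclass(frozen=True)
class DsnParams:
    """Composite second-order reassociation exposure theta = k*C0*t.

    theta = 0 means no normalization.
    """

    theta: float

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be >= 0")


@dataclass(frozen=True)
class ReadModel:
    """Single-pass 5' Sanger read model.

    Reads start near the transcript 5' end (geometric offset), have normal
    lengths clipped to [len_min, len_max], and carry Phred qualities
    Q(pos) = q_start - q_slope*pos + noise clipped to [q_min, q_max].
    Substitution errors are injected per base with probability 10**(-Q/10).
    """

    len_mean: float = 600.0
    len_sd: float = 100.0
    len_min: int = 100
    len_max: int = 800
    start_geom_p: float = 0.5
    q_start: float = 45.0
    q_slope: float = 0.04
    q_noise_sd: float = 2.0
    q_min: int = 2
    q_max: int = 60

    def __post_init__(self) -> None:
        if not (1 <= self.len_min <= self.len_max):
            raise ValueError("require 1 <= len_min <= len_max")
        if not (0 < self.start_geom_p <= 1):
            raise ValueError("start_geom_p must be in (0, 1]")
        if not (0 <= self.q_min <= self.q_max <= 60):
            raise ValueError("quality bounds must satisfy 0 <= q_min <= q_max <= 60")


@dataclass(frozen=True)
class PlantedSsr:
    gene: int
    offset: int
    motif: str
    length: int


@dataclass(frozen=True)
class PlantedSnp:
    gene: int
    offset: int
    allele_a: str
    allele_b: str
    hap_b_freq: float


@dataclass
class TranscriptomeModel:
    """A two-haplotype transcriptome with known planted features.

    ``sequences[g]`` holds the (haplotype A, haplotype B) nucleotide strings
    of gene g; the haplotypes differ only at planted SNP offsets.  ``cds[g]``
    is the 0-based half-open CDS interval on the transcript.
    """

    sequences: list[tuple[str, str]]
    abundances: np.ndarray
    planted_ssrs: list[PlantedSsr] = field(default_factory=list)
    planted_snps: list[PlantedSnp] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if len(self.sequences) != self.abundances.size:
            raise ValueError("one abundance per gene required")
        if np.any(self.abundances < 0):
            raise ValueError("abundances must be non-negative")
        if self.abundances.size and abs(self.abundances.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")

    @property
    def n_genes(self) -> int:
        return len(self.sequences)

    def hap_b_freq(self, gene: int) -> float:
        for snp in self.planted_snps:
            if snp.gene == gene:
                return snp.hap_b_freq
        return 0.5


def sample_abundances(
    n_genes: int, log_mean: float = 0.0, log_sd: float = 2.0, seed: int = 0
) -> np.ndarray:
    """Lognormal relative abundances, normalized to sum to 1.

    log_sd = 0 yields a uniform profile; larger values skew expression the
    way bulk cDNA libraries do.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if log_sd < 0:
        raise ValueError("log_sd must be >= 0")
    rng = np.random.default_rng(seed)
    x = rng.lognormal(log_mean, log_sd, n_genes)
    return x / x.sum()


def _theta_of(params) -> float:
    return params.theta if isinstance(params, DsnParams) else float(params)


def dsn_normalize(p: Sequence[float], params: DsnParams | float) -> np.ndarray:
    """Apply the second-order reassociation survivor model and renormalize.

    q_i ∝ p_i / (1 + theta*p_i).  Preserves rank order, never increases the
    max/min spread, and flattens toward uniform as theta -> infinity.
    """
    theta = _theta_of(params)
    if theta < 0:
        raise ValueError("theta must be >= 0")
    p = np.asarray(p, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("abundances must sum to 1")
    q = p / (1.0 + theta * p)
    return q / q.sum()


def _post_share(p: np.ndarray, gene: int, theta: float) -> float:
    q = p / (1.0 + theta * p)
    return float(q[gene] / q.sum())


def calibrate_theta(
    p: Sequence[float], gene: int, target_fold: float
) -> DsnParams:
    """Find theta so normalization reduces one gene's share by target_fold.

    Monotone 1-D root find on the bracket [0, 1e12].  As theta -> infinity
    the profile flattens to uniform, so the largest achievable fold for the
    gene is n_genes * p[gene]; larger requests raise ValueError.
    """
    p = np.asarray(p, dtype=float)
    if not (0 <= gene < p.size):
        raise ValueError("gene index out of range")
    if target_fold < 1:
        raise ValueError("target_fold must be >= 1")
    if target_fold == 1:
        return DsnParams(0.0)
    share0 = float(p[gene])
    limit = share0 * p.size
    target_share = share0 / target_fold
    if target_share <= 1.0 / p.size:
        raise ValueError(
            f"target fold {target_fold:g} unreachable: flattening limit for this "
            f"gene is {limit:g}-fold (share tends to 1/{p.size} as theta grows)"
        )
    theta = brentq(
        lambda th: _post_share(p, gene, th) - target_share,
        0.0,
        1e12,
        xtol=1e-12,
        rtol=1e-14,
        maxiter=200,
    )
    return DsnParams(float(theta))


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, length)]


def build_transcriptome(
    n_genes: int = 2000,
    mean_len: float = 900.0,
    len_sd: float = 250.0,
    min_len: int = 300,
    log_mean: float = 0.0,
    log_sd: float = 2.0,
    ssr_fraction: float = 0.25,
    min_ssr_len: int = 24,
    snps_per_gene: float = 1.0,
    hap_b_freq: float = 0.5,
    transition_prob: float = 0.5,
    seed: int = 0,
) -> TranscriptomeModel:
    """Build a random transcriptome with planted SSRs and SNPs.

    Each gene gets a CDS occupying roughly the middle 60% of the transcript
    (a 5'UTR of ~15% and a 3'UTR of ~25%).  SSR tracts are exact tandem
    repeats of primitive 2-4 bp units, planted with flank guards so the
    planted coordinates are the maximal tract, in the 5'UTR, ORF or 3'UTR
    with weights 0.30/0.24/0.46.  SNPs separate the two haplotypes; allele B
    is a transition with probability ``transition_prob``, otherwise a random
    transversion.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(log_mean, log_sd, n_genes)
    abundances = raw / raw.sum()

    sequences: list[tuple[str, str]] = []
    cds: list[tuple[int, int]] = []
    planted_ssrs: list[PlantedSsr] = []
    planted_snps: list[PlantedSnp] = []
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}

    for g in range(n_genes):
        length = int(max(min_len, rng.normal(mean_len, len_sd)))
        seq = _random_seq(rng, length)
        utr5 = max(10, int(0.15 * length))
        orf = max(30, int(0.60 * length))
        cds_iv = (utr5, min(utr5 + orf, length - 10))
        cds.append(cds_iv)

        blocked: list[tuple[int, int]] = []
        if rng.random() < ssr_fraction:
            unit_len = int(rng.integers(2, 5))
            motif = _SSR_MOTIFS[unit_len][rng.integers(0, len(_SSR_MOTIFS[unit_len]))]
            reps = math.ceil(min_ssr_len / unit_len) + int(rng.integers(0, 5))
            tract_len = reps * unit_len
            region = rng.choice(3, p=[0.30, 0.24, 0.46])
            lo, hi = [(1, cds_iv[0]), cds_iv, (cds_iv[1], length - 1)][region]
            if hi - lo > tract_len + 2:
                off = int(rng.integers(lo + 1, hi - tract_len - 1))
                tract = (motif * reps).encode("ascii")
                seq[off : off + tract_len] = np.frombuffer(tract, dtype=np.uint8)
                # flank guards: break period-u extension on both sides
                for pos, ref in ((off - 1, seq[off - 1 + unit_len]),
                                 (off + tract_len, seq[off + tract_len - unit_len])):
                    if seq[pos] == ref:
                        choices = _BASES[_BASES != ref]
                        seq[pos] = choices[rng.integers(0, choices.size)]
                planted_ssrs.append(PlantedSsr(g, off, motif, tract_len))
                blocked.append((off - 1, off + tract_len + 1))

        hap_a = seq
        hap_b = seq.copy()
        n_snps = rng.poisson(snps_per_gene)
        offsets = set()
        for _ in range(n_snps):
            off = int(rng.integers(0, length))
            if off in offsets or any(a <= off < b for a, b in blocked):
                continue
            offsets.add(off)
            allele_a = chr(hap_a[off])
            if rng.random() < transition_prob:
                allele_b = transitions[allele_a]
            else:
                tv = [b for b in "ACGT" if b != allele_a and b != transitions[allele_a]]
                allele_b = tv[rng.integers(0, len(tv))]
            hap_b[off] = ord(allele_b)
            planted_snps.append(PlantedSnp(g, off, allele_a, allele_b, hap_b_freq))
        sequences.append(
            (hap_a.tobytes().decode("ascii"), hap_b.tobytes().decode("ascii"))
        )

    return TranscriptomeModel(sequences, abundances, planted_ssrs, planted_snps, cds)


def simulate_reads(
    model: TranscriptomeModel,
    read_model: ReadModel = ReadModel(),
    n_reads: int = 1000,
    seed: int = 0,
    trim_policy: TrimPolicy = TrimPolicy(),
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Sample 5'-anchored reads; returns (reads, truth table).

    The truth table has one row per read: read_id, gene_id, haplotype
    (a/b), true_start/true_end (the default-policy trim interval on the
    read, 0-based half-open), tx_start (read start on the transcript) and
    read_len.  A single seeded generator drives all sampling, so the same
    seed and configuration reproduce the reads byte for byte.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if model.n_genes == 0:
        raise ValueError("empty transcriptome")
    rng = np.random.default_rng(seed)
    rm = read_model
    genes = rng.choice(model.n_genes, size=n_reads, p=model.abundances)
    hap_freqs = np.array([model.hap_b_freq(g) for g in range(model.n_genes)])

    reads: list[ReadRecord] = []
    rows = []
    for i in range(n_reads):
        g = int(genes[i])
        hap_b = rng.random() < hap_freqs[g]
        seq = model.sequences[g][1 if hap_b else 0]
        tlen = len(seq)
        start = int(rng.geometric(rm.start_geom_p)) - 1
        start = min(start, max(tlen - rm.len_min, 0))
        length = int(np.clip(round(rng.normal(rm.len_mean, rm.len_sd)),
                             rm.len_min, rm.len_max))
        length = min(length, tlen - start)
        frag = np.frombuffer(seq[start : start + length].encode("ascii"), np.uint8).copy()

        q = rm.q_start - rm.q_slope * np.arange(length) + rng.normal(
            0.0, rm.q_noise_sd, length
        )
        q = np.clip(np.rint(q), rm.q_min, rm.q_max).astype(np.int64)
        err = 10.0 ** (-q / 10.0)
        hit = np.flatnonzero(rng.random(length) < err)
        for j in hit:
            choices = _BASES[_BASES != frag[j]]
            frag[j] = choices[rng.integers(0, choices.size)]

        rid = f"r{i:06d}"
        read = ReadRecord(rid, frag.tobytes().decode("ascii"), q)
        ts, te = trim_read(read, trim_policy).kept
        reads.append(read)
        rows.append((rid, g, "b" if hap_b else "a", ts, te, start, length))

    truth = pd.DataFrame(
        rows,
        columns=["read_id", "gene_id", "haplotype", "true_start", "true_end",
                 "tx_start", "read_len"],
    )
    return reads, truth


def expected_distinct(p: Sequence[float], n_reads: int) -> float:
    """Expected number of distinct genes in n reads: sum_i 1 - (1-p_i)^n."""
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    p = np.asarray(p, dtype=float)
    return float(np.sum(1.0 - (1.0 - p) ** n_reads))


def alignments_from_truth(
    reads: Sequence[ReadRecord],
    truth: pd.DataFrame,
    model: TranscriptomeModel,
    use_kept: bool = True,
) -> dict[int, tuple[list[str], list[str]]]:
    """Positionally align simulated reads on their source transcripts.

    Simulated reads carry no indels, so a multiple alignment of a cluster is
    obtained by padding each read to transcript coordinates with gaps.
    Returns gene -> (read_ids, aligned rows of equal length).  With
    ``use_kept`` only the kept (trimmed) slice of each read is placed.
    """
    by_id = {r.read_id: r for r in reads}
    out: dict[int, tuple[list[str], list[str]]] = {}
    for gene, grp in truth.groupby("gene_id"):
        tlen = len(model.sequences[int(gene)][0])
        ids, rows_al = [], []
        for row in grp.itertuples(index=False):
            read = by_id[row.read_id]
            s, e = (row.true_start, row.true_end) if use_kept else (0, row.read_len)
            if e <= s:
                continue
            left = row.tx_start + s
            chunk = read.bases[s:e]
            rows_al.append("-" * left + chunk + "-" * (tlen - left - len(chunk)))
            ids.append(read.read_id)
        if ids:
            out[int(gene)] = (ids, rows_al)
    return out


def synthetic_protein_hits(
    truth: pd.DataFrame, model: TranscriptomeModel
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit a synthetic 12-column protein hit table for simulated reads.

    Each gene's CDS is treated as coding for a protein of length ORF/3; a
    read hits that protein over the amino-acid span its transcript footprint
    covers.  Reads not overlapping the CDS produce no hit.  Returns
    (hits, subject lengths) as DataFrames matching the standard tabular hit
    columns and the companion (subject_id, length) table.
    """
    hit_rows, lens = [], {}
    for row in truth.itertuples(index=False):
        g = int(row.gene_id)
        cs, ce = model.cds[g]
        plen = max(1, (ce - cs) // 3)
        subject = f"P{g:05d}"
        lens[subject] = plen
        a = row.tx_start
        b = row.tx_start + row.read_len
        lo, hi = max(a, cs), min(b, ce)
        if hi - lo < 30:  # too little coding overlap for a credible hit
            continue
        sstart = (lo - cs) // 3 + 1
        send = min(plen, (hi - cs) // 3)
        if send < sstart:
            continue
        aln = send - sstart + 1
        hit_rows.append(
            (row.read_id, subject, 98.0, aln, 0, 0, lo - a + 1, hi - a,
             sstart, send, 1e-50, 2.0 * aln)
        )
    hits = pd.DataFrame(
        hit_rows,
        columns=["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                 "qstart", "qend", "sstart", "send", "evalue", "bitscore"],
    )
    lengths = pd.DataFrame(
        sorted(lens.items()), columns=["subject_id", "length"]
    )
    return hits, lengths
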