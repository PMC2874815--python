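"""Library coverage and gene-discovery statistics for EST surveys.

For a library of n reads clustering into d distinct sequences, the empirical
coverage is 1 - d/n and the discovery rate (reads consumed per new sequence)
is n/d = 1/(1 - coverage).  The Good-Turing (Susko-Roger) estimator instead
uses the singleton count n1: coverage ~= 1 - n1/n, the estimated probability
that the next read resamples an already-seen gene.  Both are exposed; the
empirical form is the default because it is the one printed in per-library
clustering summaries.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import pandas as pd

from .cluster import ClusterAssignment, LibrarySummary

__all__ = [
    "coverage_empirical",
    "coverage_good_turing",
    "discovery_rate",
    "discovery_curve",
    "fold_reduction",
    "library_report",
    "write_report",
    "plot_discovery_curves",
]


def coverage_empirical(n: int, d: int) -> float:
    """Coverage 1 - d/n from read and distinct-sequence counts."""
    if not (n >= d >= 1):
        raise ValueError("require n >= d >= 1")
    return 1.0 - d / n


def coverage_good_turing(n: int, n1: int) -> float:
    """Good-Turing coverage 1 - n1/n from the singleton count."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= n1 <= n):
        raise ValueError("require 0 <= n1 <= n")
    return 1.0 - n1 / n


def discovery_rate(n: int, d: int) -> float:
    """Reads consumed per newly discovered sequence: n/d."""
    if d < 1:
        raise ValueError("d must be >= 1")
    if n < d:
        raise ValueError("require n >= d")
    return n / d


def discovery_curve(assignment: ClusterAssignment) -> list[tuple[int, float]]:
    """Discovery rate after each sequencing round, on the cumulative read set.

    Every read must carry a round tag; rounds are ordered numerically when
    possible, lexicographically otherwise.  Returns a series of
    (cumulative reads, discovery rate) points.
    """
    if not assignment.rounds:
        raise ValueError("assignment carries no round tags")
    untagged = set(assignment.clusters) - set(assignment.rounds)
    if untagged:
        raise ValueError(f"{len(untagged)} reads lack a round tag")

    tags = set(assignment.rounds.values())
    try:
        ordered = sorted(tags, key=lambda t: (0, float(t)))
    except ValueError:
        ordered = sorted(tags)

    points = []
    cum_reads = 0
    seen: set[int] = set()
    for tag in ordered:
        rids = [r for r, t in assignment.rounds.items() if t == tag]
        cum_reads += len(rids)
        seen.update(assignment.clusters[r] for r in rids)
        points.append((cum_reads, discovery_rate(cum_reads, len(seen))))
    return points


def fold_reduction(pos_a: int, tot_a: int, pos_b: int, tot_b: int) -> float:
    """Ratio of positive-clone frequencies before (a) and after (b) normalization."""
    if min(pos_a, pos_b) < 0 or min(tot_a, tot_b) < 1:
        raise ValueError("counts must be non-negative with totals >= 1")
    if pos_b == 0:
        warnings.warn("no positives after normalization: fold reduction is infinite")
        return float("inf")
    return (pos_a / tot_a) / (pos_b / tot_b)


def library_report(
    summaries: Sequence[LibrarySummary], estimator: str = "empirical"
) -> pd.DataFrame:
    """One row per library with full-precision coverage and discovery.

    estimator="empirical" uses (n, d); "good_turing" uses (n, n1) and its
    induced discovery rate n/n1.
    """
    if not summaries:
        raise ValueError("no library summaries")
    if estimator not in ("empirical", "good_turing"):
        raise ValueError(f"unknown estimator {estimator!r}")
    rows = []
    for s in summaries:
        if estimator == "empirical":
            cov = coverage_empirical(s.n, s.d)
        else:
            cov = coverage_good_turing(s.n, s.n1)
        disc = 1.0 / (1.0 - cov)
        rows.append((s.library, s.n, s.contigs, s.n1, s.d, cov, disc))
    return pd.DataFrame(
        rows,
        columns=["library", "hq_ests", "contigs", "singletons", "total",
                 "coverage", "discovery"],
    )


def write_report(report: pd.DataFrame, path) -> None:
    """Write the report TSV, coverage to 4 and discovery to 3 decimals."""
    out = report.copy()
    out["coverage"] = [f"{round(v, 4):.4f}" for v in out["coverage"]]
    out["discovery"] = [f"{round(v, 3):.3f}" for v in out["discovery"]]
    with open(path, "w") as fh:
        fh.write("# per-library clustering and redundancy statistics\n")
        out.to_csv(fh, sep="\t", index=False)


def plot_discovery_curves(
    curves: dict[str, Iterable[tuple[int, float]]], path
) -> None:
    """Plot reads vs reads-per-discovery for each library."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, pts in sorted(curves.items()):
        pts = list(pts)
        ax.plot([x for x, _ in pts], [y for _, y in pts], marker="o", label=name)
    ax.set_xlabel("sequence reads")
    ax.set_ylabel("reads per discovery")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
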