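"""End-to-end survey pipeline: simulate -> trim -> cluster -> stats ->
completeness -> ssr -> snp.

Each stage reads and writes plain-text artifacts in an output directory, so
any contiguous subset of stages can be re-run.  A JSON manifest echoing the
resolved configuration is written on every run; the same configuration and
seed reproduce every artifact byte for byte.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import cluster as clu
from . import completeness as comp
from . import io as eio
from . import redundancy as red
from . import simulate as sim
from . import snp as snpmod
from . import ssr as ssrmod
from . import trim as trm

logger = logging.getLogger("estsurvey")

STAGES = ("simulate", "trim", "cluster", "stats", "completeness", "ssr", "snp")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    # transcriptome
    "n_genes": 2000,
    "mean_len": 900.0,
    "log_sd": 2.0,
    "ssr_fraction": 0.25,
    "snps_per_gene": 1.0,
    "hap_b_freq": 0.5,
    # normalization (DSN kinetics); fold calibrated on the most abundant gene
    "normalize": True,
    "target_fold": 40.0,
    # reads
    "n_reads": 3000,
    "read_len_mean": 600.0,
    "read_len_sd": 100.0,
    # trimming
    "bracket_max_error": 0.001,
    "window_len": 10,
    "window_max_avg_error": 0.063,
    "pass_min_len": 100,
    "pass_min_avg_q": 20.0,
    # clustering
    "k": 16,
    "min_shared": 3,
    "round_size": 1000,
    # ssr / snp
    "ssr_min_len": 24,
    "snp_min_count": 2,
    "library": "synthetic",
}


def resolve_config(overrides: dict | None = None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if overrides:
        unknown = sorted(set(overrides) - set(DEFAULT_CONFIG))
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg


def _policy(cfg: dict) -> trm.TrimPolicy:
    return trm.TrimPolicy(
        bracket_max_error=cfg["bracket_max_error"],
        windows=((int(cfg["window_len"]), float(cfg["window_max_avg_error"])),),
        pass_min_len=int(cfg["pass_min_len"]),
        pass_min_avg_q=float(cfg["pass_min_avg_q"]),
    )


def stage_simulate(cfg: dict, out: Path) -> None:
    model = sim.build_transcriptome(
        n_genes=int(cfg["n_genes"]),
        mean_len=float(cfg["mean_len"]),
        log_sd=float(cfg["log_sd"]),
        ssr_fraction=float(cfg["ssr_fraction"]),
        min_ssr_len=int(cfg["ssr_min_len"]),
        snps_per_gene=float(cfg["snps_per_gene"]),
        hap_b_freq=float(cfg["hap_b_freq"]),
        seed=int(cfg["seed"]),
    )
    if cfg["normalize"]:
        top = int(model.abundances.argmax())
        params = sim.calibrate_theta(model.abundances, top, float(cfg["target_fold"]))
        model.abundances = sim.dsn_normalize(model.abundances, params)
        logger.info("DSN calibration: theta=%.4g for %.1f-fold on gene %d",
                    params.theta, cfg["target_fold"], top)
    rm = sim.ReadModel(len_mean=float(cfg["read_len_mean"]),
                       len_sd=float(cfg["read_len_sd"]))
    reads, truth = sim.simulate_reads(model, rm, int(cfg["n_reads"]),
                                      seed=int(cfg["seed"]),
                                      trim_policy=_policy(cfg))
    eio.write_fastq(reads, out / "reads.fastq")
    eio.write_truth(truth, out / "truth.tsv")
    eio.write_fasta({f"g{i:05d}": model.sequences[i][0]
                     for i in range(model.n_genes)}, out / "transcripts.fasta")
    with open(out / "cds.tsv", "w") as fh:
        fh.write("# CDS coordinates, 0-based half-open\nseq_id\tcds_start\tcds_end\n")
        for i, (cs, ce) in enumerate(model.cds):
            fh.write(f"g{i:05d}\t{cs}\t{ce}\n")
    hits, lengths = sim.synthetic_protein_hits(truth, model)
    hits.to_csv(out / "hits.tsv", sep="\t", index=False, header=False)
    lengths.to_csv(out / "protein_lengths.tsv", sep="\t", index=False, header=False)
    with open(out / "planted.tsv", "w") as fh:
        fh.write("# planted truth: SSR tracts and SNPs, 0-based\n")
        fh.write("kind\tgene\toffset\tdetail\tlength_or_freq\n")
        for t in model.planted_ssrs:
            fh.write(f"ssr\t{t.gene}\t{t.offset}\t{t.motif}\t{t.length}\n")
        for v in model.planted_snps:
            fh.write(f"snp\t{v.gene}\t{v.offset}\t{v.allele_a}>{v.allele_b}\t"
                     f"{v.hap_b_freq}\n")


def stage_trim(cfg: dict, out: Path) -> None:
    policy = _policy(cfg)
    reads = eio.read_fastq(out / "reads.fastq")
    trimmed = [trm.trim_read(r, policy) for r in reads]
    passed = {r.read_id: trm.passes_quality(r, policy) for r in trimmed}
    eio.write_trim_report(trimmed, passed, out / "trim_report.tsv")
    keepers = [r for r in trimmed if passed[r.read_id]]
    eio.write_fastq(keepers, out / "trimmed.fastq", use_kept=True)
    logger.info("trim: %d/%d reads pass (%.1f%%)", len(keepers), len(reads),
                100.0 * len(keepers) / max(1, len(reads)))


def stage_cluster(cfg: dict, out: Path) -> None:
    reads = eio.read_fastq(out / "trimmed.fastq")
    assignment = clu.cluster_reads(
        {r.read_id: r.bases for r in reads},
        k=int(cfg["k"]), min_shared=int(cfg["min_shared"]),
    )
    rs = int(cfg["round_size"])
    ordered = sorted(assignment.clusters)
    assignment.rounds = {rid: str(i // rs + 1) for i, rid in enumerate(ordered)}
    clu.write_membership(assignment, out / "membership.tsv")


def stage_stats(cfg: dict, out: Path) -> None:
    assignment = clu.read_membership(out / "membership.tsv")
    summary = clu.summarize(assignment, library=str(cfg["library"]))
    report = pd.concat([
        red.library_report([summary], estimator="empirical"),
        red.library_report([summary], estimator="good_turing"),
    ])
    report.insert(1, "estimator", ["empirical", "good_turing"])
    red.write_report(report, out / "redundancy_report.tsv")
    curve = red.discovery_curve(assignment)
    with open(out / "discovery_curve.tsv", "w") as fh:
        fh.write("# cumulative reads vs reads-per-discovery\n")
        fh.write("cumulative_reads\tdiscovery\n")
        for n, rate in curve:
            fh.write(f"{n}\t{round(rate, 3):.3f}\n")


def stage_completeness(cfg: dict, out: Path) -> None:
    hits = comp.read_tabular_hits(out / "hits.tsv", out / "protein_lengths.tsv")
    calls = comp.call_hits(hits)
    props, totals, both = comp.completeness_table(calls)
    comp.write_completeness_table(props, totals, both, out / "completeness.tsv")


def stage_ssr(cfg: dict, out: Path) -> None:
    seqs = eio.read_fasta(out / "transcripts.fasta")
    cds = pd.read_csv(out / "cds.tsv", sep="\t", comment="#")
    cds_map = {r.seq_id: (int(r.cds_start), int(r.cds_end))
               for r in cds.itertuples()}
    records = []
    for name in seqs:
        for rec in ssrmod.find_ssrs(seqs[name], seq_id=name,
                                    min_len=int(cfg["ssr_min_len"])):
            if name in cds_map:
                rec.region = ssrmod.classify_region(rec, *cds_map[name],
                                                    seq_length=len(seqs[name]))
            records.append(rec)
    eio.write_ssr_table(records, out / "ssr.tsv")
    summary = ssrmod.ssr_summary(records)
    with open(out / "ssr_summary.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        for u, c in summary.by_unit_length.items():
            fh.write(f"unit_{u}\t{c}\n")
        for m, c in summary.by_motif.items():
            fh.write(f"motif_{m}\t{c}\n")
        fh.write(f"total\t{summary.total}\n")


def stage_snp(cfg: dict, out: Path) -> None:
    reads = eio.read_fastq(out / "reads.fastq")
    truth = pd.read_csv(out / "truth.tsv", sep="\t", comment="#")
    report = pd.read_csv(out / "trim_report.tsv", sep="\t", comment="#")
    kept = {r.read_id: (int(r.kept_start), int(r.kept_end))
            for r in report.itertuples()}
    for r in reads:
        r.kept = kept.get(r.read_id, (0, len(r.bases)))
    # rebuild a pseudo-transcriptome length table from truth spans
    tlen = truth.groupby("gene_id").apply(
        lambda g: int((g.tx_start + g.read_len).max()), include_groups=False)
    candidates = []
    by_id = {r.read_id: r for r in reads}
    for gene, grp in truth.groupby("gene_id"):
        width = int(tlen[gene])
        rows, depth = [], 0
        for row in grp.itertuples(index=False):
            r = by_id[row.read_id]
            s, e = r.kept
            if e <= s:
                continue
            left = row.tx_start + s
            rows.append("-" * left + r.bases[s:e] + "-" * (width - left - (e - s)))
            depth += 1
        if depth >= 2:
            candidates.extend(
                snpmod.call_variant_columns(rows, contig_id=f"g{gene:05d}"))
    filtered = snpmod.apply_min_count_filter(candidates,
                                             min_count=int(cfg["snp_min_count"]))
    snpmod.write_snp_table(filtered, out / "snp.tsv")
    snpmod.write_vcf_like(filtered, out / "snp.vcf")
    s = snpmod.tstv_summary(filtered)
    with open(out / "tstv_summary.tsv", "w") as fh:
        fh.write("n_candidates\tn_filtered\tn_transition\tn_transversion\t"
                 "n_multiallelic\tfraction_transition\n")
        frac = "NA" if s.fraction_transition is None else f"{s.fraction_transition:.4f}"
        fh.write(f"{len(candidates)}\t{len(filtered)}\t{s.n_transition}\t"
                 f"{s.n_transversion}\t{s.n_multiallelic}\t{frac}\n")


_STAGE_FN = {
    "simulate": stage_simulate,
    "trim": stage_trim,
    "cluster": stage_cluster,
    "stats": stage_stats,
    "completeness": stage_completeness,
    "ssr": stage_ssr,
    "snp": stage_snp,
}


def run_pipeline(config: dict | None, outdir: str | Path,
                 stages: list[str] | None = None) -> dict:
    """Run the selected stages in order; returns the resolved config.

    Raises at the first failing stage, naming it.
    """
    cfg = resolve_config(config)
    stages = list(stages) if stages else list(STAGES)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; expected one of {STAGES}")
    stages = [s for s in STAGES if s in stages]

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    eio.write_manifest(out / "manifest.json", {**cfg, "stages": stages})
    logger.info("run: seed=%s stages=%s", cfg["seed"], ",".join(stages))
    for name in stages:
        logger.info("stage %s", name)
        try:
            _STAGE_FN[name](cfg, out)
        except Exception as exc:
            logger.error("stage %s failed: %s", name, exc)
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    return cfg
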