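import numpy as np
import pytest
from scipy.stats import entropy

from estsurvey import io as eio
from estsurvey.simulate import (
    DsnParams,
    ReadModel,
    TranscriptomeModel,
    alignments_from_truth,
    build_transcriptome,
    calibrate_theta,
    dsn_normalize,
    expected_distinct,
    sample_abundances,
    simulate_reads,
    synthetic_protein_hits,
)


class TestAbundances:
    def test_single_gene(self):
        assert sample_abundances(1, 0.0, 1.0, seed=4).tolist() == [1.0]

    def test_zero_variance_is_uniform(self):
        p = sample_abundances(1000, 0.0, 0.0, seed=4)
        assert np.allclose(p, 1 / 1000)

    def test_normalized_positive_deterministic(self):
        a = sample_abundances(500, 0.0, 1.8, seed=9)
        b = sample_abundances(500, 0.0, 1.8, seed=9)
        assert np.all(a > 0) and abs(a.sum() - 1) < 1e-12
        assert np.array_equal(a, b)

    def test_high_dispersion_gives_heavy_skew(self):
        hits = 0
        for seed in range(20):
            p = sample_abundances(1000, 0.0, 2.0, seed=seed)
            hits += p.max() / np.median(p) > 100
        assert hits >= 18  # skew is the typical outcome, not a fluke

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            sample_abundances(0, 0.0, 1.0, seed=1)
        with pytest.raises(ValueError):
            sample_abundances(10, 0.0, -1.0, seed=1)


class TestDsnNormalize:
    def test_theta_zero_is_identity(self):
        p = sample_abundances(50, 0.0, 1.5, seed=0)
        assert np.allclose(dsn_normalize(p, DsnParams(0.0)), p)

    def test_huge_theta_flattens(self):
        q = dsn_normalize(np.array([0.9, 0.1]), 1e6)
        assert q[0] / q[1] == pytest.approx(1.0, rel=0.01)

    def test_conserves_mass_and_order(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            p = rng.dirichlet(np.full(40, 0.3))
            theta = float(rng.uniform(0, 1e4))
            q = dsn_normalize(p, theta)
            assert abs(q.sum() - 1.0) < 1e-12
            assert np.array_equal(np.argsort(p, kind="stable"),
                                  np.argsort(q, kind="stable"))
            assert q.max() / q.min() <= p.max() / p.min() * (1 + 1e-12)
            assert entropy(q) >= entropy(p) - 1e-12

    def test_rejects_negative_theta(self):
        with pytest.raises(ValueError):
            dsn_normalize(np.array([0.5, 0.5]), -1.0)
        with pytest.raises(ValueError):
            DsnParams(-0.5)


class TestCalibrateTheta:
    def test_fold_one_means_no_normalization(self):
        p = np.array([0.7, 0.3])
        assert calibrate_theta(p, 0, 1.0).theta == 0.0

    def test_two_gene_closed_form(self):
        # fold 1.5 on gene 0 of [0.8, 0.2]: verify by direct evaluation of
        # the survivor ratios p_i/(1 + theta*p_i)
        p = np.array([0.8, 0.2])
        params = calibrate_theta(p, 0, 1.5)
        q = p / (1 + params.theta * p)
        assert q[0] / q.sum() == pytest.approx(0.8 / 1.5, rel=1e-6)

    def test_symmetric_profile_cannot_be_reduced(self):
        with pytest.raises(ValueError, match="unreachable"):
            calibrate_theta(np.array([0.5, 0.5]), 0, 2.0)

    def test_round_trip_across_folds(self):
        # profile with a dominant 10% transcript: flattening limit is 200-fold
        rest = sample_abundances(1999, 0.0, 2.0, seed=2) * 0.9
        p = np.concatenate(([0.1], rest))
        for fold in (1.5, 5.0, 40.0, 100.0):
            q = dsn_normalize(p, calibrate_theta(p, 0, fold))
            assert p[0] / q[0] == pytest.approx(fold, rel=1e-3)

    def test_unreachable_fold_reported(self):
        p = sample_abundances(100, 0.0, 1.0, seed=3)
        with pytest.raises(ValueError, match="unreachable"):
            calibrate_theta(p, int(p.argmax()), 1e6)


class TestTranscriptome:
    def test_haplotypes_differ_only_at_planted_snps(self):
        model = build_transcriptome(n_genes=40, seed=5)
        snp_by_gene = {}
        for s in model.planted_snps:
            snp_by_gene.setdefault(s.gene, set()).add(s.offset)
        for g, (a, b) in enumerate(model.sequences):
            diffs = {i for i in range(len(a)) if a[i] != b[i]}
            assert diffs == snp_by_gene.get(g, set())
        for s in model.planted_snps:
            a, b = model.sequences[s.gene]
            assert a[s.offset] == s.allele_a and b[s.offset] == s.allele_b

    def test_planted_ssrs_are_exact_tandem_repeats(self):
        model = build_transcriptome(n_genes=60, ssr_fraction=1.0, seed=6)
        assert model.planted_ssrs
        for t in model.planted_ssrs:
            seq = model.sequences[t.gene][0]
            tract = seq[t.offset : t.offset + t.length]
            assert t.length >= 24
            assert tract == (t.motif * t.length)[: t.length]

    def test_abundance_invariants_enforced(self):
        with pytest.raises(ValueError):
            TranscriptomeModel([("ACGT", "ACGT")], np.array([0.5]))


class TestSimulateReads:
    def test_single_read_single_gene(self):
        model = TranscriptomeModel([("ACGT" * 100, "ACGT" * 100)], np.array([1.0]))
        reads, truth = simulate_reads(model, ReadModel(), 1, seed=0)
        assert len(reads) == 1 and truth.gene_id.tolist() == [0]

    def test_gene_counts_binomial_bound(self):
        model = build_transcriptome(n_genes=100, mean_len=300, min_len=250,
                                    log_sd=0.0, snps_per_gene=0, ssr_fraction=0,
                                    seed=8)
        rm = ReadModel(len_mean=150, len_sd=20, len_min=80, len_max=220)
        _, truth = simulate_reads(model, rm, 10_000, seed=8)
        counts = truth.gene_id.value_counts().reindex(range(100), fill_value=0)
        sigma = np.sqrt(10_000 * 0.01 * 0.99)
        assert np.all(np.abs(counts.to_numpy() - 100) <= 4 * sigma)

    def test_reproducible_for_fixed_seed(self, tmp_path):
        model = build_transcriptome(n_genes=20, seed=1)
        r1, t1 = simulate_reads(model, ReadModel(), 50, seed=77)
        r2, t2 = simulate_reads(model, ReadModel(), 50, seed=77)
        f1, f2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        eio.write_fastq(r1, f1)
        eio.write_fastq(r2, f2)
        assert f1.read_bytes() == f2.read_bytes()
        assert t1.equals(t2)

    def test_quality_bounds_and_error_rate_contract(self):
        model = build_transcriptome(n_genes=5, snps_per_gene=0, seed=2)
        reads, truth = simulate_reads(model, ReadModel(), 400, seed=3)
        mismatches = expected = total = 0
        for read, row in zip(reads, truth.itertuples(index=False)):
            assert read.quals.min() >= 0 and read.quals.max() <= 60
            src = model.sequences[row.gene_id][0 if row.haplotype == "a" else 1]
            ref = src[row.tx_start : row.tx_start + row.read_len]
            mismatches += sum(a != b for a, b in zip(read.bases, ref))
            err = 10.0 ** (-read.quals / 10.0)
            expected += err.sum()
            total += len(read.bases)
        # observed substitutions ~ Poisson(expected error count)
        assert abs(mismatches - expected) <= 4 * np.sqrt(expected)

    def test_rejects_degenerate_inputs(self):
        model = build_transcriptome(n_genes=3, seed=0)
        with pytest.raises(ValueError):
            simulate_reads(model, ReadModel(), 0, seed=0)
        empty = TranscriptomeModel([], np.array([]))
        with pytest.raises(ValueError):
            simulate_reads(empty, ReadModel(), 1, seed=0)


class TestExpectedDistinct:
    def test_zero_reads(self):
        assert expected_distinct([0.4, 0.6], 0) == 0.0

    def test_one_read_uniform_two_genes(self):
        assert expected_distinct([0.5, 0.5], 1) == pytest.approx(1.0)

    def test_closed_form_uniform_ten(self):
        assert expected_distinct([0.1] * 10, 10) == pytest.approx(6.5132, abs=1e-4)

    def test_monotone_in_reads_and_bounded(self):
        p = sample_abundances(200, 0.0, 1.5, seed=4)
        values = [expected_distinct(p, n) for n in (0, 10, 100, 1000, 10_000)]
        assert all(b >= a for a, b in zip(values, values[1:]))
        assert values[-1] <= 200

    def test_matches_simulation_within_monte_carlo_error(self):
        model = build_transcriptome(n_genes=50, mean_len=300, min_len=250,
                                    log_sd=1.0, snps_per_gene=0, ssr_fraction=0,
                                    seed=10)
        rm = ReadModel(len_mean=150, len_sd=20, len_min=80, len_max=220)
        observed = []
        for seed in range(50):
            _, truth = simulate_reads(model, rm, 200, seed=seed)
            observed.append(truth.gene_id.nunique())
        observed = np.asarray(observed, dtype=float)
        se = observed.std(ddof=1) / np.sqrt(len(observed))
        assert abs(observed.mean() - expected_distinct(model.abundances, 200)) <= 3 * se


class TestTruthDerivedViews:
    def test_alignments_are_rectangular_and_gap_padded(self, survey):
        model, reads, truth = survey["model"], survey["reads"], survey["truth"]
        aligned = alignments_from_truth(reads, truth, model, use_kept=False)
        gene, (ids, rows) = next(iter(aligned.items()))
        assert len({len(r) for r in rows}) == 1
        assert len(ids) == len(rows)

    def test_synthetic_hits_have_valid_coordinates(self, survey):
        from estsurvey.completeness import ProteinHit

        hits, lengths = synthetic_protein_hits(survey["truth"], survey["model"])
        lmap = dict(zip(lengths.subject_id, lengths.length))
        assert len(hits) > 0
        for row in hits.itertuples(index=False):
            ProteinHit(row.qseqid, row.sseqid, row.sstart, row.send,
                       lmap[row.sseqid], row.evalue)  # validates internally
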