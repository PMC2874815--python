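import pytest

from estsurvey.completeness import (
    CLASSES,
    LENGTH_BINS,
    CompletenessCall,
    ProteinHit,
    best_hit_per_query,
    bin_by_length,
    call_hits,
    classify_completeness,
    completeness_table,
    read_tabular_hits,
)


def hit(start, end, length, qid="q", sid="s", evalue=1e-30):
    return ProteinHit(qid, sid, start, end, length, evalue)


class TestClassify:
    def test_full_length_match_is_both(self):
        assert classify_completeness(hit(1, 200, 200)) == "both"

    def test_margin_boundary_five_only(self):
        # start 11 means 10 residues missing: exactly at the margin
        assert classify_completeness(hit(11, 250, 300)) == "five_only"

    def test_one_past_margin_is_incomplete(self):
        assert classify_completeness(hit(12, 289, 300)) == "incomplete"

    def test_three_only(self):
        assert classify_completeness(hit(50, 295, 300)) == "three_only"

    def test_agrees_with_truth_table_over_small_proteins(self):
        margin = 10
        for length in range(1, 41):
            for start in range(1, length + 1):
                for end in range(start, length + 1):
                    five = start <= margin + 1
                    three = end >= length - margin
                    expected = {
                        (True, True): "both",
                        (True, False): "five_only",
                        (False, True): "three_only",
                        (False, False): "incomplete",
                    }[(five, three)]
                    assert classify_completeness(hit(start, end, length)) == expected

    def test_short_protein_full_hit_always_both(self):
        for length in range(1, 22):  # <= 2*margin + 1
            assert classify_completeness(hit(1, length, length)) == "both"

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError):
            hit(0, 10, 20)
        with pytest.raises(ValueError):
            hit(5, 30, 20)


class TestBins:
    @pytest.mark.parametrize(
        "length,label",
        [(1, "<250aa"), (250, "<250aa"), (251, "251-500aa"), (500, "251-500aa"),
         (750, "501-750aa"), (1000, "751-1000aa"), (1001, ">1000aa")],
    )
    def test_boundaries(self, length, label):
        assert bin_by_length(length) == label

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            bin_by_length(0)


class TestBestHit:
    def test_single_hit_returned(self):
        h = hit(1, 10, 100)
        assert best_hit_per_query([h]) == [h]

    def test_lower_evalue_wins(self):
        a = hit(1, 10, 100, evalue=1e-30, sid="s1")
        b = hit(1, 10, 100, evalue=1e-10, sid="s2")
        assert best_hit_per_query([b, a]) == [a]

    def test_evalue_tie_broken_by_coverage_then_name(self):
        wide = hit(1, 90, 100, sid="s2")
        narrow = hit(1, 50, 100, sid="s1")
        assert best_hit_per_query([narrow, wide]) == [wide]
        a = hit(1, 50, 100, sid="sA")
        b = hit(1, 50, 100, sid="sB")
        assert best_hit_per_query([b, a]) == [a]


class TestTable:
    def test_all_both_single_column(self):
        calls = [CompletenessCall(f"q{i}", "both", "<250aa") for i in range(4)]
        props, totals, both = completeness_table(calls)
        assert props.loc["both", "<250aa"] == 1.0
        assert totals["<250aa"] == 4 and both == 1.0

    def test_uniform_classes_quarter_each(self):
        calls = [CompletenessCall(f"q{i}", cls, "501-750aa")
                 for i, cls in enumerate(CLASSES)]
        props, totals, both = completeness_table(calls)
        assert all(props.loc[c, "501-750aa"] == 0.25 for c in CLASSES)
        assert both == 0.25

    def test_columns_sum_to_one(self):
        import numpy as np

        rng = np.random.default_rng(8)
        calls = [
            CompletenessCall(f"q{i}", CLASSES[rng.integers(0, 4)],
                             LENGTH_BINS[rng.integers(0, 5)])
            for i in range(500)
        ]
        props, totals, _ = completeness_table(calls)
        for b in LENGTH_BINS:
            if totals[b]:
                assert props[b].sum() == pytest.approx(1.0, abs=1e-9)

    def test_engineered_counts_recovered(self):
        calls = (
            [CompletenessCall(f"a{i}", "both", "<250aa") for i in range(6)]
            + [CompletenessCall(f"b{i}", "five_only", "<250aa") for i in range(3)]
            + [CompletenessCall(f"c{i}", "incomplete", "<250aa") for i in range(1)]
        )
        props, totals, both = completeness_table(calls)
        assert props.loc["both", "<250aa"] == pytest.approx(0.6)
        assert props.loc["five_only", "<250aa"] == pytest.approx(0.3)
        assert both == pytest.approx(0.6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            completeness_table([])


HIT_LINE = "est1\tP1\t97.5\t120\t3\t0\t1\t360\t5\t124\t1e-45\t250.1"


class TestHitParsing:
    def test_twelve_column_line_preserves_one_based_coords(self, tmp_path):
        hits_file = tmp_path / "hits.tsv"
        hits_file.write_text(HIT_LINE + "\n")
        lengths = tmp_path / "len.tsv"
        lengths.write_text("P1\t200\n")
        parsed = read_tabular_hits(hits_file, lengths)
        assert len(parsed) == 1
        h = parsed[0]
        assert (h.subject_start, h.subject_end, h.subject_length) == (5, 124, 200)
        assert classify_completeness(h) == "five_only"  # 200-124 > 10

    def test_reverse_frame_hits_skipped_with_warning(self, tmp_path):
        hits_file = tmp_path / "hits.tsv"
        hits_file.write_text(
            "est1\tP1\t97\t50\t0\t0\t1\t150\t60\t11\t1e-20\t100\n" + HIT_LINE + "\n"
        )
        lengths = {"P1": 130}
        with pytest.warns(UserWarning, match="reverse-frame"):
            parsed = read_tabular_hits(hits_file, lengths)
        assert len(parsed) == 1

    def test_wrong_column_count_reported(self, tmp_path):
        hits_file = tmp_path / "hits.tsv"
        hits_file.write_text("a\tb\tc\n")
        with pytest.raises(ValueError, match="12 columns"):
            read_tabular_hits(hits_file, {"b": 10})

    def test_call_hits_uses_best_hit_by_default(self, tmp_path):
        hits_file = tmp_path / "hits.tsv"
        hits_file.write_text(
            "est1\tP1\t97\t50\t0\t0\t1\t150\t1\t50\t1e-40\t100\n"
            "est1\tP2\t90\t50\t0\t0\t1\t150\t40\t90\t1e-10\t80\n"
        )
        parsed = read_tabular_hits(hits_file, {"P1": 55, "P2": 300})
        calls = call_hits(parsed)
        assert len(calls) == 1 and calls[0].cls == "both"
        assert len(call_hits(parsed, best_only=False)) == 2
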