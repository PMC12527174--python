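"""Merge rules, four-way classification, summaries, PFM and PSI."""

import math

import pytest

from u1scan.annotation import TranscriptModel
from u1scan.search import RawHit
from u1scan.targetome import (
    TargetHit,
    classify_hits,
    compute_psi,
    merge_hits,
    position_frequency_matrix,
    positional_distribution,
    predict_targetome,
    select_candidate_offtarget_exons,
    summarize,
)


def _raw(tid, t5, register="COM", annealed=11, length=11, query="CAGGTAAGTAT",
         record="rec", category="exon"):
    return RawHit(query, record, tid, category, t5, t5, length, annealed, register)


@pytest.fixture()
def model():
    # + strand, exons 1-100 and 201-300 (pre-mRNA == genomic), donor boundary 100
    return TranscriptModel("t1", "g1", "chr1", "+", [(1, 100), (201, 300)])


class TestMerge:
    def test_same_position_different_registers_merge(self):
        merged = merge_hits([
            _raw("t1", 50, "COM", 11),
            _raw("t1", 50, "BS1", 11, length=12, query="CAGGGTAAGTAT"),
        ])
        assert len(merged) == 1
        assert merged[0].register == "COM"
        assert merged[0].annealed_bases == 11

    def test_same_position_different_transcripts_distinct(self):
        merged = merge_hits([_raw("t1", 50), _raw("t2", 50)])
        assert len(merged) == 2

    def test_cross_database_duplicates_collapse(self):
        merged = merge_hits([
            _raw("t1", 95, record="t1:exon:1", category="exon"),
            _raw("t1", 95, record="t1:donor:1", category="donor_window"),
        ])
        assert len(merged) == 1

    def test_annealed_is_max_over_members(self):
        merged = merge_hits([
            _raw("t1", 50, "BA1", annealed=9, length=10, query="CAGGAAGTAT"),
            _raw("t1", 50, "BS1", annealed=11, length=12, query="CAGGGTAAGTAT"),
        ])
        assert merged[0].annealed_bases == 11
        assert merged[0].register == "BS1"

    def test_idempotent(self):
        raw = [_raw("t1", 50), _raw("t1", 50, "BS1"), _raw("t2", 9)]
        once = merge_hits(raw)
        again = merge_hits([
            RawHit(h.sequence, "x", h.transcript_id, "exon", h.t5, h.t5,
                   h.length, h.annealed_bases, h.register)
            for h in once
        ])
        assert [(h.transcript_id, h.t5) for h in once] == \
               [(h.transcript_id, h.t5) for h in again]


class TestClassify:
    def cls(self, model, t5, length=11):
        [h] = classify_hits(
            [TargetHit("t1", t5, length, "N" * length, 11, "COM")], [model])
        return h

    def test_donor_span_from_minus3(self, model):
        # 5'-most at -3 covers -3..+8: spans the junction
        h = self.cls(model, 98)
        assert h.category == "donor"
        assert h.junction_kind == "donor" and h.junction_offset == -3

    def test_intronic_at_plus17(self, model):
        h = self.cls(model, 117)
        assert h.category == "intronic"
        assert h.junction_offset == +17

    def test_exonic_ending_at_minus1(self, model):
        h = self.cls(model, 90)  # covers t 90..100 = offsets -11..-1
        assert h.category == "exonic"
        assert h.junction_offset == -11

    def test_acceptor_span(self, model):
        h = self.cls(model, 195)  # covers 195..205, acceptor boundary 200
        assert h.category == "acceptor"

    def test_footprint_outside_transcript_raises(self, model):
        with pytest.raises(RuntimeError):
            self.cls(model, 295)

    def test_micro_intron_assigned_donor(self):
        m = TranscriptModel("t1", "g1", "chr1", "+", [(1, 50), (58, 120)])
        [h] = classify_hits([TargetHit("t1", 45, 14, "N" * 14, 11, "COM")], [m])
        assert h.category == "donor"


class TestSummarize:
    def hits(self):
        return classify_hits(
            [TargetHit("t1", 98, 11, "A" * 11, a, r) for a, r in
             [(11, "COM"), (11, "COM"), (10, "BA1"), (9, "ALA")]] +
            [TargetHit("t1", 30, 11, "A" * 11, 11, "BS1")],
            [TranscriptModel("t1", "g1", "chr1", "+", [(1, 100), (201, 300)])],
        )

    def test_partition_and_monotonicity(self):
        s = summarize(self.hits(), [11, 10, 9], "u1")
        for m in (11, 10, 9):
            assert s.totals[m] == sum(s.by_category[m].values())
        assert s.totals[9] >= s.totals[10] >= s.totals[11]
        for cat in ("exonic", "intronic", "donor", "acceptor"):
            assert s.by_category[9][cat] >= s.by_category[10][cat] >= s.by_category[11][cat]

    def test_counts_at_levels(self):
        s = summarize(self.hits(), [11, 10, 9])
        assert s.totals == {11: 3, 10: 4, 9: 5}
        assert s.by_register[11] == {"COM": 2, "BS1": 1, "BS2": 0, "BA1": 0,
                                     "ALS": 0, "BA2": 0, "ALA": 0}


class TestPositionalDistribution:
    def test_counts_and_range_validation(self, model):
        hits = classify_hits(
            [TargetHit("t1", 101, 11, "A" * 11, 11, "COM"),   # +1
             TargetHit("t1", 117, 11, "A" * 11, 11, "COM"),   # +17, out of -15..10
             TargetHit("t1", 98, 11, "A" * 11, 11, "COM")],   # -3
            [model])
        counts = positional_distribution(hits, [model], "donor", (-15, 10))
        assert counts[+1] == 1 and counts[-3] == 1
        assert sum(counts.values()) == 2
        assert 0 not in counts
        with pytest.raises(ValueError):
            positional_distribution(hits, [model], "donor", (0, 10))
        with pytest.raises(ValueError):
            positional_distribution(hits, [model], "5ss", (-15, 10))

    def test_empty_hits_all_zero(self, model):
        counts = positional_distribution([], [model], "acceptor", (-15, 10))
        assert set(counts.values()) == {0}

    def test_intronic_hits_counted_in_wide_range(self, model):
        hits = classify_hits([TargetHit("t1", 117, 11, "A" * 11, 11, "COM")], [model])
        assert hits[0].category == "intronic"
        counts = positional_distribution(hits, [model], "donor", (-10, 25))
        assert counts[17] == 1


class TestPFM:
    def test_identical_sites(self):
        hits = [TargetHit("t", 1, 11, "CAGGTAAGTAT", 11, "COM")] * 3
        mat, order = position_frequency_matrix(hits)
        assert order == "ACGT"
        assert mat.sum(axis=0).tolist() == [3] * 11
        for col, base in enumerate("CAGGTAAGTAT"):
            assert mat[order.index(base), col] == 3

    def test_column_sums_equal_site_count_mixed_lengths(self):
        hits = [TargetHit("t", 1, 11, "CAGGTAAGTAT", 11, "COM"),
                TargetHit("t", 5, 12, "CAGGGTAAGTAT", 11, "BS1")]
        mat, _ = position_frequency_matrix(hits)
        assert mat.shape == (4, 11)
        assert mat.sum(axis=0).tolist() == [2] * 11

    def test_zero_sites_error(self):
        with pytest.raises(ValueError):
            position_frequency_matrix([])


class TestPSI:
    def test_ratio(self):
        psi = compute_psi({"a": 3.0, "b": 1.0}, {"e1": {"a"}}, {"a": "g", "b": "g"})
        assert psi["e1"] == pytest.approx(0.75)

    def test_exon_in_all_transcripts_is_one(self):
        psi = compute_psi({"a": 3.0, "b": 1.0}, {"e1": {"a", "b"}}, {"a": "g", "b": "g"})
        assert psi["e1"] == 1.0

    def test_low_tpm_excluded_before_ratio(self):
        psi = compute_psi({"a": 3.0, "b": 0.4}, {"e1": {"a"}}, {"a": "g", "b": "g"})
        assert psi["e1"] == 1.0

    def test_zero_expression_gene_is_nan(self):
        psi = compute_psi({"a": 0.1}, {"e1": {"a"}}, {"a": "g"})
        assert math.isnan(psi["e1"])

    def test_cross_gene_exon_rejected(self):
        with pytest.raises(ValueError):
            compute_psi({"a": 1.0, "b": 1.0}, {"e1": {"a", "b"}}, {"a": "g1", "b": "g2"})

    def test_psi_bounds(self):
        psi = compute_psi(
            {f"t{i}": float(i) for i in range(1, 6)},
            {f"e{i}": {f"t{j}" for j in range(1, i + 1)} for i in range(1, 6)},
            {f"t{i}": "g" for i in range(1, 6)},
        )
        assert all(0.0 <= v <= 1.0 for v in psi.values())


class TestCandidateSelection:
    def test_truth_table(self, model):
        hits = classify_hits([TargetHit("t1", 98, 11, "A" * 11, 11, "COM")], [model])
        psi_tables = [{"low_hit": 0.3, "high_hit": 0.6, "low_nohit": 0.2},
                      {"low_hit": 0.4, "high_hit": 0.8}]
        exon_donors = {"low_hit": [("t1", 0)], "high_hit": [("t1", 0)],
                       "low_nohit": [("t2", 0)]}
        got = select_candidate_offtarget_exons(hits, psi_tables, exon_donors, [model])
        assert got == ["low_hit"]


def test_planted_fixture_recovery(planted_fixture, planted_db, binding):
    """Every planted site is recovered at its designed MAB with the correct
    category and splice offset; summaries partition at every MAB."""
    truth = planted_fixture["fixture"].truth
    lowest = min(t["designed_annealed"] for t in truth)
    hits = predict_targetome(binding, planted_db, lowest)
    by_key = {(h.transcript_id, h.t5): h for h in hits}
    for t in truth:
        h = by_key.get((t["transcript_id"], t["t5"]))
        assert h is not None, f"planted site {t['site_id']} not recovered"
        assert h.annealed_bases >= t["designed_annealed"]
        assert h.category == t["category"], t
        if t["offset"] != "":
            assert h.junction_offset == t["offset"], t
    s = summarize(hits, [11, 10, 9], binding.id)
    s.check_partition()
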