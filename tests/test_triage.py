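"""Triage rule engine: support counting, interruptions, oracle equivalence."""

import pytest

from redexome.caller import RepeatCall
from redexome.errors import EvidenceError, NoThresholdError
from redexome.simulate import SimRead
from redexome.triage import (
    count_support,
    detect_interruptions,
    is_predicted_expanded,
    triage_call,
)

from conftest import flanking, in_repeat, make_evidence, spanning


def expanded_call(gene="HTT", short=17, long_=60, bound=False, sample="S1"):
    return RepeatCall(sample, gene, short, long_, bound, 5, 2, 3, 0, 40.0, "PASS")


def max_read(read_length, motif="CAG", hq=True):
    """Full-read-length in-repeat read of pure motif."""
    return in_repeat(read_length, motif, hq=hq)


def build_evidence(gene, read_length, n_hq, n_max, long_units=60, motif="CAG"):
    """Evidence with exactly n_hq HQ supporting spanning reads and n_max
    full-length pure in-repeat reads, plus non-counting noise."""
    reads = [spanning(long_units, motif) for _ in range(n_hq)]
    reads += [max_read(read_length, motif) for _ in range(n_max)]
    reads += [spanning(long_units, motif, hq=False)]  # low quality: never counts
    reads += [flanking(3, motif)]  # below short allele: never counts
    return make_evidence(gene=gene, read_length=read_length, reads=reads)


class TestCountSupport:
    def test_two_hq_spanning_no_in_repeat(self, by_gene):
        call = expanded_call()
        ev = build_evidence("HTT", 150, n_hq=2, n_max=0)
        assert count_support(call, ev, by_gene["HTT"]) == (2, 0)

    def test_eleven_full_length_in_repeat_reads(self, by_gene):
        call = expanded_call(bound=True)
        ev = build_evidence("HTT", 150, n_hq=0, n_max=11)
        assert count_support(call, ev, by_gene["HTT"]) == (0, 11)

    def test_low_quality_reads_count_nowhere(self, by_gene):
        call = expanded_call()
        reads = [spanning(60, hq=False), max_read(150, hq=False)]
        ev = make_evidence(gene="HTT", reads=reads)
        assert count_support(call, ev, by_gene["HTT"]) == (0, 0)

    def test_flanking_longer_than_short_allele_supports(self, by_gene):
        call = expanded_call(short=17, long_=60, bound=True)
        # 30 and 25 observed units exceed the 17-unit short allele; 10 does not
        ev = make_evidence(gene="HTT", reads=[flanking(30), flanking(25), flanking(10)])
        assert count_support(call, ev, by_gene["HTT"]) == (2, 0)

    def test_non_expanded_call_rejected(self, by_gene):
        normal = RepeatCall("S1", "HTT", 17, 20, False, 5, 5, 0, 0, 40.0, "PASS")
        with pytest.raises(EvidenceError):
            count_support(normal, make_evidence(reads=[]), by_gene["HTT"])


class TestDetectInterruptions:
    def test_cat_unit_inside_cag_tract(self, by_gene):
        seq = "CAG" * 4 + "CAT" + "CAG" * 5
        ev = make_evidence(gene="ATXN1", reads=[SimRead("spanning", seq, True, 10)])
        found, positions = detect_interruptions(ev, by_gene["ATXN1"])
        assert found and positions == [4]

    def test_pure_tract_clean(self, by_gene):
        ev = make_evidence(gene="ATXN1", reads=[spanning(10)])
        assert detect_interruptions(ev, by_gene["ATXN1"]) == (False, [])

    def test_out_of_frame_read_still_detected(self, by_gene):
        # read starts mid-unit: frame must be recovered by scanning offsets
        seq = ("CAG" * 4 + "CAT" + "CAG" * 5)[2:]
        ev = make_evidence(gene="ATXN1", reads=[SimRead("flanking", seq, True, None, 9)])
        found, _ = detect_interruptions(ev, by_gene["ATXN1"])
        assert found

    def test_locus_without_catalogued_interruptions_ignores_cat(self, by_gene):
        seq = "CAG" * 4 + "CAT" + "CAG" * 5
        ev = make_evidence(gene="HTT", reads=[SimRead("spanning", seq, True, 10)])
        assert detect_interruptions(ev, by_gene["HTT"]) == (False, [])


class TestTriageRules:
    def test_htt_two_hq_reads_long_reads_pass(self, by_gene):
        ev = build_evidence("HTT", 150, n_hq=2, n_max=0)
        verdict = triage_call(expanded_call(), ev, by_gene["HTT"])
        assert verdict.category == "pass"
        assert verdict.read_len_exceeds_cutoff

    def test_dmpk_two_hq_reads_short_reads_borderline(self, by_gene):
        # DMPK cutoff 108 bp > 100 bp reads
        call = expanded_call(gene="DMPK", short=12, long_=40, bound=True)
        reads = [flanking(35, "CTG"), flanking(38, "CTG")]
        ev = make_evidence(gene="DMPK", read_length=100, reads=reads)
        verdict = triage_call(call, ev, by_gene["DMPK"])
        assert verdict.category == "borderline"
        assert not verdict.read_len_exceeds_cutoff

    @pytest.mark.parametrize("n_max,expected", [(11, "pass"), (10, "fail")])
    def test_max_read_boundary_strictly_greater_than_ten(self, by_gene, n_max, expected):
        call = expanded_call(bound=True)
        ev = build_evidence("HTT", 150, n_hq=0, n_max=n_max)
        assert triage_call(call, ev, by_gene["HTT"]).category == expected

    def test_read_length_equal_to_cutoff_is_not_longer(self, by_gene):
        # HTT cutoff 105 bp; 105 bp reads fall to the short-read branch
        call = expanded_call(bound=True)
        ev = build_evidence("HTT", 105, n_hq=2, n_max=0)
        verdict = triage_call(call, ev, by_gene["HTT"])
        assert not verdict.read_len_exceeds_cutoff
        assert verdict.category == "borderline"

    def test_no_threshold_locus_cannot_be_triaged(self, by_gene):
        call = RepeatCall("S1", "PHOX2B", 10, 40, False, 2, 2, 0, 0, 30.0, "PASS")
        with pytest.raises(NoThresholdError):
            triage_call(call, make_evidence(gene="PHOX2B", reads=[spanning(40)]),
                        by_gene["PHOX2B"])

    def test_interruption_on_supporting_read_discards(self, by_gene):
        call = expanded_call(gene="ATXN1", short=28, long_=45)
        interrupted = "CAG" * 20 + "CAT" + "CAG" * 24
        reads = [
            SimRead("spanning", interrupted, True, 45),
            SimRead("spanning", interrupted, True, 45),
        ]
        ev = make_evidence(gene="ATXN1", reads=reads)
        assert triage_call(call, ev, by_gene["ATXN1"]).category == "discard_interruption"

    def test_interruption_on_normal_allele_does_not_discard(self, by_gene):
        # CAT on a short (normal) allele read: reported, not discarding
        call = expanded_call(gene="ATXN1", short=20, long_=45)
        normal_interrupted = "CAG" * 5 + "CAT" + "CAG" * 14  # 20 units, <= short
        reads = [
            SimRead("spanning", normal_interrupted, True, 20),
            spanning(45), spanning(45),
        ]
        ev = make_evidence(gene="ATXN1", reads=reads)
        assert triage_call(call, ev, by_gene["ATXN1"]).category == "pass"


def oracle_category(long_reads: bool, n_hq: int, n_max: int) -> str:
    """Independent brute-force restatement of the review rules as a table."""
    if long_reads:
        if n_hq >= 2 or n_max > 10:
            return "pass"
        if n_hq == 1:
            return "borderline"
        return "fail"
    if n_hq >= 2:
        return "borderline"
    return "fail"


class TestOracleEquivalence:
    @pytest.mark.parametrize("long_reads", [True, False])
    def test_engine_matches_truth_table(self, by_gene, long_reads):
        """160 enumerated (L, n_hq, n_max) cells match the brute-force table."""
        htt = by_gene["HTT"]  # cutoff 105 bp
        read_length = 150 if long_reads else 100
        for n_hq in range(5):
            for n_max in range(16):
                call = expanded_call(bound=True)
                ev = build_evidence("HTT", read_length, n_hq, n_max)
                verdict = triage_call(call, ev, htt)
                assert (verdict.n_hq_support, verdict.n_max_reads) == (n_hq, n_max)
                assert verdict.category == oracle_category(long_reads, n_hq, n_max), (
                    long_reads, n_hq, n_max,
                )

    def test_more_support_never_demotes(self, by_gene):
        rank = {"fail": 0, "borderline": 1, "pass": 2}
        htt = by_gene["HTT"]
        for read_length in (150, 100):
            for n_max in (0, 12):
                previous = -1
                for n_hq in range(5):
                    ev = build_evidence("HTT", read_length, n_hq, n_max)
                    cat = triage_call(expanded_call(bound=True), ev, htt).category
                    assert rank[cat] >= previous
                    previous = rank[cat]

    def test_interruption_precedence_over_any_support(self, by_gene):
        interrupted = "CAG" * 20 + "CAT" + "CAG" * 24
        reads = [SimRead("spanning", interrupted, True, 45)] + [
            spanning(45) for _ in range(10)
        ] + [max_read(150) for _ in range(15)]
        ev = make_evidence(gene="ATXN1", reads=reads)
        call = expanded_call(gene="ATXN1", short=20, long_=45)
        assert triage_call(call, ev, by_gene["ATXN1"]).category == "discard_interruption"
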