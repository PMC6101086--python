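import pytest

from backsplice.junction_caller import (
    REGULAR,
    SELF,
    CircCandidate,
    call_regular,
    call_self,
    classify_case,
    condense_tags,
    events_transcript_order,
    min_hit_threshold,
    passes_min_hits,
    read_calls,
    refine,
    self_circle_detectable,
    write_calls,
)
from backsplice.kmer_index import Config
from backsplice.read_scanner import BestHitCase, TagEvent

from helpers import build_toy, events_from, make_status


class TestMinHitThreshold:
    def test_short_case_formula(self, config):
        assert min_hit_threshold(make_status(1, 80), config) == 70  # 80 - 15 + 5

    def test_long_case_formula(self, config):
        assert min_hit_threshold(make_status(1, 300), config) == 36  # floor(30 * 1.2)

    def test_equal_support_is_retained(self, config):
        # only strictly-smaller support is discarded
        assert passes_min_hits(make_status(70, 80), config) is True
        assert passes_min_hits(make_status(69, 80), config) is False


class TestClassifyCase:
    def test_single_exon_is_self(self, config):
        status = make_status(20, 60, exon_index=2)
        assert classify_case(status, config) == (SELF, [2])

    def test_low_hit_exon_skipped_leaves_regular_pair(self, config):
        status = make_status(0, 0)
        status.events = events_from([(1, "E", 12), (5, "S", 2), (3, "S", 9)])
        status.hit_exon_lengths = {1: 100, 5: 80, 3: 90}
        case = classify_case(status, config)
        assert case is not None and case[0] == REGULAR
        assert sorted(case[1]) == [1, 3]

    def test_three_solid_exons_rejected(self, config):
        status = make_status(0, 0)
        status.events = events_from([(1, "E", 8), (2, "S", 8), (3, "S", 8)])
        status.hit_exon_lengths = {1: 100, 2: 80, 3: 90}
        assert classify_case(status, config) is None

    def test_pair_collapsing_to_one_after_skip_rejected(self, config):
        status = make_status(0, 0)
        status.events = events_from([(1, "E", 8), (2, "S", 3)])
        status.hit_exon_lengths = {1: 100, 2: 80}
        assert classify_case(status, config) is None


class TestCondenseTags:
    def test_noise_run_absorbed_into_dominant_tag(self, config):
        events = events_from([(0, "S", 1), (0, "E", 10)])
        condensed = condense_tags(events, SELF, config)
        assert [(c.tag, c.count) for c in condensed] == [("E", 10)]

    def test_regular_full_coverage_keeps_e_then_s(self, config):
        # both exons completely covered: S,E runs of equal size in each
        events = events_from([(3, "S", 6), (3, "E", 6), (1, "S", 6), (1, "E", 6)])
        condensed = condense_tags(events, REGULAR, config)
        assert [(c.exon_index, c.tag) for c in condensed] == [(3, "E"), (1, "S")]

    def test_single_run_unchanged(self, config):
        events = events_from([(0, "S", 7)])
        assert [(c.tag, c.count) for c in condense_tags(events, SELF, config)] == [("S", 7)]

    def test_junction_pattern_e_then_s_survives(self, config):
        events = events_from([(0, "E", 12), (0, "S", 9)])
        condensed = condense_tags(events, SELF, config)
        assert [(c.tag, c.count) for c in condensed] == [("E", 12), ("S", 9)]


@pytest.fixture(scope="module")
def plus_gene():
    # "+" gene: exon1/exon3 are internal (both signals); exon2 is long
    genome, catalog = build_toy([("+", [70, 60, 200, 80, 70], [40, 50, 40, 60])],
                                seed=9)
    return genome, catalog


@pytest.fixture(scope="module")
def minus_gene():
    genome, catalog = build_toy([("-", [70, 60, 200, 80, 70], [40, 50, 40, 60])],
                                seed=10)
    return genome, catalog


def _best(events, lengths, key=(0, 0, 0)):
    status = make_status(0, 0, key=key)
    status.events = events
    status.hit_exon_lengths = lengths
    return BestHitCase(status=status)


class TestCallSelf:
    def test_short_exon_with_both_signals_called(self, plus_gene, config):
        genome, catalog = plus_gene
        exon = catalog.exon(0, 0, 0, 1)  # 60 bp internal exon
        best = _best(events_from([(1, "S", 50)]), {1: exon.length})
        cand = call_self(best, exon, config, catalog)
        assert cand is not None
        assert (cand.start, cand.end, cand.case_type) == (exon.start, exon.end, SELF)

    def test_ordered_tags_on_long_exon_rejected(self, plus_gene, config):
        genome, catalog = plus_gene
        exon = catalog.exon(0, 0, 0, 2)  # 200 bp internal exon
        best = _best(events_from([(2, "S", 20), (2, "E", 20)]), {2: exon.length})
        assert call_self(best, exon, config, catalog) is None

    def test_out_of_order_tags_on_long_exon_called(self, plus_gene, config):
        genome, catalog = plus_gene
        exon = catalog.exon(0, 0, 0, 2)
        best = _best(events_from([(2, "E", 20), (2, "S", 20)]), {2: exon.length})
        cand = call_self(best, exon, config, catalog)
        assert cand is not None and (cand.start, cand.end) == (exon.start, exon.end)

    def test_one_sided_signal_rejected(self, plus_gene, config):
        genome, catalog = plus_gene
        exon = catalog.exon(0, 0, 0, 0)  # first exon: no head signal
        best = _best(events_from([(0, "S", 60)]), {0: exon.length})
        assert call_self(best, exon, config, catalog) is None

    def test_undercovered_short_exon_rejected(self, plus_gene, config):
        genome, catalog = plus_gene
        exon = catalog.exon(0, 0, 0, 1)  # 60 bp: needs N_h >= 46
        best = _best(events_from([(1, "S", 45)]), {1: exon.length})
        assert call_self(best, exon, config, catalog) is None


class TestCallRegular:
    def test_plus_strand_breakpoint_and_coordinates(self, plus_gene, config):
        genome, catalog = plus_gene
        events = events_from([(3, "E", 10), (1, "S", 10)])
        best = _best(events, {3: 80, 1: 60})
        cand = call_regular(best, [3, 1], config, catalog)
        assert cand is not None
        e1, e3 = catalog.exon(0, 0, 0, 1), catalog.exon(0, 0, 0, 3)
        assert (cand.start, cand.end, cand.strand) == (e1.start, e3.end, "+")
        assert cand.case_type == REGULAR

    def test_plus_strand_monotone_increase_dropped(self, plus_gene, config):
        genome, catalog = plus_gene
        events = events_from([(1, "E", 10), (3, "S", 10)])
        best = _best(events, {1: 60, 3: 80})
        assert call_regular(best, [1, 3], config, catalog) is None

    def test_minus_strand_mirror_rule(self, minus_gene, config):
        genome, catalog = minus_gene
        # genomic scan order of a "−" back-splice read: larger genomic
        # exon first with genomic-"E" tags, then smaller with "S"; the
        # transcript-order view increases 1 -> 3 with tags E then S
        events = events_from([(3, "E", 10), (1, "S", 10)])
        assert [
            (e.exon_index, e.part_tag) for e in events_transcript_order(events, "-")
        ][:1] == [(1, "E")]
        best = _best(events, {3: 80, 1: 60})
        cand = call_regular(best, [3, 1], config, catalog)
        assert cand is not None
        e1, e3 = catalog.exon(0, 0, 0, 1), catalog.exon(0, 0, 0, 3)
        assert (cand.start, cand.end, cand.strand) == (e1.start, e3.end, "-")

    def test_minus_strand_linear_pattern_dropped(self, minus_gene, config):
        genome, catalog = minus_gene
        # a linear "−" read: genomic order small exon "E" then large "S";
        # transcript order decreases monotonically -> dropped
        events = events_from([(1, "E", 10), (3, "S", 10)])
        best = _best(events, {1: 60, 3: 80})
        assert call_regular(best, [1, 3], config, catalog) is None

    def test_missing_donor_signal_rejected(self, plus_gene, config):
        genome, catalog = plus_gene
        # head exon = last exon (index 4): lacks the tail (donor) signal
        events = events_from([(4, "E", 10), (1, "S", 10)])
        best = _best(events, {4: 70, 1: 60})
        assert call_regular(best, [4, 1], config, catalog) is None


class TestRefine:
    def _cand(self, start=100, end=200, case=REGULAR):
        return CircCandidate("c1", start, end, "+", case)

    def test_support_counted_and_kept_below_threshold(self):
        config = Config(max_support=10)
        out = refine([self._cand() for _ in range(7)], config)
        assert len(out) == 1 and out[0].support == 7

    def test_support_at_threshold_dropped(self):
        config = Config(max_support=10)
        assert refine([self._cand() for _ in range(12)], config) == []

    def test_default_sentinel_keeps_everything(self, config):
        out = refine([self._cand() for _ in range(1000)], config)
        assert len(out) == 1 and out[0].support == 1000

    def test_identical_coordinates_merge_preferring_self(self, config):
        out = refine([self._cand(case=REGULAR), self._cand(case=SELF)], config)
        assert len(out) == 1 and out[0].case_type == SELF and out[0].support == 2

    def test_sorted_deterministic_output(self, config):
        cands = [self._cand(300, 400), self._cand(100, 200), self._cand(100, 150)]
        out = refine(cands, config)
        assert [(c.start, c.end) for c in out] == [(100, 150), (100, 200), (300, 400)]


class TestDetectability:
    def test_near_read_length_self_exons_undetectable(self, config):
        # wrapping reads forfeit k-1 windows per junction crossing, so
        # exons just under the read length cannot reach N_hm
        assert self_circle_detectable(60, config)
        assert self_circle_detectable(83, config)
        assert not self_circle_detectable(84, config)
        assert not self_circle_detectable(95, config)
        assert self_circle_detectable(101, config)
        assert self_circle_detectable(150, config)


def test_write_read_calls_round_trip(tmp_path):
    cands = [
        CircCandidate("chr1", 100, 250, "+", REGULAR, support=9),
        CircCandidate("chr2", 40, 99, "-", SELF, support=3),
    ]
    p = tmp_path / "calls.bed"
    write_calls(cands, p)
    assert read_calls(p) == cands
    assert p.read_text().splitlines()[0] == "chr1\t100\t250\tregular\t9\t+"
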