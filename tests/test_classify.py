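"""Record and fragment classification at the anchor."""

from __future__ import annotations

import itertools
import random

import pytest

from transclip import (
    AlignmentRecord,
    AnchorSpec,
    Category,
    ClassifyOptions,
    classify_fragment,
    classify_record,
    overlaps_anchor,
    summarize,
)

from conftest import make_record, oracle_classify, random_mapped_record


class TestOverlapsAnchor:
    def test_position_inside_span(self, anchor):
        rec = make_record("100M", position=350)  # span [350, 449]
        assert overlaps_anchor(rec, anchor)

    def test_position_outside_span(self, anchor):
        rec = make_record("100M", position=100)
        assert not overlaps_anchor(rec, anchor)

    def test_anchor_inside_splice_gap_still_overlaps(self, anchor):
        # span [350, 549]; anchor 400 falls inside the N gap [390, 489]
        rec = make_record("40M100N60M", position=350)
        assert overlaps_anchor(rec, anchor)
        assert classify_record(rec, anchor) is Category.EXCLUDED_SPLICED

    def test_other_reference_never_overlaps(self, anchor):
        rec = make_record("100M", position=350, reference="chrX")
        assert not overlaps_anchor(rec, anchor)

    def test_chr_prefix_tolerated_by_default(self):
        spec = AnchorSpec(reference_name="14", anchor_position=400)
        rec = make_record("100M", position=350, reference="chr14")
        assert overlaps_anchor(rec, spec)
        assert not overlaps_anchor(rec, spec, strict_refnames=True)


class TestClassifyRecord:
    @pytest.mark.parametrize("cigar,pos,expected", [
        ("24S76M", 400, Category.EXOGENOUS_SOFTCLIPPED),
        ("100M", 350, Category.ENDOGENOUS_MATCHED),
        ("5S95M", 350, Category.AMBIGUOUS_CLIP),     # 5 < threshold 6
        ("30M300N70M", 380, Category.EXCLUDED_SPLICED),
        ("100M", 100, Category.NOT_OVERLAPPING),
        ("6S94M", 400, Category.EXOGENOUS_SOFTCLIPPED),  # exactly threshold
    ])
    def test_cascade_examples(self, anchor, cigar, pos, expected):
        assert classify_record(make_record(cigar, position=pos),
                               anchor) is expected

    def test_flag_exclusions_win_over_everything(self, anchor):
        for kw in (dict(is_secondary=True), dict(is_supplementary=True),
                   dict(is_duplicate=True), dict(is_qc_fail=True)):
            rec = make_record("24S76M", position=400, **kw)
            assert classify_record(rec, anchor) is Category.EXCLUDED_FLAGS

    def test_duplicates_can_be_included(self, anchor):
        rec = make_record("24S76M", position=400, is_duplicate=True)
        opts = ClassifyOptions(include_duplicates=True)
        assert classify_record(rec, anchor, opts) is \
            Category.EXOGENOUS_SOFTCLIPPED

    def test_mapq_filter(self, anchor):
        rec = make_record("100M", position=350)
        rec.mapping_quality = 5
        assert classify_record(rec, anchor,
                               ClassifyOptions(min_mapq=10)) is \
            Category.EXCLUDED_FLAGS

    def test_clips_summed_over_both_ends(self, anchor):
        # 3 + 3 clipped bases reach the threshold of 6 together
        rec = make_record("3S94M3S", position=350)
        assert classify_record(rec, anchor) is Category.EXOGENOUS_SOFTCLIPPED

    def test_end_restricted_mode_counts_anchor_side_clip_only(self):
        spec = AnchorSpec(reference_name="chrT", anchor_position=400,
                          softclip_threshold=6)
        opts = ClassifyOptions(end_restricted_clip=True)
        # alignment starts at the anchor: left clip faces it (8 >= 6)
        rec = make_record("8S92M", position=400)
        assert classify_record(rec, spec, opts) is \
            Category.EXOGENOUS_SOFTCLIPPED
        # same clip on the far end only: 3 anchor-side bases, ambiguous
        rec2 = make_record("3S89M8S", position=398)
        assert classify_record(rec2, spec, opts) is Category.AMBIGUOUS_CLIP

    def test_agrees_with_per_base_oracle_on_random_records(self, anchor):
        rng = random.Random(77)
        for i in range(1000):
            rec = random_mapped_record(rng, f"r{i}")
            assert classify_record(rec, anchor) is oracle_classify(rec, anchor)

    def test_threshold_monotonicity(self):
        rng = random.Random(78)
        records = [random_mapped_record(rng, f"r{i}") for i in range(400)]
        prev_exo = None
        for thr in (1, 3, 6, 12, 24, 50):
            spec = AnchorSpec(reference_name="chrT", anchor_position=400,
                              softclip_threshold=thr)
            cats = [classify_record(r, spec) for r in records]
            n_exo = sum(c is Category.EXOGENOUS_SOFTCLIPPED for c in cats)
            n_rest = sum(c in (Category.ENDOGENOUS_MATCHED,
                               Category.AMBIGUOUS_CLIP) for c in cats)
            if prev_exo is not None:
                assert n_exo <= prev_exo[0]
                assert n_rest >= prev_exo[1]
            prev_exo = (n_exo, n_rest)


class TestTagVerification:
    TAG = "GACTACAAGGATGACGACGATAAG"

    def _spec(self, require):
        return AnchorSpec(reference_name="chrT", anchor_position=400,
                          softclip_threshold=6, tag_sequence=self.TAG,
                          require_tag_match=require)

    def test_tag_bearing_clip_stays_exogenous(self):
        rec = make_record("24S76M", position=400,
                          sequence=self.TAG + "C" * 76)
        assert classify_record(rec, self._spec(True)) is \
            Category.EXOGENOUS_SOFTCLIPPED

    def test_foreign_clip_demoted_to_ambiguous(self):
        rec = make_record("24S76M", position=400,
                          sequence="A" * 24 + "C" * 76)
        assert classify_record(rec, self._spec(True)) is \
            Category.AMBIGUOUS_CLIP

    def test_reverse_complement_clip_matches(self):
        rc = "CTTATCGTCGTCATCCTTGTAGTC"  # revcomp of the FLAG tag
        rec = make_record("24S76M", position=400, sequence=rc + "C" * 76)
        assert classify_record(rec, self._spec(True)) is \
            Category.EXOGENOUS_SOFTCLIPPED

    def test_verification_only_shrinks_the_exogenous_bin(self):
        rng = random.Random(79)
        records = []
        for i in range(300):
            rec = random_mapped_record(rng, f"r{i}")
            records.append(rec)
        on = sum(classify_record(r, self._spec(True)) is
                 Category.EXOGENOUS_SOFTCLIPPED for r in records)
        off = sum(classify_record(r, self._spec(False)) is
                  Category.EXOGENOUS_SOFTCLIPPED for r in records)
        assert on <= off


class TestClassifyFragment:
    def test_pair_counted_once_with_exogenous_precedence(self, anchor):
        m1 = make_record("24S76M", position=400, name="f", is_paired=True,
                         is_first_in_pair=True)
        m2 = make_record("100M", position=700, name="f", is_paired=True)
        fc = classify_fragment([m1, m2], anchor)
        assert fc.category is Category.EXOGENOUS_SOFTCLIPPED
        assert fc.n_records_seen == 2
        assert fc.max_softclip == 24

    def test_singleton(self, anchor):
        fc = classify_fragment([make_record("100M", position=350)], anchor)
        assert fc.category is Category.ENDOGENOUS_MATCHED

    def test_precedence_equals_bruteforce_over_all_pairs(self, anchor):
        """For every ordered pair of record archetypes, the fragment verdict
        is the max-precedence single verdict (enumerated independently)."""
        archetype = {
            Category.EXOGENOUS_SOFTCLIPPED: make_record("24S76M",
                                                        position=400),
            Category.ENDOGENOUS_MATCHED: make_record("100M", position=350),
            Category.AMBIGUOUS_CLIP: make_record("5S95M", position=350),
            Category.EXCLUDED_SPLICED: make_record("30M300N70M",
                                                   position=380),
            Category.NOT_OVERLAPPING: make_record("100M", position=100),
            Category.EXCLUDED_FLAGS: make_record("100M", position=350,
                                                 is_secondary=True),
        }
        order = [Category.EXOGENOUS_SOFTCLIPPED, Category.ENDOGENOUS_MATCHED,
                 Category.AMBIGUOUS_CLIP, Category.EXCLUDED_SPLICED,
                 Category.NOT_OVERLAPPING, Category.EXCLUDED_FLAGS]
        for a, b in itertools.product(order, repeat=2):
            expected = min(a, b, key=order.index)
            fc = classify_fragment([archetype[a], archetype[b]], anchor)
            assert fc.category is expected, (a, b)

    def test_spliced_mate_does_not_mask_matched_mate(self, anchor):
        m1 = make_record("30M300N70M", position=380, name="f")
        m2 = make_record("100M", position=350, name="f")
        assert classify_fragment([m1, m2], anchor).category is \
            Category.ENDOGENOUS_MATCHED

    def test_empty_or_mixed_input_is_an_error(self, anchor):
        with pytest.raises(ValueError):
            classify_fragment([], anchor)
        with pytest.raises(ValueError):
            classify_fragment([make_record("100M", name="a"),
                               make_record("100M", name="b")], anchor)


class TestSummarize:
    def test_empty_stream(self, anchor):
        s = summarize([], anchor)
        assert s.total_fragments == 0 and sum(s.counts.values()) == 0

    def test_three_fragment_fixture(self, anchor):
        records = [
            make_record("24S76M", position=400, name="exo"),
            make_record("100M", position=350, name="endo"),
            make_record("100M", position=100, name="away"),
        ]
        s = summarize(records, anchor)
        assert s.count(Category.EXOGENOUS_SOFTCLIPPED) == 1
        assert s.count(Category.ENDOGENOUS_MATCHED) == 1
        assert s.count(Category.NOT_OVERLAPPING) == 1
        assert s.total_fragments == 3

    def test_partition_and_shuffle_invariance(self, anchor):
        rng = random.Random(80)
        records = [random_mapped_record(rng, f"f{i % 250}")
                   for i in range(500)]  # pairs share names
        baseline = summarize(list(records), anchor)
        n_names = len({r.query_name for r in records})
        assert sum(baseline.counts.values()) == n_names
        for _ in range(20):
            rng.shuffle(records)
            s = summarize(list(records), anchor)
            assert s.counts == baseline.counts
            assert s.total_fragments == baseline.total_fragments
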