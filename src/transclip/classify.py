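"""Fragment classification at an ORF-start anchor.

A read pair (or singleton) sequenced from the endogenous transcript aligns
contiguously across the ORF start, because the 5'UTR and first coding exon
are adjacent on the reference.  A read from a lentiviral construct whose
cDNA carries an artificial tag fused at the ORF start cannot align its tag
bases, so a spliced aligner soft-clips them: the clip is the diagnostic
signature of construct origin.  This module applies that rule to every
alignment overlapping the anchor position, and counts each fragment (all
records sharing a query name) exactly once.

Decision cascade per record, first match wins:

1. secondary / supplementary / unmapped (and, by default, duplicate or
   QC-fail) records are excluded outright;
2. records not overlapping the anchor position are out of scope;
3. spliced records (CIGAR contains N) are excluded — a splice junction over
   the anchor says nothing about tag presence;
4. total soft-clip >= threshold -> exogenous (optionally demoted to
   ambiguous when tag verification is on and no clip matches the tag);
5. zero soft-clipped bases -> endogenous (fully matched);
6. otherwise (clip below threshold) -> ambiguous.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .alignment import (
    AlignmentRecord,
    AnchorSpec,
    clipped_sequences,
    is_spliced,
    reference_span,
    reverse_complement,
    total_softclip,
)

__all__ = [
    "Category",
    "ClassifyOptions",
    "FragmentClassification",
    "ClassificationSummary",
    "overlaps_anchor",
    "classify_record",
    "classify_fragment",
    "summarize",
]


class Category(enum.Enum):
    """Per-record / per-fragment verdict."""

    EXOGENOUS_SOFTCLIPPED = "exogenous_softclipped"
    ENDOGENOUS_MATCHED = "endogenous_matched"
    AMBIGUOUS_CLIP = "ambiguous_clip"
    EXCLUDED_SPLICED = "excluded_spliced"
    NOT_OVERLAPPING = "not_overlapping"
    EXCLUDED_FLAGS = "excluded_flags"


#: Fragment precedence: a tag-bearing clip is positive evidence of construct
#: origin, a fully matched mate is consistent with either origin, and an
#: excluded mate never overrides an informative one.
_PRECEDENCE = {
    Category.EXOGENOUS_SOFTCLIPPED: 0,
    Category.ENDOGENOUS_MATCHED: 1,
    Category.AMBIGUOUS_CLIP: 2,
    Category.EXCLUDED_SPLICED: 3,
    Category.NOT_OVERLAPPING: 4,
    Category.EXCLUDED_FLAGS: 5,
}


@dataclass(frozen=True)
class ClassifyOptions:
    """Behaviour toggles that are properties of the run, not of the anchor."""

    include_duplicates: bool = False
    include_qc_fail: bool = False
    min_mapq: int = 0
    #: When set, only the S op at the read end nearer the anchor counts
    #: toward the threshold (instead of the sum over both ends).
    end_restricted_clip: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.min_mapq <= 255:
            raise ValueError("min_mapq must be in [0, 255]")


DEFAULT_OPTIONS = ClassifyOptions()


@dataclass
class FragmentClassification:
    """Once-per-fragment verdict with the evidence behind it."""

    query_name: str
    category: Category
    n_records_seen: int
    max_softclip: int
    spliced_any: bool
    tag_matched: bool | None  # None = tag verification not evaluated


@dataclass
class ClassificationSummary:
    """Category counts over all fragments seen, plus run provenance."""

    counts: Counter = field(default_factory=Counter)
    total_fragments: int = 0
    skipped_malformed: int = 0
    anchor: AnchorSpec | None = None
    options: ClassifyOptions = DEFAULT_OPTIONS

    def count(self, category: Category) -> int:
        return self.counts.get(category, 0)

    def check_partition(self) -> None:
        """Assert the partition property: counts sum to total fragments."""
        if sum(self.counts.values()) != self.total_fragments:
            raise AssertionError("category counts do not partition fragments")


def overlaps_anchor(record: AlignmentRecord, anchor: AnchorSpec,
                    strict_refnames: bool = False) -> bool:
    """True iff the alignment's reference span contains the anchor position.

    A position inside an N (intron) gap still counts as overlapping here;
    such records are removed downstream by the splice exclusion.  Unless
    ``strict_refnames``, "chr14" and "14" are treated as the same reference.
    """
    if not _same_reference(record.reference_name, anchor.reference_name,
                           strict_refnames):
        return False
    start, end = reference_span(record)
    return start <= anchor.anchor_position <= end


def _same_reference(a: str, b: str, strict: bool) -> bool:
    if strict:
        return a == b
    return a.removeprefix("chr") == b.removeprefix("chr")


def _clip_for_threshold(record: AlignmentRecord, anchor: AnchorSpec,
                        options: ClassifyOptions) -> int:
    if not options.end_restricted_clip:
        return total_softclip(record)
    ops = [op for op in record.cigar if op.code != "H"]
    left = ops[0].length if ops and ops[0].code == "S" else 0
    right = ops[-1].length if len(ops) > 1 and ops[-1].code == "S" else 0
    start, end = reference_span(record)
    # the clip at the read end closer to the anchor is the junction-facing one
    if abs(start - anchor.anchor_position) <= abs(end - anchor.anchor_position):
        return left
    return right


def _tag_kmer_match(clip: str, tag: str, k: int) -> bool:
    if len(clip) < k:
        return False
    targets = (tag, reverse_complement(tag))
    for i in range(len(clip) - k + 1):
        kmer = clip[i:i + k]
        if any(kmer in t for t in targets):
            return True
    return False


def clip_matches_tag(record: AlignmentRecord, anchor: AnchorSpec) -> bool:
    """True iff either clipped sequence shares an exact ``tag_min_kmer``-mer
    with the tag or its reverse complement (no mismatches allowed)."""
    if not anchor.tag_sequence:
        return False
    left, right = clipped_sequences(record)
    k = anchor.tag_min_kmer
    return (_tag_kmer_match(left, anchor.tag_sequence, k)
            or _tag_kmer_match(right, anchor.tag_sequence, k))


def classify_record(record: AlignmentRecord, anchor: AnchorSpec,
                    options: ClassifyOptions = DEFAULT_OPTIONS) -> Category:
    """Classify a single alignment record against the anchor."""
    if (record.is_secondary or record.is_supplementary or record.is_unmapped
            or (record.is_duplicate and not options.include_duplicates)
            or (record.is_qc_fail and not options.include_qc_fail)
            or record.mapping_quality < options.min_mapq):
        return Category.EXCLUDED_FLAGS
    if not overlaps_anchor(record, anchor):
        return Category.NOT_OVERLAPPING
    if is_spliced(record):
        return Category.EXCLUDED_SPLICED
    clip = _clip_for_threshold(record, anchor, options)
    if clip >= anchor.softclip_threshold:
        if anchor.require_tag_match and not clip_matches_tag(record, anchor):
            return Category.AMBIGUOUS_CLIP
        return Category.EXOGENOUS_SOFTCLIPPED
    if total_softclip(record) == 0:
        return Category.ENDOGENOUS_MATCHED
    return Category.AMBIGUOUS_CLIP


def classify_fragment(records: list[AlignmentRecord], anchor: AnchorSpec,
                      options: ClassifyOptions = DEFAULT_OPTIONS,
                      ) -> FragmentClassification:
    """Classify all records of one fragment; count the fragment once.

    The fragment takes the highest-precedence category among its records,
    so a pair where one mate shows the clip signature and the other lies
    elsewhere is exogenous, counted once.
    """
    if not records:
        raise ValueError("classify_fragment requires at least one record")
    names = {r.query_name for r in records}
    if len(names) != 1:
        raise ValueError(f"records from multiple fragments passed: {sorted(names)}")

    best = Category.EXCLUDED_FLAGS
    max_clip = 0
    spliced_any = False
    tag_matched: bool | None = None
    for rec in records:
        cat = classify_record(rec, anchor, options)
        if _PRECEDENCE[cat] < _PRECEDENCE[best]:
            best = cat
        if not rec.is_unmapped:
            max_clip = max(max_clip, total_softclip(rec))
            spliced_any = spliced_any or is_spliced(rec)
            if anchor.require_tag_match and rec.sequence and total_softclip(rec):
                hit = clip_matches_tag(rec, anchor)
                tag_matched = hit if tag_matched is None else (tag_matched or hit)
    return FragmentClassification(
        query_name=records[0].query_name,
        category=best,
        n_records_seen=len(records),
        max_softclip=max_clip,
        spliced_any=spliced_any,
        tag_matched=tag_matched,
    )


def iter_fragments(records: Iterable[AlignmentRecord],
                   ) -> Iterator[list[AlignmentRecord]]:
    """Group a record stream by query name, in first-appearance order."""
    groups: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        groups.setdefault(rec.query_name, []).append(rec)
    yield from groups.values()


def summarize(records: Iterable[AlignmentRecord], anchor: AnchorSpec,
              options: ClassifyOptions = DEFAULT_OPTIONS,
              fragment_sink: list[FragmentClassification] | None = None,
              ) -> ClassificationSummary:
    """Classify a whole record stream, one verdict per distinct query name.

    The result is deterministic and independent of input order (fragments
    are aggregated by name; category counts are order-free).  Pass a list
    as ``fragment_sink`` to also collect the per-fragment verdicts.
    """
    summary = ClassificationSummary(anchor=anchor, options=options)
    for group in iter_fragments(records):
        fc = classify_fragment(group, anchor, options)
        summary.counts[fc.category] += 1
        summary.total_fragments += 1
        if fragment_sink is not None:
            fragment_sink.append(fc)
    summary.check_partition()
    return summary
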