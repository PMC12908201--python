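"""Shared fixtures and the independent per-base CIGAR oracle.

The oracle deliberately avoids the package's arithmetic: it expands every
CIGAR operation base by base into reference/query events and derives span,
clip totals and splice status from the expansion, then re-applies the
classification cascade from its written definition.  Tests compare the
package against this walker, never the walker against itself.
"""

from __future__ import annotations

import random

import pytest

from transclip import (
    AlignmentRecord,
    AnchorSpec,
    Category,
    CigarOp,
    parse_cigar,
)


def make_record(cigar: str, position: int = 100, name: str = "r",
                reference: str = "chrT", sequence: str | None = None,
                **kwargs) -> AlignmentRecord:
    """Build a mapped record, synthesising a sequence of the right length."""
    ops = parse_cigar(cigar)
    if sequence is None:
        qlen = sum(op.length for op in ops if op.code in "MIS=X")
        sequence = "A" * qlen
    return AlignmentRecord(query_name=name, reference_name=reference,
                           position=position, mapping_quality=60,
                           cigar=ops, sequence=sequence, **kwargs)


# ---------------------------------------------------------------- oracle --

def walk_cigar(record: AlignmentRecord) -> dict:
    """Per-base expansion of a mapped record's CIGAR.

    Returns the reference positions the alignment consumes (aligned and
    gap positions separately), the number of soft-clipped bases counted
    one at a time, and per-end clip widths.
    """
    aligned: list[int] = []   # reference positions consumed by M/=/X
    gaps: list[int] = []      # reference positions consumed by D/N
    n_soft = 0
    spliced = False
    pos = record.position
    for op in record.cigar:
        for _ in range(op.length):
            if op.code in "M=X":
                aligned.append(pos)
                pos += 1
            elif op.code in "DN":
                gaps.append(pos)
                pos += 1
                if op.code == "N":
                    spliced = True
            elif op.code == "S":
                n_soft += 1
            # I, H, P consume no reference base
    footprint = aligned + gaps
    left = record.cigar[0].length if record.cigar[0].code == "S" else 0
    last = record.cigar[-1]
    right = last.length if len(record.cigar) > 1 and last.code == "S" else 0
    return {
        "span": (min(footprint), max(footprint)) if footprint else None,
        "n_softclip": n_soft,
        "spliced": spliced,
        "left_clip": left,
        "right_clip": right,
    }


def oracle_classify(record: AlignmentRecord, anchor: AnchorSpec) -> Category:
    """Independent re-statement of the decision cascade (default options)."""
    if (record.is_secondary or record.is_supplementary or record.is_unmapped
            or record.is_duplicate or record.is_qc_fail):
        return Category.EXCLUDED_FLAGS
    same_ref = (record.reference_name.removeprefix("chr")
                == anchor.reference_name.removeprefix("chr"))
    walked = walk_cigar(record)
    span = walked["span"]
    if not same_ref or span is None or not (
            span[0] <= anchor.anchor_position <= span[1]):
        return Category.NOT_OVERLAPPING
    if walked["spliced"]:
        return Category.EXCLUDED_SPLICED
    if walked["n_softclip"] >= anchor.softclip_threshold:
        return Category.EXOGENOUS_SOFTCLIPPED
    if walked["n_softclip"] == 0:
        return Category.ENDOGENOUS_MATCHED
    return Category.AMBIGUOUS_CLIP


# ------------------------------------------------------------ generators --

def random_mapped_record(rng: random.Random, name: str,
                         reference: str = "chrT") -> AlignmentRecord:
    """Random valid mapped record: ops from {M,I,D,N,S}, lengths 1-300.

    Soft clips only at the ends and the aligned core starts/ends with M,
    as any real aligner would emit.
    """
    ops: list[CigarOp] = []
    if rng.random() < 0.5:
        ops.append(CigarOp("S", rng.randint(1, 300)))
    core_n = rng.randint(1, 5)
    for i in range(core_n):
        if i == 0 or i == core_n - 1:
            code = "M"
        else:
            code = rng.choice("MIDN")
        ops.append(CigarOp(code, rng.randint(1, 300)))
    if rng.random() < 0.5:
        ops.append(CigarOp("S", rng.randint(1, 300)))
    qlen = sum(op.length for op in ops if op.code in "MIS")
    seq = "".join(rng.choice("ACGT") for _ in range(qlen))
    return AlignmentRecord(
        query_name=name,
        reference_name=reference,
        position=rng.randint(1, 800),
        mapping_quality=rng.randint(0, 60),
        cigar=ops,
        sequence=seq,
        is_secondary=rng.random() < 0.05,
        is_duplicate=rng.random() < 0.05,
    )


@pytest.fixture
def anchor() -> AnchorSpec:
    return AnchorSpec(reference_name="chrT", anchor_position=400,
                      softclip_threshold=6)
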