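"""Alignment record model and CIGAR algebra.

The classification of transcript reads as construct-derived (exogenous) or
locus-derived (endogenous) rests entirely on three properties of an aligned
read that are encoded in its CIGAR string: the reference interval it covers,
the number of soft-clipped bases it carries, and whether it spans a splice
gap.  This module defines the record model and those primitives; everything
downstream (classification, simulation, I/O) builds on it.

Coordinates are 1-based and intervals fully closed, following SAM and
genome-browser convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "CIGAR_CODES",
    "QUERY_CONSUMING",
    "REFERENCE_CONSUMING",
    "CigarOp",
    "AlignmentRecord",
    "AnchorSpec",
    "parse_cigar",
    "cigar_to_string",
    "reference_span",
    "total_softclip",
    "is_spliced",
    "clipped_sequences",
    "reverse_complement",
]

#: The nine SAM CIGAR operation codes.
CIGAR_CODES = frozenset("MIDNSHP=X")
#: Ops that consume bases of the query (read) sequence.
QUERY_CONSUMING = frozenset("MIS=X")
#: Ops that consume reference positions.
REFERENCE_CONSUMING = frozenset("MDN=X")

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC ACGTN)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CigarOp:
    """One CIGAR operation: a code from ``MIDNSHP=X`` and a length >= 1."""

    code: str
    length: int

    def __post_init__(self) -> None:
        if self.code not in CIGAR_CODES:
            raise ValueError(f"invalid CIGAR op code {self.code!r}")
        if self.length < 1:
            raise ValueError(f"CIGAR op length must be >= 1, got {self.length}")

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"{self.length}{self.code}"


def parse_cigar(cigar: str) -> list[CigarOp]:
    """Parse a CIGAR string into a list of :class:`CigarOp`.

    ``"*"`` (CIGAR unavailable) parses to an empty list.  Raises
    :class:`ValueError` on any malformed string.
    """
    if cigar == "*":
        return []
    ops = [CigarOp(code, int(length)) for length, code in _CIGAR_RE.findall(cigar)]
    if cigar_to_string(ops) != cigar:
        raise ValueError(f"malformed CIGAR string {cigar!r}")
    return ops


def cigar_to_string(ops: Iterable[CigarOp]) -> str:
    """Inverse of :func:`parse_cigar`; empty list renders as ``"*"``."""
    s = "".join(f"{op.length}{op.code}" for op in ops)
    return s or "*"


@dataclass
class AlignmentRecord:
    """One SAM alignment line, with the flag bits unpacked.

    ``position`` is the 1-based leftmost mapped reference coordinate (SAM
    POS).  ``sequence`` may be ``""`` when the SAM SEQ field is ``"*"``.
    """

    query_name: str
    is_paired: bool = False
    is_first_in_pair: bool = False
    is_unmapped: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False
    is_duplicate: bool = False
    is_qc_fail: bool = False
    reference_name: str = "*"
    position: int = 0
    mapping_quality: int = 0
    cigar: list[CigarOp] = field(default_factory=list)
    sequence: str = ""

    def __post_init__(self) -> None:
        if not self.is_unmapped:
            if not self.cigar:
                raise ValueError(
                    f"{self.query_name}: mapped record requires a CIGAR"
                )
            if self.position < 1:
                raise ValueError(
                    f"{self.query_name}: mapped record requires position >= 1"
                )
        if not 0 <= self.mapping_quality <= 255:
            raise ValueError("mapping_quality must be in [0, 255]")
        self._check_cigar_shape()
        if self.sequence:
            qlen = sum(
                op.length for op in self.cigar if op.code in QUERY_CONSUMING
            )
            if self.cigar and qlen != len(self.sequence):
                raise ValueError(
                    f"{self.query_name}: CIGAR consumes {qlen} query bases "
                    f"but sequence has {len(self.sequence)}"
                )

    def _check_cigar_shape(self) -> None:
        # H only at the extreme ends; S only first/last among non-H ops.
        codes = [op.code for op in self.cigar]
        inner = codes[:]
        while inner and inner[0] == "H":
            inner.pop(0)
        while inner and inner[-1] == "H":
            inner.pop()
        if "H" in inner:
            raise ValueError(f"{self.query_name}: H ops only at extreme ends")
        core = inner[:]
        while core and core[0] == "S":
            core.pop(0)
        while core and core[-1] == "S":
            core.pop()
        if "S" in core:
            raise ValueError(
                f"{self.query_name}: S ops only at the ends of the alignment"
            )


@dataclass(frozen=True)
class AnchorSpec:
    """The classification contract: where to look and what counts as clipped.

    Parameters
    ----------
    reference_name:
        Chromosome / contig holding the gene (e.g. ``"chr14"``).
    anchor_position:
        1-based coordinate of the first base of the ORF's first coding exon.
        Reads must overlap this single position to be classified.
    softclip_threshold:
        Minimum total soft-clipped bases for a read to be called
        construct-derived.  Default 6.
    tag_sequence:
        Optional artificial tag fused at the ORF start of the construct
        (e.g. a 24-nt FLAG tag).  Used only when ``require_tag_match``.
    tag_min_kmer:
        Exact k-mer length required for a clip/tag match.  Default 6.
    require_tag_match:
        If true, a clip above threshold is only called exogenous when one
        of its clipped sequences shares an exact ``tag_min_kmer``-mer with
        the tag or its reverse complement.
    """

    reference_name: str
    anchor_position: int
    softclip_threshold: int = 6
    tag_sequence: str | None = None
    tag_min_kmer: int = 6
    require_tag_match: bool = False

    def __post_init__(self) -> None:
        if self.anchor_position < 1:
            raise ValueError("anchor_position must be >= 1")
        if self.softclip_threshold < 1:
            raise ValueError("softclip_threshold must be >= 1")
        if self.require_tag_match:
            if not self.tag_sequence or len(self.tag_sequence) < self.tag_min_kmer:
                raise ValueError(
                    "require_tag_match needs a tag_sequence of length "
                    ">= tag_min_kmer"
                )


#: One-line reproduction of the source study's configuration: FOS ORF start
#: on GRCh38 (chr14:75278983), six-base clip threshold, 24-nt FLAG tag.
FOS_GRCH38 = AnchorSpec(
    reference_name="chr14",
    anchor_position=75278983,
    softclip_threshold=6,
    tag_sequence="GACTACAAGGATGACGACGATAAG",
)

PRESETS: dict[str, AnchorSpec] = {"fos-grch38": FOS_GRCH38}


def reference_span(record: AlignmentRecord) -> tuple[int, int]:
    """Closed 1-based interval ``[start, end]`` covered on the reference.

    M, D, N, =, X consume reference; S, I, H, P do not.  Raises
    :class:`ValueError` for unmapped records, which have no span.
    """
    if record.is_unmapped or not record.cigar:
        raise ValueError(f"{record.query_name}: unmapped record has no reference span")
    ref_len = sum(op.length for op in record.cigar if op.code in REFERENCE_CONSUMING)
    return record.position, record.position - 1 + ref_len


def total_softclip(record: AlignmentRecord) -> int:
    """Total soft-clipped bases (sum of S op lengths; hard clips ignored)."""
    return sum(op.length for op in record.cigar if op.code == "S")


def is_spliced(record: AlignmentRecord) -> bool:
    """True iff the alignment spans at least one splice gap (N op)."""
    return any(op.code == "N" for op in record.cigar)


def clipped_sequences(record: AlignmentRecord) -> tuple[str, str]:
    """The soft-clipped read bases at each end: ``(left_clip, right_clip)``.

    Requires the sequence to be present when there are S ops (SAM permits
    SEQ ``"*"``, in which case the clipped bases are unrecoverable and a
    :class:`ValueError` is raised).
    """
    ops = [op for op in record.cigar if op.code != "H"]
    left = ops[0].length if ops and ops[0].code == "S" else 0
    right = ops[-1].length if len(ops) > 1 and ops[-1].code == "S" else 0
    if (left or right) and not record.sequence:
        raise ValueError(
            f"{record.query_name}: cannot extract clipped sequence, SEQ absent"
        )
    seq = record.sequence
    return seq[:left] if left else "", seq[len(seq) - right:] if right else ""
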