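"""Ground-truth simulator: a toy locus and aligned reads of known origin.

The simulator emulates the situation the classifier is built for.  A toy
reference carries a 5'UTR immediately followed by a CDS, so endogenous
transcript reads are reference-contiguous and align end-to-end.  The
construct transcript is the CDS with an artificial tag fused at its 5' end
(as in a CMV-driven lentiviral cDNA); a read that crosses the tag/CDS
junction carries ``t`` tag bases that have no reference counterpart, and
the deterministic aligner model soft-clips exactly those: CIGAR
``<t>S<L-t>M`` placed at the ORF start.  Truth labels travel with every
read, so recall and precision of the clip rule are measurable exactly, and
the analytic recall under uniform junction offsets is available in closed
form for cross-checking.

The aligner is modelled deterministically rather than by invoking a real
spliced aligner; this keeps the ground truth analytic.  A recipe for
regenerating fixtures with a real aligner is given in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .alignment import AlignmentRecord, AnchorSpec, CigarOp

__all__ = [
    "FLAG_TAG",
    "SyntheticLocus",
    "SimulatedRead",
    "build_locus",
    "simulate_fragments",
    "expected_exogenous_recall",
]

#: 24-nt FLAG-tag coding sequence used as the default artificial tag.
FLAG_TAG = "GACTACAAGGATGACGACGATAAG"

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticLocus:
    """Toy reference with known geometry.

    The locus starts at reference position 1; the 5'UTR occupies positions
    ``1..utr_length`` and the CDS starts at ``anchor_position =
    utr_length + 1``.  The construct transcript is ``tag_sequence`` +
    CDS; the endogenous transcript is the contiguous UTR + CDS.
    """

    reference_name: str
    reference_sequence: str
    utr_length: int
    cds_length: int
    anchor_position: int
    tag_sequence: str
    seed: int

    def __post_init__(self) -> None:
        if self.anchor_position != self.utr_length + 1:
            raise ValueError("anchor_position must equal utr_length + 1")
        if len(self.reference_sequence) < self.utr_length + self.cds_length:
            raise ValueError("reference shorter than UTR + CDS")

    @property
    def endogenous_transcript(self) -> str:
        return self.reference_sequence[: self.utr_length + self.cds_length]

    @property
    def construct_transcript(self) -> str:
        cds = self.reference_sequence[self.utr_length:
                                      self.utr_length + self.cds_length]
        return self.tag_sequence + cds

    def anchor(self, softclip_threshold: int = 6,
               require_tag_match: bool = False) -> AnchorSpec:
        """AnchorSpec pointing at this locus's ORF start."""
        return AnchorSpec(
            reference_name=self.reference_name,
            anchor_position=self.anchor_position,
            softclip_threshold=softclip_threshold,
            tag_sequence=self.tag_sequence,
            require_tag_match=require_tag_match,
        )


@dataclass
class SimulatedRead:
    """One simulated alignment record plus its ground truth."""

    truth_origin: Literal["ENDOGENOUS", "EXOGENOUS"]
    transcript_offset: int
    record: AlignmentRecord
    truth_overlaps_anchor: bool
    truth_tag_bases_in_read: int

    def __post_init__(self) -> None:
        if self.truth_origin == "ENDOGENOUS" and self.truth_tag_bases_in_read:
            raise ValueError("endogenous reads carry no tag bases")


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def build_locus(seed: int, utr_length: int = 200, cds_length: int = 500,
                tag_sequence: str = FLAG_TAG, reference_name: str = "chrT",
                collision_k: int = 6) -> SyntheticLocus:
    """Build a reproducible toy locus whose reference shares no exact
    ``collision_k``-mer with the tag.

    The collision exclusion makes the precision property exact: no
    endogenous read can be soft-clipped by tag-like sequence, so any
    false-positive exogenous call would be a classifier bug.  The
    reference is regenerated (up to 100 draws) until tag-free.
    """
    if utr_length < 1 or cds_length < 1:
        raise ValueError("utr_length and cds_length must be >= 1")
    rng = np.random.default_rng(seed)
    tag_kmers = _kmers(tag_sequence, collision_k)
    for _ in range(100):
        ref = "".join(rng.choice(_BASES, size=utr_length + cds_length))
        if not (_kmers(ref, collision_k) & tag_kmers):
            return SyntheticLocus(
                reference_name=reference_name,
                reference_sequence=ref,
                utr_length=utr_length,
                cds_length=cds_length,
                anchor_position=utr_length + 1,
                tag_sequence=tag_sequence,
                seed=seed,
            )
    raise RuntimeError(
        f"could not draw a reference free of tag {collision_k}-mers "
        "in 100 attempts"
    )


def _endogenous_read(locus: SyntheticLocus, name: str, offset: int,
                     read_length: int, rng: np.random.Generator,
                     spliced: bool, **flagkw) -> SimulatedRead:
    ref = locus.reference_sequence
    L = read_length
    if spliced and L >= 20:
        # N-gap inside the read: a matched bases, skip g, then L-a matched
        a = int(rng.integers(10, L - 9))
        g = int(rng.integers(30, 80))
        end_needed = offset + a + g + (L - a)
        if end_needed <= len(ref):
            seq = ref[offset:offset + a] + ref[offset + a + g:end_needed]
            cigar = [CigarOp("M", a), CigarOp("N", g), CigarOp("M", L - a)]
            span_end = offset + L + g
            return SimulatedRead(
                truth_origin="ENDOGENOUS",
                transcript_offset=offset,
                record=AlignmentRecord(
                    query_name=name, reference_name=locus.reference_name,
                    position=offset + 1, mapping_quality=60,
                    cigar=cigar, sequence=seq, **flagkw),
                truth_overlaps_anchor=(offset + 1 <= locus.anchor_position
                                       <= span_end),
                truth_tag_bases_in_read=0,
            )
        # fall through to unspliced when the gap would run off the locus
    seq = ref[offset:offset + L]
    return SimulatedRead(
        truth_origin="ENDOGENOUS",
        transcript_offset=offset,
        record=AlignmentRecord(
            query_name=name, reference_name=locus.reference_name,
            position=offset + 1, mapping_quality=60,
            cigar=[CigarOp("M", L)], sequence=seq, **flagkw),
        truth_overlaps_anchor=(offset + 1 <= locus.anchor_position
                               <= offset + L),
        truth_tag_bases_in_read=0,
    )


def _exogenous_read(locus: SyntheticLocus, name: str, offset: int,
                    read_length: int, **flagkw) -> SimulatedRead:
    tx = locus.construct_transcript
    tag_len = len(locus.tag_sequence)
    L = read_length
    seq = tx[offset:offset + L]
    t = max(0, tag_len - offset)
    if t >= 1:
        # junction read: tag bases have no reference home -> soft-clipped,
        # alignment starts exactly at the ORF start
        cigar = ([CigarOp("S", t), CigarOp("M", L - t)]
                 if L - t >= 1 else [CigarOp("S", t)])
        pos = locus.anchor_position
        overlaps = L - t >= 1
    else:
        cigar = [CigarOp("M", L)]
        pos = locus.anchor_position + (offset - tag_len)
        overlaps = pos <= locus.anchor_position <= pos + L - 1
    return SimulatedRead(
        truth_origin="EXOGENOUS",
        transcript_offset=offset,
        record=AlignmentRecord(
            query_name=name, reference_name=locus.reference_name,
            position=pos, mapping_quality=60,
            cigar=cigar, sequence=seq, **flagkw),
        truth_overlaps_anchor=overlaps,
        truth_tag_bases_in_read=t,
    )


def simulate_fragments(locus: SyntheticLocus, n: int, read_length: int = 100,
                       exogenous_fraction: float = 0.5, paired: bool = False,
                       seed: int = 0, endogenous_splice_fraction: float = 0.1,
                       junction_only: bool = False) -> list[SimulatedRead]:
    """Simulate ``n`` fragments with uniform start offsets and known origin.

    Parameters
    ----------
    n:
        Number of fragments (a fragment is one read, or a pair when
        ``paired``).  ``n <= 0`` yields an empty list.
    read_length:
        Bases per read; must not exceed the CDS length so every junction
        read has a mappable portion.
    exogenous_fraction:
        Probability that a fragment derives from the construct transcript.
    paired:
        Emit mate pairs (second mate one insert downstream) instead of
        singletons; both mates share the query name, so a correct
        classifier counts them once.
    endogenous_splice_fraction:
        Fraction of endogenous reads given an intron-style N-gap, to
        exercise the splice exclusion.
    junction_only:
        Restrict exogenous fragments to tag/CDS junction reads with tag
        content ``t`` uniform on ``{1..tag_length}`` — the offset model
        under which :func:`expected_exogenous_recall` is exact.
    """
    if not 0.0 <= exogenous_fraction <= 1.0:
        raise ValueError("exogenous_fraction must be in [0, 1]")
    if read_length > locus.cds_length:
        raise ValueError("read_length must not exceed cds_length")
    if n <= 0:
        return []
    rng = np.random.default_rng(seed)
    tag_len = len(locus.tag_sequence)
    endo_tx_len = len(locus.endogenous_transcript)
    exo_tx_len = len(locus.construct_transcript)
    insert = min(3 * read_length, endo_tx_len)
    width = len(str(n - 1))

    reads: list[SimulatedRead] = []
    for i in range(n):
        name = f"frag{i:0{width}d}"
        exo = bool(rng.random() < exogenous_fraction)
        tx_len = exo_tx_len if exo else endo_tx_len
        if paired:
            max_start = max(0, tx_len - insert)
            o1 = int(rng.integers(0, max_start + 1))
            o2 = min(o1 + insert - read_length, tx_len - read_length)
            offsets = [o1, o2]
            flagkws = [
                dict(is_paired=True, is_first_in_pair=True),
                dict(is_paired=True, is_first_in_pair=False),
            ]
        else:
            if exo and junction_only:
                offsets = [int(rng.integers(0, tag_len))]
            else:
                offsets = [int(rng.integers(0, tx_len - read_length + 1))]
            flagkws = [{}]
        for off, fkw in zip(offsets, flagkws):
            if exo:
                reads.append(_exogenous_read(locus, name, off, read_length,
                                             **fkw))
            else:
                spliced = bool(rng.random() < endogenous_splice_fraction)
                reads.append(_endogenous_read(locus, name, off, read_length,
                                              rng, spliced, **fkw))
    return reads


def expected_exogenous_recall(read_length: int, tag_length: int,
                              threshold: int) -> float:
    """Analytic recall of the clip rule on junction-overlapping reads.

    Among construct reads that contain at least one tag base, with start
    offsets uniform, the tag content ``t`` is uniform over
    ``{1..min(tag_length, read_length - 1)}``; the clip rule calls the
    read exogenous exactly when ``t >= threshold``.  E.g. a 24-nt tag,
    100-nt reads and threshold 6 give 19/24.
    """
    if not 1 <= threshold <= tag_length:
        raise ValueError("need 1 <= threshold <= tag_length")
    if tag_length >= read_length:
        raise ValueError("need tag_length < read_length")
    t_max = min(tag_length, read_length - 1)
    return (t_max - threshold + 1) / t_max
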