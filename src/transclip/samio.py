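"""SAM reading and writing, run configuration, and the classify runner.

The text-SAM reader is deliberately self-contained: it parses the 11
mandatory columns line by line, skips and counts malformed lines instead of
aborting, and needs no header to resolve reference names.  BAM input goes
through pysam when the file extension asks for it; the text path never
touches it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .alignment import AlignmentRecord, AnchorSpec, cigar_to_string, parse_cigar
from .classify import (
    Category,
    ClassificationSummary,
    ClassifyOptions,
    FragmentClassification,
    summarize,
)

__all__ = [
    "SamReader",
    "read_sam",
    "write_sam",
    "RunConfig",
    "run_classify",
    "write_summary_tsv",
    "write_fragments_tsv",
]

logger = logging.getLogger(__name__)

_FLAG_PAIRED = 0x1
_FLAG_UNMAPPED = 0x4
_FLAG_FIRST = 0x40
_FLAG_SECOND = 0x80
_FLAG_SECONDARY = 0x100
_FLAG_QCFAIL = 0x200
_FLAG_DUP = 0x400
_FLAG_SUPPLEMENTARY = 0x800


def _record_from_fields(fields: list[str]) -> AlignmentRecord:
    if len(fields) < 11:
        raise ValueError("fewer than 11 mandatory columns")
    flag = int(fields[1])
    seq = fields[9]
    return AlignmentRecord(
        query_name=fields[0],
        is_paired=bool(flag & _FLAG_PAIRED),
        is_first_in_pair=bool(flag & _FLAG_FIRST),
        is_unmapped=bool(flag & _FLAG_UNMAPPED),
        is_secondary=bool(flag & _FLAG_SECONDARY),
        is_supplementary=bool(flag & _FLAG_SUPPLEMENTARY),
        is_duplicate=bool(flag & _FLAG_DUP),
        is_qc_fail=bool(flag & _FLAG_QCFAIL),
        reference_name=fields[2],
        position=int(fields[3]),
        mapping_quality=int(fields[4]),
        cigar=parse_cigar(fields[5]),
        sequence="" if seq == "*" else seq.upper(),
    )


def _record_to_flag(rec: AlignmentRecord) -> int:
    flag = 0
    if rec.is_paired:
        flag |= _FLAG_PAIRED
        flag |= _FLAG_FIRST if rec.is_first_in_pair else _FLAG_SECOND
    if rec.is_unmapped:
        flag |= _FLAG_UNMAPPED
    if rec.is_secondary:
        flag |= _FLAG_SECONDARY
    if rec.is_supplementary:
        flag |= _FLAG_SUPPLEMENTARY
    if rec.is_duplicate:
        flag |= _FLAG_DUP
    if rec.is_qc_fail:
        flag |= _FLAG_QCFAIL
    return flag


class SamReader:
    """Iterate :class:`AlignmentRecord` from a text SAM file.

    Header lines are skipped; malformed alignment lines are counted in
    ``skipped_malformed`` and logged, never silently dropped or fatal.
    """

    def __init__(self, path: str | os.PathLike):
        self.path = Path(path)
        if not self.path.exists():
            raise FileNotFoundError(self.path)
        self.skipped_malformed = 0

    def __iter__(self) -> Iterator[AlignmentRecord]:
        with open(self.path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("@"):
                    continue
                try:
                    yield _record_from_fields(line.split("\t"))
                except (ValueError, IndexError) as exc:
                    self.skipped_malformed += 1
                    logger.warning("%s:%d skipped malformed line (%s)",
                                   self.path, lineno, exc)


class _BamReader:
    """BAM input via pysam; imported lazily so SAM text needs no htslib."""

    def __init__(self, path: str | os.PathLike):
        self.path = Path(path)
        if not self.path.exists():
            raise FileNotFoundError(self.path)
        self.skipped_malformed = 0

    def __iter__(self) -> Iterator[AlignmentRecord]:
        import pysam

        with pysam.AlignmentFile(str(self.path), "rb") as bam:
            for seg in bam:
                yield AlignmentRecord(
                    query_name=seg.query_name or "",
                    is_paired=seg.is_paired,
                    is_first_in_pair=seg.is_paired and seg.is_read1,
                    is_unmapped=seg.is_unmapped,
                    is_secondary=seg.is_secondary,
                    is_supplementary=seg.is_supplementary,
                    is_duplicate=seg.is_duplicate,
                    is_qc_fail=seg.is_qcfail,
                    reference_name=seg.reference_name or "*",
                    position=(seg.reference_start + 1
                              if not seg.is_unmapped else 0),
                    mapping_quality=seg.mapping_quality,
                    cigar=parse_cigar(seg.cigarstring or "*"),
                    sequence=seg.query_sequence or "",
                )


def read_sam(path: str | os.PathLike) -> SamReader | _BamReader:
    """Reader for a SAM text file (or BAM, by ``.bam`` extension)."""
    if str(path).endswith(".bam"):
        return _BamReader(path)
    return SamReader(path)


def write_sam(records: Iterable[AlignmentRecord], path: str | os.PathLike,
              references: dict[str, int]) -> None:
    """Write records as SAM text with an @SQ header per reference.

    Output is byte-deterministic for a fixed record list.  Mate fields
    (RNEXT/PNEXT/TLEN) and qualities are written as unset, which is all
    the classification model needs.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in references.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for rec in records:
            fh.write("\t".join([
                rec.query_name,
                str(_record_to_flag(rec)),
                rec.reference_name,
                str(rec.position),
                str(rec.mapping_quality),
                cigar_to_string(rec.cigar),
                "*", "0", "0",
                rec.sequence or "*",
                "*",
            ]) + "\n")


@dataclass
class RunConfig:
    """Everything one classify run needs."""

    anchor: AnchorSpec
    input_path: str
    output_prefix: str
    options: ClassifyOptions = field(default_factory=ClassifyOptions)
    per_fragment_output: bool = False


#: Fixed row order for the summary TSV (byte-stable output).
_CATEGORY_ORDER = [
    Category.EXOGENOUS_SOFTCLIPPED,
    Category.ENDOGENOUS_MATCHED,
    Category.AMBIGUOUS_CLIP,
    Category.EXCLUDED_SPLICED,
    Category.NOT_OVERLAPPING,
    Category.EXCLUDED_FLAGS,
]

_OVERLAPPING = {
    Category.EXOGENOUS_SOFTCLIPPED,
    Category.ENDOGENOUS_MATCHED,
    Category.AMBIGUOUS_CLIP,
    Category.EXCLUDED_SPLICED,
}


def write_summary_tsv(summary: ClassificationSummary,
                      path: str | os.PathLike) -> None:
    n_overlap = sum(summary.count(c) for c in _OVERLAPPING)
    with open(path, "w") as fh:
        fh.write("category\tcount\tfraction_of_overlapping\n")
        for cat in _CATEGORY_ORDER:
            n = summary.count(cat)
            if cat in _OVERLAPPING and n_overlap:
                frac = f"{n / n_overlap:.6f}"
            else:
                frac = "NA"
            fh.write(f"{cat.value}\t{n}\t{frac}\n")


def write_fragments_tsv(fragments: list[FragmentClassification],
                        path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("query_name\tcategory\tmax_softclip\tspliced_any\t"
                 "tag_matched\n")
        for fc in sorted(fragments, key=lambda f: f.query_name):
            tag = "NA" if fc.tag_matched is None else str(fc.tag_matched)
            fh.write(f"{fc.query_name}\t{fc.category.value}\t"
                     f"{fc.max_softclip}\t{fc.spliced_any}\t{tag}\n")


def _provenance(config: RunConfig, summary: ClassificationSummary) -> dict:
    return {
        "anchor": dataclasses.asdict(config.anchor),
        "options": dataclasses.asdict(config.options),
        "input": os.path.basename(config.input_path),
        "total_fragments": summary.total_fragments,
        "skipped_malformed": summary.skipped_malformed,
        "counts": {c.value: summary.count(c) for c in _CATEGORY_ORDER},
    }


def run_classify(config: RunConfig) -> ClassificationSummary:
    """Classify one input file and write summary TSV + JSON provenance.

    Outputs: ``<prefix>.summary.tsv``, ``<prefix>.provenance.json`` and,
    when requested, ``<prefix>.fragments.tsv``.  Byte-identical outputs
    for identical inputs and configuration.  Partial outputs are removed
    on failure.
    """
    reader = read_sam(config.input_path)
    sink: list[FragmentClassification] | None = (
        [] if config.per_fragment_output else None)
    summary = summarize(reader, config.anchor, config.options,
                        fragment_sink=sink)
    summary.skipped_malformed = reader.skipped_malformed
    prefix = config.output_prefix
    outputs = [f"{prefix}.summary.tsv", f"{prefix}.provenance.json"]
    if sink is not None:
        outputs.append(f"{prefix}.fragments.tsv")
    try:
        write_summary_tsv(summary, outputs[0])
        with open(outputs[1], "w") as fh:
            json.dump(_provenance(config, summary), fh, indent=2,
                      sort_keys=True)
            fh.write("\n")
        if sink is not None:
            write_fragments_tsv(sink, outputs[2])
    except Exception:
        for out in outputs:
            Path(out).unlink(missing_ok=True)
        raise
    return summary
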