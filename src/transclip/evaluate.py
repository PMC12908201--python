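"""Score classifier output against simulator ground truth.

Recall is measured on the fragments the clip rule is *meant* to find:
construct-derived fragments with at least one tag base in a read (only
those acquire a soft clip at the junction).  Precision-style error is the
count of endogenous, anchor-overlapping, unspliced fragments called
exogenous — with tag/reference k-mer collisions excluded by construction
this must be exactly zero.
"""

from __future__ import annotations

import pandas as pd

from .classify import Category, FragmentClassification
from .simulate import SimulatedRead

__all__ = ["truth_table", "evaluate_classifications"]


def truth_table(reads: list[SimulatedRead]) -> pd.DataFrame:
    """Per-fragment truth: origin, tag bases, anchor overlap, splice status.

    Mate-level truths aggregate per query name: tag bases and overlap by
    max/any (a fragment is a junction fragment if either mate crosses the
    junction), splice likewise.
    """
    rows = []
    for sr in reads:
        rows.append({
            "query_name": sr.record.query_name,
            "truth_origin": sr.truth_origin,
            "truth_tag_bases_in_read": sr.truth_tag_bases_in_read,
            "truth_overlaps_anchor": sr.truth_overlaps_anchor,
            "truth_spliced": any(op.code == "N" for op in sr.record.cigar),
        })
    df = pd.DataFrame(rows)
    return (df.groupby("query_name", sort=True)
              .agg(truth_origin=("truth_origin", "first"),
                   truth_tag_bases_in_read=("truth_tag_bases_in_read", "max"),
                   truth_overlaps_anchor=("truth_overlaps_anchor", "any"),
                   truth_spliced=("truth_spliced", "any"))
              .reset_index())


def evaluate_classifications(fragments: list[FragmentClassification],
                             truth: pd.DataFrame) -> dict:
    """Confusion summary of fragment verdicts vs simulator truth."""
    calls = pd.DataFrame(
        {"query_name": [f.query_name for f in fragments],
         "category": [f.category.value for f in fragments]}
    )
    merged = truth.merge(calls, on="query_name", how="inner", validate="1:1")
    exo_call = merged["category"] == Category.EXOGENOUS_SOFTCLIPPED.value

    junction = merged[(merged["truth_origin"] == "EXOGENOUS")
                      & (merged["truth_tag_bases_in_read"] >= 1)
                      & merged["truth_overlaps_anchor"]]
    n_junction = len(junction)
    n_junction_called = int(
        (junction["category"] == Category.EXOGENOUS_SOFTCLIPPED.value).sum())

    endo_clean = merged[(merged["truth_origin"] == "ENDOGENOUS")
                        & merged["truth_overlaps_anchor"]
                        & ~merged["truth_spliced"]]
    n_false_exo = int(
        (endo_clean["category"] == Category.EXOGENOUS_SOFTCLIPPED.value).sum())
    n_exo_calls = int(exo_call.sum())

    return {
        "n_fragments": len(merged),
        "n_junction_exogenous": n_junction,
        "n_junction_called_exogenous": n_junction_called,
        "junction_recall": (n_junction_called / n_junction
                            if n_junction else float("nan")),
        "n_endogenous_overlapping_unspliced": len(endo_clean),
        "n_endogenous_called_exogenous": n_false_exo,
        "n_exogenous_calls": n_exo_calls,
        "exogenous_call_precision": (
            (n_exo_calls - n_false_exo) / n_exo_calls
            if n_exo_calls else float("nan")),
    }
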