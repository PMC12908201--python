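"""Downstream table utilities: DEG filtering, 4-set Venn counts, RT-qPCR.

These are the small, exactly specified computations applied to the study's
result tables: calling genes differentially expressed at |log2FC| >= 1 and
FDR < 0.01, decomposing per-timepoint DEG sets into unique and shared
regions of a four-set Venn diagram, and converting qPCR Ct values to
relative expression as 2^(Ct_reference - Ct_target).  No differential
expression model is fitted here — tables arrive pre-computed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "TIMEPOINTS",
    "DegRecord",
    "CtMeasurement",
    "deg_filter",
    "deg_sets",
    "venn_decompose",
    "venn_table",
    "relative_expression",
]

logger = logging.getLogger(__name__)

#: The study's four sampling timepoints (weeks of osteogenic differentiation).
TIMEPOINTS = ("week0", "week1", "week2", "week3")

LOG2FC_THRESHOLD = 1.0
FDR_THRESHOLD = 0.01


@dataclass(frozen=True)
class DegRecord:
    """One gene's differential-expression result at one timepoint."""

    gene_id: str
    log2fc: float
    fdr: float
    timepoint: str

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        if not math.isnan(self.fdr) and not 0.0 <= self.fdr <= 1.0:
            raise ValueError("fdr must lie in [0, 1]")


@dataclass(frozen=True)
class CtMeasurement:
    """Paired qPCR threshold cycles for a reference gene and a target."""

    sample_id: str
    ct_reference: float
    ct_target: float

    def __post_init__(self) -> None:
        for v in (self.ct_reference, self.ct_target):
            if not math.isfinite(v) or v <= 0:
                raise ValueError("Ct values must be finite and > 0")


def _status(log2fc: float, fdr: float) -> str:
    # boundary semantics: |log2FC| = 1 passes (>=), FDR = 0.01 fails (<)
    if pd.isna(fdr) or not fdr < FDR_THRESHOLD:
        return "not_significant"
    if log2fc >= LOG2FC_THRESHOLD:
        return "up"
    if log2fc <= -LOG2FC_THRESHOLD:
        return "down"
    return "not_significant"


def deg_filter(records: Iterable[DegRecord] | pd.DataFrame) -> pd.DataFrame:
    """Label every (gene, timepoint) row as up / down / not_significant.

    Accepts DegRecords or a DataFrame with columns ``gene_id, log2fc, fdr,
    timepoint``; returns the table with a ``status`` column added.
    Duplicate (gene, timepoint) pairs are an error; rows with missing FDR
    are conservatively not significant (their count is logged).
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        missing = {"gene_id", "log2fc", "fdr", "timepoint"} - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
    else:
        df = pd.DataFrame([r.__dict__ for r in records],
                          columns=["gene_id", "log2fc", "fdr", "timepoint"])
    bad_tp = set(df["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise ValueError(f"unknown timepoints: {sorted(bad_tp)}")
    dup = df.duplicated(subset=["gene_id", "timepoint"])
    if dup.any():
        pairs = df.loc[dup, ["gene_id", "timepoint"]].itertuples(index=False)
        raise ValueError(f"duplicate (gene, timepoint) rows: {list(pairs)[:5]}")
    n_na = int(df["fdr"].isna().sum())
    if n_na:
        logger.warning("%d rows with missing FDR treated as not significant",
                       n_na)
    df["status"] = [_status(fc, q) for fc, q in zip(df["log2fc"], df["fdr"])]
    return df


def deg_sets(filtered: pd.DataFrame, direction: str = "up",
             ) -> dict[str, set[str]]:
    """Per-timepoint DEG sets from a :func:`deg_filter` result.

    ``direction`` is ``"up"``, ``"down"`` or ``"both"`` (union of up and
    down, for a combined Venn).  Timepoints with no rows map to empty sets.
    """
    if direction not in ("up", "down", "both"):
        raise ValueError("direction must be 'up', 'down' or 'both'")
    wanted = {"up", "down"} if direction == "both" else {direction}
    sets: dict[str, set[str]] = {tp: set() for tp in TIMEPOINTS}
    hits = filtered[filtered["status"].isin(wanted)]
    for tp, genes in hits.groupby("timepoint")["gene_id"]:
        sets[str(tp)] = set(genes)
    return sets


def venn_decompose(sets: Mapping[str, set[str]],
                   ) -> dict[frozenset[str], int]:
    """Counts for all 15 non-empty-membership regions of the 4-set Venn.

    Keys are frozensets of timepoints; the value for, say,
    ``{week0, week2}`` counts genes in exactly those two sets and no
    others, so singleton keys give the genes unique to one week and the
    full key the genes shared by all four.  Region counts sum to the size
    of the union.
    """
    missing = set(TIMEPOINTS) - set(sets)
    if missing:
        raise ValueError(f"missing timepoint keys: {sorted(missing)}")
    regions: dict[frozenset[str], int] = {
        frozenset(c): 0
        for r in range(1, len(TIMEPOINTS) + 1)
        for c in combinations(TIMEPOINTS, r)
    }
    universe = set().union(*(sets[tp] for tp in TIMEPOINTS))
    for gene in universe:
        members = frozenset(tp for tp in TIMEPOINTS if gene in sets[tp])
        regions[members] += 1
    return regions


def venn_table(regions: dict[frozenset[str], int]) -> pd.DataFrame:
    """Render region counts as a tidy table, largest memberships last."""
    rows = sorted(
        ((tuple(sorted(k)), v) for k, v in regions.items()),
        key=lambda kv: (len(kv[0]), kv[0]),
    )
    return pd.DataFrame(
        {"region": ["&".join(k) for k, _ in rows],
         "n_timepoints": [len(k) for k, _ in rows],
         "count": [v for _, v in rows]}
    )


def relative_expression(m: CtMeasurement) -> float:
    """Relative expression from Ct values: ``2^(Ct_reference - Ct_target)``.

    Equal cycles give 1.0; a target detected 5 cycles later than the
    reference gives 2^-5 = 0.03125.
    """
    return 2.0 ** (m.ct_reference - m.ct_target)
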