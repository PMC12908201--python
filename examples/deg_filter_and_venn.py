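"""Filter a DEG table and decompose per-week DEG sets into Venn regions.

A gene counts as differentially expressed at a timepoint when
|log2 fold change| >= 1 and FDR < 0.01 (note the boundary semantics:
log2FC exactly 1 passes, FDR exactly 0.01 fails).  The up-regulated sets
of the four weeks are then split into the 15 unique/shared regions of a
four-set Venn diagram.
"""

import pandas as pd

from transclip import deg_filter, deg_sets, venn_decompose, venn_table

table = pd.DataFrame(
    [
        # gene    log2fc  fdr     timepoint
        ("RUNX2",  2.1,  0.0001, "week0"),
        ("RUNX2",  1.8,  0.0005, "week1"),
        ("RUNX2",  1.2,  0.004,  "week2"),
        ("SP7",    1.0,  0.009,  "week0"),   # boundary |FC| = 1: passes
        ("SP7",    2.0,  0.010,  "week1"),   # boundary FDR = 0.01: fails
        ("COL1A1", 1.5,  0.002,  "week2"),
        ("COL1A1", 1.7,  0.001,  "week3"),
        ("MMP13",  -1.4, 0.003,  "week3"),   # down, not in the "up" Venn
        ("ALPL",   0.8,  0.0001, "week1"),   # |FC| < 1: never a DEG
    ],
    columns=["gene_id", "log2fc", "fdr", "timepoint"],
)

labelled = deg_filter(table)
print("per-row verdicts:")
print(labelled.to_string(index=False))

up = deg_sets(labelled, direction="up")
print("\nup-regulated genes per week:",
      {tp: sorted(s) for tp, s in up.items()})

regions = venn_table(venn_decompose(up))
print("\nnon-zero Venn regions (unique and shared up-DEGs):")
print(regions[regions["count"] > 0].to_string(index=False))
print("\nEach gene lands in exactly one region, so the region counts sum "
      "to the union of the four weekly sets.")
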