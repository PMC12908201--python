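# transclip

Separate endogenous from construct-derived transcript reads in RNA-seq by
their soft-clip signature at the start of a gene's open reading frame.

## The problem

When cells are transduced with a lentiviral expression construct for a gene
they also express natively, bulk RNA-seq counts pool both sources: the
construct's CMV-driven cDNA and the endogenous locus produce (near-)identical
mature transcripts. The two can still be told apart at a single genomic
coordinate — the ORF start. The endogenous transcript's 5′UTR is contiguous
with exon 1 on the reference, so endogenous reads crossing the ORF start
align end-to-end (`100M`). The construct transcript instead carries an
artificial tag (e.g. a 24-nt FLAG tag, `GACTACAAGGATGACGACGATAAG`) fused at
the ORF start; when a read crossing that junction is aligned to the genome,
the `t` tag-derived bases have nowhere to go and a spliced aligner
soft-clips them: CIGAR `<t>S<L−t>M` placed at the ORF start. The soft clip
is the diagnostic signature of construct origin.

## The classification rule

For every alignment record overlapping a single anchor coordinate (the first
base of the ORF's first coding exon), with first match winning:

1. secondary / supplementary / unmapped (and by default duplicate or
   QC-fail) records → **excluded (flags)**;
2. records not overlapping the anchor → **not overlapping**;
3. spliced records (CIGAR contains `N`) → **excluded (spliced)** — a splice
   over the anchor says nothing about tag presence;
4. total soft-clipped bases ≥ threshold (default **6**) →
   **exogenous (softclipped)**;
5. zero soft-clipped bases → **endogenous (fully matched)**;
6. clip below threshold → **ambiguous**.

All records sharing a query name form one *fragment* (a read pair or a
singleton) and are counted exactly once: the fragment takes the
highest-precedence verdict among its records, with exogenous > endogenous >
ambiguous > excluded. Optionally, an exogenous call can additionally be
required to share an exact k-mer (default k = 6) with the tag sequence or
its reverse complement.

With read length `L`, tag length `T` and threshold `s`, a junction-crossing
construct read carries `t ∈ {1..T}` tag bases (uniform under uniform start
offsets), so the expected recall of the clip rule on junction reads is
`(T − s + 1)/T` — for `L=100, T=24, s=6`: 19/24 ≈ 0.792. The package
computes this closed form and verifies it by simulation.

The package also bundles a ground-truth simulator (toy locus, deterministic
aligner model, truth labels per read) and the small downstream utilities
used alongside such an experiment: DEG threshold filtering
(|log2FC| ≥ 1 and FDR < 0.01), four-timepoint Venn decomposition of DEG
sets, and qPCR relative expression `2^(Ct_reference − Ct_target)`.

## Worked example

```bash
python examples/classify_simulated_reads.py
```

```
locus: 700 nt reference, ORF start at position 201, 24 nt tag on the construct transcript

fragment counts by category:
  ambiguous_clip         10
  endogenous_matched     131
  excluded_spliced       31
  exogenous_softclipped  37
  not_overlapping        1791

junction fragments (construct reads crossing the tag/CDS junction): 47
recall of the >=6-softclip rule on them: 0.787 (analytic expectation 0.792 — junction reads with fewer than 6 tag bases are unavoidably ambiguous)
endogenous fragments miscalled exogenous: 0 (must be 0: the toy reference shares no 6-mer with the tag)
```

Of 2,000 simulated fragments most lie far from the ORF start
(`not_overlapping`); among anchor-overlapping fragments, every construct
read with ≥ 6 clipped tag bases is called exogenous, reads fully matched
across the junction are endogenous, spliced reads are set aside, and no
endogenous fragment is ever miscalled. The other examples
(`fos_preset_worked_example.py`, `deg_filter_and_venn.py`,
`qpcr_relative_expression.py`) each print a capability in a few lines.

## Command line

```bash
transclip simulate --seed 1 --n 2000 -o sim            # reads.sam + truth + locus
transclip classify sim.sam --reference chrT --anchor-position 201 -o out
transclip classify aligned.sam --preset fos-grch38 -o fos   # chr14:75278983, threshold 6, FLAG tag
transclip evaluate out.fragments.tsv sim.truth.tsv
transclip deg-filter deg.tsv ; transclip venn deg.tsv --direction up
transclip qpcr ct.tsv
```

`classify` writes `<prefix>.summary.tsv` (category counts and fractions),
`<prefix>.provenance.json` (anchor and options echo) and, with
`--per-fragment`, a per-fragment verdict table. Outputs are byte-identical
across reruns on identical input.

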