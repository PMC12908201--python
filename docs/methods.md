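# Methods

## Model

transclip decides, per sequenced fragment, whether a transcript read came
from a native genomic locus or from an integrated expression construct, by
inspecting alignments at one genomic coordinate: the first base of the
ORF's first coding exon (the *anchor*).

The decision rests on two structural facts. First, the endogenous
transcript's 5′UTR and first coding exon are contiguous on the reference,
so an endogenous read crossing the anchor aligns without interruption and
without clipped bases. Second, the construct transcript is a promoter-driven
cDNA carrying an artificial tag fused at the ORF start; its 5′ side is not
genomic, so a read crossing the tag/CDS junction has `t ≥ 1` bases the
aligner cannot place. A local/spliced aligner (e.g. STAR) reports those as
soft clips: CIGAR `<t>S<L−t>M` anchored at the ORF start. Classification is
therefore pure CIGAR algebra — no re-alignment, no sequence model.

The per-record cascade (first match wins) is: flag exclusions → anchor
overlap → splice exclusion → clip threshold → fully matched → ambiguous.
Two points deserve justification:

* **Splice exclusion before the clip test.** A read spliced across the
  anchor region overlaps the anchor through its `N` gap without sampling
  the junction sequence; it carries no evidence either way and is set
  aside. Overlap is still evaluated against the full reference span
  (including `N` gaps), so such reads are *extracted* and then *excluded*,
  keeping the partition accounting explicit rather than silently dropping
  them.
* **An explicit ambiguous bin.** Only two categories are biologically
  interpreted (soft-clipped = exogenous, fully matched = endogenous), but a
  record with 1–5 clipped bases is neither "fully aligned" nor confidently
  tagged. Binning it as ambiguous keeps "fully matched" literal (zero
  clips) and makes the six categories a true partition: counts always sum
  to the number of distinct fragments, which is asserted on every run.

Fragments, not records, are the counting unit: all records sharing a query
name (a pair or a singleton) yield one verdict, the highest-precedence
record verdict under exogenous > endogenous > ambiguous > excluded-spliced >
not-overlapping > excluded-flags. A tag-bearing clip is positive evidence
of construct origin, while a fully matched mate is consistent with either
origin, hence exogenous wins; an excluded or distant mate never overrides
an informative one.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `anchor_position` | — | 1-based bp | ORF start; the `fos-grch38` preset uses chr14:75278983 (GRCh38) |
| `softclip_threshold` | 6 | bases | short clips arise from sequencing errors and aligner end-trimming; six bases is long enough that a random 6-mer match to flanking sequence is rare (p ≈ 2.4 × 10⁻⁴ per position) yet short enough to catch most junction reads |
| `tag_sequence` | none (preset: 24-nt FLAG) | — | only needed for optional clip/tag verification |
| `tag_min_kmer` | 6 | bases | exact-match k-mer length for verification; mirrors the clip threshold |
| `require_tag_match` | off | — | the length-only rule is the primary definition; sequence verification is a stricter opt-in (see Design choices) |
| `min_mapq` | 0 | — | no mapping-quality filter by default; exposed because upstream pipelines differ |
| `include_duplicates` | false | — | upstream UMI deduplication is assumed; flagged duplicates are excluded to avoid double counting |
| `end_restricted_clip` | false | — | count only the clip at the read end nearer the anchor instead of summing both ends |

Soft clips are summed over both read ends by default: the threshold is
stated as a property of the read ("at least six softclipped bases"), not of
one end. The end-restricted mode is provided for users who want the
junction-facing clip only; "nearer the anchor" is decided by comparing the
distances from the alignment's span endpoints to the anchor. Hard clips
never count — the clipped bases are absent from the record, so their origin
cannot be inspected.

Coordinates are 1-based with fully closed intervals throughout (SAM
convention). CIGAR `=` and `X` are treated as `M` for span and
classification purposes, tolerating both aligner dialects.

## Simulator

The simulator provides ground truth, not realism. A toy locus (defaults:
200 nt 5′UTR + 500 nt CDS, uniform base composition, reference name
`chrT`) defines two transcripts: the endogenous one (UTR + CDS, contiguous
with the reference) and the construct one (tag + CDS). Reads of length
`L` (default 100) start at uniform offsets along a transcript; the aligner
is modelled deterministically — endogenous reads get `<L>M` at the
corresponding reference position, construct reads with `t ≥ 1` tag bases
get `<t>S<L−t>M` at the anchor, construct reads entirely inside the CDS get
`<L>M`. An optional mode gives a configurable fraction (default 0.1) of
endogenous reads an intron-style `N` gap (30–80 nt, placed ≥ 10 nt from the
read ends), with the read sequence taken from the two reference blocks so
spliced records remain internally consistent. Paired mode emits two mates
per fragment (insert = 3 read lengths, capped by transcript length) sharing
a query name.

Two constructions make the headline properties exact rather than
statistical:

* **Tag/reference collision exclusion.** The reference is redrawn (up to
  100 times) until it shares no 6-mer with the tag. Consequently no
  endogenous read can carry tag-like sequence, and a single endogenous
  fragment called exogenous would be a classifier bug — the precision check
  asserts exactly zero.
* **Uniform junction offsets.** With `junction_only`, construct reads are
  restricted to starts with `t ∈ {1..24}` uniform, the model under which
  the recall of the clip rule has the closed form `(T − s + 1)/T`
  (19/24 ≈ 0.792 for the default geometry). The empirical recall is
  checked within three binomial standard errors at n = 10,000.

What passing these tests does *not* show: behaviour under sequencing
error inside the clip, non-uniform coverage, aligner-specific end-trimming
heuristics, multi-isoform loci, or reads whose clipped sequence is
vector-derived rather than tag-derived. The simulator writes qualities as
`*` and models no error process; real-data performance depends on the
upstream aligner's clipping behaviour, which this package consumes but does
not emulate. To regenerate fixtures with a real spliced aligner instead:
write the locus reference as FASTA (`SyntheticLocus.reference_sequence`),
write simulated transcript reads as FASTQ, align with STAR or minimap2
(`--splice` / default spliced presets), and feed the resulting SAM to
`transclip classify`; truth labels still apply because read names are
preserved.

Simulator defaults (fragment counts, the 0.5 exogenous fraction, the 0.1
splice fraction, locus geometry) are the package's own choices of a
plausible desk-scale regime; they are not calibrated to any particular
dataset, and real samples can sit anywhere on the endogenous:exogenous
axis.

## Numerical and I/O choices

* All randomness flows from one integer seed through
  `numpy.random.default_rng`; no global RNG state. Identical seeds and
  parameters give byte-identical SAM/TSV/JSON outputs (no timestamps in
  files).
* The SAM text reader parses the 11 mandatory columns itself, skipping and
  counting malformed lines (including CIGAR `*` on a mapped flag) instead
  of aborting — a whole run should not die on one bad line, and the skip
  count is reported in the provenance JSON. BAM input goes through pysam;
  the text path has no htslib dependency. Round-tripping through the
  writer preserves every modelled field; mate coordinates and qualities
  are not modelled and are written unset.
* Reference-name matching tolerates the `chr` prefix ("chr14" ≡ "14")
  unless strict matching is requested.
* Fragment grouping is by an in-memory map of query names; category counts
  are order-free, so summaries are invariant under input shuffling (tested
  over 100 shuffles).
* DEG boundary semantics are literal: |log2FC| = 1.0 passes (≥), FDR =
  0.01 fails (<). Rows with missing FDR are conservatively not significant
  and their count is logged. Venn decomposition is an exact 15-region
  partition of the union; region counts are checked against a per-gene
  membership-bitmask tally.
* qPCR relative expression is the plain closed form
  `2^(Ct_reference − Ct_target)`; swapping reference and target inverts it
  exactly (checked to 1e-12).

## Design choices where the design was open

* **Tag verification is off by default.** The primary rule is clip length
  alone; the clipped sequence at the 5′ junction of a construct read may be
  vector backbone rather than the tag (the tag's placement in the construct
  is a cloning detail the classifier should not assume), so sequence
  verification is optional, exact-match (k = 6 against tag or reverse
  complement), and user-supplied. When it is on, a long clip without a tag
  k-mer is demoted to ambiguous, never to endogenous.
* **No MAPQ filter by default.** Whether upstream pipelines filtered on
  mapping quality before categorisation is unknowable from the inputs;
  defaulting to no filter reproduces the permissive reading, and the option
  is exposed.
* **Direction-specific Venns.** Up- and down-regulated DEG sets are
  decomposed separately by default (a combined mode exists), since the two
  directions answer different biological questions.

## Limitations

* One anchor per invocation; multi-gene batching is a shell loop.
* Fragment counts only — no TPM/CPM quantification, no DE model fitting,
  no enrichment analysis; DEG tables arrive pre-computed.
* No CRAM input; BAM requires pysam.
* The classifier trusts the aligner: if an aligner end-trims rather than
  soft-clips junction bases, those reads land in the ambiguous or
  endogenous bins and recall drops accordingly.
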