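# Methods

## The analysis in one paragraph

A DRB exon 2 + partial intron 2 amplicon holds two kinds of signal: the
alignable sectors (exon 2 and the intron-2 sectors 2A/2B flanking the
microsatellite), which support ordinary distance-based phylogenetics,
and the (GA)y microsatellite (STR, sector 2R), which cannot be reliably
aligned across alleles. The STR is therefore compared alignment-free:
tandem-amplify each STR sequence ×100, compress with an adaptive
Lempel-Ziv (LZW) coder, take the compressed size in bytes as a
length-and-complexity summary, derive pairwise distances, and cluster
hierarchically. Concordance between the STR grouping and the trees from
the alignable sectors is then quantified with shared bipartitions and
the adjusted Rand index (ARI).

## Synthetic panel generator

The generator (`drbstr.panel`) emulates a 34-allele, 12-lineage *Aotus*
panel. Each record is

    intron1 (15 nt, panel-conserved)
    + exon2 (270 nt)
    + intron2A (40 nt)
    + strFlank5 (20 nt) + central (GA)xN with CT insertions + strFlank3 (20 nt)
    + intron2B (268 nt)

All sectors except the central tract are generated without indels, so a
panel becomes a 1,378-column alignment by right-padding the STR sector
to 785 columns. The 15-nt intron-1 stub is included so that panels lie
on the published coordinate frame; it carries no signal.

Mutation model: per-site substitution to one of the three other bases,
applied hierarchically (base prototype → lineage prototype → allele).
Defaults and their calibration:

| parameter | default | rationale |
|---|---|---|
| between-lineage exon divergence | 0.049/site | yields ~91% mean pairwise exon-2 identity over the panel |
| between-lineage intron divergence | 0.026/site | yields ~95% mean pairwise intron-2A+B identity |
| within-lineage exon / intron rate | 0.005 / 0.0025 | alleles of a lineage are close (~99% within-lineage identity) |
| STR flank divergence | 0.02/site | initial/final STR sectors "similar in all sequences" |
| central repeat count | lineage-specific mean ± sd, rounded Gaussian truncated at 1 | per-lineage length regimes: long (DRB1\*03-like, mean 164 units), intermediate (DRB3\*06-like, 142), short W-lineages (13–56) |
| STR length window | [66, 761] nt | observed extremes of the real panel; draws outside the window are redrawn |
| interruption motif / rate | CT, 2.0 per 10 repeat units | see below |

Interruption positions are drawn **once per lineage** (as relative
positions along the tract) and shared by its alleles: the interruption
pattern is a lineage characteristic, while alleles differ mainly in
repeat count. Interruptions are insertions between repeat units, never
substitutions, so the unit count stays interpretable.

The interruption rate (one CT per five GA units on average) was set so
that the compressed size of the tandem-amplified STR scales
near-linearly with its length, which is the regime the real panel's
printed compressed-size range implies. With much sparser interruptions
a pure (GA)y tract compresses along a square-root law and both the
byte range and the bytes-on-length R² shrink.

What the generator does **not** emulate: PCR/cloning artefacts,
sequencing error, indels in the alignable sectors, recombination
between lineages, compound (GT)x(GA)y repeat architecture, and any
species-level generative difference (species tags are decorative, as
most real lineages are trans-specific). Passing tests therefore show
that the pipeline's logic is sound under the intended signal structure,
not that it is robust to real-data artefacts.

## Sector partition and identity

Coordinates are 1-based inclusive externally (the published
convention), 0-based half-open internally. Partitioning is lossless by
construction and verified by a concatenation round trip. Pairwise
identity uses pairwise gap deletion: columns with a gap in either
sequence of a pair are dropped from numerator and denominator; a pair
with no comparable columns scores 0% with a warning. The published
"±1%" dispersion is not defined further in the source material; we
report both SD and SE over the C(n,2) pairs and compare on the mean.

## Imperfect repeat scanner

"Imperfect search" is defined here explicitly (the original scanning
software's tolerance model is not recoverable): greedy maximal perfect
runs (motif sizes 1–6, primitive motifs only, canonical = smallest
rotation) are merged when the same canonical motif resumes within
`max_gap` nt (default 4 = two dinucleotide units, and never across N);
a merged chain must reach purity ≥ 0.85 (fraction of span bases inside
perfect tilings). Merged chains compete with their constituent perfect
runs, so a clean sub-run survives when its chain fails the purity
filter. Validity thresholds: ≥12 units for mononucleotide runs, ≥4
units otherwise, applied to the floor of the real-valued unit count
(span / unit length — partial trailing units are common). Overlaps are
resolved longest-span first, ties by smaller start then
lexicographically smaller motif, for cross-platform determinism.

The STR 3-sector decomposition takes as central core the detected run
richest in the central motif (GA by default). This covers both a pure
(GA)y run and the compound periodic runs (e.g. GACT-periodic) that
arise when interruptions are dense; boundaries follow motif structure,
not alignment anchors. A sequence whose best run carries fewer than
four GA units is flagged as having no central sector.

## Compression distances

The coder is a faithful classic Unix `compress` implementation: magic
`1F 9D`, flags `0x90` (16-bit max code, block mode), LZW codes growing
from 9 bits, packed LSB-first, with the code stream padded to an 8-code
group boundary at each width change (group counting restarts at the
change, mirroring the reference encoder's buffer flush). CLEAR is never
emitted — panel-scale inputs cannot fill a 16-bit dictionary — which is
a valid stream; the decoder nevertheless honours CLEAR and the KwKwK
special case. Streams are verified byte-exactly against the system
reference decoder (`gzip -d`).

Sequences are encoded as uppercase ASCII (A,C,G,T) with no newlines,
i.e. exactly the bytes of a single-sequence file. Tandem amplification
(×100, no separators) lets the adaptive dictionary saturate on each
sequence's own repeat structure before sizes are read off; the
resolution gain is measurable as a higher lineage-recovery ARI than at
×1.

The "vector obtained from the bytes" of a compressed sequence is
ambiguous between the scalar stream size and the byte-content vector.
Default mode is `size`: d(i,j) = |B_i − B_j|, under which the
Euclidean, Maximum and Manhattan metrics coincide exactly — consistent
with the observation that all metrics gave equivalent results — and
the per-sequence B annotation is what the published figure shows.
`byte_vector` mode (streams zero-padded after the 3-byte header to the
common maximum, standard L2/L∞/L1) is provided for sensitivity
analysis only.

R² is from an ordinary least-squares regression of B on L; it is
undefined (error) for constant L and defined as 0 for constant B.

## Clustering, trees, concordance

Hierarchical clustering uses standard Lance-Williams single/complete
linkage (via scipy); merge heights are monotone for both linkages.
Dendrograms export as rooted ultrametric-style Newick with leaf depth =
merge height / 2.

Neighbour joining runs on p-distances (proportion of differing
comparable columns) — model-based distances are out of scope, a
documented limitation. NJ is exact on additive matrices (property-
tested on random 7–12-taxon trees). Internal edges of numerically zero
length are collapsed before bipartitions are read, so equal-distance
(star) inputs yield no spurious groups. Bootstrap resamples alignment
columns with replacement, rebuilds the tree per replicate, and reports
per-bipartition percentages; replicates on which the builder fails are
skipped with a warning and the denominator adjusted. Supports ≥70% are
treated as supported; the interior-branch test is out of scope.

Grouping concordance reports (support-filtered) shared bipartitions and
the ARI of k-cut clusterings, with k defaulting to the number of truth
lineages. Trees are k-cut by removing the k−1 longest internal edges;
dendrograms by the standard maxclust cut. With truth labels the
comparison also names fused lineages (sharing a cluster in both
groupings) and split lineages.

## Problem sizes and determinism

The default panel is 34 records; tests and the acceptance script use
panels of this size, bootstrap at 20–100 replicates, NJ exactness at
7–12 taxa, the coder corpus at 50 inputs up to ~76 kB, and the scanner
oracle at 50 sequences of ≤200 nt. All randomness flows from explicit
seeds (numpy `default_rng`); a fixed seed reproduces every artifact
byte-identically, which the pipeline manifest checksums verify.

## Known limitations

- The scalar-size distance deliberately discards byte-content
  information; sequences of equal length and similar complexity are
  indistinguishable, so STR clustering fuses length-matched lineages
  (also observed on the real data this emulates).
- p-distance NJ underestimates divergence at high distances; adequate
  for the ~91–95% identity regime of these sectors.
- The scanner's imperfection model (gap ≤ 4 nt, purity ≥ 0.85) is an
  explicit stand-in for an unpublished tolerance model; thresholds are
  exposed as parameters.
- Compressed sizes depend on the pinned `.Z` dialect; other LZW
  dialects (different max width, early-change variants) shift B by
  small amounts and are not supported.
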