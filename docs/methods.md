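# Methods

This note records the models, conventions and numerical choices behind
`mitochar`, and what the synthetic-data tests do and do not demonstrate.

## Coordinate model and annotation arithmetic

Coordinates are 1-based and fully inclusive, the convention of printed
mitogenome annotation tables: a feature at 13,380–14,151 spans 772 bp.
A feature with `end < start` wraps the origin of a circular genome; its
length is `L − start + 1 + end` and its sequence is the genome tail
concatenated with the head before orientation. GFF3 export writes
wrapping features with `end > L`, the usual circular-genome convention,
and maps strands J→`+`, N→`−`.

Intergenic nucleotides between adjacent located features are
`start(next) − end(prev) − 1` (negative values are overlaps), with a
closing pair over the origin when the genome is circular. Printed Size
and IGN columns of input tables are parsed but used only for
cross-checking: published tables are not always internally consistent
(in the bundled weevil table, tRNA-Asp's coordinates span 71 bp against
a printed size of 66, and tRNA-Tyr's span 56 against 64; the COI row
prints IGN −8 although COI starts at position 1). All arithmetic here is
therefore recomputed from coordinates, and the gap bookkeeping can
legitimately differ from a publication's own tally. Rows with `n.d.`
coordinates are kept as unlocated placeholders (so reports can say "gene
not located", as is common for tRNA-Ile in weevil mitogenomes) and are
excluded from arithmetic.

Start-codon validation accepts the four initiators observed in these
genomes (ATT, ATG, ATA, TTG); stops may be complete (TAA/TAG) or
truncated (`T--`, `TA-`), completed to UAA by polyadenylation. Truncated
stops must agree with the feature length mod 3; disagreement is a
warning, not an error, since the validator is report-based.

## Composition and skews

AT-skew = (A−T)/(A+T) and GC-skew = (G−C)/(G+C). Every per-gene value is
computed on that gene's **sense strand** and labelled with the strand, so
skew signs are always self-consistent; published tables sometimes mix
strands (a gene can print A% > T% alongside a negative AT-skew), which
this package deliberately does not reproduce. Ambiguity codes count
toward region size but are excluded from percentage denominators; skews
are undefined (None) when the denominator is zero. Display rounding is
2 dp half-up; all machine outputs carry full precision.

## Codon-usage indices

All indices use the invertebrate mitochondrial code (NCBI table 5),
taken from Biopython: 62 sense codons in twelve 2-fold, six 4-fold, one
6-fold (Leu) and one 8-fold (Ser) families; UAA/UAG are the only stops.
Codon counting reads non-overlapping triplets from position 1, discards
a trailing incomplete codon (truncated stop) and a complete terminal
stop, skips ambiguous codons, and records internal stops as findings
without counting them. All 13 protein-coding genes feed the pooled
table; the ND2 exclusion used for phylogenetic matrices does not apply
to codon-usage statistics.

* **RSCU(c)** = n_c·k / Σ_family n; undefined when the family is absent.
  Family sums equal the degeneracy k exactly whenever the family is
  observed.
* **ENC** uses Wright's homozygosity F = (nΣp² − 1)/(n − 1) per amino
  acid with n ≥ 2, averaged within each degeneracy class, and
  ENC = Σ_k N_k/F̄_k with (N₂,N₄,N₆,N₈) = (12,6,1,1). The attainable
  range for this code is 20–62. Because F carries a finite-sample bias
  correction, an exactly uniform count table yields an estimate slightly
  above 62; estimates are clamped to 62, the standard convention. For
  the same reason ENC is not exactly invariant under scaling all counts
  by an integer (it moves by ~0.3 when the bundled counts are scaled
  ×10); it is exactly invariant under relabelling codons within a
  family. A class with no amino acid at n ≥ 2 makes ENC undefined, and
  the error names the class.
* **CBI** = (N_opt − N_rand)/(N_tot − N_rand) over degenerate amino
  acids, with N_rand = Σ_aa n_aa·(k_opt/k). The optimal-codon set is a
  genuine modelling choice that published values rarely state; the
  default rule takes every codon with RSCU > 1, with a
  `most_frequent`-per-family alternative. On the bundled weevil counts
  the default rule gives 0.673; small differences from a published CBI
  (0.675 for this dataset) reflect the unstated optimal-set convention
  of the original software, not the three sums, and CBI is therefore
  compared only loosely.

Codons are reported in the RNA alphabet (UUA); DNA input is transcribed
on read.

## Barcode distances and networks

Haplotype collapsing uses complete deletion: any column with a gap or
ambiguity code in any sequence is removed before comparison. Distances
use pairwise deletion, mirroring the defaults of the common
distance-matrix software; both behaviors are explicit function
parameters. K2P: d = −½ln(1−2P−Q) − ¼ln(1−2Q) with P, Q the transition
and transversion proportions; non-positive logarithm arguments
(saturation) yield NaN, which the maximum-distance report excludes with
a warning. An independent cross-check against ape's `dist.dna(model =
"K80")` is part of the test suite.

The median-joining network is built as: (1) Hamming distances on the
collapsed haplotypes; (2) a minimum-spanning network containing every
link within ε (default 0) of its pair's bottleneck (minimax-path)
distance; (3) majority-consensus median vectors of triplets joined in
the network, admitted one at a time (best first, lexicographic
tie-break; three-way column ties resolve to the first haplotype's state,
keeping builds deterministic) whenever they strictly reduce the total
spanning cost; (4) iteration to a fixed point, then deletion of median
nodes absent from every shortest path between observed haplotypes. Edge
lengths are Hamming steps. On homoplasy-free data the network reproduces
the generating tree's edges exactly.

## Supermatrix preparation

"Removing stops and gaps" is implemented as the strictest reading:
terminal codon columns in which any row reads a stop are dropped as
whole triplets (preserving frame), then every column containing a gap in
at least one row is removed. Concatenation pads taxa missing from a gene
with `?` and records 1-based inclusive partitions; by-gene partitioning
only. Writers: relaxed PHYLIP, NEXUS with a sets block, FASTA, and
RAxML-style partition files; PHYLIP/NEXUS round-trip bit-exact.

## Synthetic-data generator

The generator emulates the study system: the default gene order, kinds,
strands and lengths are those of the bundled weevil annotation
(ancestral arthropod arrangement, 37 located features, ~15.4 kb when
features abut); default A+T content 0.76; default codon profile
proportional to the bundled pooled codon counts; default barcode samples
of 23 specimens in 4 haplotypes one mutational step apart (path or star
genealogy, 658 bp, the standard COI barcode length). Protein-coding
genes are sampled codon-by-codon (start from ATT/ATG/ATA/TTG, stop
TAA/TAG, truncated to `T`/`TA` when the requested length is not a
multiple of 3, exercising incomplete-stop handling); non-coding regions
are i.i.d. at the target A+T. Every haplotype receives at least one
specimen; the rest are assigned uniformly at random, so frequencies are
random but the haplotype count is guaranteed — the quantity the recovery
tests assert. Randomness is seed-scoped per operation
(`SeedSequence([seed, op])`), so generated artifacts are reproducible
and order-independent.

Because the default codon profile has its own A+T (~75% across codon
positions), the whole-genome A+T of a default synthetic genome is the
length-weighted mixture of the coding and non-coding targets (~74.6%),
not the non-coding knob itself; the parameter-recovery test asserts
exactly that mixture expectation, and the 0.76 knob directly on
non-coding sequence. Features abut by construction (all gaps zero),
which makes length conservation exact but means the generator does not
emulate real intergenic spacing or overlaps; gap logic is instead tested
on randomized toy annotations and the published table.

What the synthetic tests do **not** show: performance on real
alignments with indels and sequencing ambiguities beyond the handful of
constructed cases, recombination or homoplasy in networks (the MJ
recovery tests use homoplasy-free genealogies by design), and
assembly/annotation quality of real genomes (annotation is an input
here, never inferred).

## Problem sizes

All bundled analyses are desk-scale (a 62-codon table, a 38-row
annotation, ≤23 barcode sequences); the heaviest tests are Monte-Carlo
convergence checks at 30–50k sampled codons and a 15 kb synthetic
genome, chosen as the smallest sizes at which sampling error is well
inside the asserted tolerances (binomial error < 0.5 percentage points
on composition, <0.5 on ENC). The full suite runs in a few seconds.

## Known limitations

* The intergenic-nucleotide tally of a publication may not be
  reproducible from its own coordinates (see above); this package
  reports only the recomputed values.
* De novo annotation, read mapping, multiple alignment and tree
  inference are out of scope by design; the package starts from an
  annotation table and aligned sequences.
* CBI depends on the optimal-codon convention (documented above).
* Median-joining networks are built on complete-deletion haplotypes;
  very gappy alignments can collapse distinct haplotypes.
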