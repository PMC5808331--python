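# Methods

## Scope and model

`lncfam` treats lncRNA family discovery as a graph problem over pairwise
local sequence homology. The unit of analysis is the **locus** (gene-level
identifier), represented by a single isoform; matches between isoforms of
one locus are self-hits by definition and never count as homology. A
**gene family** is a connected component of ≥3 loci in the graph whose
edges are qualifying matches (same-species ncRNA subject, ≥100 alignment
columns, E ≤ threshold). Connected components (single linkage) are the
minimal-assumption reading of "loci sharing significant matches": they
make family sizes well defined without requiring that every pair of
members share the same block. A stricter variant (requiring a common block
across all members) can be emulated by raising `min_match_length`, which
provably only splits or shrinks components (tested).

Degree tallies (loci with exactly one / exactly two distinct partners) are
computed on the full pre-screen graph, alongside — not after — TE
screening; the spectrum of family sizes, by contrast, excludes TE-flagged
families. Both choices are explicit function parameters.

## Alignment engine

The built-in aligner is a shared-k-mer pair prefilter (default k = 11 on
either strand; a pair with no common k-mer is skipped) followed by an
**exact** Smith–Waterman dynamic program (numba kernel, linear gap
penalty). This is deliberately not a heuristic extension stage: exactness
makes the engine's best score per pair provably equal to a full-DP oracle,
which the test suite verifies against an independent implementation
(Bio.Align.PairwiseAligner) on every pair of 50 random sequences. The
k-mer prefilter cannot discard a biologically qualifying hit in practice:
a ≥100 bp match at ≥94% identity contains an exact 11-mer with
overwhelming probability, while random ~1 kb sequence pairs that share no
11-mer have optimal scores far below any significance cutoff.

* Scoring: match +1, mismatch −2, linear gap 2.5/base (megablast-style);
  all configurable via `AlignmentParams`.
* Significance: Karlin–Altschul `E = K·m·n·e^(−λS)` with the ungapped
  +1/−2 constants (λ = 1.28, K = 0.46); search space is query length ×
  total target length; default cutoff E ≤ 1e−6. Any monotone surrogate
  would do for thresholding; the BLAST-style form keeps imported BLASTN
  tabular hits on a comparable scale.
* Secondary alignments of a pair come from greedy Waterman–Eggert-style
  declumping: report the best alignment, mask its query span with the
  never-matching symbol, re-run, up to `max_alignments_per_pair` (default
  4). Ties in the DP argmax resolve to the smallest row/column index, so
  output is deterministic.
* `N` is encoded as a fifth symbol that mismatches everything, including
  another `N`.
* When queries and targets are the same set, each unordered pair is
  aligned once and mirrored — exact, because local alignment is symmetric
  under swapping and reverse complement.

Known limitation: with linear gap costs the DP and the declumping
bookkeeping are exact, but E-values for gapped alignments use ungapped
constants, so absolute E-values are approximate (ordering is preserved).

## Filter cascade and classification

The three filters (rRNA subject, intra-locus, minimum length) are
independent row predicates, so their order is irrelevant (tested across
all six orders). rRNA-ness is judged by subject biotype when the subject
is in the catalog, else by a description-keyword fallback ("ribosomal
RNA"/"rRNA") for external subjects. The ≥100 bp rule is applied to
**alignment columns of a single alignment** (not summed HSPs, not query
coverage): "significant match length" reads most plainly as the length of
one significant match, and per-alignment filtering is monotone and easy to
reason about. The boundary is inclusive ("100 bp or more").

Classification is exhaustive and disjoint: catalog subjects are
same-species (coding vs non-coding by biotype); other subjects resolve via
the accession2taxid map, defaulting to other-species/"unknown" with a
logged warning when unmapped.

## TE screening

A family is flagged when ≥50% of its members have a transposon-library
alignment of ≥100 columns covering ≥50% of that member's
family-supporting span (the envelope of its matched spans on intra-family
edges). The thresholds quantify "family associated with TE matches"
without re-deciding per locus; both fractions and the length are
parameters. Flagged families are retained in output with the reason
string, but excluded from the size spectrum.

## Splicing-event tables

The rMATS junction-count dialect is parsed with pandas; only GeneID,
PValue, FDR and IncLevelDifference are required, so JC and JCEC flavors
both load. The significance rule is strict (`p < 0.005` and
`FDR < 0.05`); rows with missing statistics fail every threshold. MXE
tables parse but are excluded from the four-type report. Intersections
across comparisons operate on deduplicated locus sets (a locus with SE and
RI events counts once); per-event tallies are reported separately, since
printed event counts and locus counts differ whenever a locus has several
events.

## Synthetic data: what it emulates, what it does not

`generate_genome` plants, in an otherwise i.i.d.-uniform ACGT genome
(GC = 0.5 by default, configurable): lncRNA families as independently
mutated copies of a common ancestral block (default lengths 605, 382,
208 nt); lone pairs; TE-decoy families built from fragments of the emitted
transposon library; rRNA loci plus rRNA-contaminated lncRNAs; coding genes
embedding a lncRNA region; and optional cross-species homolog transcripts
listed under a foreign taxon. Genes receive real intron/exon structure and
a fraction of loci get extra isoforms via exon skipping or intron
retention, so isoform selection is exercised; planted blocks are
constrained to lie within one exon, since an intron retained inside the
block would make the longest (representative) isoform carry a split — and
therefore sub-threshold — homology signal by construction, defeating the
planted truth.

`per_base_substitution_rate` (default 0.03) is the expected **pairwise**
divergence between family members; each copy is mutated at half that rate
from the ancestor, so within-family identity sits near 97%. Indels are off
by default and available through `indel_rate`. All randomness flows from
one integer seed through a single numpy Generator in a fixed order, so
outputs are byte-identical across runs and platforms (tested).

What passing on synthetic data does **not** show: real lncRNA families
have composition bias, repeat-rich flanks, and fragmented annotations;
real homology search confronts paralog gradations rather than planted
blocks with clean backgrounds. The generator validates the machinery
(filters, graph logic, screening, tallies), not genome-scale recall.

Event tables plant exact per-type significant counts (defaults 217 SE,
247 RI, 85 A5SS, 131 A3SS, of which 17/55/11/23 on lncRNA loci) and, for
the three-comparison suite, a 29-locus core significant in every
comparison with disjoint private pools elsewhere, so intersection regions
are known exactly. Fillers include exact-boundary rows (p = 0.005,
FDR = 0.05) that a strict filter must exclude.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: genomes of
roughly 40–100 loci (default family sizes 3, 3, 4, 5, 7, 35), 20 fresh
seeds for recovery and TE-screen checks, and 50 sequences (≤1 kb) for the
aligner/oracle comparison — sizes at which exact DP over all pairs is
comfortable and every expected value is countable from the planted truth.
Genome-scale runs (thousands of loci) should substitute external BLASTN
via `import_blast_tabular`; the built-in engine is quadratic per pair.

Other numerical details: coordinates are 0-based half-open everywhere
internally; GFF3 (1-based closed) and BLAST tabular (1-based closed,
subject reversed on minus strand) are converted at the boundaries, each
conversion covered by a test. Isoform-length ties break toward the
lexicographically smallest transcript id. The Rand index used for
recovery is exact pair counting over the lncRNA universe, with
non-family loci treated as singletons; it is cross-checked against
scikit-learn's `rand_score` in the tests.
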