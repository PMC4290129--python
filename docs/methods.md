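# Methods

## The curation model

A similarity search against a classified TE library reports local
alignments, not insertions. Three systematic artefacts separate the two:
overlapping predictions where related references compete for the same
locus; fragmentation of one copy into several matches against different
parts (or different members) of its family, caused by divergence and by
assembly gaps; and the splitting of old elements into distant segments
by younger elements nested inside them. Curation inverts these
artefacts using only hit coordinates, family membership, and the
annotated LTR positions of the reference elements.

Internally, genome coordinates are 0-based half-open; reference
(consensus) coordinates are 1-based inclusive and normalised so
`te_start <= te_end` on both strands, with orientation carried by a
single strand flag. Conversion to the 1-based external formats
(RepeatMasker `.out`, GFF3) happens only in the I/O layer.

**Overlap resolution.** Among two overlapping hits, the one covering a
reference extremity (within `extremity_tol`, 50 nt — the same tolerance
the completeness rule uses) is kept intact; otherwise the longer hit
wins, with deterministic tie-breaks (higher score, then smaller query
start). The loser is trimmed on the overlapping side; its consensus
interval shrinks by linear proportion of the removed query length,
because exact alignment columns are not recoverable from tabular hit
files. Remnants shorter than `min_hit_len` (20 bp) are discarded as
sub-seed noise.

**Collinear merging.** Consecutive hits merge into one feature when
they share family and strand, the query gap is at most `max_gap`
(200 bp, bridging assembly gaps and diverged stretches), and the
consensus coordinates advance, allowing a backward step of at most
`max_consensus_overlap` (50 bp, absorbing target-site duplications and
fuzzy alignment ends). Because the two LTRs of a retrotransposon are
identical at insertion, a search assigns LTR matches to either copy
arbitrarily; a hit lying within an annotated LTR interval (±50 bp) is
therefore tested under both placements and re-placed if that makes the
junction collinear. At most one side of a junction may be re-placed:
re-placing both sides simultaneously can chain the 3'-LTR tail of one
copy onto the 5'-LTR head of the next copy of the same family, which is
exactly the error the dispensation must not introduce.

**Nested reconstruction.** Two features of one family are joined into a
multi-part feature when 1 to `max_intervening` (10) whole predicted TEs
lie wholly inside the junction gap and the junction is collinear under
the same rule (LTR dispensation included). A join with zero intervening
TEs is not attempted — bridging plain sequence gaps is the merge
stage's job and is bounded by `max_gap`, whereas the joining rule is
specifically about crossing other predictions. All intervening features
become nested children of the joined feature. Candidate junctions are
closed greedily until a fixed point, ordered by (i) forward consensus
discontinuity across the junction, clamped below at zero, then (ii) gap
size, then position. The rationale: a true split has essentially no
discontinuity (the two segments overlap by the target-site
duplication), so all true junctions sort together and are closed
innermost-first — nested insertions are younger than their hosts, so
inner junctions are the most reliable — while a spurious same-family
junction (one element truncated immediately before another begins)
shows a large unexplained consensus skip and is only considered after
the true junctions have consumed its pieces. Pure innermost-first
ordering without the continuity key demonstrably mis-joins such
configurations.

**Completeness.** A model is `complete` when the union of consensus
positions covered by its parts reaches `coverage_min` (90%) of a
reference flagged complete, and both extremities are reached within
`extremity_tol` (50 nt); otherwise `fragmented`. Models whose reference
is not a complete element are fragmented by definition.

All thresholds live in `CurateConfig` and are exposed via the CLI's
TOML config.

## Evaluation

Sn = TP/(TP+FN) and Sp = TP/(TP+FP) at three levels. Nucleotide: set
algebra on covered bases. Feature: every contiguous part is an item;
a reference item matches at most one predicted item whose two borders
lie within `border_tol` (10 bp), assigned greedily by smallest total
border distance (the assignment procedure is our choice; the tolerance
is the domain standard). Nested feature: only multi-part features are
items, matched on their outer borders with the same tolerance plus an
exact reconstructed-child-count requirement. Matching is on coordinates
only by default; a `strict_family` flag adds family identity. Sn is
undefined (NA) for an empty reference level, Sp for an empty prediction
level — e.g. an uncurated hit set has no multi-part features, so its
nested-feature Sp is NA and its Sn is 0 whenever the reference has any.

## Insertion dating and dynamics

For an intact LTR-RT, the two LTR sequences are extracted by mapping the
reference's annotated LTR intervals through the feature's parts (linear
interpolation inside a part; exact when the alignment is 1:1), falling
back to de novo terminal-repeat detection on the feature sequence when
the library lacks LTR annotation (repeats must sit within 50 bp of the
feature extremities). The pair is globally aligned (match +2, mismatch
−3, gap open −5, gap extend −2; Biopython's PairwiseAligner), gap
columns are excluded, and divergence K is either the raw mismatch
proportion (default, and what the dating calibration r = 1.3×10⁻⁸
substitutions/site/year was established with) or the Kimura
two-parameter correction; the model used is recorded in the output.
Age T = K/(2r), so K = 0.026 is exactly 1.0 MY.

Per family (≥ 20 dated copies), the activity period is the shortest
order-statistic interval containing strictly more than 80% of the dated
insertions (smallest count `floor(0.8 n) + 1`), found by an exact scan
that a brute-force search over all interval pairs confirms. The burst
date is the midpoint of the fullest 0.1-MY histogram bin among
insertions inside the activity window — restricting to the window keeps
the burst inside it even for pathological age distributions.

Solo-LTR calling takes hits of an LTR library (LTRs of intact elements,
kept only with canonical 5'-TG…CA-3' ends) against the genome and
requires: ≥ 90% coverage of the source LTR (separating solo-LTRs from
short truncated matches), no overlap with any part of an intact LTR-RT,
and flanking 5-mers differing at ≤ 1 position — the target-site
duplication that distinguishes a clean solo-LTR (produced with its TSD
intact by unequal recombination between the two LTRs) from a truncation
remnant.

## Landscape statistics

Windowed profiles (TE bp fraction by coverage union; feature counts by
span midpoint, so no feature is double-counted across overlapping
windows; N99 = smallest number of most-abundant families jointly
reaching 99% of the window's TE bp). Standard scores use the population
standard deviation. Density segmentation is an exact least-squares
dynamic program over window values with user-chosen k — the upstream
literature reports a five-region structure without naming its
algorithm, so the DP is a clean, deterministic stand-in with ties
broken toward the smallest breakpoint positions; model selection for k
is out of scope. Family-distribution clustering drops families never
reaching 0.01% in any window, uses 1 − Pearson correlation with
average linkage (scipy), and reports bootstrap support as the fraction
of window-resampled dendrograms containing each node's leaf set
(default 1,000 replicates; the original protocol used 10,000 — support
values, not topology, are affected by this cost choice). Gene-context
profiles average TE coverage at each oriented position within 20 kb
upstream/downstream of gene starts/ends, excluding positions beyond the
sequence from the denominator.

## Gene capture and chimeras

A capture candidate is a gene whose nearest TE parts upstream and
downstream (each within 5 kb — unbounded adjacency would inflate
candidates) belong to one family. Whether the two flanks are parts of a
single reconstructed element (`same_element`) and whether
superfamily-length k-mers (CACTA 3, LTR-RT 5, Mutator 9, hAT 8)
immediately outside the outer boundaries match with ≤ 1 mismatch
(`tsd_support`) are reported as separate evidence bits rather than
folded into a single yes/no, since either signal alone is ambiguous.
Note that a gene captured inside an element splits it without leaving
any intervening predicted TE, so hit-level curation legitimately
reports such a host as two same-family features; the `same_element`
bit is only expected from annotations that know the insertion history.

Chimera detection takes a tabular protein-similarity result, removes
queries where any single subject's merged hits cover > 70% of the query
length, resolves the rest greedily by descending score (a hit survives
if its overlap with already-kept segments is ≤ 10% of its own length),
merges kept same-subject segments separated by ≤ 5 residues, and calls
a chimera when ≥ 2 segments of ≥ 30 residues from ≥ 2 subjects remain.

## Family classification

Markov clustering on the symmetrised all-by-all similarity graph:
column-stochastic matrix with per-node self-loops equal to the maximum
incident weight, expansion (squaring) alternating with inflation
(entrywise power 1.2 — the coarse granularity used for TE family
definition — then column renormalisation), pruned below 1e-6, to a
1e-6 convergence tolerance or 200 iterations. Attractor rows seed
clusters; overlapping attractor systems merge, and stray nodes attach
to their strongest attractor, so the output is always a partition. On
graphs whose components are cliques this equals the component
partition. Families are named `<superfamily>_famc<rank>` with ranks
assigned per superfamily code by decreasing size (ties by smallest
member id); mixed clusters take the majority code. Variant
sub-numbering (famc8.1-style), which required manual alignment
curation, is out of scope. Terminal-repeat detection self-compares the
first and last 40% of a sequence with exact 12-mer seeds chained per
diagonal and extended ungapped under an X-drop; the best pair needs
≥ 100 bp at ≥ 80% identity with both copies within 50 bp of the
sequence extremities.

## The simulator, and what it does not emulate

Genomes grow by sequential insertion into a random background (GC 0.46,
wheat-like): each insertion duplicates the superfamily-specific
target-site k-mer, optionally nests inside an existing element —
splitting one of its parts, at least 50 bp from part boundaries so
completeness labels stay well-defined — and, for LTR-RTs, mutates each
LTR copy independently with per-site probability r·T (uniform base
exchange, at most one hit per site), so expected pairwise divergence is
2rT to first order and the dating oracle stays analytic. Insertions are
applied oldest-first so hosts predate their guests. Planted solo-LTRs
carry TSDs; planted truncated LTR fragments (40–70% of an LTR) do not;
planted captured genes split a DNA-transposon host without a TSD of
their own. Hit noise: per-part over-fragmentation at a uniform internal
point with consistent consensus sub-ranges, rounded Gaussian border
jitter applied consistently to query and consensus coordinates, false
hits at a configurable rate, and separate re-coding of 3'-LTR-contained
hits to 5'-LTR coordinates (the mis-assignment the merge dispensation
corrects).

Two deliberate idealisations bound what passing tests show about real
data. Nested insertions always choose a host of a different family: a
same-family zero-gap junction is collinear by construction and
therefore unidentifiable from hit coordinates — no coordinate-based
curation could reconstruct it, and real annotations will undercount
such events. And the generator produces neither indel evolution within
elements nor assembly gaps, so the round-trip results certify the
reconstruction logic, not robustness to alignment-level artefacts
beyond the explicit noise models.

## Problem sizes

The test suite and the acceptance script run entirely on simulated
data chosen to exercise each property at convincing but economical
scale: round trips on twenty ~1 Mb genomes of 150–250 insertions at
nesting probability 0.4; noise robustness at over-fragmentation 0.8 and
5 bp jitter; dating recovery with 200 LTR pairs per true age in
{0.5, 1, 2, 3} MY at 300 bp LTR length (recovery is required within 3
binomial standard errors of the truth); solo-LTR calling with 30
planted solo-LTRs against 30 truncated decoys per seed across ten
seeds; ten planted capture events per genome; brute-force oracle
comparisons on ≤ 100 kb evaluation cases, ≤ 40-window segmentations
with k ≤ 5, and ≤ 50-point activity windows.
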