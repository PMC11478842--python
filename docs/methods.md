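# Methods

This note documents the models, estimators and numerical choices behind
`plastomarker`, and what the synthetic data generator does and does not
emulate.

## Coordinates and data model

All coordinates are 0-based half-open on the linearized circle; GenBank's
1-based inclusive locations are converted on read and restored on write.
Circular genomes are linearized at their stored origin; features that wrap
the origin are split into two parts and flagged. IR-duplicated genes are
distinct features sharing a name; "unique genes" counts names. Intergenic
spacers are named `upstream-downstream` from the flanking genes in
forward-strand order. Ns are permitted in sequences and excluded from GC
and diversity denominators.

## Quadripartite detection

The IR pair is found by seed-and-extend: 2-bit-packed k-mers (k = 25,
reduced automatically for very short sequences) of the doubled sequence are
matched against the k-mers of its reverse complement; seeds sharing an
anti-diagonal are merged and extended to maximal exact identity blocks.
Exact identity is the default because assemblers emit byte-identical IR
copies; a mismatch fraction can be allowed, in which case blocks are
greedily extended while the running mismatch fraction stays within budget.
Among blocks ≥ `min_ir_len` (default 1,000 bp) whose two occurrences are
disjoint on the circle, the longest wins; ties are broken by maximizing the
shorter single-copy region, which avoids an unjustifiable appeal to a
"canonical" LSC length. The longer single-copy arc is labelled LSC. The
detector works across the linearization origin (intervals may wrap). A
`canonical_rotation` helper rotates a record so the LSC starts at 0.

Junction reports locate, for each of JLB/JSB/JSA/JLA, the feature
overlapping the boundary (bases on either side are reported; their sum is
the feature's span) or the nearest feature (sides `(0, length)` with the
distance attached). A same-name feature shorter than the longest copy in
the record is flagged as a pseudogene fragment — this is how the truncated
rps19-type copy at JLA and the ycf1-type fragment at JSB surface.

## Variation statistics

SNPs are called per query against a designated reference row of the
alignment: one record per column where both rows carry an unambiguous base
and the bases differ; runs of adjacent differing columns are deliberately
counted column-by-column (multinucleotide variants are positions, not
events). Transitions are purine↔purine / pyrimidine↔pyrimidine exchanges.
Indels are event-based: each maximal gap run present in exactly one of the
two rows is one event, positioned at the nearest preceding reference
coordinate; columns gapped in both rows are ignored.

π is the unweighted average over row pairs of (differences / usable sites),
where a site is usable for a pair when both rows have A/C/G/T. Gap-rich
spacer alignments make pairwise deletion the right choice over complete
deletion, and no Jukes–Cantor correction is applied to π or p-distances
(raw proportions). Windows tile the alignment columns; the window width
defaults to 100 columns with a non-overlapping step — the step is
configurable because published window analyses rarely state theirs.
A window in which no pair has a usable site carries NaN and a `defined`
flag.

Per-locus tables report π, indel diversity, a mutation count and the
aligned locus length. "Indel diversity" is not a standardized quantity; here
it is the mean over row pairs of pairwise indel events divided by the
aligned locus length. The mutation count is the number of distinct
polymorphic columns plus the mean pairwise indel events, since published
hotspot tables conflate substitutions and indels in one column. Hotspots
are the top-k loci by π, ties broken by mutation count then name.

## Repeat finders

**SSRs.** Maximal perfect tandem runs of primitive 1–6 bp units with copy
thresholds 7 (mono), 4 (di) and 3 (tri–hexa). A run is reported at its
smallest period (a homopolymer is never a dinucleotide repeat), spans cover
complete copies only, N breaks runs, and motifs are canonicalized to their
lexicographically minimal rotation (a TA run reports as "AT"). When runs of
different periods overlap, the smaller period claims the locus first and
overlapping calls at larger periods are suppressed; a suppressed run does
not block phase-shifted runs beyond the claimed span. Compound
(interrupted) microsatellites are not merged — no interruption distance is
defined here. The finder is exactly equivalent to a brute-force
every-(start, period) oracle; this equivalence is a test invariant.

**Dispersed repeats.** Gapless repeated pairs ≥ 30 bp with ≤ 3 mismatches,
in four orientations: forward (F), palindromic (reverse complement, P),
reverse (R) and complement (C). A reported pair is *maximal*: extending it
on either side would exceed the mismatch budget or the sequence. With
mismatch positions m₁ < … on an alignment offset, the maximal windows are
exactly those delimited by the (k+1)-th mismatch on each side, which is how
both the implementation and the independent oracle enumerate them. Seeding
uses exact seeds of the pigeonhole length `min_len // (max_mismatch + 1)`
(= 7), which guarantees every qualifying pair contains a seed; for
sequences long enough that random 7-mer matches would dominate
(≳ 20 kb) the seed length grows logarithmically with sequence length, so
genome-scale scans remain fast while near-identical repeats (the realistic
case) stay detectable. Pairs nested inside a longer reported pair of the
same orientation are dropped; results are capped (default 500) by
descending length. The IR pair itself surfaces as the dominant P repeat.

**Tandem repeats.** A bespoke period scan, not a reimplementation of any
external tool (alignment-scoring parameters of such tools are not
emulated): for each period p ≥ 7, positions with S[i] = S[i+p] are marked;
runs of ≥ 8 consecutive matches seed an array, which is extended while the
extension segment's mismatch fraction stays ≤ 0.2 (consecutive-mismatch gaps
are capped at p/2, so random flanks terminate arrays quickly). Arrays must
span ≥ max(22, 2p); the consensus unit is the column majority, near-periodic
units are rejected, and arrays explained by a smaller reported period at the
same locus are suppressed.

Repeat calls are attributed to LSC/SSC/IR by span midpoint (junction-
straddling calls are flagged) and to gene region/intron/IGS through the
per-position annotation.

## Codon usage and selection

The plastid/bacterial genetic code (translation table 11) is used
throughout. RSCU(c) = count(c) · degeneracy / family total, with stop
codons forming their own family; incomplete terminal codons are trimmed
with a log message, and internal stops are counted with a warning (the
synthetic CDSs are not ORF-corrected). Amino-acid group fractions use a
fixed hydropathy/charge assignment (hydrophobic AVLIFMW, hydrophilic
STCYNQ, acidic DE, basic KRH, neutral GP).

Ka/Ks follows the classic counting method: per-codon synonymous site
fractions averaged over both sequences; observed differences averaged over
all minimal mutational pathways with equal weights, pathways through stop
codons excluded (unless all are); Jukes–Cantor correction applied to the
raw proportions, raising an error at p ≥ 3/4. Codons containing gaps or
ambiguity in either sequence are skipped. Selection classes: ratio > 1
positive, = 1 (within 1e-9) neutral, < 1 purifying; Ks = 0 with Ka > 0 is
classed positive (a logged convention), 0/0 is undefined. Gene-set averages
are unweighted means over defined ratios — genes with undefined ratios are
excluded, since no weighting rule is standard. Site-model selection tests
(FUBAR/MEME-style) are out of scope; the per-gene counting estimator is
the implemented screen. Note that under neutral simulation (ω = 1) roughly
half of all genes fall on either side of 1 by sampling noise — classing is
a screen, not a test.

## Diagnostic markers and in-silico PCR

A diagnostic SNP column must satisfy: one shared base across *all* target-
species accessions (intraspecific fixation is enforced whenever multiple
target accessions are present), that base absent from every background
accession, and no gap or N anywhere in the column. Each column carries the
fraction of invariant columns within ±25 bp ("flank conservation",
threshold 0.8 by default — the window and threshold are design choices, as
no published number exists for "conserved flanks").

Primer design is exhaustive and deterministic: all ordered SNP pairs whose
spacing can satisfy the product-size range (default 300–2,500 bp) are
enumerated; the forward primer is target-genome sequence ending 3′ on the
upstream SNP, the reverse primer the reverse complement ending 3′ on the
downstream SNP; primer bodies may cover only columns invariant across all
accessions (except the anchor), which makes binding uniform off the anchor.
Candidates are filtered on length 18–27, GC 35–65%, Tm 52–62 °C (nearest-
neighbour Tm at 50 mM Na⁺, 500 nM primer) and ranked by Tm balance then
flank conservation. `product_size` is the amplicon length (forward 5′ end
to reverse-primer 5′ end). The control pair is drawn from invariant runs
that are contiguous *in alignment columns* — a run interrupted by an indel
column is not co-linear across accessions and is split — with the product
clamped toward the requested ~400 bp.

In-silico PCR scans both strands for full-length primer alignments with at
most 2 internal mismatches and, in strict mode, zero mismatches in the
3′-terminal 3 bases. This purely combinatorial rule is the allele-specific
failure model; no thermodynamic mismatch penalties are applied, matching
the qualitative design of such assays. Convergent site pairs within the
maximum product size (default 3,000 bp) yield amplicons; templates are
treated as circular by scanning a wrap appendix.

## Synthetic data generator

The generator provides families with known truth so every stage is testable
without downloads. The ancestor is a random sequence at 38% GC assembled as
LSC + IRb + SSC + revcomp(IRb), with defaults of 150 kb genome / 25 kb IR
(an ~82:18 LSC:SSC split of the single-copy total); the desk-scale
`compact` variant is 24 kb / 3 kb with 14 genes, used by tests, the
analysis scripts and the acceptance script so that twenty-family
experiments finish in seconds. Genes take standard plastid symbols; the
layout plants an rps19-like gene across JLB (whose IRb portion mirrors into
a truncated JLA pseudogene), rRNA/tRNA genes inside the IR (fully
duplicated), an ndhF-like SSC gene and a ycf1-like gene spanning JSA with a
truncated mirror at JSB; some LSC genes carry one or two introns.

Evolution runs on the ancestor coordinate frame along a five-species tree
(newick, branch lengths in expected substitutions per site; the outgroup-
like last taxon is the reference; the barcoding target gets two accessions
separated by short terminal branches). Substitutions are placed per site
with probability branch length × region multiplier (LSC/SSC 1.0, IR 0.1,
one designated spacer ×6 as the planted hotspot) and resolved by a
two-parameter kernel with Ts:Tv = 1.2, inside the range observed in real
plastome comparisons. Because one IR copy is simulated and the genome is
assembled with its reverse complement, the IR evolves concertedly by
construction. Indels (events at ~0.14 per substitution, geometric lengths
with mean 8, matching the relative SNP and indel frequencies reported for
plastome alignments) are confined to single-copy intergenic positions, so
gene coordinates map cleanly between genomes and the true alignment is
exact by construction — no realignment step separates the generator from
the statistics under test. Planted SSR loci undergo unit-aligned slippage
(±1 unit per branch with probability 0.3). Planted diagnostic columns are
placed in LSC spacers at ~400 bp spacing with ±25 bp frozen flanks; after
evolution the target allele is forced into all target accessions and the
ancestral allele elsewhere. Lineage-private substitutions that would create
*unplanned* diagnostic columns are reverted (or, for the rare double hit,
neutralized by a single homoplasy), so the planted set is exactly the
diagnostic truth of the emitted dataset. Four single-copy bases flanking
the region junctions are frozen in a non-complementary state so the IR pair
cannot coincidentally extend by one base — without this, exact boundary
recovery would fail stochastically for a quarter of genomes. The optional
IR expansion captures a prefix of the SSC into the IR for one species
(genes in the captured region gain IR duplicates), emulating the
SSC-gene-capture events seen in real plastomes.

Things the generator does not emulate, and which passing tests therefore do
not establish for real data: compositional heterogeneity (real IRs are
GC-rich because of rRNA genes; simulated IR GC equals genome GC), selection
on coding sequence within genomes (CDSs accumulate internal stops; the
Ka/Ks recovery tests use a dedicated codon-pair simulator with an ω
knob instead), indels inside exons or the IR, rate variation beyond the
region multipliers, alignment error (the truth alignment is used directly;
an unaligned FASTA export exists for external realignment), and
rearrangements other than the single IR-expansion event.

Determinism: one `numpy` Generator seeded from the config seed drives
everything; the same seed reproduces records, alignment and truth tables
byte-for-byte.

## Problem sizes

The test suite and `scripts/acceptance.py` use the 24 kb compact family
(20 seeds for recovery statistics), one 150 kb full-size family for
structural metrics, 200 fuzzed sequences of 0.15–2.5 kb for the
repeat-oracle equivalence, 100 simulated codon-aligned pairs for the Ka/Ks
oracle, and 40 genes × 200 codons per ω regime for selection recovery —
sizes chosen so the whole acceptance run completes in well under a minute
per family while keeping Monte-Carlo errors small relative to the
tolerances tested.

## Known limitations

- The IR detector assumes a single dominant inverted pair; genomes with
  multiple long inverted duplications could tie in pathological ways
  (resolved deterministically, but not biologically).
- Small IR-internal inversions are not auto-detected; they would surface
  only through junction-gene orientation.
- Whether a reported IR length includes junction-straddling gene fragments
  is convention-dependent; raw interval lengths are reported.
- The tandem finder's copy numbers include short chance extensions at array
  edges (bounded by the mismatch budget); spans, not copy counts, are the
  reliable quantity.
- `find_dispersed_repeats` trades guaranteed sensitivity for speed above
  ~20 kb (see above); at the scale where oracle equivalence is asserted the
  pigeonhole seed guarantees completeness.
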