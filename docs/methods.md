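# Methods

This note documents the models, parameters and design choices behind
berrylink, and what the synthetic-community validation does and does not
demonstrate.

## Conventions

All coordinates are 0-based half-open internally; GFF3 and SAM are emitted
1-based at serialization, BED 0-based. The residue alphabet is
`{A,C,G,T,N}`; other IUPAC codes are mapped to `N` on ingest with a logged
warning, and `N` counts as a mismatch in *every* comparison (conservative
and deterministic). All randomized steps take an explicit seed and are
reproducible bit-for-bit.

## Quality trimming

`quality_trim` fixes the stage order adapter-clip → end-trim → sliding
window → length filter, mirroring the common trimmer convention for the
corresponding flags. Defaults: window 4 bp, minimum window mean quality 15,
end-quality threshold 2, minimum retained length 100 bp. Adapter removal is
exact-match search of the supplied adapter strings anywhere in the read,
clipping from the leftmost adapter start — simple, testable, and sufficient
for synthetic reads; palindrome-mode adapter trimming is out of scope. The
operation is idempotent, and the Phred encoding (Sanger +33 on disk) and
adapter list are configurable since upstream instruments vary.

## CRISPR array detection

`detect_arrays` is a CRT-style detector: an exact 8-mer seed recurring at a
spacing compatible with one array unit (repeat 19–48 bp + spacer 18–60 bp)
nominates a candidate repeat; the seed is extended outward while the two
copies agree; all occurrences of the candidate with ≤2 substitutions are
then located genome-wide and chained when consecutive gaps are
spacer-sized. Chains with ≥3 units are reported. Because chance agreement
in the flanking bases can extend a candidate past the true repeat
boundary, overlapping calls of the same locus are resolved by preferring
more units, then the call whose copies disagree least with their own
majority-rule consensus (the true repeat phase has near-zero disagreement;
phase-shifted candidates accumulate mismatches in the chance-matching
columns). Consensus ties break alphabetically. Detection runs on the given
strand only; reverse-complement duplicates across genomes are collapsed by
`dereplicate_repeats`, which keeps every taxon label and assigns
zero-padded repeat ids in sorted (taxon, genome, sequence) order.

The bounds bracket the ~36-bp repeats typical of the target communities;
they are exposed in the API rather than tuned per dataset.

## Spacer mining from reads

`extract_spacers` scans each read for each repeat (both strands, ≤2
substitutions per placement, repeat length within ±12 of the nominal size
36). A *full* candidate is the subsequence strictly between two consecutive
same-strand repeat hits whose length lies in [18, 60]; candidates flanked
on only one side have ambiguous boundaries and are kept as diagnostic
partials, never in the catalog. Candidates are canonicalized to the
repeat's array orientation (minus-strand hits are reverse-complemented), so
plus- and minus-strand reads yield identical catalogs.

"Minimum coverage of supporting neighbor spacers of 2" is read as: a
(repeat, spacer) pair must be observed in ≥2 *distinct* reads. This is the
conservative, implementable reading of a neighbor-support rule whose
internal graph semantics are not otherwise pinned down; it is a config knob
(`min_neighbor_support`), and raising it can only shrink the catalog
(tested monotonicity). Reverse-complement spacer pairs anchored on
*different* repeats are deliberately kept as distinct records — they are
genuine biological observations of the same protospacer from two arrays.
Spacer ids are `repeatID-serial` with serials assigned by descending
support, then lexicographic sequence, so ids are stable across runs.

## Protospacer matching and host prediction

`match_spacers` reports every ungapped full-length placement of every
spacer on every phage, both strands, with mismatches ≤ ⌊(1 − 0.80)·L⌋ (an
epsilon guards the floor against floating-point, so L=30 allows exactly 6).
Ungapped alignment is the defensible reading of "identity over the entire
spacer length"; a gapped mode is deliberately not the default. No PAM
requirement is applied. The matcher is tested for exact agreement with an
exhaustive Hamming scan.

`predict_hosts` formalizes the informal majority reasoning used when a
phage matches spacers from several taxa: argmax of per-taxon hit counts;
an exact tie yields "unassigned" with the ambiguous flag; a runner-up with
≥ half the winner's hits also flags ambiguity; a winner supported by a
single hit is flagged weak. These thresholds are the package's own
deterministic rule, not a statistical test.

## Read mapping and abundance

The internal mapper (`map_reads`) indexes exact 15-mers of both reference
strands, scores candidate placements by full-read Hamming distance, keeps
the best placement when mismatches ≤ 5% of the read length, and breaks
ties uniformly at random under a recorded seed. It is intentionally
minimal — the package's claims concern the downstream statistics, not
alignment quality — and any external mapper can be substituted through the
SAM import path. "Mapped reads" counts primary placements only.

RPKM uses the total trimmed read count of the sample in the denominator
(the natural reading of normalizing to "sequencing depth of the sample");
per-position coverage tracks are normalized the same way. Depth
conservation (Σ depth = Σ aligned length) is asserted in tests.

## Variants, windows, enrichment, logos

Pileups count A/C/G/T per position from reference-oriented read sequences
(`N` excluded). A position is a variant when any non-reference base has
≥ `min_alt_reads` supporting reads; the default is 1 — deliberately
unfiltered, to maximize recovered variants — with the threshold exposed
for noisy data. Windows are fixed 100-bp tiles anchored at position 0; the
short terminal window is kept and counted un-normalized. A window is
"CRISPR-targeted" when it overlaps a protospacer interval by ≥1 bp — the
minimal reading, with flank size configurable.

Two enrichment estimators are provided. The window estimator
(`protospacer_enrichment`) is the figure-style summary: mean variants per
targeted window over mean variants per background window. Note that it
conflates the underlying rate ratio with window composition: a 34-bp
protospacer inside a 100-bp window contributes only a third of the
window's bases, so a true 3× rate ratio appears as
(66 + 34·3)/100 ≈ 1.7× in window units. The per-bp estimator
(`per_bp_enrichment`) divides variant density inside protospacer bases by
density outside and therefore recovers the substitution-rate ratio
directly; it is the estimator used for parameter-recovery validation.

Sequence-logo matrices (`protospacer_logo`) count only reads that fully
span the interval, and report per-column information content
2 − H(column) in bits. Rendering is left to standard logo tools.

### Choice of `min_alt_reads` in the recovery analyses

With uniform per-base error rate e and depth d, the expected number of
error reads at a site is d·e (0.15 at d=30, e=0.005) and
P(≥3 error reads) ≈ 5·10⁻⁴, while a planted allele at frequency 0.5 is
seen ≥3 times with probability >0.999. The recovery analyses therefore
call variants at `min_alt_reads=3`; this is an error-model calculation,
not a fitted constant, and the package default remains 1.

## HGT scan

*High-coverage regions*: candidate runs where depth ≥ fold × the global
median are merged across sub-threshold gaps <50 bp (shot-noise at finite
depth), then each run must have median depth ≥ fold × the median of its
two 1-kb circular flanks (genomes are treated as circular); runs shorter
than 200 bp are dropped. Regions within one flank of the assembly origin
are *flagged* as possible circular-permutation artifacts rather than
filtered — terminal redundancy of circularly permuted phage genomes
produces the same signal.

*Region→host alignment*: exact 12-mer seeds, ungapped X-drop extension
(match +1, mismatch −1, X=12), all alignments ≥100 bp at ≥80% identity,
both strands. A single-base indel in the host copy therefore splits the
alignment into two segments flanking the indel, which is itself diagnostic.

*Short repeats*: `find_short_repeats` enumerates, per diagonal of the
(a, b) comparison (direct) or (a, revcomp(b)) comparison (inverted), every
maximal window containing ≤ `max_mismatch` mismatches, reporting those
with length in [min_len, max_len]. This is exact — verified against an
O(n·m) dynamic-programming enumeration — unlike heuristic short-word
BLAST. Maximal windows absorb chance-matching flanking bases, so a planted
17-bp repeat is reported as a ≥17-bp pair containing it. Self-comparison
excludes the trivial identity diagonal and reports symmetric pairs once.
`find_tirs` filters inverted pairs to inward-facing arms bracketing
≥500 bp and ranks by arm length, then mismatches.

*Frameshift report*: a global affine-gap alignment (match +1, mismatch −1,
gap open −3, extend −1; scores exposed in the API) locates single-base
gaps; the putative pseudogene is translated in the intact ORF's frame and
the first stop codon before the intact ORF's own stop is reported with its
codon index. Gap placement is unique when the indel base differs from its
neighbors; in homopolymer context the reported offset may shift by the run
length, as with any aligner.

*ANI*: Goris-style — consecutive 1020-bp fragments of the query, each
placed on the subject by exact 16-mer seeding plus ungapped full-fragment
identity on the best diagonal (both strands); fragments with identity
≥30% over ≥70% coverage are kept; ANI is the mean identity of kept
fragments, one-way query→subject (the direction is recorded; reciprocal
averaging is off by default since the convention is ambiguous).
Self-comparison gives exactly 100. Unrelated random genomes share
essentially no 16-mers, so no fragment passes and the result is flagged
undefined rather than reported as a number.

## The synthetic community generator

`build_community`/`simulate_community` emulate the study design the
package targets: 2–4 host genomes (i.i.d. uniform ACGT backbones, which
minimizes accidental repeat structure that would confound array
detection), each carrying CRISPR arrays as `repeat (spacer repeat)ⁿ` runs
written into the backbone at recorded coordinates; 5–10 phage genomes with
per-sample abundance weights; a configurable fraction of spacers copied
from phage genomes with an exact number of substitutions (strand chosen at
random); optional planted variants on phage genomes (background rate
outside protospacers, elevated rate inside, applied to reads at allele
frequency 0.5); and an optional HGT scenario. Reads are drawn with
probability ∝ abundance × length, from either strand with probability 0.5,
with independent substitution errors and constant base quality (no quality
model — trimming is tested on hand-built reads).

Each phage is targeted by exactly one host taxon when phage-derived
spacers are drawn, so "the true host of phage X" is well defined and
host-prediction accuracy can be scored exactly.

The HGT scenario plants: a valid donor ORF (ATG…TAA, 600 bp) written into
the donor phage; an imperfect 17-bp direct-repeat copy (1 substitution)
near, but not flush against, the donor gene (in real genomes the repeat
marks a different ORF's N-terminus, and placing it flush would merge it
into the long gene-to-gene alignment); a host insert DR + gene copy + DR
where the gene copy carries one inserted base chosen to differ from both
neighbors (making the optimal alignment's gap placement unique, so the
recovered offset can be compared exactly) and to create a premature stop;
and a separate IS-like element with 25-bp terminal inverted repeats. The
donor-gene region's elevated copy number is emulated by an auxiliary read
source spanning the gene ±150 bp with weight (boost − 1) × the phage's;
its read origins are recorded in phage coordinates, and planted variants
are not applied to these extra copies.

### Reference scenarios and problem sizes

* `default_config`: 3 hosts × 40 kb (2 arrays × 10 spacers of 34 bp,
  36-bp repeats), 5 phages × 30 kb over 3 samples with varied abundances
  (one phage absent from one sample), 50% phage-derived spacers with 2
  substitutions, 36,000 × 150 bp reads per sample (~20× community
  coverage), 0.5% error.
* `enrichment_config`: one 50-kb phage at ~30× with 240 planted
  protospacers (~8.2 kb targeted footprint) at `ratio` × the 0.025/bp
  background variant rate. The footprint is sized by a power argument —
  the relative sampling error of the recovered ratio scales as
  1/√(targeted_bp × rate), ~7% here at ratio 1 — so recovery to within
  25% is a property of the method, not of a lucky seed.
* `hgt_config`: one host, one 30-kb donor phage at ~30×, coverage boost
  4×.

These sizes keep any single validation scenario within seconds to a couple
of minutes on one CPU while leaving ≥3σ margins on the statistical checks.

## What the synthetic validation does not show

Backbones are i.i.d. uniform: there are no genuine repeat families,
mobile elements, GC skew or shared ancestry, so false-positive rates for
array detection and short-repeat finding on real genomes will be higher
than the near-zero rates seen here. Reads are single-end, indel-free and
uniform-error; mapper behavior under real error profiles, and spacer
mining across indel sequencing errors, are untested. Abundance weights are
static per sample — there is no within-sample strain variation except the
planted variants. The host-prediction validation plants a one-host-per-
phage world; real communities can show genuine multi-taxon targeting,
which the ambiguity flags surface but the synthetic truth does not
exercise deeply.

## Known limitations

Gapped spacer-protospacer alignment is reserved but not implemented;
BAM/CRAM and gapped SAM records are out of scope (SAM with `<len>M` CIGARs
only); variant calling is substitution-only (no indels, no phasing); IS
elements are found by their TIR geometry, not classified into families;
and the array detector reports neither leader-end orientation nor CRISPR
subtype.
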