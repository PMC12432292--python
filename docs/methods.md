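# Methods

This note documents the models, conventions and design choices behind
`cladediag`, in the spirit of a methods appendix: what the algorithms
assume, which knobs matter, what the synthetic data does and does not
emulate, and where the design was genuinely open.

## Coordinates, alphabet, missing data

Internally all column arithmetic is 0-based half-open; every reported
position (motif starts, landmark columns) is a 1-based inclusive
alignment column, because that is how diagnostic positions are quoted in
taxonomic writing.

Residues are normalised to uppercase DNA over {A,C,G,T}, the IUPAC
ambiguity letters and the gap `-` (`U→T`, `.`/`~`→`-`); anything else is
a hard error naming the character and position, since a corrupt alignment
silently skews every downstream count. Each residue is represented as a
4-bit base-set mask (A=1, C=2, G=4, T=8), so consensus building is
bitwise OR and "residue r is compatible with code c" is `r & ~c == 0`.
The gap maps to mask 0, a member of no set — this single convention
implements "a gap never matches" everywhere.

**Terminal gap runs are missing data, internal gaps are indels.** Each
row has a coverage span from its first to its last residue column. A
sequence covers a window only if its span contains all of it; otherwise
it is excluded from that window's support and from out-clade denominators
(an incompletely sequenced molecule is not evidence against a motif). An
*internal* gap inside a window, by contrast, positively rejects the
window for that clade: the clade does not share an ungapped motif there.
This distinction mirrors how partial Sanger-derived rDNA sequences behave
in curated alignments, where short sequences simply lack the early
motifs.

## The synapomorphy screen

For a clade C, window w = [s, s+L):

* **Conservation context.** Per column: `gap_fraction` (internal gaps
  among covering sequences) and `majority_frequency` (modal non-gap
  residue among non-gap residues of covering sequences). A column is
  conserved when `majority_frequency ≥ c_min` (default 0.90) and
  `gap_fraction ≤ g_max` (default 0.10); a window is conserved when at
  least `r_min` (default 0.80, inclusive) of its columns are. The 20%
  slack is essential: diagnostic columns are by construction variable
  across the whole alignment, so a screen demanding fully conserved
  windows would never report anything. The thresholds are exposed knobs.
* **Clade consensus.** Per column the minimal IUPAC code covering every
  residue observed among supporting members (input ambiguity codes
  contribute their whole set). Windows with fewer than `min_support`
  (default 2) covering members, or with an internal gap in a covering
  member, are rejected.
* **Out-clade occurrence.** An out-clade sequence (including sequences
  absent from the clade table — they are background for every clade)
  matches iff at every window column its residue set is contained in the
  consensus set. The occurrence fraction must be **strictly** below `t`
  (default 0.10): exactly 10% fails. Matching is positional — the
  alignment already establishes homology — while the *uniqueness* rule
  scans the consensus as a degenerate pattern along each supporting
  member's gap-stripped sequence and demands exactly one occurrence, so
  repeat-region motifs are never reported. When no out-clade sequence
  covers the window the fraction is 0 with a `low_evidence` flag rather
  than a rejection, mirroring how short comparators are handled in
  practice.
* **Degeneracy cap.** At most `d_max` (default 2) degenerate consensus
  characters; a heavily degenerate motif is not diagnostic.
* **Selection.** All candidate windows (lengths 10–40 by default, stride
  1) are reduced per clade by a deterministic greedy: ascending out-clade
  fraction, then descending length, then ascending start; a candidate is
  kept iff it shares no column with one already kept. This automates the
  manual redundancy pruning a human curator would do, with explicit
  tie-breaks so reports are byte-stable. The screen contains no
  randomness at all; reports are invariant under permuting the input
  sequence order.

The enumeration is vectorised (per length, sliding-window cumulative
sums over the mask matrix, with the start axis partitioned into runs of
constant supporting-member sets so each run shares one consensus column
mask), but its contract is the direct definition: the test suite checks
exact equality against an independent brute force on small alignments.

## Two-pass percent distance

Pass 1 aligns the raw sequences globally with **free end gaps**, so
length differences surface as terminal gap blocks; the maximal terminal
blocks in which either row is gapped are cut, and the gap-stripped cores
are realigned with end gaps penalised. The percent difference is counted
over the pass-2 columns. Rationale: overhang trimming requires the
end-gap-free first pass, and penalised end gaps in the second pass stop
the core alignment from drifting apart again.

The aligner is an affine-gap Needleman–Wunsch/Gotoh (match +2, mismatch
−1, gap open −4, gap extend −1 by default; a gap of length k costs
`open + k·extend`). No published scoring scheme exists for this
procedure, so the values are exposed in `ScoringScheme`; the defaults
favour long ungapped cores, which is what a conserved rDNA comparison
wants. Tie-breaking is deterministic (substitution preferred over gap,
gap in the first sequence over gap in the second; with free end gaps,
among equal-scoring end cells the corner, then the largest aligned
prefix). Results are additionally made exactly symmetric by canonically
ordering the input pair. The implementation is checked against a
plain-Python dynamic-programming oracle and against Biopython's
`PairwiseAligner` scores; Biopython is never the implementation.

Gap handling in the percent is a first-class switch because published
figures rarely state it: `exclude` (default, pairwise deletion) drops
internal gap columns from numerator and denominator; `count` scores a
residue-against-gap column as a difference. Ambiguity codes are compared
strictly by default (`R` vs `A` differs); `iupac_overlap=True` treats
intersecting sets as identical. `compared_columns` is always the
denominator actually used, so
`percent = 100·mismatches/compared_columns` holds in every mode.

The master-alignment variant (`msa_column_distance`) applies the same
counting to two rows of an existing MSA, always excluding columns outside
either row's coverage span. `combination_report` runs every
method × gap-mode combination for a set of pairs — when a published
distance does not document its procedure, this table shows which
combination reproduces it.

## The synthetic generator

`generate_dataset` builds an alignment from a random template plus
per-clade recipes: planted motifs (template blocks overwritten
clade-wide), inserts (blocks of new columns, residues in owning clades
and gaps elsewhere; identical inserts may be shared by several clades,
which is how the freshwater-clade insert pattern is emulated),
single-member single-column deletions and single-site variants
(within-clade polymorphism), iid substitution noise outside the clade's
own motif columns, and per-member terminal truncation. All draws come
from one `numpy` generator in a fixed documented order, so the dataset
and its truth tables are byte-stable functions of (config, seed). There
is no tree simulation, no rate heterogeneity, no sequencing-error model:
the screen is positional and never consults a tree, so clade templates
with iid noise are sufficient to exercise every code path. Passing tests
therefore demonstrate correctness of the algorithms under these
conditions, not robustness to phylogenetic rate structure in real data.

**Default dataset** (the study conditions): template length 2000, GC 0.5;
three clades of eight members; eight planted 12-column motifs in the
freshwater-style clade; two 15-column clade-specific inserts; noise rate
0.005; two members with terminal truncation (up to 200/100 residues).
Each planted motif carries exactly two diagnostic substitutions — enough
to be clade-exclusive, few enough that the window still counts as
conserved context — and is flanked by single-column deletion
polymorphisms in two members. The flanks give each motif a hard boundary:
any window extending past them hits an internal gap in a covering member
and is rejected, so the greedy selector (which prefers longer windows)
reports the planted window at its exact start. Length-variable context
around conserved blocks is also how real rDNA behaves; without such
boundaries, "the" motif start is genuinely ill-defined, since every
conserved extension of a diagnostic window is equally diagnostic.

**Landmark fixture** (`landmark_dataset`): four clades of four members,
total alignment length 2188; a 15-column insert shared by the two
freshwater-style clades starting at column 136 (so all other clades show
a gap after position 135); one private diagnostic motif per clade; and a
planted motif at columns 334–345 in the Poseidogoniomonas clade whose
last column carries a two-member C / two-member T polymorphism, giving a
Y consensus at position 345. That motif is flank-bounded like the default
motifs so the reported window always covers the polymorphic column.

`summarize_dataset` reports per-clade mean within/between percent
distances; for iid noise at rate p on a shared template the expected
pairwise difference is `2p(1−p) + (2/3)p²`, which the tests verify.

## Numerical choices and edge cases

* Threshold comparisons: conservation and selection thresholds are
  inclusive (`≥`), the out-clade rule is strict (`<`), as stated.
  Fractions are compared as computed floats; the boundary case
  1 match / 10 evaluated against t = 0.10 is exact in binary and tested.
* Alignment scores use float64; traceback ties are resolved with a 1e-9
  tolerance (scores are small sums of the scheme constants, so this is
  far below the smallest meaningful difference).
* Degenerate inputs: alignments need ≥ 2 rows; empty sequences, ragged
  alignments, duplicate ids, unknown ids and conflicting clade
  assignments raise typed errors; a pair with no mutually covered core
  raises `AllTrimmedError`, which the CLI reports as a row status rather
  than a crash; clades below `min_support` yield an empty report plus a
  warning.
* Problem sizes: the shipped datasets (24×2030 and 16×2188) screen in
  under a second each and a full 1.8 kb two-pass distance takes well
  under a second, so the complete suite and the acceptance script run in
  seconds.

## Acceptance stand-ins

The acceptance script reports percent distances and difference counts on
synthetic stand-in pairs whose planted divergences mirror published 18S
comparisons (3.8%, 0.12%, 38%, 21%, 0.47%, a 2-nucleotide pair, and a
7-difference pair where five differences come from a small insert and are
visible only under gap counting). Fragment lengths (1500–1800 nt) are
typical of the deposited sequences. Each stand-in is constructed with an
exact substitution count, doubles as its own master alignment, and is
pushed through the combination harness; the value reported is computed,
never assigned. At high divergence (38%) the two-pass route scores
slightly below the planted fraction — the optimal alignment trades some
mismatch runs for gaps — which is itself informative: the harness shows
the master-alignment route is the combination that reproduces such
figures exactly.

## Known limitations

* The screen is positional: a motif that migrated to a non-homologous
  location would be missed (the anywhere-scan is used only for the
  uniqueness rule).
* Conservation thresholds interact with clade sizes; with very few
  sequences `majority_frequency` is coarse and the defaults may need
  adjusting.
* The generator's noise model is iid and clade-free; it does not emulate
  rate heterogeneity across sites, secondary-structure constraints, or
  alignment error, so recovery results bound what the screen does under
  clean homology, not under MAFFT artefacts.
* `gap_mode="count"` scores every residue-vs-gap column equally; long
  indels therefore dominate such distances, which is the intended
  behaviour for reproducing insert-driven difference counts but is not an
  evolutionary distance. No model corrections (Jukes–Cantor, K2P) are
  provided by design.
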