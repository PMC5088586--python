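# Methods

## Scope and data model

The package compares annotated circular plastomes. Internally every
coordinate is 0-based half-open; all file formats (GenBank-style feature
tables, the TSV feature dialect, GFF3) are 1-based inclusive, so the
conversion happens at exactly one boundary. Features that wrap the
circular origin are stored unwrapped as two ordered intervals with a wrap
flag, keeping interval arithmetic linear. Ambiguity codes are collapsed
to N on input and N is excluded from composition statistics and never
matches anything in repeat detection — including another N — which
prevents runs of unknown sequence from masquerading as repeats.

"Conserved gene" means: member of an explicit gene list when one is
supplied, otherwise any gene/tRNA/rRNA feature whose name is not
orf-like. Free-standing ORFs with no similarity to known genes are
intergenic by definition, and genes duplicated in the inverted repeat are
counted once. The mean intergenic size divides total intergenic bp by the
number of maximal gaps on the circle (not by the gene count; the
alternative convention would change the number, so the choice is stated
here and in the docstring).

## Inverted-repeat detection

The IR is the longest pair of disjoint segments on the circle such that
one is exactly the reverse complement of the other. Exact identity
(mismatch tolerance zero) is the default because plastid IR copies are
homogenized by gene conversion; the underlying repeat finder is shared
with the dispersed-repeat module, so a mismatch-free maximal pair is what
is reported. Ties on length break to the smallest start coordinate. The
two arcs between the copies become SC1 and SC2, labeled by size (SC1 is
the larger), never by gene content. Junction reports give, for each of
the four IR/SC boundaries, the gene overlapping the junction (the
smallest such feature, so a gene nested in another's span wins) and the
bp of that gene inside either IR copy; junctions falling in intergenic
spacers report the nearest gene at overlap 0.

## Maximal exact repeats

A repeated pair is maximal when no one-position extension on either side
preserves the exact (reverse-complement, for inverted pairs) match.
Detection is seed-and-extend over a k-mer index: matching positions form
contiguous runs on a diagonal (direct, offset pos2−pos1) or an
anti-diagonal (inverted, constant pos1+pos2+len−1), each candidate seed
is extended to the full run it sits in, and seeds covered by an
already-reported run are skipped, so every maximal pair is extended
exactly once. A run that is its own mirror — an exact palindrome — is
reported as its two half-copies. Circularity is handled by seeding on the
sequence extended with min_len−1 wrap-around bases and extending with
indices modulo the genome length; wrapped duplicates are canonicalized
away. For IR-scale searches the seed k-mer is capped (64 bp by default in
the IR detector) because a 5-kb seed index costs more than the extra
candidate checks it saves. The implementation is checked for exact
hit-set equality against an independent quadratic per-diagonal scanner on
random and structured sequences.

Masked coverage is the plain merged union of every interval participating
in at least one hit, divided by genome length. This deliberately replaces
scoring/defragmentation heuristics of dedicated masking tools with union
semantics: no base is counted twice and the number is exactly
reproducible.

## Gene orders and reversal distance

Two genomes reduce to signed permutations over their shared gene set:
IR-duplicated genes collapse to the copy in IR-A, trans-spliced genes are
represented once at their 5′-most exon, and the circle is linearized by
cutting before an anchor gene (default: the first shared gene of genome
A) oriented +. Anchor choice does not affect the distance — the flip of
the whole circle conjugates the permutation without changing d — and this
dihedral invariance is asserted by test.

The distance is the exact Hannenhalli–Pevzner formula for linear signed
permutations, d = (n+1) − c + h + f. The permutation is framed with 0 and
n+1; cycles c are counted on the breakpoint graph (black edges between
adjacent elements, gray edges between consecutive values); a gray edge is
oriented iff its two endpoint positions share parity; components are
connected components of the gray-edge interleaving graph; a nontrivial
unoriented component is a hurdle iff its positions are contiguous within
the circular sequence of all unoriented-component positions; and the
fortress indicator is set when the hurdle count is odd (≥3) and deleting
any hurdle promotes some non-hurdle unoriented component. Hurdle and
fortress handling is implemented in full even though two closely related
plastomes typically sit at d ≤ 1, because the synthetic studies exercise
arbitrary permutations. The implementation agrees with a breadth-first
search over the reversal graph exhaustively for n ≤ 5 (and n = 6 during
development) and on 500 sampled permutations each for n = 6, 7.

Sorting scenarios are produced greedily: at every step some reversal
lowers d by one (d is realizable), so the O(n²) candidates are scanned
and the first distance-decreasing reversal applied. This doubles as a
structural self-check — an incorrect distance would strand the greedy
search.

Substitution counts use pairwise closed-form estimators (raw Hamming,
JC69, K80 with its transition/transversion decomposition) after dropping
gap/N columns; p ≥ 3/4 (JC69) or non-positive log arguments (K80) raise a
saturation error rather than returning a number. This pairwise plug-in
replaces tree-based codon-model branch lengths by design; the rate
operation also accepts an externally estimated substitution count so any
upstream pipeline can be slotted in. ρ = 1000·r/s.

## Intron registry and site mapping

Insertion sites are compared only after mapping onto a common reference
gene (the reference sequences are user-supplied inputs, not bundled
data — the convention is the contract). The concatenated host exons are
globally aligned to the reference with free end gaps (match +1, mismatch
−1, gap open −5, gap extend −2); the site is the reference position
aligned to the host nucleotide immediately preceding the intron, or the
nearest upstream reference position flagged approximate when that host
base sits in a deletion. Alignments below 40% identity raise a homology
error instead of returning a meaningless site. Positional homologs are
grouped by exact (host gene, site) equality. Pairwise intron identity
uses the same scoring, with the denominator counting all alignment
columns including gaps, so the figure reads "identical over an alignment
spanning their entire lengths". Intron class (I/IIA/IIB) is taken from
the annotation; class inference is out of scope.

## EBS/IBS pairing and mobility classification

A group IIA target site is the last 24 nt of the 5′ exon plus the first
3 nt of the 3′ exon. Default windows are the canonical IIA geometry:
IBS1 at positions −6..−1 (abutting the intron), IBS2 at −13..−7, δ′ the
first nucleotide of the 3′ exon (length 1–3, default 1, configurable).
Pairing is antiparallel — motif 5′→3′ against window 3′→5′ — with
Watson–Crick pairs and, by default, G·T wobbles counting as pairing
(wobble is a toggle because either convention is defensible). Verdicts:
perfect = 0 mismatches, near_perfect = exactly 1 (the tightest reading of
"nearly perfect"), otherwise incompatible.

The mobility signature of a family (≥3 members, each with its own target
site) computes D, the mean pairwise mismatch fraction across members'
concatenated EBS1+EBS2+δ motifs, and C, the fraction of members whose
EBS1 and EBS2 both pair (near-)perfectly with their own site.
Retrohoming-like requires D ≥ 0.2 and C ≥ 0.8 (motifs diverged, yet each
copy fits its site); retrotransposition-like requires C < 0.5 (copies
tolerate poor complementarity); anything else is indeterminate — notably
a family of identical, perfectly pairing motifs, which carries no
divergence signal. The thresholds are package defaults exposed as
arguments: the underlying argument is qualitative, so classifier validity
rests on synthetic-recovery tests (≥95% correct over 40 seeds per mode),
not on fitted constants. Consensus conservation f(k) — the fraction of
alignment columns whose most common residue occurs ≥ k times, gaps never
counted — summarizes family-level conservation.

## Synthetic data: what it emulates, and what it does not

The generator plants a quadripartite circular genome: random background
sequence at A+T 0.70 (matching typical plastome composition), an exact IR
(default 8 kb) containing the rRNA-operon gene block duplicated by name
with the IR-B copy on the minus strand, and named, stranded genes in the
two single-copy arcs. Genome sizes default to 50 kb with 60 single-copy
genes of 200–600 bp — a deliberately scaled-down plastome that keeps
every recovery study fast while preserving the structures being measured.
IR maximality is enforced by breaking both one-step extensions at the
planted boundaries, so recovery "exact in length and coordinates" is a
meaningful assertion.

Reversals are sampled between gene boundaries (never splitting a gene),
within a single single-copy arc (never through an IR copy), and a draw
that fails to raise the reversal distance by exactly one — for instance a
segment that undoes an earlier draw — is resampled, so the planted k is
the true minimum distance by construction. Substitutions are i.i.d. per
site under JC69 or K80 at a given expected distance; in paired-genome
simulations the IR copies are re-homogenized after mutation (as gene
conversion does in real plastomes), so derived genomes keep an exact IR.
Repeat planting writes fresh random segment pairs (direct or inverted)
into free intergenic space until the planted union reaches the coverage
target; the truth stores the exact intervals. Intron families copy one
ancestral IIA core (~380 nt, 2% background divergence outside the motifs)
into distinct host-gene sites; retrohoming mode rewrites each copy's
EBS1/EBS2/δ to the reverse complement of its own IBS windows with at most
one residual mismatch, retrotransposition mode keeps the ancestral motifs
and resamples sites until every element carries at least the configured
number of mismatches.

A single top-level seed drives independent named substreams
(sequence/layout/reversals/evolve/repeats/introns), so changing one
component's draw never perturbs another, and identical configurations are
byte-identical.

What the generator does not emulate — and hence what passing recovery
tests cannot show about real data: no indels or rate heterogeneity across
sites, no degenerate/approximate repeats, no IR expansion-contraction
dynamics, no nested or overlapping gene structures, and intron/host
sequences with none of the secondary-structure constraints of real group
II introns. Recovery results on synthetic data demonstrate algorithmic
correctness under the stated model, not robustness to annotation error or
alignment ambiguity in real genomes.

## Numerical and degenerate-input choices

- Ties in repeat/IR selection break to the smallest start coordinate;
  motif location ties break leftmost.
- All-N sequences make A+T undefined (an error, not 0); s = 0 makes the
  rearrangement rate undefined likewise.
- A gene present twice outside the IR is a hard error naming the gene,
  not a silent collapse.
- Fewer than 3 shared genes (gene order) or 3 family members (mobility)
  is an insufficient-data error.
- Stages of the two-genome pipeline with missing inputs are marked absent
  in the report, never zeroed; the renderer recomputes nothing.

## Problem sizes

The test suite and acceptance studies run at desk scale: 50-kb genomes,
60-gene orders, 8-kb IRs, 2-kb oracle sequences, exhaustive reversal
oracles to n = 5 plus 500 samples at n = 6, 7, and 20–40 seeds per
recovery study. These sizes were chosen as the smallest at which each
planted structure is unambiguous against the random background (e.g. a
spontaneous 30-bp repeat in 50 kb of random sequence has probability
~10⁻⁹).
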