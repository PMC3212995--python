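# Methods

This note records the models, algorithms and numerical choices behind
tecat, the assumptions they carry, and what the synthetic benchmark does
and does not demonstrate.

## Discovery: genome self-alignment and family calling

The discovery contract is purely coordinate-based: every pair of genomic
substrings sharing at least `min_identity` (default 0.94) over at least
`min_hit_len` (default 400 nt), stored once with canonical ordering.  The
built-in aligner is a banded seed-and-extend scheme: exact 14-mer seeds
(vectorized integer encoding; k-mers occurring more than 200 times are
skipped as low-complexity guards), chained along diagonals with a 120-nt
gap tolerance, fragments re-stitched across diagonal shifts of up to 16 nt
(indels between copies break exact-diagonal chains), and each candidate
pair refined by a global edit-distance alignment (edlib) whose extended
cigar gives identity over alignment columns.  Both strand relations are
searched; a hit overlapping its partner by more than half the shorter
footprint is discarded as self-diagonal/tandem.  Any external aligner can
replace this stage through the 12-column hit table (`read_hit_dump`).

Hit footprints are merged into piles by interval union per scaffold.  Two
piles are linked when one hit covers ≥ `cov_frac` (default 0.90) of both
pile footprints — the operational meaning of "globally alignable"; families
are the connected components with ≥ 3 members, each ≥ 400 nt.  Piles
containing both ends of a hit are flagged tandem and excluded: the target
is dispersed, isolated insertions.  The 0.90 pile-coverage fraction is a
declared default (mirroring the 90/90 clustering), not a value inherited
from any published aligner, and is exposed in the config.

Assumption: copies of a family are mostly co-linear.  Heavily rearranged
or nested copies would fragment into multiple piles and may fall below the
coverage linkage; nested insertions are out of scope (see Limitations).

## Clustering

Primary clustering is single linkage with the edge rule: best placement of
the shorter sequence inside the longer (edlib infix alignment) exceeds 90%
identity; the infix alignment consumes the whole shorter sequence, which
implements "over ≥ 90% of the length" with the *shorter* sequence as the
denominator.  That choice is deliberate: it lets 5′-truncated copies and
internal fragments join their family.  Components of fewer than 3 members
are reported as unclustered.  Input order never matters: members are
canonically sorted before component labelling.

The relaxed pass compares cluster consensus sequences in translated space:
all 36 frame pairs under BLOSUM62 local alignment; a cluster pair is
linked at threshold *t* when some frame pair reaches identity ≥ *t* with
the aligned span covering ≥ 50% of the shorter consensus.  One
(identity, coverage) value per pair serves every threshold, so link sets
are nested across {0.35, 0.50, 0.75, 0.90} by construction.  The top
threshold is configurable (0.90 or 0.95 are both reasonable readings of
the original protocol).

## Progressive alignment, consensus, centroid

Members are sorted by decreasing length (ties by id); the two longest are
aligned first and every further member is aligned to the running profile.
The profile aligner is an affine-gap Gotoh dynamic program over profile
columns, vectorized row-by-row (the insertion state is computed by a
prefix-scan identity that is exactly equivalent to the sequential affine
recurrence).  Terminal gaps are free on both sides, so fragments attach
with clean terminal gap runs instead of paying end penalties.  Scoring:
match +300 / mismatch −300 on the profile scale against the prescribed gap
open −500 and gap extend −50; a gap in the profile column scores 0.
Members shorter than half the profile go through the same profile-addition
step as everyone else.  By-eye end curation is replaced by an automatic,
logged trim of terminal columns with > 80% gaps.

Consensus: a row *spans* a column unless the column lies in the row's
leading/trailing gap run; internal gaps span (they are deletion states).
Per column, the base held by > 50% of spanning rows is emitted
(independently of how many rows span — this maximises consensus length);
the column is dropped when the deletion state holds a strict majority.
Lowercase marks positions spanned by < 50% of all rows *or* without a
majority base; in the latter case the plurality base is emitted with
alphabetical tie-break.  The tie rule is a design decision: lowercase
signals low confidence without inventing IUPAC output.

Centroid: the member maximising the sum of its all-to-all local alignment
scores (match +1 / mismatch −3, gaps 5/2 — blastn-like), self-score
excluded; ties break toward the longer sequence, then the smaller id, so
the selection is permutation-invariant.

## Structural signatures

Inverted repeats: exact 8-mer seeds between the sequence and its reverse
complement, ungapped extension at +1/−2 with maximal-scoring-span trimming
(ties extend outward, so a single terminal mismatch costs at most 1-2 nt
of endpoint error).  Matches crossing a palindrome center are split into
two adjacent arms; mirrored duplicates collapse to one record.  Reported
IRs must clear arm length (default 10), arm identity (default 0.80) *and*
a Karlin–Altschul-style E-value gate (default 0.1) against an i.i.d. null
with search space L²/2.  The gate matters: in multi-kb sequence,
~15-nt near-perfect inverted coincidences occur at a per-sequence rate
that no identity/length rule alone can suppress without destroying
sensitivity to genuinely short TIRs.  Geometry: palindromic when
near-adjacent arms cover ≥ 80% of the sequence; terminal (TIR) when arm 1
starts in the first 10% and arm 2 ends in the last 10% (the only reading
of the terminal rule consistent with a "sub-terminal" remainder);
sub-terminal otherwise.

Direct repeats (LTR candidates): 12-mer same-strand seeds chained by
diagonal, then refined to the maximal-scoring ungapped span (Kadane on the
diagonal, +1/−2) so endpoints come from signal rather than seed bounding
boxes; retained when both copies fall in the terminal 20% windows, lengths
agree within 20%, and global identity ≥ 0.85.  Within-element LTR identity
is the global-alignment identity over all columns (indel columns count
against identity), in percent.

ORFs are stop-to-stop segments in all six frames with no start-codon
requirement — degenerate TE copies lose their starts, and the reported
quantity is "the largest ORF", which stop-bounded segments measure
directly.  PPT: longest A/G run ≥ 8 within 20 nt upstream of the 3′ LTR.
PBS: exact reverse-complement match ≥ 8 nt between the 20 nt downstream of
the 5′ LTR and the 3′-terminal 18 nt of any supplied tRNA; all qualifying
tRNAs are reported.  These three parameter sets are declared defaults
(the signals' biology fixes their neighbourhoods, not their exact sizes)
and are configurable.

## Homology and positivity

E-values use the ungapped Karlin–Altschul form E = K·m·n·e^(−λS) with
standard parameter sets (+1/−3 nucleotide: λ=1.374, K=0.711; BLOSUM62:
λ=0.3176, K=0.134) and effective space = query length × total library
residues.  They are a ranking/thresholding device: the annotation logic
depends only on the positivity rule (e < 10⁻¹⁵, strictly) and on hit
order, not on numeric agreement with any external engine — externally
computed tables can be loaded instead.  Translated modes search all six
query frames (and all 36 frame pairs for nucleotide libraries), keeping
the best HSP per subject; multi-HSP bookkeeping (`number_of_segments`)
applies to externally supplied tables.

## Classification ladder

A first-match ladder, deterministic by construction (its inputs are sets
of features, never ordered evidence):

1. non-TE when the only positive hits are rRNA/host-gene libraries;
2. order LTR on a terminal direct-repeat pair, an LTR-diagnostic domain
   (protease Peptidase_A17 or integrase RVE), or a known-LTR-element hit;
3. non-LTR on reverse-transcriptase/polyprotein or known-NLTR evidence
   without terminal direct repeats — RVT alone is deliberately *not*
   LTR evidence, since both retroelement orders carry it and the
   structural LTR pair or LTR-specific enzymes must decide;
4. Class II (subclass 1, order TIR) on terminal IRs plus transposase or
   known-element support; non-autonomous (Class II-NA) only via library
   metadata, which is not re-derivable structurally;
5. MITE when short (< 800 nt), non-coding, and its TIR matches a known
   family's TIR at ≥ 0.80 identity over ≥ 15 nt;
6. MITE-like-novel when TIR- or palindrome-flanked, non-coding, and
   without any positive library hit;

"Non-coding" for the MITE rungs means the longest ATG-initiated stretch
inside any stop-bounded segment stays below 300 nt.  The distinction from
the reported "largest ORF" (stop-to-stop, no start requirement) is
deliberate: random DNA of MITE size contains a ≥ 300-nt stop-to-stop
segment in roughly a fifth of sequences, but an ATG-initiated one in only
a twentieth — and coding capacity, which is what a MITE lacks, requires a
start.
7. otherwise repeat-no-signature.

Element type from canonical coverage: full ≥ 0.90, remnant < 0.10,
fragment between (0.90 replaces a literal "100%" to absorb alignment
slop); without a canonical element, structural completeness (intact
termini plus a ≥ 900-nt domain-bearing ORF) decides full vs fragment.
Solo-LTR re-labelling: a consensus matching some LTR family's arm at
≥ 0.80 identity over ≥ 0.80 of the arm, and no longer than 1.5× the arm.
TIR-subfamily linking groups clusters whose arms agree (infix identity
≥ 0.80, ≥ 15 nt) while whole-consensus relatedness stays below 0.50 —
measured as matched residues of the best local alignment over the shorter
consensus, because edit-distance identity of *unrelated* sequences sits
near 0.5 and cannot separate the cases.  Activity indicators (identical
within-element LTRs, intact domain ORF, expression hit) are reported as
flags only; "active" is never a verdict.

## Evolutionary statistics

p-distance: mismatches over compared sites with pairwise deletion of any
column holding a gap or N in either row; mean and population (ddof 0) sd
over all pairs; pairs with no comparable sites are skipped with a log.

Nei–Gojobori (1986): synonymous-site fractions per codon from the 9
single-nt changes (changes to stops count as nonsynonymous); observed
differences split syn/nonsyn by averaging over all minimal mutational
pathways, excluding pathways through stops when a stop-free one exists;
Jukes–Cantor correction d = −¾·ln(1 − 4p/3), flagged undefined at
p ≥ ¾; the reading frame is the cluster's longest consensus ORF projected
back onto alignment columns, and gap/N codons are excluded pairwise.  The
reported ratio is mean dN over mean dS across pairs.

Tajima's D: S counts columns with ≥ 2 base states among rows holding a
base; π is the mean pairwise difference count; the 1989 constants are
recomputed from n alone.  D is NaN (not significant) at S = 0.
Significance uses the beta-distribution approximation: D is rescaled to
[D_min, D_max] = [(2/n − 1/a₁)/√e₂, (n/(2(n−1)) − 1/a₁)/√e₂] and compared
with the two-sided 95% interval of the matching beta law.

## The synthetic benchmark

The simulator plants families into i.i.d. background (default GC 0.44, a
mosquito-like composition), which makes chance 400-bp/94% alignments
effectively impossible and keeps discovery tests sharp.  The default
benchmark is a 2 Mb genome with 12 families at per-copy substitution rate
0.01 and indel rate 5×10⁻⁴: three LTR families (250-300-nt LTRs, a
PBS matching a bundled tRNA 3′ end, a purine tract, and a pol-like ~400-aa
stop-free ORF cassette carrying the bundled synthetic RVT tags; one family
converts half its copies to solo LTRs), three non-LTR families with
geometric 5′ truncation (mean 150 nt — most copies stay near full length,
as needed for 90%-coverage linkage, while the tail exercises the
truncation profiling), three transposase-cassette TIR families (arms
30-50 nt) and three non-coding MITEs (450-600 nt, arms 25-40 nt).  Copy
numbers (5-10) keep every family above the 3-copy floor with margin.

Evaluation matches discovered members to truth copies one-to-one by
reciprocal overlap ≥ 0.5; a family counts as recovered when a single
discovered family matches a strict majority of its *eligible* copies —
those longer than 400 nt, the contract's own visibility limit (solo-LTR
copies of 250 nt are deliberately invisible).  Classification accuracy
maps planted kinds to expected (class, order); planted MITEs are accepted
as (II, TIR) whether labelled MITE or MITE-like-novel, since no known-TIR
library ships with the benchmark.

What passing does **not** show about real genomes: real repeat landscapes
have compositional bias, satellites and low-complexity tracts (the
benchmark's i.i.d. background sidesteps the aligner's low-complexity
behaviour beyond a simple k-mer occurrence cap), nested and rearranged
insertions, families far below 94% identity, and libraries whose homology
relationships are much denser than five synthetic domain tags.  The
benchmark validates the machinery and its thresholds, not genome-scale
completeness.

Coding-sequence recovery checks: sequences descend independently from a
random stop-free ancestor; proposed substitutions fix with probability 1
(synonymous) or ω = 0.2 (nonsynonymous), never through stops, at a per-nt
proposal rate of 0.08 — chosen to put pairwise dS near 0.1, inside the
Jukes–Cantor linear regime.  Nei–Gojobori on the output recovers ≈ 0.19,
the small downward offset being the method's known behaviour at these
divergences.  Neutral Tajima's D calibration samples n = 10 haplotypes
from msprime coalescent simulations with JC69 mutations.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open internally; reports are 1-based.
- Non-ACGTN letters normalize to N (logged); N never counts as a match.
- Genomes shorter than `min_hit_len` return no hits with a warning;
  empty FASTA, duplicate ids and gap characters in unaligned FASTA are
  hard errors naming the offender.
- Single-member clusters cannot be aligned (error at the aligner; the
  pipeline only aligns clusters of ≥ 3).
- All stages sort canonically, so the emitted database is byte-identical
  across runs and member orderings; the only randomness anywhere is the
  simulator's seed.
- Profile-alignment memory is O(profile × member) with three float64
  score matrices; clusters of ~6 kb members peak near 1 GB transiently.

## Known limitations

- Discovery extracts all family members on the + strand; a family planted
  in mixed orientations would cluster only per orientation.
- Nested insertions and tandem satellite structure are not modelled by the
  simulator and not resolved by pile condensation (flagged future work).
- Endpoint accuracy of signature detection is evidence-limited: mutations
  in the terminal 2-3 nt of a TIR/LTR arm remove the only signal that the
  arm extends there, so ±2-nt endpoints are guaranteed only for intact
  arm ends.
- The Karlin–Altschul constants are nominal, not lattice-corrected; the
  positivity rule at 10⁻¹⁵ is far from the regime where that matters.
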