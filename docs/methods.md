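# Methods

`truthbench` couples a truth-aware RNA-seq simulator with a qualitative
evaluator.  The simulator's defining property is that every read carries
its own ground truth: the true alignments (in original-reference
coordinates) and the sequencing-error offsets are encoded in the read
name, and the events supported by the reads — mutations, splice
junctions, fusion junctions — are written to separate truth files.  The
evaluator scores any pipeline's output against that truth without
needing the simulator's internal state.

## Simulation model

**Mutation injection.**  SNVs, insertions and deletions are introduced
into a haploid copy of the reference.  Random mutations are per-base
Bernoulli trials at configurable rates (defaults: SNV 0.0014,
insertion 10⁻⁴, deletion 10⁻⁴ per base — rates typical of germline
polymorphism levels in human data), so counts are binomial.  Indel
lengths are uniform on 1..15 (`max_indel_len`); inserted bases are
uniform over ACGT; N bases are never mutated.  Mutations may instead be
sampled from a VCF of biallelic sites; `vcf_ratio` (default 0.95) is the
fraction of the final mutation set drawn from the VCF, the remainder
being generated randomly.  Overlapping footprints are forbidden: the
earliest-generated mutation wins (SNV footprint = its base, deletion =
its deleted run, insertion = its anchor base).

**Coordinate map.**  Applying the mutation set yields the mutated
genome together with a piecewise segment map.  SNVs are map-neutral;
each indel starts a new segment.  The map is an exact bijection between
mutated and original coordinates outside inserted runs; a position
inside an insertion has no original image and lifts to the insertion's
anchor base with a flag.  The forward direction (original → mutated)
snaps positions inside a deletion to the first surviving base after it;
annotation exons are mapped by taking the full mutated span of their
surviving image (so an exon keeps interior insertions), dropping exons
whose bases were all deleted and merging exons left touching after an
intron deletion.

**Fusions.**  A fusion joins two genes by picking two exons uniformly at
random (from one representative transcript per gene — the longest —
resampling until the parent genes differ).  The contig is the genomic
upstream part of gene A (transcript 5′ end through the chosen exon, in
transcription orientation) concatenated with the genomic downstream
part of gene B; the two chosen exons are merged into a single exon to
force the chimeric junction.  Contigs are cut from the *mutated* genome
so fusion transcripts carry mutations like any other transcript.

**Expression and reads.**  Transcripts are assigned distinct expression
ranks `x` by random permutation and weighted by the mixed
power/exponential rank law

    w(x) = x^k · exp(−x/x₀ − (x/x₁)²),   defaults k = −0.7, x₀ = 15000, x₁ = x₀²,

with molecule counts multinomial over the normalized weights
(`n_molecules` = 10⁶).  Fragments are drawn per molecule: the source
transcript proportionally to its molecule count, length
Normal(250, 50) rounded and clamped to `[read_length, transcript
length]` (clamping rather than resampling guarantees progress on short
transcripts), start uniform.  Each fragment yields one pair: end 1 is
its first `read_length` bases, end 2 the reverse complement of its last
`read_length` bases.  Sequencing errors are uniform per-base
substitutions (default 10⁻³) with recorded positions; qualities are
constant.  Any generator producing the same read-pair records can be
plugged in place of this one.

**Liftover and truth encoding.**  Each read end's exonic blocks are
lifted through the coordinate map: bases over insertions become I ops,
spanned deletions D ops, introns N ops (with original-coordinate
lengths).  Ends simulated from a fusion contig are split at the
registered breakpoint into one record per locus, soft-clipping (S) the
non-local portion as in chimeric SAM conventions.  The read name is

    read_id:(chr,(-)pos,cigar(;)?)+:base64(err_pos?)

with 1-based positions (negative = reverse strand), end-1 records
before end-2 records, and error offsets merged over the concatenated
pair (0-based, end 2 offset by the read length) as comma-joined
decimals in padding-stripped standard base64.  Per-end record grouping
is recoverable because local query lengths (M+I) sum to the read length
within each end.

**Truth database.**  An event enters the truth only when expressed by at
least one read: SNVs and deletions when a read's M/D footprint covers
them; insertions when a read carries the I op at the anchor (coverage of
the anchor base alone does not express the inserted sequence — this
keeps every truth entry re-derivable from read names + original genome,
which the test suite verifies by an independent scan).  Junctions are
classified purely from geometry, never from provenance: different
chromosomes, strands, or reverse transcription order → non-colinear
fusion; colinear junctions spanning more than 300 kb → colinear fusion
(so a huge intron of an unfused gene also counts); otherwise splice.
Junction strands are normalized to the transcript strand so both mates
report the same entry.

## Evaluation model

Truth events are indexed in per-(chromosome, strand) interval trees.
Rules per event type (defaults in parentheses):

| event      | match rule |
|------------|-----------|
| alignment  | first SAM record per read end with NH ≤ `max_hits` (1); TP on ≥ 1 base same-chromosome overlap with any truth record of the read |
| splice     | overlapping truth junction with d = &#124;Δstart&#124; + &#124;Δend&#124; ≤ threshold (10) |
| SNV        | truth SNV within ± threshold (5) positions with the same alternate base |
| indel      | truth indel of the same kind within ± threshold (5) and length within threshold of the truth length |
| fusion     | composite interval (chr = chr1·chr2, start = pos1, end = len(chr1)+pos2, strand = strand1·strand2), splice-style distance ≤ threshold (20) |

Fusion side pairs are orientation-normalized (lexicographic by
chromosome/position, flipping both strands on swap) before comparison.
When several candidates match a prediction the minimum-distance one is
taken (ties broken by truth order, deterministically); when several
predictions hit the same truth entry only the first is a TP and later
duplicates are ignored — excluded from both TP and FP — unless
`count_ignored_as_fp` is set (both readings of the duplicate-handling
convention are defensible; the switch exposes the alternative).
Precision = TP/(TP+FP), recall = TP/(TP+FN), F-score their harmonic
mean; zero denominators yield 0 so empty outputs rank last.  The
alignment recall denominator is the number of simulated read ends
(2 × pairs), making TP + FN equal the truth size for every event type.
VCF predictions are split per alternate allele and left-trimmed before
classification.

## Synthetic data

The fixture generator produces uniform-composition random chromosomes,
non-overlapping multi-exon gene models with alternating strands, and
biallelic VCF sites whose REF matches the genome.  It emulates none of
the structure of real genomes — no repeats, homopolymer runs, GC bias,
splice-site motifs, overlapping genes or realistic intron lengths — so
passing tests demonstrate the correctness of the bookkeeping
(coordinates, codecs, matching rules), not robustness to the ambiguity
real aligners face on repetitive sequence.  In particular, alignment
self-matching is trivially unambiguous on random 100 kb chromosomes.

## Numerical and degenerate-input choices

- Internal coordinates are 0-based half-open everywhere; GTF/VCF/SAM
  emission is 1-based, BED 0-based, converted only at I/O boundaries.
- One `numpy` generator seeded once drives the entire simulation;
  identical seeds give byte-identical outputs (tested).
- Deletions that would run past a chromosome end have their length
  resampled among the lengths that fit; a deletion reaching exactly the
  end is allowed.
- A VCF with fewer usable records than requested is topped up with
  random mutations and a warning.
- A read end entirely inside an inserted run (possible only when the
  insertion is at least as long as the read) is encoded as an all-I
  record positioned after the anchor.
- Transcripts shorter than the read length are excluded from sampling
  with a warning; an annotation whose every transcript is excluded is an
  error.
- Multi-allelic VCF records are skipped (with a count) on the simulation
  side and split per allele on the prediction side.

## Verification problem sizes

The test suite checks the codec on 10⁴ randomized names; the liftover
exhaustively per base against an independently built edit script on
genomes up to 10 kb with up to 50 mutations; each evaluator against an
all-pairs brute-force matcher on 200 randomized truth/prediction sets;
self-matching (truth fed back as predictions scores 1.0 everywhere) and
truth re-derivability on a 20 000-pair simulation over a 2 × 100 kb
fixture; and conservation (TP + FN = |truth|) plus threshold
monotonicity across 50 random benchmarks.  These sizes keep the whole
suite around ten seconds while still exercising every code path,
including fusion-crossing reads and mutated introns.

## Known limitations

- Haploid mutated genome: no genotypes, phasing or allele fractions.
- The error model is uniform substitution only (no indel errors, no
  positional profile); qualities are constant.
- Library preparation is idealized: per-molecule uniform fragment
  sampling, no PCR duplicates or GC bias.
- Expression estimates and transcript reconstruction are not evaluated.
- Exon boundaries landing in a deletion snap outward, which can lengthen
  an exon by the deletion remainder; with realistic (low) indel rates
  this is rare.
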