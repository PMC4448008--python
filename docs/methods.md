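# Methods

This note documents the models and procedures implemented in `mirpipe`,
the defaults they ship with, and the reasoning behind choices the
underlying methodology leaves open.

## Read cleanup and normalization

Adapter trimming is exact: the insert ends at the leftmost occurrence of
the adapter's prefix with at least 6 nt of overlap and no mismatch
tolerance. This keeps the step deterministic and testable; real base-call
errors in the adapter leave a read untrimmed, after which the 17–25-nt
length window usually removes it. The junk rules (one base > 80% of the
read, > 2 undetermined bases, homopolymer runs A₇/C₈/G₆/T₇) are applied
to the post-trim insert, before length filtering. The > 80% rule is
strict inequality. Annotation screening replaces database BLAST with
exact substring matching (either strand) against user-supplied exclusion
FASTA sets; the class of the first matching set in configuration order is
recorded. "Normalized expression" is defined as reads per million clean
reads of the same library — the gates (≥ 10 normalized) and fold changes
need a scale, and per-million is the field standard. Every raw read is
assigned exactly one fate (no-insert, junk, length, exclusion class, or
clean), so accounting tables sum to the raw totals.

## Genome mapping

Mapping is exact on both strands (a seed dictionary of 17-mers plus
full-length verification). Mismatches are deliberately *not* allowed
against the genome — only against reference precursors. Tags with more
than `max_hits = 100` occurrences are flagged multi-mapped: they retain
their expression but never seed hairpin prediction, since repeat-derived
tags would otherwise flood the candidate list. The threshold is a
pipeline choice, configurable.

## Known miRNAs and isomiRs

A tag is placed on a precursor as an ungapped full-length alignment with
at most one substitution (tag length 17–25 nt). The substitution may sit
at any position, including position 1 — variant names such as `_1ss1TG`
require it. End offsets against the documented mature are capped at
|n| ≤ 3 by default; unconstrained end variation would let unrelated tags
adopt documented names. Ties across precursors resolve by fewest
mismatches, then smallest total end offset, then lexicographic precursor
id. Arm assignment uses the position of the placement midpoint relative
to the precursor midpoint; an exact tie raises an "ambiguous arm" error
for the single placement and the batch annotator skips such tags
(precursor-matched but unnameable — they are consumed, not forwarded to
novel prediction). Tags on the arm opposite all documented matures
become p5/p3 species; the most abundant tag on that arm defines the
species and rarer tags on the same arm are named as its isomiR variants.
IsomiR records are never aggregated into their parent's counts: each
variant is tested and reported separately.

## Secondary-structure prediction

The folder is a deliberately simple nearest-neighbor dynamic program,
not a Turner-parameter reimplementation:

- stacked pairs contribute −(s₁ + s₂) kcal/mol with strengths
  s(GC) = 1.6, s(AU) = 1.0, s(GU) = 0.5 — so a GC/GC stack costs −3.2,
  in the range of measured stacking energies;
- a hairpin loop (minimum 3 nt) pays a flat +4.0 closing penalty;
- bulges and interior loops pay +3.0 + 0.25/nt, with at most 16
  unpaired nt per loop;
- multibranch loops are not formed inside a helix; independent
  stem-loops may only sit side by side at the external level.

This yields a unique, deterministic minimum-energy structure (ties break
toward leaving bases unpaired), folds a 240-nt window in ~10 ms, and is
calibrated so canonical pre-miRNA stems land far below the −15 kcal/mol
criterion while random sequence stays near zero. When structural parity
with an external folder matters, a precomputed dot-bracket file
(id → structure, energy) overrides the built-in folder per sequence.

## The 11 hairpin criteria

Criteria are measured on the stem-loop **component containing the
candidate mature**, not on the whole folded window: flanking genomic
sequence almost always folds into small incidental hairpins at the window
edges, and a whole-window single-hairpin requirement would reject
essentially every real locus. A multiloop *inside* the mature's component
still fails outright ("not a hairpin"). Bookkeeping definitions, chosen
so that the criteria are independently violable (each has a decoy that
fails it and only it):

- a *bulge* is a maximal unpaired region between consecutive stem pairs;
  its size counts both strands; it is *biased* when all unpaired
  nucleotides lie on one strand;
- *errors in the mature region* are unpaired mature positions within the
  stem extent; mature positions inside the terminal loop count against
  the percent-in-stem criterion (11) but not as errors (9);
- the hairpin extent (criterion 4) runs from the component's first to
  last paired base inclusive;
- the energy criterion re-scores the mature's component alone under the
  shipped model, so unrelated side stems cannot rescue an unstable
  candidate; an externally supplied structure uses its stated energy.

The free-energy cutoff is interpreted as ΔG ≤ −15 kcal/mol (folding
energies are negative for stable hairpins). The expression gate
(normalized ≥ 10 in ≥ 1 library, inclusive) is applied to candidate tags
before folding — it is both the reporting rule and a large constant-factor
saving. When several tags map within one window, the most abundant tag
defines the candidate mature; weaker tags within 220 nt on the same
strand are absorbed into that locus.

## Differential expression

Tests run on **raw counts** with library clean totals as margins — an
exact hypergeometric test cannot consume normalized values — while fold
change and direction use normalized values. The Fisher two-sided p-value
sums the probabilities of all tables at most as probable as the observed
one (relative tie tolerance 10⁻⁷), computed in log space; a batch variant
(`fisher_grid`, numba-compiled) produces all p-values for fixed margins
and is what the exhaustive verification uses. The χ² test is Pearson's
without continuity correction; any expected cell < 1 flags the test
unreliable with p = 1. DE requires the *Fisher* q to pass (BH over the
retained set only, after excluding species with < 10 raw reads in both
libraries); χ² is reported alongside. With a zero count on one side the
fold change uses a 0.5-normalized-unit pseudocount on the zero side only,
keeping direction well-defined for library-specific species. The BH
choice for q-values and the normalized-scale fold change are pipeline
decisions where the methodology names no procedure.

## Degradome analysis

Tags shorter than 15 nt after trimming are discarded. Mapping is exact
and sense-strand; a tag matching k positions adds weight 1/k (feeding
tags-per-billion, tpb = weight × 10⁹ / raw library total) and its full
raw count at every position (feeding the category rules — "one raw read"
is a statement about reads, not weights). Duplex scoring follows the
plant pairing scheme: mismatch 1.0, G:U 0.5, bulged nucleotide 1.0, all
doubled at miRNA positions 2–13; at most one bulge per duplex, and a
bulge directly at position 10 is not considered (it would leave the
cleavage site undefined). The cleavage site is the transcript position
opposite miRNA position 10. Site search is restricted to positions with
at least one raw read in at least one library — given the ≥ 1-read
reporting requirement this cannot change the hit set, and it turns an
O(transcriptome) scan into an O(peaks) one; per-peak scoring is
vectorized over bulge configurations via prefix sums and re-verified
with the scalar scorer before reporting. Ties between equal-scoring
anchorings resolve to the leftmost transcript position. The category
median is taken over positions with at least one read; including the
zero positions of a full-length transcript would make "≤ median" empty.

## Synthetic data generator

The generator emulates the statistical structure of a two-condition
plant sRNA experiment: 21-nt-biased known matures (5'-U-rich) and
24-nt-biased novel matures (5'-A-rich) giving the familiar bimodal size
distribution; isomiR end variation (12% of species reads) and single
substitution errors (2%); star-arm reads at 15% of the mature, sharing
the mature's fold effect (they come from the same precursor); junk reads
exercising every junk rule; excludable fragments drawn from synthetic
stand-in exclusion sets; an abundant background of fixed siRNA-like
genomic 24-mers (250 loci) plus low-copy random fragments. Known-miRNA
expression is log-normal (median weight 30, σ = 1.1); novel and decoy
loci sit an order of magnitude lower (median 3, σ = 1.0), mirroring the
low expression of recently evolved MIR genes while keeping nearly all
planted loci above the ≥ 10 reporting gate; decoy weights have a floor so
every decoy reaches the prediction stage. A fifth of known + novel
species receive a 4-fold effect, alternating directions so the two
libraries stay roughly compositionally balanced. Reads are drawn
multinomially per library at 2 × 10⁵ depth.

Planted loci are validated *as the pipeline will see them*: a novel
locus is accepted only when, scanning every genome occurrence of its
mature (both strands, with the prediction stage's locus-absorption rule),
some occurrence folds into a window passing all 11 criteria; a decoy is
accepted only when its standalone precursor fails exactly its designated
criterion *and* no genome occurrence is recoverable. This matters in
practice: a perfect-stem mature also occurs as the exact reverse
complement on the opposite arm, and flanking context around that second
occurrence can refold into a perfectly legitimate hairpin.

Degradome truth plants complementary sites at pairing scores 0, 2, and 4
(and score-5 decoy sites) in synthetic transcripts, with read peaks of
1–8 at the exact cleavage positions over a uniform background (30% of
the configured depth spread across all transcripts; 2% sub-15-nt reads
exercise the length filter).

What the generator does **not** emulate: sequencing quality-score error
models, repeat structure and multi-copy MIR families, RNA editing,
partial degradation of precursors, or transcript isoform complexity.
Passing the planted-truth suites therefore demonstrates the pipeline's
internal correctness and its behavior under realistic count statistics —
not performance on the full messiness of real libraries.

## Problem sizes and determinism

The shipped study conditions are a 200-kb genome, 60 known + 30 novel +
11 decoy loci, 2 × 10⁵ sRNA reads and 2 × 10⁵ degradome-depth units per
library; the end-to-end suite runs in well under two minutes on one
core. One master seed fixes every generated byte; pipeline runs are
idempotent, and every output table header records the configuration hash
and seed.

## Known limitations

- The folder is a simplified energy model: structures can differ from
  Turner-parameter folders on marginal hairpins. The external-structure
  input exists precisely for that case.
- One library per condition: the Fisher/χ² design tests proportions, not
  biological variance; with replicates a count-model framework (e.g.
  negative binomial) would be the right tool.
- Exclusion screening is exact substring matching, not covariance-model
  or E-value search; it is faithful to intent only insofar as the
  supplied exclusion sets are.
- Known-miRNA assignment gives each tag a single best precursor; members
  of multi-copy families are attributed to one locus.
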