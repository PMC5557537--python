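# Methods

## Model overview

`tandemq` treats mapping-quality prediction as supervised learning with
self-generated training data. The key assumption is that reads simulated
from random genome locations, but shaped by templates learned from the
input alignments (length, quality strings, mismatch/gap patterns,
fragment geometry), expose the aligner to the same ambiguity structure —
repeats, sequencing error, score ties — as the input reads, so a model
trained on their known-truth alignments transfers to the input. Aspects
of real data the simulation deliberately does not mimic: positional
enrichment (tandem reads are uniform over the genome), and
technology-specific artifacts such as homopolymer indels, which cannot
line up with a randomly drawn substring.

Only wrong-locus errors are modeled. Reads whose origin is absent from
the reference, and reads that fail to align at all, receive no
prediction (the former are assumed rare; the latter need none).

## Templates and replay

A template stores strand, quality string, CIGAR and MD in *read
orientation*: reverse-strand records are flipped at extraction (CIGAR
reversed, qualities reversed, MD reverse-complemented) so replay is
orientation-free. `=`/`X` CIGAR ops are normalized to `M`; MD remains
the authority on mismatch placement. Replay walks CIGAR+MD left to
right: `M`-match copies the substring base; `M`-mismatch substitutes a
base drawn uniformly from the three alternatives (MD records where a
mismatch occurred and the reference base, not the read base, so the
substitute is unconstrained); `D` skips substring bases; `I` emits
uniform random bases; `S` copies substring bases unmutated, drawn from
the flanking reference so every read position has sequence. The
extraction span is therefore ref-span + soft-clip lengths. Substrings
containing non-ACGT characters are redrawn (up to 1,000 attempts) under
the default `redraw` policy; `keep` passes them through.

Paired templates additionally store `|TLEN|` and which end aligned
upstream; a pair is replayed by placing a fragment uniformly and taking
the two extreme slices. Pair ends share one read name that encodes both
origins (`qt!ref!start1!strand1!start2!strand2!cat!p`), because SAM
mates must share QNAME; unpaired names use
`qt!ref!start!strand!cat!s`. `!` is used as the delimiter since SAM
QNAMEs permit it; contig names containing `!` or whitespace are rejected
at load.

Reservoir sampling (Algorithm R, one reservoir per category, default
capacity 10,000, RNG seeded as pipeline-seed + category index) keeps a
uniform template subsample in constant memory. Tandem-read counts per
category default to `ceil(45·√x)` with minimums 30,000 (`unp`, `conc`)
and 10,000 (`disc`, `bad_end`); `--sim-function` supports `sqrt`,
`linear`, `const` and `--sim-factor` scales it. A category with no input
alignments gets no simulation and no model.

Bad-end templates keep only the aligned end (the unaligned mate's
properties cannot be learned from an alignment it does not have), and
bad-end tandem reads are simulated unpaired. Tandem training records are
grouped by the category they were *simulated for* (carried in the read
name), not by the flags of their own alignment, so they always train the
model that will serve matching input records.

## Quality model

Per category, a scikit-learn random forest (100 trees, unlimited depth,
`min_samples_leaf = 25`, bootstrap resampling, deterministic per seed)
is trained on: best alignment score; an indicator for whether a
second-best alignment was found; the score difference (encoded as
`best − (−2·read_len)`, the largest difference the builtin scoring could
produce, when no second exists); read length; summed base qualities of
aligned and of soft-clipped bases; `|TLEN|` for concordant pairs; plus
any extra numeric fields the aligner appends to the `ZT` tag (the
builtin aligner appends its best-score tie count). Tree models are
scale-invariant, so new features need no normalization.

Predictions are the average over trees of **Laplace-corrected leaf
frequencies** `(c + 1)/(n + 2)` rather than raw leaf votes. Two
numerical failure modes motivate both choices. With `min_samples_leaf`
of 1, deep trees memorize individual training points, and a genuinely
ambiguous alignment (score tie, ~50% correct) can land in a
single-point leaf and receive p ≈ 1 — a confidently wrong MAPQ of 60.
With raw votes, every confident alignment saturates at exactly p = 1,
collapsing groups with very different evidence (a score tie of two vs. a
unique best hit) onto a single quality; the Laplace correction keeps p
graded by the amount of leaf evidence, which matters for rank-based
evaluation and costs nothing elsewhere. Predictions are clamped so that
q ≤ `q_cap` (default 60): a unanimous vote would otherwise imply
q = ∞. Degenerate single-label training sets yield a constant predictor
(p = p_max or 0). MAPQ is written as round-half-up of q; everything
outside the MAPQ column passes through byte-identically and one `@PG`
header line is appended. Input records whose category has no model, or
that lack the `ZT` tag, keep their original MAPQ and are counted in the
run report. Models are rebuilt on every run — they are tailored to one
dataset/aligner/parameter combination and are deliberately not
persisted.

## Evaluation statistics

An alignment is *correct* when its leftmost involved base — SAM POS
minus the leading soft-clip length — is within 30 nt of the leftmost
base of the simulated substring, on the same contig; strand is not
compared. Only the leading-clip adjustment is applied.

The cumulative incorrect vector C sorts alignments by descending
quality (stable sort) and accumulates `incorrect(a)`; within a maximal
equal-quality group every element adds the group mean, so within-group
input order is irrelevant (asserted by a shuffle test). The cumulative
squared-error vector E does the same on the probability scale
p = 1 − 10^(−q/10), each prediction series sorted by its own P, with
equal-p groups adding the group mean squared error. CID = C′ − C,
CSED = E′ − E, RCA = (ΣC′ − ΣC)/ΣC, RCE = (SSE(P′) − SSE(P))/SSE(P);
both ratios are reported as NA when the denominator is zero. CSED plots
use the signed-log scale `sign(y)·log10(|y| + 1)`. The sorting/grouping
machinery is implemented once and parameterized by key (q or p); since
p is monotone in q the two orderings coincide. MAPQ 255 ("unavailable")
is excluded from comparisons.

## Fixture: genome, reads, toy aligner

The genome generator writes an i.i.d. backbone at a requested GC, then
overwrites `round(fraction·length/unit_len)` non-overlapping `unit_len`
slots with copies of uniformly chosen earlier segments, each base
substituted with the divergence probability (default 0.02). Sources may
themselves be repeats, so multi-copy families arise; the planted-copy
annotation is returned. Defaults (500 nt units, 2% divergence) give a
young-transposon-like repeat landscape in which a 100 nt read from a
copy has a ~13% chance of being locally identical to its counterpart —
enough exact ties to make mapping quality a real problem.

The read simulator draws positions uniformly, emits an Illumina-like
quality profile (linear 35→27 decay plus Gaussian noise, clipped to
[2, 40]), and substitutes each base with probability
`sub_rate · 10^(−q/10)` — `sub_rate` is a multiplier on the
quality-implied rate, 1.0 by default, 0 for error-free reads. Paired
mode draws FR fragments uniformly on (2L, 4L), the same window the
toy aligner uses for concordance, and flips which physical strand end 1
comes from with probability ½.

The toy aligner indexes every genomic 21-mer, seeds each read at three
offsets on both strands, and scores candidates ungapped on the seed
diagonal (match +1, mismatch −2) with numpy. A candidate showing ≥ 3
mismatches is refined by a banded glocal alignment (±8 nt window,
gap of length g costing −4 − g); with this scoring a gap can never beat
two or fewer substitutions, so cheaper candidates skip the refinement.
Ties break deterministically by (refname, position, strand). The
second-best score is the best score at a locus more than a read length
from the reported one; the native MAPQ is
`min(40, floor(2·(best − second)))`, or 40 with no second — a
deliberately coarse two-score heuristic that gives the trained model a
beatable but honest baseline. Alignments scoring below
`min_score_frac · read_len` (default 0.5) are suppressed, emulating a
minimum-similarity threshold. The aligner never soft-clips, so the
clipped-quality feature is 0 in fixture runs (the feature is exercised
through the tag contract and parser tests).

## Problem sizes and determinism

Default test-suite scales: the directional check uses a 1 Mbp genome
with 30% repeats and 50,000 unpaired 100 nt reads, ten trials repeated
from the input-modeling step with seeds 0–9 against one fixed step-1
alignment; calibration uses 60,000 tandem records (half held out);
replay fidelity uses 30,000 tandem reads on a 150 kb genome. These
sizes were chosen so a full run completes in minutes on one core while
keeping every statistical check comfortably powered (≥ 10⁴ events per
chi-square or calibration bin).

All randomness flows from explicit seeds: the pipeline derives reservoir
seeds (seed + category index), the simulation RNG (seed + 10), and
per-category training seeds (seed + 20 + index), all reduced mod 2³¹.
Identical inputs and seed give byte-identical output SAMs.

## Known limitations

* One score scale: the builtin aligner is end-to-end with fixed scoring;
  behavior across local/end-to-end score scales is untested by design.
* Bad-end pairs simulate only the aligned end; the unaligned mate is not
  emitted.
* Trailing-clip adjustment for the correctness rule is not applied; only
  the leading clip is considered.
* Insertion bases and mismatch substitutes are uniform — no
  context-dependent error spectrum.
* The native-MAPQ baseline is intentionally simple; margins measured
  against it do not predict margins against production aligners.
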