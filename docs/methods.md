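# Methods

This note documents the statistical models, the defaults and the design
choices behind `metagsim`, in the spirit of a model reference rather than a
user guide.

## Chimeric-read detection

A *subalignment* is one aligned block of a read (primary, supplementary or
secondary record) against one reference interval. Two subalignments of the
same read are *compatible* when their query intervals overlap by at most
`slack` bases and, if they hit the same contig, their reference intervals do
too. The best compatible set maximizes total aligned bases, with ties broken
by higher mean MAPQ, then fewer segments, then the lexicographically smallest
query-start tuple.

Numerical/algorithmic choices:

* `slack = 10 bp`. A strict no-overlap rule rejects the few-base junction
  jitter real aligners produce at split points; 10 bp absorbs it without
  admitting genuine overlaps.
* `min_segment = 100 bp`. Short spurious supplementary hits otherwise
  inflate chimera counts. If filtering empties a read's pool, the single
  best remaining subalignment is used.
* Search is exhaustive up to `max_exact = 12` subalignments (4,096 subsets);
  beyond that, weighted interval scheduling on query space (weight = aligned
  bases) with reference compatibility enforced greedily on backtrack. The
  DP is exact for query-space conflicts; reference-space conflicts among
  more than 12 subalignments are rare enough that the greedy repair is an
  acceptable approximation.
* "Alignment quality" enters only as a tiebreaker after total aligned
  length: aligned length is the better-defined primary criterion, and the
  ordering between the two is otherwise ambiguous.
* Secondary alignments never seed compatible-set search; they are retained
  for the multialignment pool of the abundance estimator.
* Circular-origin bridges: two adjacent same-contig, same-strand segments,
  the first ending within `end_tolerance = 50 bp` of the contig end and the
  second starting within 50 bp of the origin (mirrored on the minus strand),
  are merged into one wrapped segment; merging is applied iteratively and
  chimera status recomputed. Merged segments store `ref_end` past the
  contig end (unwrapped coordinate) with a `wrapped` flag. 50 bp reflects
  that alignments rarely reach the exact terminus.
* Gaps are measured in query space only; reference-space distance between
  consecutive segments is not penalized.

The per-read segment count is modeled as Geometric(p) on support {1, 2, …}
(mean 1/p, chimeric fraction 1 − p); p̂ = N / Σk is the maximum-likelihood
estimate. Simulation truncates draws at `max_segments = 10` by redrawing,
since an unbounded geometric tail occasionally yields pathological reads.

## Source-species chain and the shrinkage rate

The source species of consecutive chimeric segments follows a first-order
chain: start distribution = the community abundance profile; transitions
scale every other-species probability by the shrinkage rate `s ∈ (0, 1]` and
inflate the self-transition to keep rows stochastic. The abundance profile
is the stationary distribution for any s, so long simulated libraries keep
their target composition regardless of s.

`learn_shrinkage` divides the observed switch probability out of species A
by the homogeneous expectation Σ_{i≠A} p_i and averages the per-species
reductions **unweighted** (a pair-count-weighted mean is available via a
flag). Species with fewer than `min_pairs = 20` first-segment observations
are excluded; with no qualifying species the estimator refuses and suggests
the fallback default `s = 0.75`. Pairs are formed only within a read, never
across reads. When both an expected and an estimated abundance profile are
available, the estimated profile is used for training. At simulation time
s can be overridden by the user (e.g. `s = 1` for homogeneously suspended
DNA).

## Base-level EM abundance estimation

Counting aligned bases rather than reads removes the length bias that makes
read-level estimators unreliable for nanopore data. The estimator:

1. tallies each counted segment's aligned bases toward its species
   (chimera-aware mode counts every segment of the best compatible set;
   otherwise only the primary alignment);
2. marks a segment *multialigned* when another alignment of the same read to
   a different species overlaps it by ≥ 50% in query space, has aligned
   bases ≥ 0.9× the counted segment's, and MAPQ within 10 — the closeness
   thresholds are implementation policy, since "equivalently aligned" has no
   canonical definition;
3. runs EM: E-step splits multialigned bases across candidates proportional
   to current abundances; M-step renormalizes; stop when the maximum
   per-species change falls below `rel_tol × min(positive abundances)` with
   `rel_tol = 0.01`. The minimum is taken over positive entries because a
   zero-abundance species would otherwise make the threshold zero and the
   loop nonterminating.

Species with no unique bases and no candidate membership stay at zero; the
E-step cannot revive them (an epsilon floor exists but is off by default —
fidelity to the plain fixed-point iteration first). If every candidate of a
multialigned segment sits at zero abundance, its bases are split equally.
Non-EM modes split multialigned bases equally among candidates. Read-level
modes count 1 per segment (CR) or per primary read (ER) regardless of
length.

Copy numbers are abundances divided by genome sizes, renormalized. The
deviation report gives signed percent deviation per species, the summed
absolute percent error, squared Pearson correlation (plus a log10 variant
that excludes zero entries), and the residual standard deviation.

## Length models

Read, segment and gap lengths are fitted with Gaussian KDEs on log lengths
(gaps on log1p, admitting zeros). The default bandwidth starts from Scott's
rule and is refined by 3-fold cross-validated likelihood over the candidates
scott/2^k, k = 0…5, on a deterministic subsample of ≤ 2,000 points: length
and gap distributions are strongly multimodal, and the plain global-σ rule
oversmooths them to the point of visibly distorting sampled distributions.
For unimodal data the CV picks Scott's value itself. Sampling resamples a
training point plus kernel noise and applies the smoothed-bootstrap variance
correction so the sampled variance matches the training variance; draws are
rounded to integers and clipped to `[min_clip, 1.1 × training max]`.

The alignment-ratio model is the empirical joint distribution of
(head fraction of the unaligned budget, unaligned fraction of the read),
sampled by resampling observed pairs; untrained it contributes no extra
unaligned sequence and splits head/tail uniformly.

## Error model

Basecall events are a first-order chain over maximal match / mismatch /
insertion / deletion runs extracted by walking CIGAR strings (`M` is treated
as match; mismatches are only visible with `=`/`X` operators). Run lengths
use empirical histograms; transition counts get Laplace smoothing (+1) with
a structurally zero diagonal (runs are maximal). This empirical-histogram
parameterization is this package's own design; per-event parametric mixture
fits would be an alternative with more extrapolation and less fidelity at
the observed scale. Substituted bases are drawn uniformly from the three
alternatives; inserted bases and unaligned junk follow the trained base
composition (uniform if untrained). Quality scores, when trained from
FASTQ, are drawn per base from event-type-conditional Phred histograms.
Event sampling is pool-batched (chunks of presampled draws, doubling up to
8,192) so per-base simulation stays fast in pure Python.

## Simulation

Per sample: (1) optionally perturb the profile — relative errors drawn
Uniform(lo, hi) (the distribution is pluggable; uniform is the simplest
choice consistent with bounded deviation), sorted by |error| and assigned to
species by descending genome size, reflecting the observed positive
correlation between genome size and deviation magnitude; clamp at zero and
renormalize. (2) Allocate per-species **base** budgets (abundance is DNA
weight, so simulation must allocate in the same currency the estimator
measures; a requested read count is converted via the mean of the aligned-
read KDE's training sample). (3) Draw reads whose first segment belongs to
the budgeted species until its budget is spent (the last read may overshoot,
and chimeric segments debit their own species' budgets).

Within a read: segment count from the geometric model; species chain from
the source model; segment lengths from the segment KDE (the aligned-read KDE
when k = 1); gaps from the gap KDE; head/tail junk from the alignment-ratio
model. Segment start positions are uniform over the contig (uniform-coverage
assumption); contigs within a species are chosen proportional to length
(chromosomes vs plasmids); strands are equiprobable. Circular contigs wrap
past the origin (at most one full rotation); linear contigs resample the
start into range. Gap and head/tail junk are random sequence from the
trained base composition and are not error-mutated — they model unalignable
junk; reference-derived segments pass through the error chain, and each
read stores per-segment event logs so ground truth replays exactly.

Per-sample seeds are `sha256(master_seed, sample_id)`-derived, so adding a
sample to a batch never changes another sample's reads, and reruns are
bit-identical. Samples run sequentially by default.

Remote genome retrieval is exposed only as a loader hook on
`load_genomes`; the default build resolves local FASTA paths.

## Synthetic fixtures: what they do and do not show

The fixture generator emulates the *structural* features the models care
about — genome sizes and topologies, logarithmically skewed abundances (10
species over two decades by default), a 2.17% chimeric fraction with
shrinkage 0.77, ~2-kb median lognormal read lengths, planted byte-identical
homologous blocks inducing controlled multialignments, and ~9% basecall
error (4% mismatch / 2% insertion / 3% deletion) — with uniform-random
nucleotide sequence. Passing tests therefore demonstrate correctness of the
detection/estimation/simulation machinery under known ground truth, not
robustness to real phylogenetic sequence similarity, aligner idiosyncrasies,
or nanopore homopolymer artifacts, none of which the fixtures model. The
planted alignment fixture keeps same-contig segments reference-disjoint so
the planted chain is provably the best compatible set (the oracle for
search tests).

## Problem sizes

The test suite and acceptance script run at desk scale, chosen so the Monte
Carlo error is comfortably below each tolerance: 100,000 draws for the
segment-count mean (SE ≈ 0.0006 against a ±0.01 band), 200,000 for the
chimeric fraction (SE ≈ 0.03 points against ±0.2), 50,000 pairs for
shrinkage recovery (observed spread ≈ 0.005 against ±0.02), and 100,000
reads for the simulate→quantify round trip (per-species error ≪ 0.5
points). The 10-species logarithmic profile spans two decades so that even
the rarest species clears the `min_pairs` threshold at 50,000 pairs.

## Known limitations

* Chimera detection cannot distinguish library/sequencing chimeras from
  true structural variants relative to the reference; both look identical
  to alignment-based detection.
* The EM estimator cannot assign abundance to species with zero unique
  bases.
* Quality-score simulation requires FASTQ training input.
* The DP fallback for > 12 subalignments is heuristic in reference space.
* Junk/gap sequence is compositionally matched random sequence, not adapter
  or low-complexity sequence.
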