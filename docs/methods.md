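# Methods

This note documents the models, conventions and design choices behind
`ccs16s`, in the order a read travels through the pipeline.

## Input conventions

PacBio consensus FASTQ assigns quality 0 to ambiguous calls; real qualities
span 2–93.  Parsing with `pacbio_mode=True` rewrites every quality-0 base to
`N` (idempotent), and writing inverts the rule.  Consensus metadata — the
number of polymerase passes and the caller's predicted error rate — has no
tag field in plain FASTQ, so it rides in the record id as
`@id;np=<int>;pe=<float>`; a sidecar `read_id ⟶ (passes, predicted_error)`
table takes precedence when supplied.  The real consensus caller's
predicted-error algorithm is proprietary, so when neither source is present
the fallback estimate is the mean of `10^(-Q/10)` with ambiguous positions
charged 0.75 (a uniform guess over four bases).  This fallback is an
artifact of this package, not a reconstruction of the caller.

## Region designs

Six nested primer pairs spanning V4 up to the near-full-length V1–V9 ship as
packaged data.  Coordinates are 1-based inclusive on the *E. coli* 16S
reference, and the insert length is defined as the amplified span excluding
both primers:

    insert = ref_end − ref_start + 1 − |fwd primer| − |rev primer|

The identity is validated on load for every row (V4 253, V1–V3 490,
V3–V5 551, V1–V5 881, V1–V6 1033, V1–V9 1464 nt).  Primers use IUPAC codes;
two codes match when their expansion sets intersect.  Barcodes are concrete
16-nt sequences, paired symmetrically on both ends of the amplicon.

## Trimming and screening

A consensus read may be emitted in either strand, so trimming scores both
orientations: the forward barcode+primer is sought within `max_shift`
(default 2) leading positions and the reverse-complemented reverse
primer+barcode within the same window of the 3′ end, minimizing mismatches
(Hamming at the best offset; IUPAC-aware for primers, exact for barcodes).
Mismatch counting at the best offset means small indels inside a barcode
surface through the offset search rather than as separate events.  The
"at most one mismatch" allowance is applied per element (each barcode, each
primer) — the stricter plausible reading; a combined budget is a
configuration alternative.  `max_shift = 2` is a default, not a claim about
the original tooling's window.  A read matching nothing in either
orientation is returned unassigned, never raised.

The screen is a pure conjunction of individually enableable filters:

| filter            | default           | rationale                                  |
|-------------------|-------------------|--------------------------------------------|
| homopolymer       | max run ≤ 8       | long runs are error-prone                  |
| insert length     | expected ± 10%    | proxy for alignment-coordinate screening   |
| barcode/primer mm | ≤ 1 each          | mismatches correlate with read error       |
| coverage          | ≥ 10 passes       | error rate plateaus beyond 10-fold         |
| predicted error   | ≤ 0.01%           | strongest single filter                    |

The kept set is order-independent; the report attributes each removed read
to the first filter it fails, in the order of the table.  The original
coordinate screen used a profile alignment against a curated reference
alignment; this package substitutes the insert-length window, which serves
the same intent (reject mis-primed or truncated amplicons) without the
external alignment dependency.

## Alignment conventions

All difference counting is alignment-based.  Read-versus-reference
alignments are unit-cost (Levenshtein, via edlib): the optimum then *is* the
minimal `n_sub + n_ins + n_del`, which is exactly the quantity that drives
best-reference selection, chimera distances and pre-clustering.  Reads align
in `HW` mode — terminal gaps on the reference are free and excluded from all
counts — so a partial fragment is not charged for reference overhang.  The
error-rate denominator is all non-terminal alignment columns
(matches + subs + ins + del), making every `AlignmentResult` self-consistent
and testable; this is noted as an approximation of the original
error-counting tool, whose denominator convention is not documented.  Ties
between equally distant references resolve to input order.

Where gap *placement* matters — enumerating chimera breakpoint columns and
computing OTU distances — unit cost is not enough (a cluster of nearby
substitutions can tie with an indel-pair re-alignment), so those paths use
an affine-scored aligner (match +1, mismatch −1, gap open −2, extend −1;
Biopython `PairwiseAligner`), which prefers substitutions over indel pairs
and keeps gap runs contiguous.

OTU distances additionally count each contiguous internal gap run as a
single difference event and exclude terminal gap runs entirely (free end
gaps in the alignment), so a 3-nt indel over 100 columns gives
1/98 ≈ 0.0102.  Both behaviors are switches.  Distances are computed on the
lexicographically ordered pair, which makes the measure exactly symmetric
under co-optimal alignment ambiguity.

## Chimeras

Single-breakpoint bimeras are the implemented reading of "all possible
chimeras": for every ordered pair of references the parents are aligned and
one product emitted per internal breakpoint column, degapped, deduplicated,
and discarded if identical to a parent.  A read is flagged chimeric when its
distance to the nearest chimera is at least Δ = 3 differences smaller than
its distance to the nearest reference.  Two shortcuts follow from the rule
itself: a read with `d_ref < Δ` can never be flagged, and only chimeras
within `d_ref − Δ` matter, so the search is bounded (edlib's `k` cutoff).
Multi-breakpoint products are out of scope — the enumeration would be
unbounded and single-breakpoint bimeras are the standard model of PCR
template switching.

## Pre-clustering

Unique sequences are sorted by decreasing abundance (ties broken
lexicographically by sequence, for determinism) and each is merged into the
*first* already-retained sequence within the threshold; the threshold is
`floor(length/100)` differences at the default 1 nt per 100 nt.  "Fewer
mismatches than a defined threshold" is implemented as ≤ threshold, which is
the behavior that actually denoises a 250-nt fragment at its worked
threshold of 2.  Closest-match merging is available as an alternative
policy.  Comparisons use pairwise global alignment rather than a multiple
alignment; for near-identical sequences the difference counts coincide.
Total abundance is conserved exactly.

## OTUs and rarefaction

Average-neighbor clustering is agglomerative average linkage (cluster
distance = unweighted mean of cross pairs), cut at 3% by default; the
implementation delegates to `scipy.cluster.hierarchy` and is cross-checked
in the test suite against a naive O(n³) agglomerator.  Rarefied richness
uses the closed-form expectation

    E[S_d] = Σ_i [ 1 − C(N−n_i, d) / C(N, d) ]

evaluated in log-gamma space (exact, deterministic); a seeded Monte-Carlo
subsampler exists purely as a cross-check.  Samples shallower than the
rarefaction depth are rejected rather than extrapolated.

## The simulator

The generator emulates the measured CCS error structure and is the truth
source for every recovery test.  Defaults:

| parameter                | default                           |
|--------------------------|-----------------------------------|
| per-base error rate      | 0.0065                            |
| type mixture (ins/del/sub) | 0.312 / 0.179 / 0.509           |
| deletion base weights    | G 0.394, A 0.243, C 0.183, T 0.180 |
| substitution targets     | uniform over the 3 alternatives   |
| inserted bases           | uniform                           |
| max quality              | 93                                |
| P(max quality) correct/sub/ins | 0.805 / 0.800 / 0.804       |
| other qualities          | uniform 2–92                      |
| passes                   | uniform 3–25                      |
| read-rate dispersion σ   | 1.0 (lognormal, unit mean)        |
| predicted-error scale / σ | 0.015 / 0.5                      |
| chimera rate             | 0                                 |

Mock references descend from one uniformly random ancestor; each template
mutates every site independently with probability `q` chosen so the expected
pairwise divergence equals the requested value (`2q(1−q) + (2/3)q²`,
inverted in closed form).  The default divergence of 0.10 keeps templates
well apart from the 3% OTU cutoff while leaving realistic homology for
chimera formation.

Error positions are i.i.d. uniform along the read (consensus errors carry no
positional decay); the event count is Binomial(length, rate).  Event types
draw from the mixture; deletion victims draw a base class from the deletion
weights and then a uniform position of that base, so the deleted-base
composition matches the weights by construction on balanced templates.
Collisions (a second event on an occupied position) drop the later event —
negligible at these rates, and deterministic.  A systematic-error mode emits
one fixed recurrent 1-nt variant of the first template at a configurable
rate, reproducing the heavy tail of the variant spectrum; by default it is
off.

Two choices extend the stated error model, both motivated by making the
predicted-error filter behave realistically:

1. **Per-read dispersion.** Consensus quality varies enormously between
   reads (it tracks pass count), so each read multiplies the base rate by a
   lognormal factor with unit mean (σ = 1).  Without dispersion, essentially
   no read at the average rate would ever clear a 0.01% predicted-error
   threshold, and the filter would be all-or-nothing instead of selecting
   the better half of the reads.
2. **Predicted-error calibration.** The simulated prediction is the read's
   latent rate scaled down by 0.015 and perturbed by lognormal noise
   (σ = 0.5).  The downward scale reflects that predicted errors sit far
   below observed errors on the absolute scale — a 0.01% threshold retains
   roughly half the reads whose observed error is two orders of magnitude
   larger.  Only the qualitative behavior (negative predicted-vs-observed
   correlation, filter lowers the measured error rate) is asserted anywhere;
   no quantitative claim is tied to this sub-model.

When barcodes and a region are supplied, errors are injected across the
whole assembled read (barcodes and primers included), so barcode/primer
mismatches correlate with read quality the way they do in real data; the
truth table records whole-read injected event counts.  Half the reads are
reverse-complemented to exercise orientation recovery.  Identical seeds give
byte-identical reads and truth tables.

### What the simulator does and does not capture

It reproduces the error rate, type mixture, deletion base bias, quality
cross-tabulation, pass-count metadata, orientation ambiguity, PCR bimeras
and a recurrent-variant mode.  It does not model chemistry-specific
behavior, pass-by-pass subread structure, positional error correlation,
length-dependent loading bias, or the true predicted-error algorithm.
Passing recovery tests therefore demonstrates that the *pipeline measures
what the generator injects* under realistic mixtures and rates — not that
real instrument data will show these exact numbers.

## Problem sizes in tests and the acceptance script

Unit and property tests run on small mock communities (4–6 templates,
120–800 nt, hundreds of reads) chosen to keep every stochastic assertion
inside three standard errors of its expectation with comfortable margin.
The acceptance script simulates full-length (V1–V9, 21 templates) reads in
chunks until at least 100,000 errors and 50,000 deletions have been
injected (~30,000 reads), then trims, aligns and profiles them; these sizes
are the package's own choice of a scale at which binomial noise on the
recovered percentages drops below half a percentage point.

## Known limitations

- The coordinate screen is an insert-length window, not a profile-alignment
  coordinate check; severely mis-assembled reads of coincidentally correct
  length pass the basic screen.
- Unit-cost alignment slightly re-attributes events at read edges (a
  terminal deletion can trade against the free reference overhang),
  visible as a few tenths of a percentage point in recovered type
  fractions at scale — well inside the tolerances asserted.
- Chimera enumeration is quadratic in references and linear in length;
  exhaustive screening against hundreds of long references is expensive
  (the rule's `d_ref − Δ` bound prunes most of the cost per read).
- The greedy pre-cluster is exactly the described algorithm; it is not a
  model-based denoiser and inherits its length-scaled resolution floor.
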