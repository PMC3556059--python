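# Methods

This note documents the models, conventions and numerical choices behind
ciskit, what the synthetic data generator does and does not emulate, and
the design decisions taken where several reasonable options existed.

## Data model and coordinates

All genomic evidence lives in feature tracks aligned to a named sequence
set: DNA tracks (one letter per position, alphabet A,C,G,T,N,X with case
preserved), numeric tracks (one finite float per position), and region
tracks (sorted, possibly overlapping typed intervals with scores, strands,
open property maps, and optional child regions for composite occurrences).

Coordinates are 0-based half-open on the genomic forward strand
everywhere in memory. Strand handling is applied by operations, never by
storage: minus-strand sequences keep their DNA in forward orientation and
reverse complements are computed on demand. On disk, GFF3 is written
1-based inclusive and BED/bedGraph 0-based half-open, per those standards.
A sequence may carry a TSS offset; "x bp upstream" of it means
genomic − x on a plus-strand sequence and genomic + x on a minus-strand
one, which is also how positional histograms assign signs.

IUPAC consensus strings are derived from a matrix column as the symbol
covering exactly the set of bases with frequency ≥ 0.25; since four
frequencies summing to one always contain at least one ≥ 0.25, the rule is
total, and an all-equal column yields N.

## Background models and motif scoring

Background models are order-k Markov chains (k ≤ 5) trained on forward
strands with +1 pseudocount per context cell and complete lower-order
fallback tables used for sequence starts and after masked bases. All
conditional probabilities are therefore strictly positive and sum to one.

A window is scored S = Σᵢ log(M[bᵢ,i]/Q(bᵢ)) with Q the order-0 view of
the background (uniform when none is supplied). The reported relative
score r = (S − S_min)/(S_max − S_min) uses the per-motif extreme
achievable window scores, so r ∈ [0,1], r = 1 exactly at the best-scoring
window, and r is invariant to rescaling matrix columns. A "80 % match"
threshold is r ≥ 0.8. Whether the min-max normalization happens on the
log-odds scale (default) or on the raw probability-ratio scale is a
`scale` switch on the scanners, since tools in this area disagree and the
convention is rarely stated.

Numerical choices: matrix cells are floored at 1e-9 inside the scorer so
hard-zero columns (e.g. a literal consensus matrix) stay finite in log
space; count matrices get +0.25 per cell, probability matrices +0.01 per
cell with renormalization; N/X bases contribute 0 to S (the background
expectation); a motif whose S_max = S_min (uniform matrix) is skipped with
a warning and its score profile is all zeros.

## Positional priors and the priors generator

Any numeric track becomes a prior by joint min-max rescaling over all
sequences (a constant track maps to 0.5 with a warning). The
discriminative conversion d = p(1−q̄)/(p(1−q̄)+q̄(1−p)) is the
odds-correction form: it fixes 0 and 1, maps p = q̄ to ½, and is strictly
order-preserving for any q̄ ∈ (0,1); q̄ may be given as a constant or taken
as the mean prior over a control sequence collection.

The priors generator represents each position by the centered windowed
means of every input feature at window sizes {1, 11, 101} bp by default
(point, local and broad context; configurable). Training labels a
position positive iff it lies inside a target region and subsamples
negatives to a 1:1 ratio. The classifier is a bagged ensemble of three
single-hidden-layer networks (8 logistic units, logistic output, L2
penalty 1e-3, L-BFGS to tolerance 1e-4 or 500 iterations). Each member
draws its own seeded negative subsample and min-max input scaling; the
prior is the mean of member probabilities. The ensemble exists because a
single network fit on a 1:1 subsample of rare positives is high-variance:
occasional bad fits ranked background bursts above sites, and averaging
over independently subsampled members removed those failures without
changing the model class. Generators serialize to a single JSON document
(features, windows, per-member scaling and weights, training metadata);
applying a reloaded generator is bit-identical because application is an
explicit forward pass over the stored float64 matrices.

Prior merit is AUC over site vs background positions, computed by the
Mann-Whitney rank formula with midrank tie correction, with ROC points at
every distinct threshold. Degenerate all-positive or all-negative
labelings are errors rather than silently defined values.

## Module models

A module model is ≥ 2 ordered slots of alternative motif ids with an
overall span bound, an optional order requirement, per-slot strand
constraints, and per-adjacent-pair gap bounds. All distance constraints
are nearest-edge distances, with overlap counting as 0 — the same
convention as the interaction filter, so "within 10 bp" means the same
thing in both. For unordered models the gap constraints apply to the
genomically sorted arrangement of the chosen sites. Scanning enumerates
combinations of one distinct site per slot (member sites may overlap);
occurrences with identical member-site sets are emitted once, occurrences
sharing only some sites are kept separately. The module score is the sum
of member scores by default (mean and min available). Module occurrences
carry their member sites as children and serialize to GFF with
Parent-linked child records.

The interaction filter keeps a site iff some other site in the same
sequence, whose motif is a declared partner, lies within the gap bound;
survival is evaluated against the input track, so removals never cascade.

## Statistics

Overrepresentation uses the exact binomial survival function with the
number of trials equal to the scanned base pairs and the success
probability equal to the control-derived per-bp site frequency — base
pairs are the natural exposure when frequencies come from dividing
control site counts by control length. Significance is flagged at the
Bonferroni threshold α/m over the m motifs tested. Group comparison uses
a two-sided Fisher exact test per motif on (sites, non-site bp) × (group
A, group B); classes are A (higher rate in A, Bonferroni-significant),
B (higher in A, nominally significant), D (higher in B, nominally or
better), C otherwise — the class boundaries are this package's
definition, documented rather than inherited.

Positional clustering uses Pearson kurtosis m₄/m₂² of site midpoints
(population moments; normal ≈ 3; an `excess` option subtracts 3) relative
to the TSS or sequence end, with midpoint = ⌊(start+end)/2⌋ for integer
determinism; motifs with < 4 sites, or zero positional variance, get a
blank. Site-vs-feature averages are position-weighted (longer sites weigh
more). Rank sums rank each input map 1..n in its stated direction with
midranks for ties; members missing from a map share the trailing midrank.

Benchmark metrics label each position by coverage of ≥ 1 predicted
(answer) region and derive Sn, Sp, PPV, Acc, PC, ASP, F and the Matthews
correlation from the four counts; zero-denominator rates (and CC) are defined
as 0 so empty tracks do not crash batch benchmarking. Site-level
sensitivity counts an answer site as found when a single prediction
overlaps at least 25 % of that site's length (configurable fraction).

Rendering is deterministic by construction: raw output is UTF-8 TSV with
histograms as comma-joined bin counts, and HTML embeds hand-generated SVG
histograms and motif logos rather than raster images, because identical
input must produce identical bytes.

## Protocol scripts

Protocols are linear statement lists `target = operation arg=value ...
[where condition]` with `#` comments, no control flow. Values are
numbers, quoted strings, or bare names resolved against the repository at
execution. Execution runs on a copy of the repository and aborts on the
first error, leaving the input untouched. One master seed derives a
per-statement seed by mixing a CRC32 of (statement index, target name), so
editing one statement does not reshuffle unrelated downstream randomness.
Recording through the workbench emits canonical statements whose replay is
bit-identical, including background-sampled sequences.

The external-tool adapter takes an XML description of a command template
with declared input/output file slots and parameters; it validates that
every placeholder is bound, serializes inputs through the standard
writers, and parses declared outputs back into data objects, failing with
captured stdout/stderr on nonzero exit. It exchanges data with the tool
only through the declared slots.

## The synthetic data generator

`generate_planted_dataset` samples background DNA from a Markov model
(uniform by default), implants PWM-sampled sites without overlap at
positions from a uniform or TSS-anchored Gaussian law with a configurable
strand probability, and records the exact implants as the answer key. A
matched control track holds the same background without implants. Each
companion feature track is ρ · (11 bp-smoothed answer coverage) +
(1−ρ) · noise, min-max normalized: ρ = 1 is perfectly informative and
ρ = 0 pure noise. `generate_module_dataset` implants motif pairs with
gaps from a fixed or uniform law and emits both the flat site answer and
module-level regions with children. Identical spec + seed reproduces
every bundle bit-exactly.

The noise is lognormal (μ = −1.5, σ = 1.0) by default, not uniform.
Real evidence tracks in this domain — DNase signal, conservation scores,
ChIP enrichment — are bursty and heavy-tailed, and the noise law decides
what the benchmark can measure: under uniform noise a ρ = 0.8 feature is
nearly separable from background by construction (single-feature AUC
≈ 0.999), so combining features has no measurable headroom; under
heavy-tailed noise single features sit at realistic AUCs (~0.95) and
integrating independent evidence demonstrably helps, which is the
phenomenon the priors machinery exists to exploit. Uniform noise remains
available via `PlantSpec.noise_law`.

What a green test on synthetic data does establish: the algorithms
recover planted structure whose generative assumptions they match, and
every pipeline stage composes deterministically. What it does not: real
conservation has phylogenetic block structure, real ChIP coverage has
fragment-length autocorrelation, real promoters have compositional
heterogeneity (CpG islands, repeats) — none of which the mixing formula
emulates, so synthetic AUCs and CCs say nothing quantitative about
performance on genomic data.

## Known limitations

De novo motif discovery and published module-discovery algorithms are
deliberately not implemented natively; they are reachable only through
the external-tool adapter. Peak/valley/edge detectors beyond thresholded
runs are not provided. Tracks are in-memory; genome-scale lazy tracks and
binary formats (bigWig, 2bit) are out of scope. The module scanner is an
exact enumerator, appropriate for promoter-scale candidate counts, not
for genome-wide site sets.
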