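# ciskit

A scriptable workbench core for regulatory-sequence analysis: find and
evaluate transcription factor binding sites and cis-regulatory modules in
promoter-scale DNA by combining motif scanning with heterogeneous genomic
evidence (conservation, DNase accessibility, repeats, ChIP peaks, ...).

ciskit is a library for people who analyse sets of co-regulated promoters:
it represents every kind of genomic evidence as a *feature track* over a
named sequence set (DNA letters, one number per position, or region lists),
lets arbitrary Boolean conditions over those tracks drive masking, filtering
and transformation operations, and makes whole workflows reproducible
through a recordable, replayable protocol-script language with one master
seed.

## What it computes

**Motif scanning.** A motif is a column-stochastic position weight matrix
M (4 × w). A window b₁..b_w scores S = Σᵢ log(M[bᵢ,i]/Q(bᵢ)) against an
order-k Markov background Q, reported as the relative score
r = (S − S_min)/(S_max − S_min) ∈ [0,1], so "80 % match" means r ≥ 0.8.
Both strands are scanned; N/X bases score as the background expectation.

**Positional priors.** Any evidence track rescales into a prior P(position
is in a site) ∈ [0,1]; priors combine by weighted sums, convert to
discriminative form d = p(1−q̄)/(p(1−q̄)+q̄(1−p)) against a control mean q̄,
or come from a trained *priors generator* — a per-position classifier (a
small bagged ensemble of one-hidden-layer networks) mapping windowed
feature values to a prior. Merit is measured as ROC/AUC over site vs
background positions (Mann-Whitney rank formula, midrank ties).

**Module scanning.** A cis-regulatory module model is a list of slots
(alternative motif ids) with span, order, orientation and nearest-edge gap
constraints; scanning enumerates candidate-site combinations that satisfy
the model. Interaction-partner filtering keeps only sites with a partner
site within a given distance.

**Statistics.** Exact binomial overrepresentation against control-derived
motif frequencies with Bonferroni correction; Fisher-exact group
comparison; positional clustering via kurtosis m₄/m₂² of TSS-relative site
midpoints; position-weighted site conservation; rank-sum combination of
any of these; and benchmark metrics against an answer key (nucleotide-level
Sn, Sp, PPV, Acc, PC, ASP, F, Matthews CC, and site-level sensitivity at a
25 % overlap rule).

Everything is testable offline: `ciskit.synth` plants motif sites (or
motif pairs with gap laws) in background-model DNA and emits the answer
key, companion evidence tracks of chosen informativeness, and a matched
control set.

## Worked example

`examples/03_overrepresentation_report.py` plants a CREB-like motif
(TGACGTCA) at TSS-proximal positions in ten 400 bp synthetic promoters,
scans them and background-sampled controls with the true motif plus two
decoys, and collates the full report:

```
motif	total	support	p_value	mean	kurtosis	histogram
creb_like	28	7	1.71357e-09	0.265897	1.81344	0,0,0,0,10,8,10,0
decoy1	40	9	0.331699	0.057998	1.50935	0,8,12,0,2,6,6,6
decoy2	36	10	0.958927	0.0567513	1.51292	10,6,4,4,6,4,2,0

Bonferroni-corrected threshold: 0.0167
```

Reading the table: `total`/`support` count sites and sequences with ≥ 1
site; `p_value` is the exact binomial tail of the observed count against
the control-derived frequency — only the planted motif is significant
(1.7 × 10⁻⁹ ≪ 0.05/3); `mean` is average pseudo-conservation over site
positions (the planted sites sit in the conserved signal, decoy hits do
not); `kurtosis`/`histogram` show the planted motif clustering upstream of
the TSS. Rows are sorted by the combined rank of p-value (ascending),
conservation (descending) and kurtosis (descending) — the planted motif
ranks first.

The other examples cover track operations and conditions (01), scanning
and consensus matching (02), priors and priors generators (04), module
scanning and interaction filtering (05), and protocol record/replay (06).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
runs a complete seeded analysis (planting, background training, control
sampling, scanning, overrepresentation, positional and conservation
analyses) and recomputes the analytically checkable quantity — the
Bonferroni-corrected overrepresentation threshold for α = 0.05 over a
931-motif library — writing it to the JSON file named by `--out`.
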