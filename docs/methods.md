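# Methods

This note records the models, the defaults and why they were chosen, the
numerical decisions taken where the analysis conventions were genuinely
open, and what the synthetic validation does and does not establish.

## Combination-screen model

A screen is a dose grid (drug A × drug B) of replicate wells plus
vehicle-only controls on the same plate. Percent viability is
100 · raw / mean(controls); inhibition is its complement. The additive
expectation at a dose pair is the **plain sum** of the two single-agent
inhibitions at the pair's marginal doses, capped at 100% by default: an
uncapped sum exceeds total kill at high doses and makes the delta
uninterpretable there; the uncapped literal sum is available via
`cap=None`. Negative inhibition (growth stimulation) is retained —
flooring it would hide antagonism.

The per-pair test compares replicate observed inhibitions with
replicate-matched expected values (each expected replicate is the capped
sum of the same replicate's two monotherapy inhibitions). Welch's
two-sample t is the default because equal variances are not guaranteed;
a paired t on the replicate-matched differences is a flag away, since
the pairing convention of the original analyses of this kind is usually
unstated. The multiple-testing family is all dose pairs of one screen,
Benjamini–Hochberg. When both groups have zero variance the test is
defined as p = 1 at equal means and p = 0 otherwise.

Two estimator properties matter for interpretation. First, with plate
noise on every well, the delta estimate at one pair combines 3 cells × r
replicates of noise; at noise sd 5% and quadruplicates its sampling sd
is ≈ 4.3 percentage points, so single-screen deltas are read with that
error bar (the acceptance script averages replicate screens for its
headline value). Second, near total kill the viability floor at 0
truncates noise asymmetrically and biases deltas negative (spurious
antagonism); additivity calibration is therefore evaluated on dose
ranges whose additive expectation stays clearly below the cap, and
contour/delta values at saturated cells should be treated as
qualitative.

## Synthetic screen generator

Monotherapy curves are 4-parameter Hill functions (bottom 0, top 90%,
configurable EC50/slope) — the generic sigmoid shape of multi-dose
viability screens. Combination inhibition is the capped additive sum
plus any planted excess from `embedded_delta_map` plus Gaussian noise on
percent viability, truncated to [0, 120] to mimic plate scatter above
100%. Controls receive the same noise around the control level. With
noise 0 the observed inhibition equals the capped sum exactly, so
planted deltas are recovered exactly — the construction oracle used in
tests.

## NES switch analysis

Input tables are per-condition GSEA outputs (term, NES, adjusted p).
Significance is adjusted p < 0.05 by default (the convention, not a
published choice), and a term must be significant in **both** conditions
to be eligible — the stricter reading; passing unfiltered tables
effectively relaxes this. A switch requires strictly opposite NES signs;
NES = 0 has no sign and never switches. ΔNES = |NES₁ − NES₂| is the only
definition under which flips rank by combined magnitude, and for a true
sign flip it is ≥ max(|NES₁|, |NES₂|). Keyword classification is
case-insensitive substring matching with first-match-wins in the
declared category order; since GSEA term names rarely contain the
literal phrase "nuclear receptor", that category ships with a
receptor-token word list (ESTROGEN, ANDROGEN, RECEPTOR, ESR, AR_, ...),
overridable.

## Interval engine

Coordinates are 0-based half-open throughout (BED convention; touching
intervals do not overlap). Overlap queries run on interval trees; the
O(n²) scan exists only as the test oracle. Venn membership assigns each
region of each set the ``&``-joined set of labels it overlaps by ≥ 1 bp
— a region overlapping several regions of another set counts once, so
per-source-set class counts always sum to the set size. Partitioning is
guarded at k ≤ 4 (15 classes) by default. Peak-to-gene annotation
measures region-edge-to-TSS distance (0 inside the region), windows at
100 kb, with a gene-body option; nearest-gene ties break alphabetically
so outputs are deterministic. Strand is ignored everywhere — cistrome
peaks are unstranded.

## Hypergeometric enrichment

`hypergeom_upper` returns P(X ≥ k) as an exact rational tail sum over
integer binomials (a `Fraction` on request); the acceptance suite checks
it against exhaustive enumeration of all draws for every configuration
with universe ≤ 15, and against `scipy.stats.hypergeom.sf` as an
independent cross-check. Reported log p-values are −log10 with p floored
at 1e-320.

Universe choices, which published analyses rarely state, are explicit
here: for cistrome-vs-cistrome significance the universe is a supplied
region set — the merged union of tested windows when available,
otherwise fixed-width genome bins (the pipeline default, 2 kb); every
result row records its universe size. Chromatin-state enrichment counts
**regions**, not base pairs: universe = all segmentation segments,
targets = segments of the state, draws = query regions, successes =
query regions intersecting the state by ≥ 1 bp (a region spanning two
states counts toward both).

The co-enrichment scan scores each collection dataset as (query regions
overlapped) / √(dataset size) — a size normalization that preserves the
rank behavior the published rule operates on — then applies the quoted
rule: a factor is co-enriched when its share of the top 200 datasets
exceeds 1.2× its share of the whole collection; tissue-filtered scans
report mean overlap score per factor instead.

## Motif coverage

Scanning is a log-odds PWM scan: probabilities get a 0.01 pseudocount
(then renormalize) to avoid −∞ on zero entries; window score is
Σ log2(p/background) over both strands; windows containing N score −∞; a
region is covered when its best window reaches `score_fraction` (default
0.8; the validation uses 0.9) of the motif's maximum attainable score.
Coverage is the percent of regions with ≥ 1 hit — the
fraction-of-regions reading of "coverage", chosen over bp-coverage as
the conventional one. Background defaults to uniform; a region-set
composition can be supplied. Family summaries count motifs whose delta
passes ±threshold (default 5 points) and report the family mean delta.

## Integration and signature

"Absolute fold change" is |log2FC| by default (`fc_measure="linear"`
gives 2^|log2FC|); the source convention is ambiguous and the choice
only rescales scores monotonically. The DEG gate is −log10 p > 1 and
|log2FC| > 0.263, configurable. A gene reached by several peaks of one
factor keeps all records by default; `collapse_per_gene` keeps the
highest-scoring peak per (factor, gene, direction) and is what the
statistical validation uses, because the group t-test assumes
independent records and multi-peak genes duplicate the same expression
value. Peak score is treated as an opaque non-negative column — whether
it is a differential-binding statistic or a peak-caller score does not
enter the method.

Signature rules are fixed as (AR, loss, up), (MYC, loss, down),
(H3K27ac, loss, down); the union is deduplicated and sorted. Tumor
clustering is Ward on Euclidean distance of the tumor columns
(correlation/complete-linkage available), k = 2 by default since the
downstream contrast is cluster-vs-category; inputs are already Z-scores
so no re-scaling is applied by default. The association test applies
Yates' continuity correction exactly on 2×2 tables
(Σ(|O−E|−0.5)²/E, clamped) and plain Pearson otherwise, keyed to table
shape with an override — published reports mix the two and rarely state
the table dimensions. Expected counts of 0 are an error; counts below 5
attach a warning.

## Synthetic genome, cistromes and cohort

The simulation genome is small (default 2 × 10 Mb; the statistical
checks use 1 × 4 Mb) — all interval code is genome-agnostic, and these
sizes keep hundreds of Monte-Carlo replicates cheap. The chromatin
segmentation tiles the genome into 2 kb segments with states drawn from
a fixed frequency vector (promoter 8%, bivalent 4%, active enhancer 12%,
poised enhancer 12%, Polycomb 8%, quiescent 56%). Differential sites
occupy one segment each (loss in the left half, gain in the right, so
the directions of one factor never collide even in a shared segment);
loss sites pick their segment with odds multiplied by
`loss_enhancer_enrichment` for poised enhancers and a third of that
excess for active enhancers — loss of binding concentrates most strongly
in poised enhancers, the structure the state-enrichment stage is meant
to recover — while gain sites pick uniformly. A planted block of
identical loss sites is shared between the first two factors. Because
sites are drawn from segments without replacement, the state counts are
exactly hypergeometric under the null (odds 1), which makes the
enrichment p-values honestly calibrated but also **discrete**: null
uniformity is checked on a 2-state half/half segmentation (the least
discrete support) with one state p-value per replicate, since pooling
the stepped p-values of many small states makes a Kolmogorov–Smirnov
comparison against the continuous uniform fail for granularity alone.

DEG tables are a null/DE mixture: null log2FC ~ N(0, 0.05), DE
magnitude |N(1, lfc_sd)|. P-values are the ones implied by
z = log2FC/0.05 — fold change and significance thresholds stay jointly
meaningful, null p-values are uniform, and at `deg_fraction = 0` no gene
passes the DEG gate. Binding–expression coupling applies to DE genes
whose TSS lies within 10 kb of a loss site: they go down with
probability 0.5 + coupling/2 and their magnitude scales by
(1 + coupling) when down. The 10 kb coupling window is deliberately
tighter than the 100 kb annotation window: on a 20 Mb genome a 100 kb
coupling window would cover essentially every gene and erase the null
contrast between near-loss and far genes.

NES tables plant exactly round(switch_fraction · n_terms) terms
significant in both conditions with opposite signs; all other terms
share a sign or fail significance in at least one condition, so the
planted count is recovered exactly. The cohort is two latent subtypes of
equal size; half the signature genes shift up (+shift/2 vs −shift/2) and
half down in subtype 1, and per-tumor AR (2-level) and NE (3-level)
categories take the subtype-typical label with probability
`category_strength`. Sequences are i.i.d. nucleotides at a configurable
composition with PWM consensuses inserted at random offsets and strands
in a without-replacement sample of regions; the bundled demo PWM set is
deliberately sharp (0.91 on the consensus base) so that a 0.9
fraction-of-max threshold has a negligible background hit rate at 200 bp
and planted coverage rates are recovered within sampling error.

## What the synthetic validation does not show

The generators reproduce the *statistical structure* the methods assume
— additive-plus-excess dose responses, enhancer-skewed loss sites,
effect-coupled expression, block-structured cohorts — not the
complexity of real data: no spatial autocorrelation along the genome, no
peak-width or GC structure, no batch effects, no dependence between
replicate wells beyond shared truth, no heavy-tailed expression noise.
Passing the recovery and calibration checks shows the implementations
compute what they claim and detect what they are pointed at; it does not
certify power or error rates on real screens or sequencing data.

## Validation problem sizes

Hypergeometric enumeration: all universes ≤ 15. Screen calibration: 500
null 6×6 screens (quadruplicates, noise sd 5) plus a fixed-seed planted
screen and a 50-screen bias check. Interval oracles: 100 random
instances of ≤ 200 intervals plus half-open boundary cases. Chromatin
states: 500 planted loss sites at odds 10 on a 4 Mb genome; 500 null
replicates for calibration. Motifs: 200 regions × 200 bp per arm at
plant rates 0.4 vs 0.1. Integration: 200 null replicates for p-value
uniformity. Cohort: 100 tumors × 192 genes, 200 null replicates. The
end-to-end demo pipeline runs in well under a minute.
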