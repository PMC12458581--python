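# Methods

## Scope and design

The package analyzes a two-age-group (weaning → young adulthood),
multi-exposure liver study: gene counts, histone-mark window counts,
an enhancer catalog, and human-like disease cohorts. The bespoke content —
trajectory attenuation/acceleration classification, enhancer-anchor
construction and concordance partitioning, the pathway-overlap permutation
test, and summed z-score signature activity — is implemented here;
standard steps (BH adjustment, t-tests, hypergeometric tails,
Jensen–Shannon distance, Pearson correlation) are delegated to
scipy/statsmodels behind the module interfaces.

All genomic coordinates are 0-based half-open throughout. Overlap means
≥ 1 shared base; an interval ending at position *x* does not overlap one
starting at *x*.

## Differential stand-ins

Production studies use negative-binomial frameworks (genes) and
sliding-window scanners (peaks). This package deliberately ships simpler,
fully-specified substitutes that apply the same significance rule
(FDR < α, fold change > τ; defaults α = 0.05, τ = 1.5):

- **Genes.** CPM normalization; Welch two-sample *t* on log₂(CPM + 0.5);
  BH across genes. Fold change is the ratio of group mean CPMs with a 0.5
  pseudo-count added to each mean, which keeps the ratio finite and makes
  it invert exactly under a group swap (directions flip symmetrically).
  All-zero genes are retained with p = 1.
- **Peaks.** Pooled group counts per tiled window; G-test (likelihood-ratio
  χ², df = 1) against expectations proportional to pooled library sizes;
  BH across tested windows; windows empty in both groups are skipped.
  Significant, strictly adjacent windows with the same direction merge
  into one peak carrying the extreme log₂FC and minimum q. Merging bridges
  zero-gap neighbors only, so a non-significant window always splits a
  peak.

Adequacy is established empirically rather than by matching a reference
tool: on all-null simulated counts (2,000 genes, 5 vs 5) the q < 0.05
fraction stays within binomial bounds of zero, and planted |log₂FC| = 1
effects at 10 per group are recovered at ≥ 80% (see the acceptance tests).
Samples are treated as exchangeable; no blocking factor (e.g. litter) is
modeled.

The ChIP QC statistic is the Jensen–Shannon *distance* (square root of the
base-2 divergence) between binned coverage fractions, 0 for identical
histograms and 1 for disjoint support.

## Trajectory classification

Signatures are pairs of disjoint up/down gene sets derived from
differential tables (ns excluded). For each gene in both an exposure
signature and the aging signature, the call is *attenuated* when the two
directions differ and *accelerated* when they agree; the two classes
partition the overlap by construction. Sex-specific signatures partition
into shared/sex-only/discordant sets; the composite signature is the union
of same-direction calls with discordant genes excluded (the partition
output retains them) — the union was chosen over the intersection because
the composite is meant to cover every gene either sex shows plasticity
for, and the choice is localized in `composite_signature`.

Reported percentages carry three forms (raw, nearest-integer
half-away-from-zero, truncated) because published summaries mix the two
integer conventions; callers pick explicitly.

## Regulatory map

Promoter windows are [TSS − flank, TSS + flank), default flank 3,000 bp,
clipped at zero. Anchors merge catalog enhancers that overlap or are
book-ended (`max_gap = 0` by default, configurable); the anchor takes the
union of constituent gene links and remembers its source count. The merge
is a sorted sweep, order-independent and idempotent, and is tested against
an O(n²) transitive-closure oracle.

Peak assignment is plain ≥ 1 bp interval intersection against promoter
windows and anchors; a peak over a three-gene anchor yields three rows,
and the same peak may be counted through both a promoter and an anchor
(both raw records and the per-gene deduplicated categories are available).
Concordance uses mark polarity (active: H3K27ac, H3K4me1, H3K4me3;
repressive: H3K27me3, H3K9me3). A gene counts as concordant if at least
one of its assigned records is concordant — discordant records do not
cancel — and genes then land in exactly one of promoter-only /
enhancer-only / both / neither. H3K9me3 is excluded from aging concordance
by default because that mark is modeled as flat across this age range;
`exclude_marks=()` re-includes it.

## Enrichment

ORA is the upper-tail hypergeometric P(X ≥ k) with the gene set clipped to
the universe. Preranked GSEA uses the weighted KS running sum (hit steps ∝
|score|^w normalized, default w = 1; miss steps 1/(N−K)); ES is the signed
extremum, the null is built from random same-size sets, NES divides by the
sign-matched null mean |ES|, and p is the one-sided empirical tail with
the +1 correction. Ties keep input order (GSEA tie handling is
implementation-defined; this makes it deterministic). Across a collection,
the FDR is BH on empirical p by default, with the classic NES-based
empirical FDR as an option. A set equal to the whole ranked list has no
misses and is assigned ES = 0.

The pathway-overlap test draws both pathway lists uniformly without
replacement from the universe and records intersection sizes over 10,000
permutations, fits a normal, and reports the upper-tail survival of the
observed overlap (the test targets *over*-sharing). Conditionally on one
draw the intersection count is exactly hypergeometric, so the permutation
is realized as hypergeometric sampling — identical in distribution and
fast enough for calibration suites. Uniform (non-size-stratified) sampling
is used. When the permutation sd is zero the result carries a degeneracy
flag with p = 1 (observed ≤ mean) or the smallest positive float. The
realized type-I error at moderate sizes (universe 100, lists 20/30) is
slightly conservative (≈ 0.04 at nominal 0.05) because the overlap is
discrete; the calibration test measures this directly. Network edges
connect exposures sharing same-direction enriched pathways, positive and
negative directions networked separately.

## Signature scoring

Genes are z-scored across samples with the population (divisor-*n*)
standard deviation; zero-variance genes get z = 0 everywhere and are
counted. The activity score is the raw sum (up minus down) — not a mean —
with `n_genes_used` reported so callers can normalize; this matches the
"add and subtract z-scores" definition literally. Scores of a centered
matrix sum to zero across the cohort, and z-scoring makes the statistic
invariant to per-gene affine rescaling (a·x + b, a > 0), both asserted as
properties. Severity association encodes the supplied state order as
0..k−1 with unit spacing (the minimal assumption for "numerical values in
order of severity") and reports two-sided Pearson r/p. Homolog mapping
expands a mouse gene to all its human homologs, drops unmapped genes with
a count, and excludes human genes that would receive both directions.
Cohorts are z-scored per cohort, separately.

## Synthetic data

The generator is the study-conditions oracle, not a tuning surface.

- **Counts.** Negative binomial via gamma–Poisson with variance
  μ + φμ² (default φ = 0.1); per-gene base means log-normal
  (meanlog 5, sdlog 1 → median ≈ 150 counts); per-sample library factors
  log-normal (σ = 0.2) so CPM normalization is actually exercised.
- **Aging effects.** Fractions of genes (defaults 5% up, 15% down,
  mirroring the down-dominated plasticity set) get ± `age_log2fc`
  (default 1.5, clearing the 1.5× call threshold) applied as a linear
  log₂ ramp across the ordered age groups.
- **Exposure effects** apply only at the adult age group (matching the
  adult-timepoint exposure contrasts). Each exposure perturbs
  `n_exposure_genes` (default 300): a fraction `frac_attenuated` drawn
  from planted aging genes with the opposite direction, `frac_accelerated`
  with the same direction, the remainder from null genes with random sign.
  `n_exposure_genes` is the one knob the configuration needs beyond the
  stated proportions, since the fractions are defined relative to a DEG
  count; 300 is a typical exposure-signature size for this design.
- **Enhancer catalog.** Per-gene link counts Poisson(8); each enhancer
  links 1–3 genes; enhancers occupy non-overlapping slots except that a
  unit is a book-ended pair with probability `adjacency_rate`, so anchor
  merging has known ground truth (rate 0 → no merges; rate 1 → half the
  anchors).
- **Mark peaks.** One peak (promoter ±750 bp of TSS, a linked enhancer,
  or both) per planted aging gene per mark, with the direction concordant
  with expression — given the mark's polarity — with probability
  `concordance_rate` (default 0.8). Window counts are Poisson, baseline 20
  per 500-bp window, planted fold change 4 so the window G-test recovers
  peaks with high power at this depth.
- **Cohorts.** Balanced round-robin severity assignment; expression is
  unit Gaussian noise plus `effect × direction × severity-index`, with 200
  background genes as a null backdrop.

Everything derives from one `numpy` generator per seed; identical config +
seed reproduces every table exactly (set iteration is sorted wherever it
feeds the generator).

What the generator does **not** emulate: batch/litter structure, realistic
mean–dispersion trends, length/GC biases, read-level noise, correlated
genes, multiple chromosomes, cell-type mixtures. Passing recovery tests
therefore demonstrates the pipeline's logic and calibration under a clean
NB/Poisson world, not robustness to those real-data complications.

## Pipeline sizes and reproducibility

Default end-to-end runs use a few hundred to a few thousand genes with
five replicates per group, sizes at which every stage completes in seconds
and planted-parameter recovery is already stable (attenuated-share
estimates land within a few percent of truth; see the acceptance suite).
The pipeline report is rebuilt from persisted intermediates only, and
reruns with the same config are byte-identical.

## Known limitations

- The differential stand-ins are calibrated, not equivalent to
  edgeR/diffReps; absolute DEG lists on real data would differ.
- The overlap permutation test ignores pathway-size structure and
  inter-pathway gene sharing.
- Trajectory classification treats directions as binary; magnitude of
  attenuation is not modeled.
- `simulate_study` plants at most one peak per (gene, mark, region), so
  multi-peak promoters are unrepresented.
- Severity association assumes unit spacing between ordinal states;
  only the sign is invariant to monotone re-encodings.
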