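# Methods

## Methylation-state mixture model

The converted-read count k at a cytosine with coverage n is modelled as a
three-component mixture:

    P(k | n) = π_m BB(k; n, α_m, β_m) + π_u BB(k; n, α_u, β_u) + π₀ /(n+1)

The beta-binomial components describe fully methylated (low converted
fraction; bisulfite conversion fails only at the non-conversion error
rate) and fully unmethylated sites (converted fraction near the
conversion efficiency); they accommodate the site-to-site overdispersion
a plain binomial cannot. The third state is a discrete uniform over
{0..n} given the site's coverage, pmf 1/(n+1) — an explicit "anything
goes" state for sites that fit neither component (partial methylation,
mapping artifacts, allele-specific signal). The pmf is evaluated through
log-gamma functions (`scipy.special.gammaln`/`betaln`), never through
factorials, so it is exact at any coverage.

**Identifiability.** Converted reads indicate *un*methylation, so the
methylated component is defined as the one with the lower mean converted
fraction α_m/(α_m+β_m); after every M-step the components are swapped if
needed to maintain this ordering.

**EM.** The E-step and the likelihood are computed on the unique (k, n)
pairs weighted by multiplicity — an exact reformulation that makes the
cost independent of the number of sites (coverage ~15 gives a few hundred
distinct pairs for any number of sites). Weight updates are the mean
responsibilities (analytic); the beta-binomial shapes have no closed-form
MLE, so they are updated by bounded L-BFGS-B in (log α, log β) with
bounds [10⁻³, 10⁴]. The optimizer maximizes the responsibility-weighted
component log-likelihood, so the EM lower bound — and hence the
log-likelihood trajectory — is non-decreasing; this is asserted in tests
at a 10⁻⁸ relative slack for floating-point noise. Convergence: relative
log-likelihood change < 10⁻⁶ (default), cap 500 iterations. The default
initialization is deterministic method-of-moments on the lower/upper
terciles of k/n with weights (0.45, 0.45, 0.10). If the fitted
components collapse onto each other or hit the shape bounds (e.g. data
containing only k = 0), a RuntimeWarning is raised and the clamped model
returned rather than crashing.

**Calling.** Posteriors are computed per site by log-sum-exp. A site is
*discarded* iff all three posteriors exceed τ = 10⁻⁴ — i.e. kept exactly
when at least one state can be ruled out at that level. Kept sites get
the arg-max state, ties broken methylated > unmethylated > undetermined.
This is a literal reading of the discard rule: a kept site whose two top
posteriors are nearly equal (say 0.50/0.4999) is still called by arg-max.
The methylation level (n−k)/n is reported for every site regardless of
status. Note the rule's asymmetry at moderate coverage: a site can be
discarded not because it is ambiguous between the two main states but
because the uniform state cannot be excluded; with the default weights
this discards sites in the overlap region between a component's tail and
the uniform floor.

## Motif scanning and the empirical filter

PWMs are parsed from JASPAR text (both the bracketed `A [ 4 19 0 ]` and
the plain 4-row dialect, via Biopython) in fixed alphabet order A,C,G,T.
Column probabilities get a background-proportional pseudocount: with
column total c and pseudocount rate ε (default 10⁻³),
p = (counts + ε·c·bg) / (c·(1+ε)). The score matrix is log₂(p/bg);
windows are scored by summing per-position entries, minus-strand windows
on the reverse complement but reported on forward coordinates, and
windows containing N are skipped.

The scan threshold default is 60% of the maximum attainable score — a
deliberately lenient pre-filter whose only job is to bound the candidate
list; the statistical gate is the empirical p-value. The null is the
score distribution of windows drawn i.i.d. from a background composition
(default uniform; configurable), with at least 1000 samples (default
100,000). The single-tail p-value uses the add-one estimator
p = (1 + #{null ≥ s}) / (N + 1), which can never return 0 and makes the
retained fraction on true background converge to the cutoff from below.
Matches with p > 5% are discarded. "Lies within" a ChIP-seq peak is
implemented as full containment of the match interval, the strict reading;
overlap-based association (≥ 1 shared base) is a separate operation used
to attach matches to features.

Per-column information content is 2 + Σ_b p_b log₂ p_b bits on the
pseudocounted probabilities (0·log 0 := 0), bounded in [0, 2]. The score
ratio reported for display is score / max_score and can be ≤ 0 for poor
matches; it is not clamped.

## Regulatory build

Inputs are per-cell segmentation states over the eight-label vocabulary
{tss, flank, transcribed, enhancer, ctcf, repressed, low,
heterochromatin} and experimental peaks. Only tss, flank, enhancer and
ctcf generate features; the other four labels influence nothing but may
coexist in the input. Per label, segments are unioned across cell types
(merge gap 0); overlaps across classes are resolved by the fixed priority
tss > flank > enhancer > ctcf, subtracting every higher-priority
footprint from lower-priority candidates. This makes all features —
same-class and cross-class — pairwise disjoint by construction. Peaks
with no overlap against any existing feature are merged per evidence kind
and become unannotated TF-binding-site or open-chromatin features (the
open-chromatin assay vocabulary defaults to DNase1/DNase/ATAC/FAIRE and
is configurable), so no evidence is silently dropped. Activity is binary:
a feature is active in cell c iff it overlaps a segment of its own class
in c, or any peak observed in c. Stable ids are the rank in
(contig, start, class) order, zero-padded to 8 digits under a
configurable prefix, so rebuilds on identical input are byte-identical.

A caveat on monotonicity: adding a cell type never shrinks the build's
total covered bases nor the top-priority class, but it can reassign bases
from a lower-priority class to a higher one (a newly observed promoter
claims bases previously called enhancer). This is inherent to
priority-based disjointness and is asserted as such in the tests.

## Variant consequences

For an SNV at motif offset j (minus-strand matches index from the 3'
genomic end, alleles complemented), the score change is
logodds[j, alt] − logodds[j, ref]: exact, because a substitution changes
one term of the window sum. The high-information flag is
column_information(j) ≥ 1.5 bits, computed with the same pseudocounted
probabilities as scanning, keeping the flag consistent with the scores.
Non-SNV variants overlapping a match are reported with position and
information flag but no score change, flagged `non_snv`.

## Synthetic data

The generators are pure functions of (parameters, seed); all randomness
uses `numpy.random.default_rng`.

- `simulate_methylome` draws states from the mixing weights and counts
  from the state's distribution; coverage is shifted Poisson
  (mean 15, +1) so n ≥ 1. The default "well-separated" model in tests
  and the CLI is (α_m, β_m) = (5, 120), (α_u, β_u) = (120, 5), weights
  (0.45, 0.45, 0.10): mean conversion 4% for methylated sites
  (non-conversion error) and 96% for unmethylated (conversion
  efficiency), values typical of bisulfite libraries. The separation was
  chosen analytically so that the posterior rule misclassifies or
  discards well under 1% of pure-component sites at coverage ≥ 10 —
  the regime the ≥ 99% calling-accuracy check assumes.
- `simulate_genome` is i.i.d. sequence; `plant_motifs` overwrites
  non-overlapping windows with the PWM consensus (exact mode, default) so
  scan recall is exactly testable, or with draws from the PWM columns
  (`exact=False`).
- `make_peaks` and `make_segmentation` materialize peaks around plants
  and a per-cell segmentation design verbatim.

What the generators do **not** emulate: spatial correlation of
methylation along the genome, CpG-island structure, repeats or
non-uniform background composition, read-level errors, and correlated
activity across cell types. Green tests therefore demonstrate
correctness of the algorithms under their stated model, not performance
on real libraries — on real data the uniform-state fraction, the
component separation and the background composition all have to be
estimated, and the empirical null should be built from genuine genomic
background rather than an i.i.d. model.

## Problem sizes and numerical choices

Simulation-based tests use 20,000 methylation sites (where parameter
recovery is asserted to ±0.02) and 100,000 windows/null samples for
filter calibration (Monte-Carlo error on the retained fraction
~0.07 pp, asserted at ±0.5 pp). Degenerate inputs: empty site lists and
empty score nulls raise; empty BED/JASPAR files return empty lists;
sequences shorter than the motif scan to nothing. Tolerances asserted in
tests: beta-binomial pmf vs quadrature 10⁻⁸ relative; EM monotonicity
slack 10⁻⁸ relative per step; posterior simplex 10⁻⁹.

## Known limitations

- The mixture assumes exactly two pure states plus uniform noise;
  intermediate (allele-specific or partial) methylation is absorbed by
  the uniform state rather than modelled.
- Empirical p-values are bounded below by 1/(N+1); ranking among matches
  far above the null maximum needs a larger null, not this estimator.
- The empirical null is i.i.d. by composition; no dinucleotide or
  repeat-aware background model.
- The build's activity flag is binary overlap; no signal-strength
  thresholds.
- PWM→gene association consumes precomputed cross-reference and best-hit
  tables; the protein alignment that produces them is out of scope.
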