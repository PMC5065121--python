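# Methods

## The competition model

A pooled screen is modeled as deterministic discrete-generation relative
growth. Strain *i* with per-generation selection coefficient sᵢ (> −1, with
s = 0 neutral) has frequency

    f_i(t) = f_i(0) (1+s_i)^t / Σ_j f_j(0) (1+s_j)^t .

Drift is deliberately absent: chemostat pools contain ~10⁹ cells, so
stochastic frequency changes over 20 generations are negligible relative to
sequencing noise. All randomness of the readout enters at one point — each
sequenced sample is a single multinomial draw of `depth` reads over the
current frequency vector. Consequences used throughout the tests: the
simulate → FASTQ → demultiplex → count path reproduces the drawn counts
exactly (read generation and exact-match counting are inverses), and a
"noiseless" run (expected counts instead of a draw) exposes the estimator's
deterministic behavior in isolation.

Timepoint 0 is the sample taken at the switch to continuous culture;
pre-steady-state batch growth is not modeled separately. Default design:
generations (0, 3, 6, 9, 12, 15, 18, 20), two replicate screens, expected
depth 462 reads per strain per sample — the scale of the assay this package
emulates.

## Synthetic pools and what they do and do not capture

`build_pool` draws true fitness from a three-component mixture: a point mass
at 0 (default weight 0.90), beneficial ~ U(0, 0.4) (0.05) and deleterious ~
U(−0.3, 0) (0.05), spanning the fitness range such screens report. Barcodes
are unique random 20-mers; reads are 36 bp laid out as
`[6-mer sample tag][10-bp constant spacer][20-bp barcode]` with uniform
dummy qualities — real amplicon structure varies, but a fixed layout makes
counting exactly testable. Not emulated: PCR amplification bias,
sequencing-error models (hence the exact-match rules are lossless here,
while on real data they discard a sequencer-dependent fraction of reads),
barcode cross-contamination, de-novo mutation during the competition, and
drift. Passing recovery tests therefore demonstrates correctness of the
computation, not robustness to those artifacts.

A consequence of this mixture worth stating explicitly: 5% of strains
uniform up to s = 0.4 is a much heavier beneficial tail than a typical
screen's, and over 20 generations those strains grow to dominate the pool
(Σ f₀(1+s)²⁰ ≈ 8). Every other strain's counts are compressed ~8× on top of
its own trajectory. Two estimator-level effects follow (both visible in the
tests):

1. **Common population term.** Each OLS slope is log2(1+sᵢ) − g, where g is
   the slope of the log₂ pool-mean term — identical for every strain. It
   cancels exactly in pairwise differences and leaves Pearson correlations
   untouched, but under heavy takeover g ≈ 0.19, so classification against
   fixed ±0.10 cutoffs requires removing it. The pipeline's
   `center_on_control` flag subtracts the control-collection median per
   condition; it is off by default (matching the convention of reporting
   raw slopes when the control distribution is centered on zero) and on in
   analyses of heavy-tailed synthetic pools.
2. **Pseudocount floor.** The +10 pseudocount exists to keep log ratios
   finite when a strain drops out. Once counts reach zero the measured
   log-ratio saturates at log2(pc / (T + n·pc) / f₀) (≈ −5.6 at default
   scale), so the fitted slope of a strongly deleterious strain is bounded
   and — perversely — shallower the earlier the strain collapses. Strongly
   deleterious fitness is therefore systematically under-called at finite
   depth; no choice permitted by this estimator (fixed window, unweighted
   OLS, fixed pseudocount) recovers information the counts no longer
   contain. Raising depth 10× pushes the floor down and measurably reduces
   recovery RMSE (asserted in the suite).

## Fitness estimation choices

* Normalization divides by the sum of pseudocount-incremented counts so
  frequencies sum to 1; dividing by the raw total would rescale every
  frequency in a sample equally and cancel in the regression slope.
* The generation-0 reference point (log-ratio 0 by construction) is *not*
  part of the regression; only points with 6 ≤ t ≤ 20 (closed interval)
  enter, where 6 is the generation by which continuous cultures reach
  steady state. `include_t0=True` is available.
* Fitness is reported as the raw log₂-per-generation slope. No
  linearization (2^slope − 1) is applied; for |s| ≲ 0.1 the two scales
  differ by under 5%.
* The <20-count filter is applied per screen (condition × replicate,
  summing a strain's counts over that screen's timepoints, strict `<`);
  a strain failing in one replicate keeps its other replicate's value with
  `n_replicates = 1`. `scope="all"` pools all samples instead.
* Replicates are fitted independently and combined by arithmetic mean.

## Classification and contingency tests

Class boundaries are strict: beneficial requires fitness > +cutoff,
deleterious < −cutoff; boundary values are neutral. Summaries are produced
at cutoffs 0.10 and 0.05 (the latter a sensitivity check), counting both
strain × condition events and per-strain deduplicated calls (each strain
represented by its most extreme value across conditions), plus
cross-condition overlap of beneficial sets. Enrichment of test vs control
classifications uses a 2×2 chi-square without continuity correction
(`correction=True` available).

Mutation-spectrum tests on an evolve-and-resequence catalog: per-class 2×2
tables (class vs rest × haploid vs diploid) default to the Yates-corrected
chi-square — which reproduces the published p ≈ 0.003 for stop-codon gains
from the printed event counts — with Fisher's exact test by flag. The
overall class × ploidy heterogeneity test is a Monte-Carlo Fisher exact
test: tables with the observed margins are sampled (`scipy.stats.random_table`)
and p = (#{prob ≤ prob_obs} + 1)/(n_mc + 1), the standard simulated Fisher
p-value; exact enumeration of a 10×2 table is not attempted. Rank
comparisons (gene length of recurrent vs singleton genes, clone vs
population driver ratios, found vs not-found fitness) use the two-sided
Wilcoxon rank-sum (`mannwhitneyu`, exact for small untied samples — checked
against full enumeration in the tests).

Driver prediction joins each catalog mutation to the screen by gene within
the same condition, taking the maximum replicate-averaged fitness over
collections (`agg="mean"` gives the across-collection mean instead):
`predicted_beneficial` at ≥ 0.10 (the driver rule is inclusive, per the
"at least 10%" convention, unlike the strict DFE class boundary),
`intermediate` in [0.05, 0.10), `not_predicted` below, `absent_from_screen`
when unmeasured. A strict mode additionally requires mechanism concordance
(high/moderate-impact mutations may only match deletion collections,
modifiers only amplification collections); it is off by default because
gene-level matching is the conventional reading.

## Selection dynamics

Single-locus haploid logistic dynamics: odds(t) = odds(0)·(1+s)^t,
equivalent to iterating p′ = p(1+s)/(1+ps). `time_to_frequency` returns the
smallest integer t with p_t ≥ threshold via the closed-form odds solution,
guarded to the exact integer boundary, and can verify itself against the
stepped recursion. Defaults: N = 10⁹, p₀ = 1/N (one founding cell);
"fixation" is operationalized as p ≥ 1 − 1/N since the deterministic model
never literally reaches 1. For s = 0.10 these give 187 generations to 5%
and 435 to fixation, consistent with (and slightly under) the ~200/~500
figures usually quoted; establishment stochastics and clonal interference,
which would lengthen real waiting times, are out of scope.

## Numerical notes

* Propagation works in log-space (`log f₀ + t·log1p(s)`, max-subtracted)
  so large t and extreme s do not overflow; zero input frequencies stay
  exactly zero.
* Slopes are computed with a single vectorized least-squares solve over all
  strains (`numpy.linalg.lstsq` on a shared [1, t] design).
* TSV outputs carry `#` header lines (tool version, seed, parameters);
  catalogs are written at 17 significant digits and read back with
  round-trip float parsing, so validated catalogs survive I/O losslessly.
  Re-running a pipeline configuration reproduces outputs byte-for-byte.
* Problem sizes in the test suite (pools of 50–2,000 strains, 2,000–20,000
  Monte-Carlo tables) were chosen as the smallest scales at which the
  asserted statistical properties are stable across seeds.

## Known limitations

* Strongly deleterious fitness saturates at the pseudocount floor (above);
  the package reports what the assay can measure, not the underlying s.
* Exact-match counting is correct for the simulator's error-free reads but
  conservative on real data.
* No standard errors are attached to fitness slopes; replicate spread is
  the only dispersion information carried forward.
* The heterogeneity test's Monte-Carlo p has resolution 1/(n_mc + 1).
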