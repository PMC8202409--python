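# Methods

This note records the statistical model behind each analysis stage, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that make results
reproducible.

## Input model

The unit of analysis is a genus × sample matrix of non-negative integer
read counts, with a taxonomy map (genus → phylum → domain) and a sample
metadata table (cohort/"dataset", sex, age, sampling site, tissue
source). Counts are assumed to already be aggregated at the genus level;
the package takes no position on how reads were classified. Relative
abundances are counts divided by the sample's total genus-level reads;
samples with zero total are flagged and excluded from all
abundance-based analyses but retained in QC reporting. The QC rule
removes samples with total reads strictly below `min_reads`
(default 100), the conventional floor below which compositional
estimates from classifier output are noise-dominated.

## Diversity and heterogeneity

Shannon diversity uses the natural logarithm (configurable base), the
default of the community-ecology packages this workflow descends from.
Beta diversity is Bray–Curtis on relative abundances — the standard
semimetric for compositional community data; phylogeny-aware metrics are
out of scope.

The *divergence* of a sample is its Bray–Curtis dissimilarity to the
per-taxon **median** profile of its group. The median reference is not
renormalized to sum to one: the Bray–Curtis formula tolerates an
unnormalized reference, and skipping the renormalization keeps the
definition exactly reproducible. Group mean divergence measures
community heterogeneity (dispersion), deliberately separate from the
location test: two groups can share a centroid while one is far more
variable, and that is precisely the pattern the sex/age analyses look
for.

Group comparisons of scalar quantities (Shannon, divergence) use the
unpaired Mann–Whitney rank-sum test. The groups being compared (male vs
female, old vs young, stroma vs epithelium) are independent samples, so
a paired signed-rank test is not applicable; this package standardizes
on the unpaired test. The exact null distribution is used when both
groups have ≤ 12 observations and the pooled values are tie-free;
otherwise the normal approximation with midrank tie correction and
continuity correction applies. At the 12+12 boundary the two branches
agree to well under 0.02 in p.

## PERMANOVA

One-factor PERMANOVA is implemented from first principles on the
squared-dissimilarity decomposition

    SS_T = (1/N) Σ_{i<j} d_ij²
    SS_W = Σ_g (1/n_g) Σ_{i<j ∈ g} d_ij²
    pseudo-F = ((SS_T − SS_W)/(a−1)) / (SS_W/(N−a))

with significance from permuting group labels over a seeded generator:
`p = (1 + #{F_perm ≥ F_obs}) / (1 + n_permutations)`, so `p` is never 0
and its floor is `1/(n_permutations+1)` — with the default 999
permutations the smallest reportable p is 0.001. When the number of
distinct label assignments `N!/Πn_g!` does not exceed the requested
permutation count, all assignments are enumerated instead and the exact
tail fraction is reported. Permuted pseudo-F values are computed in
batches via indicator-matrix products (`x_gᵀ D² x_g` per group), so a
999-permutation test on ~550 samples runs in seconds. Comparisons use a
1e-12 slack so that permutations tied with the observed statistic count
as at least as extreme. Every group must have ≥ 2 members; pairwise
PERMANOVA reports degenerate pairs as not-testable rather than failing
the whole scan. The age analysis re-runs the binary old/young test over
a threshold grid (default 45–70 in steps of 5), reporting degenerate
splits as not-testable.

Multi-factor and stratified designs are out of scope; the analyses this
package serves are single-factor tests within cohorts.

*Separating coefficients* for a binary contrast are signed differences
of group mean relative abundances per taxon (the regression coefficient
of a binary design up to coding), ranked by magnitude. Fold changes are
ratios of group mean relative abundances; a zero denominator triggers a
pseudo-abundance of half the smallest nonzero relative abundance in the
table, recorded in the output.

## Core microbiota, overlap, pan-microbiome

A genus is *detected* in a sample when its relative abundance strictly
exceeds the detection threshold (default 0.002, i.e. 0.2%); its
*prevalence* is the fraction of samples where it is detected; it is
*core* when prevalence ≥ the prevalence threshold (default 0.20). Both
inequalities are configurable. Core sets are computed per cohort and on
the pooled collection; the "shared core" is the intersection of the
per-cohort core sets.

Cohort overlap is reported as the full partition of the genus union into
2^k − 1 membership regions plus the k-way intersection and per-set
shared fractions.

The accumulation (collector's) curve adds samples in uniformly random
order and counts cumulative genera with count > 0 (presence for
accumulation is any read, not the core detection threshold —
configurable). Each replicate is computed by placing every genus at its
first occurrence under the permutation (O(G·N) per replicate), and the
default 1,000 replicates make the mean curve stable to within ±2%
across seeds. The mean curve is fitted with Heaps' law
`P(n) = κ·n^γ` by least squares on `ln P = ln κ + γ ln n` over
`n = 1..N`, with R² reported on the log–log scale (a raw-scale
nonlinear fit was considered and rejected as the default because the
log fit is the convention of pan-genome openness analysis and has a
closed form). The pan-microbiome estimate `P(n_extra) = κ̂·n_extra^γ̂`
always requires an explicit extrapolation point — a bare "pan size" is
meaningless for an open community — and the open/closed call is
`γ̂ > 0.02`, the same margin used to declare saturation in the tests.
Note the log–log R² of a real accumulation curve is well below 1
(the curve is not an exact power law at small n); this is expected and
mirrors what such fits look like on real cohorts.

## Synthetic study generator

The generator emulates the statistical structure of a four-cohort
tumor-tissue RNA-Seq microbiome study so that every analysis stage has
a realistic, fully-known input:

* **Open genus pool.** `G = 2,500` genera with Zipf-like rank-abundance
  weights `w_g ∝ g^-0.7`.
* **Cohort structure.** Per cohort `d`, a base composition
  `θ_d ~ Dirichlet(A·w)` with `A = 500`; cohorts therefore share their
  abundant head but differ substantially in the tail, making the cohort
  the dominant axis of compositional variation.
* **Samples.** `p_s ~ Dirichlet((c/r_s)·θ_d·m_s)` with sample
  concentration `c = 200`, dispersion ratio `r_s` and effect vector
  `m_s` (below); counts are `Multinomial(R_s, p_s)` with log-normal
  read depth (`exp(N(ln 5·10⁴, 1))`).
* **Cohort archetypes** mirroring the study design: a site-resolved
  cohort of 214 (stroma/epithelium/bulk ≈ 128/71/15), a mixed-source
  cohort of 191 (163 human / 28 PDX), a 30-sample all-PDX cohort with
  sex labels (16/14), and a 147-sample cohort with sex (79/68) and age
  at diagnosis (normal around 65, clipped to 40–85 so the 45–70
  threshold scan produces both testable and degenerate splits).
* **Planted effects.** Site and source effects multiply ~10 designated
  mid-abundance taxa per direction by `e^1.5` and `e^2.5`; sex and age
  location effects are **zero** by default. The male and old groups
  instead get `dispersion_ratio = 1.2` (their Dirichlet concentration is
  divided by 1.2), which raises their divergence-to-median reliably
  while leaving the PERMANOVA location test near its nominal level —
  the heterogeneity-without-shift regime. At ratio 2 the dispersion
  itself drives PERMANOVA rejection, which is a different (and less
  interesting) regime.
* **QC tail.** 9 libraries are forced to zero reads and 33 to 1–99
  reads.
* **Taxonomy.** Domains drawn as bacteria/virus/archaea =
  0.86/0.12/0.02; phyla Zipf-assigned within domain; 5% of genera carry
  no phylum assignment ("None").

The concentration/exponent defaults were fixed once so that the default
study lands in the regime such cohorts actually occupy: several hundred
genera per usable sample, per-cohort richness of 1,000–1,350, a union
of ~2,200 genera that keeps growing (γ̂ ≈ 0.13, extrapolating past
2,500 genera at 2,000 samples), and Bray–Curtis separation between
cohorts exceeding within-cohort spread.

**What the generator does not emulate:** classifier misassignment and
contamination, library-preparation artifacts, correlated taxon dynamics
(the Dirichlet is the sole covariance model), phylogenetic structure,
and any association between read depth and composition. Passing tests
therefore demonstrate that the statistics behave correctly under a
clean compositional model, not that they are robust to classification
error on real sequencing data.

`generate_null_pair` draws two equal groups from one homogeneous
population with labels independent of composition; it backs the
calibration experiments.

## Experiment sizes used by the test suite

The statistical acceptance tests run at sizes chosen to make their
Monte-Carlo error small relative to the asserted margins: 50 random
12-sample instances for oracle equivalence; 1,000 null pairs (10+10
samples, 200-genus pool, 199 permutations) for calibration and
uniformity; 100 replicates for noisy Heaps recovery; 25 replicates of
the 214-sample site cohort for power; 100 replicates of a 60-sample
sex-labelled cohort (400-genus pool) for the dispersion contrast, whose
behavior does not depend on cohort size.

## Numerical conventions and edge cases

* All stochastic code paths take a seed; fixed seed ⇒ byte-identical
  output.
* Zero-total samples: flagged, excluded from relative-abundance
  analyses, never an error.
* Top-N collapse ranks by mean relative abundance over all samples,
  ties broken lexicographically; the "Other" row preserves column sums.
* Genera missing from the taxonomy file cannot be assigned a domain and
  are rejected at load time; an empty phylum field is the "None"
  sentinel, retained as its own category in phylum aggregation.
* Distance matrices are validated (symmetry, zero diagonal) before any
  permutation test.
* Degenerate PERMANOVA inputs (a group of one, a one-sided age split)
  are reported as not-testable rather than raised, except when *every*
  configuration in a scan is degenerate.

## Known limitations

* Bray–Curtis is a semimetric; in pathological configurations the
  among-group sum of squares can be slightly negative, in which case
  pseudo-F is reported as computed rather than clipped.
* The Heaps fit weights all curve points equally on the log scale, so
  the small-n region influences γ̂; fits should be read together with
  their log–log R².
* PERMANOVA, like its reference implementations, conflates location and
  dispersion when dispersion differences are large; the divergence
  statistic exists to separate the two, and the generator's default
  dispersion ratio was chosen where the separation is clean.
* The rank-sum exact branch refuses ties; heavily tied data always use
  the corrected normal approximation.
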