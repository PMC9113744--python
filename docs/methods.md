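# Methods

This note documents the models, numerical choices and known limitations of
`thermatlas`. It is the package's own account of its science; every number it
mentions is computed by the test suite or by `scripts/acceptance.py`.

## Study design addressed

The pipeline targets multi-tissue bulk RNA-seq designs with strictly
two-group contrasts per tissue: a control housing temperature (22 °C) against
one or two treatment temperatures (cold 10 °C, mild warm 34 °C), with 3–6
replicate samples per tissue × temperature group, each sample typically a
pool of two animals. The input is a raw gene × sample count table (genes as
rows, integer counts); everything upstream of counting — trimming, alignment,
read counting — is out of scope, as are covariates and batch terms (the
design has none to exploit).

## Differential expression

**Normalization.** Library-size only: counts per million (CPM). No TMM or
median-ratio normalization is applied on the default path, matching the
library-size-only normalization of the workflow the package reproduces. The
consequence — composition bias when regulation is strongly unbalanced — is
discussed under *Simulator* and *Limitations*.

**Expression filter.** The default `logcpm_positive` rule keeps genes with
CPM > 1 (log-CPM > 0) in at least half the samples of *each* compared group.
"Half of each group" makes the rule symmetric in the groups and reproducible;
the alternative `min_raw_counts` rule (≥ 5 raw counts in ≥ 1 sample) is the
expression-breadth criterion and is also available as a DE filter. Both
quantifiers are configurable and recorded in the run manifest. Filtered
genes are reported as `untested`, which is distinct from "not DE": breadth
bookkeeping treats them as unobserved in that tissue.

**Dispersion.** A single common negative-binomial dispersion φ per contrast
(variance = μ + φμ²), estimated by maximizing the conditional log-likelihood
on library-equalized pseudo-counts (qCML): conditioning each group's counts
on their total removes the mean parameter and leaves φ identifiable. The
optimizer is bounded Brent on log₁₀φ ∈ [−8, 1] (xatol 1e-4); if it fails, a
pooled method-of-moments estimate is used and a warning lands in the run
manifest. Per-gene dispersions are deliberately not fitted: with n = 3–6 per
group they are poorly identified, and the common-φ exact test is the
reference behaviour being reproduced. Simulation checks: Poisson data give
φ̂ < 0.01; data at φ = 0.2 give φ̂ ∈ [0.15, 0.25] (2000 genes × 10 samples).

**Exact test.** Counts are equalized by rescaling each sample to the
geometric-mean library size (plain rescaling, not quantile adjustment — the
difference is immaterial for the oracle-checked behaviour and plain scaling
is transparent). Group sums of pseudo-counts are rounded and conditioned on
their total t. With groups of n_A and n_B samples, the group sums are
NB(n_A/φ) and NB(n_B/φ) with a common success probability, so the
conditional law of the split is negative-hypergeometric; the two-sided
p-value sums P(s|t) over all splits with P(s|t) ≤ P(s_obs|t). At φ = 0 the
conditional law is Binomial(t, n_A/(n_A+n_B)) and the implementation agrees
with exact-rational enumeration to < 1e-12 relative error for every split of
every total ≤ 200 (the tie comparison uses a 1e-10 relative band so that
mathematically equal probabilities compared in floating point still count as
ties). t = 0 gives p = 1. Fold changes are log2 of the ratio of per-group
mean pseudo-counts with a prior count of 0.5 per group, which keeps zero
groups finite; the treatment group is the numerator. Antisymmetry (group
swap negates log2FC, preserves p) is a tested invariant.

**Calling.** Default thresholds |FC| > 1.5 and raw p ≤ 0.05 with no
multiple-testing correction, mirroring the reproduced workflow;
`adjust="bh"` switches the comparison to Benjamini–Hochberg adjusted p and
is recommended for new analyses. A t-test on log2(CPM+1) is provided as a
secondary method and is never the default. On simulated null data (2000
genes, 2 × 5 samples, φ = 0.1) the exact test's rejection rate at p < 0.05
sits inside the 99% binomial band around 0.05.

## Specificity and breadth

DE breadth counts the tissues in which a gene is called up or down,
irrespective of direction consistency; breadth 1 defines a tissue-specific
profile, and a gene up in one tissue and down in another is *not*
tissue-specific (breadth 2, flagged inverse). Per-tissue tissue-specific
tallies use that tissue's own up (or down) call totals as percentage
denominators, displayed rounded to whole percent; a tissue with zero calls
reports NaN, not 0. Because tissue-specific sets are pairwise disjoint,
collective totals are plain sums — the aggregation used for the worked
reconciliation examples. Expression breadth applies the ≥ 5-raw-counts rule
per tissue. Continuous specificity indices (τ, Gini) are deliberately not
provided; the definitions here are set-based.

## Concordance

Common genes between two contrasts are genes called significant in **both**
(a relaxed mode accepts called-in-one/tested-in-the-other but is not the
default); classification is by log2FC sign disagreement. Cross-study
recurrence takes each study's own reported significance (p < 0.05 flags
precomputed at load), since recomputation from foreign raw data is out of
scope; unreported gene × study cells never count. Gene families are formed
purely from nomenclature: the maximal leading alphabetic prefix before the
first digit (unnumbered symbols key on their full name, so "Ucp" joins the
family of "Ucp1"); singleton groups are dropped.

## Enrichment

Classic one-sided Fisher/hypergeometric over-representation on a flat
term → genes collection (GMT). No ontology DAG, no propagation, no
elim/weight decorrelation — this is the package's single largest deliberate
simplification relative to topGO-style tooling, chosen because the
decorrelation algorithm is not part of the reproduced behaviour and a flat
collection keeps the statistic exactly checkable against enumeration
(verified exhaustively for every 2×2 with universe ≤ 50). Tests are split by
direction (separate up and down gene lists) because up- and down-regulated
term counts are reported separately. The universe is the set of genes tested
in that tissue's contrast, not the global union, so low-complexity tissues do
not inflate enrichment. Terms with p < 0.01 are retained. Cross-condition
term classes are assigned with precedence cross_condition_opposite >
cross_condition_same > shared_mixed > shared_same_direction >
tissue_specific, which makes the (otherwise overlapping) prose classes
exhaustive and mutually exclusive. Venn decomposition assigns each driver
gene to the exact subset of tissues whose driver lists contain it —
a disjoint cover by construction.

## QC

PCA operates on gene-centered log2(CPM+1) over a configurable gene universe
(default for the combined view: genes expressed in every tissue); components
are sign-fixed by making each component's largest-magnitude loading positive,
so results are fully deterministic. Clustering uses distance 1 − Pearson on
log2(CPM+1) with average linkage by default (complete/single configurable);
the pseudo-count and linkage are recorded in the manifest because neither is
dictated by the reproduced workflow. A constant expression profile has
undefined correlation and is rejected naming the sample (detected at
standard deviation < 1e-10 to absorb floating-point jitter).

## Simulator

`simulate_experiment` draws counts per **animal** from
NB(mean = library size × relative expression × 2^log2FC, dispersion φ) and
sums `pool_size` animals per sample; pooling two animals halves the
effective sample-level dispersion, which is why estimated dispersions of
≈ 0.05 on pooled data simulated at φ = 0.1 are correct, not a bias. Baseline
expression is a shared per-gene log2-mean drawn uniformly from
`baseline_logmean_range` plus a per-tissue normal offset
(`tissue_offset_sd`), so most genes are expressed everywhere; a configurable
fraction is strictly tissue-exclusive (baseline 0 elsewhere). Defaults
(range (3,7), offset 0.8, library 6×10⁵ for 2000 genes ≈ mean CPM 500)
emulate the post-filter analysis universe of a deeply sequenced study —
genes a CPM filter would keep — rather than a full genome with its silent
tail. Library sizes are log-normal with CV 0.2. Planted log2FCs apply at
treatment temperatures relative to the 22 °C control; the `inverse` role
carries opposite-sign effects at the two treatment temperatures.

**Mass balance.** Up- and down-regulation are asymmetric in read mass
(a doubling gene adds 3× its baseline reads at |log2FC| = 2; a halving gene
removes only 0.75×), so naively planted signals shift treatment library
totals and library-size-only normalization then biases *every null gene's*
fold change — measured as a null p ≤ 0.05 rate of 0.11–0.16 instead of 0.05.
Because the generator's job is to provide exact ground truth (null means
log2FC = 0, estimable as 0), planted baselines are rescaled per tissue so
the expected library size is identical at every temperature
(`mass_balance=True`, default). This mirrors the roughly balanced up/down
regulation real tissues show and restores exact null calibration. Disabling
it reproduces the composition-bias regime, which is itself informative.

**Random numbers.** One root seed; per-tissue child `SeedSequence` streams
with fixed keys, so adding tissues never perturbs existing tissues' draws
(gene draws within a tissue are order-fixed; the tissue-exclusive layout is
necessarily a function of the tissue count). Fixed seed ⇒ bit-identical
output; the committed toy fixture is regenerated byte-identically by
`make_toy_fixture()`.

**What the simulator does not model** — and hence what passing tests do not
show about real data: per-gene dispersion heterogeneity, GC/length bias,
batch effects beyond library-size variation, correlated genes, isoforms, and
read-level artifacts. Recovery results (sensitivity/precision ≥ 0.9 for
tissue-specific classification and inverse-gene detection at |log2FC| = 2,
φ = 0.1, n = 6) are statements about this generative model at those effect
sizes, not about weaker or confounded real signals.

## Problem sizes

The test suite and acceptance script use desk-scale problems chosen to keep
the statistical claims meaningful: 2000-gene simulations for calibration and
recovery (3 tissues × 3 temperatures × 6 pooled samples), exhaustive oracle
sweeps to universe 50 (hypergeometric) and conditioned totals ≤ 200
(conditional binomial), and a 180-gene committed toy fixture for examples
and pipeline tests.

## Known limitations

* Library-size-only normalization is biased under strongly unbalanced
  regulation; TMM is deliberately absent from the default path. Users with
  asymmetric designs should expect inflated null fold changes, as the
  simulator demonstrates when `mass_balance=False`.
* Raw-p calling at p ≤ 0.05 does not control FDR across ~10⁴ genes;
  `adjust="bh"` exists for that reason.
* The exact test conditions on *rounded* equalized totals; with wildly
  unequal library sizes the rounding is a further approximation.
* The flat-GMT enrichment inherits GO's redundancy: parent/child terms are
  tested independently and will co-occur in the retained lists.
* Table-2-style 34 °C columns in the reproduced study are internally
  inconsistent (printed totals 3132/2376 vs column sums 3138/2393, the brain
  row); only the 10 °C columns, which reconcile exactly, are used as
  aggregation anchors.
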