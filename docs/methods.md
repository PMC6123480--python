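# Methods

This note records the statistical model behind `gepmi`, the default
parameters and why they were chosen, the numerical decisions that affect
results, and the known limitations.

## 1. Model and assumptions

**Similarity statistic.** Each sample is reduced to its set of canonical
k-mers (a k-mer and its reverse complement are the same object; the
lexicographically smaller encoding is kept). Sample relatedness is
measured by the Jaccard similarity of these sets, estimated with
bottom-n MinHash: every canonical k-mer is hashed to 64 bits, a sketch
keeps the n smallest hashes, and for two sketches the estimator is

```
U  = the min(n, |union|) smallest hashes of S(A) ∪ S(B)
Ĵ  = |U ∩ S(A) ∩ S(B)| / |U|
```

This is exact when the true union has at most n elements and is an
unbiased, concentrated estimator otherwise (standard error about
√(J(1−J)/n)).

**Null hypothesis.** For a *target* sample t, collect its similarities
to every sample from a *different* individual. These inter-individual
similarities are treated as i.i.d. draws from a continuous distribution
on [0, 1], fitted parametrically — beta by default. For a *query* q, H₀
says Ĵ(q, t) is one more draw from that distribution, and the p-value is
the fitted survival function at the observed similarity:

```
p = Pr(X ≥ s | H₀) = 1 − F̂(s)
```

The test is **directed**: testing q against t uses t's null, and testing
t against q uses q's null, so the two ordered pairs can disagree. Same-
individual pairs appear as (ideally reciprocal) edges in a directed
identification network.

**Multiple testing.** P-values are adjusted with the
Benjamini–Yekutieli (BY) step-up procedure, which controls the FDR under
arbitrary dependence — appropriate here because tests sharing a query or
a target are strongly dependent. Adjustment is **per query** by default
(each query's m = N − 1 tests form one family); a global option adjusts
across the whole table.

**Key assumptions.**
- Inter-individual similarities for a fixed target are exchangeable and
  well approximated by a unimodal parametric family on [0, 1].
- Individuals in the cohort used to fit the null are genuinely
  unrelated; undeclared same-individual samples inflate the null's tail
  and cost power.
- Sketches being compared share k, hash seed, and sketch size (enforced;
  violating pairs raise `SketchCompatibilityError`).

## 2. Parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| k (k-mer length) | 18 | bases | Long enough that shared 18-mers imply shared strain-level sequence rather than chance (4¹⁸ ≈ 7·10¹⁰ ≫ any metagenome); short enough to tolerate sequencing error. Must be ≤ 31 for 2-bit packing in a 64-bit word. |
| n (sketch size) | 10 000 | hashes | Jaccard standard error ≈ √(J(1−J)/n) ≤ 0.005 at J = 0.5; sketches stay a few hundred kB. Desk-scale examples use n = 1 000. |
| S (base budget) | 10⁹ | bases | Down-sampling all samples to a common budget removes depth as a confounder before sketching. 0 disables. |
| C (abundance cutoff) | 2 | counts | A k-mer must be seen ≥ C times to enter the sketch; singletons are dominated by sequencing errors. |
| hash seed | 42 | — | Any fixed value works; it only has to be shared across sketches. |
| null family | beta | — | Natural support on [0, 1]; empirically the best KS fit for inter-individual Jaccard similarities. `auto` selects by KS among beta, gamma, normal, and [0,1]-truncated normal. |
| min_fit | 30 | samples | Below ~30 inter-individual similarities the MLE fits are unstable; targets with fewer are skipped with a warning. |
| p_cut, q_cut | 0.001 | — | Strict defaults: on labelled cohorts q < 0.001 yields zero observed false edges while still recovering most intra-individual pairs. Thresholds are strict `<`; 0 disables a criterion, and a p/q cutoff ≥ 1 passes everything (q-values are capped at 1). |
| sim_cut | 0 | Jaccard | Optional raw-similarity floor (strict `>`); disabled by default so decisions are purely statistical. |

## 3. Synthetic cohort generator

`gepmi.synthgen` is a first-class component used for calibration and
testing. What it emulates:

- **Individual-specific strain content**: per species, an ancestral
  genome plus private SNPs for each individual at rate `snp_rate` on the
  non-core fraction (1 − `core_fraction`) of sites. Private SNPs are the
  mechanism that makes two visits of one person more similar than two
  people.
- **Temporal abundance drift**: per-visit species abundances are a blend
  `(1 − drift)·previous + drift·fresh-Dirichlet`, so visits of one
  individual have correlated but not identical compositions.
- **Sequencing**: fixed-length reads with per-base substitution error
  and random strand.
- **Perturbations**: `antibiotic_like` (drop a species fraction from a
  visit onward) and `replace` (swap in foreign genomes) model treatment
  and colonisation events.

Defaults (12 individuals × 3 visits, 5 species × 100 kb, core fraction
0.7, snp rate 0.005, 2 Mb of 150 b reads per sample, 0.5 % error) are
sized so a full cohort run finishes in well under a minute on one CPU
while leaving a realistic, imperfect intra/inter separation.

What it does **not** emulate: real taxonomic breadth (hundreds of
species), genome rearrangements or gene gain/loss, shared strain
transfer between cohabiting individuals, uneven coverage, read quality
profiles, or host contamination. Conclusions about absolute power on
real data cannot be read off the simulator; it is for verifying the
machinery and its calibration.

**Null cohorts.** For FDR experiments the generator ships a dedicated
configuration (`null_cohort_config`): 16 individuals × 2 visits, 3
species × 50 kb, core fraction 1.0 and snp rate 0 (so *no* individual
signal exists), 300 kb per sample. These sizes were fixed before any FDR
experiment was run: 32 samples give each target 30 inter-individual
similarities (the minimum fit size), and 20 replicates give a binomial
standard error on the mean false-discovery proportion small enough to
detect gross miscalibration.

## 4. Numerical choices

- **Hashing.** Canonical k-mers are 2-bit packed (A=0, C=1, G=2, T=3,
  most significant base first, so packing preserves lexicographic order)
  and hashed with the 64-bit finalizer of MurmurHash3, vectorised in
  numpy. The *packed integer* is hashed, not the string — identical
  k-mer, identical hash, no allocation per k-mer. The seed is mixed in
  via one splitmix64 scramble.
- **Abundance trim is set-level.** `trim_low_abundance` filters the
  counted k-mer table before sketching; the sketch itself stores no
  abundances.
- **Beta/gamma fits** use maximum likelihood with method-of-moments
  initialisation, location 0 and scale 1 fixed. Data are clipped to
  [1e−6, 1 − 1e−6] first: exact 0/1 values have −∞ log-likelihood under
  a beta with α, β > 1 and would poison the fit. The [0,1]-truncated
  normal is fitted by Nelder–Mead on (μ, log σ).
- **KS family selection** takes the smallest KS statistic; ties break in
  the fixed order beta > gamma > truncated normal > normal (most
  domain-appropriate first).
- **BY correction** is implemented directly (stable argsort, harmonic
  factor c(m) = Σ 1/j, reverse cumulative minimum, cap at 1) and is
  cross-checked in the tests against both a brute-force implementation
  and `statsmodels`' `multipletests(method="fdr_by")` to agreement
  within 1e−12.
- **Serialisation round-trips are bit-identical**: sketches as
  sorted-key JSON, similarity matrices as CSV with `repr()`-formatted
  floats, so a save/load cycle never changes a downstream number.

## 5. Design decisions and observed behaviour

- **Per-query BY scope.** Adjusting within each query matches the
  operational question ("which samples match *this* one?") and keeps the
  harmonic penalty c(m) small. A `correct_global` flag exists for a
  single table-wide family.
- **q-value granularity at desk scale.** With per-query families of
  m = 35 tests, BY maps most clearly-null p-values to q = 1 (typically
  ~90 % of the table), and occasionally an intra-individual pair lands
  there too. Ranking by q is therefore coarser than ranking by p: on the
  default signal cohort the p-value auROC is stably ≈ 0.995 across
  seeds, while the q-value auROC varies ≈ 0.93–0.98 and the q-based PRC
  can fall below the raw-similarity PRC on unlucky seeds. This is a
  property of the correction's discreteness at small m, not of the test;
  it shrinks as cohorts grow. The acceptance script reports both p- and
  q-based areas for this reason.
- **Beta(5, 20) as the family-selection condition.** For beta
  distributions with small mean, Beta(α, β) converges to Gamma(α, 1/β)
  and no finite sample can tell them apart — KS selection is at chance
  there, which is harmless because the two fits give near-identical
  tail probabilities. The selection behaviour is therefore verified in a
  regime where the families genuinely differ (Beta(5, 20), mean 0.2,
  visible right boundary), where KS picks beta essentially always.
- **Merged-bottom-n exactness.** The estimator is exact precisely when
  |A ∪ B| ≤ n (then U is the full union). The tests verify exactness in
  that regime and concentration (4σ coverage) outside it.

## 6. Known limitations

- The beta null is an approximation; with very tight inter-individual
  similarity clusters the fitted tail can be optimistic. Calibration is
  verified on synthetic nulls (PIT uniformity, empirical FDR ≈ 0 at
  q < 0.05), not on real cohorts.
- Targets need ≥ `min_fit` inter-individual samples; tiny cohorts cannot
  be tested, only thresholded on raw similarity
  (`similarity_threshold_network`).
- Monozygotic-twin-like microbiome similarity, cohabitation, or
  mother–infant strain sharing would appear as (true-positive, but
  identity-violating) edges; the framework detects shared strain
  content, and "same individual" is the dominant, not the only, cause.
- k ≤ 31 (2-bit packing in 64 bits); reads shorter than k contribute
  nothing.
- Down-sampling assumes depth is the only budget confounder; it does not
  correct for differing error rates or insert-size distributions.
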