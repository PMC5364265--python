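# Methods

## Model and procedure

The statistic operates on one direction (up or down) of one experimental
condition.  Inputs are a ranked gene list (genes ordered by decreasing
|log2FC|), a gene-set collection, and a universe of U measured genes.  For
a category with K members in the universe and h(n) members among the top n
ranks, the prefix enrichment probability is the upper hypergeometric tail

f_n = P(X ≥ h(n)), X ~ Hypergeometric(U, K, n),

identical to the one-sided Fisher exact test on the 2×2 table
[[h, n−h], [K−h, U−K−n+h]].  Categories are always tested against the
universe, not against the ranked list: members absent from the list still
count in the table margins, so "a random gene" means a random measured
gene.  The test statistic is t = min_n f_n with n* the smallest prefix
size attaining it; ties in t resolve to the smallest n (the conservative
"fewest genes needed for peak enrichment").

**Null model and e-values.**  The ranking is informative only through the
positions of the category members, so the null hypothesis is
exchangeability of the order of the same N genes with membership fixed.
B shuffles (default B = 1000) each yield a null statistic t0, and the
e-value is the add-one estimator e = (1 + #{t0 ≤ t})/(B + 1).  Add-one is
the standard Monte-Carlo permutation estimator: it can never report 0, its
floor is 1/(B+1), and it is (discretely) uniform under the null.  e-values
are BH-adjusted to q-values across all categories of one direction of one
condition; a pooled-across-directions family is available behind a flag
(`--bh-family pooled`).  An alternative null that re-draws the N list
genes from the universe per iteration (`--null-model resample-genome`) is
provided for sensitivity analysis; order-shuffling is the default because
it conditions on the observed list content and is the exchangeability the
statistic actually tests.

## Numerical and algorithmic choices

* **Hit-position scan.**  For fixed hit count a, P(X ≥ a | n) is strictly
  increasing in n until it saturates at 1, so the minimum over all n ∈ 1..N
  occurs at a rank where a member enters the prefix.  The scan evaluates f
  only at those positions plus n = 1 and n = N (n = 1 so a fully saturated
  profile reports n* = 1; n = N so the full-set probability is always
  recorded).  This is exact — asserted bit-for-bit against a naive
  all-prefix scan in the tests — and reduces each profile to O(K) tail
  evaluations.  `full_scan=True` forces the O(N) grid for profile export.
* **Null sampling.**  A shuffle is realized by drawing a uniform random
  k-subset of the N ranks for the k in-list members rather than permuting
  the gene array; the induced distribution of the statistic is identical
  (verified distributionally against literal gene permutation in the
  tests) and allows all B draws to be vectorized against one precomputed
  table of tail probabilities P(X ≥ j | n), j ≤ k, n ≤ N.
* **Extreme tails.**  scipy's hypergeometric survival function sums the
  upper tail directly and keeps relative precision down to ~1e-300, so
  t values such as 5e-136 (a 50-member block at the top of the list) are
  represented exactly rather than flushed to 0.
* **Reproducibility.**  Each category's null uses a substream derived from
  (master seed, SHA-256 of direction and category name), so results are
  bit-identical regardless of category iteration order.  Fold-change ties
  in ranking are broken lexicographically by gene id.
* **Degenerate inputs.**  A category with no members in the universe
  yields a flagged profile with t = 1, n* = 1 (not an exception); an empty
  collection yields an empty result with a warning; zero-variance features
  with equal group means get p = 1, flagged.

## Differential expression front end

log2FC is the difference of log2 group means of linear-scale intensities
(ratio of group means; exact sign-flip under role swap), treated vs
time-matched controls.  Significance is a Welch two-sample t test on log2
intensities (pooled-variance Student behind `--equal-var`; Welch is the
safer default for triplicate groups), BH-corrected per condition.  These
q-values are **descriptive only**: no fold-change or significance filter
is ever applied to the ranked lists the enrichment consumes.  Probe-level
tables collapse to genes via the probe with maximal |log2FC| (ties: smaller
p, then probe id), keeping per-gene statistics interpretable as those of
one real probe.

## Synthetic data: what it emulates and what it does not

The generator produces (i) random category memberships over a synthetic
universe, (ii) null rankings — N genes sampled from the universe with
half-normal |log2FC| magnitudes, order uniform w.r.t. every category,
(iii) planted rankings — m members of a category forced into uniformly
random positions within the top `window` ranks, covering both the
few-strong-drivers regime (small window) and the diffuse-weak-signal
regime (wide window), and (iv) triplicate treated/control expression
matrices with per-gene multiplicative effects 2^Δ and lognormal replicate
noise.  Defaults (U = 10 000, N = 1 000 per direction, 25 categories of
20–200 genes, σ = 0.25, triplicates with 0.25 log2 replicate sd, 10 % of
genes affected at |Δ| = 1) describe a realistic single-condition
transcriptomics experiment at desk scale.

Only the order of the ranking matters to the statistic, so the magnitude
law is a free choice; the half-normal gives a realistic dense pile of
near-zero fold changes.  The generator does not emulate probe-level
artifacts, normalization effects, correlated co-expression between
categories, or dose–response kinetics — passing tests therefore
demonstrate the statistical behaviour of the method under its own
assumptions (exchangeable null, independent planted placement), not
robustness to those real-data features.

## Calibration and power checks

`idea.calibration` packages the two simulation studies the test suite and
`scripts/acceptance.py` run:

* **Null calibration** — one fixed list of N = 500 genes over U = 10 000
  with one K = 50 category (the list draw is redrawn until it contains at
  least one member; a member-free list has the degenerate statistic t ≡ 1
  and carries no information), then 2 000 independent reshuffles, each
  calibrated with B = 200.  Uniformity of the resulting e-values is
  summarized by the KS distance to Uniform(0,1) and the rejection rate at
  e ≤ 0.05.  Content is held fixed because the null being tested is
  exchangeability of order given the list.
* **Planted recovery** — 100 independent replicates with m = 50 members in
  the top 100 of N = 1 000 (U = 10 000, B = 500), reporting the detection
  rate at e ≤ 0.05 and the median n*; n* should land near the planted
  window.
* **Extreme placement** — all m members at ranks 1..m, where the statistic
  has the closed form f_m = C(K,m)·…/C(U,m), n* = m and e hits the
  1/(B+1) floor.

Problem sizes for the end-to-end determinism check (U = 2 000, N = 400,
B = 200, 10 categories) were chosen as the smallest configuration that
exercises every pipeline stage; determinism does not depend on size.

## Known limitations

* e-value resolution is 1/(B+1); ranking categories below that floor
  requires raising B.
* The BH family is per direction × condition; meta-analysis across
  conditions is out of scope.
* No moderated-variance (empirical Bayes) testing and no within-namespace
  identifier mapping (probe→gene collapse only); symbol aliasing between
  gene-set databases must be resolved upstream — same-named categories are
  unioned, differently named aliases are kept separate.
* The weighted-KS style of enrichment (score-weighted running sum) is not
  implemented; RNK export provides interoperability with tools that do.
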