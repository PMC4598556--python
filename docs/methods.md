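# Methods

## The analysis problem

The unit of analysis is a clade — an insect order, family or subfamily —
summarized by four quantities: described species richness *n*, stem age *t*
in Myr (the time back to the clade's split from its sister lineage),
the proportion of herbivorous species *h* ∈ [0, 1], and binary traits
(wings, holometaboly). The question is whether *h* (or the binary traits)
predicts the clade's net diversification rate, accounting for the shared
ancestry of clades.

Stem ages, not crown ages, are used throughout: sparse sampling within
clades makes crown ages unreliable (a missed basal split shrinks the crown
age and inflates the rate), and the stem age covers the clade's entire
history. A crown-age estimator is deliberately not provided.

## Net diversification rates

The method-of-moments estimator for stem ages is

  r̂ = ln(n(1 − ε) + ε) / t,

with ε = μ/λ the assumed relative extinction fraction. ε cannot be
estimated from (n, t) pairs alone, so the analysis is repeated at
ε ∈ {0, 0.5, 0.9} (none, intermediate, high extinction), applied globally
per run. Natural logarithms throughout; r̂ = 0 exactly when n = 1. The
estimator assumes rates constant within clades over time; it is used to
explain *variation* in rates among clades, not their absolute values.

Records with missing richness, missing age, or unknown diet are excluded
row-wise with a logged reason rather than failing the run, since curated
clade tables routinely contain such gaps.

## Trait coding

* Order-level herbivory proportions aggregate family-level survey
  fractions by a richness-weighted mean, Σnᵢfᵢ/Σnᵢ.
* Clades described only by a list of feeding types are coded by assuming
  the listed types are equally frequent (herbivory share = count/len).
  Xylophagy is a distinct diet, not herbivory; herbivory means feeding on
  living vascular-plant tissue.
* Non-monophyletic subunits can be amalgamated into their family
  (`merge_clades`): richness sums, herbivory is richness-weighted, binary
  traits combine by OR, and the merged unit's stem age must be supplied
  from the tree (member stem ages refer to shallower splits).
* Proportions enter the regression untransformed (no arcsine), and binary
  predictors are 0/1 columns through the same machinery.

## PGLS with maximum-likelihood Pagel's λ

The model is y = Xβ + e with e ~ N(0, σ²C_λ), where C is the Brownian
variance–covariance matrix of the tips (entry (i, j) = root-to-MRCA shared
path length; diagonal = root-to-tip depth) and C_λ multiplies the
off-diagonal entries by λ ∈ [0, 1] (κ and δ fixed at 1). Trees must be
binary for covariance construction; polytomies are rejected unless
explicitly resolved with zero-length branches (which leaves C unchanged and
is logged). Before fitting among-clade models, species-level trees are
pruned to one exemplar per clade — the lexicographically first member tip,
a deterministic stand-in for an arbitrary choice, valid because all members
share the clade's stem path on an ultrametric tree.

Fitting whitens by the Cholesky factor of C_λ and runs least squares in the
whitened space. Conventions (software differs, so they are stated):

* σ̂² = RSS/n (ML) defines the log-likelihood and AIC.
* Coefficient SEs, t-tests and the model F-test use RSS/(n − k), so a fit
  at λ = 0 on an ultrametric tree reproduces OLS exactly (this is a tested
  invariant).
* r² = 1 − RSS/TSS in the λ̂-whitened space, TSS from the intercept-only
  GLS fit at the same λ̂. A constant response fitted exactly by the
  intercept reports r² = 0; a constant response that cannot be fit raises
  an error.
* Model P is the F-test of all non-intercept terms at λ̂, treating λ̂ as
  fixed — the common comparative-methods practice.
* AIC = 2k − 2logL with k = #coefficients + 1 (σ²) + 1 more when λ is
  estimated. Counting λ is the honest choice but not universal among
  comparative-methods packages, so AIC values are comparable within this
  package, not necessarily across software. r² and P are the quantities to
  compare externally.
* λ̂ maximizes the profile likelihood by bounded scalar search (tolerance
  1e−8) with both endpoints evaluated; exact ties break toward λ = 1,
  which only occurs on star phylogenies where the likelihood is flat.
* No multiple-testing correction is applied across the model battery; the
  battery replicates one hypothesis across ε values and trees rather than
  testing many hypotheses.

When richness replaces the rate as the response, natural-log richness is
used, because richness is log-linear in rate × age under the estimator.
This transform choice is the package's own and is printed in the report
header.

## Sister-clade comparisons

At each internal node (post-order, tips first) whose two child subtrees
have herbivory entirely absent in one and present in the other (presence =
proportion > threshold, default 0), and whose tips are not already inside a
reported pair, the two subtrees form a pair. Post-order traversal makes the
selection least-inclusive and non-overlapping by construction; both clades
of a pair share the parent node's age as their stem age (a tested
invariant). Richness ties are dropped from n and logged. Aggregation uses
the exact one-tailed binomial sign test P = Σᵢ₌ₖⁿ C(n, i)/2ⁿ — the
herbivorous clade should be richer more often than a fair coin predicts.
Published sign-test P values computed in legacy statistics software
sometimes follow other conventions (two-tailed, or normal-approximate);
this package standardizes on the exact one-tailed test, so small
discrepancies with older reported values are expected for some counts.

## Synthetic data generator

The generator produces the same trait table the pipeline consumes, from a
fully known model:

* **Tree**: Yule topology on n_clades tips (default 31, an ordinal-scale
  analysis), rescaled to depth 350 Myr. Because each tip stands for an
  ancient higher clade on a long stem branch, divergences are compressed
  into [min_stem_age, depth] with min_stem_age = 100 Myr by default; a
  plain Yule tree would scatter splits to the present, producing clades far
  younger than any ordinal dataset and outside the rate estimator's
  operating regime (rt ≥ 3). The simulation clock is also run one
  exponential waiting time past the final speciation so tips are distinct.
* **Herbivory**: hᵢ ~ Beta(0.5, 0.5) — U-shaped, matching the empirical
  bimodality of clades near 0% or 100% herbivorous.
* **Rates**: rᵢ = a + b·hᵢ + BM deviate, with a = 0.02 lineages/Myr
  (baseline), b = 0.05 (a 3.5-fold rate difference between fully
  non-herbivorous and fully herbivorous clades), Brownian σ² = 2.5e−7
  rate²/Myr (sd ≈ 0.009 at the root-to-tip scale, i.e. weak but real
  phylogenetic rate noise) at λ = 1. Rates are truncated at 0 with a
  count recorded in the ground-truth sidecar.
* **Richness**: a single stem lineage evolved for the clade's stem age
  under birth–death rates λ_b = r/(1 − ε), μ = εr/(1 − ε), conditioned on
  survival (only extant clades are observed), giving a geometric clade-size
  law with success probability (1 − ε)/(e^{rt} − ε); pure birth reduces to
  Geometric(e^{−rt}). ε_true = 0 by default.
* Binary traits are iid Bernoulli(1/2) with no rate effect, serving as
  negative controls.

One integer seed determines everything; outputs are byte-identical across
runs. What the generator does **not** emulate: diversification rate shifts
within clades, trait-dependent sampling, richness undercounting biases, and
correlated evolution between herbivory and the binary traits. Passing tests
therefore validate the estimators and their calibration under the stated
model, not the robustness of conclusions to these real-data complications.

## Calibration results and problem sizes

The test suite and `scripts/acceptance.py` compute (sizes are the package's
chosen experiment scales):

* estimator vs closed form on a 10⁴-point grid; monotonicity in n, t, ε;
* PGLS at λ = 0 vs OLS on 100 random 25-taxon datasets (agreement 1e−8);
* λ recovery: 100 replicates of fully Brownian data on a 200-tip tree;
* type-I error of the herbivory term: 1000 null replicates of the 31-clade
  pipeline; measured ≈ 0.05–0.065, mildly inflated relative to nominal
  because the rate-estimation noise is heteroskedastic (variance ∝ 1/t²),
  which the PGLS covariance does not model;
* slope recovery: 200 replicates of the direct regression experiment
  (y = a + bh + Brownian noise, 100 tips) — unbiased to Monte-Carlo
  precision, with 95% CI coverage ≈ 0.95;
* end-to-end slope recovery through richness simulation and rate
  estimation: attenuated by ~2–3% relative (E[ln N] is concave in rt, so
  the estimated rate is a slightly nonlinear function of the true rate at
  small rt). This small bias is inherent to the age–richness method, not
  to the implementation;
* sign test vs exhaustive 2ⁿ enumeration for all n ≤ 15;
* pure-birth simulator mean vs e^{rt} at 10⁵ replicates.

## Numerical choices and degenerate inputs

* Ages are measured backward from the present (deepest tip); trees whose
  tip depths differ by more than 1e−6 of the depth trigger a warning and
  ages are measured from the deepest tip.
* Covariance matrices are validated symmetric/PSD (minimum eigenvalue
  ≥ −1e−9 of scale) before Brownian simulation.
* Singular designs report the collinear columns by name; taxa mismatches
  report the symmetric difference.
* rt > 40 in the richness simulator is rejected (clade sizes would exceed
  integer range).
* CLI exit codes: 0 success, 2 input error, 3 numerical failure.

## Limitations

* AIC values depend on the λ-parameter-counting convention (above) and are
  not directly comparable to software that conditions on λ̂.
* The sister-pair extractor requires a binary tree; polytomies must be
  resolved upstream, because "the two children of a node" is undefined at
  a polytomy.
* The pipeline treats ε as global; clade-specific extinction fractions are
  out of scope.
* State-dependent diversification models (e.g. BiSSE-type likelihoods) are
  deliberately not included: they require dense, randomly sampled
  species-level trees unavailable at these scales.
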