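# Methods

## DL decay model and fitting

A delayed-luminescence record is a vector of photon counts in 600
consecutive 0.05-s bins (30 s). The expected count rate follows the
hyperbolic law I(t) = I0/(1 + t/τ)^β with I0 > 0 (counts/bin), τ > 0 (s)
and β > 0 (dimensionless); the derived decay time is
T = (e^{1/β} − 1)·τ, which reduces to τ/β for large β. The model is
evaluated at bin midpoints t_k = (k + ½)·Δt — counts are integrals over
bins, and midpoint evaluation is second-order accurate in Δt.

The default objective is the Poisson deviance between observed counts and
the model (photon counting is Poisson); variance-weighted least squares is
available for comparison. A constant background (counts/bin) can be fixed
(default 0; the instrument's dark rate of ~10 counts/s corresponds to ~0.5
counts/bin) or estimated. Optimization is bounded L-BFGS-B in
log-parameter space — bounds I0 ∈ (0, 10·max count], τ ∈ (10⁻⁴, 30] s,
β ∈ (0.01, 20] — initialized with I0 from the first bin, τ₀ = 10 bin
widths and β from the slope of log counts against log(1 + t/τ₀), with a
small multi-start over τ₀ (×¼, ×1, ×4) because τ is the least identifiable
parameter. Convergence: relative objective change < 10⁻¹⁰ or 500
iterations; a non-converged fit is returned flagged rather than raised.
Tests verify the optimum against an independent grid search, and under
Poisson noise at I0 = 1500 the single-curve sampling error of τ is itself
3–5%, so recovery is asserted on the median over replicate simulations.

Replicates: fits are made per replicate and the fitted properties
arithmetically averaged per sample (the alternative — summing counts over
the three replicates before one fit — is available as an option; see the
replicate-handling ambiguity below). Only converged fits enter the
average.

## Fingerprint similarity and RSI grouping

Peak tables (peak id, retention time, area) are assembled into a
sample × common-peak matrix; a common peak missing from a sample is
imputed as area 0 with a warning (the reference peak may never be
missing). Relative retention times and relative areas divide by the
reference peak (No. 13 by default), whose entry is exactly 1.

Similarity is the included-angle cosine of relative-area vectors (Pearson
correlation optional); cosine is invariant to per-sample positive
rescaling, so raw and relative areas give identical indices. The standard
fingerprint is the arithmetic mean of the cohort's relative-area vectors
(median optional), and each sample's RSI is its similarity to that mean.
Grouping uses two thresholds: RSI ≥ 0.885 → A, RSI ≤ 0.84 → B, the open
gap → unassigned with a warning rather than a forced label. Both
thresholds are configurable. Similarity is computed on common-peak
vectors, not full chromatogram traces: peak tables are the reproducible
representation, and full traces are out of scope. Report output is
rounded to 3 decimals; internal values keep full precision.

## Chemometrics

PCA uses a full SVD after optional centering/autoscaling; constant
features are dropped (with a warning) when scaling, since unit-variance
scaling is undefined for them.

OPLS-DA encodes the two classes as ±1, autoscales X, removes
`n_orthogonal` (default 1) components of X-variation orthogonal to the
class variable by the standard two-block NIPALS scheme, and fits one
predictive PLS component on the filtered matrix. R² is the in-fit
fraction of class variance explained; Q² = 1 − PRESS/TSS under stratified
k-fold cross-validation (default 7 folds, deterministic given the seed)
in which centering, scaling and the orthogonal filter are re-estimated on
each training fold. Fold counts shrink with a warning when the smaller
class has fewer members than folds. Q² is capped at R² (cross-validation
noise can otherwise nudge it past the in-fit statistic by rounding). In
the pipeline, compound concentrations are log-transformed before
autoscaling: assay concentrations are lognormal and a squared-error CV
statistic is otherwise dominated by the occasional extreme sample.

Ward clustering runs on Euclidean distances via the Lance–Williams
recurrence (scipy linkage); reported heights follow scipy's convention,
under which the first merge of a pair equals their Euclidean distance.
In the wild workflow the four DL properties are autoscaled before
clustering so each carries equal weight, the tree is cut at k = 2, and
the cluster with the higher mean (autoscaled) DL values is named group 1.

The two-group t test defaults to the Student pooled-variance variant
(df = n₁ + n₂ − 2), with Welch optional. Spearman's ρ is Pearson on
mean-ranked data; a constant input yields a not-computable marker (NaN)
rather than a value. The correlation network computes ρ for every
(compound or class total) × (I0, τ, β, T) pair and classifies |ρ|:
≤ 0.30 none (the "linear relationship" definition is a strict
inequality), < 0.50 weak, < 0.70 moderate, else strong — the 0.50 and
0.70 boundaries belong to the higher class. All pairs are exported;
edges above "none" carry a linear-relationship flag.

## Bioassay statistics

Diarrhea incidence is 100·n_loose/n_total (reported to 1 decimal, full
precision internally); the propelling ratio is 100·distance/length with
distance ≤ length enforced at the record level. One-way ANOVA uses the
classical between/within decomposition. The post hoc gate is
Brown–Forsythe (median-centered Levene) at α = 0.05: acceptance selects
LSD (pairwise t tests on the pooled within-group mean square), rejection
selects Tamhane's T2 (Welch t statistics with Sidak-adjusted
per-comparison p values, reported capped at 1). Diarrhea counts get an
overall Pearson chi-square across groups and pairwise two-sided Fisher
exact tests under the probability-mass definition (sum of tables no more
probable than the observed one), which the test suite verifies
exhaustively against hypergeometric enumeration for all 2×2 tables with
n ≤ 20. A mouse that never passed charcoal faeces within the 5-h window
has no incubation period; such mice are excluded from incubation means
with a logged count rather than censored at 300 min.

## Synthetic cohorts

The generator plants exactly the structure the analysis is meant to
detect, with one seed determining every output.

* **Compounds.** 15 compounds in three classes (5 free anthraquinones,
  7 anthraquinone glucosides + sennoside A, 2 polyphenols), lognormal
  with CV 0.25 around class means of a few mg/g. Group B (11 of 28 by
  default) doubles the glycoside means and additionally spikes 2
  randomly chosen glucosides per sample by a lognormal factor around 8.
  The spike structure matters: a uniform coherent elevation of all eight
  glycoside coordinates makes cosine similarity insensitive (all-positive
  near-uniform vectors are always similar) and pulls the cohort mean
  toward group B, whereas idiosyncratic spikes make B samples mutually
  dissimilar and individually far from the mean fingerprint — the
  pattern the real similarity tables show. Class totals are exact sums
  of their members. A species factor is generated with no chemical
  effect, mirroring the finding that sub-species do not separate.
* **DL.** Each of I0, τ, β follows intercept − slope·log(glycoside
  total) + Gaussian noise, clipped positive (I0 ≈ 9000 − 1600·log g,
  τ ≈ 0.62 − 0.11·log g, β ≈ 2.6 − 0.20·log g), and T derives from
  (β, τ). The slope ratio is deliberate: because T = (e^{1/β} − 1)·τ,
  a steep β slope makes T *rise* as glycosides increase even while τ and
  β fall; the chosen slopes keep all four properties negatively linked.
  Three Poisson curves per sample are drawn from the hyperbolic model
  with a 0.5 counts/bin dark background (~10 counts/s).
* **Peaks.** The 15 compounds map to fixed common-peak ids (reference
  peak 13 remains a stable baseline peak); compound-peak areas are
  calibration slope × concentration with lognormal noise (σ = 0.10),
  baseline peaks come from a shared template (1.2×10⁵ area units, the
  reference 1.2× that), and retention times follow a fixed 5–100 min
  template with 0.05-min jitter.
* **Bioassay.** Seven groups (control + two samples × three doses,
  n = 8–9) with loose-stool flags Bernoulli under
  logit p = −4.4 + slope·dose (slope 0.8 for the milder sample, 1.6 for
  the stronger one, matching the observed dose–response pattern), faeces
  counts Poisson, weights and incubation truncated normal, and
  propulsion distances Beta-distributed fractions of the intestine
  length (so distances never exceed lengths).

What the generator does *not* emulate: real chromatogram traces and
peak-integration error, retention-time drift across instruments,
inter-batch correlation structure, environmental covariates (altitude,
harvest year) beyond a noise term, and any species effect. Passing tests
therefore demonstrate that the pipeline recovers planted structure of the
stated shape and size — not that real rhubarb cohorts have that
structure.

## Problem sizes and numerical choices

The default suite exercises the 28-sample commercial design with 3×600-bin
curves (84 fits), the 118-sample wild design from the DL truth table, 100
curves for parameter recovery, 100 label permutations for the OPLS-DA
null, and 5000 replicates for each null-calibration simulation; these
sizes give stable statistics while keeping the whole suite fast. Boundary
behavior is pinned by tests at the |ρ| class edges (0.30, 0.50, 0.70 ± ε),
the RSI thresholds, zero-variance t-test inputs, all-zero DL curves,
missing common peaks and degenerate (near-constant) clustering input.

## Known limitations

* The similarity indices of the original software cannot be reproduced
  exactly: whether it used full chromatograms or common-peak vectors, and
  cosine or correlation, is not documented, and the per-sample
  relative-area tables are not public. The package computes cosine on
  common-peak vectors and exposes both method options.
* The printed OPLS-DA R²/Q² values depend on an unspecified
  cross-validation scheme and component count; the package reports its
  own scheme (stratified 7-fold, 1 orthogonal component) and makes both
  configurable. Exact reproduction is not promised.
* Whether the original DL analysis fitted per-replicate curves or the
  summed triplicate is ambiguous (both are described); both paths are
  implemented, defaulting to per-replicate fits with property averaging.
* Tamhane's T2 p values use the Sidak inequality and are slightly
  conservative for strongly correlated comparisons.
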