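# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `netdim`.  Everything stated here is computed by the
package's tests or examples; nothing is quoted from external analyses.

## The dimensionality problem

Likert batteries built from conceptually adjacent constructs (here: defeat
— a sense of failed struggle — and entrapment — a sense of blocked escape)
produce correlation matrices dominated by one large eigenvalue even when
several distinct-but-correlated factors generated the data.  Eigenvalue
heuristics (scree elbow, parallel analysis) key on that spectrum and
undercount.  Community detection on the *partial*-correlation network keys
on conditional dependence instead: items in the same cluster stay densely
connected after conditioning on all other items, however correlated the
clusters are with each other.  The package implements both routes so they
can be compared on data with known ground truth.

## Synthetic ordinal generator

Latent item responses follow a common-factor model

    y* = Λ η + m w + ε,   η ~ N(0, Φ),  w ~ N(0, 1),  ε ~ N(0, Θ)

with standardized loadings Λ (p × k), factor correlations Φ (unit diagonal,
positive definite), an optional orthogonal *wording* factor w loading on a
chosen item subset with loading `method_effect_loading` (modelling the
method variance shared by positively worded items), and uniquenesses Θ
chosen so each y*ᵢ has unit variance.  Observed categories 0–4 come from
cutting y*ᵢ at four strictly increasing thresholds; the default thresholds
are the standard-normal quintiles (each category 20% in the population) and
a `SKEWED_THRESHOLDS` preset shifts mass toward low categories as in
clinical severity data.  The model-implied latent correlation matrix
Σ = ΛΦΛᵀ + mmᵀ + Θ is available in closed form
(`population_correlation`), which is what makes every downstream estimator
testable.

Preset design points (chosen once, as plausible values for well-constructed
clinical scales; the generator is a study-design device, not a tuning knob):

| preset | clusters (items) | Φ off-diagonals | default n |
|---|---|---|---|
| `online_4dim` | 13 / 3 / 10 / 6 | 0.60–0.80 | 480 |
| `clinical_3dim` | 16 / 9 / 7 | 0.70–0.80 | 150 |
| `unidimensional` | 32 | — | 480 |
| `high_overlap` | 16 / 16 | 0.91 | 480 |

Loadings cycle through {0.70, 0.80, 0.65, 0.75, 0.60, 0.85} so each cluster
mixes stronger and weaker indicators (`high_overlap` uses a uniform 0.8).
The generator emulates the statistical structure the estimators assume —
ordinal responses from a smooth unidimensional-per-item latent process with
simple structure.  It does **not** emulate response styles other than the
single wording factor, missing data, local item dependence beyond the
factor model, or floor effects stronger than the skewed-threshold preset;
recovery results on these presets therefore speak to the estimators'
behaviour under the assumed model, not to every failure mode of real
questionnaire data.

One seed governs a dataset; bootstrap replicates derive child seeds as
`seed + replicate_index`, so all results are bit-reproducible.

## Network estimation

* **Correlations.** Pearson by default (common practice for 5-point items
  at these lengths); two-step polychoric optional — thresholds from
  marginal category proportions via Φ⁻¹, then pairwise ρ by bounded 1-D
  maximization of the bivariate-normal cell likelihood.  Either choice is
  recorded in the result.
* **Positive definiteness.** Undersized samples can produce indefinite
  (especially polychoric) matrices.  These are smoothed by eigenvalue
  clipping (floor 10⁻⁶, rescale to unit diagonal, iterate) with a logged
  warning rather than aborting — downstream results then warrant cautious
  interpretation, and the pipeline report surfaces the warning verbatim.
* **Graphical lasso.** Authored block coordinate descent (lasso per
  row/column with incremental residual updates), penalty on off-diagonal
  precision entries only, warm starts along a 100-point log-spaced penalty
  path from λmax = max|rᵢⱼ| down to λmax/100.  The EBIC scan runs at
  tolerance 10⁻⁴ (selection is insensitive to it — verified against a
  10⁻⁶ scan) and the selected solution is re-solved at 10⁻⁷ so it satisfies
  the KKT stationarity conditions to well under 10⁻⁴.  The solver is
  cross-checked against scikit-learn's implementation in the test suite.
* **EBIC.** −2ℓ + E log n + 4γE log p with γ = 0.5 by default; γ = 0
  reduces to BIC.  An edge is |ρ| > 10⁻⁷ (float-noise guard).
* **Selection behaviour.** Path selection keeps every true edge in the
  sparse-recovery tests, but weak spurious edges (an order of magnitude
  below the true partial correlations) routinely survive: decreasing λ
  un-shrinks true edges, and that likelihood gain outweighs the per-edge
  penalty.  Strict monotonicity of the edge count in λ holds on sparse
  problems and can be violated by a single edge near the dense end of the
  path.  Both behaviours are documented properties of ℓ₁ path selection,
  not defects of the solver.

## Community detection

Walktrap (t = 4 steps by default) on nonnegative weights: |ρᵢⱼ| by default
(`absolute`), or `truncate` to drop negative edges.  Transition matrix
P = D⁻¹W, node distance rᵢⱼ = ‖(Pᵗᵢ· − Pᵗⱼ·)/√d‖₂, Ward-style merging of
adjacent communities (minimal increase in mean squared node-to-community
distance), final cut at maximum modularity.  Separate connected components
never merge.  On small graphs the returned cut attains the exhaustive-
enumeration maximum modularity; against igraph's implementation the cut is
never worse, though merge order can differ at near-ties.

Policies (the method literature leaves these open; all are explicit
arguments and recorded in reports):

* **Isolated items** (no surviving edges) support no dimension claim: they
  are excluded from the count and listed separately (membership label 0).
* **Fractional bootstrap medians** (e.g. 3.5) are reported as-is in
  `median_dimensions` and rounded half-up for the integer headline.
* **Parametric bootstrap** draws from the Pearson correlation matrix even
  when polychoric estimation was requested (with a warning): the replicates
  are continuous multivariate-normal samples, the simplest coherent
  parametric model.  Replicate failures are logged and excluded; more than
  10% failures aborts.

## Factor-analytic arm

* **Scree elbow**: acceleration-factor rule — the elbow is the position of
  the largest discrete second difference of the eigenvalues; retained
  count = elbow − 1, floor 1.
* **Parallel analysis**: observed eigenvalues against the 95th percentile
  (configurable) of eigenvalues from standard-normal data of the same
  n × p; counting stops at the first failure.
* **EFA**: principal axes (communalities start at squared multiple
  correlations, iterate to 10⁻⁶ or 100 iterations; Heywood communalities
  clamp to 0.999 with a warning) or minres (L-BFGS-B on communalities).
* **CFA**: simple structure, unit-variance factors, free loadings,
  uniquenesses (log-parameterized) and factor correlations (row-normalized
  Cholesky parameterization, so Φ stays a valid correlation matrix).  ML
  minimizes F = log|Σ| + tr(SΣ⁻¹) − log|S| − p; χ² = (n−1)F_min; three
  jittered starts guard against bad local minima.  Fit indices:
  CFI with the free-variance independence baseline, RMSEA with the (n−1)
  denominator, SRMR as the root mean square of standardized residuals over
  the lower triangle including the diagonal.  Conventions differ across
  software; these are stated so numbers can be compared correctly.
* **WLSMV is not replicated.**  The `dwls` estimator gives diagonally
  weighted least-squares point estimates on polychoric correlations with
  *unit* diagonal weights, and an SRMR; the mean-and-variance-adjusted test
  statistic requires an asymptotic covariance machinery out of proportion
  to this package, so χ²/CFI/RMSEA are NaN under `dwls` and ML indices are
  not comparable to published WLSMV values.
* **Model comparison**: χ² difference test for nested ML fits; the general
  model is preferred iff p < 0.05, otherwise parsimony keeps the restricted
  model.  `dwls` fits are rejected (scaled difference tests out of scope).

### Built-in model specs

Four confirmatory structures for the 32-item battery ship with the package:
`one_factor_32`, `two_factor_DS_ES` (defeat vs entrapment),
`online_4factor` and `clinical_3factor`.  The four-factor spec follows the
published cluster listing verbatim, which assigns the "winner" cluster the
items {3, 4, 9} and leaves item 27 unassigned — even though by item wording
the positively framed defeat items are {2, 4, 9} (flagged as reverse-coded
in the scale metadata) and item 27 belongs with internal entrapment in the
6/10 split the same report describes.  Both readings are representable as
`FactorModelSpec`s; neither is hard-coded as truth.  The clinical
three-factor spec groups item 17 with internal entrapment, exactly as
listed.

### Reverse coding is opt-in

Network and factor stages analyze raw item responses.  Recoding the three
positively worded defeat items before analysis would fold the wording
cluster back into the defeat factor — the separate "winner" dimension is
only observable on raw items — so `reverse_code` is never applied
implicitly.

## Pipeline

`run_pipeline` executes: Pearson correlations (smoothed if needed) → EFA
(eigenvalues, scree, parallel analysis, one-factor loadings) → one-factor
CFA → bootstrap EGA → CFA of the EGA-derived structure → nested χ²
comparison.  The EGA-derived spec comes from the most frequent membership
pattern among replicates at the headline dimension count; singleton
communities are merged into their strongest-connected neighbour (single-
item factors are not identified) with the merge logged, and the comparison
one-factor model is refit on the same item subset so the models are nested.
Given a seed the numeric JSON report is byte-identical across runs
(timestamps excluded).

## Problem sizes used in checks

The test suite and acceptance script run at n = 2000 for recovery claims
(20 seeds × 100 bootstrap replicates for the four-dimension recovery; 50
seeds for the EGA-vs-scree contrast) and at the study-sized n = 480 /
n = 150 for the descriptive pipeline quantities, with B = 100 bootstrap
replicates — a scaled-down replicate count that leaves the median estimator
unchanged in distribution while keeping the full battery of checks
desk-runnable.

## Known limitations

* Pearson input attenuates ordinal correlations; polychoric input is
  available but slower and more fragile at small n (non-PD matrices).
* No Ising/mixed graphical models, no nonparanormal transforms, no
  centrality or item-stability statistics.
* The walktrap implementation targets questionnaire-sized graphs (tens of
  nodes); it is O(p³)-ish per merge sweep and not meant for large networks.
* `dwls` is a point-estimation convenience, not a WLSMV replacement.
* Bootstrap EGA on samples far below p(p−1)/2 participants frequently
  returns empty or fragmented networks; the frequency table (and the
  isolated-item list) makes that instability visible rather than hiding it.
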