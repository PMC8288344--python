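# Methods

## The model

`treehoi` quantifies how a focal tree's survival and growth respond to its
neighbours through two kinds of neighbourhood terms, both built from the same
size- and distance-dependent kernel

    w(DBH, d) = DBH^u / d^v        if d < R,    0 otherwise,

where DBH is the neighbour's diameter at breast height (cm), d the planar
Euclidean distance (m), and (u, v, R) kernel parameters: u scales the effect
with neighbour size (u = 0 ignores size; u = 2 is close to weighting by basal
area), v sets the distance decay, and R truncates interactions at a maximum
radius.

For a focal tree i and neighbour groups (species, or size classes) the
**direct interaction (DI)** term for group j sums the kernel over group-j
neighbours within R of the focal.  The **higher-order interaction (HOI)**
term for the ordered pair (j, k) sums, over chains, the product of two
kernel weights: a *transmitter* j_p within R of the focal times an
*initiator* k_q within R of the transmitter.  The HOI term captures
interaction modification — the initiator changes the transmitter's effect on
the focal — and is asymmetric in (j, k) whenever u ≠ 0 or v ≠ 0.

Chains with j_p = k_q are excluded (a tree cannot modify its own effect
through itself), and the focal is excluded from both roles by default
(allowing it as initiator is a flag, `allow_focal_initiator`; whether a
published analysis would include those chains is genuinely ambiguous, and
excluding them keeps direct and higher-order effects unconfounded).
Initiators may lie up to 2R from the focal — they only need to be within R
of a transmitter — which is exactly why focal eligibility requires a 2R
buffer from every plot edge: a focal's neighbours *and its neighbours'
neighbours* must be fully observed.  The buffer rule uses strict
inequalities, so a tree exactly 2R from an edge is eligible.

Truncation is implemented as an explicit `d < R` indicator.  The tempting
shortcut of setting out-of-radius distances to infinity fails silently at
v = 0, where `inf**0 == 1` re-admits every excluded tree; v = 0 is a real
case (it is part of the search grid and can be the optimum), so the
indicator form is load-bearing and has a dedicated regression test.

The terms enter two per-focal-group regression models:

* **Survival** (logistic):
  `logit P(survive) = lambda_i + g1/DBH + g2*DBH + g3*DBH^2
  + sum_j alpha_ij * di_j + sum_jk beta_ijk * hoi_jk`.
  The hyperbolic, linear and quadratic DBH terms track high seedling
  mortality and U-shaped senescence.  The logistic is oriented so that
  negative alpha (competition) lowers survival; with the opposite
  orientation the published sign semantics (alpha < 0 competitive,
  alpha > 0 facilitative) would be inverted.
* **Growth** (log-linear):
  `Growth = G_pot,i * DBH^gamma * exp(DI) * exp(HOI)`, fitted by OLS after
  log transform on survivors with a strictly positive DBH increment
  (`min_increment`, default 0, is a config switch; the log response forces
  positivity and the field protocol leaves negative-increment handling
  open).

Model classes SIZE, SIZE+DI and SIZE+DI+HOI are nested; for G groups the
free-parameter counts are 4 / 4+G / 4+G+G^2 (survival) and 2 / 2+G /
2+G+G^2 (growth).  Each focal group gets its own fit, so the intercept is
the group-specific lambda_i or ln G_pot,i.

## Fitting and evaluation

(u, v) are not estimated jointly: terms are recomputed on a grid (default
u, v in {0, 0.1, ..., 2}, R in {10, 20, 30} m — 1323 cases) and each class
is refitted per cell; the optimum is the log-likelihood argmax, with ties
broken toward smaller u then smaller v.  The R^2 argmax is reported for
cross-checking: it must coincide exactly for OLS and under McFadden's
pseudo-R^2 (1 − loglik/loglik_null, a monotone transform) for the logistic;
McFadden is used precisely to preserve that coincidence.  Cells that fail to
fit (e.g. separation at extreme exponents where a term column becomes
near-degenerate) are flagged and dropped from the argmax rather than
aborting the sweep.

Classes are compared at their own optima by AIC = 2k − 2·loglik and
BIC = k·ln n − 2·loglik (a gap ≥ 2 to the runner-up is flagged as a
meaningful parsimony improvement) and by repeated k-fold cross-validation
(default 10 folds × 10 repeats, reshuffled each repeat, pooled RMSE and
MAE).  Survival CV errors are predicted probability minus the 0/1 outcome —
consistent with error magnitudes well below the class-label scale — and
survival folds are stratified by outcome because deaths are rare enough
that unstratified folds can contain none.  The optimum (u, v) is selected
on the full sample before CV, matching the sequential procedure the method
describes; this leaks a little optimism into the CV scores of the
DI/HOI classes, which is accepted and documented rather than corrected.

Survival fits use Newton-scored maximum likelihood (statsmodels `Logit`,
cap 100 iterations, relative tolerance 1e-8) with internal column
standardisation: term sums span orders of magnitude across the grid, and
rescaling — exactly undone on output — keeps the information matrix well
conditioned.  Perfect separation, non-convergence (reported with the
gradient norm) and rank deficiency (reported with the collinear columns)
raise typed errors.

## Effects decomposition

Each fitted term times its coefficient, classified by origin relative to
the focal's group: DI_ii / DI_ij (conspecific / heterospecific direct) and
HOI_ii,i / HOI_ii,j / HOI_ij,i / HOI_ij,j by (transmitter, initiator)
identity.  Components live on the linear-predictor scale so additivity is
exact: di_total + hoi_total = total, and size terms + total reconstruct the
fitted linear predictor to machine precision (an invariant under test).
Summaries use boxplot conventions (1.5×IQR whiskers); a component whose
distribution lies entirely above zero is read as facilitative, entirely
below as competitive, otherwise mixed.  An optional natural-scale view for
growth is just the exponential of the components.

## The synthetic generator

`default_scenario()` is the desk-scale analogue of the system the method
was built for: a 150 m × 150 m plot with an abundant, widespread group A
(9000 stems, homogeneous Poisson — ~5000 focal-eligible inside the 2R
buffer) and a rare, aggregated group B (340 stems, Thomas cluster process:
34 uniform parents, 6 m Gaussian scatter), mirroring a two-species forest
where the dominant outnumbers the subordinate by ~50:1.  DBH is log-normal
(median 5 cm, log-sd 0.5) with the 1-cm census floor; stems are separated
by ≥ 1 mm (jitter-and-retry) because the 1/d^v kernel is undefined at
d = 0.  Fates are drawn from the survival and growth models themselves at
kernel truth (u, v, R) = (1.0, 0.8, 10 m): survival Bernoulli on the
logistic predictor; growth multiplicative with log-normal noise
(sd 0.3, mean-corrected by −sd²/2 so the expected natural-scale increment
equals the model prediction — the corollary is that the fitted log-scale
intercept estimates ln G_pot − sd²/2, which recovery reports account for).
Buffer-zone trees receive fates too: they are neighbours even though they
are never focal.

True coefficients follow the regime the source system exhibits —
competitive direct effects (alpha < 0), facilitative higher-order effects
(beta > 0) — with magnitudes set by a strong-effects rule: what identifies
a coefficient (and, through the fit surface, the kernel exponents) is the
*between-focal variation* its term contributes to the linear predictor, the
mean being absorbed by the intercept; each coefficient is therefore sized
to contribute roughly 0.3 linear-predictor units of standard deviation,
comparable to the growth model's residual scale.

Because the generative family and the fitted family coincide, parameter
recovery closes the loop and is the definitive end-to-end test of terms +
models together.  The experiments shipped with the package (and re-run by
`scripts/acceptance.py`):

* **Recovery** — 20 replicates of the default scenario, SIZE+DI+HOI fitted
  at kernel truth for focal group A, both responses: 95% Wald-CI coverage
  of all alpha and beta, and mean bias within 3 Monte-Carlo SE of zero.
  The ~5000-focal size matters: at ~1500 focals the logistic's O(1/n)
  small-sample bias, amplified by di–hoi collinearity, is already visible
  against 20-replicate Monte-Carlo error.
* **Model selection** — at kernel truth, AIC among the three classes
  (growth response): with the default (strong) beta the HOI class should
  win in ≥ 80% of 20 replicates; with beta ≡ 0 in ≤ 30% (AIC's known
  overfitting rate for 4 spurious terms is P(chi²₄ > 8) ≈ 9%).
* **Grid recovery** — argmax of the growth log-likelihood over an 11 × 11
  (u, v) grid at the native 0.1 step, spanning a 1.0-wide window around
  the truth (u in 0.5–1.5, v in 0.3–1.3); a hit is an argmax within one
  step (0.1) per coordinate, expected in ≥ 80% of 10 replicates.  The
  window, rather than the full 0–2 range, keeps the sweep at 121 cells;
  the graph of within-R neighbour pairs is built once per replicate and
  reused across cells, which is what makes the sweep affordable.

What the generator does *not* emulate: measurement error in DBH, multi-stem
individuals, environmental heterogeneity, non-equilibrium mortality agents
(e.g. insect outbreaks with ranges beyond R), or more than two censuses.
Passing recovery therefore certifies the estimator under the model's own
assumptions — correct specification, independent fates given terms — not
robustness to the ways real census data violate them.

## Numerical choices and conventions

* `0**0 = 1`, so u = 0 or v = 0 degrade exactly to counts.
* Strict inequalities throughout: interaction requires d < R; edge
  eligibility excludes x < 2R from a boundary; "large" trees in the size
  grouping are strictly above the threshold (the threshold itself is
  "small").
* Batch terms use a cKDTree fixed-radius pair enumeration plus vectorised
  segment sums (near-linear in stem count for fixed R); they agree with the
  exhaustive O(N²)–O(N³) oracle to ~1e-12 relative, and the oracle — a
  direct transcription of the defining sums with no index and no
  rearrangement — is the ground truth in tests.
* Coincident stems raise an error naming both ids rather than being
  dropped.
* Growth loglik is the Gaussian profile likelihood; reported k counts only
  linear coefficients (not sigma), matching the convention in which the
  two-group HOI models have 10 (survival) and 8 (growth) parameters.

## Known limitations

* Wald CIs can be poorly calibrated for beta coefficients whose term has
  mass only near zero (rare-group chains); coverage is monitored pooled
  over coefficients.
* The HOI term count grows as G², so the method is practical only for few
  groups; grouping by size class (the `by_size_threshold` scheme) is the
  built-in mitigation.
* CV scores for DI/HOI classes inherit the optimism of full-sample (u, v)
  selection (see above).
* No spatial autocorrelation corrections, random effects or regularisation:
  plain ML/OLS by design.
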