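# treehoi

Size- and distance-dependent direct and **higher-order** neighbourhood
interactions (HOIs) for stem-mapped forest censuses.

Neighbourhood models of tree survival and growth traditionally stop at
pairwise ("direct") effects: each neighbour pushes on a focal tree with a
strength proportional to its size and inversely related to its distance.
But neighbours also interact with *each other*, and a third tree can modify
how a second tree affects the first — an interaction modification, or
higher-order interaction.  `treehoi` implements an individual-level,
size- and distance-explicit formulation of those three-way effects, embeds
them in standard survival and growth regressions, and provides the full
model-selection and effects-decomposition machinery needed to ask whether
HOIs earn their parameters.  It is aimed at forest ecologists working with
ForestGEO-style mapped census data (x, y, species, DBH, two-census fates),
and ships a generative simulator so the entire pipeline is testable with
known ground truth.

## The model

Pairwise kernel, for a neighbour of diameter DBH (cm) at distance d (m):

    w(DBH, d) = DBH^u / d^v   if d < R,   else 0.

For focal tree *i* and neighbour groups j, k (species identities, or
large/small size classes):

* direct term:  `di_j  = Σ_p w(DBH_jp, d[i, jp])` over group-j neighbours
  within R;
* higher-order term, ordered pair (j, k):
  `hoi_jk = Σ_p Σ_q w(DBH_jp, d[i, jp]) · w(DBH_kq, d[jp, kq])`
  over transmitter jp within R of the focal and initiator kq within R of
  the transmitter (kq ≠ jp, and neither equal to the focal).

These enter three nested model classes — SIZE, SIZE+DI, SIZE+DI+HOI:

    logit P(survive) = λ_i + γ₁/DBH + γ₂ DBH + γ₃ DBH² + Σ_j α_ij di_j + Σ_jk β_ijk hoi_jk
    Growth           = G_pot,i · DBH^γ · exp(Σ_j α_ij di_j) · exp(Σ_jk β_ijk hoi_jk)

α < 0 is competitive, α > 0 facilitative; β modifies the corresponding
direct effect.  The kernel exponents (u, v) and radius R are chosen by
refitting on a grid (default 21 × 21 × {10, 20, 30 m} = 1323 cases) and
taking the likelihood argmax; classes are then compared by AIC, BIC and
repeated stratified k-fold cross-validation, and each tree's fitted
neighbourhood effect is decomposed by origin (conspecific/heterospecific
transmitter × initiator).  Focal trees must lie ≥ 2R from every plot edge
so that their neighbours' neighbours are fully observed.

## Worked example

Simulate the built-in two-group scenario (abundant Poisson-distributed
group A, rare cluster-distributed group B, true kernel (u, v, R) =
(1.0, 0.8, 10 m), competitive α, facilitative β), compute terms, and fit
growth:

```python
import treehoi as th

sc = th.default_scenario(seed=42)
plot = th.simulate_census(sc)                       # 9340 trees, 2 groups
terms = th.terms_batch(plot, sc.kernel, focal_group="A")   # 4879 focals
fit = th.fit_model(terms, plot, "growth", "SIZE_DI_HOI", focal_group="A")
print(fit.params)
```

    intercept    0.132504   (truth ln G_pot − sd²/2 = 0.137)
    log_dbh      0.248786   (truth 0.25)
    di_A        -0.012459   (truth -0.012)
    di_B        -0.029955   (truth -0.03)
    hoi_A_A      0.000053   (truth 5e-05)
    hoi_A_B      0.000214   (truth 2e-04)
    hoi_B_A      0.000148   (truth 1.5e-04)
    hoi_B_B      0.000420   (truth 5e-04)

Every coefficient lands within about two standard errors of its generating
value.  Comparing the three classes at the same terms
(`th.information_criteria`, `th.repeated_kfold_cv`):

    SIZE         k=2  loglik=-2173.3  AIC=4350.7  BIC=4363.3  RMSE=0.733  MAE=0.518
    SIZE_DI      k=4  loglik=-1161.0  AIC=2330.0  BIC=2355.2  RMSE=0.655  MAE=0.408
    SIZE_DI_HOI  k=8  loglik= -810.9  AIC=1637.7  BIC=1688.3  RMSE=0.512  MAE=0.368

The HOI-inclusive model wins every criterion, in-sample and out-of-sample —
as it should, since the data contain real higher-order effects.  Decomposing
the fitted neighbourhood effects (`th.decompose_effects`,
`th.summarize_effects`):

    component  median      verdict
    di_total   -2.547  competitive
    hoi_total   2.323  facilitative
    total      -0.219        mixed

Direct effects are competitive for every focal, higher-order effects
facilitative — they partially offset the competition, and the decomposition
recovers the generating regime.  The dominant components are di_intra
(A on A) and hoi_ii_i (A on A through A), as expected when conspecifics
vastly outnumber the rare group.

A command-line interface wraps the same pipeline for shell use:
`treehoi simulate | terms | fit | evaluate | decompose` (see `--help`).

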