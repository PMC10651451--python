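# Methods

## The calibration problem

`spipls` calibrates a linear model that predicts the saliva precipitation
index (SPI, in g/L gallic-acid equivalent) of a red wine from a panel of
physico-chemical assays (organic acids, pH, buffer capacity, flavan-3-ol and
proanthocyanidin fractions, colour, proteins, polysaccharides, ...).  The
setting is the classic chemometric one: more predictors (p = 52) than can be
supported by the sample count (n ≈ 110 wines split 70/30), strong
within-family collinearity among assays, and a response measured with
appreciable assay noise.  Partial least squares regression (PLS1) handles the
p ≈ n collinear regime by projecting the predictors onto a few latent
components that maximize covariance with the response.

## Model and fitting

The core fit is the NIPALS PLS1 recursion on autoscaled data (each column
centred and divided by its SD, n−1 denominator; same for y).  Per component:

    w_a = X_a' y_a / ||X_a' y_a||,  t_a = X_a w_a,
    p_a = X_a' t_a / (t_a' t_a),    q_a = y_a' t_a / (t_a' t_a),
    X_{a+1} = X_a − t_a p_a',       y_{a+1} = y_a − q_a t_a.

Weights are unit-norm and scores orthogonal; y-deflation is algebraically
redundant for a single response but is kept to fix the convention.
Coefficients for any leading block of A components are b = W (P'W)^{-1} q;
the (P'W) system is solved per block so the whole coefficient path b(1..A)
comes from one fit.  Deflation stops early when ||X_a' y_a|| < 1e−12 (the
achieved count is recorded).  Raw-unit coefficients are obtained by
back-transforming through the scaling statistics,
b_raw_j = b_j · s_y / s_j and intercept = ȳ − b_raw'x̄, so an exported model
can be applied to unscaled assay values — this is the "portable" form the
final model ships in, and the form of the bundled published calibration
(`fixtures/eq1_model.json`).

Variable importance for projection is
VIP_j = sqrt( p Σ_a SSY_a w_ja² / Σ_a SSY_a ) with SSY_a = q_a²(t_a't_a);
its mean square is 1 by construction, making VIP = 1 the natural importance
threshold.

## Resampling machinery

**Cross-validation.** Repeated randomized k-fold CV (default 8 folds, 10
repetitions) re-randomizes fold membership every repetition and — by default —
refits the autoscaling inside each training segment so held-out statistics
never leak into calibration (`scale_in_cv: false` reproduces the variant that
scales once on the full training set).  RMSEcv and R²cv per component count
pool all held-out squared errors across repetitions.  The working component
count of any refit is the RMSEcv minimizer.

**Jack-knife significance.** Per repetition the k segment models give a
Martens-style variance for each coefficient,
s²_j = ((k−1)/k) Σ_m (b_j − b_j^(m))², averaged over repetitions; t_j = b_j/s_j
is referred to a Student t with k−1 = 7 degrees of freedom.  Pooling all 80
segments as degrees of freedom would overstate certainty, since segments
within a repetition are strongly dependent.  A degenerate zero spread yields
p = 0 for a nonzero coefficient and p = 1 otherwise.  Under a null response
the resulting p-values are close to uniform (slightly conservative in the
far tail), verified by a Kolmogorov–Smirnov check in the test suite.

**Permutation test for components.** Component a is scored by the absolute
score covariance |t_a' u_a| (for PLS1 the y-score u_a is the deflated
response, so the statistic equals |q_a|·t_a't_a).  The response is permuted
nperm times (default 1000) with a full refit per permutation, and
alpha_a = (1 + #{null ≥ observed}) / (nperm + 1) — never exactly zero.  The
certified component count is the largest A with all of components 1..A at
alpha ≤ 0.05.  The statistic is taken component-wise after deflation rather
than from separate refits per A; the two readings of the procedure differ
only in bookkeeping for PLS1.

**Cook's distance.** Outliers are screened on the ordinary least-squares
regression of y on the A-component score matrix (with intercept), where the
hat matrix is well-posed even though p > n for the raw panel; A is the
RMSEcv-minimizing pilot choice.  The classical closed form
D_i = e_i²/(p's²) · h_ii/(1−h_ii)² (computed via statsmodels' influence
machinery) is verified in tests against explicit leave-one-out refits.
Flagging rules: `4/n` (default), a fixed numeric threshold, or `top:k` to
mirror a fixed removal count.  A numerically perfect score regression
(residual variance at rounding level) reports all distances as zero.

## The m0 → m3 selection pipeline

1. Stratified 70/30 split by variety×region: per-stratum training counts by
   largest-remainder rounding (totals exactly match the half-up rounding of
   0.7·n), membership randomized under the seed.  The test partition is
   content-hashed at split time and the hash re-checked at evaluation, so no
   intermediate stage can touch it.
2. **m0**: PLS on all variables of the raw training set.
3. Cook's screening and removal of flagged training wines → **m1**.
4. Stage-1 filter: remove variables that are both unimportant (VIP < 1.0)
   and insignificant (jack-knife p > 0.1).  The conjunction is deliberate —
   an important-but-noisy variable or a low-VIP-but-significant variable
   survives to the next stage (an `or` variant is available as
   `stage1_rule`).  Stage-2: backward elimination of the single worst
   variable with p > 0.05, refitting (and re-choosing the working A) after
   every removal, ties broken by column order, until all survivors are
   significant → **m2**.
5. The permutation test and the overfit report gate the final complexity:
   admissible component counts keep |R²cal − R²cv| ≤ 0.20, and the final A is
   the most parsimonious of (largest significant, largest admissible).  The
   (R²cv, gap) trade-off is additionally summarized by a knee point: the
   Pareto-optimal vertex with maximum perpendicular distance to the chord
   joining the Pareto extremes (with fewer than three Pareto points, the
   max-R²cv point).
6. **m3**: the final model, evaluated exactly once on the untouched test set
   (overall R²/RMSE plus per-stratum RMSE) and exported as portable JSON.

If the permutation test certifies no component, overfit control admits no
component count, or elimination empties the variable set, the pipeline
reports `no_significant_model` instead of fabricating a fit.

A caveat worth stating: because the permutation test runs *after* variable
selection (as in the workflow it implements), its alpha on the selected
variables is optimistically biased.  On pure-noise data the pipeline refuses
outright in a little under half of runs and otherwise terminates with only
one or two spurious variables; it never certifies a sizeable null model.
The unselected permutation test itself is well calibrated (type-I error ≈ 5%).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of the study data, not its chemistry:

- 12 variety×region strata with the study's per-stratum counts (total 110);
- 52 predictors from a 5-factor latent model, giving correlated assay
  families; own-family loadings are heterogeneous (±30% around
  sqrt(0.5)) with one mild cross-loading each, because uniformly
  equicorrelated blocks would give a two-eigenvalue covariance that PLS
  saturates after two components;
- a sparse linear response over 19 active variables whose sign pattern
  (12 positive, 7 negative) and magnitude ordering follow the published
  final model.  Standardized magnitudes decline geometrically from 0.40 to
  0.20: since every one of the 19 published coefficients was individually
  significant at n ≈ 72, the weakest standardized effect cannot be far below
  the strongest — an information-budget constraint, not an aesthetic choice;
- actives are grouped by effect sign into three assay families (two
  positive, one negative), leaving two families inert.  Mixing signs within
  a correlated family would make block-mates cancel in the X–y covariance,
  which is not how a coherent assay panel behaves; the study likewise
  discarded entire families (e.g. the polymerization-degree and alcohol
  panels);
- stratum-level SPI differences that span the study's per-variety training
  means (1.7–5.9 g/L GAE).  These are carried *through the predictors*: each
  stratum's assay profile is displaced along the true-coefficient direction,
  iteratively calibrated so per-stratum signal means match the centred
  targets.  The alternative — adding stratum shifts to y directly — would
  make the stratum variance unexplainable from X and cap the attainable R²
  well below the population value;
- noise calibrated so the population R² = Var(signal)/(Var(signal)+σ²) hits
  a target (default 0.65, near the published held-out R² of 0.630), or an
  explicit `noise_sd`;
- optional gross outliers: ⌈fraction·n⌉ wines (default 5/110) get their SPI
  displaced by ±6 SD, emulating the five removals in the study.

Not emulated: real assay units and ranges, measurement-method biases,
non-linear tannin–protein binding, and any multi-directional structure in
the response — the synthetic truth is a single linear combination of the
predictors, so the permutation test typically certifies one component on
synthetic data even though the study certified three.  Passing tests
therefore demonstrate that the machinery is correct and calibrated, not that
three latent dimensions of real wine chemistry are recoverable.

## Numerical and design choices

- Autoscaling uses the n−1 SD; constant columns are rejected, not imputed.
- Split totals use half-up rounding (`floor(f·n + 0.5)`); banker's rounding
  would give 10+10.5 → 10.
- Deflation tolerance 1e−12 on ||X'y||; degenerate CV segments freeze the
  coefficient path at the last achieved component.
- Stage-2 ties (identical p-values above threshold) remove the
  earlier column; exact ties are vanishingly rare with continuous data but
  the rule keeps runs byte-reproducible.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical config + seed reproduces every
  report byte-for-byte.
- Default problem sizes in tests and the acceptance script (20 replicate
  studies, 199 permutations per randomization test, 200 null datasets for
  calibration checks) were chosen to keep a full verification run in the
  low minutes on one CPU while leaving the Monte-Carlo bands comfortably
  resolvable.

## Known limitations

- Recovery of the active set on synthetic data operates partly in the
  family-coherence regime: correlated inactive neighbours of true actives
  are sometimes retained, and the method cannot resolve attribution within a
  tightly correlated family — the same caveat the original workflow carries
  for strongly correlated assays.
- The jack-knife t with 7 degrees of freedom is conservative; genuinely weak
  effects (standardized |β| ≲ 0.2 at n ≈ 72) are routinely discarded.
- Selection-then-permutation ordering biases the component alpha on selected
  variables (see above); a fully nested protocol is out of scope.
- PLS2 (multiple responses), sparse/kernel PLS, robust PLS variants and
  X-space diagnostics (leverage, DModX) are not implemented.
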