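# Methods

This note records the model, the defaults and the judgement calls behind
`isspu`, in the spirit of a model-description appendix.  Nothing here states
an empirical number that the test suite or `scripts/acceptance.py` does not
itself compute.

## The PU model and its assumptions

Each class is learned from positives and unlabeled pixels only.  Writing
x for the feature vector, y ∈ {0, 1} for the true class indicator and
s ∈ {0, 1} for "carries a label", the model assumes labels are *selected
completely at random* (SCAR) among positives: p(s=1 | x, y=1) = c, a
constant, and negatives are never labeled, p(s=1 | x, y=0) = 0.  Then the
non-traditional scorer g(x) = p(s=1 | x) factorises as c · p(y=1 | x), so
the class posterior is f(x) = g(x)/c.

Consequences worth keeping in mind:

- g must be a *probability*, not a margin; every simulator backend is
  required to expose `predict_proba` (for gradient-boosted trees the
  logistic-transformed score).
- The ratio g/c can exceed 1 because c is estimated; we clip to
  f = min(g/c, 1).  Posteriors of different classes are independent
  one-class estimates and deliberately do not sum to one; only their argmax
  matters for labeling.
- c is estimated per routine as the mean score over the routine's held-out
  positives (count max(1, round(0.25·|P|)), never shown to the simulator;
  Python's round-half-to-even is used).  Held-out *unlabeled* rows are
  discarded: the estimator needs positives only.
- A raw mean ≤ ε = 1e−6 marks the routine invalid instead of dividing by a
  vanishing constant.  Invalid routines are dropped from the ensemble mean
  (with a warning); fitting fails only if a class loses all J routines.

The SCAR assumption is the method's main limitation: labeling biased toward
easy or typical positives inflates ĉ and deflates the calibrated posterior.
No correction for labeling bias is attempted.

## Ensemble defaults

- J = 10 routines per class; each routine draws, without replacement, as
  many unlabeled pixels as the class has positives.  Draws are independent
  across routines.
- The unlabeled pool is the whole image (all rows of the supplied pool)
  minus only the target class's own labeled positives; other classes'
  labeled samples remain eligible as unlabeled — they are legitimate draws
  from the marginal pixel distribution.
- One model seed deterministically derives every per-routine seed from the
  class identity (CRC of its repr) and routine index, so results are
  reproducible and invariant to catalogue permutation (which can change tie
  resolution only).  All derived seeds stay below 2³¹.
- Default simulator: XGBoost with 200 estimators, learning rate 0.3, depth
  6, min child weight 1, subsample 1.0, histogram tree method, one thread.
  These sit inside the accepted search bounds (estimators 1–1000, rate
  0.1–1, depth 2–23, min leaf 1–29, subsample 0.1–1); hyperparameter search
  is config-driven and off by default.

## Accuracy assessment

Confusion matrices are oriented reference-rows × prediction-columns.  The
population matrix re-weights sample counts by map-class proportions
stratified by *predicted* class: p̂ᵢⱼ = Wⱼ · nᵢⱼ / n₊ⱼ.  Quantity
disagreement is QD = ½·Σ|pᵢ₊ − p₊ᵢ|·100 and allocation disagreement
AD = ½·Σ 2·min(omissionᵢ, commissionᵢ)·100, so OA_pop + QD + AD = 100 on
any valid matrix.  Validity: a predicted class with zero samples
invalidates the conversion (QD/AD reported NaN, OA still defined) — unless
explicit weights assign that class zero map share.  When no map weights are
supplied, sample column proportions are used and a notice is logged; QD/AD
under default weights are therefore sample-level quantities, not population
estimates.

Minority-class QD′/AD′ normalise the class's error counts by its reference
amount: QD′ = |FP − FN|/row, AD′ = 2·min(FP, FN)/row (×100).  Complete
omission gives (100, 0).

The kappa comparison uses Cohen's kappa with the large-sample delta-method
variance (Fleiss–Cohen–Everitt; the Congalton-style two-map z-test):
|Z| = |κ₁ − κ₂| / √(v₁ + v₂), significant at 1.96.  Published |Z| values
from other software are generally not reproducible because the exact
variance formula is rarely stated; ours is pinned against a long-form
cell-by-cell oracle in the tests.

SHDI is the natural-log Shannon entropy of class proportions.

## Texture features

Per band: linear min–max quantisation to 32 gray levels (configurable),
then a symmetric co-occurrence matrix per 3×3 window at displacement
(0, 1), normalised to sum to one, summarised by mean, variance,
homogeneity, contrast, dissimilarity, entropy, angular second moment and
correlation (marginal-moment definitions; correlation = 0 at zero marginal
variance; 0·ln 0 = 0).  Edges use replicate padding so the feature stack
stays raster-aligned.  The 32-level depth and edge policy are
config-exposed because acquisition software varies here and no single
convention is canonical; exact bit-compatibility with any particular GIS
package is a non-goal.  The production path is a vectorised sliding-slot
formulation; a window-at-a-time reference path exists alongside it and the
tests pin their equivalence and their agreement with skimage's
co-occurrence counts.

## Synthetic scenes and the sampling design

Scenes emulate VHR imagery at fixture scale: per class a Gaussian random
field smoothed at `spatial_scale` pixels, standardised, plus a calibrated
bias; labels are the per-pixel argmax, with biases iterated until every
realized proportion is within ±2 points of target.  Spectra are class means
on a ring in the first two bands with *adjacent-class spacing exactly
`spectral_separability`* (in units of the unit-variance, 0.3-correlated
Gaussian pixel noise), so every class — the minority included — overlaps
its spectral neighbours by the same controlled amount.  The default
separability 3.0 puts the Bayes-optimal overall accuracy near 0.9,
matching the accuracy scale real suburban VHR scenes exhibit; the generator
intentionally does *not* reproduce sensor-specific spectra, mixed pixels,
shadows or spatially correlated noise, so passing tests demonstrate the
method's statistical behaviour, not sensor realism.

Training sets follow the a:b design: the test set is drawn first, uniformly
over the scene; then each majority class receives `per_majority` samples
(default 1000, the 1000 × n layout) and the minority receives
round(per_majority · a/b), all without replacement and disjoint from the
test set.  The two published descriptions of this design (fixed total vs
fixed per-majority count) conflict for a ≠ b; we fix the per-majority count
and log the realized counts on every run.

SMOTE is the classic interpolation (x + u·(neighbour − x), u ~ U(0,1),
k = 5 neighbours, 100% synthesis; the harness extends synthesis to full
equalisation with the majority count).

## Verification-study problem sizes

The studies in `isspu.studies` (shared by the acceptance tests and
`scripts/acceptance.py`) run at sizes chosen for a single desktop CPU:

- calibration: two-Gaussian PU pools of n = 2000, separation 4 sd, 50
  replicates per labeling frequency c ∈ {0.25, 0.5, 0.75}; the routine is
  trained on labeled-vs-all-remaining (natural PU proportions) because the
  equal-size draw of the ensemble estimates a case-control-reweighted
  constant, not c itself;
- imbalance contrast: one 96×96, 6-class, 3-band scene (spatial scale 6,
  separability 3), per-majority 500 (minority 10 at 2:98), J = 10,
  test set 3000 pixels, 10 trials per condition;
- identity audit: 1000 random 2–7-class matrices with Dirichlet weights;
- texture audit: 100 random 3×3 windows at 8 levels vs a double-loop
  reference; SMOTE audit: 1000 points, exact segment membership.

## Known limitations

- SCAR only; no selection-bias correction and no alternative c estimators.
- Posterior columns are uncalibrated across classes; use the argmax, not
  the raw matrix, for decision-making.
- The equal-draw design estimates a reweighted labeling constant; the
  calibrated posterior remains monotone in g, so labels are unaffected,
  but per-class posteriors should not be read as absolute probabilities.
- Raster I/O is plain multiband TIFF; geo-referencing metadata is not
  preserved.
- The sweep harness parallelises nothing; wall time scales linearly in
  ratios × methods × trials × J.
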