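# Methods

This note documents the models, the tunable parameters that matter, the
numerical choices, and what the synthetic data does and does not show.

## Correlation dimension estimation

A scalar series is delay-embedded with dimension m and delay τ (point
j = (x[j], x[j+τ], …, x[j+(m−1)τ])). The correlation integral is the
fraction of unordered point pairs at strict Euclidean distance < ε,
normalized by Q(Q−1)/2. The textbook h/Q² normalization (a Q→∞ limit)
differs only by a constant factor; since the estimator uses only the
log-log slope, the choice is immaterial and the pair normalization keeps
C within [0, 1] at finite Q. Strict inequality at the boundary is a
documented convention.

The dimension w is the ordinary-least-squares slope of log C(ε) on
log ε over the admissible radii (0 < C < 1). Two ε-grid regimes:

- **Well-sampled sets** (`estimate_cd` default): 12 log-spaced radii
  between the 1st and 10th percentile of pairwise distances. At radii
  comparable to the set's diameter the correlation integral saturates and
  boundary effects flatten the curve, biasing the slope low (a filled
  unit square fit up to the 95th percentile reads ≈ 1.55 instead of 2);
  the small-radius band sits inside the scaling region. Verified against
  known dimensions: line segment 1.02, filled square 1.90, Hénon
  attractor 1.20 at 2000–5000 points.
- **Windowed features** (`extract_cd_features`): each window contributes
  only Q = window_len − (m−1)τ embedded points (9 by default, 36 pair
  distances), so the grid spans the 5th–95th percentile of the window's
  own distances — a narrow band would often contain no usable radii at
  all. Window CD values are therefore noisy by construction; the
  pipeline consumes them in aggregate (channel templates, distance
  features), never individually.

Defaults: m = 2, τ = 1, window_len = hop = 10 (non-overlapping), which
realizes the 2560 → 256 per-channel reduction and the 16 384-feature
record. None of m, τ, the grid, or window overlap is forced by the
problem; all are configuration. Degenerate windows (constant signal, or
fewer than two admissible radii) yield CD = 0 with a warning rather than
an error, keeping feature matrices rectangular. `window_len ≥ (m−1)τ + 2`
is enforced so every window has at least two embedded points.

## Synthetic data

`generate_eeg_dataset` emulates the study geometry (64 channels × 2560
samples at 256 Hz) with a class difference carried by nonlinear dynamics:

    x[t] = mix·c[t] + (1 − mix)·g[t] + noise_sd·w[t]

where c is the standardized first coordinate of the Hénon map (a = 1.4,
b = 0.3, ≥ 1000 burn-in steps, random initial condition near the origin),
g is standardized AR(1) noise with φ = 0.9 (a cheap stand-in for EEG's
red spectrum), w is white measurement noise (sd 0.05 by default), and the
channel is re-standardized. Mixing weights default to 0.2 (class 0) vs
0.8 (class 1). The Hénon map was chosen because its CD (≈ 1.2) is well
characterized, giving the estimator a known-answer test. Seeding: record
i draws from `default_rng([seed, i])`, so realizations never depend on
how many records are requested.

What this does *not* emulate: band structure (alpha/beta rhythms),
event-related potentials, artifacts, inter-channel correlation, or
non-stationarity. Consequently the class signal is purely a *level shift*
in windowed CD (higher chaotic weight → lower CD), stationary in time.
Two implications for interpreting green tests: (1) pipeline accuracy here
says the machinery recovers a CD-mediated class difference, not that real
alcoholic EEG is this separable; (2) the distance-correlation metric —
being invariant to translation of either sample — cannot see a pure level
shift, so on this generator its template features carry no out-of-sample
signal and magnitude metrics (Chebyshev, city-block) are the informative
ones. The pipeline default metric is therefore Chebyshev; distance
correlation remains fully implemented and is the right choice when
classes differ in the *shape* of the window profile rather than its
level.

`generate_feature_dataset` draws class-conditional Gaussians with
compound-symmetric covariance (equicorrelation ρ, via a shared factor)
and mean shift δ — the standard stress input for multicollinearity:
ρ = 0.95 makes unpenalized least squares ill-conditioned while the class
signal stays fixed.

## Feature selection

Per channel, the class-0 training records define a template (the mean CD
window-vector). Every record's channel is summarized by its dissimilarity
to that template — 1 − dCor (Székely double-centering construction),
city-block, Chebyshev, or cosine distance — and channels are ranked by
the training separation score |mean distance in class 1 − mean distance
in class 0|, keeping the top k (default 32, matching the 32-input
classifier configurations). Rank ties break toward the lower channel
index. The selector is fit on training folds only; templates and the
channel set are frozen before any test record is transformed, so test
labels are never consulted. Constant vectors make dCor undefined; the
selector treats them as carrying no dependence (dissimilarity 1).

Targets: class 0 → 0.0, class 1 → 1.0; continuous outputs decode to
class 1 when ≥ 0.45. The 0.45 threshold is consumed as a constant of the
method; the ≥ convention at the boundary is a documented choice.

## Boosting

**Standard Adaboost.RT** (ψ = 0.2, c = 1, Z = 50 defaults): per round,
fit the weak learner on the current distribution D, compute absolute
relative errors |(pred − y)/y| (absolute error when |y| < 1e−12),
ε_z = D-mass of samples with ARE > ψ, β_z = ε_z^c, multiply correct
samples' weights by β_z and renormalize. Prediction is the
log(1/β_z)-weighted mean of weak outputs. ε_z is floored at 1e−10 and
clipped below 1 so exactly-fit or degenerate rounds keep finite votes.
The default weak learner is near-OLS ridge (λ = 1e−6, a pure
singularity guard).

**Modified Adaboost.RT** (λ_rel = 0.5, λ_pen = 1.0, Z = 50 defaults):
per round, fit a ridge or lasso weak learner on the current distribution;
form the residual signal r = prediction − target and soft-threshold it,
treating r as a noisy observation of the genuine misfit: T is the
MAD-based universal threshold `MAD(r)/0.6745 · sqrt(2 ln n)` (or a
constant via `threshold_rule=("constant", T)`). Noise-level residuals
collapse to exactly 0; the surviving denoised errors e enter the robust
band: samples with |e − ē| > λ_rel·σ(e) are rejected, ε_z is their
probability mass, β_z = ε_z/(1−ε_z), α_z = −log β_z, rejected samples'
weights are multiplied by β_z, and a round with ε_z > 1/2 is rolled back
and terminates the loop (an error if it is the first round). Final α are
normalized to sum to 1 and the ensemble output is their convex
combination of weak outputs.

Two design points deserve emphasis:

- *What gets soft-thresholded.* Applying the universal threshold to the
  raw predictions (scale ≈ the 0–1 target coding) zeroes the entire
  class-1 signal, makes the round errors bimodal, and puts more than half
  the mass outside ±λσ for every λ in (0, 1) — the algorithm would reject
  its first round on any realistic data. Denoising the *residual* signal
  preserves the intended semantics (detect genuine misfit against
  Gaussian noise) and makes the λσ band meaningful; this is the
  implemented default.
- *Weight-update direction.* The update multiplies **rejected** samples'
  weights by β_z < 1, i.e. down-weights high-error samples — opposite to
  classic AdaBoost emphasis. It is implemented in that printed form;
  `classic_emphasis=True` selects the complementary update
  (down-weighting accepted samples) for comparison.

Weak-learner objectives: weighted ‖b − Aβ‖² + λ_pen‖β‖² (ridge, closed
form, unpenalized intercept; λ_pen = 0 is weighted OLS and raises on
singular systems) and weighted ‖b − Aβ‖² + λ_pen‖β‖₁ (lasso,
covariance-update coordinate descent, convergence when the largest
coefficient change in a sweep < 1e−8 or after 10⁴ sweeps, warm-started
across boosting rounds). Inside the boosting loops the round distribution
(summing to 1) is rescaled to sum to n before the weak-learner call — the
glmnet weight convention — so λ_pen = 1.0 sits on the familiar scale of
an unweighted n-sample fit. On an orthonormal centered design the lasso
solution equals soft-thresholding of the OLS coefficients at λ_pen/2,
which the tests verify along with agreement with an independent
coordinate-descent implementation.

## Baselines

Random forest: sklearn's Gini forest (bootstrap multisets of size N,
msub = ⌈√M⌉ random features per split, trees grown pure), with the
bootstrap indices reproduced exactly for out-of-bag accounting; OOB error
predicts each record only with trees whose bootstrap excluded it and
averages over records with at least one such tree. KNN (K = 4, Euclidean,
vote ties broken toward the single nearest neighbor), Gaussian naive
Bayes (variance floor 1e−9) and Lloyd's K-means (centroid-shift
tolerance 1e−8, 300 iterations, clusters labeled by training majority)
are written out directly so their tie-break and flooring rules are exactly
as documented — K-means in particular exposes its per-iteration
within-cluster SSQ, whose monotone decrease is property-tested. The RBF
network (centers from K-means, shared width = mean center distance,
ridge-solved linear output), MLP (64 tanh hidden units, logistic output)
and SVMs (linear, degree-1 polynomial, RBF γ = 2.0; support-vector
regression on the 0/1 targets) delegate to scikit-learn optimizers behind
the common fit/predict surface. γ = 2.0 presumes features on a compact
[0, 1]-like scale — the scale of the distance features it is configured
for.

## Evaluation

PC, MC, FA are percentages of the full test set (correct, missed
positive, false positive) and partition 100% — the only reading under
which all the derived scores are simultaneously well-behaved. The derived
scores divide these percentages (PI, Sens, Spec, GDR as in the README);
they are deliberately *not* the conventional TPR/TNR, and Accuracy is
always exactly (Sens + Spec)/2 — the test suite verifies this identity
against 36 published sensitivity/specificity/accuracy triples at printed
precision. PI is undefined (reported missing) when PC = 0. MSE compares
continuous classifier outputs with the encoded targets over the
evaluation set. Cross-validation is stratified k-fold (default 10),
shuffled under the report's seed, with selectors and models refit per
fold; fold averages use NaN-aware means so an undefined PI in one fold
does not poison the summary.

## Problem sizes

The shipped tests and the acceptance script run entirely on synthetic
data at the sizes the generators default to: one full-size record
(64 × 2560) for the structural check, 2000–5000 points for the known-
dimension checks, 40 records per class for the end-to-end pipeline, and
20 seeds × 200 × 32 features for the multicollinearity comparison. These
sizes make every result reproducible on a single CPU in minutes while
keeping each quantity in its asymptotic regime (the CD bands and CV
accuracies quoted are stable across seeds).

## Known limitations

- Window-level CD at Q = 9 points is a very coarse estimate; the
  pipeline's validity rests on aggregate separation, not per-window
  accuracy.
- The 16384 → 32 reduction is one defensible scheme (channel templates +
  separation ranking) among several; alternative pairings are left to
  configuration rather than explored exhaustively.
- The printed-form weight update makes the modified booster's rounds
  nearly independent when few samples are rejected; with ε at the floor
  the ensemble degenerates gracefully to (near-)equal votes over
  identical learners.
- No Theiler-window correction for temporally correlated embeddings, no
  maximum-likelihood CD estimators, and no surrogate-data nonlinearity
  tests; the diagnostics module is descriptive only.
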