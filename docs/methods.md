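# Methods

## The classification framework

`bvfusion` classifies subjects into two groups from parcellated
resting-state fMRI time-series matrices `X ∈ R^{T×R}` (rows = time
points, columns = ROIs; the reference configuration is T = 170,
R = 116). The pipeline has four stages.

**1. Per-ROI features.** Each ROI column is summarised by seven
scalars: mean, unbiased variance, population skewness, excess
(Fisher) kurtosis, the energy of the slowest variational mode (VMD),
the amplitude of low-frequency fluctuations (ALFF), and sample
entropy. Each feature type yields one vector of length R per subject.
ROI screening then keeps, per feature type, the ROIs whose two-sided
Welch two-sample t-test between groups (training subjects only) has
p below a threshold tuned on an inner cross-validation grid
{0.01, …, 0.05}; if none pass, the single minimum-p ROI is kept and
flagged.

**2. Margin classifiers.** One linear SVM per feature type is fit on
the screened feature vectors. A training point's labelled geometric
margin is r_i = y_i (w·x_i + b)/‖w‖₂; a test point uses the
unlabelled signed distance (w·x + b)/‖w‖₂, whose sign is the
predicted side. Margins become signed probabilities through the odd
sigmoid s = sign(r)/(1 + e^{−|r|}), so |s| ∈ (1/2, 1) off the
boundary and s(0) = 0 (a boundary point carries no class evidence).
The labelled form is kept for training points — where the label is
known, a negative margin means "misclassified", which is exactly the
information the belief-value needs — while test points, whose labels
are unknown, use the predicted-sign form.

**3. Belief-values.** For a test sample x, the training points on
x's predicted side act as its neighbour set NN (the whole side, no
k cutoff). Their distances to x (Euclidean, Manhattan, or
Mahalanobis under the shrinkage-regularised training covariance) are
z-scored using the population SD of the distance set, mapped through
the standard-normal density to weights w_j ∈ (0, φ(0)], and each
neighbour contributes an effect f_j = w_j·s_j (ablations: f_j = s_j,
distance information alone; f_j = w_j·sign(s_j), local-density
information alone). The belief-value B−V is the arithmetic mean of
the effects; its sign is the per-feature prediction, its magnitude a
per-sample confidence bounded by φ(0) ≈ 0.3989 in the product mode.
If the predicted side holds no training points (possible in tiny
inner folds), B−V falls back to the sample's own margin probability
and the event is logged.

**4. Fusion.** The seven belief-values F = [B−V₁ … B−V₇] are fused
by (a) majority voting over component signs, ties broken toward the
largest |B−V|; (b) a linear SVM on F; or (c) an MLP with two tanh
hidden layers of five units and a linear output trained under squared
error, which can exploit non-linear complementarity between feature
types.

## Evaluation protocol

Stratified k-fold outer cross-validation repeated several times
(reference protocol: 10 folds, with 10 repeats in the full protocol
and 3 in the synthetic study below). Within each outer training set,
an inner stratified CV jointly selects the screening p-threshold and
the SVM C (log grid 0.01–100) per feature type by maximising
held-out belief-value accuracy. Final models are refit on the outer
training set; the fuser is trained on out-of-fold belief vectors of
the training subjects (resubstitution belief values are available
behind `fusion_train_bv="resubstitution"` but are optimistically
biased). Metrics treat the control group (+1) as the positive class:
ACC, SEN, SPE, PPV, NPV and F1 from pooled confusion counts, with
mean ± SD across repeats; zero-denominator rates are reported as
missing rather than zero. ROI-selection tallies across the outer
folds give per-feature ROI frequencies.

Leakage is controlled structurally — screening, tuning, covariance
estimation and fusion training take only training data — and audited
by a canary test: perturbing a held-out subject leaves every model
trained in its fold bit-identical.

## Synthetic cohorts

The generator emulates a two-group cohort of parcellated rs-fMRI
matrices. The control-like group (+1) is stationary AR(1) Gaussian
noise per ROI (unit innovation SD; coefficient 0.3, a mild temporal
autocorrelation giving non-trivial spectra); the patient-like group
(−1) additionally carries, on a declared ROI subset only: an additive
mean shift, a multiplied innovation variance, and an added in-band
sinusoid (default 0.05 Hz at TR = 2 s). Each effect targets a feature
family — the shift drives the mean, the variance ratio drives
variance/entropy, the oscillation drives ALFF/VMD — so recovery can
be checked feature by feature. Per-subject random substreams are keyed
by (group, index): enlarging the cohort never reshuffles existing
subjects.

The reference study cohort (`bvfusion.study`) uses 46 subjects per
group, a 10-ROI affected subset, mean shift 2.0 (2× the innovation
SD, matching the magnitude used in the screening power checks),
variance ratio 2.0 and oscillation amplitude 1.5. These conditions
make three feature families clearly informative, which is what the
end-to-end claim — fusion preserves and combines single-feature
signals — needs; they are deliberately favourable and say nothing
about effect sizes in real clinical data. The generator has no
hemodynamics, scanner artifacts, head motion or site effects, so
passing tests demonstrate correctness of the pipeline, not expected
performance on real cohorts.

## Numerical choices

- **Mahalanobis distance** uses the full-training-set covariance
  (per-side estimates would be rank-deficient near n = 45) plus a
  ridge of `shrinkage × (trace/dim) × I`, shrinkage 0.01.
- **Distance z-scoring** divides by the population standard deviation
  of the distance set; an all-equal set maps to all zeros.
- **VMD** is the classic ADMM scheme (mirror extension, analytic
  half-spectrum, Wiener-filter mode updates, spectral-centroid
  frequency updates), defaults K = 4 modes, bandwidth penalty 2000,
  convergence tolerance 1e−7 with a 2000-iteration cap (exceeding it
  raises; typical broadband series converge within a few hundred
  iterations). The per-ROI scalar is the variance of the
  lowest-centre-frequency mode, the closest spectral analogue of a
  slow-fluctuation energy. Known degeneracy: at large penalties a
  lone pure tone can be duplicated across modes with its energy
  split; this does not affect energy totals and is invisible to the
  slow-mode-energy feature on broadband signals.
- **ALFF** is the mean of the amplitude spectrum (square root of the
  periodogram) over 0.01–0.08 Hz, DC excluded, demeaned input.
- **Sample entropy** uses m = 2, tolerance 0.2 × SD, Chebyshev
  matching over the first T−m templates at both lengths, self-matches
  excluded. An undefined estimate (zero match count) returns a
  sentinel that `build_feature_sets` replaces with the largest finite
  sample entropy in the cohort, logged.
- **MLP fusion** is trained with L-BFGS (full-batch, deterministic
  given its seed) under an iteration cap of 2000 and tolerance 1e−6.
  L-BFGS was chosen over plain full-batch gradient descent because it
  needs no learning-rate tuning on a 7-dimensional input and
  converges in seconds; no input scaling is applied (belief-values
  are already bounded by φ(0)).
- **Ties**: a belief-value of exactly 0 classifies to the SVM's
  predicted side; a zero majority-vote sum defers to the component
  with the largest magnitude; inner-CV accuracy ties prefer the
  smaller p-threshold, then the smaller C.

## Problem sizes used in validation

The automated checks run the full pipeline at the reference cohort
size (92 × 170 × 116) with 3 repeats of 10-fold outer CV and 5-fold
inner tuning over the full 5 × 5 hyperparameter grid, averaged over
5 master seeds; screening calibration uses 200 null and 100
shifted cohorts; oracle equivalence uses 200 random instances across
all three metrics and all three effect modes. `scripts/acceptance.py`
repeats the reference study once for a given seed.

## Known limitations

- Belief-value normalisation statistics (μ, σ) come from the test
  sample's own distance set, not pooled training-pair distances; with
  very few neighbours the z-scores are coarse.
- Majority voting cannot in general match the best single classifier
  when most components are uninformative (a one-informative-vote
  majority is capped by the binomial noise of the other votes); the
  trainable fusers do not share this cap.
- The pipeline assumes balanced-ish two-class cohorts; stratified
  folds require each class to have at least `n_folds` members.
- Sample entropy is O((T−m)²) per series; fine at T ≈ 170.
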