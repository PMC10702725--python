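# bvfusion

Belief-value multi-classifier fusion for two-group classification of
parcellated resting-state fMRI time series.

## The problem

Given per-subject ROI time-series matrices `X ∈ R^{T×R}` (rows = time
points, columns = atlas parcels; typically 170 × 116) and a binary
diagnosis label, single-feature classifiers leave information on the
table: different summaries of the signal (moments, spectral amplitude,
complexity) are discriminative for different subjects. `bvfusion`
trains one linear SVM per feature type and fuses them through
**belief-values** — per-sample confidence scores that combine two
sources of evidence:

- *distance information*: each training neighbour's signed margin
  probability `s = sign(r)/(1 + e^{−|r|})`, where
  `r = y (w·x + b)/‖w‖₂` is its geometric margin;
- *local density information*: a Gaussian weight `w_j = φ(d′_j)` of the
  neighbour's z-scored distance `d′_j = (d_j − μ)/σ` from the test
  sample (Euclidean, Manhattan or shrinkage-regularised Mahalanobis).

The belief-value is the mean neighbour effect
`B−V = mean_j(w_j · s_j)` over all training points on the test
sample's predicted side of the hyperplane; its sign is the per-feature
prediction and its magnitude a per-sample confidence. The seven
belief-values `F = [B−V₁ … B−V₇]` are fused by majority voting, a
linear SVM, or a small MLP (two tanh hidden layers of five units) that
captures non-linear complementarity between the feature types.
Evaluation uses repeated stratified nested cross-validation with
inner-loop tuning of the ROI-screening p-threshold and the SVM C.

The seven per-ROI features: mean, variance, kurtosis, skewness, the
energy of the slowest variational mode (VMD), the amplitude of
low-frequency fluctuations (ALFF, 0.01–0.08 Hz), and sample entropy.
A synthetic-cohort generator with planted group effects (mean shift,
variance ratio, low-frequency oscillation amplitude) makes every stage
testable without any imaging data; see `docs/methods.md` for the model
and its assumptions.

## Worked example

Simulate a 30-subject cohort with three effects planted on ROIs 0–4,
extract features, and evaluate with MLP fusion:

```bash
cat > cohort.yaml <<EOF
n_per_group: 15
n_timepoints: 120
n_rois: 30
affected_rois: [0, 1, 2, 3, 4]
mean_shift: 2.0
var_ratio: 2.0
osc_amplitude_delta: 1.5
EOF
cat > cv.yaml <<EOF
outer_folds: 5
repeats: 2
inner_folds: 3
p_grid: [0.01, 0.05]
c_grid: [0.1, 1.0, 10.0]
fusion_method: mlp
EOF
bvfusion simulate --config cohort.yaml --out cohort_dir --seed 7
bvfusion extract  --cohort cohort_dir/cohort.csv --out features_dir
bvfusion evaluate --cohort cohort_dir/cohort.csv --config cv.yaml \
                  --out report.json --metrics-tsv metrics.tsv --seed 7
```

which prints

```
wrote 30 subjects to cohort_dir/cohort.csv
wrote 7 feature matrices to features_dir
mlp fusion accuracy: 100.00 +/- 0.00 % over 2 repeat(s)
metric table written to metrics.tsv
top ROI (index, frequency) per feature: {"mean": [0, 1.0], "variance": [0, 1.0],
 "kurtosis": [3, 0.5], "skewness": [14, 0.3], "vmd": [2, 0.7], "alff": [0, 1.0],
 "sampen": [4, 0.8]}
```

and `metrics.tsv` holds the per-method table (mean ± SD over repeats):

```
method            acc           sen           spe
mean              100.00±0.00   100.00±0.00   100.00±0.00
kurtosis          51.67±5.00    50.00±10.00   53.33±0.00
skewness          26.67±3.33    30.00±3.33    23.33±3.33
vmd               60.00±3.33    70.00±10.00   50.00±3.33
alff              100.00±0.00   100.00±0.00   100.00±0.00
sampen            61.67±1.67    56.67±3.33    66.67±0.00
fused_majority    95.00±1.67    90.00±3.33    100.00±0.00
fused_linear_svm  100.00±0.00   100.00±0.00   100.00±0.00
fused_mlp         100.00±0.00   100.00±0.00   100.00±0.00
```

Reading it: the planted mean shift, variance ratio and oscillation make
the mean, variance and ALFF features individually perfect on this easy
cohort, while kurtosis and skewness carry no signal (near-chance); the
trainable fusers preserve the dominant signals at 100%, and majority
voting loses a few points because the uninformative features out-vote
the informative ones for some subjects. The "top ROI" line shows the
screening frequency tally — the informative features select planted
ROIs in every outer fold (frequency 1.0).

The same works in Python:

```python
from bvfusion import CohortSpec, generate_cohort, run_nested_cv, CVConfig

cohort = generate_cohort(CohortSpec(n_per_group=15, n_rois=30,
                                    affected_rois=(0, 1, 2), mean_shift=2.0))
report = run_nested_cv(cohort, CVConfig(outer_folds=5, repeats=2, inner_folds=3))
print(report.summarize())          # fused metrics, mean ± SD over repeats
print(report.aggregate(feature="alff").acc)  # single-feature pooled accuracy
```

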