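# epshar

Feature extraction, dimensionality reduction and classification for
wearable-sensor human activity recognition (HAR): **enveloped power
spectrum (EPS)** features, **Fisher linear discriminant analysis (LDA)**
reduction, and a **one-against-all multiclass SVM** with a Gaussian RBF
kernel, together with the evaluation protocol (stratified splits, k-fold
cross-validation, feature-count sweep) and a seeded synthetic IMU signal
generator so the whole pipeline is testable without downloading any
dataset.

It is aimed at researchers working with windowed inertial recordings
(3-axis accelerometer + 3-axis gyroscope, e.g. the public UCI-HAR layout:
128-sample windows at 50 Hz) who want a transparent, classical baseline
pipeline with deterministic, reproducible artifacts.

## The model

For a window, channels are concatenated into one sequence `y[n]` of
length N (6 × 128 = 768 for the standard smartphone layout). The EPS
feature vector is the one-sided periodogram of the amplitude envelope:

    e[n]   = |y[n] + j·H{y}[n]|            (analytic-signal envelope)
    I_N(ω) = |DFT(e)(ω)|² / N              (periodogram)

keeping bins 0..N/2 after zero-padding odd N to even, so 768 samples give
385 spectral points and 303 samples give 153.

Supervised reduction uses Fisher LDA on the spectra: with within-class
scatter `S_w = Σ_k Σ_{n∈C_k} (x_n−m_k)(x_n−m_k)ᵀ` and between-class
scatter `S_B = Σ_k N_k (m_k−m)(m_k−m)ᵀ` (so `S_T = S_B + S_w`), the
projection rows solve `S_B w = λ (S_w + εI) w`, sorted by λ descending;
"top-k features" means the first k coordinates of `y = Wx`.

Classification is one-against-all: one soft-margin binary SVM per class
on standardized reduced features with kernel
`k(xa,xb) = exp(−‖xa−xb‖²/(2γ²))`; the predicted class maximizes the
per-class decision value.

## Worked example

```python
import epshar

# 5 synthetic activity classes (3 postures + walking + stair climbing),
# 200 windows each, 128 samples at 50 Hz
dataset = epshar.generate(epshar.default_spec(5, 200, 128, seed=1))
train, test = epshar.split_train_test(dataset, 0.5, stratified=True, seed=1)

fitted = epshar.fit_pipeline(train, epshar.PipelineConfig(n_features=5), seed=1)
report = epshar.evaluate_pipeline(fitted, test)
print(f"top-5 accuracy: {report.accuracy:.3f}")

sweep = epshar.feature_sweep(train, test, seed=1)
for row in sweep.rows:
    print(row["n_features"], f"{row['accuracy']:.2f}")
```

prints

```
top-5 accuracy: 0.996
5 99.60
10 93.20
15 87.60
20 81.40
25 81.20
30 74.40
35 73.60
40 72.60
all 21.20
```

Five discriminant coordinates carry essentially all class information
(99.6 % test accuracy); adding higher-order directions — eigenvectors of
the near-null between-class eigenspace — dilutes the representation with
noise until the all-features classifier collapses. The same inverse
relation between feature count and accuracy is the pipeline's
characteristic behaviour on real HAR data.

The same chain is scriptable:

```sh
epshar simulate --seed 1 --out ds.csv
epshar extract  --dataset ds.csv --out features.csv
epshar train    --seed 1 --dataset ds.csv --out-lda lda.json --out-svm svm.json
epshar evaluate --dataset ds.csv --model-lda lda.json --model-svm svm.json --out report.json
epshar sweep    --train train.csv --test test.csv --out sweep.csv
epshar cv       --dataset ds.csv --k 3 --out cv.json
```

Every artifact embeds the resolved-config hash and seed; reruns with the
same config reproduce all numbers exactly. Real UCI-HAR-layout data loads
with `epshar.read_ucihar_inertial` (whitespace-delimited channel files +
label file) and flows through the identical pipeline.

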