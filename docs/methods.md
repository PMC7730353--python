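# Methods

## Pipeline

The package classifies fixed-length windows of multi-channel inertial
data in three stages: enveloped-power-spectrum (EPS) feature extraction,
Fisher LDA reduction, and a one-against-all (OAA) multiclass SVM with a
Gaussian RBF kernel. All data-dependent state — discriminant projection,
feature scaler, kernel width, support vectors — is estimated from
training windows only; cross-validation refits every stage inside each
training fold.

## EPS feature extraction

Channels are concatenated (default order: accelerometer x, y, z then
gyroscope x, y, z; configurable) into one sequence of length N. The
amplitude envelope is the magnitude of the FFT-based analytic signal —
the standard envelope-spectrum construction from machine condition
monitoring, which demodulates quasi-periodic activity signatures
independent of carrier phase. The feature vector is the one-sided
periodogram `I_N(ω) = |DFT|²/N` of the envelope.

Numerical conventions:

* **Odd lengths are zero-padded by one sample** before the FFT, so the
  one-sided bin count is `⌊(N + N mod 2)/2⌋ + 1`: 768 → 385 features,
  303 → 304 → 153. This is the unique even-padding convention consistent
  with both of those published dimensionalities.
* **Scaling is exactly 1/N** with a straight one-sided truncation (no 2×
  energy correction). Downstream LDA is insensitive to a global scale, so
  only internal consistency matters; under this scaling Parseval's
  identity `Σ I_N = Σ y²` holds bin-exactly and is property-tested.
* **No taper, no detrending, DC kept.** Static postures differ chiefly
  in their gravity components, which live at and near DC; removing the
  mean would discard the most discriminative information for them.
* The envelope step can be disabled (`envelope_enabled=False`) for
  sensitivity analyses; the default pipeline keeps it.

The biased sample autocorrelation `R(n) = (1/N) Σ_k y[n+k] y[k]` (zero
for |n| ≥ N) is exposed alongside; the test suite verifies the
Wiener–Khinchin correspondence between the periodogram and a brute-force
O(N²) autocorrelation oracle on zero-padded signals.

## Fisher LDA

Scatter matrices follow the textbook unnormalized definitions
(`S_T = S_B + S_w` is asserted as an invariant). The projection solves
the symmetric-definite generalized eigenproblem
`S_B w = λ (S_w + εI) w` via `scipy.linalg.eigh`, whose eigenvectors are
(S_w+εI)-orthonormal.

Open design points, resolved as follows:

* **All `input_dim` directions are returned**, not only the K−1 with
  nonzero between-class rank. The feature-count sweep goes up to 40 and
  "all" features, which a strict K−1 truncation could not serve; the
  trailing directions have near-zero eigenvalues and behave as noise,
  which is exactly the degradation the sweep measures.
* **Regularization** defaults to the scaled ridge ε = 1e-6·tr(S_w)/d.
  S_w is singular whenever d > N − K, the usual case for 385-dim spectra
  with a few hundred training windows. ε = 0 is honoured only when S_w
  is positive definite; otherwise fitting aborts with instructions.
* **Determinism**: eigenvalues are sorted descending; each direction's
  sign is fixed so its first non-negligible component is positive; rows
  are unit-normalized after sign fixing. This makes "top-k features"
  well defined across linear-algebra backends.

A known discrepancy: the source material for this pipeline reports LDA
output sizes of 49 and 123 for 153/385-dim inputs, which no standard LDA
construction reproduces with 10 or 5 classes; those sizes are therefore
not targeted. Likewise a stray reference to wavelet (DWT) coefficients
as the LDA input is treated as editorial; the implementation feeds EPS
spectra to LDA.

## OAA RBF SVM

The kernel is `exp(−‖xa−xb‖²/(2γ²))` — the printed formula omits the
minus sign, which would make the "Gaussian radial basis" kernel
unbounded, so the sign is restored. Features are standardized with
training-set mean and standard deviation (zero-variance features get
unit scale) before the kernel; spectrum magnitudes span orders of
magnitude and an RBF width is unusable without this.

The binary subproblems are delegated to scikit-learn's `SVC`
(`gamma_sklearn = 1/(2γ²)`); the OAA architecture, scaling, kernel
convention, argmax aggregation with lowest-id tie-breaking, and a
pure-JSON serialization (support vectors, dual coefficients, intercepts,
scaler) are implemented here. Decision values are always computed from
the extracted support-vector form, so serialized and in-memory models
are bit-identical; a test cross-checks this evaluation against
`SVC.decision_function`.

No hyperparameters are published for this pipeline; defaults are
γ = median pairwise distance of a seeded ≤ 500-row training subsample
(median heuristic) and C = 1.0, both exposed in `SvmConfig` together
with an `inverse-dim-variance` mode matching scikit-learn's `scale`
convention.

## Evaluation protocol

Per-class Tp/Fp/Fn/Tn come from the confusion matrix (rows = truth);
accuracy = trace/total; precision, recall and F1 use the 0/0 → 0
convention. Macro (unweighted class mean) and micro (pooled counts)
averages are both always computed; reports default to macro. The choice
is deliberately surfaced because published HAR tables often mix
conventions — micro precision identically equals accuracy for
single-label problems, an identity the tests assert.

Splitting is seeded and stratified (per-class train count =
round(fraction·N_k), half-up). Cross-validation offers two modes:
`rotating` (standard k-fold, metrics averaged over folds; the default)
and `single-split` (train on folds 1..k−1, test fold k only), because
"first folds for training, last for testing" descriptions of 3-fold CV
are ambiguous between the two. Folds are stratified by round-robin
dealing within class, so balanced classes give exactly equal folds.

The feature-count sweep fits EPS+LDA once on the training set, then
retrains the SVM at each count in {5, 10, ..., 40, all} and reports
percentage metrics in that table structure (2-decimal CSV formatting).

## Synthetic data generator

The generator emulates waist-mounted smartphone IMU recordings: 6
channels at 50 Hz (defaults), fixed-length windows, C classes. Static
postures are a constant 1 g gravity vector along a class-specific
orientation plus Gaussian noise (default sd 0.05 g); dynamic activities
add an amplitude-modulated oscillation (default amplitude 0.4 g,
modulation depth 0.3, modulator at a quarter of the fundamental) at a
class-specific fundamental in the human-gait band, projected on a
per-window random axis with per-window random phase. Gyroscope channels
carry 5-point-smoothed Gaussian noise (sd 0.05 rad/s) plus, for dynamic
classes, the oscillation's time derivative scaled by 1/(2πf) to keep
rad/s-scale magnitudes. The 5-class default mirrors the common
smartphone-HAR class list: laying, sitting, standing, walking
(1.0 Hz), stair climbing (2.0 Hz); dynamic fundamentals are pairwise
separated by ≥ 0.5 Hz for every class count.

Static orientations are chosen with *distinct per-channel gravity
magnitude patterns* ((0,0,1), (0.8,0,0.6), (0.36,0.8,0.48)) rather than
axis permutations: after channel concatenation the power spectrum is
nearly blind to which channel carries the gravity block, so permuted
orientations would be (realistically but unhelpfully) inseparable. Real
postures differ by non-trivial device tilts, which this reflects.

One `numpy` Generator seeded per dataset is consumed class-major,
window-major, with a fixed per-window draw order (phase, movement axis,
accelerometer noise, gyroscope noise — drawn for static windows too, to
keep the stream layout uniform), so identical specs give bit-identical
datasets.

What the generator does **not** emulate: biomechanical gait harmonics,
sensor bias/drift, orientation changes within a window, inter-subject
variability, and class imbalance. Passing the end-to-end separability
test therefore demonstrates that the pipeline's stages compose correctly
and that its discriminative mechanism (DC gravity signatures + envelope
fundamentals) works — not that real-data accuracies are reproduced.

## Study sizes and runtime

The end-to-end study conditions are 5 classes × 200 windows of 128
samples (1000 windows, 50/50 stratified split), chosen to match the
standard smartphone window geometry while keeping the full sweep
(9 SVM retrains) around a second on one CPU. Published headline
accuracies on the real UCI-HAR and DU-MD datasets (98.67 %, 100 %,
99.73 % under 3-fold CV) require downloading those datasets and depend
on unreported hyperparameters and averaging conventions; the CLI and the
UCI-HAR reader support running those experiments, but they are not part
of the test surface and no numeric replication of them is claimed.

## Known limitations

* The envelope mechanism (analytic signal) is a design choice; the
  source text names the enveloped power spectrum without specifying the
  envelope construction. The flag to disable it exists for exactly this
  sensitivity question.
* LDA directions beyond K−1 are numerically arbitrary within the
  near-null between-class eigenspace; only their (near-zero) eigenvalues
  are meaningful, so tests compare subspaces/leading directions rather
  than trailing eigenvectors.
* The portable CSV container stores window values and integer labels
  only; class and channel names are carried by the CLI's JSON sidecars.
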