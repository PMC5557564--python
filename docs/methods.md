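# Methods

## Problem setting

A pattern-recognition controller for a multi-grip hand prosthesis must run
on a microcontroller with a few hundred kilobytes of memory. The package
benchmarks four gesture classifiers on multi-channel surface-EMG (sEMG)
envelope signals under exactly that constraint: nonlinear logistic
regression on polynomial features (NLR), a multi-layer perceptron (MLP), an
RBF-kernel support vector machine (SVM), and linear discriminant analysis
(LDA) on windowed time-domain features as the benchmark. The raw-signal
branch (NLR/MLP/SVM) classifies each scaled sample directly; the LDA branch
follows the classical feature pipeline. Selection combines classification
performance (F1Score) with the memory footprint of the trained model
through a single index (EOF).

## Signal model of the synthetic cohort

No public dataset accompanies the protocol, so a seeded generator emulates
its statistical structure. A session is 5 gesture classes x 10 repetitions
x 2 s at 1 kHz on 6 channels (10^5 x 6 samples), class-major, with each
(class, repetition) block

    x[t, c] = m[g, c] + a sin(2 pi f t + phi_r) + n[t, c],

clipped to the 0-5 V sensor range. `m` is the per-gesture channel
activation pattern (packaged default: "Rest" near the 0.3 V baseline, each
grasp loading a distinct flexor/extensor channel subset); the sinusoid
(f = 0.5 Hz, amplitude `within_rep_jitter` = 0.1 V, random phase per
repetition) models slow within-repetition drift; `n` is Gaussian white
noise shaped by a single-pole low-pass at `noise_bandwidth` = 10 Hz and
rescaled to `noise_sd` = 0.25 V, matching the smooth envelope output of
commercial active sEMG sensors. A `separability` factor scales between-class
mean differences about the grand mean; per-subject variability adds a
seeded Gaussian shift (sd 0.15 V) to every (class, channel) mean.

What the generator does *not* emulate: raw (unrectified) EMG spectra,
inter-stimulus rest gaps (never sampled in the protocol), motion artifacts,
electrode shift, or residual-limb anatomy. Its classes are
near-Gaussian with approximately equal covariance, so a **linear boundary
is close to Bayes-optimal**: complexity selection on this cohort correctly
plateaus at the simplest levels, and passing tests show that the pipeline's
mechanics are right, not that nonlinear classifiers would win on clinical
data.

## Preprocessing and the set protocol

Raw-branch scaling is per channel: subtract the mean, divide by the range
(max - min); a zero-range channel is an error. Scaling statistics are
fitted on the downsampled pool and applied unchanged to the generalization
set, which avoids test-set leakage while keeping one affine map per
session. Downsampling by step `s` keeps rows at indices = 0 (mod s)
(phase 0, deterministic); the kept pool is split 60/20/20 into TR/CV/TS and
the discarded rows form GS, so step 10 gives 6/2/2/90 percent. The split is
stratified: per-class seeded shuffles with largest-remainder allocation hit
the global 60/20/20 sizes exactly while keeping every per-class count
within one sample of proportionality. (The protocol's "random shuffle until
proportionated" is implemented constructively; a global-reshuffle rejection
loop would essentially never meet a 1-sample tolerance at realistic n.)

The LDA branch extracts, per channel, MAV, RMS, slope-sign changes (SSC),
waveform length and unbiased variance on 250 ms windows with 200 ms
overlap. Windows restart at every (class, repetition) boundary so no window
mixes gestures. SSC uses the Hudgins-style dead-zone rule (both adjacent
increments above 10 mV). Splitting is stratified 70/30.

## Classifiers

* **NLR** - one logistic unit per class (one-vs-all) on polynomial
  features. Degree code D maps to all distinct-variable products of size
  <= D plus pure powers x_i^d, d <= D (6, 27, 53, 74, 86, 93, 99 features
  for D = 1..7 on 6 inputs; D = 1 is plain logistic regression).
  Unregularized cross-entropy, minimized per class by RProp.
  Probabilities are used unnormalized (no softmax).
* **MLP** - logistic units throughout; equal-width hidden layers; one
  output per class; mean-squared-error cost over one-hot targets;
  backpropagation gradients; RProp; trained as a single multi-output net.
* **SVM** - soft-margin C-SVM with RBF kernel, one-vs-one, solved by the
  libsvm engine behind scikit-learn's `SVC`. The kernel exponent follows
  the |x - s|^2 / (2 gamma) convention with an explicit converter to the
  usual gamma' = 1/(2 gamma). Prediction is our own majority vote over the
  pairwise decision-value signs so the tie-break (lowest class index) is
  explicit. The stored model is the support vectors (nSV x dim), dual
  coefficients (nSV x (K-1)) and pairwise offsets (K(K-1)/2).
* **LDA** - closed form: class means, pooled within-class covariance
  (scatter / (n - K)), priors; score_c = (Sigma^-1 mu_c) . x
  - 0.5 mu_c' Sigma^-1 mu_c + ln Pi_c; argmax with lowest-index ties. A
  ridge of 1e-6 trace(Sigma)/dim is added when the condition number
  exceeds 1e12.

Decisions for all probabilistic classifiers: label = argmax over classes
with probability >= TH (default 0.5); when none clears TH the argmax is
still emitted with a low-confidence flag, because downstream F1 scoring
needs a label and the protocol defines no rejection class. Weight
initialization is uniform [-0.5, 0.5], seeded.

Parameter counts (the memory-relevant quantity) include biases:
NLR K(T+1); MLP sum_l (w_l w_{l-1} + w_l); SVM nSV·dim + nSV·(K-1)
+ K(K-1)/2; LDA K(d+1), e.g. 5 x 31 = 155 for 5 classes on 30 TD features.

## Optimization and model selection

RProp is the iRprop- variant: one step size per coordinate, grown by 1.2
while the partial derivative keeps its sign, shrunk by 0.5 on a flip (the
coordinate skips that iteration); delta in [1e-6, 50], initial 0.1. Only
gradient signs steer the path, so it is invariant to positive cost
rescaling. Stopping: iteration cap or |delta cost| below tolerance;
non-finite cost/gradient raises with the iteration index.

Grid search trains one model per internal-parameter configuration on TR and
scores macro-F1 on CV; ties go to the fewest parameters, then grid order.
The SVM plane (C doubling from 0.01 within 0-10^4 - 20 values - and gamma
in (0, 50] at pitch 0.1) is searched coarse-then-fine by default: a thinned
C sequence with a log-spread gamma subset, then refinement around the
winner at the full pitch; the exhaustive grids remain available. Gamma
excludes 0, where the kernel exponent is undefined.

The sequential complexity selection takes a subjects x levels F1 matrix
(levels ordered simplest first), keeps the simplest level as benchmark, and
promotes a level to benchmark whenever a paired two-sided Wilcoxon test
against the current benchmark is significant at alpha = 0.05; the final
benchmark is the last level with no significant difference to any
subsequent level. Cohorts below 6 subjects cannot support the test; the
runner then falls back to best-mean-F1 (simplest on ties) and records the
fallback.

## Scoring

F1 per class from the one-vs-rest confusion tallies, on a 0-100 scale; the
aggregate is the unweighted macro mean (robust to class-cardinality
imbalance, and the aggregation consistent with reporting one score for 5
classes). A class absent from both truth and prediction scores 0 with a
warning.

EOF (Embedding Optimization Factor): with N_max = floor(memory_bytes /
bytes_per_parameter) the largest storable parameter count,
P = (N_max - n) / N_max * 100 for n < N_max else 0, and EOF is the harmonic
mean of F1 and P (0 when either is 0; the 0/0 case is defined 0). The
default budget is 256 KB at 4 bytes per float; the budget arithmetic uses
decimal kilobytes as microcontroller datasheets do, giving N_max = 64,000.

Wilcoxon signed-rank: zero differences dropped (classical policy; all-zero
input returns p = 1 with a warning); exact two-sided p by enumerating all
2^n sign assignments of the (possibly tied) ranks for n <= 15, otherwise a
normal approximation with tie and continuity corrections. No
multiple-comparison correction, mirroring the per-pair alpha = 0.05 usage
of the protocol. Comparison reports carry boxplot-style summaries (mean,
sample std, median, quartiles, Tukey whiskers).

## Study runner and problem sizes

`run_study` executes the three parts with every stage seed derived from the
global seed plus stable integer keys (subject, step, classifier), making a
run bit-reproducible. Part 1 runs at the 100 Hz step only; part 2 sweeps
steps {200, 100, 50, 25, 10}; part 3 picks, per subject and classifier, the
step with the best EOF on GS and compares against the per-subject LDA
branch at full rate.

The default `StudyConfig` carries the protocol scale (30 subjects, degree
guesses 1-7, layer guesses 1-10, neuron grid {3, 8, 13, 18, 23, 28} - the
"vary by 5 up to 23" wording is ambiguous, so the grid is configurable).
`desk_scale_config` is the package's reduced operating point for the
`analysis/` drivers and interactive use: 8 subjects, degree grid 1-3,
layers 1-2, neurons {4, 8, 16}, a 4 x 4 coarse SVM stage and 200 RProp
iterations, at the full acquisition geometry; a complete three-part run
takes on the order of a minute per part on one core. Tests exercise the
same code paths at still smaller sizes.

## Known limitations

* The cohort's linear separability means model-complexity effects visible
  in clinical data (degree/layer gains, TS-vs-GS gaps) do not reproduce
  here; only their machinery is verified.
* The unnormalized one-vs-all probabilities are not calibrated; TH
  compares each against a fixed threshold as specified, nothing more.
* The SVM objective is the standard C-SVM dual as solved by libsvm;
  per-pair probability outputs, alternative kernels and regularized NLR are
  out of scope.
* LDA assumes a shared class covariance; the ridge handles
  ill-conditioning, not genuine rank deficiency from duplicated features.
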