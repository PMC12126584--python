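# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of `pdmotor`.

## Problem setting

Each observation is one performance of a prescribed motor task by one
patient: a tri-axial acceleration series at 50 Hz with a single clinical
annotation per symptom (tremor 0–4 on an ordinal scale, bradykinesia and
dyskinesia yes/no). Classification operates on fixed-length windows cut
from the recordings; every window inherits the recording's label. Because
patients contribute many windows with strongly patient-specific signal
characteristics, all data splits are grouped by patient — a window of a
test patient must never have a training neighbour from the same person.

## Synthetic cohorts

The generator replaces access-controlled clinical data with cohorts that
have the same statistical structure. Its defaults encode the study
conditions the pipeline assumes:

- sampling 50 Hz; recording durations truncated-normal with mean 29.2 s,
  S.D. 11.6 s, and a 5 s floor (the floor is this package's choice to
  avoid recordings shorter than any useful window);
- an 18-task ADL battery (drawing, nuts-and-bolts assembly, walking
  variants, typing, postural tasks, …), each task with a characteristic
  voluntary-motion frequency band and intensity;
- default symptom prevalences mirror the duration-weighted imbalance of a
  clinical cohort: tremor (0.675, 0.227, 0.076, 0.021, 0.001) across
  severities 0–4 — severity 4 is very rare — bradykinesia present in ~32 %
  and dyskinesia in ~11 % of recording time.

The signal model is additive on top of a constant gravity offset along a
random fixed sensor orientation:

- **voluntary motion**: Gaussian noise band-limited to the task's band
  (brick-wall mask in the rFFT domain — exactly band-limited and cheap),
  scaled to the task's intensity in m/s²;
- **tremor**: a sinusoid with frequency uniform in 4–6 Hz (the classical
  parkinsonian tremor band), amplitude = effect scale × ordinal severity
  (default 0.6 m/s² per severity point), random phase and axis loading;
- **dyskinesia**: band noise in 1–4 Hz (slower than tremor, faster than
  most voluntary motion), default scale 0.5 m/s²;
- **bradykinesia**: multiplicative attenuation of the voluntary component
  (default 0.55) plus a 30 % narrowing of the band's upper edge, which
  reproduces the signature that bradykinetic recordings have lower
  magnitude S.D.

Labels are drawn once per (patient, task) and shared by that task's
repetitions, emulating a stable symptom state within one test-battery pass.
A cohort is a pure function of (config, seed).

What the generator does **not** emulate: medication (levodopa) dynamics and
wearing-off, within-recording symptom fluctuation (the single-label
limitation is inherited deliberately), gyroscope channels, sensor
repositioning, and the between-patient heterogeneity of real voluntary
motion. Passing recovery tests on these cohorts therefore demonstrates that
the estimators and the evaluation machinery work — not that the clinical
problem is solved at these scores.

The `easy_cohort_config` preset used by recovery tests raises effect sizes
(tremor 1.5 m/s² per severity point, bradykinesia attenuation 0.4), evens
out class balance, shortens recordings, and gives its four tasks comparable
intensities. It can restrict the cohort to a single symptom so the others'
components cannot confound a recovery experiment; this single-factor design
is what makes "balanced accuracy ≥ 0.9" a meaningful pass criterion.

## Windowing

Windows are half-open sample ranges [start, start + L) with 0-based starts
at multiples of step = round(L·(1 − overlap)) (round-half-away-from-zero;
a step of 0 samples is a configuration error). Only full windows are
emitted: a recording shorter than L contributes nothing. In severely
imbalanced cohorts this silently removes rare classes — all severity-4
tremor examples can be shorter than a 30 s window — which is why tremor
severities 3 and 4 are merged into a "3–4" class for the 4-class task.
Window counts obey count = ⌊(T − L)/step⌋ + 1 exactly.

No normalization happens at this stage; each classifier owns its input
convention (see below).

## Splitting and hyperparameter search

Stratified grouped assignment is greedy bin-packing: patients in decreasing
order of window count, each assigned to the split or fold whose class
counts least overshoot its target share of every class. The stratification
target is per-class window count (a duration proxy). Assignment is
invariant to input order and deterministic under the seed (used only for
tie-breaking).

The random-search driver samples window length uniformly in [3, 30] s with
replacement; filter length (8–255), depth (1–11) and filter count
(2, 4, …, 64) uniformly **without** replacement, with a pool refilling once
an axis is exhausted (necessary because 60 trials exceed the small axes'
cardinalities). 60 trials × 5 folds schedules 300 fits per symptom; job
failures mark the trial failed and the search continues.

## Classifiers

**Random kernel transform + ridge.** Kernel parameters follow the
transform's published defaults: length ∈ {7, 9, 11}, standard-normal
weights mean-centered per kernel, bias uniform on [−1, 1], dilation 2^a
with a uniform up to the largest fitting power, padding on/off
equiprobably. Kernels are applied per channel independently; each
(window, channel, kernel) yields PPV (strictly positive outputs; exact
zeros count as non-positive) and the maximum, so a 3-channel window with
10 000 kernels gives 60 000 features. Windows are z-normalized per channel
before convolution (the transform's convention). Features are standardized
and fed to a one-vs-rest ridge classifier whose regularization strength is
chosen from 10 log-spaced values in [1e-3, 1e3] by internal cross-validation
(grouped by patient when groups are available, scored by balanced
accuracy). Ridge likelihoods become probabilities through softmax.

**Inception-style network.** Each module: 1×1 bottleneck (default 32
channels), three parallel convolutions of lengths (f, f/2, f/4, min 2) with
n_filters each, a max-pool(3, stride 1) branch with its own 1×1 bottleneck,
channel concatenation, batch normalization, ReLU; output length equals
input length. Residual 1×1-projected shortcuts join every third module and
always the final one. Global average pooling and a dense softmax layer
close the network; training minimizes categorical cross-entropy with Adam
(step size 1e-3 — an assumption, as is common for this family — batch 64,
a fixed epoch budget, no early stopping). The full ensemble averages the
probabilities of five networks that differ only in initialization seed.
Both passes are NumPy; a numerical gradient check covers every layer
including the residual and batch-norm paths. Inputs are per-window
mean-centered per channel (removing the gravity offset) but **not**
variance-scaled: bradykinesia is an amplitude effect and per-window
z-normalization would erase it. An alternative reading of "number of
filters" — n_filters branches of halving length with one filter each — is
available as `branch_mode="halving_count"`.

Desk-scale configurations: the recovery and pipeline tests train compact
networks (depth 2, 8 filters, 2 s windows, ≤ 40 epochs) and small kernel
counts (300–500) on cohorts of ~10 patients. These sizes are the package's
choice for routine verification; the default configuration (depth 6, 32
filters, 30 s windows, 600 epochs, 10 000 kernels) is what a full
experiment would use.

**Wavelet-feature MLP.** The acceleration magnitude is decomposed with a
9-level discrete wavelet transform (Daubechies-4 by default; the wavelet
family is an assumption and configurable). Seven statistics — RMS, S.D.,
maximum, kurtosis, skew, Welch-PSD maximum and minimum — on the original
magnitude and each detail level give 70 ordered, named features (a per-axis
mode with 210 features exists but is non-default). Kurtosis and skew of a
constant series are defined as 0 to avoid NaN propagation; decomposition
beyond the depth the window length supports proceeds with boundary-dominated
coefficients (symmetric extension) and is logged. The head is a
70→128→128→K network with sigmoid hidden units trained by Adam on
multinomial log-loss (scikit-learn's MLP; for binary tasks it uses the
mathematically equivalent single logistic output unit).

## Metrics and calibration

AP is the literal non-interpolated sum over descending unique score
thresholds with R₋₁ = 0; mAP averages one-vs-rest APs with equal class
weight. Multiclass AUROC averages, over unordered class pairs, the two
directed binary AUROCs restricted to the pair's samples (one-vs-one — less
sensitive to class imbalance than one-vs-rest). MAMAE is the equal-weight
mean over classes of the per-class mean |ŷ − y|; an alternative
normalization that divides the class sum by N instead is kept behind
`as_printed=True`. Predicted class is the argmax with first-index
tie-break. These implementations are cross-checked in the test suite
against scikit-learn and against brute-force enumeration oracles.

smECE bins predicted probabilities onto a 4096-point grid, smooths the
signed residual (y − f) histogram with a Gaussian kernel reflected at the
[0,1] boundaries, and integrates its absolute value. The reported value
uses the self-consistent bandwidth σ* with smECE_{σ*} = σ*, found by
bisection to 1e-4 with σ clamped to [1e-3, 1] (the map σ ↦ smECE_σ is
non-increasing, so the crossing is unique). A perfectly anti-calibrated
predictor scores exactly 1; a perfectly calibrated one approaches 0.

## Significance

The ASO violation ratio is computed from empirical quantile functions on a
1000-point grid: ε = ∫_{q_A < q_B} (q_B − q_A)² dt / ∫ (q_A − q_B)² dt, so
ε(A,B) + ε(B,A) = 1 whenever the samples differ and identical samples give
0.5 (degenerate, flagged; self-comparison cannot dominate). The reported
bound is the asymptotic (1 − α) upper confidence bound from 1000 bootstrap
resamples preserving group sizes; dominance is declared below 0.2. The
bootstrap power analysis resamples both sides and counts how often a
two-sided Welch t-test at the (Bonferroni-corrected) α reaches
significance; with 10-run score sets this mirrors the convention of
requiring power ≥ 0.8 before interpreting a comparison.

## Misclassification analysis

Observed counts O_{t,ŷ,y} are tallied per task, predicted class and true
class, pooled across training repetitions; expected counts allocate each
(ŷ, y) column total to tasks in proportion to the task's share of all
samples at true class y, so column sums are conserved by construction.
Cells are flagged when the observed/expected ratio is at least 1.4 in
either direction and both counts are at least 10. The "at least 40 %"
difference is read as a ratio, not an absolute difference, because flagged
pairs are naturally reported as observed/expected ratios. Tremor is
binarized (severity ≥ 1 = present) before tallying. Signal explanations use
the acceleration magnitude: Welch PSD (Hann window, 256-sample segments,
50 % overlap — common defaults), trapezoidal 4–6 Hz band power, the
magnitude S.D., and sample entropy with m = 2, r = 0.2·S.D. (the standard
physiological-signal convention), Chebyshev distance, self-matches
excluded; zero matches yield +∞ with a warning.

## Pipeline

`run_experiment` executes simulate → clean → window → grouped holdout →
(train × repetitions per roster model) → per-run metric reports → ASO
comparisons (both metrics, Bonferroni over all ordered pairs) → pooled
misclassification table, and writes a manifest with every seed
(base_seed + run index + a stable hash of the model name) so any run is
exactly reproducible. The confusion/misclassification analyses select the
run of approximately median performance: the fourth-best by mAP when ten
runs exist, the ⌈n/2⌉-th best otherwise, ties to the lowest run index.
Classes absent from a windowed dataset (e.g. "3–4" tremor after short
recordings are dropped) are relabelled away before fitting.

The `pdmotor` CLI is a thin layer over these functions; the library API is
the primary interface.

## Known limitations

- The NumPy network trains at desk scale only; a 600-epoch, depth-6,
  30 s-window configuration is far outside a single-CPU test budget.
- Trainable-parameter counts of the network depend on architectural details
  (bottleneck width, residual projections) that published descriptions
  leave open; counts are reportable but not treated as reference values.
- Synthetic cohorts cannot certify clinical performance (see above);
  recovery thresholds are statements about the pipeline, not about PD.
- The ASO bound uses the asymptotic normal approximation for the bootstrap
  distribution; with very small run counts (< 5) the bound is conservative
  but noisy.
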