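# Methods

`winbci` studies a single question end to end: how does the length of
the time window fed to a recurrent classifier change the accuracy — and
the response latency — of an eyes-open (EO) / eyes-closed (EC)
brain–computer interface built on occipital alpha power from a low-cost
14-channel, 128 Hz wireless headset? Because no public recordings
accompany this protocol, the package ships a synthetic cohort generator
with ground truth, and every claim the package makes is measured on
that generator.

## The processing chain

1. **Blink denoising** (regression-based). The reference AFZ is the
   mean of AF3 and AF4. Its 1–7 Hz 5th-order Butterworth band-pass is
   the regression component; the detection signal is the derivative of
   that component, standardized, squared and moving-averaged (125 ms).
   Maximal runs above `k · median` (k = 5), padded by 0.1 s, are blink
   intervals. Inside each interval every channel is corrected as
   `x_ch(t) − w_ch · regr(t)` with `w_ch = mean|x_ch| / mean|AFZ|`.
   The interval over which `w_ch` is estimated matters: over the whole
   recording the amplitude ratio reflects the background-noise ratio of
   the channels (≈√2 for AF3 vs AFZ, since AFZ averages two channels),
   not the blink coupling, which over-corrects channels that carry
   little blink. The default therefore estimates `w_ch` over the
   detected blink intervals, where the blink dominates both numerator
   and denominator; `weight_scope="all"` restores the whole-recording
   variant.
2. **Band-pass** 5–40 Hz (Butterworth order 5). Filters are zero-phase
   (forward–backward) in this offline chain.
3. **Automatic rejection.** Each channel is standardized with
   population (1/N) statistics; the combined signal is
   `z_sum = Σ_ch z_ch / √c`; samples with `z_sum > µ + 3σ` are masked
   and dilated by 0.1 s per side. Masking, not trial deletion: masked
   samples are excluded from the power series and from every dataset.
   Note a structural property: a µ+3σ threshold flags ~0.1–0.3 % of
   samples of *any* stationary signal, and the dilation multiplies each
   isolated crossing by ~25 samples, so even an artifact-free recording
   loses a few percent of samples. The padding can be set to 0 when
   that matters.
4. **Alpha power.** Complex Morlet wavelets (7 cycles) on a 8:0.5:12 Hz
   grid at O1 and O2; power is the squared magnitude, normalized so a
   unit-amplitude tone at a grid frequency has power ≈ 1 µV². The
   frequency-mean is block-averaged 8× to a 16 Hz power series. Samples
   within half a wavelet support of the edges are masked.
5. **Datasets.** Sequences: for each labelled EO/EC segment, windows of
   `n_w = round(window_s · 16)` power samples end at the segment's last
   sample and slide backwards by `hop` (default 1); windows never cross
   state boundaries or masked samples. Points: one (P_O1, P_O2, label)
   row per unmasked EO/EC sample, untransformed.
6. **Classifiers.** The LSTM (8 cells, 1 layer, dense + softmax head)
   is trained by full BPTT with Adam (lr 0.012, batch 64, 60 epochs,
   cosine learning-rate decay, global-norm gradient clipping at 5,
   Glorot initialization, forget-gate bias 1). Inputs to the recurrent
   models are standardized with training-set statistics stored in the
   model; raw alpha powers span orders of magnitude and would saturate
   the gates at initialization. The classical roster (decision trees
   with ≤100/20/4 splits, linear/quadratic discriminants, SVMs with
   linear/quadratic/cubic/Gaussian kernels at kernel scales √P/4, √P,
   4√P for P = 2 predictors, k-NN with k ∈ {1, 10, 100} and
   euclidean/cubic/weighted/cosine distances) runs on the untransformed
   2-D points, backed by scikit-learn with those option semantics
   mapped directly (a tree with s splits → `max_leaf_nodes = s+1`; a
   Gaussian kernel scale σ → `gamma = 1/σ²`; SVM solver iterations
   capped at 5·10⁴ since the polynomial kernels barely converge on raw
   power features). A tap-delay recurrent network (8 units,
   `h_t = tanh(W_x x_t + W_h h_{t−d} + b)`) covers the simple-RNN
   comparison; `d = max(1, round(delay_s · 16))`.
7. **Evaluation.** EC is the positive class. Per subject, the dataset
   is split 75/25 (stratified) J times; ACC/SEN/SPE/MCC are computed on
   each validation set. Cohort aggregation: mean of per-subject means,
   and the sample (n−1) standard deviation across subjects. An
   undefined MCC (zero denominator) is reported as missing, never as 0.
   Windows are compared with the Friedman rank test over subjects and
   post-hoc pairwise two-sided Wilcoxon signed-rank tests (exact
   distribution for n ≤ 25 without zeros; zero differences dropped by
   default, Pratt handling available; raw p values, Holm correction
   available but off by default, matching the practice of reporting the
   uncorrected matrix).
8. **Streaming.** At every power sample the window ending there is
   classified, mixed states and all. For each true transition the
   detection delay is the time until the prediction first switches to
   the new state and holds it for 1 s (the hold suppresses the
   single-sample flicker that pointwise classifiers produce);
   transitions never matched before the next true transition count as
   missed rather than as a delay.

## The synthetic cohort

The generator emulates the recording protocol — per trial 20 s EO
fixation, 10 s rest, 20 s EC, ten trials per subject, 13 subjects —
and the statistical features the analysis depends on:

* **Occipital alpha.** A 9–11 Hz carrier at O1/O2 whose log-amplitude
  is `log a_state + u_segment + s(t) + x(t)`: a state level (EO median
  7 µV, EC/EO ratio 2.0), a per-segment (per-trial) Gaussian effect
  (sd 0.28), a quasi-periodic infra-slow waxing/waning `s(t)` (sd 0.40,
  period ~4.5 s jittered per subject, fresh phase per segment —
  infra-slow amplitude modulation of posterior alpha is a documented
  feature of resting EEG), and a fast Ornstein–Uhlenbeck component
  `x(t)` (sd 0.35, timescale 0.4 s, clipped at ±2 sd — real alpha
  waxes and wanes within a bounded dynamic range, and unbounded
  lognormal excursions would dominate the rejection threshold). O1 and
  O2 share the envelope up to small channel-specific factors, so the
  second channel adds little independent information, as with real
  posterior alpha coherence.
* **Blinks.** Difference-of-Gaussians pulses (~400 ms, ~150 µV,
  spectrum below ~5 Hz) at 10/min while the eyes are open, mixed into
  the frontal channels with fixed weights (AF3 1.0, AF4 0.95, F7/F8
  0.5, F3/F4 0.3). No blinks during EC.
* **Background.** Pink (8 µV) plus white (4 µV) noise per channel, and
  occasional broadband bursts (0.5/min, ~80 µV, 0.4 s) on all channels
  as rejection targets.
* **Subjects** differ in alpha frequency, EO level (log-sd 0.20),
  EC/EO ratio (log-sd 0.12) and envelope timescale (log-sd 0.30).

This architecture is what produces the window-size phenomenon. A
window of length T averages the fast OU component down by roughly
2τ/T, and the infra-slow modulation by a sinc² factor that collapses
once T exceeds its period (~4.5 s); the per-trial effect is constant
within a trial and no amount of within-trial averaging removes it.
Accuracy therefore grows steeply from 1 s windows, and saturates once
T clears the infra-slow period — the plateau around 7 s. The
short-window EO/EC power distributions overlap heavily (this is why
pointwise classifiers stall in the low 0.7s), while multi-second
windows separate. The component variances were chosen from a Gaussian
discriminability calculation on log-power (targeting pointwise
accuracy ≈ 0.72, 1-s windows ≈ 0.74, a ≥ 10-point window gain and a
7–10 s plateau) and then verified against the realized pipeline.

What the generator does **not** model: non-alpha rhythms, volume
conduction and realistic channel covariance, eye movements other than
blinks, electrode drift or popping, non-stationary fatigue effects,
and any subject behaviour beyond the protocol. Passing tests therefore
demonstrate that the pipeline recovers the intended structure from
data of this kind, not performance on human recordings.

## Problem sizes and numerical choices

The default study — 13 subjects, windows {1, 2, 4, 7, 10} s, J = 5
repeated splits, training/validation capped at 120/200 sequences per
class (windows at hop 1 overlap almost completely, so the caps discard
little information; they are drawn at random per split) and 1000
points per class for the classical roster — keeps a full run in the
ten-minute range on one CPU. The single-layer LSTM training step runs
through a numba-compiled kernel that reproduces the numpy reference
implementation bit for bit (checked to machine precision in the
tests); multi-layer networks use the numpy path.

Degenerate inputs are errors, not silent defaults: constant channels
cannot be standardized, a constant `z_sum` yields no threshold, a
window longer than every segment refuses to build a dataset, a class
missing from a training set refuses to train, k-NN with k larger than
the training set refuses to fit. Argmax ties in prediction resolve to
EO (the negative class). Random behaviour is controlled by explicit
seeds everywhere; repeated splits derive per-iteration seeds from a
`SeedSequence` of (seed, subject, iteration).

## Known limitations

* Sequences sampled from overlapping windows share trials between
  training and validation splits, as in the emulated study design;
  reported accuracies are therefore within-session, same-trials
  estimates, optimistic relative to a trial-held-out split.
* The Friedman p value uses the chi-square approximation (k−1 df),
  which is rough for very small cohorts; the tests verify it against a
  permutation null at the cohort sizes used here.
* The blink-weight formula is an amplitude ratio, not a regression
  coefficient; it is unbiased only where the blink dominates both the
  channel and the reference, which is why the default estimation scope
  is the detected blink intervals.
* With 20-s trials, a 10 s window leaves at most 11 distinct window
  positions per trial at hop 1, so long-window accuracy estimates are
  intrinsically noisier than short-window ones.
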