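# Methods

`emophys` implements an emotion-classification pipeline for low-cost
physiological sensing: a single-channel EEG headset that emits relative
band powers about once per second, and a PPG pulse sensor that emits
inter-beat intervals (IBIs). Trials are one-minute stimulus windows
labelled by the participant's Self-Assessment Manikin (SAM) rating of
arousal and valence on a 1..9 scale. This note records the model, the
numerical choices, and what the synthetic study does and does not show.

## Feature extraction

**EEG (22 indexes).** The sensor provides eight relative band powers
(δ, θ, low/high α, low/high β, low/mid γ; unitless). Composite wide
bands are sums: α = low α + high α, β = low β + high β, γ = low γ +
mid γ. Each of the 11 indexes is additionally smoothed by a trailing
moving average with a 15-sample window (MA15); MA15 values are missing
until 15 samples have accumulated. No spectral decomposition is done in
the package — the sensor already outputs band powers.

**HRV time domain (11 indexes).** Recomputed each time a new IBI
arrives, over a sliding window of the trailing 30 beats: IBI itself,
HR = 60000/IBI (bpm), SDNN (population, divide-by-N, standard
deviation, ms), RMSSD (root mean square of successive differences, ms),
SDNN/RMSSD (missing when RMSSD = 0), CVNN = SDNN / mean IBI, and pNNx
for x ∈ {10, 20, 30, 40, 50} — the proportion (in [0, 1], not percent)
of successive differences with |Δ| > x ms. Population SDNN is used
because the window statistic is descriptive, and it keeps CVNN =
SDNN/mean internally consistent. All windowed values are missing, not
zero-filled, until 30 beats have accumulated.

**HRV frequency domain (3 indexes).** LF and HF are spectral powers of
the IBI signal in 0.04–0.15 Hz and 0.15–0.40 Hz over the trailing
200 s (at least 8 beats). The estimation procedure is fixed as: linear
interpolation of the irregular tachogram onto a uniform 4 Hz grid, mean
removal, Hann taper, periodogram, and rectangular integration of bins
whose centres fall in each band (the shared 0.15 Hz edge is assigned to
HF so no bin is counted twice). LF/HF is missing when HF = 0. Adding a
constant to all IBIs leaves LF and HF unchanged (mean removal), and
both are non-negative by construction.

**Alignment.** The two sensors are unsynchronised, so the dataset is
built at 1 Hz: at each whole second of the stimulus window, every
feature takes the most recently computed value at or before that
second; features with no prior sample are missing. A 60-s trial yields
at most 60 rows of the 36-column feature record.

## Labels

High arousal (valence) iff the SAM score is ≥ 5, the scale mid-point.
The four-quadrant label is derived from the two binary labels under the
default `threshold` convention (HAHV = high/high, HALV = high arousal /
low valence, LALV = low/low, LAHV = low arousal / high valence). A
`literal` convention applying the published boundary clauses verbatim is
retained for audits; those clauses attach the HALV name to a
low-arousal/high-valence region, which contradicts the quadrant
semantics, so they are not the default. Both conventions partition the
9×9 grid. Three tasks are evaluated: the 4-class quadrant task and the
two binary tasks.

## Feature selection

Four importance scorers per task:

* **Correlation ratio (η²)** — between-class sum of squares over total
  sum of squares (squared deviations in both), 0 when total variance
  is 0.
* **Mutual information** — plug-in estimate in nats after
  equal-frequency discretisation into 10 bins. The estimator is
  deterministic; tied quantile edges can merge bins. Log base is
  irrelevant to the ranking because scores are min-max normalised.
* **Random forest** — mean impurity-decrease importance of a
  1000-tree Gini forest (unlimited depth, min-split 2, bootstrap);
  importances sum to 1.
* **L1 linear SVM** — mean |w| across class vectors of an
  L1-regularised linear SVM with C = 1.0, one-vs-rest beyond two
  classes. Features are standardised before this fit only (L1 weights
  are scale-dependent; the other three scorers are scale-invariant or
  scale-robust); zero-variance columns are dropped and scored 0. The
  solver uses the squared-hinge loss, the standard differentiable form
  for L1-penalised linear SVMs; only |w| is consumed, so the ranking is
  insensitive to this choice.

Each scorer's vector is min-max normalised to [0, 1] (a constant vector
maps to all zeros), the four maps are averaged per feature, features
are sorted descending, and the top 10 are selected. Ties are broken by
the fixed registry order so rankings are reproducible; forest and
solver seeds are explicit arguments. Rows with any missing feature are
dropped before scoring so all four algorithms see the same
complete-case sample.

## Evaluation

21 feature groups: #1 EEG (11), #2 MA15 EEG (11), #3 time-domain HRV
(11), #4 frequency-domain HRV (3), #5 TD+FD HRV (14), #6 all 36, and
#7–#21 the top-10 lists of (ensemble, CR, MI, RF, SVML1) × (quadrant,
arousal, valence).

The classifier is a feed-forward network with three 256-unit ReLU
hidden layers, softmax output, SGD optimisation and no dropout
(scikit-learn `MLPClassifier`). Training-loop parameters are not fixed
by the architecture and default to learning rate 0.01, batch 32, up to
100 epochs with the library's loss-plateau stopping; validation-based
early stopping is off. Scores are computed under stratified 10-fold
cross-validation after merging all participants; per-fold, features are
standardised with training-fold statistics only (no leakage into the
held-out part; a test asserts the scaler never sees held-out rows).
Rows with a missing value in the group's features are dropped before
splitting, not imputed.

Macro F1 is the unweighted mean over the classes of `y_true` of the
per-class harmonic mean of precision and recall; a class with undefined
precision or recall contributes 0, the conservative convention that
keeps the score defined on degenerate folds. The no-learning reference
is a uniform-random predictor over the observed class set (its
closed-form expectation on four classes with the published quadrant
sizes is ≈ 0.25, which the Monte-Carlo baseline reproduces);
class-frequency-weighted prediction is deliberately not used.

## Synthetic study

Real recordings from the study design this pipeline targets are not
redistributable, so the generator emulates their statistical structure
with known ground truth: 25 participants × 8 one-minute trials, two per
quadrant in shuffled order, ~1 Hz EEG band-power samples and IBIs in a
physiological 600–1100 ms range.

Per-quadrant structure: the IBI mean shifts by class (defaults 600 /
750 / 900 / 1050 ms for HAHV / HALV / LAHV / LALV — faster hearts under
high arousal, all four classes separated by 7.5 beat-noise standard
deviations), sinusoidal IBI modulation at 0.1 Hz and 0.3 Hz with
per-class amplitudes plants LF- and HF-band power, and selected EEG
bands (defaults mid γ and δ) are multiplied by per-class shifts.
Beat-to-beat noise is Gaussian (sd 20 ms) truncated at 300 ms to keep
IBIs positive and physiological; band powers are log-normal because
relative powers are positive and right-skewed. SAM ratings are drawn
uniformly from the grid cells of the trial's target quadrant, so every
rating labels back to its quadrant by construction.

Because LF/HF needs a trailing 200-s window and a stimulus lasts only
60 s, each trial stream carries a 240-s lead-in segment emulating the
continuous recording through the pre-stimulus rest, with the same
class-conditional dynamics; features are sampled only over the final
60 s. One global seed feeds a SeedSequence spawned per participant and
trial, so output is byte-identical across runs and independent of
generation order.

**What the generator does not emulate:** participant heterogeneity
(baseline HR differences within class), non-stationarity and habituation
across trials, sensor artefacts and dropouts, rating noise
(SAM ratings always match the target quadrant), and any genuine
EEG–emotion physiology. Default effects are deliberately strong —
the defaults are a positive control. Passing tests therefore show the
pipeline recovers known structure and that its statistics are computed
correctly; they do not certify accuracy on real recordings.

## Problem sizes used in tests

The cross-validated pipeline check runs the full default study
(25 × 8 trials, ~12 000 feature rows). The planted-LF recovery
experiment uses one participant per replicate over 100 seeds (the
planted amplitude difference is large, so recovery is insensitive to
study size), with a 30-replicate null calibration; fixture-level unit
tests use two-participant studies. These sizes are the package's test
design, chosen to exercise every code path at full default parameters
where the claim depends on them.

## Pseudo-replication in feature rankings

Labels are constant within a trial, but rows are sampled every second,
and the windowed HRV indexes change slowly relative to a 60-s trial:
successive LF/HF values share ~70–100% of their 200-s window, and the
30-beat statistics overlap heavily too. A slow feature is therefore
nearly constant within a trial, and ordinary association measures see
its *between-trial* sampling noise as class structure whenever the
trial count is small: for a trial-constant feature the spurious η²
under the null is about (k−1)/(T−1) for k classes and T trials, orders
of magnitude above the i.i.d.-row level at any realistic T. The
practical consequence, reproduced by the test suite, is that null
simulations do **not** give uniform top-10 inclusion — the
frequency-domain indexes always enter, the 30-beat statistics often do
— and a dedicated test documents this at its design threshold rather
than hiding it. Planted-effect recovery claims are therefore phrased
against this non-uniform null (LF leading the ranking, monotone
recovery of a *fast* planted EEG channel), and rankings on real data
with few trials per class should be read with the same caution;
trial-level aggregation or clustered inference would remove the
confound and is out of scope here.

## Known limitations

* The spectral procedure (4 Hz resampling, Hann periodogram) is one of
  several defensible estimators for irregular tachograms
  (Lomb–Scargle, autoregressive); band *ratios* are robust to the
  choice, absolute LF/HF powers are not comparable across estimators.
* The MI estimator's fixed 10-bin discretisation biases absolute MI at
  small n; rankings are much less sensitive than values.
* Uniform-random baselines for the binary tasks are exactly derivable
  (≈ 0.5 balanced) but published binary baselines for this design are
  not reproducible from class counts alone and are not targeted.
* `MLPClassifier` stops early when the training loss plateaus; with
  strongly separable data this is reached well before 100 epochs. Set
  a larger `epochs` and smaller learning rate for marginal problems.
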