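# Methods

This note documents the models, procedures and design choices behind
`steersense`, in the spirit of the methods documentation shipped with
statistical packages: what is computed, under which assumptions, with which
defaults, and what the synthetic experiments do and do not demonstrate.

## Problem setting

A neck-mounted collar samples acceleration at 10 Hz (±2 g, 12-bit). The
vertical (y) axis captures head and jaw-driven neck motion, so only that
axis is analysed. The signal is cut into non-overlapping 90 s blocks
(900 samples); each block receives a single behaviour label — eating,
rumination or other — by majority vote over a 10 Hz per-sample label
stream. Ties are broken by the fixed precedence eating > rumination > other
and counted; trailing partial blocks are dropped. The majority fraction is
retained as `label_purity` (≥ 1/3 for three states); an optional purity
threshold can discard mixed blocks but is off by default.

## Synthetic herd

The simulator generates the structure the classification method exploits,
not a biomechanical jaw model:

* **Behaviour sequence.** A semi-Markov chain over the three states. Dwell
  times are `dwell_min + Exp(dwell_mean − dwell_min)` (defaults 30 s floor,
  300 s mean — bouts last minutes, and the shifted exponential makes the
  configured mean exact). Successor states are drawn from a configurable
  non-negative weight matrix with zero diagonal; zero-weight states are
  unreachable.
* **Signal signatures.** Rumination: a sinusoid of amplitude 0.3 g whose
  frequency is drawn per bout from 3.0 ± 0.4 Hz, plus 0.05 g RMS noise. The
  per-bout frequency wander is deliberate: it keeps the 2–4 Hz band
  amplitude the *stable* rumination marker while de-correlating fixed-lag
  autocorrelations, which mirrors why a band feature is the right prior for
  this physiology. Eating: white noise of 0.3 g RMS shaped by a slow
  (0.3–0.7 Hz) rectified-sine burst envelope, giving a flat spectrum.
  Other: 0.05 g RMS white noise.
* **Collar placement.** Each steer gets a multiplicative lognormal gain
  (σ = 0.15) and an additive offset (σ = 0.05 g), reflecting collars
  shifting and rotating between animals. Traces are clipped at ±2 g;
  12-bit quantisation is available but off by default.
* **Herd layout.** 18 steers in 3 trials (round-robin), 2 h per steer by
  default — a desk-scale stand-in for multi-thousand-hour farm corpora; the
  duration is a package choice, since per-steer observation lengths are a
  property of each deployment.
* **Determinism.** Every random draw comes from a `SeedSequence` keyed by
  (seed, steer index, purpose), so datasets are byte-identical across runs
  and machines for a given configuration.

What the simulator does **not** emulate: sensor drift and temperature
effects, posture changes within a behaviour, transitional/mixed jaw motion
(the main source of eating–rumination confusion in farm data), missing data,
or label noise from the halter itself. Accuracies on synthetic herds
(~0.98) are therefore upper bounds with clean class structure; they validate
the machinery, not field performance (~0.8 in realistic deployments).

## Feature catalogue

42 named features per block, fixed order, version "1.0". Two encode prior
knowledge: `fft_amplitude_2_4hz` (mean real-FFT magnitude over bins in
[2, 4] Hz, rectangular window on the raw block) and `spectral_flatness`
(geometric/arithmetic mean of the periodogram). The other 40 are standard
time-series descriptors with their usual parameterisations (recorded in the
catalogue entries): moments, extremes, change statistics, threshold and
range counts, run lengths, extremum locations, quartiles, autocorrelations
at lags 1–3, the c3 and time-reversal-asymmetry nonlinearity statistics,
normalised complexity (CID), binned entropy, Fourier entropy, Welch density
at the bin nearest 3 Hz, the spectral centroid, and a local-peak count.

Numerical conventions: the flatness floors periodogram bins at 1e-12 of the
maximum, which makes it exactly scale-invariant and 1 for an impulse;
constant blocks map all variance-normalised features to 0; every feature is
guaranteed finite. `count_above_global_mean` takes its reference level as a
catalogue parameter (default 0 g) so a block's features never depend on
other blocks; `range_count` defaults to [−1, 1) g.

## Mutual-information estimator

For a scalar feature X and discrete label Y, the kNN estimator
`ψ(N) − ⟨ψ(N_x)⟩ + ψ(k) − ⟨ψ(m)⟩` (k = 3, natural log) is used: the
distance to the k-th nearest *within-class* neighbour defines a radius per
point; `m` counts neighbours from all classes within it. Ties are resolved
in exactly one place (`mi_knn`): the radius is shrunk by one ulp so
counting is strictly-inside, and the count enters the digamma as `m + 1`.
Estimates are reported raw (they can be slightly negative under
independence) and rankings use raw means over the 25 training folds. Each
class must have more than k members. Features are standardised with
training-fold parameters before scoring — a pipeline-consistency choice;
the estimator itself is invariant under monotone transformations.

## Backward feature elimination

The wrapper removes features in blocks along the schedule
[42, 37, 32, 27, 22, 17, 12, 7, 2, 1] — steps of five until a single
feature remains, nine transitions in total. At each transition, every
remaining feature is excluded in turn, the classifier retrained and
validated on all 25 folds, and its importance taken as the mean validation
balanced accuracy *without* it (higher ⇒ less important). The lowest-
importance block is removed; ties break by catalogue order. A fold where
the model fails (e.g. EM at a local optimum) is logged and dropped from
that mean; a feature whose exclusion fails everywhere is treated as
important and kept. The MI filter, by contrast, is one-shot: subsets are
truncations of a single ranking (a re-computation per step would be a
wrapper in disguise; the one-shot reading matches how filters are used).

## Classifiers

* **HMM.** 3 hidden states (one per behaviour), Gaussian-mixture emissions
  with K = 1 component per state by default (configurable; the mixture
  machinery is fully implemented). Training is unsupervised Baum–Welch in
  log space over per-steer sequences (no transitions across steers), with
  the stopping rule |Δ total log-likelihood| < 0.04 — the tolerance is
  interpreted as an absolute change in total log-likelihood, the natural
  reading when none is specified. Initialisation is an in-package
  k-means++ on the pooled observations with a mild self-transition bias
  (0.8); since EM is prone to local minima, `n_init` seeded restarts are
  run and the best final likelihood kept. Labels enter only *after*
  fitting, to map hidden states to behaviours by maximum Viterbi-path
  overlap (Hungarian assignment). Decoding is most-probable-path by
  default; posterior-marginal decoding is available behind a flag.
  Covariances carry a 1e-6 diagonal regulariser, escalated with a warning
  on singularity.
* **LDA.** Class Gaussians with pooled covariance; linear discriminant
  scores `x'Σ⁻¹μ_c − ½μ_c'Σ⁻¹μ_c + log π_c`; argmax with canonical-order
  tie-breaking. Singular pooled covariance is ridge-regularised with an
  escalating logged epsilon. The between/within scatter matrices and the
  ≤ K−1 generalised eigen-directions are retained for diagnostics.
* **PLS-DA.** Classic NIPALS on column-centred X and {0,1} one-hot Y
  (PLS2 convention; X is already standardised upstream, Y centring is part
  of the algorithm): tolerance 1e-6 on the relative score change, 500
  iterations maximum with a warning on non-convergence; zero-variance
  columns are dropped with a warning. Coefficients are
  `B = W(PᵀW)⁻¹Qᵀ`. Prediction takes the maximum output; when no output is
  positive the argmax is still used and the event counted. With components
  equal to rank(X) the fit reproduces ordinary least squares — used as a
  correctness oracle in the tests.

## Evaluation protocol

One test steer per trial is drawn (seeded) before any statistics are
computed; the 15 development steers are split 12/3 in 5 folds, repeated 5
times with reshuffling — 25 runs, each steer validating exactly once per
repetition. The same 25 splits are shared by the MI and BFE arms via the
master seed. Training sets are balanced per steer to the minimum block
count (random under-sampling, time order preserved) and standardised to
zero mean / unit variance with training parameters only; constant columns
are zeroed and flagged.

Balanced accuracy is ½(TP/P + TN/N) per class — the ½ is required for the
metric to live in [0, 1] and to agree with the standard definition of
balanced accuracy as the mean of sensitivity and specificity — macro
averaged over classes present in the actuals (absent classes are excluded
with a warning). Weighted aggregates use validation-support weights.
Confidence intervals are percentile bootstrap (B = 10000) over the 25
per-run accuracies. The grid search evaluates every
(selection, model, count[, components]) cell; PLS-DA cells with more
components than features are marked skipped. The deployed count is the
smallest whose mean accuracy is within δ = 0.01 of the curve maximum
("knee" rule), with a manual override available since knee choices are
ultimately judgement calls.

## Problem sizes

Defaults are desk-scale by design: 2 h per steer → 80 blocks per steer,
1440 blocks for the 18-steer herd; the full two-arm LDA experiment
(feature extraction, MI ranking, nine-step BFE, grid, bootstrap, final
test evaluation) completes in well under a minute on one CPU. HMM arms are
supported in the same grid but are an order of magnitude slower per fold
and are not part of the default experiment.

## Known limitations

* The generic-feature parameterisations follow common library defaults;
  other choices (entropy bin counts, range bounds) would change individual
  feature values, though not the pipeline's structure.
* The BFE is greedy in blocks of five and never revisits a removal, so
  mid-schedule dips (as seen with EM-based models) are possible by
  construction.
* With near-saturated synthetic accuracy, several catalogue features are
  deliberately redundant (band amplitude, Welch density at 3 Hz,
  autocorrelation at lag 3), so the *identity* of the surviving subset can
  vary between equally good choices across seeds even though its
  performance does not.
* Real-recording ingestion is limited to the package's own CSV schema; no
  adapter is provided for third-party archive layouts.
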