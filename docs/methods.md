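# Methods

This note records the models, conventions and open design choices behind
`ecgscreen`, in the order the pipeline runs.

## Signal conditioning

The ECG is bandpass-filtered with a windowed-sinc FIR (Hamming window),
cutoffs 3 and 45 Hz. Only the cutoffs are externally fixed; the tap count is
our choice: the next odd integer ≥ the sampling rate (101 taps at 100 Hz,
i.e. a ~1 s impulse response), which gives more than 20 dB of rejection at
0.3 Hz baseline wander and at 50 Hz mains hum. The filter is applied
forward-backward (`filtfilt`), so the output is strictly zero-phase and peak
times are not biased; the effective magnitude response is the square of the
designed one, which only sharpens the band edges.

## R-peak detection

A Hamilton-style detector: differentiate, rectify, moving-window integrate
(80 ms), then classify the local maxima of the integrated waveform with an
adaptive threshold `noise + 0.3125 × (signal − noise)` over running averages
of the last 8 peak/noise amplitudes, a 200 ms refractory period, and a
search-back pass that revisits sub-threshold candidates whenever the gap since
the last beat exceeds 1.5 × the running mean RR (accepting the best candidate
above half the threshold). Detections are finally localized to the
filtered-signal maximum within ±100 ms, where the amplitude is read. All
constants are config-exposed (`DetectorSpec`); the defaults are the published
ones. Amplitudes are read from the *filtered* signal: detection operates
there, and baseline wander would otherwise contaminate the amplitude series
whose spectrum is itself a feature.

## RR cleaning

Physiologically uninterpretable intervals — outside 300–2000 ms by default —
are replaced by the median of the 5-beat window centred on them (edge windows
shrink symmetrically; the suspect value participates in its own median).
In-band intervals pass through untouched: the filter targets outliers, it
does not smooth. If the window median is itself out of band the median of the
in-band values in a progressively widened window is used, so the corrected
series is always in band and the operation is idempotent. A record whose
every interval is out of band is rejected rather than fabricated. Window
length and band edges are config-exposed since no external convention fixes
them.

## Features

Eighteen features per annotated minute. An RR interval belongs to the minute
containing its *terminating* R peak; amplitudes to the minute containing
their peak (half-open minute windows, so the per-minute subsets partition the
recording exactly).

Time domain: MRR, MHR (mean over beats of 60000/RR), RMSSD, SDNN, NN50
(successive differences strictly > 50 ms), pNN50. Two conventions are ours:
SDNN uses the population (divide-by-N) standard deviation by default, with a
``sample_sd`` switch for the N−1 variant; and pNN50 divides by the number of
RR intervals rather than the number of difference pairs, following the usual
wording of the definition literally.

Frequency domain: the beat series is cubic-interpolated onto a uniform 3 Hz
grid spanning the segment's beats, mean-removed, and a Welch estimate with
FFT length 256 integrates to VLF/LF/HF band powers over half-open bands.
One minute at 3 Hz gives ~180 samples < 256, so the estimate is a single
zero-padded, Hamming-windowed segment — a modified periodogram, fully
deterministic. Ratios: LF/HF, LF/(LF+HF), HF/(LF+HF), identically for the
amplitude series. The algebraically odd literal variant LF/(LF/HF) (which
reduces to HF) is available behind `SpectralEstimatorSpec(literal_ratio=True)`
but is not the default. If LF+HF = 0 (degenerate segment) all ratios are
defined as 0 rather than dividing by zero.

Segments with fewer than 10 beats, or whose beats span under 30 s, are kept
in the minute grid with `valid=False` and NaN features; after normalization
they are imputed with the training-set mean (0 in z-space). The grid must
stay complete because the AHI denominator is the number of annotated minutes.

Normalization is a z-score with training-partition mean and population SD,
computed per CV fold or on the training cohort only — never on test rows.
Constant columns get scale 1.

## Windowing

The row for target minute *t* concatenates the (normalized) base vectors of
minutes *t−past … t+future*; rows never cross recordings. At recording edges
the nearest existing minute's vector is replicated (default), keeping every
annotated minute classifiable; zero-fill and drop policies exist for
comparison. The grid search scores each (past, future) pair in 0–15 × 0–15 by
mean grouped-CV accuracy; ties prefer the smallest past+future, then the
smallest future (the cheapest window to realize online).

## Classifiers

Configuration only — fitting delegates to scikit-learn and xgboost. Fixed
settings: MLP hidden layer = 2 × n_features + 1 (n_features is the *windowed*
width, the matrix the model actually sees), alpha 1, max_iter 1000; SVM
C 9.9, tol 5e−4, RBF kernel with built-in probability calibration; RF 148
trees, max_depth 185, max_features min(15, n_features), random_state 42;
XGBoost eta 0.1, up to 10000 rounds with early stopping after 50 on a
10 % grouped hold-out of the training rows (the early-stopping set is not
externally specified; grouping by recording avoids subject leakage into it);
LR random_state 42. Everything not listed stays at library defaults and every
value actually used is written to the run log. Scores are class-1
probabilities and the decision is score ≥ 0.5, so labels and scores never
disagree.

## Evaluation

Grouped k-fold: record ids are shuffled with a seeded generator and dealt
round-robin, so 35 records give five validation folds of exactly 7. AUC uses
midranks for ties and is checked against a brute-force pairwise oracle in the
tests. AHI = 60/T × (apneic minutes) with T = the number of annotated minutes
(not raw signal length — the classifier scores exactly that grid); SAS at
AHI ≥ 5, boundary inclusive. Disjointness of train and test records is
asserted on every run.

## Synthetic cohorts

The generator emulates what the features must detect, not ECG
electrophysiology in detail:

* labels come in contiguous episodes (normal 2–8 min, apneic 2–6 min,
  apneic fraction kept in [0.1, 0.7]); 35 % of records are "healthy"
  (rare 1–2 min events, AHI < 5) so cohorts contain both screening classes;
* the tachogram is baseline (850 ± 60 ms between records) + RSA
  (30 ms at 0.25 Hz, normal breathing) + cyclical heart-rate variation
  (120 ms at 0.025 Hz, apnea) + 25 ms white jitter, clipped to 400–1800 ms;
  the apnea terms are scaled by a first-order envelope with a 45 s time
  constant rather than switching per minute — breathing transitions are
  gradual, which makes episode-edge minutes genuinely ambiguous in isolation
  and is what gives past/future context something to contribute;
* R-peak amplitudes are modulated at the apnea oscillation rate (depth 0.2);
* the rendered ECG is a Gaussian-bump PQRST template train (R bump ~20 ms
  wide) plus 0.3 Hz wander, 50 Hz hum and white noise, sampled at 100 Hz.

Per-record streams derive from (master seed, record index), so datasets are
bit-reproducible and parallelizable. The generator does **not** model QRS
morphology changes, ectopy (unless the artifact option is enabled), movement
artifacts, sensor detachment, or the obstructive/central distinction — so
passing tests demonstrate that the pipeline recovers the planted spectral
signatures under realistic noise, not clinical-grade performance on patients.

## Problem sizes

The acceptance harness uses cohorts of 30 recordings × 60 annotated minutes
(20 train / 10 test) and ten independent seeds for the context-window
comparison, and 5–10-minute recordings for detector benchmarks; these sizes
make every quantity stable at desk scale while each experiment stays within a
few tens of seconds.

## Known limitations

* The Hamilton constants are tuned for adult sinus rhythm at 100 Hz; very low
  sampling rates or paediatric rates would need re-tuning.
* Real per-minute annotation files in the wild vary; the binary annotation
  reader supports the one-symbol-per-minute dialect only, and rejects
  anything else rather than guessing.
* The per-minute detector is calibrated on balanced-ish synthetic cohorts; on
  strongly imbalanced data the 0.5 score threshold may need revisiting.
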