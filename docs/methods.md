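# Methods

## Scope and model

The package implements a segment-level EEG biometric pipeline with two
tasks: closed-set **identification** (assign a 2 s EEG segment to one of N
enrolled users) and **verification/authentication** (accept or reject a
claimed identity from one run's worth of segments). The discriminative
signal is assumed to live in the *relative spectral composition* of the EEG:
each user has a stable per-(channel, band) power profile, and a classifier
on standardised band powers can separate users. Temporal/event structure
(e.g. P300 latencies) is deliberately not used by the features.

## Synthetic data generator

`eegauth.synth` emulates an 8-user, 8-channel, 256 Hz campaign with 7 runs
per user and a chronological 3-train/4-test run split. Per user a
*signature* `A[m, b]` (channel × band amplitude) is drawn as a shared
log-normal baseline (log-sd 0.3) multiplied by `exp(separation · z)`,
`z ~ N(0,1)`, so `separation` is exactly the between-user log-amplitude
spread and `separation = 0` makes users statistically identical. A run is

    x_m(t) = Σ_b A[m, b] · n_b(t)  +  noise_sd · pink(t)  [+ ERP transients]

where `n_b` is unit-variance Gaussian noise band-limited to band `b` by a
firwin/Hamming band-pass applied zero-phase in the frequency domain (squared
magnitude, i.e. filtfilt-equivalent attenuation) with cutoffs pulled inward
by half the transition width so ground-truth band energy stays essentially
inside the nominal edges; `pink` is 1/f-shaped unit-variance noise.
P300-like events (positive half-sine, 200 ms wide, 300 ms latency, largest
over centro-parietal channels, Poisson-scheduled) are off by default: the
features are purely spectral, so transients add realism, not signal.

Defaults: `run_duration = 60 s`, `separation = 0.5`, `noise_sd = 1.0`,
`erp_rate = 0.5 /s`. Run length and montage follow the emulated campaign;
separation/noise have no stated values anywhere, so moderate values were
fixed once — a band-power SNR around 1 with partially overlapping user
profiles, which a practitioner would call a realistic mid-difficulty
regime. End-to-end checks that demand a *high-separation* regime use
`separation = 2.0` and `run_duration = 30 s` (the shorter runs only bound
runtime; segment counts per run drop from 59 to 29).

What the generator does **not** emulate: volume conduction and channel
correlation from a head model, non-stationarity across runs/sessions,
artifacts (blinks, EMG) unless injected by hand, and ALS-specific signal
properties. A green end-to-end test therefore establishes that the pipeline
recovers *planted spectral identity* under pink noise — not that it would
reach the same numbers on clinical recordings.

Determinism: one global seed fans out via `SeedSequence(seed, spawn_key)` —
`(0,)` for signatures, `(1, user, run)` per recording — so adding users or
runs never perturbs existing data.

## Preprocessing

* Band-pass 1–50 Hz: windowed-FIR (Hamming) design with automatic length
  `ceil(3.3 · fs / Δf)` (forced odd) from a transition width
  `Δf = min(low, 0.25·low + 2 Hz)`; cutoffs widened by `Δf/2` so the nominal
  edges sit at full gain; applied forward–backward (`filtfilt`) for zero net
  phase. Contract (tested): passband sinusoids within 5% amplitude, 60 Hz
  attenuated > 90% in RMS.
* Common-average reference: subtract the per-sample channel mean (requires
  ≥ 2 channels). Commutes with the filter in effect.
* ICA artifact rejection (off by default; synthetic data is artifact-light):
  FastICA with 6 components; sources with excess kurtosis > 8 have their
  contribution subtracted. This is an automated surrogate for manual
  component inspection and claims no equivalence to it. If nothing exceeds
  the threshold the input is returned unchanged.
* Windowing: 512 samples, stride 256 (50% overlap). Windows never cross a
  run boundary; trailing partial windows are dropped, recordings shorter
  than one window are skipped with a warning. Count per recording is
  `floor((S − window)/stride) + 1`.

## Features

One Hann-tapered periodogram per segment and channel (`nfft = T`, one-sided
density scaling via `scipy.signal.periodogram`, so the PSD integrates to the
signal variance; tested within 15% on white noise). Band powers are plain
sums of PSD bins inside delta [1,4), theta [4,8), alpha [8,12), beta
[12,30), gamma [30,50] Hz — half-open edges with gamma closing at 50 Hz
inclusive, a convention fixed here because the printed band edges overlap.
Only relative values matter downstream. Standardisation (z-score) is fitted
on training rows only; zero-variance columns are centred and flagged. The
scaling step is this package's addition: raw band powers span orders of
magnitude and destabilise network training.

## Feature selection

Plug-in mutual information between each feature and the labels on an
equal-frequency 10-bin discretisation (quantile edges, hence rank-invariant;
natural log). The top `Q = 10` features are kept; ties break toward the
smaller column index. The estimator has the usual positive plug-in bias of
order `(bins−1)(classes−1)/(2n)` nats — irrelevant for ranking. A
redundancy-penalised (mRMR-style) criterion is intentionally not
implemented: ranking is by MI with the labels only.

## Classifier

`Q → 64 → 32 → N` dense network: ReLU, inverted dropout 0.2 after each
hidden layer (training only), softmax, cross-entropy, Adam (0.9/0.999,
eps 1e-8) at lr 1e-3, 50 epochs, shuffled batches of 32, no early stopping
or validation split (a fixed-budget recipe, implemented literally).
Weights/biases use fan-in-scaled uniform init `U(±1/√fan_in)`. Everything is
seeded; training is deterministic single-threaded. Baselines: linear SVM
(C=1, one-vs-rest, softmax over margins as confidence), KNN (k=3, Euclidean,
uniform vote fractions), random forest (100 trees, seed 123, full depth),
gradient boosting (100 trees, depth 2, lr 0.01) standing in for XGBoost,
which is not an available dependency. Predicted labels are always the argmax
of the probability row, so label/probability consistency holds by
construction for every model kind.

## Authentication

Votes `V(j) = Σ_i 1[ŷ_i = j]`, majority `v = argmax_j V(j)` (ties toward the
smaller label), `β = Nv/Nseg ∈ (0, 1]`. Decision: *genuine* iff `β ≥ θ`
**and** `v` equals the claimed label. The claimed-match conjunct is a design
choice: β alone measures prediction consistency, not claim correctness, so
an imposter consistently classified as some other enrolled user would
otherwise pass. The pure β-threshold rule is available via
`require_claimed_match=False`. θ defaults to 0.5 (no stated value exists);
all curve metrics sweep θ, and the claim-aware score `β·1[v = claimed]`
feeds ROC/DET/AUC.

An attempt is one (user, run)'s test segments. LOPO: per held-out user u,
the pipeline (selection, scaler, classifier) is refitted on the other users'
training runs; genuine trials are each enrolled user's test runs claiming
themselves, imposter trials are u's test runs claiming every enrolled
identity. The held-out user can never be a softmax class, which is exactly
why they are the imposter population.

## Metrics

Macro one-vs-rest accuracy/precision/recall/specificity as unweighted means
of per-class ratios (×100); F1 from the macro precision and recall
(per-class averaging behind a flag); plain fraction-correct is reported
separately as `overall_accuracy` because the macro one-vs-rest "accuracy"
is inflated by true negatives for K > 2. FAR = false accepts / imposter
attempts and FRR = false rejects / genuine attempts by default; a
pooled-attempts mode divides both by all attempts (that form conflates class
balance with error rates, hence not the default). ROC/DET sweep the unique
scores; AUC is trapezoidal (equals the Mann–Whitney pair-count statistic,
tested); EER is linearly interpolated where FAR crosses FRR. The empirical
chance level retrains the network on permuted training labels (default 100
shuffles; tests use 20) against an untouched test set.

## Numerical and degenerate-input choices

* Majority and argmax ties always break toward the smaller index.
* MI of a feature with < 2 distinct values is 0 (with a warning); `0·log 0`
  terms are dropped; estimates are clipped at 0.
* Scaler uses ddof = 1; constant columns are centred only.
* Filter edge effects are handled by odd-reflection padding capped at the
  signal length; tests evaluate the central half of short signals.
* Non-finite data is rejected at Recording construction and at file read,
  with channel/sample location in the error.

## Known limitations

* The synthetic world has uncorrelated channels and stationary runs; LOPO
  FAR at high separation stays nonzero by construction (an imposter's
  segments are always absorbed by *some* enrolled class; only the
  claimed-match conjunct and θ limit acceptance).
* The binned MI estimator is biased upward for small n; Q and the bin count
  are fixed, not tuned.
* The gradient-boosting baseline approximates XGBoost's algorithm family,
  not its exact implementation.
* Headline accuracies reported on the original clinical dataset are not
  reproducible here and are not targets of this package's tests.
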